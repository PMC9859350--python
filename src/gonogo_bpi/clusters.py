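"""Connected-component tables and mask-overlap (conjunction) reports.

Cluster tables report size in mm^3 (voxel count times the voxel volume,
so on a 3-mm grid every size is a multiple of 27 mm^3), the unweighted
centroid of member-voxel mm coordinates, and up to eight local maxima of
|values| at least 8 mm apart. Anatomical naming is left to the user via
the free-text ``label`` column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .bayes import DecisionMap, LABEL_NULL
from .freq import connectivity_structure
from .volumes import MaskVolume, affines_close, voxel_volume_mm3

MAX_PEAKS = 8
PEAK_SEPARATION_MM = 8.0

TSV_COLUMNS = [
    "cluster_id", "size_mm3", "centroid_x", "centroid_y", "centroid_z",
    "peak_value", "peak_x", "peak_y", "peak_z", "label",
]

__all__ = ["ClusterTable", "extract_clusters", "overlap_masks", "conjunction_report"]


@dataclass
class ClusterTable:
    """One row per cluster (``df``) plus a long table of local maxima."""

    df: pd.DataFrame
    peaks: pd.DataFrame
    label_volume: np.ndarray
    affine: np.ndarray

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.df[TSV_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="n/a",
                                    float_format="%.6g")
        return path


def _local_maxima(
    values: np.ndarray,
    members: np.ndarray,
    affine: np.ndarray,
) -> list[tuple[float, np.ndarray]]:
    """Greedy SPM-like peak list: 26-neighbourhood maxima of |values|
    within the cluster, at least PEAK_SEPARATION_MM apart, largest first."""
    lo = members.min(axis=0)
    hi = members.max(axis=0) + 1
    box = np.full(tuple(hi - lo), -np.inf)
    local = members - lo
    absvals = np.abs(values[tuple(members.T)])
    box[tuple(local.T)] = absvals
    dilated = ndimage.maximum_filter(box, size=3, mode="constant", cval=-np.inf)
    is_peak = (box >= dilated) & np.isfinite(box)
    cand = np.argwhere(is_peak)
    cand_vals = box[tuple(cand.T)]
    order = np.argsort(cand_vals)[::-1]

    kept: list[tuple[float, np.ndarray]] = []
    mm = lambda v: (affine @ np.append(v + lo, 1.0))[:3]
    for i in order:
        pos_mm = mm(cand[i])
        if all(np.linalg.norm(pos_mm - p) >= PEAK_SEPARATION_MM for _, p in kept):
            signed = values[tuple((cand[i] + lo))]
            kept.append((float(signed), pos_mm))
        if len(kept) >= MAX_PEAKS:
            break
    return kept


def extract_clusters(
    binary: MaskVolume,
    values: np.ndarray | None = None,
    connectivity: int = 18,
) -> ClusterTable:
    """Connected components of a binary volume, tabulated.

    ``values`` (optional, same grid) provides the statistic whose local
    maxima are reported; without it, peak columns are NaN. An empty
    input yields an empty table, not an error. Clusters are sorted by
    size descending.
    """
    data = binary.data
    if values is not None and np.asarray(values).shape != data.shape:
        raise ValueError("values grid differs from the binary grid")
    structure = connectivity_structure(connectivity)
    labeled, n = ndimage.label(data, structure=structure)
    affine = binary.affine
    vox_mm3 = voxel_volume_mm3(affine)

    rows, peak_rows = [], []
    if n:
        sizes = np.bincount(labeled.ravel())[1:]
        order = np.argsort(sizes)[::-1]
        for rank, ci in enumerate(order, start=1):
            members = np.argwhere(labeled == ci + 1)
            hom = np.c_[members, np.ones(len(members))]
            centroid = (hom @ affine.T)[:, :3].mean(axis=0)
            row = {
                "cluster_id": rank,
                "n_voxels": int(sizes[ci]),
                "size_mm3": float(sizes[ci] * vox_mm3),
                "centroid_x": centroid[0],
                "centroid_y": centroid[1],
                "centroid_z": centroid[2],
                "peak_value": np.nan,
                "peak_x": np.nan,
                "peak_y": np.nan,
                "peak_z": np.nan,
                "label": "",
            }
            if values is not None:
                peaks = _local_maxima(np.asarray(values, float), members, affine)
                if peaks:
                    row.update(
                        peak_value=peaks[0][0],
                        peak_x=peaks[0][1][0], peak_y=peaks[0][1][1], peak_z=peaks[0][1][2],
                    )
                for val, pos in peaks:
                    peak_rows.append(
                        {"cluster_id": rank, "value": val, "x": pos[0], "y": pos[1], "z": pos[2]}
                    )
            rows.append(row)
    df = pd.DataFrame(rows, columns=[
        "cluster_id", "n_voxels", "size_mm3", "centroid_x", "centroid_y", "centroid_z",
        "peak_value", "peak_x", "peak_y", "peak_z", "label",
    ])
    peaks_df = pd.DataFrame(peak_rows, columns=["cluster_id", "value", "x", "y", "z"])
    return ClusterTable(df=df, peaks=peaks_df, label_volume=labeled, affine=affine)


def overlap_masks(a: MaskVolume, b: MaskVolume) -> MaskVolume:
    """Voxelwise logical AND of two masks on the same grid.

    Refuses silently mismatched affines (beyond 1e-4): resample one mask
    onto the other's grid first. Disjoint masks yield an empty overlap.
    """
    if a.data.shape != b.data.shape:
        raise ValueError("masks are on different grids; resample before overlapping")
    if not affines_close(a.affine, b.affine):
        raise ValueError(
            "mask affines differ beyond 1e-4; resample one mask onto the other's grid"
        )
    return MaskVolume(data=a.data & b.data, affine=a.affine)


def conjunction_report(
    decision: DecisionMap,
    external_mask: MaskVolume,
    connectivity: int = 18,
) -> ClusterTable:
    """Clusters of practically-null voxels inside an external mask.

    The overlap of the decision map's null label with the externally
    supplied (e.g. meta-analysis) mask is clustered and tabulated with
    the null-hypothesis log posterior odds as peak values — the
    conjunction that localizes non-selective response inhibition.
    """
    if external_mask.data.shape != decision.labels.shape:
        raise ValueError("external mask grid differs from the decision grid")
    null_mask = MaskVolume(data=decision.labels == LABEL_NULL, affine=decision.affine)
    both = overlap_masks(null_mask, external_mask)
    return extract_clusters(both, values=decision.lpo_null, connectivity=connectivity)
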