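"""First-level GLM: design matrices, OLS fits, and contrast maps.

Task regressors are stick functions at *target* (second-stimulus) onsets
convolved with the canonical double-gamma HRF and sampled at scan times;
cue onsets are deliberately not modelled and null events contribute
nothing. Six head-motion columns may be appended, followed by a cosine
high-pass drift basis and a trailing intercept. Estimation is ordinary
least squares per voxel; group analyses consume only the contrast point
estimates (an AR(1) prewhitening hook can be added around
:func:`fit_glm` without changing its interface).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .events import NULL_EVENT, TASK_TRIAL_TYPES, validate_events
from .synthetic import MOTION_COLUMNS, regressor_timecourse
from .volumes import BoldRun, ContrastMap, MaskVolume

#: canonical contrast weight sets
CONTRASTS: dict[str, dict[str, float]] = {
    "nogo_minus_go": {"nogo": 1.0, "go": -1.0},
    "go_plus_nogo": {"go": 1.0, "nogo": 1.0},
}

__all__ = ["DesignMatrix", "GLMResult", "CONTRASTS", "build_design_matrix", "fit_glm", "contrast_map"]


@dataclass
class DesignMatrix:
    """Scans-by-regressors design with named columns and the TR."""

    matrix: np.ndarray
    names: list[str]
    tr: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix shape inconsistent with regressor names")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate regressor names: {dupes}")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def _cosine_drift(n_scans: int, tr: float, hp_cutoff: float) -> np.ndarray:
    """Unit-norm DCT-II basis up to the high-pass cutoff (excludes the
    constant term; mutually orthogonal and orthogonal to the intercept)."""
    if not hp_cutoff or not np.isfinite(hp_cutoff):
        return np.empty((n_scans, 0))
    order = int(np.floor(2.0 * n_scans * tr / hp_cutoff))
    order = min(order, n_scans - 1)
    if order < 1:
        return np.empty((n_scans, 0))
    i = np.arange(n_scans)
    cols = [np.cos(np.pi * k * (2 * i + 1) / (2 * n_scans)) for k in range(1, order + 1)]
    basis = np.stack(cols, axis=1)
    return basis / np.linalg.norm(basis, axis=0)


def build_design_matrix(
    events: pd.DataFrame,
    n_scans: int,
    tr: float,
    motion: pd.DataFrame | None = None,
    hp_cutoff: float | None = 128.0,
) -> DesignMatrix:
    """Assemble the first-level design from target onsets.

    One column per task trial type present in the events (canonical
    order go, nogo, ignore_pa, ignore_pp), then six motion columns when
    ``motion`` is supplied, then the cosine drift basis for periods
    longer than ``hp_cutoff`` seconds, then the intercept.
    """
    validate_events(events)
    task = events[events["trial_type"] != NULL_EVENT]
    run_end = n_scans * tr
    late = task["onset"].to_numpy(float) >= run_end
    if late.any():
        raise ValueError(
            f"{late.sum()} event(s) at/after the run end ({run_end:.1f} s); "
            "extend n_scans or trim the schedule"
        )

    columns: list[np.ndarray] = []
    names: list[str] = []
    for ttype in TASK_TRIAL_TYPES:
        onsets = task.loc[task["trial_type"] == ttype, "onset"].to_numpy(float)
        if onsets.size == 0:
            continue
        columns.append(regressor_timecourse(onsets, n_scans, tr))
        names.append(ttype)
    if not names:
        raise ValueError("no task trials in the event table")

    if motion is not None:
        m = motion[MOTION_COLUMNS] if set(MOTION_COLUMNS) <= set(motion.columns) else motion
        m = np.asarray(m, dtype=float)
        if m.shape != (n_scans, 6):
            raise ValueError(f"motion table must be {n_scans} scans x 6 columns")
        columns.extend(m.T)
        names.extend(MOTION_COLUMNS)

    drift = _cosine_drift(n_scans, tr, hp_cutoff)
    columns.extend(drift.T)
    names.extend(f"drift_{k}" for k in range(1, drift.shape[1] + 1))

    columns.append(np.ones(n_scans))
    names.append("intercept")
    return DesignMatrix(matrix=np.stack(columns, axis=1), names=names, tr=tr)


@dataclass
class GLMResult:
    """Per-voxel OLS estimates: ``betas[k, x, y, z]`` aligned with ``names``."""

    betas: np.ndarray
    resid_var: np.ndarray
    names: list[str]
    df: int
    affine: np.ndarray
    mask: MaskVolume

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.names.index(name)]


def _check_full_rank(design: DesignMatrix) -> None:
    x = design.matrix
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # pivoted QR: trailing pivots index the (nearly) dependent columns
        _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = sorted(design.names[piv[i]] for i in range(len(diag)) if diag[i] <= tol)
        raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")


def fit_glm(run: BoldRun, design: DesignMatrix, mask: MaskVolume) -> GLMResult:
    """Ordinary least squares per in-mask voxel.

    Residual variance uses ``n - rank`` degrees of freedom. Voxels
    outside the mask are NaN in every output volume.
    """
    if design.n_scans != run.n_scans:
        raise ValueError(
            f"design has {design.n_scans} rows but the run has {run.n_scans} scans"
        )
    if mask.data.shape != run.shape:
        raise ValueError("mask grid differs from the run grid")
    _check_full_rank(design)

    x = design.matrix
    n, k = x.shape
    flat = run.data.reshape(-1, n)
    idx = np.flatnonzero(mask.data.ravel())
    y = flat[idx].T  # scans x voxels

    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    df = n - k
    rvar = (resid**2).sum(axis=0) / df

    betas = np.full((k,) + run.shape, np.nan)
    betas.reshape(k, -1)[:, idx] = beta
    resid_var = np.full(run.shape, np.nan)
    resid_var.ravel()[idx] = rvar
    return GLMResult(
        betas=betas, resid_var=resid_var, names=list(design.names), df=df,
        affine=run.affine, mask=mask,
    )


def contrast_map(
    result: GLMResult,
    weights: dict[str, float] | str,
    subject_id: str = "",
) -> ContrastMap:
    """Linear combination of task betas per voxel.

    ``weights`` is either a name registered in :data:`CONTRASTS`
    (``nogo_minus_go``, ``go_plus_nogo``) or a mapping from task
    regressor names to weights. Weights on non-task regressors are
    rejected.
    """
    if isinstance(weights, str):
        name = weights
        if name not in CONTRASTS:
            raise ValueError(f"unknown contrast {name!r}; registered: {sorted(CONTRASTS)}")
        weights = CONTRASTS[name]
    else:
        name = "+".join(f"{w:+g}*{r}" for r, w in sorted(weights.items()))
    unknown = set(weights) - set(result.names)
    if unknown:
        raise ValueError(f"unknown regressor name(s) {sorted(unknown)}")
    non_task = {r for r, w in weights.items() if r not in TASK_TRIAL_TYPES and w != 0}
    if non_task:
        raise ValueError(f"contrast weights on non-task regressors: {sorted(non_task)}")
    data = np.zeros(result.betas.shape[1:])
    for reg, w in weights.items():
        data = data + w * result.beta(reg)
    return ContrastMap(data=data, affine=result.affine, contrast_name=name, subject_id=subject_id)
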