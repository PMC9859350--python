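"""Conjunction of practical-equivalence voxels with an external mask.

Re-runs the Bayesian classification of script 03 and intersects its
practically-null (NoGo = Go) voxels with a synthetic stand-in for an
externally supplied response-inhibition meta-analysis mask (spheres
placed in null territory). The resulting cluster table — size mm^3,
centroid mm, LPO peaks — is the pipeline's analogue of a
non-selective-response-inhibition node table. Output under
results/overlap/.
"""

import argparse
from pathlib import Path

from gonogo_bpi.bayes import fit_global_shrinkage, rope_classify
from gonogo_bpi.clusters import conjunction_report
from gonogo_bpi.synthetic import Region, simulate_group_contrast_maps
from gonogo_bpi.volumes import MaskVolume, save_volume

import importlib.util

_spec = importlib.util.spec_from_file_location(
    "bayes_rope", Path(__file__).with_name("03_bayes_rope.py"))
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
reference_scene = _mod.reference_scene

RESULTS = Path(__file__).resolve().parent.parent / "results" / "overlap"

# synthetic stand-in for the external meta-analysis mask: seven spheres
# in territory the scene leaves null (mirrors the seven-node structure
# of the non-selective inhibition system)
META_SPHERES = [
    Region((8, 10, 28), 3, 1.0),
    Region((32, 10, 28), 3, 1.0),
    Region((8, 38, 28), 3, 1.0),
    Region((32, 38, 28), 3, 1.0),
    Region((20, 38, 10), 3, 1.0),
    Region((10, 22, 8), 3, 1.0),
    Region((30, 22, 8), 3, 1.0),
]


def main(seed: int = 1) -> None:
    scene = reference_scene()
    gs = simulate_group_contrast_maps(scene, seed=seed)
    decision = rope_classify(fit_global_shrinkage(gs.hc))

    meta = scene.field(META_SPHERES) > 0
    meta_mask = MaskVolume(data=meta & gs.mask.data, affine=scene.affine)
    save_volume(meta_mask.data, meta_mask.affine, RESULTS / "synthetic_meta_mask.nii.gz")

    table = conjunction_report(decision, meta_mask, connectivity=18)
    table.to_tsv(RESULTS / "conjunction_table.tsv")
    table.peaks.to_csv(RESULTS / "conjunction_peaks.tsv", sep="\t", index=False)

    print(f"{len(table)} overlap cluster(s) between 'NoGo = Go' voxels and the "
          "external mask:")
    cols = ["cluster_id", "n_voxels", "size_mm3", "centroid_x", "centroid_y", "centroid_z"]
    print(table.df[cols].round(1).to_string(index=False))


if __name__ == "__main__":
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    main(**vars(parser.parse_args()))
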