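"""First-level design matrices, OLS estimation, and contrast maps."""

import numpy as np
import pandas as pd
import pytest

from gonogo_bpi.firstlevel import (
    CONTRASTS,
    DesignMatrix,
    build_design_matrix,
    contrast_map,
    fit_glm,
)
from gonogo_bpi.hrf import double_gamma_hrf
from gonogo_bpi.synthetic import (
    NoiseSpec,
    SceneSpec,
    generate_event_schedule,
    simulate_bold_run,
)
from gonogo_bpi.volumes import BoldRun, MaskVolume, mni_like_affine


def _events(rows):
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "cue_onset",
                                       "response_time"])


@pytest.fixture(scope="module")
def medium_schedule():
    return generate_event_schedule(seed=4, n_per_type=20, n_null=5)


def _tiny_run(data_2d, shape=(1, 1, 1), tr=2.0):
    """Wrap a (n_scans,) or (voxels, n_scans) array as a BoldRun + mask."""
    arr = np.atleast_2d(np.asarray(data_2d, dtype=float))
    n_scans = arr.shape[1]
    vol = np.zeros(shape + (n_scans,))
    vol.reshape(-1, n_scans)[: arr.shape[0]] = arr
    affine = mni_like_affine(shape)
    return (
        BoldRun(data=vol, affine=affine, tr=tr),
        MaskVolume(np.ones(shape, bool), affine),
    )


def test_single_condition_design_columns():
    ev = _events([(4.1, 0.1, "go", 3.0, np.nan), (9.1, 0.1, "go", 8.0, np.nan)])
    design = build_design_matrix(ev, n_scans=100, tr=2.0)
    assert design.names[0] == "go"
    assert design.names[-1] == "intercept"
    assert all(n.startswith("drift_") for n in design.names[1:-1])


def test_full_design_has_all_blocks(default_schedule):
    """400-trial schedule + motion: 4 task + 6 motion + drift + intercept."""
    n_scans = int(np.ceil(default_schedule.duration / 2.0)) + 8
    motion = pd.DataFrame(np.zeros((n_scans, 6)), columns=[f"motion{i}" for i in range(1, 7)])
    design = build_design_matrix(default_schedule.events, n_scans, 2.0, motion=motion)
    task = [n for n in design.names if n in ("go", "nogo", "ignore_pa", "ignore_pp")]
    drift = [n for n in design.names if n.startswith("drift_")]
    assert len(task) == 4
    assert sum(n.startswith("motion") for n in design.names) == 6
    assert len(drift) == int(np.floor(2 * n_scans * 2.0 / 128.0))
    assert design.names[-1] == "intercept"


def test_drift_orthogonal_to_intercept(medium_schedule):
    design = build_design_matrix(medium_schedule.events, 250, 2.0)
    drift = design.matrix[:, [i for i, n in enumerate(design.names) if n.startswith("drift_")]]
    gram = drift.T @ drift
    assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)
    assert np.allclose(drift.sum(axis=0), 0.0, atol=1e-9)


def test_event_at_origin_gives_sampled_hrf():
    """A single Go event at t=0 makes the go column the HRF sampled at
    scan times — a direct convolution oracle."""
    ev = _events([(0.0, 0.1, "go", -1.1, np.nan)])
    design = build_design_matrix(ev, n_scans=30, tr=2.0, hp_cutoff=None)
    expected = np.zeros(30)
    kern = double_gamma_hrf(2.0)
    expected[: len(kern)] = kern
    assert np.allclose(design.column("go"), expected, atol=1e-12)


def test_events_after_run_end_rejected(small_schedule):
    with pytest.raises(ValueError, match="run end"):
        build_design_matrix(small_schedule.events, n_scans=4, tr=2.0)


def test_duplicate_names_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        DesignMatrix(matrix=np.ones((5, 2)), names=["a", "a"], tr=2.0)


def test_noiseless_recovery_is_exact(medium_schedule):
    """y = X @ beta with no noise recovers beta to 1e-8."""
    design = build_design_matrix(medium_schedule.events, 250, 2.0)
    rng = np.random.default_rng(0)
    beta = rng.normal(size=len(design.names))
    run, mask = _tiny_run(design.matrix @ beta)
    result = fit_glm(run, design, mask)
    got = np.array([result.beta(n)[0, 0, 0] for n in design.names])
    assert np.allclose(got, beta, atol=1e-8)


def test_projection_identity():
    """Orthonormal two-column design with y = col1 yields beta = (1, 0)."""
    q, _ = np.linalg.qr(np.random.default_rng(1).normal(size=(20, 2)))
    design = DesignMatrix(matrix=q, names=["a", "b"], tr=2.0)
    run, mask = _tiny_run(q[:, 0])
    result = fit_glm(run, design, mask)
    assert result.beta("a")[0, 0, 0] == pytest.approx(1.0, abs=1e-12)
    assert result.beta("b")[0, 0, 0] == pytest.approx(0.0, abs=1e-12)


def test_residual_variance_calibrated(medium_schedule):
    """On pure-noise runs the mean residual variance matches the
    generator sigma^2 within 5% (10 seeds)."""
    design = build_design_matrix(medium_schedule.events, 250, 2.0)
    sigma = 0.7
    vars_ = []
    for seed in range(10):
        noise = np.random.default_rng(seed).normal(0, sigma, size=(50, 250))
        run, mask = _tiny_run(noise, shape=(50, 1, 1))
        result = fit_glm(run, design, mask)
        vars_.append(np.nanmean(result.resid_var))
    assert np.mean(vars_) == pytest.approx(sigma**2, rel=0.05)


def test_glm_unbiased_across_seeds():
    """Mean estimation bias over 50 seeded simulations stays below 0.02
    at noise SD 0.5."""
    sched = generate_event_schedule(seed=5, n_per_type=12, n_null=4)
    scene = SceneSpec(grid_shape=(3, 3, 3), smooth_fwhm=0.0, brain_fraction=4.0,
                      n_subjects_hc=2, n_subjects_ocd=2)
    design = None
    biases = []
    for seed in range(50):
        run, _ = simulate_bold_run(
            sched.events, {"go": 1.0, "nogo": 1.0}, seed=seed, scene=scene,
            noise=NoiseSpec(sigma=0.5, ar1_rho=0.2),
        )
        if design is None:
            design = build_design_matrix(sched.events, run.n_scans, run.tr)
            mask = scene.brain_mask()
        result = fit_glm(run, design, mask)
        biases.append(np.nanmean(result.beta("go")) - 1.0)
    assert abs(np.mean(biases)) < 0.02


def test_motion_regressors_remove_motion_leakage():
    """With heavy motion leakage, including the six motion columns keeps
    the contrast unbiased (<2%) while omitting them inflates the error."""
    sched = generate_event_schedule(seed=6, n_per_type=12, n_null=4)
    scene = SceneSpec(grid_shape=(4, 4, 4), smooth_fwhm=0.0, brain_fraction=4.0,
                      n_subjects_hc=2, n_subjects_ocd=2)
    err_with, err_without = [], []
    for seed in range(12):
        run, motion = simulate_bold_run(
            sched.events, {"go": 1.0}, seed=seed, scene=scene,
            noise=NoiseSpec(sigma=0.05, ar1_rho=0.0, motion_leak=1.0),
        )
        mask = scene.brain_mask()
        d_with = build_design_matrix(sched.events, run.n_scans, run.tr, motion=motion)
        d_without = build_design_matrix(sched.events, run.n_scans, run.tr)
        err_with.append(np.nanmean(fit_glm(run, d_with, mask).beta("go")) - 1.0)
        err_without.append(np.nanmean(fit_glm(run, d_without, mask).beta("go")) - 1.0)
    assert abs(np.mean(err_with)) < 0.02
    assert np.mean(np.abs(err_without)) > 2 * np.mean(np.abs(err_with))


def test_rank_deficient_design_names_columns():
    x = np.random.default_rng(2).normal(size=(30, 2))
    mat = np.c_[x, x[:, 0] + x[:, 1]]
    design = DesignMatrix(matrix=mat, names=["a", "b", "c"], tr=2.0)
    run, mask = _tiny_run(np.zeros(30))
    with pytest.raises(ValueError, match="rank deficient"):
        fit_glm(run, design, mask)


def test_design_run_length_mismatch_rejected():
    design = DesignMatrix(matrix=np.ones((10, 1)), names=["go"], tr=2.0)
    run, mask = _tiny_run(np.zeros(12))
    with pytest.raises(ValueError, match="scans"):
        fit_glm(run, design, mask)


def test_contrast_selection_and_null_pattern():
    """Weights {go: 1} select beta_go; the NoGo-Go contrast of equal
    betas is identically zero — the practical-equivalence pattern."""
    sched = generate_event_schedule(seed=9, n_per_type=5, n_null=0)
    design = build_design_matrix(sched.events, 120, 2.0)
    beta = np.zeros(len(design.names))
    beta[design.names.index("go")] = 2.0
    beta[design.names.index("nogo")] = 2.0
    run, mask = _tiny_run(design.matrix @ beta)
    result = fit_glm(run, design, mask)
    sel = contrast_map(result, {"go": 1.0})
    assert sel.data[0, 0, 0] == pytest.approx(2.0, abs=1e-9)
    null = contrast_map(result, "nogo_minus_go")
    assert null.data[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
    both = contrast_map(result, "go_plus_nogo")
    assert both.data[0, 0, 0] == pytest.approx(4.0, abs=1e-9)


def test_contrast_rejects_bad_weights():
    sched = generate_event_schedule(seed=9, n_per_type=2, n_null=0)
    design = build_design_matrix(sched.events, 60, 2.0)
    run, mask = _tiny_run(np.zeros(60))
    result = fit_glm(run, design, mask)
    with pytest.raises(ValueError, match="unknown regressor"):
        contrast_map(result, {"stop": 1.0})
    with pytest.raises(ValueError, match="non-task"):
        contrast_map(result, {"intercept": 1.0})
    with pytest.raises(ValueError, match="unknown contrast"):
        contrast_map(result, "go_versus_baseline")
    assert set(CONTRASTS) == {"nogo_minus_go", "go_plus_nogo"}
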