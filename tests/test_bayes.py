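"""Global shrinkage prior, ROPE classification, and LPO conversions."""

import numpy as np
import pytest

from gonogo_bpi.bayes import (
    LABEL_LOW_CONFIDENCE,
    LABEL_NEGATIVE,
    LABEL_NULL,
    LABEL_POSITIVE,
    DecisionConfig,
    DecisionMap,
    PosteriorMap,
    em_prior_variance,
    equivalence_report,
    fit_global_shrinkage,
    lpo_from_probability,
    marginal_log_likelihood,
    probability_from_lpo,
    rope_classify,
)
from gonogo_bpi.synthetic import Region, SceneSpec, simulate_group_contrast_maps
from gonogo_bpi.volumes import MaskVolume, mni_like_affine


def grid_search_lambda(m, se2, lo=1e-10, hi=None, n_coarse=4000, n_fine=4000):
    """Independent oracle: dense grid maximization of the marginal
    likelihood, refined once around the coarse optimum."""
    m = np.asarray(m, float)
    se2 = np.asarray(se2, float)
    if hi is None:
        hi = max(float((m**2).max()), 1.0) * 10
    grid = np.linspace(lo, hi, n_coarse)
    ll = [marginal_log_likelihood(l, m, se2) for l in grid]
    best = grid[int(np.argmax(ll))]
    step = (hi - lo) / (n_coarse - 1)
    fine = np.linspace(max(lo, best - step), best + step, n_fine)
    ll = [marginal_log_likelihood(l, m, se2) for l in fine]
    return float(fine[int(np.argmax(ll))])


# frozen 10-voxel instance; expected value computed with grid_search_lambda
TOY_M = np.array([0.93, -1.41, 0.22, 2.05, -0.11, 0.67, -0.85, 1.12, 0.04, -1.96])
TOY_SE2 = np.array([0.30, 0.55, 0.21, 0.40, 0.18, 0.62, 0.35, 0.27, 0.44, 0.50])


def test_em_matches_grid_oracle_on_frozen_toy():
    lam_em = em_prior_variance(TOY_M, TOY_SE2)
    lam_grid = grid_search_lambda(TOY_M, TOY_SE2)
    assert lam_em == pytest.approx(lam_grid, abs=1e-4)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_em_matches_grid_oracle_random_instances(seed):
    """EM and a dense-grid maximizer of the marginal likelihood agree to
    1e-4 on instances of up to 100 voxels."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 101))
    lam_true = rng.uniform(0.3, 2.0)
    se2 = rng.uniform(0.1, 1.0, size=n)
    m = rng.normal(0, np.sqrt(lam_true + se2))
    assert em_prior_variance(m, se2) == pytest.approx(grid_search_lambda(m, se2), abs=1e-4)


def test_em_input_validation():
    with pytest.raises(ValueError):
        em_prior_variance(np.array([1.0]), np.array([0.0]))
    with pytest.raises(ValueError):
        em_prior_variance(np.array([]), np.array([]))
    with pytest.raises(ValueError):
        em_prior_variance(np.array([1.0, 2.0]), np.array([1.0]))


def test_posterior_symmetry_and_shrinkage_monotonicity():
    """A zero observation has zero posterior mean for any prior variance,
    and increasing the sampling variance shrinks the posterior mean
    toward zero (the sign of d|post_mean|/d s^2 is negative)."""
    lam = 0.8
    se2 = np.linspace(0.1, 5.0, 40)
    w = 1.0 / (1.0 / lam + 1.0 / se2)
    mu = w * 1.0 / se2  # m = 1
    assert np.all(np.diff(np.abs(mu)) < 0)
    assert np.all(w * 0.0 / se2 == 0.0)  # m = 0


def _noise_sample(factory, n=34, shape=(6, 6, 6), sd=0.2, seed=0, loc=0.0):
    rng = np.random.default_rng(seed)
    return factory(loc + rng.normal(0, sd, size=(n,) + shape))


def test_fit_global_shrinkage_invariants(group_sample_factory):
    """Shrinkage never inflates uncertainty beyond the classical standard
    error and never moves a posterior mean past the sample mean."""
    sample = _noise_sample(group_sample_factory, sd=1.0, seed=3)
    post = fit_global_shrinkage(sample)
    data = sample.stack()
    m = data.mean(axis=0)
    classical_se = data.std(axis=0, ddof=1) / np.sqrt(sample.n_subjects)
    assert np.all(post.post_sd <= classical_se + 1e-12)
    assert np.all(np.abs(post.post_mean) <= np.abs(m) + 1e-12)
    assert post.prior_var > 0


def test_fit_rejects_degenerate_inputs(group_sample_factory):
    with pytest.raises(ValueError, match="at least 100 in-mask"):
        fit_global_shrinkage(_noise_sample(group_sample_factory, shape=(3, 3, 3)))
    const = group_sample_factory(np.ones((5, 6, 6, 6)))
    with pytest.raises(ValueError, match="zero between-subject variance"):
        fit_global_shrinkage(const)


def test_zero_variance_voxel_flagged_low_confidence(group_sample_factory):
    arr = np.random.default_rng(0).normal(0, 1, size=(10, 6, 6, 6))
    arr[:, 0, 0, 0] = 5.0  # constant across subjects
    sample = group_sample_factory(arr)
    post = fit_global_shrinkage(sample)
    assert post.degenerate[0, 0, 0]
    decision = rope_classify(post)
    assert decision.labels[0, 0, 0] == LABEL_LOW_CONFIDENCE
    assert np.isnan(decision.lpo_null[0, 0, 0])


def _posterior(mu, sd, prior_var=1.0):
    """Wrap scalar/array posterior moments as a 3D PosteriorMap."""
    mu = np.atleast_1d(np.asarray(mu, float))
    shape = mu.shape + (1, 1) if mu.ndim == 1 else mu.shape
    mu = mu.reshape(shape)
    sd = np.asarray(sd, float)
    sd = np.broadcast_to(sd.reshape(sd.shape + (1,) * (mu.ndim - sd.ndim)), shape).copy()
    affine = mni_like_affine(shape)
    return PosteriorMap(
        post_mean=mu, post_sd=sd, prior_var=prior_var, n_subjects=10,
        mask=MaskVolume(np.ones(shape, bool), affine), affine=affine,
    )


def test_rope_classification_canonical_cases():
    """Posterior concentrated inside the ROPE is null; far above gamma is
    positive; centred on gamma with wide spread is low-confidence with
    P(theta > gamma) = 0.5 and P(ROPE) = Phi(0) - Phi(-2) ~= 0.477."""
    gamma = 0.7
    cfg = DecisionConfig(gamma_rule="absolute", gamma=gamma)
    post = _posterior([0.0, 5 * gamma, gamma, -5 * gamma], [gamma / 10, gamma / 10, gamma, gamma / 10])
    decision = rope_classify(post, cfg)
    labels = decision.labels[:, 0, 0]
    assert labels[0] == LABEL_NULL
    assert labels[1] == LABEL_POSITIVE
    assert labels[2] == LABEL_LOW_CONFIDENCE
    assert labels[3] == LABEL_NEGATIVE
    p_pos = probability_from_lpo(decision.lpo_pos[2, 0, 0])
    p_rope = probability_from_lpo(decision.lpo_null[2, 0, 0])
    assert p_pos == pytest.approx(0.5, abs=1e-12)
    assert p_rope == pytest.approx(0.47725, abs=1e-4)


def test_decision_exclusivity_and_probability_sum():
    """Over 1e5 random posteriors the three hypothesis probabilities sum
    to one and at most one acceptance criterion fires at P_thr > 0.5."""
    rng = np.random.default_rng(42)
    shape = (50, 50, 40)
    mu = rng.normal(0, 3, size=shape)
    sd = rng.uniform(0.05, 3, size=shape)
    post = _posterior(mu, sd)
    cfg = DecisionConfig(gamma_rule="absolute", gamma=1.0)
    decision = rope_classify(post, cfg)
    p_pos = probability_from_lpo(decision.lpo_pos)
    p_neg = probability_from_lpo(decision.lpo_neg)
    p_rope = probability_from_lpo(decision.lpo_null)
    assert np.nanmax(np.abs(p_pos + p_neg + (1 - p_pos - p_neg) - 1)) < 1e-10
    fired = (p_pos > 0.95).astype(int) + (p_neg > 0.95).astype(int) + (p_rope >= 0.95).astype(int)
    assert fired.max() <= 1
    # labels match the criteria
    assert np.array_equal(decision.labels == LABEL_POSITIVE, p_pos > 0.95)
    assert np.array_equal(decision.labels == LABEL_NULL, p_rope >= 0.95)


def test_gamma_validation():
    with pytest.raises(ValueError):
        DecisionConfig(gamma_rule="absolute", gamma=-1.0)
    with pytest.raises(ValueError):
        DecisionConfig(p_thr=0.4)
    post = _posterior([0.0], [1.0], prior_var=0.0)
    with pytest.raises(ValueError, match="non-positive"):
        rope_classify(post, DecisionConfig())


def test_lpo_conversions():
    assert lpo_from_probability(0.5) == 0.0
    assert lpo_from_probability(0.95) == pytest.approx(2.944, abs=1e-3)
    assert round(lpo_from_probability(0.95)) == 3
    assert lpo_from_probability(0.9990) == pytest.approx(6.9068, abs=1e-4)
    assert probability_from_lpo(lpo_from_probability(0.73)) == pytest.approx(0.73)
    for bad in (0.0, 1.0, -0.2, 1.3):
        with pytest.raises(ValueError):
            lpo_from_probability(bad)


def test_null_scene_calibration(group_sample_factory):
    """Zero-mean white-noise maps: the prior variance collapses and, with
    gamma at a plausible effect size much larger than the noise, nearly
    every voxel is declared practically null."""
    sample = _noise_sample(group_sample_factory, n=34, sd=0.2, seed=11)
    post = fit_global_shrinkage(sample)
    assert post.prior_var < 0.05
    decision = rope_classify(post, DecisionConfig(gamma_rule="absolute", gamma=1.0))
    report = equivalence_report(decision)
    null_frac = report.loc[report["label"] == "null", "fraction"].iloc[0]
    assert null_frac >= 0.95


def test_equivalence_report_fractions():
    shape = (2, 2, 1)
    affine = mni_like_affine(shape)
    labels = np.array([LABEL_POSITIVE, LABEL_NEGATIVE, LABEL_NULL,
                       LABEL_LOW_CONFIDENCE]).reshape(shape).astype(np.uint8)
    mask = MaskVolume(np.ones(shape, bool), affine)
    decision = DecisionMap(
        labels=labels, lpo_pos=np.zeros(shape), lpo_neg=np.zeros(shape),
        lpo_null=np.zeros(shape), gamma=1.0, p_thr=0.95, mask=mask, affine=affine,
    )
    report = equivalence_report(decision)
    assert np.allclose(report["fraction"], 0.25)
    assert np.allclose(report["volume_mm3"], 27.0)
    with pytest.raises(ValueError, match="empty"):
        equivalence_report(decision, MaskVolume(np.zeros(shape, bool), affine))


def test_low_confidence_shrinks_with_sample_size():
    """At fixed truth the low-confidence fraction decreases as the group
    grows (n = 8, 16, 34, 64): more subjects sharpen every posterior."""
    fracs = []
    for n in (8, 16, 34, 64):
        scene = SceneSpec(
            grid_shape=(16, 16, 16), smooth_fwhm=4.0, between_subject_sd=1.0,
            n_subjects_hc=n, n_subjects_ocd=2, brain_fraction=2.0,
            effect_regions=[Region((5, 8, 8), 3, 2.0), Region((11, 8, 8), 3, -2.0)],
        )
        gs = simulate_group_contrast_maps(scene, seed=99)
        decision = rope_classify(fit_global_shrinkage(gs.hc))
        report = equivalence_report(decision)
        fracs.append(report.loc[report["label"] == "low_confidence", "fraction"].iloc[0])
    assert all(a >= b for a, b in zip(fracs, fracs[1:]))
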