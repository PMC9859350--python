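"""Second-level Bayesian parameter inference with a global shrinkage prior.

Model. For each in-mask voxel v, the observed group statistic is the
sample mean m_v of the subject contrast values, with sampling variance
s_v^2 / n (s_v^2 the between-subject sample variance). The effect theta_v
carries a zero-mean Gaussian prior shared across the brain,

    m_v | theta_v ~ N(theta_v, s_v^2 / n),    theta_v ~ N(0, lambda),

encoding the prior belief that on average there is no global experimental
effect. The single prior variance lambda is an empirical-Bayes estimate:
expectation-maximization on the marginal likelihood
prod_v N(m_v; 0, lambda + s_v^2/n). The posterior at each voxel is
Gaussian with precision 1/lambda + n/s_v^2.

Decisions. With an effect-size threshold gamma (by default one prior SD,
sqrt(lambda)) and probability threshold P_thr (default 0.95), a voxel is
classified positive when P(theta > gamma | D) > P_thr, negative when
P(theta < -gamma | D) > P_thr, practically null when the posterior mass
inside the ROPE [-gamma, gamma] is at least P_thr, and low-confidence
otherwise. Posterior probabilities are reported as logarithmic posterior
odds, LPO = ln(p / (1 - p)); LPO = 3 corresponds to p ~= 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, log_ndtr, logit

from .volumes import GroupSample, MaskVolume, voxel_volume_mm3

#: integer label codes used in decision volumes
LABEL_OUT_OF_MASK, LABEL_POSITIVE, LABEL_NEGATIVE, LABEL_NULL, LABEL_LOW_CONFIDENCE = range(5)
LABEL_NAMES = {
    LABEL_OUT_OF_MASK: "out_of_mask",
    LABEL_POSITIVE: "positive",
    LABEL_NEGATIVE: "negative",
    LABEL_NULL: "null",
    LABEL_LOW_CONFIDENCE: "low_confidence",
}

MIN_MASK_VOXELS = 100  # hyperparameter estimability floor for full fits
LAMBDA_FLOOR = 1e-12

__all__ = [
    "PosteriorMap",
    "DecisionConfig",
    "DecisionMap",
    "em_prior_variance",
    "marginal_log_likelihood",
    "fit_global_shrinkage",
    "rope_classify",
    "lpo_from_probability",
    "probability_from_lpo",
    "equivalence_report",
    "classification_recovery",
    "LABEL_NAMES",
    "LABEL_POSITIVE",
    "LABEL_NEGATIVE",
    "LABEL_NULL",
    "LABEL_LOW_CONFIDENCE",
    "LABEL_OUT_OF_MASK",
]


@dataclass
class PosteriorMap:
    """Voxelwise Gaussian posterior plus the fitted global prior variance."""

    post_mean: np.ndarray
    post_sd: np.ndarray
    prior_var: float
    n_subjects: int
    mask: MaskVolume
    affine: np.ndarray
    #: in-mask voxels with zero between-subject variance (degenerate input)
    degenerate: np.ndarray | None = None


@dataclass(frozen=True)
class DecisionConfig:
    """ROPE decision rule: effect threshold gamma and probability P_thr.

    ``gamma_rule='one_prior_sd'`` resolves gamma to sqrt(lambda) of the
    fitted prior at classification time; ``'absolute'`` uses ``gamma``
    as given (contrast units).
    """

    p_thr: float = 0.95
    gamma_rule: str = "one_prior_sd"
    gamma: float | None = None

    def __post_init__(self) -> None:
        if not 0.5 < self.p_thr < 1:
            raise ValueError("p_thr must be in (0.5, 1)")
        if self.gamma_rule not in ("one_prior_sd", "absolute"):
            raise ValueError("gamma_rule must be 'one_prior_sd' or 'absolute'")
        if self.gamma_rule == "absolute" and (self.gamma is None or self.gamma <= 0):
            raise ValueError("absolute gamma_rule requires a positive gamma")

    def resolve_gamma(self, prior_var: float) -> float:
        if self.gamma_rule == "absolute":
            return float(self.gamma)
        gamma = float(np.sqrt(prior_var))
        if gamma <= 0:
            raise ValueError("resolved gamma is non-positive (prior variance is zero)")
        return gamma


@dataclass
class DecisionMap:
    """Four-way voxel classification with log-posterior-odds volumes."""

    labels: np.ndarray  # uint8, codes in LABEL_NAMES
    lpo_pos: np.ndarray
    lpo_neg: np.ndarray
    lpo_null: np.ndarray
    gamma: float
    p_thr: float
    mask: MaskVolume
    affine: np.ndarray


def lpo_from_probability(p):
    """Logarithmic posterior odds ln(p / (1 - p)); p must lie in (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probability must lie strictly inside (0, 1)")
    out = logit(p)
    return float(out) if out.ndim == 0 else out


def probability_from_lpo(lpo):
    """Inverse of :func:`lpo_from_probability`."""
    out = expit(np.asarray(lpo, dtype=float))
    return float(out) if out.ndim == 0 else out


def marginal_log_likelihood(lam: float, m: np.ndarray, se2: np.ndarray) -> float:
    """Log marginal likelihood of the prior variance given voxel summaries.

    ``m`` are voxel sample means and ``se2`` their squared standard
    errors (s_v^2 / n). This is the objective EM maximizes; exposed so a
    direct 1-D maximization can serve as an independent check.
    """
    v = lam + se2
    return float(-0.5 * np.sum(np.log(2 * np.pi * v) + m**2 / v))


def em_prior_variance(
    m: np.ndarray,
    se2: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 1024,
) -> float:
    """EM estimate of the global prior variance lambda.

    E-step: posterior moments of theta_v under the current lambda;
    M-step: lambda <- mean_v(mu_v^2 + w_v). Iterates until the relative
    change in lambda falls below ``tol`` (floored at 1e-12).
    """
    m = np.asarray(m, dtype=float).ravel()
    se2 = np.asarray(se2, dtype=float).ravel()
    if m.shape != se2.shape or m.size == 0:
        raise ValueError("m and se2 must be equal-length, non-empty")
    if np.any(se2 <= 0):
        raise ValueError("squared standard errors must be positive")
    # method-of-moments start, floored well above zero: lambda = 0 is an
    # absorbing fixed point of EM, so the iteration must begin interior
    lam = max(float(np.mean(m**2) - np.mean(se2)), 0.1 * float(np.mean(se2)))
    for _ in range(max_iter):
        w = 1.0 / (1.0 / lam + 1.0 / se2)  # posterior variance
        mu = w * m / se2  # posterior mean (shrunk)
        new = max(float(np.mean(mu**2 + w)), LAMBDA_FLOOR)
        if abs(new - lam) <= tol * max(lam, LAMBDA_FLOOR):
            return new
        lam = new
    return lam


def fit_global_shrinkage(
    sample: GroupSample,
    tol: float = 1e-9,
    max_iter: int = 1024,
) -> PosteriorMap:
    """Fit the global-shrinkage model to one group's contrast maps.

    Requires at least 2 subjects and at least 100 in-mask voxels (the
    single hyperparameter is estimated from the voxel ensemble). Voxels
    whose between-subject variance is exactly zero are excluded from the
    EM and flagged in ``degenerate``; they are later labelled
    low-confidence rather than silently dropped.
    """
    if sample.mask is None:
        raise ValueError("GroupSample.mask is required for fitting")
    n = sample.n_subjects
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mask = sample.mask.data
    if mask.sum() < MIN_MASK_VOXELS:
        raise ValueError(f"need at least {MIN_MASK_VOXELS} in-mask voxels")
    data = sample.stack()[:, mask]  # subjects x voxels
    m = data.mean(axis=0)
    s2 = data.var(axis=0, ddof=1)
    good = s2 > 0
    if not good.any():
        raise ValueError("all in-mask voxels have zero between-subject variance")
    se2 = s2 / n
    lam = em_prior_variance(m[good], se2[good], tol=tol, max_iter=max_iter)

    w = np.zeros_like(m)
    mu = np.zeros_like(m)
    w[good] = 1.0 / (1.0 / lam + 1.0 / se2[good])
    mu[good] = w[good] * m[good] / se2[good]

    shape = mask.shape
    post_mean = np.full(shape, np.nan)
    post_sd = np.full(shape, np.nan)
    degenerate = np.zeros(shape, dtype=bool)
    post_mean[mask] = mu
    post_sd[mask] = np.sqrt(w)
    deg_flat = np.zeros(mask.sum(), dtype=bool)
    deg_flat[~good] = True
    degenerate[mask] = deg_flat
    return PosteriorMap(
        post_mean=post_mean, post_sd=post_sd, prior_var=lam, n_subjects=n,
        mask=sample.mask, affine=sample.affine, degenerate=degenerate,
    )


def _lpo_from_log_p(log_p: np.ndarray, log_q: np.ndarray) -> np.ndarray:
    """ln(p/(1-p)) from the log probability and log complement."""
    return log_p - log_q


def rope_classify(post: PosteriorMap, cfg: DecisionConfig | None = None) -> DecisionMap:
    """Four-way ROPE classification of a fitted posterior map.

    Probabilities come from the Gaussian posterior CDF. Directional
    hypotheses require posterior probability strictly above P_thr; the
    practical-null decision is tie-inclusive (>= P_thr). Degenerate
    voxels (zero between-subject variance) are labelled low-confidence
    with NaN odds.
    """
    cfg = cfg or DecisionConfig()
    gamma = cfg.resolve_gamma(post.prior_var)
    mask = post.mask.data
    mu = post.post_mean[mask]
    sd = post.post_sd[mask]
    deg = post.degenerate[mask] if post.degenerate is not None else np.zeros(mu.shape, bool)
    ok = ~deg & (sd > 0)

    z_hi = np.where(ok, (mu - gamma) / np.where(ok, sd, 1.0), 0.0)
    z_lo = np.where(ok, (-gamma - mu) / np.where(ok, sd, 1.0), 0.0)
    log_p_pos = log_ndtr(z_hi)  # P(theta > gamma)
    log_p_neg = log_ndtr(z_lo)  # P(theta < -gamma)
    p_pos = np.exp(log_p_pos)
    p_neg = np.exp(log_p_neg)
    p_rope = np.clip(1.0 - p_pos - p_neg, 0.0, 1.0)

    lpo_pos = _lpo_from_log_p(log_p_pos, log_ndtr(-z_hi))
    lpo_neg = _lpo_from_log_p(log_p_neg, log_ndtr(-z_lo))
    with np.errstate(divide="ignore"):
        log_rope = np.log(p_rope)
        log_not_rope = np.logaddexp(log_p_pos, log_p_neg)
    lpo_null = _lpo_from_log_p(log_rope, log_not_rope)

    lab = np.full(mu.shape, LABEL_LOW_CONFIDENCE, dtype=np.uint8)
    lab[p_pos > cfg.p_thr] = LABEL_POSITIVE
    lab[p_neg > cfg.p_thr] = LABEL_NEGATIVE
    lab[p_rope >= cfg.p_thr] = LABEL_NULL
    lab[~ok] = LABEL_LOW_CONFIDENCE

    shape = mask.shape
    labels = np.full(shape, LABEL_OUT_OF_MASK, dtype=np.uint8)
    labels[mask] = lab

    def volume(flat: np.ndarray) -> np.ndarray:
        out = np.full(shape, np.nan)
        out[mask] = np.where(ok, flat, np.nan)
        return out

    return DecisionMap(
        labels=labels,
        lpo_pos=volume(lpo_pos),
        lpo_neg=volume(lpo_neg),
        lpo_null=volume(lpo_null),
        gamma=gamma,
        p_thr=cfg.p_thr,
        mask=post.mask,
        affine=post.affine,
    )


def equivalence_report(decision: DecisionMap, mask: MaskVolume | None = None) -> pd.DataFrame:
    """Per-label voxel counts, volume in mm^3, and in-mask fractions."""
    mask = mask or decision.mask
    if mask.data.shape != decision.labels.shape:
        raise ValueError("mask grid differs from the decision grid")
    if not mask.data.any():
        raise ValueError("mask is empty")
    labels = decision.labels[mask.data]
    vox_mm3 = voxel_volume_mm3(decision.affine)
    total = labels.size
    rows = []
    for code in (LABEL_POSITIVE, LABEL_NEGATIVE, LABEL_NULL, LABEL_LOW_CONFIDENCE):
        n = int((labels == code).sum())
        rows.append(
            {
                "label": LABEL_NAMES[code],
                "n_voxels": n,
                "volume_mm3": n * vox_mm3,
                "fraction": n / total,
            }
        )
    return pd.DataFrame(rows)


def classification_recovery(labels: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> dict:
    """Recovery rates of decision labels against scene ground truth.

    Returns the fraction of in-mask true-positive-core voxels labelled
    positive, of true-negative-core voxels labelled negative, of
    true-null voxels labelled null, plus a 4x4 confusion table
    (truth null/positive/negative/ambiguous x decision labels).
    """
    from .synthetic import TRUTH_AMBIGUOUS, TRUTH_NEGATIVE, TRUTH_NULL, TRUTH_POSITIVE

    t = truth[mask]
    d = labels[mask]

    def rate(tcode: int, dcode: int) -> float:
        sel = t == tcode
        return float((d[sel] == dcode).mean()) if sel.any() else float("nan")

    confusion = pd.DataFrame(
        {
            LABEL_NAMES[dc]: [
                int(((t == tc) & (d == dc)).sum())
                for tc in (TRUTH_NULL, TRUTH_POSITIVE, TRUTH_NEGATIVE, TRUTH_AMBIGUOUS)
            ]
            for dc in (LABEL_POSITIVE, LABEL_NEGATIVE, LABEL_NULL, LABEL_LOW_CONFIDENCE)
        },
        index=["null", "positive", "negative", "ambiguous"],
    )
    return {
        "positive_recovery": rate(TRUTH_POSITIVE, LABEL_POSITIVE),
        "negative_recovery": rate(TRUTH_NEGATIVE, LABEL_NEGATIVE),
        "null_recovery": rate(TRUTH_NULL, LABEL_NULL),
        "confusion": confusion,
    }
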