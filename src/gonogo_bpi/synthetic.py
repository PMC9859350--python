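"""Synthetic cued equiprobable Go/NoGo study generator.

Everything downstream of acquisition is testable against this module:

* :func:`generate_event_schedule` — seeded trial schedules with the task's
  timing (100-ms stimuli, 1000-ms cue-target interval, jittered ITI
  2.8–3.2 s, null events 3–5 s);
* :func:`simulate_behavior` / :func:`simulate_cohort` — shifted-gamma
  response times, omissions on Go trials and false alarms on NoGo trials,
  with healthy-control and patient (OCD) parameter sets;
* :func:`simulate_bold_run` — a forward BOLD model (stick functions at
  target onsets convolved with the canonical HRF, AR(1) noise, slow
  drift, leakage of six simulated head-motion traces);
* :func:`simulate_group_contrast_maps` — group-level contrast-map scenes
  with known voxelwise ground truth for recovery experiments.

All randomness flows from one integer seed through
``numpy.random.default_rng``; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .events import (
    CUE_TARGET_SOA_S,
    EVENT_COLUMNS,
    ITI_CHOICES_S,
    NULL_DURATIONS_S,
    NULL_EVENT,
    STIM_DURATION_S,
    TASK_TRIAL_TYPES,
    validate_events,
)
from .hrf import double_gamma_hrf
from .volumes import BoldRun, ContrastMap, GroupSample, MaskVolume, mni_like_affine

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: integer codes for voxelwise ground-truth labels
TRUTH_NULL, TRUTH_POSITIVE, TRUTH_NEGATIVE, TRUTH_AMBIGUOUS = 0, 1, 2, 3

__all__ = [
    "BehaviorParams",
    "GROUP_PARAMS",
    "Region",
    "SceneSpec",
    "NoiseSpec",
    "GroupScene",
    "Schedule",
    "generate_event_schedule",
    "simulate_behavior",
    "draw_subject_params",
    "simulate_cohort",
    "simulate_bold_run",
    "truth_labels",
    "simulate_group_contrast_maps",
    "scene_from_dict",
    "TRUTH_NULL",
    "TRUTH_POSITIVE",
    "TRUTH_NEGATIVE",
    "TRUTH_AMBIGUOUS",
]


# --------------------------------------------------------------------------
# event schedules
# --------------------------------------------------------------------------

@dataclass
class Schedule:
    """An event table plus the total scheduled duration in seconds."""

    events: pd.DataFrame
    duration: float


def generate_event_schedule(
    seed: int,
    n_per_type: int = 100,
    n_null: int = 100,
    t_start: float = 3.0,
    sessions: int = 1,
) -> Schedule:
    """Build a seeded-random schedule of task trials and null events.

    Exactly ``n_per_type`` trials of each of the four task types (go,
    nogo, ignore_pa, ignore_pp) and ``n_null`` null events are placed in
    random order. A task trial occupies cue (100 ms) + cue-target
    interval (1000 ms) + target (100 ms) + an ITI drawn from
    {2.8, ..., 3.2} s; a null event is a fixation period of
    {3.0, ..., 5.0} s. With ``sessions=2`` two independent schedules are
    generated and concatenated in time (counts split between sessions).
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be at least 1")
    if n_null < 0:
        raise ValueError("n_null must be non-negative")
    if sessions < 1:
        raise ValueError("sessions must be at least 1")
    rng = np.random.default_rng(seed)

    per_type = _split_counts(n_per_type, sessions)
    per_null = _split_counts(n_null, sessions)
    rows: list[tuple] = []
    t = float(t_start)
    for s in range(sessions):
        labels = np.repeat(np.arange(5), [per_type[s]] * 4 + [per_null[s]])
        rng.shuffle(labels)
        for lab in labels:
            if lab == 4:
                dur = float(rng.choice(NULL_DURATIONS_S))
                rows.append((t, dur, NULL_EVENT, np.nan, np.nan))
                t += dur
            else:
                cue = t
                onset = cue + CUE_TARGET_SOA_S
                rows.append((onset, STIM_DURATION_S, TASK_TRIAL_TYPES[lab], cue, np.nan))
                iti = float(rng.choice(ITI_CHOICES_S))
                t = onset + STIM_DURATION_S + iti
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    # guard against float accumulation breaking the SOA contract
    validate_events(events)
    return Schedule(events=events, duration=t)


def _split_counts(total: int, sessions: int) -> list[int]:
    base = total // sessions
    counts = [base] * sessions
    counts[0] += total - base * sessions
    return counts


# --------------------------------------------------------------------------
# behaviour
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorParams:
    """Response-generation parameters for one subject or one group.

    RT is a shifted gamma: ``rt_shift_ms`` plus a gamma variable with
    mean ``rt_mean_ms - rt_shift_ms`` and SD ``rt_sd_ms``. Omission and
    false-alarm probabilities are given as percentages.
    """

    rt_mean_ms: float = 384.0
    rt_sd_ms: float = 60.0
    rt_shift_ms: float = 150.0
    omission_pct: float = 2.97
    false_alarm_pct: float = 0.35

    def __post_init__(self) -> None:
        if self.rt_mean_ms <= 0 or self.rt_sd_ms < 0 or self.rt_shift_ms < 0:
            raise ValueError("RT parameters must be non-negative (mean positive)")
        if self.rt_mean_ms <= self.rt_shift_ms:
            raise ValueError("rt_mean_ms must exceed rt_shift_ms")
        for p in (self.omission_pct, self.false_alarm_pct):
            if not 0 <= p <= 100:
                raise ValueError("probabilities must be percentages in [0, 100]")


#: trial-level defaults matching the reported group behaviour
GROUP_PARAMS: dict[str, BehaviorParams] = {
    "hc": BehaviorParams(384.0, 60.0, 150.0, 2.97, 0.35),
    "ocd": BehaviorParams(491.1, 117.5, 150.0, 3.21, 0.43),
}

#: between-subject SDs of the behavioural summaries (for cohort simulation)
GROUP_BETWEEN_SD: dict[str, dict[str, float]] = {
    "hc": {"rt_sd_ms": 60.0, "omission_sd_pct": 3.92, "false_alarm_sd_pct": 0.64},
    "ocd": {"rt_sd_ms": 117.5, "omission_sd_pct": 3.45, "false_alarm_sd_pct": 0.94},
}

#: within-subject trial-to-trial RT SD used when simulating cohorts
WITHIN_SUBJECT_RT_SD_MS = 100.0


def _draw_rt(rng: np.random.Generator, params: BehaviorParams, n: int) -> np.ndarray:
    mu = params.rt_mean_ms - params.rt_shift_ms
    sd = params.rt_sd_ms
    if sd == 0:
        return np.full(n, params.rt_mean_ms)
    shape = (mu / sd) ** 2
    scale = sd**2 / mu
    return params.rt_shift_ms + rng.gamma(shape, scale, size=n)


def simulate_behavior(
    events: pd.DataFrame,
    group: str = "hc",
    seed: int = 0,
    params: BehaviorParams | None = None,
) -> pd.DataFrame:
    """Fill the ``response_time`` column of a schedule.

    Go rows receive an RT unless an omission is drawn; NoGo rows receive
    an RT only when a false alarm is drawn; Ignore and null rows never
    receive responses. Returns a new event table.
    """
    validate_events(events)
    if params is None:
        if group not in GROUP_PARAMS:
            raise ValueError(f"unknown group {group!r}; expected one of {sorted(GROUP_PARAMS)}")
        params = GROUP_PARAMS[group]
    rng = np.random.default_rng(seed)
    out = events.copy()
    rt = np.full(len(out), np.nan)
    types = out["trial_type"].to_numpy()

    go = np.flatnonzero(types == "go")
    answered = rng.random(go.size) >= params.omission_pct / 100.0
    rt_go = _draw_rt(rng, params, go.size)
    rt[go[answered]] = rt_go[answered]

    nogo = np.flatnonzero(types == "nogo")
    alarms = rng.random(nogo.size) < params.false_alarm_pct / 100.0
    rt_nogo = _draw_rt(rng, params, nogo.size)
    rt[nogo[alarms]] = rt_nogo[alarms]

    out["response_time"] = rt
    return out


def _gamma_with_moments(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Gamma draws with exact mean/SD; degenerate at ``mean`` when sd=0."""
    if sd == 0 or mean == 0:
        return np.full(n, mean)
    shape = (mean / sd) ** 2
    return rng.gamma(shape, sd**2 / mean, size=n)


def draw_subject_params(
    group: str,
    n_subjects: int,
    rng: np.random.Generator,
    within_rt_sd_ms: float = WITHIN_SUBJECT_RT_SD_MS,
) -> list[BehaviorParams]:
    """Subject-level parameter draws around the group's summary statistics.

    Subject mean RTs are Normal(group mean, group between-subject SD);
    omission and false-alarm percentages are Gamma with the group's
    between-subject mean/SD (positive, exact first two moments). Each
    subject then produces trials with within-subject SD
    ``within_rt_sd_ms``.
    """
    base = GROUP_PARAMS[group]
    between = GROUP_BETWEEN_SD[group]
    means = rng.normal(base.rt_mean_ms, between["rt_sd_ms"], size=n_subjects)
    means = np.maximum(means, base.rt_shift_ms + 50.0)
    omis = np.minimum(
        _gamma_with_moments(rng, base.omission_pct, between["omission_sd_pct"], n_subjects), 100.0
    )
    fas = np.minimum(
        _gamma_with_moments(rng, base.false_alarm_pct, between["false_alarm_sd_pct"], n_subjects),
        100.0,
    )
    return [
        replace(
            base,
            rt_mean_ms=float(means[i]),
            rt_sd_ms=within_rt_sd_ms,
            omission_pct=float(omis[i]),
            false_alarm_pct=float(fas[i]),
        )
        for i in range(n_subjects)
    ]


def simulate_cohort(
    n_subjects: int,
    group: str,
    seed: int,
    n_per_type: int = 100,
    n_null: int = 100,
    schedule: pd.DataFrame | None = None,
) -> list[pd.DataFrame]:
    """Simulate a cohort: per-subject schedules with filled responses.

    Between-subject heterogeneity follows :func:`draw_subject_params`.
    Passing ``schedule`` reuses one fixed schedule for every subject
    (responses still vary), which is cheaper for purely behavioural
    experiments.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    rng = np.random.default_rng(seed)
    params = draw_subject_params(group, n_subjects, rng)
    out = []
    for i in range(n_subjects):
        ev = (
            schedule
            if schedule is not None
            else generate_event_schedule(
                int(rng.integers(2**31)), n_per_type=n_per_type, n_null=n_null
            ).events
        )
        out.append(simulate_behavior(ev, group=group, seed=int(rng.integers(2**31)), params=params[i]))
    return out


# --------------------------------------------------------------------------
# scenes (spatial ground truth)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """A spherical effect region on the voxel grid.

    ``center`` and ``radius`` are in voxel units; ``effect_size`` is in
    contrast units and its sign determines the direction. ``trial_type``
    optionally restricts the region to one task regressor when used by
    the BOLD forward model.
    """

    center: tuple[float, float, float]
    radius: float
    effect_size: float
    trial_type: str | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("region radius must be positive")

    def indicator(self, shape: Sequence[int]) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, self.center))
        return d2 <= self.radius**2

    def distance(self, shape: Sequence[int]) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, self.center))
        return np.sqrt(d2)


@dataclass
class SceneSpec:
    """Spatial layout and sampling plan of a synthetic group study.

    ``effect_regions`` carry the mean contrast signal shared by both
    groups; ``group_offset_regions`` are added to the second (patient)
    group only, so a negative offset emulates hypoactivation;
    ``rt_slope_regions`` make the patient maps co-vary with the centered
    RT covariate (effect size per 1 SD of the covariate). Subject maps
    are truth + Gaussian between-subject noise, smoothed at
    ``smooth_fwhm`` mm. ``ambiguous_shell_mm`` (default 1.5 x FWHM)
    declares the transition shell around effect spheres whose labels are
    neither reliably signal nor reliably null after smoothing.
    """

    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_mm: float = 3.0
    effect_regions: list[Region] = field(default_factory=list)
    group_offset_regions: list[Region] = field(default_factory=list)
    rt_slope_regions: list[Region] = field(default_factory=list)
    between_subject_sd: float = 1.0
    smooth_fwhm: float = 8.0
    n_subjects_hc: int = 34
    n_subjects_ocd: int = 14
    ambiguous_shell_mm: float | None = None
    brain_fraction: float = 0.92

    def __post_init__(self) -> None:
        if self.smooth_fwhm < 0:
            raise ValueError("smooth_fwhm must be non-negative")
        if self.between_subject_sd <= 0:
            raise ValueError("between_subject_sd must be positive")
        if min(self.n_subjects_hc, self.n_subjects_ocd) < 2:
            raise ValueError("need at least 2 subjects per group")
        self._check_sign_conflicts()

    def _check_sign_conflicts(self) -> None:
        regions = [r for r in self.effect_regions if r.effect_size != 0]
        for i, a in enumerate(regions):
            for b in regions[i + 1:]:
                if np.sign(a.effect_size) != np.sign(b.effect_size):
                    dist = np.linalg.norm(np.subtract(a.center, b.center))
                    if dist < a.radius + b.radius:
                        raise ValueError(
                            "overlapping effect regions with contradictory signs: "
                            f"{a.center} and {b.center}"
                        )

    @property
    def shell_mm(self) -> float:
        if self.ambiguous_shell_mm is not None:
            return self.ambiguous_shell_mm
        return 1.5 * self.smooth_fwhm

    @property
    def affine(self) -> np.ndarray:
        return mni_like_affine(self.grid_shape, self.voxel_mm)

    def brain_mask(self) -> MaskVolume:
        """Axis-aligned ellipsoid occupying ``brain_fraction`` of each axis."""
        shape = self.grid_shape
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        center = [(s - 1) / 2.0 for s in shape]
        semi = [self.brain_fraction * s / 2.0 for s in shape]
        r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
        return MaskVolume(data=r2 <= 1.0, affine=self.affine)

    def field(self, regions: list[Region]) -> np.ndarray:
        out = np.zeros(self.grid_shape)
        for r in regions:
            out[r.indicator(self.grid_shape)] += r.effect_size
        return out


def scene_from_dict(cfg: dict) -> SceneSpec:
    """Build a :class:`SceneSpec` from a plain (e.g. YAML-loaded) mapping."""

    def regions(key: str) -> list[Region]:
        return [
            Region(
                center=tuple(r["center"]),
                radius=float(r["radius"]),
                effect_size=float(r["effect_size"]),
                trial_type=r.get("trial_type"),
            )
            for r in cfg.get(key, [])
        ]

    kwargs = {
        k: cfg[k]
        for k in (
            "voxel_mm",
            "between_subject_sd",
            "smooth_fwhm",
            "n_subjects_hc",
            "n_subjects_ocd",
            "ambiguous_shell_mm",
            "brain_fraction",
        )
        if k in cfg
    }
    if "grid_shape" in cfg:
        kwargs["grid_shape"] = tuple(cfg["grid_shape"])
    return SceneSpec(
        effect_regions=regions("effect_regions"),
        group_offset_regions=regions("group_offset_regions"),
        rt_slope_regions=regions("rt_slope_regions"),
        **kwargs,
    )


def truth_labels(scene: SceneSpec) -> np.ndarray:
    """Voxelwise ground-truth labels, a pure function of the scene.

    Voxels inside an effect sphere are positive/negative according to the
    sign of its effect; voxels within ``shell_mm`` of a sphere surface
    are ambiguous (smoothing mixes signal and null there); all remaining
    voxels are null. Group offsets and RT slopes do not enter: the labels
    describe the shared mean contrast field that the one-group posterior
    analysis estimates.
    """
    labels = np.full(scene.grid_shape, TRUTH_NULL, dtype=np.uint8)
    shell_vox = scene.shell_mm / scene.voxel_mm
    for r in scene.effect_regions:
        if r.effect_size == 0:
            continue
        d = r.distance(scene.grid_shape)
        labels[(d > r.radius) & (d <= r.radius + shell_vox) & (labels == TRUTH_NULL)] = (
            TRUTH_AMBIGUOUS
        )
        labels[d <= r.radius] = TRUTH_POSITIVE if r.effect_size > 0 else TRUTH_NEGATIVE
    return labels


@dataclass
class GroupScene:
    """Output bundle of :func:`simulate_group_contrast_maps`."""

    hc: GroupSample
    ocd: GroupSample
    rt_covariate_ms: np.ndarray  # per OCD subject, raw (uncentered) mean RT
    truth: np.ndarray  # truth_labels array
    mask: MaskVolume
    scene: SceneSpec


def _smooth(data: np.ndarray, fwhm_mm: float, voxel_mm: float) -> np.ndarray:
    if fwhm_mm <= 0:
        return data
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    return gaussian_filter(data, sigma_vox)


def simulate_group_contrast_maps(scene: SceneSpec, seed: int) -> GroupScene:
    """Draw per-subject contrast maps for both groups on a known scene.

    Each subject map is the truth mean field (plus the group offset for
    the patient group, plus RT-slope fields times the subject's
    standardized centered RT) plus white between-subject Gaussian noise,
    then Gaussian-smoothed at the scene's FWHM.
    """
    rng = np.random.default_rng(seed)
    base = scene.field(scene.effect_regions)
    offset = scene.field(scene.group_offset_regions)
    slope = scene.field(scene.rt_slope_regions)
    mask = scene.brain_mask()

    rt = rng.normal(GROUP_PARAMS["ocd"].rt_mean_ms, GROUP_BETWEEN_SD["ocd"]["rt_sd_ms"],
                    size=scene.n_subjects_ocd)
    z = (rt - rt.mean()) / rt.std(ddof=1)

    def subject_map(mean_field: np.ndarray, sid: str) -> ContrastMap:
        noise = rng.normal(0.0, scene.between_subject_sd, size=scene.grid_shape)
        data = _smooth(mean_field + noise, scene.smooth_fwhm, scene.voxel_mm)
        return ContrastMap(data=data, affine=scene.affine, subject_id=sid)

    hc_maps = [subject_map(base, f"hc{i + 1:02d}") for i in range(scene.n_subjects_hc)]
    ocd_maps = [
        subject_map(base + offset + slope * z[j], f"ocd{j + 1:02d}")
        for j in range(scene.n_subjects_ocd)
    ]
    return GroupScene(
        hc=GroupSample(maps=hc_maps, mask=mask, group_label="hc"),
        ocd=GroupSample(maps=ocd_maps, mask=mask, group_label="ocd"),
        rt_covariate_ms=rt,
        truth=truth_labels(scene),
        mask=mask,
        scene=scene,
    )


# --------------------------------------------------------------------------
# BOLD forward model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise for the BOLD forward model.

    ``sigma`` is the stationary SD of the AR(1) process, ``ar1_rho`` its
    lag-1 autocorrelation, ``drift_amplitude`` scales two slow cosine
    drift components with per-voxel random coefficients, and
    ``motion_leak`` scales per-voxel linear leakage of the six simulated
    head-motion traces into the signal.
    """

    sigma: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 0.0
    motion_leak: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not -1 < self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in (-1, 1)")


MOTION_COLUMNS = [f"motion{i}" for i in range(1, 7)]
MOTION_STEP_SD = 0.2  # mm or degrees per scan, before smoothing


def _simulate_motion(rng: np.random.Generator, n_scans: int) -> pd.DataFrame:
    steps = rng.normal(0.0, MOTION_STEP_SD, size=(n_scans, 6))
    walks = np.cumsum(steps, axis=0)
    smooth = gaussian_filter1d(walks, sigma=3.0, axis=0)
    return pd.DataFrame(smooth, columns=MOTION_COLUMNS)


def _ar1_noise(rng: np.random.Generator, n_vox: int, n_scans: int, spec: NoiseSpec) -> np.ndarray:
    innov = rng.standard_normal((n_vox, n_scans)) * spec.sigma * np.sqrt(1 - spec.ar1_rho**2)
    innov[:, 0] = rng.standard_normal(n_vox) * spec.sigma  # stationary start
    return signal.lfilter([1.0], [1.0, -spec.ar1_rho], innov, axis=1)


def regressor_timecourse(
    onsets: np.ndarray, n_scans: int, tr: float, oversampling: int = 20
) -> np.ndarray:
    """Stick functions at ``onsets`` convolved with the canonical HRF,
    sampled at scan times (shared by the forward model and the GLM)."""
    dt = tr / oversampling
    n_fine = n_scans * oversampling
    sticks = np.zeros(n_fine)
    idx = np.round(np.asarray(onsets, dtype=float) / dt).astype(int)
    if np.any(idx >= n_fine) or np.any(idx < 0):
        raise ValueError("event onset outside the run")
    np.add.at(sticks, idx, 1.0)
    kern = double_gamma_hrf(dt)
    conv = signal.fftconvolve(sticks, kern)[:n_fine]
    return conv[::oversampling].copy()


def simulate_bold_run(
    events: pd.DataFrame,
    amplitudes: dict[str, float],
    seed: int,
    scene: SceneSpec,
    noise: NoiseSpec | None = None,
    tr: float = 2.0,
    n_scans: int | None = None,
    pad_s: float = 16.0,
) -> tuple[BoldRun, pd.DataFrame]:
    """Forward-model a BOLD run from a schedule on a scene's grid.

    The signal at each in-brain voxel is the sum over trial types of
    ``amplitude[type]`` times that type's HRF-convolved stick regressor,
    restricted to scene regions tagged with the type (brain-wide when the
    scene declares no region for a type with a non-zero amplitude), plus
    AR(1) noise, slow drift, and motion leakage. Returns the run and the
    six-column motion table.
    """
    validate_events(events)
    noise = noise or NoiseSpec()
    unknown = set(amplitudes) - set(TASK_TRIAL_TYPES)
    if unknown:
        raise ValueError(f"amplitudes for unknown trial types {sorted(unknown)}")
    task = events[events["trial_type"] != NULL_EVENT]
    end = float((events["onset"] + events["duration"]).max())
    if n_scans is None:
        n_scans = int(np.ceil((end + pad_s) / tr))
    elif end > n_scans * tr:
        raise ValueError(
            f"run of {n_scans} scans ({n_scans * tr:.1f} s) too short for the "
            f"last event at {end:.1f} s"
        )

    rng = np.random.default_rng(seed)
    mask = scene.brain_mask().data
    flat = np.flatnonzero(mask.ravel())
    n_vox = flat.size

    sig = np.zeros((n_vox, n_scans))
    for ttype, amp in amplitudes.items():
        if amp == 0:
            continue
        onsets = task.loc[task["trial_type"] == ttype, "onset"].to_numpy(float)
        if onsets.size == 0:
            continue
        course = regressor_timecourse(onsets, n_scans, tr)
        tagged = [r for r in scene.effect_regions if r.trial_type == ttype]
        if tagged:
            weight = np.zeros(scene.grid_shape)
            for r in tagged:
                weight[r.indicator(scene.grid_shape)] = 1.0
            w = weight.ravel()[flat]
        else:
            w = np.ones(n_vox)
        sig += amp * np.outer(w, course)

    data_flat = sig + _ar1_noise(rng, n_vox, n_scans, noise)

    if noise.drift_amplitude != 0:
        t = np.arange(n_scans) / n_scans
        basis = np.stack([np.cos(np.pi * k * t) for k in (1, 2)])  # slow trends
        coefs = rng.standard_normal((n_vox, 2)) * noise.drift_amplitude
        data_flat += coefs @ basis

    motion = _simulate_motion(rng, n_scans)
    if noise.motion_leak != 0:
        weights = rng.standard_normal((n_vox, 6)) * noise.motion_leak
        data_flat += weights @ motion.to_numpy().T

    data = np.zeros(scene.grid_shape + (n_scans,))
    data.reshape(-1, n_scans)[flat] = data_flat
    return BoldRun(data=data, affine=scene.affine, tr=tr), motion
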