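"""Synthetic split-belt cohorts with known ground truth.

The generator emulates the study design the rest of the package analyses:
two age groups walking on a split-belt treadmill (baseline slow 0.7 m/s,
baseline fast 1.4 m/s, then a split trial with the left belt fast and the
right belt slow), yielding per-step gait-parameter series, optional
continuous marker trials, a covariate table, and 3D brain-metric maps with a
planted linear association to the behavioral symmetry score.

Adaptation dynamics are dual-rate exponential: during the split condition
the percent-change (Δ) series of each foot approaches its plateau as

    Δ(k) = plateau ± (A_fast·exp(−k/τ_fast) + A_slow·exp(−k/τ_slow)) + ε_k

with i.i.d. Gaussian step noise ε.  The two feet receive opposite-signed
plateaus (±s*/2) and transients, so the between-feet symmetry series
(slow-stance minus fast-stance Δ) decays from s* + 2(A_fast+A_slow) to the
subject's true plateau symmetry s*, drawn per subject from the group's
Normal(mean, SD).  Group plateau-symmetry defaults are the published cohort
values for 31 younger / 19 older adults.

Everything is a pure function of (spec, seed): identical specs give
bit-identical output, and marker trials can be regenerated subject by
subject without rebuilding the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from gaitbrain.gait import GaitTrial

__all__ = [
    "BrainSimSpec",
    "CohortSpec",
    "CohortSpecError",
    "SyntheticCohort",
    "make_atlas",
    "simulate_brain_maps",
    "simulate_marker_trial",
    "simulate_step_series",
]

GAIT_PARAMS = ("CoM", "intCoPCoM", "StepCoM", "StepLength")
GROUPS = ("young", "old")
#: Split assignment: the right belt runs slow, the left belt fast.
FOOT_BELT = {"right": "slow", "left": "fast"}

# Published group plateau-symmetry scores (% change units), mean and SD.
PLATEAU_MEAN = {
    "young": {"CoM": -4.6, "intCoPCoM": -63.3, "StepCoM": 29.0, "StepLength": 11.7},
    "old": {"CoM": -1.7, "intCoPCoM": 11.4, "StepCoM": 3.2, "StepLength": 16.6},
}
PLATEAU_SD = {
    "young": {"CoM": 5.2, "intCoPCoM": 68.1, "StepCoM": 16.0, "StepLength": 8.0},
    "old": {"CoM": 6.0, "intCoPCoM": 51.9, "StepCoM": 23.4, "StepLength": 15.0},
}
SEX_FEMALE_PROP = {"young": 17 / 31, "old": 10 / 19}
AGE_MEAN_SD = {"young": (22.3, 3.9), "old": (72.0, 5.0)}
#: Raw-unit baselines the Δ series are expressed against (mm / mm·s); chosen
#: as plausible slow-walking magnitudes, nonzero so percent change is defined.
BASELINE_RAW = {"CoM": 20.0, "intCoPCoM": 30.0, "StepCoM": 120.0, "StepLength": 600.0}
TIV_MEAN_SD = {"F": (1380.0, 110.0), "M": (1550.0, 110.0)}  # ml

_HIP_HALF_WIDTH = 60.0  # mm, hip-marker offset from the midline
_SWAY_AMPLITUDE = 5.0  # mm, ML sway superposed between step knots


class CohortSpecError(ValueError):
    """A cohort specification field is invalid; the message names it."""


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise CohortSpecError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic split-belt cohort.

    Plateau symmetry means/SDs (% units) default to the published two-group
    cohort values; adaptation amplitudes and time constants (steps) shape
    the dual-rate transient; ``step_noise_sd`` is the i.i.d. per-step noise
    on the Δ scale.  ``n_steps_split`` defaults to 600 steps per foot
    (≈10 min of split walking); baselines get 120 steps (≈2 min trials).
    """

    n_young: int = 31
    n_old: int = 19
    gait_params: tuple[str, ...] = GAIT_PARAMS
    plateau_mean: dict = field(default_factory=lambda: {g: dict(PLATEAU_MEAN[g]) for g in GROUPS})
    plateau_sd: dict = field(default_factory=lambda: {g: dict(PLATEAU_SD[g]) for g in GROUPS})
    amp_fast: float = 15.0  # % units
    amp_slow: float = 10.0
    tau_fast: float = 15.0  # steps
    tau_slow: float = 100.0
    step_noise_sd: float = 5.0  # % units, per foot per step
    n_steps_split: int = 600
    n_steps_baseline: int = 120
    belt_speed_slow: float = 0.7  # m/s
    belt_speed_fast: float = 1.4
    baseline_raw: dict = field(default_factory=lambda: dict(BASELINE_RAW))
    sex_female_prop: dict = field(default_factory=lambda: dict(SEX_FEMALE_PROP))
    step_duration: float = 0.6  # s, used by the marker-trial generator
    sample_rate: float = 100.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_young >= 1, "n_young", "must be >= 1")
        _check(self.n_old >= 1, "n_old", "must be >= 1")
        _check(len(self.gait_params) >= 1, "gait_params", "must name at least one parameter")
        for g in GROUPS:
            for p in self.gait_params:
                _check(p in self.plateau_mean.get(g, {}), "plateau_mean", f"missing {g}/{p}")
                _check(p in self.plateau_sd.get(g, {}), "plateau_sd", f"missing {g}/{p}")
                _check(self.plateau_sd[g][p] >= 0, "plateau_sd", f"{g}/{p} must be >= 0")
        _check(self.step_noise_sd >= 0, "step_noise_sd", "must be >= 0")
        if self.amp_fast != 0 and self.amp_slow != 0:
            _check(self.tau_fast < self.tau_slow, "tau_fast", "must be < tau_slow")
        _check(self.tau_fast > 0, "tau_fast", "must be > 0")
        _check(self.tau_slow > 0, "tau_slow", "must be > 0")
        _check(self.n_steps_split >= 1, "n_steps_split", "must be >= 1")
        _check(self.n_steps_baseline >= 1, "n_steps_baseline", "must be >= 1")
        _check(
            self.belt_speed_fast > self.belt_speed_slow,
            "belt_speed_fast",
            "must exceed belt_speed_slow",
        )
        for p in self.gait_params:
            _check(p in self.baseline_raw, "baseline_raw", f"missing {p}")
            _check(self.baseline_raw[p] != 0, "baseline_raw", f"{p} must be nonzero")
        _check(self.step_duration > 0, "step_duration", "must be > 0")
        _check(self.sample_rate > 0, "sample_rate", "must be > 0")

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise CohortSpecError(f"{sorted(unknown)[0]}: unknown field")
        if "gait_params" in data:
            data = {**data, "gait_params": tuple(data["gait_params"])}
        return cls(**data)

    @property
    def subjects(self) -> list[tuple[str, str]]:
        """(subject_id, group) pairs, young first."""
        return [(f"YA{i + 1:02d}", "young") for i in range(self.n_young)] + [
            (f"OA{i + 1:02d}", "old") for i in range(self.n_old)
        ]

    def n_steps_for(self, condition: str) -> int:
        return self.n_steps_split if condition == "split" else self.n_steps_baseline


CONDITIONS = ("baseline_slow", "baseline_fast", "split")


@dataclass
class SubjectDraw:
    """Everything drawn for one subject: covariates, truth, raw series."""

    subject: str
    group: str
    sex: str
    age: float
    tiv: float
    true_plateau: dict[str, float]  # parameter -> true plateau symmetry (%)
    series: dict[tuple[str, str, str], np.ndarray]  # (condition, foot, parameter) -> raw


def _draw_subject(spec: CohortSpec, subject: str, group: str, rng: np.random.Generator) -> SubjectDraw:
    sex = "F" if rng.random() < spec.sex_female_prop[group] else "M"
    mu, sd = AGE_MEAN_SD[group]
    age = float(rng.normal(mu, sd))
    tmu, tsd = TIV_MEAN_SD[sex]
    tiv = float(rng.normal(tmu, tsd))
    true_plateau = {
        p: float(rng.normal(spec.plateau_mean[group][p], spec.plateau_sd[group][p]))
        for p in spec.gait_params
    }
    series: dict[tuple[str, str, str], np.ndarray] = {}
    for condition in CONDITIONS:
        n = spec.n_steps_for(condition)
        k = np.arange(1, n + 1, dtype=float)
        transient = spec.amp_fast * np.exp(-k / spec.tau_fast) + spec.amp_slow * np.exp(
            -k / spec.tau_slow
        )
        for foot in ("left", "right"):
            sign = 1.0 if FOOT_BELT[foot] == "slow" else -1.0
            for p in spec.gait_params:
                noise = rng.normal(0.0, spec.step_noise_sd, n)
                if condition == "split":
                    delta = sign * (0.5 * true_plateau[p] + transient) + noise
                else:
                    delta = noise
                series[(condition, foot, p)] = spec.baseline_raw[p] * (1.0 + delta / 100.0)
    return SubjectDraw(subject, group, sex, age, tiv, true_plateau, series)


def _subject_rngs(spec: CohortSpec) -> list[np.random.Generator]:
    root = np.random.SeedSequence(spec.seed)
    return [np.random.default_rng(child) for child in root.spawn(len(spec.subjects))]


@dataclass
class SyntheticCohort:
    """Generated cohort: tidy step series, covariates, and ground truth."""

    steps: pd.DataFrame  # subject, group, condition, foot, step_index, parameter, value
    covariates: pd.DataFrame  # subject, group, sex, age, tiv
    truth: pd.DataFrame  # subject, group, parameter, true_plateau_symmetry
    spec: CohortSpec


def simulate_step_series(spec: CohortSpec) -> SyntheticCohort:
    """Generate per-subject, per-condition step series for each foot and
    gait parameter, plus covariates and per-subject ground truth."""
    rows = []
    cov_rows = []
    truth_rows = []
    for (subject, group), rng in zip(spec.subjects, _subject_rngs(spec)):
        draw = _draw_subject(spec, subject, group, rng)
        cov_rows.append((subject, group, draw.sex, draw.age, draw.tiv))
        for p in spec.gait_params:
            truth_rows.append((subject, group, p, draw.true_plateau[p]))
        for (condition, foot, p), values in draw.series.items():
            n = values.size
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "group": group,
                        "condition": condition,
                        "foot": foot,
                        "step_index": np.arange(1, n + 1),
                        "parameter": p,
                        "value": values,
                    }
                )
            )
    steps = pd.concat(rows, ignore_index=True)
    covariates = pd.DataFrame(cov_rows, columns=["subject", "group", "sex", "age", "tiv"])
    truth = pd.DataFrame(truth_rows, columns=["subject", "group", "parameter", "true_plateau_symmetry"])
    return SyntheticCohort(steps, covariates, truth, spec)


def _strike_plan(n_steps: int) -> list[tuple[int, str, str, int]]:
    """(strike index i, striking foot, stance foot, stance-series step k) for
    strikes 1..2n; strike 0 is an uninstrumented lead-in (left foot)."""
    plan = []
    for i in range(1, 2 * n_steps + 1):
        striking = "left" if i % 2 == 0 else "right"
        stance = "right" if striking == "left" else "left"
        k = (i + 1) // 2 if stance == "left" else i // 2
        plan.append((i, striking, stance, k))
    return plan


def simulate_marker_trial(
    spec: CohortSpec,
    subject: str,
    condition: str,
    n_steps: int | None = None,
) -> tuple[GaitTrial, pd.DataFrame, pd.DataFrame]:
    """Continuous marker/CoP trajectories realising a subject's step series.

    The trial is constructed so that the per-step parameters recomputed by
    :mod:`gaitbrain.gait` from the trajectories reproduce the subject's step
    series: marker traces are piecewise-linear through per-strike knots (with
    an ML sway component that vanishes at the knots), heel strikes fall
    exactly on sampling instants, and the CoP−CoM displacement is a triangle
    over each single-stance interval whose area equals the target integral.

    Returns ``(trial, events_truth, steps_truth)`` where ``events_truth``
    lists all ground-truth heel-strike times/feet and ``steps_truth`` the
    per-strike parameter targets (stance-foot tagged; the lead-in strike has
    no targets).

    Raises
    ------
    KeyError
        Unknown subject or condition.
    ValueError
        ``n_steps`` too small for one full stride per foot.
    """
    ids = [s for s, _ in spec.subjects]
    if subject not in ids:
        raise KeyError(f"unknown subject {subject!r}")
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}")
    idx = ids.index(subject)
    draw = _draw_subject(spec, subject, spec.subjects[idx][1], _subject_rngs(spec)[idx])

    n = spec.n_steps_for(condition) if n_steps is None else int(n_steps)
    if n < 2:
        raise ValueError("trial too short: need at least two steps per foot (one full stride)")
    series = {
        (foot, p): draw.series[(condition, foot, p)][:n]
        for foot in ("left", "right")
        for p in spec.gait_params
    }
    for p in GAIT_PARAMS:  # marker construction needs all four parameters
        if p not in spec.gait_params:
            for foot in ("left", "right"):
                series[(foot, p)] = np.full(n, BASELINE_RAW[p])

    t_step = spec.step_duration
    spp = int(round(t_step * spec.sample_rate))
    if spp < 4 or spp % 2:
        raise CohortSpecError("sample_rate: step_duration*sample_rate must be an even integer >= 4")
    dt = t_step / spp
    n_strikes = 2 * n + 1  # incl. lead-in strike 0
    n_samples = (n_strikes + 2) * spp + spp // 2 + 1
    time = np.arange(n_samples) * dt
    strike_idx = (np.arange(n_strikes) + 1) * spp
    strike_t = time[strike_idx]

    plan = _strike_plan(n)
    # Per-strike knot targets.
    com_knots = np.empty(n_strikes)
    com_knots[0] = series[("right", "CoM")][0]  # lead-in mirrors the first right-stance step
    sl_knots = np.empty(n_strikes)
    sl_knots[0] = series[("right", "StepLength")][0]
    stepcom = np.empty(n_strikes)
    stepcom[0] = series[("right", "StepCoM")][0]
    integ = np.empty(n_strikes)
    integ[0] = 0.0
    for i, striking, stance, k in plan:
        com_knots[i] = series[(stance, "CoM")][k - 1]
        sl_knots[i] = series[(stance, "StepLength")][k - 1]
        stepcom[i] = series[(stance, "StepCoM")][k - 1]
        integ[i] = series[(stance, "intCoPCoM")][k - 1]

    sway = _SWAY_AMPLITUDE * np.sin(np.pi * time / t_step)
    com = np.interp(time, strike_t, com_knots) + sway
    hip_ml = {"left": com - _HIP_HALF_WIDTH, "right": com + _HIP_HALF_WIDTH}
    hip_ap = {"left": np.zeros(n_samples), "right": np.zeros(n_samples)}

    # Heel AP: a knot at *every* strike — +SL/2 for the striking foot,
    # −SL/2 for the trailing foot — so each foot's trace peaks at its own
    # strikes (relative to the hip midpoint, which sits at AP 0).
    striking_feet = ["left"] + [s for _, s, _, _ in plan]
    # Anchor knots one step before/after the strike train keep the edge
    # strikes detectable as true local maxima.
    anchor_t = np.concatenate(([strike_t[0] - t_step], strike_t, [strike_t[-1] + t_step]))
    heel_ap = {}
    for foot in ("left", "right"):
        knots = np.where(np.array(striking_feet) == foot, 0.5 * sl_knots, -0.5 * sl_knots)
        knots = np.concatenate(([-0.5 * sl_knots[0]], knots, [-0.5 * sl_knots[-1]]))
        heel_ap[foot] = np.interp(time, anchor_t, knots)

    # Heel ML: knots only at the foot's own strikes (CoM + StepCoM target).
    heel_ml = {}
    for foot in ("left", "right"):
        own = np.array([f == foot for f in striking_feet])
        own_t = strike_t[own]
        own_v = com[strike_idx[own]] + stepcom[own]
        heel_ml[foot] = np.interp(time, own_t, own_v)

    # CoP: CoM plus a triangle over each inter-strike interval whose area is
    # the stance foot's target integral; triangle vertices lie on the grid.
    cop_rel = np.zeros(n_samples)
    tri_t, tri_v = [time[0]], [0.0]
    for i, _, _, _ in plan:
        mid = (strike_t[i - 1] + strike_t[i]) / 2.0
        tri_t.extend([strike_t[i - 1], mid, strike_t[i]])
        tri_v.extend([0.0, 2.0 * integ[i] / t_step, 0.0])
    cop_rel = np.interp(time, np.array(tri_t), np.array(tri_v))
    cop = com + cop_rel

    trial = GaitTrial(
        time=time,
        heel_ml=heel_ml,
        heel_ap=heel_ap,
        hip_ml=hip_ml,
        hip_ap=hip_ap,
        cop_ml=cop,
        condition=condition,
        belt_speed_slow=spec.belt_speed_slow,
        belt_speed_fast=spec.belt_speed_fast,
    )
    events_truth = pd.DataFrame({"time": strike_t, "foot": striking_feet})
    steps_truth = pd.DataFrame(
        {
            "time": strike_t[1:],
            "stance_foot": [st for _, _, st, _ in plan],
            "step_index": [k for _, _, _, k in plan],
            "CoM": com_knots[1:],
            "intCoPCoM": integ[1:],
            "StepCoM": stepcom[1:],
            "StepLength": sl_knots[1:],
        }
    )
    return trial, events_truth, steps_truth


# ---------------------------------------------------------------------------
# Brain-map simulation


@dataclass(frozen=True)
class BrainSimSpec:
    """Synthetic 3D brain-metric maps with a planted behavioral association.

    The maps stand in for preprocessed voxelwise metrics (gray-matter
    intensity, cerebellar volume, FA skeleton values): a constant baseline,
    a linear effect of the symmetry score inside a planted ROI, additive
    group/sex/TIV nuisance effects, and spatially smoothed Gaussian noise
    whose per-voxel SD is ``noise_sd`` after smoothing.  FWHM is in voxels
    and converts to the Gaussian sigma by 2·sqrt(2·ln 2).
    """

    shape: tuple[int, int, int] = (12, 14, 12)
    roi_halfwidth: int = 1  # planted cube of (2h+1)^3 voxels
    roi_center: tuple[int, int, int] | None = None
    slope: float = 0.05  # metric units per unit symmetry score
    baseline: float = 100.0
    noise_sd: float = 1.0
    noise_fwhm: float = 4.0  # voxels; 0 = white noise
    beta_group: float = -2.0  # old minus young offset
    beta_sex: float = 1.0  # male minus female offset
    beta_tiv: float = 0.005  # per ml about the 1500 ml reference
    voxel_size: float = 2.0  # mm, isotropic
    seed: int = 0

    def __post_init__(self) -> None:
        _check(len(self.shape) == 3 and min(self.shape) >= 3, "shape", "must be 3 dims, each >= 3")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _check(self.noise_fwhm >= 0, "noise_fwhm", "must be >= 0")
        _check(self.roi_halfwidth >= 0, "roi_halfwidth", "must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "BrainSimSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise CohortSpecError(f"{sorted(unknown)[0]}: unknown field")
        data = dict(data)
        for key in ("shape", "roi_center"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def default_mask(self) -> np.ndarray:
        """All voxels except a one-voxel border."""
        mask = np.zeros(self.shape, dtype=bool)
        mask[1:-1, 1:-1, 1:-1] = True
        return mask

    def roi_mask(self, mask: np.ndarray | None = None) -> np.ndarray:
        mask = self.default_mask() if mask is None else mask
        center = self.roi_center or tuple(s // 2 for s in self.shape)
        roi = np.zeros(self.shape, dtype=bool)
        h = self.roi_halfwidth
        if any(c - h < 0 or c + h >= s for c, s in zip(center, self.shape)):
            raise CohortSpecError("roi_center: planted ROI must lie inside the mask")
        roi[
            center[0] - h : center[0] + h + 1,
            center[1] - h : center[1] + h + 1,
            center[2] - h : center[2] + h + 1,
        ] = True
        if not (roi <= mask).all():
            raise CohortSpecError("roi_center: planted ROI must lie inside the mask")
        return roi

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -self.voxel_size * (np.asarray(self.shape) - 1) / 2.0
        return aff


def _smoothing_norm(sigma: float, shape: tuple[int, int, int]) -> float:
    """sqrt of the sum of squared effective kernel weights: the factor by
    which smoothing shrinks the SD of white noise (interior voxels)."""
    delta = np.zeros(shape)
    delta[tuple(s // 2 for s in shape)] = 1.0
    k = gaussian_filter(delta, sigma=sigma)
    return float(np.sqrt((k**2).sum()))


def simulate_brain_maps(
    brain_spec: BrainSimSpec,
    scores: np.ndarray,
    covariates: pd.DataFrame,
    mask: np.ndarray | None = None,
):
    """Generate one masked 3D map per subject with a planted association.

    Parameters
    ----------
    scores:
        Per-subject behavioral symmetry scores (the planted regressor).
    covariates:
        One row per subject with columns ``group`` (young/old), ``sex``
        (F/M) and ``tiv`` (ml), aligned with ``scores``.
    mask:
        Optional analysis mask; defaults to the spec's border-free box.

    Returns
    -------
    (CohortStack, dict)
        The stacked maps and a ground-truth record (ROI mask, slope, and
        the per-subject noiseless ROI signal).
    """
    from gaitbrain.voxelwise import CohortStack

    scores = np.asarray(scores, dtype=float)
    if len(covariates) != scores.size:
        raise ValueError(
            f"mismatched subject counts: {scores.size} scores vs {len(covariates)} covariate rows"
        )
    mask = brain_spec.default_mask() if mask is None else np.asarray(mask, dtype=bool)
    roi = brain_spec.roi_mask(mask)
    n = scores.size
    rng = np.random.default_rng(np.random.SeedSequence(brain_spec.seed))
    group = (covariates["group"].to_numpy() == "old").astype(float)
    sex = (covariates["sex"].to_numpy() == "M").astype(float)
    tiv = covariates["tiv"].to_numpy(dtype=float)

    sigma = brain_spec.noise_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    norm = _smoothing_norm(sigma, brain_spec.shape) if sigma > 0 else 1.0

    data = np.empty((n,) + brain_spec.shape)
    for i in range(n):
        vol = np.full(brain_spec.shape, brain_spec.baseline, dtype=float)
        vol += brain_spec.slope * scores[i] * roi
        vol += (
            brain_spec.beta_group * group[i]
            + brain_spec.beta_sex * sex[i]
            + brain_spec.beta_tiv * (tiv[i] - 1500.0)
        )
        if brain_spec.noise_sd > 0:
            white = rng.standard_normal(brain_spec.shape)
            noise = gaussian_filter(white, sigma=sigma) / norm if sigma > 0 else white
            vol += brain_spec.noise_sd * noise
        data[i] = np.where(mask, vol, 0.0)
    stack = CohortStack(
        data=data,
        mask=mask,
        affine=brain_spec.affine(),
        metric="synthetic_brain_metric",
        subjects=list(covariates.get("subject", pd.Series(range(n)).astype(str))),
    )
    truth = {
        "roi": roi,
        "slope": brain_spec.slope,
        "roi_signal": brain_spec.slope * scores,
    }
    return stack, truth


def make_atlas(
    shape: tuple[int, int, int],
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthetic label volume: the mask split into octants (labels 1-8),
    with a lookup table of label ids and names."""
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    half = [s / 2 for s in shape]
    labels = 1 + (zz >= half[0]) * 4 + (yy >= half[1]) * 2 + (xx >= half[2]) * 1
    labels = np.where(mask, labels, 0).astype(np.int32)
    lookup = pd.DataFrame(
        {"label_id": np.arange(1, 9), "label_name": [f"synthetic octant {i}" for i in range(1, 9)]}
    )
    return labels, lookup


def with_seed(spec, seed: int):
    """Copy of a spec with a different seed (specs are frozen)."""
    return replace(spec, seed=seed)
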