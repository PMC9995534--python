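"""Per-step spatiotemporal gait parameters from marker and CoP trajectories.

A :class:`GaitTrial` holds the mediolateral (ML) and anterior-posterior (AP)
positions of four markers — left/right heel and left/right posterior hip —
plus the ML centre-of-pressure (CoP) trace, for one subject in one treadmill
condition.  The body centre of mass (CoM) is proxied by the midpoint of the
two posterior hip markers.

Four parameters are computed at each heel strike of the swing foot:

* **CoM** (mm, ML): hip-midpoint ML position at the heel strike.
* **intCoPCoM** (mm·s): CoP−CoM ML displacement integrated over the stance
  foot's single-stance interval preceding the strike.
* **StepCoM** (mm, ML): swing-foot heel ML displacement from the CoM.
* **StepLength** (mm, AP): leading minus trailing heel AP position.

Each step record is tagged by the *stance* foot (the foot supporting the body
while the contralateral swing foot lands), which is the foot whose belt
defines the step's speed condition during split-belt walking.

Heel strikes are detected as local maxima of the heel AP position relative to
the hip-midpoint AP position; values at event times are linearly interpolated
between samples, and integrals use the trapezoidal rule on the recorded grid.
Because toe-off is not instrumented, the single-stance interval of the stance
foot is approximated by the inter-strike interval ending at the swing foot's
strike; the first record of a trial integrates over whatever pre-strike
window the recording contains (possibly truncated at the trial start).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "GaitEventError",
    "GaitEvents",
    "GaitTrial",
    "StepRecord",
    "assemble_step_records",
    "compute_com_ml",
    "compute_int_cop_com",
    "compute_step_com",
    "compute_step_length",
    "detect_heel_strikes",
]

FEET = ("left", "right")


class GaitEventError(ValueError):
    """Raised when gait events cannot be detected or are inconsistent."""


@dataclass
class GaitTrial:
    """Time-indexed marker/CoP trajectories for one subject × condition.

    All positions are in millimetres; time in seconds, strictly increasing.
    ``cop_ml`` may be omitted, in which case ``intCoPCoM`` is unavailable.
    """

    time: np.ndarray
    heel_ml: dict[str, np.ndarray]  # foot -> ML trace
    heel_ap: dict[str, np.ndarray]
    hip_ml: dict[str, np.ndarray]  # posterior hip markers, foot side -> ML
    hip_ap: dict[str, np.ndarray]
    cop_ml: np.ndarray | None = None
    condition: str = "split"
    belt_speed_slow: float = 0.7
    belt_speed_fast: float = 1.4

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time must be a 1D vector with >= 2 samples")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time vector must be strictly increasing")
        n = self.time.size
        for group in (self.heel_ml, self.heel_ap, self.hip_ml, self.hip_ap):
            for foot in FEET:
                if foot not in group:
                    raise ValueError(f"missing trajectory for foot {foot!r}")
                group[foot] = np.asarray(group[foot], dtype=float)
                if group[foot].shape != (n,):
                    raise ValueError("all trajectories must match the time vector length")
        if self.cop_ml is not None:
            self.cop_ml = np.asarray(self.cop_ml, dtype=float)
            if self.cop_ml.shape != (n,):
                raise ValueError("CoP trace must match the time vector length")

    @property
    def hip_mid_ml(self) -> np.ndarray:
        """CoM proxy: ML midpoint of the two posterior hip markers."""
        return 0.5 * (self.hip_ml["left"] + self.hip_ml["right"])

    @property
    def hip_mid_ap(self) -> np.ndarray:
        return 0.5 * (self.hip_ap["left"] + self.hip_ap["right"])

    def to_frame(self) -> pd.DataFrame:
        """Wide representation: one column per marker-axis."""
        data = {"time": self.time}
        for foot in FEET:
            data[f"heel_{foot}_ml"] = self.heel_ml[foot]
            data[f"heel_{foot}_ap"] = self.heel_ap[foot]
            data[f"hip_{foot}_ml"] = self.hip_ml[foot]
            data[f"hip_{foot}_ap"] = self.hip_ap[foot]
        if self.cop_ml is not None:
            data["cop_ml"] = self.cop_ml
        return pd.DataFrame(data)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        condition: str = "split",
        belt_speed_slow: float = 0.7,
        belt_speed_fast: float = 1.4,
    ) -> "GaitTrial":
        """Build a trial from the wide CSV layout written by :meth:`to_frame`."""
        return cls(
            time=frame["time"].to_numpy(),
            heel_ml={f: frame[f"heel_{f}_ml"].to_numpy() for f in FEET},
            heel_ap={f: frame[f"heel_{f}_ap"].to_numpy() for f in FEET},
            hip_ml={f: frame[f"hip_{f}_ml"].to_numpy() for f in FEET},
            hip_ap={f: frame[f"hip_{f}_ap"].to_numpy() for f in FEET},
            cop_ml=frame["cop_ml"].to_numpy() if "cop_ml" in frame else None,
            condition=condition,
            belt_speed_slow=belt_speed_slow,
            belt_speed_fast=belt_speed_fast,
        )


@dataclass
class GaitEvents:
    """Ordered heel-strike events, alternating between feet."""

    times: np.ndarray  # strictly increasing strike times (s)
    feet: list[str]  # striking foot per event

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size != len(self.feet):
            raise GaitEventError("event times and feet must align")
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise GaitEventError("event times must be strictly increasing")
        for a, b in zip(self.feet, self.feet[1:]):
            if a == b:
                raise GaitEventError("heel strikes must alternate between feet")

    def __len__(self) -> int:
        return int(self.times.size)

    def times_for(self, foot: str) -> np.ndarray:
        return self.times[[f == foot for f in self.feet]]

    def single_stance_intervals(self) -> list[tuple[float, float, str]]:
        """(start, end, stance_foot) per event; the interval ends at the
        swing foot's strike and starts at the preceding strike.  The first
        event has no preceding strike and is not listed."""
        out = []
        for k in range(1, len(self)):
            stance = "left" if self.feet[k] == "right" else "right"
            out.append((float(self.times[k - 1]), float(self.times[k]), stance))
        return out


@dataclass
class StepRecord:
    """One per-step parameter set, tagged by the stance foot."""

    step_index: int
    stance_foot: str
    com: float
    int_cop_com: float
    step_com: float
    step_length: float
    time: float = field(default=np.nan)


def detect_heel_strikes(trial: GaitTrial, min_prominence_frac: float = 0.1) -> GaitEvents:
    """Detect heel strikes as local maxima of heel AP relative to the hips.

    For each foot the heel's AP position relative to the hip-midpoint AP
    position is scanned for peaks whose prominence exceeds
    ``min_prominence_frac`` of the trace's range.  Events from both feet are
    merged in time order and must alternate.

    Raises
    ------
    GaitEventError
        If no periodic foot motion is detectable (e.g. motionless input), if
        fewer than two strides per foot are present, or if events do not
        alternate between feet.
    """
    hip_ap = trial.hip_mid_ap
    times: list[float] = []
    feet: list[str] = []
    for foot in FEET:
        rel = trial.heel_ap[foot] - hip_ap
        span = float(np.ptp(rel))
        if span < 1e-9:
            raise GaitEventError(f"no gait events: {foot} heel shows no AP excursion")
        peaks, _ = find_peaks(rel, prominence=min_prominence_frac * span)
        if peaks.size < 2:
            raise GaitEventError(f"no gait events: fewer than two strides detected ({foot})")
        times.extend(trial.time[peaks])
        feet.extend([foot] * peaks.size)
    order = np.argsort(times)
    return GaitEvents(np.asarray(times)[order], [feet[i] for i in order])


def _interp_at(trial: GaitTrial, y: np.ndarray, t: np.ndarray | float) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if t.min() < trial.time[0] - 1e-12 or t.max() > trial.time[-1] + 1e-12:
        raise ValueError("event time outside the trial time range")
    return np.interp(t, trial.time, y)


def _integrate_between(time: np.ndarray, y: np.ndarray, t1: float, t2: float) -> float:
    """Trapezoidal integral of sampled ``y`` over [t1, t2] with linear
    interpolation at the interval end points."""
    if t2 <= t1:
        return 0.0
    y1 = float(np.interp(t1, time, y))
    y2 = float(np.interp(t2, time, y))
    inside = (time > t1) & (time < t2)
    tt = np.concatenate(([t1], time[inside], [t2]))
    yy = np.concatenate(([y1], y[inside], [y2]))
    return float(np.trapezoid(yy, tt))


def compute_com_ml(trial: GaitTrial, events: GaitEvents) -> np.ndarray:
    """CoM (hip-midpoint ML, mm) at each heel strike."""
    return _interp_at(trial, trial.hip_mid_ml, events.times)


def compute_step_com(trial: GaitTrial, events: GaitEvents) -> np.ndarray:
    """Swing-foot heel ML minus CoM ML (mm) at each heel strike."""
    com = compute_com_ml(trial, events)
    out = np.empty(len(events))
    for k, (t, foot) in enumerate(zip(events.times, events.feet)):
        out[k] = float(_interp_at(trial, trial.heel_ml[foot], t)[0]) - com[k]
    return out


def compute_step_length(trial: GaitTrial, events: GaitEvents) -> np.ndarray:
    """Leading minus trailing heel AP position (mm) at each heel strike."""
    out = np.empty(len(events))
    for k, (t, foot) in enumerate(zip(events.times, events.feet)):
        other = "left" if foot == "right" else "right"
        lead = float(_interp_at(trial, trial.heel_ap[foot], t)[0])
        trail = float(_interp_at(trial, trial.heel_ap[other], t)[0])
        out[k] = lead - trail
    return out


def compute_int_cop_com(trial: GaitTrial, events: GaitEvents) -> np.ndarray:
    """∫(CoP−CoM) ML displacement (mm·s) over each step's single stance.

    The integral for event ``k`` runs over the inter-strike interval ending
    at event ``k`` (the stance foot's single-stance approximation).  For the
    first event the window starts one median inter-strike interval earlier,
    truncated at the trial start.
    """
    if trial.cop_ml is None:
        raise ValueError("trial has no CoP trace; intCoPCoM is unavailable")
    disp = trial.cop_ml - trial.hip_mid_ml
    out = np.empty(len(events))
    dt_med = float(np.median(np.diff(events.times))) if len(events) > 1 else 0.0
    for k, t in enumerate(events.times):
        t1 = events.times[k - 1] if k > 0 else max(float(trial.time[0]), t - dt_med)
        out[k] = _integrate_between(trial.time, disp, float(t1), float(t))
    return out


def assemble_step_records(trial: GaitTrial, events: GaitEvents) -> pd.DataFrame:
    """One :class:`StepRecord` per heel strike, tagged by stance foot.

    Returns a tidy frame with columns ``step_index`` (1-based, in time
    order), ``stance_foot``, ``time`` and the four parameters ``CoM``,
    ``intCoPCoM``, ``StepCoM`` and ``StepLength``.  ``intCoPCoM`` is NaN when
    the trial carries no CoP trace.
    """
    com = compute_com_ml(trial, events)
    step_com = compute_step_com(trial, events)
    step_len = compute_step_length(trial, events)
    if trial.cop_ml is not None:
        integ = compute_int_cop_com(trial, events)
    else:
        integ = np.full(len(events), np.nan)
    stance = ["left" if f == "right" else "right" for f in events.feet]
    return pd.DataFrame(
        {
            "step_index": np.arange(1, len(events) + 1),
            "stance_foot": stance,
            "time": events.times,
            "CoM": com,
            "intCoPCoM": integ,
            "StepCoM": step_com,
            "StepLength": step_len,
        }
    )
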