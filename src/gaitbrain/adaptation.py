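"""Δ percent-change, between-feet symmetry, and plateau detection.

The behavioral outcome pipeline converts per-foot step series into:

1. **Δ series** — percent change of each step from the mean of the
   baseline-slow steps of the same foot: ``Δ_k = 100·(x_k − b̄)/b̄``.
2. **Symmetry series** — slow-stance Δ minus fast-stance Δ, pairing steps
   by within-condition ordinal; positive values mean the slow-stance foot
   changed more from its slow baseline than the fast-stance foot.
3. **Plateau** — the mean of the final ``n_last`` (default 50) values; the
   series is said to have reached plateau at the first step from which the
   next ``n_consec`` (default 9) consecutive values all stay within
   ``k_sd`` (default 2) standard deviations of the plateau, the SD being
   taken over the same final window.
4. **Magnitude at plateau** — the plateau value of the symmetry series in
   the split condition; this scalar per subject and gait parameter is the
   behavioral regressor for the voxelwise brain-behavior models.

:class:`SplitBeltAdaptation` wraps the whole chain for a tidy step table;
its :meth:`~SplitBeltAdaptation.fit` returns an :class:`AdaptationResults`
with per-subject series, plateau diagnostics and a score table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AdaptationResult",
    "AdaptationResults",
    "DeltaSeries",
    "SplitBeltAdaptation",
    "SymmetrySeries",
    "ZeroBaselineError",
    "detect_plateau",
    "magnitude_at_plateau",
    "percent_change",
    "symmetry_series",
]


class ZeroBaselineError(ValueError):
    """Percent change is undefined for a zero baseline mean."""


@dataclass
class DeltaSeries:
    """Per-step percent change from the baseline-slow mean, for one foot."""

    parameter: str
    foot: str
    values: np.ndarray  # % units
    baseline_mean: float  # raw units

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class SymmetrySeries:
    """Between-feet difference of Δ (slow-stance minus fast-stance), %."""

    parameter: str
    values: np.ndarray
    pairing: str = "ordinal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class AdaptationResult:
    """Plateau diagnostics of one series.

    ``plateau_value`` is always the mean of the final ``n_last`` values;
    ``plateau_step`` is 1-based and equals ``steps_to_plateau`` when the
    criterion was met, otherwise ``reached_plateau`` is false and
    ``steps_to_plateau`` is the series length.
    """

    plateau_value: float
    plateau_step: int | None
    steps_to_plateau: int
    reached_plateau: bool
    band_sd: float
    n_last: int = 50
    n_consec: int = 9
    k_sd: float = 2.0


def percent_change(
    values: np.ndarray,
    baseline_mean: float,
    parameter: str = "",
    foot: str = "",
) -> DeltaSeries:
    """Δ series: ``100·(x − baseline_mean)/baseline_mean`` per step."""
    if baseline_mean == 0 or not np.isfinite(baseline_mean):
        raise ZeroBaselineError(
            f"zero/invalid baseline mean for parameter {parameter!r}, foot {foot!r}"
        )
    values = np.asarray(values, dtype=float)
    return DeltaSeries(parameter, foot, 100.0 * (values - baseline_mean) / baseline_mean, baseline_mean)


def symmetry_series(delta_slow: DeltaSeries, delta_fast: DeltaSeries) -> SymmetrySeries:
    """Slow-stance minus fast-stance Δ, paired by step ordinal.

    Unmatched trailing steps of the longer series are dropped.
    """
    if delta_slow.parameter != delta_fast.parameter:
        raise ValueError(
            f"parameter mismatch: {delta_slow.parameter!r} vs {delta_fast.parameter!r}"
        )
    if delta_slow.values.size == 0 or delta_fast.values.size == 0:
        raise ValueError("both Δ series must be nonempty")
    n = min(delta_slow.values.size, delta_fast.values.size)
    return SymmetrySeries(delta_slow.parameter, delta_slow.values[:n] - delta_fast.values[:n])


def detect_plateau(
    series: np.ndarray,
    n_last: int = 50,
    n_consec: int = 9,
    k_sd: float = 2.0,
) -> AdaptationResult:
    """Plateau value and steps-to-plateau of an ordered series.

    The plateau is the mean of the final ``n_last`` values and the band SD
    their sample standard deviation; scanning forward from the first step,
    the plateau is reached at the earliest step whose next ``n_consec``
    consecutive values (itself included) all lie within ``k_sd`` band SDs of
    the plateau.  A zero band SD collapses the criterion to exact equality.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1D")
    if x.size < n_last:
        raise ValueError(f"series length {x.size} is shorter than n_last={n_last}")
    if x.size < n_consec:
        raise ValueError(f"series length {x.size} is shorter than n_consec={n_consec}")
    tail = x[-n_last:]
    plateau = float(tail.mean())
    sd = float(tail.std(ddof=1)) if n_last > 1 else 0.0
    within = np.abs(x - plateau) <= k_sd * sd
    # first index whose next n_consec values are all within the band
    ok = np.convolve(within.astype(int), np.ones(n_consec, dtype=int), mode="valid") == n_consec
    hits = np.flatnonzero(ok)
    if hits.size:
        step = int(hits[0]) + 1  # 1-based
        return AdaptationResult(plateau, step, step, True, sd, n_last, n_consec, k_sd)
    return AdaptationResult(plateau, None, int(x.size), False, sd, n_last, n_consec, k_sd)


def magnitude_at_plateau(sym: SymmetrySeries, result: AdaptationResult) -> float:
    """The symmetry value at plateau: the plateau (last-``n_last`` mean) of
    the symmetry series itself — the behavioral regressor."""
    del sym  # the plateau is computed on the symmetry series by the caller
    return result.plateau_value


# ---------------------------------------------------------------------------
# Model / Results


@dataclass
class SubjectAdaptation:
    """Per-subject, per-parameter behavioral outcome."""

    subject: str
    parameter: str
    delta_slow: DeltaSeries
    delta_fast: DeltaSeries
    symmetry: SymmetrySeries
    result: AdaptationResult
    magnitude: float


@dataclass
class AdaptationResults:
    """Fitted behavioral outcomes for a cohort.

    ``scores`` has one row per subject × parameter with the
    magnitude-at-plateau symmetry score, steps-to-plateau and the
    reached-plateau flag; ``detail`` maps (subject, parameter) to the full
    per-step series.
    """

    scores: pd.DataFrame
    detail: dict[tuple[str, str], SubjectAdaptation] = field(repr=False, default_factory=dict)
    model: "SplitBeltAdaptation | None" = field(repr=False, default=None)

    def scores_wide(self) -> pd.DataFrame:
        """One row per subject, one ``sym_<parameter>`` column per score."""
        wide = self.scores.pivot(index="subject", columns="parameter", values="magnitude_at_plateau")
        wide.columns = [f"sym_{c}" for c in wide.columns]
        meta_cols = [c for c in ("group", "sex", "age", "tiv") if c in self.scores.columns]
        if meta_cols:
            meta = self.scores.drop_duplicates("subject").set_index("subject")[meta_cols]
            wide = meta.join(wide)
        return wide.reset_index()

    def summary(self) -> str:
        """Group-stratified mean ± SD of each symmetry score."""
        lines = ["Split-belt adaptation summary (magnitude-at-plateau symmetry, %)", ""]
        if "group" in self.scores.columns:
            grouped = self.scores.groupby(["parameter", "group"])["magnitude_at_plateau"]
        else:
            grouped = self.scores.groupby(["parameter"])["magnitude_at_plateau"]
        stats = grouped.agg(["mean", "std", "count"])
        lines.append(f"{'parameter':<12} {'group':<8} {'n':>4} {'mean±SD':>16}")
        for idx, row in stats.iterrows():
            param, group = idx if isinstance(idx, tuple) else (idx, "all")
            lines.append(
                f"{param:<12} {group:<8} {int(row['count']):>4} "
                f"{row['mean']:>8.1f}±{row['std']:<6.1f}"
            )
        reached = self.scores["reached_plateau"].mean() * 100
        lines.append("")
        lines.append(f"Series reaching plateau: {reached:.0f}%")
        return "\n".join(lines)

    def plot(self, subject: str, parameter: str, ax=None):
        """Symmetry series with the plateau band and detected plateau step."""
        import matplotlib.pyplot as plt

        sub = self.detail[(subject, parameter)]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3.5))
        values = sub.symmetry.values
        ax.plot(np.arange(1, values.size + 1), values, lw=0.6, color="0.4", label="symmetry")
        res = sub.result
        ax.axhline(res.plateau_value, color="C0", label=f"plateau {res.plateau_value:.1f}%")
        ax.axhspan(
            res.plateau_value - res.k_sd * res.band_sd,
            res.plateau_value + res.k_sd * res.band_sd,
            color="C0",
            alpha=0.15,
        )
        if res.reached_plateau:
            ax.axvline(res.plateau_step, color="C3", ls="--", label=f"step {res.plateau_step}")
        ax.set_xlabel("split step")
        ax.set_ylabel(f"{parameter} symmetry (Δ %, slow − fast)")
        ax.set_title(subject)
        ax.legend(frameon=False, fontsize=8)
        return ax


class SplitBeltAdaptation:
    """Behavioral model of split-belt adaptation for a cohort.

    Parameters
    ----------
    steps:
        Tidy step table with columns ``subject, condition, foot,
        step_index, parameter, value`` (a ``group`` column is carried
        through when present).
    covariates:
        Optional per-subject table merged into the score output.
    slow_foot:
        The foot on the slow belt during the split condition (right, per
        the standard assignment with the left belt fast).
    n_last, n_consec, k_sd:
        Plateau rule parameters (last-window mean, run length, band width).
    """

    def __init__(
        self,
        steps: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        parameters: tuple[str, ...] | None = None,
        slow_foot: str = "right",
        baseline_condition: str = "baseline_slow",
        split_condition: str = "split",
        n_last: int = 50,
        n_consec: int = 9,
        k_sd: float = 2.0,
    ) -> None:
        required = {"subject", "condition", "foot", "step_index", "parameter", "value"}
        missing = required - set(steps.columns)
        if missing:
            raise ValueError(f"steps table is missing columns: {sorted(missing)}")
        self.steps = steps
        self.covariates = covariates
        self.parameters = parameters or tuple(steps["parameter"].unique())
        self.slow_foot = slow_foot
        self.fast_foot = "left" if slow_foot == "right" else "right"
        self.baseline_condition = baseline_condition
        self.split_condition = split_condition
        self.n_last = n_last
        self.n_consec = n_consec
        self.k_sd = k_sd

    @classmethod
    def from_csv(cls, steps_path, covariates_path=None, **kwargs) -> "SplitBeltAdaptation":
        steps = pd.read_csv(steps_path)
        cov = pd.read_csv(covariates_path, sep="\t") if covariates_path else None
        return cls(steps, covariates=cov, **kwargs)

    def _series(self, sub: pd.DataFrame, condition: str, foot: str, parameter: str) -> np.ndarray:
        sel = sub[
            (sub["condition"] == condition)
            & (sub["foot"] == foot)
            & (sub["parameter"] == parameter)
        ].sort_values("step_index")
        return sel["value"].to_numpy()

    def fit(self) -> AdaptationResults:
        """Run Δ → symmetry → plateau → magnitude for every subject and
        parameter; only the split condition's symmetry score is scored."""
        detail: dict[tuple[str, str], SubjectAdaptation] = {}
        rows = []
        meta_cols = [c for c in ("group",) if c in self.steps.columns]
        for subject, sub in self.steps.groupby("subject", sort=False):
            meta = {c: sub[c].iloc[0] for c in meta_cols}
            for parameter in self.parameters:
                deltas = {}
                for foot in (self.slow_foot, self.fast_foot):
                    base = self._series(sub, self.baseline_condition, foot, parameter)
                    split = self._series(sub, self.split_condition, foot, parameter)
                    if base.size == 0 or split.size == 0:
                        raise ValueError(
                            f"missing {self.baseline_condition}/{self.split_condition} steps for "
                            f"subject {subject!r}, foot {foot!r}, parameter {parameter!r}"
                        )
                    deltas[foot] = percent_change(split, float(base.mean()), parameter, foot)
                sym = symmetry_series(deltas[self.slow_foot], deltas[self.fast_foot])
                res = detect_plateau(sym.values, self.n_last, self.n_consec, self.k_sd)
                mag = magnitude_at_plateau(sym, res)
                detail[(str(subject), parameter)] = SubjectAdaptation(
                    str(subject), parameter, deltas[self.slow_foot], deltas[self.fast_foot], sym, res, mag
                )
                rows.append(
                    {
                        "subject": subject,
                        **meta,
                        "parameter": parameter,
                        "magnitude_at_plateau": mag,
                        "steps_to_plateau": res.steps_to_plateau,
                        "reached_plateau": res.reached_plateau,
                    }
                )
        scores = pd.DataFrame(rows)
        if self.covariates is not None:
            extra = [c for c in self.covariates.columns if c not in scores.columns or c == "subject"]
            scores = scores.merge(self.covariates[extra], on="subject", how="left")
        return AdaptationResults(scores=scores, detail=detail, model=self)
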