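"""Gait-parameter extraction: event detection, per-step values, round trip."""

import numpy as np
import pytest

from gaitbrain.cohort import CohortSpec, simulate_marker_trial
from gaitbrain.gait import (
    GaitEventError,
    GaitEvents,
    GaitTrial,
    assemble_step_records,
    compute_com_ml,
    compute_int_cop_com,
    compute_step_com,
    compute_step_length,
    detect_heel_strikes,
)


def _flat_trial(n=500, dt=0.01, cop=True, **overrides):
    """A minimal hand-built trial; defaults are motionless markers."""
    time = np.arange(n) * dt
    z = np.zeros(n)
    traces = {
        "heel_ml": {"left": z.copy(), "right": z.copy()},
        "heel_ap": {"left": z.copy(), "right": z.copy()},
        "hip_ml": {"left": z.copy(), "right": z.copy()},
        "hip_ap": {"left": z.copy(), "right": z.copy()},
        "cop_ml": z.copy() if cop else None,
    }
    traces.update(overrides)
    return GaitTrial(time=time, **traces)


@pytest.fixture(scope="module")
def synthetic_trial(small_spec):
    trial, events_truth, steps_truth = simulate_marker_trial(
        small_spec, "YA01", "split", n_steps=12
    )
    return trial, events_truth, steps_truth


class TestEventDetection:
    def test_detected_times_match_ground_truth(self, synthetic_trial):
        """Detected heel strikes fall within half the inter-sample interval
        of the generator's ground-truth event times."""
        trial, events_truth, _ = synthetic_trial
        events = detect_heel_strikes(trial)
        assert len(events) == len(events_truth)
        dt = float(np.diff(trial.time).mean())
        np.testing.assert_allclose(events.times, events_truth["time"], atol=dt / 2)
        assert events.feet == events_truth["foot"].tolist()

    def test_motionless_trial_raises(self):
        with pytest.raises(GaitEventError, match="no gait events"):
            detect_heel_strikes(_flat_trial())

    def test_reversed_time_raises(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _flat_trial()  # sanity: builds fine forward
            GaitTrial(
                time=np.arange(100)[::-1] * 0.01,
                heel_ml={"left": np.zeros(100), "right": np.zeros(100)},
                heel_ap={"left": np.zeros(100), "right": np.zeros(100)},
                hip_ml={"left": np.zeros(100), "right": np.zeros(100)},
                hip_ap={"left": np.zeros(100), "right": np.zeros(100)},
            )

    def test_non_alternating_events_rejected(self):
        with pytest.raises(GaitEventError, match="alternate"):
            GaitEvents(np.array([0.5, 1.0, 1.5]), ["left", "left", "right"])


class TestParameterDefinitions:
    def test_com_is_hip_midpoint(self):
        """Hip markers at ML 100 and 140 mm give CoM = 120 mm."""
        tr = _flat_trial(
            hip_ml={"left": np.full(500, 100.0), "right": np.full(500, 140.0)}
        )
        ev = GaitEvents(np.array([1.0, 2.0]), ["left", "right"])
        np.testing.assert_allclose(compute_com_ml(tr, ev), [120.0, 120.0])

    def test_com_symmetric_markers_zero(self):
        tr = _flat_trial(hip_ml={"left": np.full(500, -30.0), "right": np.full(500, 30.0)})
        ev = GaitEvents(np.array([1.0]), ["left"])
        assert compute_com_ml(tr, ev)[0] == 0.0

    def test_event_interpolation_matches_linear_oracle(self):
        """On a linear trajectory, the value at an off-sample event time
        equals the exact line evaluated there."""
        n, dt = 500, 0.01
        slope, intercept = 7.3, -2.0
        line = intercept + slope * np.arange(n) * dt
        tr = _flat_trial(hip_ml={"left": line, "right": line})
        t_exact, t_between = 1.0, 1.0037
        ev = GaitEvents(np.array([t_exact, t_between]), ["left", "right"])
        got = compute_com_ml(tr, ev)
        np.testing.assert_allclose(got, intercept + slope * np.array([t_exact, t_between]),
                                   rtol=1e-12)

    def test_event_outside_trial_range(self):
        tr = _flat_trial()
        ev = GaitEvents(np.array([999.0]), ["left"])
        with pytest.raises(ValueError, match="outside"):
            compute_com_ml(tr, ev)

    def test_step_com_displacement_and_sign(self):
        """Heel at 150 mm with CoM 120 mm gives +30; a medial heel flips sign."""
        tr = _flat_trial(
            hip_ml={"left": np.full(500, 100.0), "right": np.full(500, 140.0)},
            heel_ml={"left": np.full(500, 150.0), "right": np.full(500, 90.0)},
        )
        ev = GaitEvents(np.array([1.0, 2.0]), ["left", "right"])
        np.testing.assert_allclose(compute_step_com(tr, ev), [30.0, -30.0])

    def test_step_length_trailing_to_leading(self):
        """Trailing heel at −300, leading at +400 → step length 700 mm."""
        tr = _flat_trial(
            heel_ap={"left": np.full(500, 400.0), "right": np.full(500, -300.0)}
        )
        ev = GaitEvents(np.array([1.0]), ["left"])
        assert compute_step_length(tr, ev)[0] == pytest.approx(700.0)
        ev_r = GaitEvents(np.array([1.0]), ["right"])
        assert compute_step_length(tr, ev_r)[0] == pytest.approx(-700.0)

    def test_step_length_heels_level_is_zero(self):
        tr = _flat_trial(heel_ap={"left": np.full(500, 50.0), "right": np.full(500, 50.0)})
        ev = GaitEvents(np.array([1.0]), ["left"])
        assert compute_step_length(tr, ev)[0] == 0.0


class TestIntCoPCoM:
    def test_constant_displacement_rectangle(self):
        """Constant 50 mm CoP−CoM displacement over a 0.6 s stance → 30 mm·s."""
        tr = _flat_trial(cop_ml=np.full(500, 50.0))
        ev = GaitEvents(np.array([1.0, 1.6]), ["left", "right"])
        got = compute_int_cop_com(tr, ev)
        assert got[1] == pytest.approx(30.0)

    def test_zero_displacement_zero_integral(self):
        tr = _flat_trial()
        ev = GaitEvents(np.array([1.0, 1.6]), ["left", "right"])
        np.testing.assert_allclose(compute_int_cop_com(tr, ev), 0.0)

    def test_linear_ramp_matches_fine_grid_quadrature(self):
        """A 0→50 mm ramp over 0.6 s integrates to 15 mm·s, agreeing with an
        independent fine-grid quadrature."""
        n, dt = 500, 0.01
        time = np.arange(n) * dt
        ramp = np.clip((time - 1.0) / 0.6, 0, None) * 50.0
        ramp[time > 1.6] = 0.0
        tr = _flat_trial(cop_ml=ramp)
        ev = GaitEvents(np.array([1.0, 1.6]), ["left", "right"])
        got = compute_int_cop_com(tr, ev)[1]
        fine_t = np.linspace(1.0, 1.6, 20001)
        oracle = np.trapezoid(np.interp(fine_t, time, ramp), fine_t)
        assert got == pytest.approx(15.0, rel=1e-3)
        assert got == pytest.approx(oracle, rel=1e-9)

    def test_missing_cop_trace_raises(self):
        tr = _flat_trial(cop=False)
        ev = GaitEvents(np.array([1.0, 1.6]), ["left", "right"])
        with pytest.raises(ValueError, match="CoP"):
            compute_int_cop_com(tr, ev)


class TestAssembly:
    def test_count_conservation_and_ordering(self, synthetic_trial):
        trial, _, _ = synthetic_trial
        events = detect_heel_strikes(trial)
        records = assemble_step_records(trial, events)
        assert len(records) == len(events)
        assert list(records["step_index"]) == list(range(1, len(events) + 1))
        assert records["time"].is_monotonic_increasing
        n_left = (records["stance_foot"] == "left").sum()
        n_right = (records["stance_foot"] == "right").sum()
        assert abs(n_left - n_right) <= 1

    def test_roundtrip_zero_noise_matches_generator_truth(self, small_spec):
        """Parameters re-extracted from a zero-noise synthetic trial match
        the generator's step-level ground truth to 1e-6 relative tolerance."""
        for condition in ("split", "baseline_slow"):
            trial, _, steps_truth = simulate_marker_trial(
                small_spec, "OA01", condition, n_steps=10
            )
            events = detect_heel_strikes(trial)
            records = assemble_step_records(trial, events)
            got = records.iloc[1:].reset_index(drop=True)  # lead-in strike has no truth
            assert got["stance_foot"].tolist() == steps_truth["stance_foot"].tolist()
            for col in ("CoM", "intCoPCoM", "StepCoM", "StepLength"):
                scale = np.abs(steps_truth[col].to_numpy()).max()
                np.testing.assert_allclose(
                    got[col].to_numpy(), steps_truth[col].to_numpy(), atol=1e-6 * scale
                )

    def test_missing_cop_gives_nan_integral_only(self):
        spec = CohortSpec(n_young=1, n_old=1, step_noise_sd=0.0, seed=2)
        trial, _, _ = simulate_marker_trial(spec, "YA01", "split", n_steps=4)
        trial.cop_ml = None
        records = assemble_step_records(trial, detect_heel_strikes(trial))
        assert records["intCoPCoM"].isna().all()
        assert records[["CoM", "StepCoM", "StepLength"]].notna().all().all()
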