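"""Pacing, APD90 and the paired-clamp membrane-resistance protocol."""

import numpy as np
import pytest

from cardiofit.ionic_model import linear_leak_model
from cardiofit.protocols import (APTrace, ClampSpec, InfiniteResistanceError,
                                 NoCrossingError, NoRepolarizationError,
                                 SubthresholdStimulusError, apd90, measure_rm,
                                 pace, quiescent_baseline,
                                 rm_delay_sensitivity, rm_slope)


class TestAPTrace:
    def test_rejects_nonuniform_grid(self):
        with pytest.raises(ValueError):
            APTrace(np.array([0.0, 1.0, 3.0]), np.zeros(3))

    def test_csv_round_trip(self, tmp_path, paced_control):
        f = tmp_path / "trace.csv"
        paced_control.trace.to_csv(f)
        back = APTrace.from_csv(f, stim_times=paced_control.trace.stim_times)
        assert np.allclose(back.times, paced_control.trace.times)
        assert np.allclose(back.voltages, paced_control.trace.voltages)

    def test_json_round_trip(self, tmp_path):
        tr = APTrace(np.arange(5.0), np.linspace(-80, 20, 5), np.array([0.0]))
        f = tmp_path / "trace.json"
        tr.to_json(f)
        back = APTrace.from_json(f)
        assert np.allclose(back.voltages, tr.voltages)
        assert np.allclose(back.stim_times, tr.stim_times)


class TestPace:
    def test_final_beat_returns_to_rest_near_minus_86(self, paced_control):
        # diastolic V of the paced control model
        assert paced_control.trace.voltages[-1] == pytest.approx(-86.0, abs=0.5)
        assert paced_control.t_beat == 3000.0

    def test_zero_amplitude_stimulus_is_subthreshold(self, model, control):
        with pytest.raises(SubthresholdStimulusError):
            pace(model, control, duration=2000.0, stim_amp=0.0)

    def test_consecutive_beats_have_converged_apd(self, model, control):
        """After long pacing, successive APD90s differ by well under 1%."""
        nine = pace(model, control, duration=9000.0)
        ten = pace(model, control, duration=10000.0)
        a9, a10 = apd90(nine.trace), apd90(ten.trace)
        assert abs(a10 - a9) / a9 < 0.01


class TestApd90:
    def test_rectangular_pulse_has_analytic_duration(self):
        t = np.arange(0.0, 400.0, 1.0)
        v = np.where((t >= 50) & (t < 250), 0.0, -85.0)
        tr = APTrace(t, v)
        assert apd90(tr) == pytest.approx(200.0, abs=1.0)

    def test_monotone_ramp_has_no_upstroke(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(NoRepolarizationError):
            apd90(APTrace(t, np.linspace(-85, -80, len(t))))

    def test_control_apd_in_physiological_band(self, paced_control):
        assert 250.0 <= apd90(paced_control.trace) <= 330.0


class TestRmSlope:
    def test_two_point_slope(self):
        assert rm_slope(10.0, 2.0, -10.0, 0.0) == pytest.approx(10.0)

    def test_antisymmetric_currents(self):
        assert rm_slope(10.0, 1.0, -10.0, -1.0) == pytest.approx(10.0)

    def test_branch_swap_leaves_slope_unchanged(self):
        assert rm_slope(-10.0, -1.3, 10.0, 2.1) == rm_slope(10.0, 2.1, -10.0, -1.3)

    def test_flat_slope_raises_or_returns_sentinel(self):
        with pytest.raises(InfiniteResistanceError):
            rm_slope(10.0, 1.0, -10.0, 1.0)
        assert np.isinf(rm_slope(10.0, 1.0, -10.0, 1.0, sentinel=np.inf))


class TestLinearLeakOracle:
    """For a purely ohmic membrane the protocol must return exactly 1/g."""

    @pytest.mark.parametrize("g", [0.05, 0.1, 1.0, 4.0])
    @pytest.mark.parametrize("onset,delay,delta",
                             [(10.0, 5.0, 10.0), (40.0, 2.0, 10.0),
                              (25.0, 5.0, 1.0)])
    def test_rm_equals_inverse_conductance(self, g, onset, delay, delta):
        m = linear_leak_model(g)
        base = quiescent_baseline(m, None, duration=60.0)
        meas = measure_rm(m, None, base, ClampSpec(
            onset_time=onset, delta_v=delta, duration=delay, delay=delay))
        assert meas.r_m == pytest.approx(1.0 / g, rel=1e-6)


class TestMeasureRmTNNP:
    def test_measurement_is_deterministic(self, model, control, paced_control):
        a = measure_rm(model, control, paced_control, ClampSpec(onset_time=3050.0))
        b = measure_rm(model, control, paced_control, ClampSpec(onset_time=3050.0))
        assert a == b

    def test_reference_voltage_matches_trace(self, model, control,
                                             paced_control_fine):
        m = measure_rm(model, control, paced_control_fine,
                       ClampSpec(onset_time=3050.0))
        v_trace = paced_control_fine.trace.resample([3050.0])[0]
        assert m.v_ref == pytest.approx(v_trace, abs=0.1)

    def test_smaller_steps_converge_to_differential_resistance(
            self, model, control, paced_control):
        """Shrinking delta_v stabilizes the estimate (finite-difference
        consistency at diastole, where the I-V relation is smooth)."""
        rm = {d: measure_rm(model, control, paced_control,
                            ClampSpec(onset_time=3350.0, delta_v=d)).r_m
              for d in (10.0, 5.0, 2.0, 1.0)}
        assert abs(rm[2.0] - rm[1.0]) < abs(rm[10.0] - rm[1.0])
        assert abs(rm[5.0] - rm[1.0]) < abs(rm[10.0] - rm[1.0])

    def test_voltage_onset_lands_on_requested_voltage(self, model, control,
                                                      paced_control_fine):
        m = measure_rm(model, control, paced_control_fine,
                       ClampSpec(onset_voltage=-59.87))
        assert m.v_ref == pytest.approx(-59.87, abs=0.5)

    def test_unreachable_voltage_raises(self, model, control, paced_control):
        with pytest.raises(NoCrossingError):
            measure_rm(model, control, paced_control,
                       ClampSpec(onset_voltage=80.0))


class TestDelaySensitivity:
    def test_identical_delays_give_zero_percent_error(self, model, control,
                                                      paced_control):
        clamps = [ClampSpec(onset_time=t) for t in (3050.0, 3320.0)]
        sens = rm_delay_sensitivity(model, control, paced_control, clamps,
                                    delays=(5.0, 5.0))
        assert np.allclose(sens.table["percent_error"], 0.0)

    def test_empty_clamp_list_rejected(self, model, control, paced_control):
        with pytest.raises(ValueError):
            rm_delay_sensitivity(model, control, paced_control, [])
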