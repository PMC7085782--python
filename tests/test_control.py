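"""Controller: current LUT, ATC-matrix updates, moving median, pulse shape."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atcfes import (
    ControlState,
    build_current_matrix,
    build_fes_command,
    lookup_currents,
    median_index,
    synthesize_pulse_waveform,
    update_control,
)
from atcfes.control import InvalidCalibrationError, SafetyError
from atcfes.signals import InvalidParameterError


@pytest.fixture
def lut10():
    return build_current_matrix(10, 20.0)


class TestCurrentLUT:
    def test_noise_gate_and_linear_ramp(self, lut10):
        levels = lut10.levels_ma[0]
        assert levels[0] == levels[1] == 0.0
        assert levels[5] == pytest.approx(10.0)
        assert levels[10] == pytest.approx(20.0)

    def test_levels_non_decreasing(self, lut10):
        levels = np.array(lut10.levels_ma[0])
        assert np.all(np.diff(levels) >= 0)

    def test_atc_max_below_gate_rejected(self):
        with pytest.raises(InvalidCalibrationError):
            build_current_matrix(1, 20.0)


class TestControlState:
    def test_zeros_stay_zero(self):
        s = update_control(ControlState.zeros(2), [0, 0])
        assert np.all(s.atc_matrix == 0)

    def test_ring_buffer_shift(self):
        s = ControlState(atc_matrix=np.array([[1, 2, 3, 4]]))
        s2 = update_control(s, [5])
        np.testing.assert_array_equal(s2.atc_matrix, [[2, 3, 4, 5]])
        # pure update: original untouched
        np.testing.assert_array_equal(s.atc_matrix, [[1, 2, 3, 4]])

    def test_channel_count_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            update_control(ControlState.zeros(2), [1, 2, 3])

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            update_control(ControlState.zeros(1), [-1])


class TestMedianLookup:
    @pytest.mark.parametrize("row, expected_idx", [
        ([0, 0, 0, 0], 0),
        ([3, 5, 4, 6], 5),     # median 4.5 rounds half-up
        ([40, 40, 40, 40], 10),  # clamped to atc_max
    ])
    def test_median_index(self, lut10, row, expected_idx):
        s = ControlState(atc_matrix=np.array([row]))
        assert median_index(s, lut10)[0] == expected_idx

    @pytest.mark.parametrize("idx, expected_ma", [(0, 0.0), (1, 0.0), (7, 14.0)])
    def test_lookup(self, lut10, idx, expected_ma):
        assert lookup_currents(lut10, [idx])[0] == pytest.approx(expected_ma)

    @given(st.lists(st.lists(st.integers(0, 30), min_size=4, max_size=4),
                    min_size=2, max_size=2))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_pointwise_dominance_preserved(self, rows):
        """A channel with pointwise >= counts gets >= amplitude."""
        lut = build_current_matrix([10, 10], [20.0, 20.0])
        lo, hi = rows
        hi = [max(a, b) for a, b in zip(lo, hi)]
        s = ControlState(atc_matrix=np.array([lo, hi]))
        amps = lookup_currents(lut, median_index(s, lut))
        assert amps[1] >= amps[0]

    def test_noise_gateway_blocks_low_medians(self, lut10):
        """Count streams whose 4-window medians never exceed 1 never stimulate."""
        s = ControlState.zeros(1)
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = update_control(s, [int(rng.integers(0, 2))])  # counts in {0,1}
            amps = lookup_currents(lut10, median_index(s, lut10))
            assert amps[0] == 0.0

    def test_step_response_settling(self, lut10):
        """A sustained count step crosses the median after 2 updates and
        settles once 3 of the 4 buffer entries carry the new value."""
        s = ControlState(atc_matrix=np.array([[8, 8, 8, 8]]))
        old = lookup_currents(lut10, median_index(s, lut10))[0]
        target = lookup_currents(lut10, median_index(
            ControlState(atc_matrix=np.array([[2, 2, 2, 2]])), lut10))[0]
        amps = []
        for _ in range(3):
            s = update_control(s, [2])
            amps.append(lookup_currents(lut10, median_index(s, lut10))[0])
        assert target < amps[1] < old  # after 2 updates: middle-pair mean
        assert amps[2] == pytest.approx(target)  # settled after 3

    def test_amplitude_never_exceeds_i_max_randomized(self, lut10):
        rng = np.random.default_rng(1)
        s = ControlState.zeros(1)
        for _ in range(300):
            s = update_control(s, [int(rng.integers(0, 60))])
            amps = lookup_currents(lut10, median_index(s, lut10))
            cmd = build_fes_command(amps, i_max_ma=[20.0])
            assert cmd.amplitudes_ma[0] <= 20.0


class TestFESCommand:
    def test_zero_amplitude_valid(self):
        cmd = build_fes_command([0.0])
        assert cmd.amplitudes_ma == (0.0,)

    def test_interphase_fixed_at_150us(self):
        assert build_fes_command([5.0]).interphase_us == 150.0

    def test_amplitude_clamped_to_calibrated_limit(self):
        cmd = build_fes_command([40.0], i_max_ma=[20.0])
        assert cmd.amplitudes_ma[0] == pytest.approx(20.0)

    @pytest.mark.parametrize("kwargs", [
        dict(frequency_hz=500.0), dict(phase_width_us=5000.0),
    ])
    def test_out_of_bounds_parameters_rejected(self, kwargs):
        with pytest.raises(SafetyError):
            build_fes_command([5.0], **kwargs)


class TestPulseWaveform:
    FS = 1_000_000.0

    def test_zero_amplitude_all_zero(self):
        cmd = build_fes_command([0.0])
        wave = synthesize_pulse_waveform(cmd, self.FS, 0.1)
        assert np.all(wave == 0.0)

    def test_charge_balance_per_period(self):
        cmd = build_fes_command([10.0])
        period_n = int(self.FS / cmd.frequency_hz)
        wave = synthesize_pulse_waveform(cmd, self.FS, 1.0 / cmd.frequency_hz)
        assert wave.size == period_n
        assert abs(wave.sum()) / (10.0 * period_n) < 1e-12

    def test_interphase_gap_150us(self):
        cmd = build_fes_command([10.0])
        wave = synthesize_pulse_waveform(cmd, self.FS, 1.0 / cmd.frequency_hz)
        pos_end = np.flatnonzero(wave > 0)[-1]
        neg_start = np.flatnonzero(wave < 0)[0]
        gap_us = (neg_start - pos_end - 1) / self.FS * 1e6
        assert gap_us == pytest.approx(150.0, abs=1e6 / self.FS)

    def test_unresolvable_width_rejected(self):
        cmd = build_fes_command([10.0])
        with pytest.raises(InvalidParameterError):
            synthesize_pulse_waveform(cmd, 10_000.0, 0.01)
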