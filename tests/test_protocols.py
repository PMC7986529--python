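"""Trigger detection, threshold calibration and stimulus scheduling."""

import numpy as np
import pytest

from ifnet.params import SimulationParams
from ifnet.protocols import (
    ProtocolSpec,
    calibrate_trigger_threshold,
    deliver_conditioning,
    detect_cycle_trigger,
    detect_spike_trigger,
    detect_threshold_trigger,
    preset,
    schedule_tetanic,
)


class TestSpikeTrigger:
    def test_silent_unit_yields_no_triggers(self, sim):
        spec = preset("spike_triggered")
        assert detect_spike_trigger(np.empty(0, np.int64), spec, sim).size == 0

    def test_lockout_suppresses_close_spikes(self, sim):
        spec = preset("spike_triggered", lockout=10.0)
        spikes = np.array([0, 50, 120, 1000, 1050])     # steps (0.1 ms each)
        trig = detect_spike_trigger(spikes, spec, sim)
        assert trig.tolist() == [0, 120, 1000]          # 10 ms = 100 steps


class TestThresholdTrigger:
    def test_constant_signal_never_triggers(self):
        assert detect_threshold_trigger(np.full(1000, 2.0), 1.0).size == 0
        assert detect_threshold_trigger(np.full(1000, 0.0), 1.0).size == 0

    def test_sine_crossings_both_edges(self, sim):
        t = np.arange(0, 1.0, 1e-4)     # 1 s at 10 kHz
        x = np.sin(2 * np.pi * 5 * t)   # 5 Hz
        rising = detect_threshold_trigger(x, 0.5, "rising")
        falling = detect_threshold_trigger(x, 0.5, "falling")
        assert rising.size == 5 and falling.size == 5
        assert np.all(falling > rising)     # each falling follows its rising

    def test_lockout_enforced(self):
        x = np.tile([0.0, 1.0], 500)        # crossing every 2 samples
        trig = detect_threshold_trigger(x, 0.5, "rising", lockout_steps=10)
        assert np.all(np.diff(trig) >= 10)

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_threshold_trigger(np.zeros(10), np.nan)


class TestCalibration:
    def test_bisection_hits_target_rate(self, sim, rng):
        x = rng.normal(0, 1.0, size=600_000)    # 60 s of noise at 10 kHz
        thr = calibrate_trigger_threshold(x, 6.0, sim, lockout_steps=200)
        rate = detect_threshold_trigger(x, thr, "rising", 200).size / 60.0
        assert rate == pytest.approx(6.0, rel=0.10)

    def test_zero_target_disables_triggering(self, sim, rng):
        x = rng.normal(0, 1.0, size=10_000)
        thr = calibrate_trigger_threshold(x, 0.0, sim)
        assert detect_threshold_trigger(x, thr).size == 0

    def test_doubling_target_halves_intervals(self, sim, rng):
        x = rng.normal(0, 1.0, size=600_000)
        t6 = calibrate_trigger_threshold(x, 6.0, sim)
        t12 = calibrate_trigger_threshold(x, 12.0, sim)
        assert t12 < t6
        med6 = np.median(np.diff(detect_threshold_trigger(x, t6)))
        med12 = np.median(np.diff(detect_threshold_trigger(x, t12)))
        assert med12 < med6

    def test_unreachable_rate_raises(self, sim):
        with pytest.raises(ValueError):
            calibrate_trigger_threshold(np.zeros(10_000), 50.0, sim)


class TestCycleTrigger:
    def make_beta(self, sim, f=20.0, amp=1.0, n_cycles=8, pad_ms=200.0):
        pad = round(pad_ms / sim.h)
        t = np.arange(0, n_cycles / f * 1000.0, sim.h) * 1e-3
        sig = amp * np.sin(2 * np.pi * f * t)
        return np.concatenate([np.zeros(pad), sig, np.zeros(pad)]), pad

    def test_phase_zero_stimulates_at_rising_crossing(self, sim):
        y, pad = self.make_beta(sim)
        cross, stim, edge, offset = detect_cycle_trigger(y, 0.5, 0.0, sim)
        assert edge == +1 and offset == 0
        assert np.array_equal(cross, stim)
        # rising zero crossings of the sine occur at full periods (50 ms)
        rel = (stim - pad) * sim.h
        assert np.allclose(rel % 50.0, 0.0, atol=0.2) or np.allclose(
            50.0 - rel % 50.0, 0.0, atol=0.2
        )

    def test_phase_180_uses_falling_crossing(self, sim):
        y, pad = self.make_beta(sim)
        cross, stim, edge, offset = detect_cycle_trigger(y, 0.5, 180.0, sim)
        assert edge == -1 and offset == 0
        rel = (cross - pad) * sim.h % 50.0
        assert np.allclose(rel, 25.0, atol=0.2)     # half period after rising

    def test_intermediate_phase_offsets(self, sim):
        y, _ = self.make_beta(sim)
        _, stim90, _, off90 = detect_cycle_trigger(y, 0.5, 90.0, sim)
        assert off90 == round(90.0 / 360.0 * 50.0 / sim.h)
        _, _, edge, off345 = detect_cycle_trigger(y, 0.5, -15.0, sim)
        assert edge == -1                               # (345 mod 360) >= 180
        assert off345 == round(165.0 / 360.0 * 50.0 / sim.h)

    def test_triggers_only_during_episode(self, sim):
        y, pad = self.make_beta(sim, n_cycles=6)
        cross, _, _, _ = detect_cycle_trigger(y, 0.5, 0.0, sim)
        assert cross.size >= 5
        assert cross.min() >= pad
        assert cross.max() <= y.size - pad + round(75.0 / sim.h)


class TestTetanic:
    def test_zero_rate_is_empty(self, rng):
        assert schedule_tetanic(0.0, 10.0, 10_000.0, rng).size == 0

    def test_rate_and_refractory(self, rng):
        times = schedule_tetanic(10.0, 10.0, 500_000.0, rng)
        rate = times.size / 500.0
        se = np.sqrt(10.0 / 500.0)
        assert abs(rate - 10.0) < 3 * se
        assert np.min(np.diff(times)) >= 10.0

    def test_rate_refractory_product_validated(self, rng):
        with pytest.raises(ValueError):
            schedule_tetanic(200.0, 10.0, 1000.0, rng)


class TestDeliverConditioning:
    def test_paired_pulse_emits_both_columns(self, sim):
        spec = preset("paired_pulse", delay=10.0)
        steps, cols, amps, trunc = deliver_conditioning(
            spec, np.array([100.0]), 10_000.0, sim
        )
        assert trunc == 0
        assert steps.tolist() == [1000, 1100]
        assert cols.tolist() == [0, 1]          # A then B
        assert np.all(amps == 2000.0)

    def test_negative_delay_reverses_order(self, sim):
        spec = preset("paired_pulse", delay=-30.0)
        steps, cols, _, _ = deliver_conditioning(spec, np.array([100.0]), 10_000.0, sim)
        assert cols[np.argmin(steps)] == 1      # B fires first

    def test_triplets_at_33ms_spacing(self, sim):
        spec = preset("paired_triplet", delay=10.0)
        steps, cols, _, _ = deliver_conditioning(spec, np.array([100.0]), 10_000.0, sim)
        a = np.sort(steps[cols == 0]) * sim.h
        assert np.allclose(np.diff(a), 33.0)
        assert steps.size == 6

    def test_truncation_counted(self, sim):
        spec = preset("spike_triggered", delay=10.0)
        _, _, _, trunc = deliver_conditioning(spec, np.array([9995.0]), 10_000.0, sim)
        assert trunc == 1

    def test_inhibition_preset_is_negative(self):
        assert preset("spike_triggered_inhibition").amplitude == -2000.0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(variant="nope")
        with pytest.raises(KeyError):
            preset("nope")
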