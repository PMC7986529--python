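"""STDP curve, trace dynamics and weight updates against a pairwise oracle."""

import numpy as np
import pytest

from ifnet.params import PlasticityParams, SimulationParams, with_step
from ifnet.plasticity import (
    TraceArrays,
    apply_weight_updates,
    clip_weight,
    stdp_curve,
    step_traces,
    strength_from_weight,
    weight_from_strength,
)


class TestStdpCurve:
    def test_zero_interval_gives_zero(self, plast):
        assert stdp_curve(0.0, plast) == 0.0

    def test_reference_values(self, plast):
        # direct evaluation of the two-lobe curve at +-10 ms
        assert stdp_curve(10.0, plast) == pytest.approx(
            100.0 * (np.exp(-10 / 15.4) - np.exp(-5.0)), abs=1e-12
        )
        assert stdp_curve(10.0, plast) == pytest.approx(51.56, abs=0.01)
        assert stdp_curve(-10.0, plast) == pytest.approx(
            -55.0 * (np.exp(-10 / 33.3) - np.exp(-5.0)), abs=1e-12
        )
        assert stdp_curve(-10.0, plast) == pytest.approx(-40.36, abs=0.01)

    def test_signs_and_vectorization(self, plast):
        dt = np.linspace(-80, 80, 401)
        y = stdp_curve(dt, plast)
        assert np.all(y[dt > 0] > 0)
        assert np.all(y[dt < 0] < 0)


class TestTraces:
    def test_pure_decay_without_spikes(self, sim, plast):
        tr = TraceArrays(4)
        tr.s_slow[:] = 1.0
        tr.t_slow[:] = 2.0
        zero = np.zeros(4)
        step_traces(tr, zero, zero, plast, sim)
        assert np.allclose(tr.s_slow, 1 - sim.h / plast.a_s)
        assert np.allclose(tr.t_slow, 2 * (1 - sim.h / plast.b_s))

    def test_impulse_response_matches_curve(self, sim, plast):
        """r * S_j(t) after one arrival equals the strengthening lobe at t."""
        tr = TraceArrays(1)
        one = np.ones(1)
        zero = np.zeros(1)
        step_traces(tr, zero, one, plast, sim)   # arrival at t=0
        n10 = round(10.0 / sim.h)
        for _ in range(n10):
            step_traces(tr, zero, zero, plast, sim)
        # Euler discretization error is O(h)
        assert plast.r * tr.s[0] == pytest.approx(stdp_curve(10.0, plast), rel=0.03)


def pairwise_oracle(pre_arrivals, posts, plast):
    """Brute-force double sum of the STDP curve over all (post, pre) pairs."""
    total = 0.0
    for tp in posts:
        for ta in pre_arrivals:
            total += stdp_curve(tp - ta, plast)
    return total


def trace_based_dw(pre_arrivals, posts, plast, sim, w0=500.0, n_ms=400.0):
    """Accumulate Eq.-style trace updates step by step on one connection."""
    n_steps = round(n_ms / sim.h)
    pre_steps = {round(t / sim.h) for t in pre_arrivals}
    post_steps = {round(t / sim.h) for t in posts}
    tr = TraceArrays(2)       # unit 0: source, unit 1: target
    w = np.array([[0.0, 0.0], [w0, 0.0]])     # w[1,0]: 0 -> 1
    plastic = np.zeros((2, 2), dtype=bool)
    plastic[1, 0] = True
    big = PlasticityParams(max_strength=1e9, w_min=1e-9)   # avoid clipping
    dw = 0.0
    for t in range(n_steps):
        arr = np.array([1.0 if t in pre_steps else 0.0, 0.0])
        now = np.array([0.0, 1.0 if t in post_steps else 0.0])
        before = w[1, 0]
        apply_weight_updates(w, plastic, tr, now, arr, big, sim)
        dw += w[1, 0] - before
        step_traces(tr, now, arr, plast, sim)
    return dw


class TestPairwiseOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_trace_updates_equal_brute_force_sum(self, seed, sim, plast):
        """Cumulative trace-based dw equals the pairwise curve sum within 1%.

        The error is normalized by the gross pairwise magnitude
        (sum over pairs of |STDP|): opposite-sign pairs can cancel in the net
        sum, so a net-relative bound is ill-posed for arbitrary spike sets.
        """
        rng = np.random.default_rng(seed)
        pre = np.sort(rng.uniform(0, 150, size=rng.integers(1, 10)))
        post = np.sort(rng.uniform(0, 150, size=rng.integers(1, 10)))
        pre = np.round(pre, 1)     # on the step grid
        post = np.round(post, 1)
        expected = pairwise_oracle(pre, post, plast)
        gross = sum(
            abs(stdp_curve(tp - ta, plast)) for tp in post for ta in pre
        )
        got = trace_based_dw(pre, post, plast, sim)
        assert abs(got - expected) <= 0.01 * max(gross, 1.0)

    def test_discretization_error_shrinks_with_h(self, plast):
        pre = np.array([10.0, 30.0, 52.0])
        post = np.array([18.0, 40.0, 47.0])
        expected = pairwise_oracle(pre, post, plast)
        errs = []
        for h in (0.1, 0.05, 0.025):
            sim = with_step(SimulationParams(), h)
            errs.append(abs(trace_based_dw(pre, post, plast, sim) - expected))
        assert errs[2] < errs[1] < errs[0]


class TestWeightUpdates:
    def test_no_spikes_leaves_weights_unchanged(self, sim, plast):
        w = np.array([[0.0, 200.0], [0.0, 0.0]])
        plastic = w != 0
        before = w.copy()
        tr = TraceArrays(2)
        tr.s_slow[:] = 5.0
        apply_weight_updates(w, plastic, tr, np.zeros(2), np.zeros(2), plast, sim)
        assert np.array_equal(w, before)

    def test_clipping_holds_at_w_max(self, sim, plast):
        w_max = plast.w_max(sim)
        w = np.array([[0.0, 0.0], [w_max, 0.0]])
        plastic = w != 0
        tr = TraceArrays(2)
        tr.s_slow[0] = 3.0     # strong positive source trace
        apply_weight_updates(
            w, plastic, tr, np.array([0, 1]), np.zeros(2), plast, sim
        )
        assert w[1, 0] == w_max

    def test_inhibitory_connection_strengthens_in_magnitude(self, sim, plast):
        w = np.array([[0.0, 0.0], [-200.0, 0.0]])
        plastic = w != 0
        tr = TraceArrays(2)
        tr.s_slow[0] = 1.0     # pre arrived ~recently, post fires now
        apply_weight_updates(
            w, plastic, tr, np.array([0, 1]), np.zeros(2), plast, sim
        )
        assert w[1, 0] < -200.0     # same STDP rule: |w| grows

    def test_sign_never_flips_under_any_updates(self, sim, plast, rng):
        w = np.array([[0.0, -150.0], [150.0, 0.0]])
        plastic = w != 0
        tr = TraceArrays(2)
        for _ in range(500):
            tr.s_slow[:] = rng.uniform(0, 5, 2)
            tr.t_slow[:] = rng.uniform(0, 5, 2)
            now = (rng.random(2) < 0.3).astype(float)
            arr = (rng.random(2) < 0.3).astype(float)
            apply_weight_updates(w, plastic, tr, now, arr, plast, sim)
            assert w[0, 1] <= -plast.w_min
            assert w[1, 0] >= plast.w_min


class TestClipAndStrength:
    def test_clip_examples(self, sim, plast):
        assert clip_weight(0.5, +1, plast, sim) == 1.0
        assert clip_weight(2 * plast.w_max(sim), +1, plast, sim) == plast.w_max(sim)
        assert clip_weight(-0.5, -1, plast, sim) == -1.0
        with pytest.raises(ValueError):
            clip_weight(1.0, 0, plast, sim)

    def test_strength_weight_roundtrip(self, sim, plast):
        assert strength_from_weight(plast.w_max(sim), sim) == pytest.approx(500.0)
        assert strength_from_weight(0.0, sim) == 0.0
        # initial 100-300 uV strengths map to weights ~[211.7, 635.0]
        assert weight_from_strength(100.0, sim) == pytest.approx(211.65, abs=0.05)
        assert weight_from_strength(300.0, sim) == pytest.approx(634.96, abs=0.05)
        w = np.array([10.0, -400.0])
        back = weight_from_strength(strength_from_weight(w, sim), sim)
        assert np.allclose(back, np.abs(w))
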