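"""Trace-based spike-timing-dependent plasticity.

The STDP curve is a pair of exponential-difference lobes: presynaptic spike
arrival before a postsynaptic spike (dt >= 0) strengthens, the reverse order
weakens, with the weakening lobe lower in amplitude but slower to decay so
that its area exceeds the strengthening area at default parameters.  Rather
than scanning spike pairs, each source unit carries a strengthening trace
``S_j`` (incremented by delayed spike arrivals) and each target unit a
weakening trace ``T_i`` (incremented by its own spikes); a weight update
reads the traces at spike events:

    dw_ij = r * sgn(w_ij) * (S_j * U_i(t) - c * T_i * U_j(t - d))

``r`` and ``c`` are applied only here, not in the trace increments, so an
isolated pre/post pair reproduces the curve exactly.  Updates are clipped
hard to [w_min, w_max] (excitatory) or [-w_max, -w_min] (inhibitory); the
sign of a weight can never flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import PlasticityParams, SimulationParams

__all__ = [
    "TraceArrays",
    "stdp_curve",
    "step_traces",
    "apply_weight_updates",
    "clip_weight",
    "strength_from_weight",
    "weight_from_strength",
]


def stdp_curve(delta_t, params: PlasticityParams):
    """STDP weight change for post-minus-pre-arrival interval ``delta_t`` (ms).

    Positive intervals (pre arrival before post spike) strengthen:
    ``r (e^{-dt/a_s} - e^{-dt/a_f})``; negative intervals weaken:
    ``-c r (e^{dt/b_s} - e^{dt/b_f})``.  Vectorized over ``delta_t``.
    """
    dt = np.asarray(delta_t, dtype=float)
    if not np.all(np.isfinite(dt)):
        raise ValueError("delta_t must be finite")
    pos = params.r * (np.exp(-dt / params.a_s) - np.exp(-dt / params.a_f))
    neg = -params.c * params.r * (np.exp(dt / params.b_s) - np.exp(dt / params.b_f))
    out = np.where(dt >= 0, pos, neg)
    return out if out.ndim else float(out)


@dataclass
class TraceArrays:
    """Per-unit strengthening (source) and weakening (target) accumulators.

    Twin-integrator pairs identical in form to the membrane accumulators but
    never reset by threshold crossings.
    """

    n_units: int
    s_slow: np.ndarray = field(init=False)
    s_fast: np.ndarray = field(init=False)
    t_slow: np.ndarray = field(init=False)
    t_fast: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name in ("s_slow", "s_fast", "t_slow", "t_fast"):
            setattr(self, name, np.zeros(self.n_units))

    @property
    def s(self) -> np.ndarray:
        """Strengthening trace S_j = S^s_j - S^f_j."""
        return self.s_slow - self.s_fast

    @property
    def t(self) -> np.ndarray:
        """Weakening trace T_i = T^s_i - T^f_i."""
        return self.t_slow - self.t_fast


def step_traces(
    traces: TraceArrays,
    spikes_now: np.ndarray,
    spikes_delayed: np.ndarray,
    plast: PlasticityParams,
    sim: SimulationParams,
) -> TraceArrays:
    """Advance all four trace components by one step.

    Source components decay by ``(1 - h/a)`` and increment by the *delayed*
    spike indicator (arrival times); target components decay by
    ``(1 - h/b)`` and increment by the current spike indicator.
    """
    h = sim.h
    traces.s_slow = (1.0 - h / plast.a_s) * traces.s_slow + spikes_delayed
    traces.s_fast = (1.0 - h / plast.a_f) * traces.s_fast + spikes_delayed
    traces.t_slow = (1.0 - h / plast.b_s) * traces.t_slow + spikes_now
    traces.t_fast = (1.0 - h / plast.b_f) * traces.t_fast + spikes_now
    return traces


def clip_weight(w, sign: int, plast: PlasticityParams, sim: SimulationParams):
    """Hard clip to [w_min, w_max] (excitatory) or [-w_max, -w_min] (inhibitory)."""
    if sign not in (+1, -1):
        raise ValueError("connection sign must be +1 or -1 (never zero)")
    w_max = plast.w_max(sim)
    if sign > 0:
        return np.clip(w, plast.w_min, w_max)
    return np.clip(w, -w_max, -plast.w_min)


def apply_weight_updates(
    w: np.ndarray,
    plastic: np.ndarray,
    traces: TraceArrays,
    spikes_now: np.ndarray,
    spikes_delayed: np.ndarray,
    plast: PlasticityParams,
    sim: SimulationParams,
) -> np.ndarray:
    """One step of the STDP update on a target-major weight matrix, in place.

    Trace values are read *before* this step's increments, so a coincident
    pre-arrival/post-spike contributes neither lobe (the curve is zero at
    dt = 0).  Only plastic, existing connections are touched.
    """
    u_post = np.asarray(spikes_now, dtype=bool)
    u_pre = np.asarray(spikes_delayed, dtype=bool)
    if not (u_post.any() or u_pre.any()):
        return w
    n = w.shape[0]
    sgn = np.sign(w)
    dw = np.zeros_like(w)
    if u_post.any():
        dw[u_post, :] += plast.r * traces.s[None, :n]
    if u_pre.any():
        dw[:, u_pre] -= plast.r * plast.c * traces.t[:n, None]
    upd = plastic & (dw != 0.0)
    w_max = plast.w_max(sim)
    w_new = w + sgn * dw
    pos = upd & (sgn > 0)
    neg = upd & (sgn < 0)
    w[pos] = np.clip(w_new[pos], plast.w_min, w_max)
    w[neg] = np.clip(w_new[neg], -w_max, -plast.w_min)
    return w


def strength_from_weight(w, sim: SimulationParams) -> np.ndarray:
    """Connection strength (PSP maximum, uV) of a weight: ``|w| k*``."""
    _, k_star = sim.psp_peak()
    return np.abs(w) * k_star


def weight_from_strength(strength, sim: SimulationParams) -> np.ndarray:
    """Absolute weight producing a given PSP maximum (uV)."""
    _, k_star = sim.psp_peak()
    return np.asarray(strength, dtype=float) / k_star
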