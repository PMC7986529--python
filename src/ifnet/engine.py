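"""Reference fixed-step engine for the twin-integrator unit model.

Each unit carries two leaky accumulators ``v_slow`` and ``v_fast`` receiving
identical synaptic input ``A_i(t)``; the membrane potential is their
difference and a spike is emitted when it strictly exceeds the threshold,
after which both accumulators are zero on the next step.  Within-step order:

1. gather delayed spikes and external events into ``A(t)``;
2. evaluate ``U(t)`` from the current potential;
3. advance the accumulators by forward Euler (reset wins over input);
4. apply any stimulus steps (after the reset, so they are never swallowed).

This module is deliberately straightforward; the production path is the
compiled kernel in :mod:`ifnet.kernels`, which is held to agree with this
implementation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SimulationParams

__all__ = [
    "NetworkState",
    "StimulusEvent",
    "accumulate_input",
    "step_network",
    "apply_stimulus",
    "psp_peak_factor",
    "psp_kernel",
]


def psp_peak_factor(params: SimulationParams) -> tuple[float, float]:
    """Closed-form PSP peak time (ms) and peak amplitude per unit weight."""
    return params.psp_peak()


def psp_kernel(t_ms: np.ndarray, params: SimulationParams, weight: float = 1.0) -> np.ndarray:
    """Continuous-time PSP waveform ``w (e^{-t/tau_s} - e^{-t/tau_f})`` for t >= 0."""
    t = np.asarray(t_ms, dtype=float)
    out = weight * (np.exp(-t / params.tau_s) - np.exp(-t / params.tau_f))
    return np.where(t >= 0, out, 0.0)


@dataclass
class StimulusEvent:
    """Direct stimulation: an immediate step in V decaying with tau_s."""

    step: int
    target_units: np.ndarray    # int indices
    amplitude: float            # uV; negative models inhibition

    def __post_init__(self) -> None:
        self.target_units = np.asarray(self.target_units, dtype=np.int64)
        if not np.isfinite(self.amplitude):
            raise ValueError("stimulus amplitude must be finite")


@dataclass
class NetworkState:
    """Per-unit accumulators plus the spike-history ring buffer."""

    n_units: int
    params: SimulationParams
    v_slow: np.ndarray = field(init=False)
    v_fast: np.ndarray = field(init=False)
    spike_now: np.ndarray = field(init=False)
    spike_history: np.ndarray = field(init=False)   # (depth, n_units) binary
    t: int = 0

    def __post_init__(self) -> None:
        self.v_slow = np.zeros(self.n_units)
        self.v_fast = np.zeros(self.n_units)
        self.spike_now = np.zeros(self.n_units, dtype=np.uint8)
        depth = max(self.params.d_cortical_steps, self.params.d_motor_steps) + 1
        self.spike_history = np.zeros((depth, self.n_units), dtype=np.uint8)

    @property
    def v(self) -> np.ndarray:
        """Membrane potential V = v_slow - v_fast (uV)."""
        return self.v_slow - self.v_fast

    def delayed_spikes(self, delay_steps: int) -> np.ndarray:
        """U(t - d) for the given delay; zero before the history is populated."""
        depth = self.spike_history.shape[0]
        if delay_steps >= depth:
            raise ValueError("requested delay exceeds ring-buffer depth")
        return self.spike_history[(self.t - delay_steps) % depth]


def accumulate_input(
    state: NetworkState,
    weights: np.ndarray,
    external: np.ndarray | None,
    params: SimulationParams,
    motor_targets: np.ndarray | None = None,
) -> np.ndarray:
    """Synaptic input ``A_i(t) = E_i(t) + sum_j U_j(t - d_ij) w_ij``.

    ``weights`` is target-major (``w[i, j]``).  Cortical targets read the
    spike history at the cortical delay; targets flagged in ``motor_targets``
    read it at the motor delay.
    """
    n = state.n_units
    if weights.shape != (n, n):
        raise ValueError("weight matrix shape mismatch")
    u_c = state.delayed_spikes(params.d_cortical_steps).astype(float)
    a = weights @ u_c
    if motor_targets is not None and motor_targets.any():
        u_m = state.delayed_spikes(params.d_motor_steps).astype(float)
        a[motor_targets] = weights[motor_targets] @ u_m
    if external is not None:
        ext = np.asarray(external, dtype=float)
        if not np.all(np.isfinite(ext)):
            raise ValueError("non-finite external input")
        a = a + ext
    return a


def step_network(
    state: NetworkState,
    a: np.ndarray,
    params: SimulationParams,
    thresholds: np.ndarray | float | None = None,
) -> np.ndarray:
    """Evaluate U(t) from the current potential, then advance the accumulators.

    Returns the spike vector U(t).  Spiking units have both accumulators set
    to exactly zero at t+h (reset overrides input accumulation); all others
    decay by ``(1 - h/tau)`` and receive ``A(t)``.
    """
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite synaptic input")
    theta = params.theta if thresholds is None else thresholds
    u = (state.v > theta).astype(np.uint8)
    cs = 1.0 - params.h / params.tau_s
    cf = 1.0 - params.h / params.tau_f
    fired = u.astype(bool)
    state.v_slow = np.where(fired, 0.0, cs * state.v_slow + a)
    state.v_fast = np.where(fired, 0.0, cf * state.v_fast + a)
    depth = state.spike_history.shape[0]
    state.spike_history[state.t % depth] = u
    state.spike_now = u
    state.t += 1
    return u


def apply_stimulus(state: NetworkState, event: StimulusEvent) -> None:
    """Add the stimulus amplitude to v_slow of the targets (v_fast untouched).

    Produces an immediate step in V at the next evaluation, decaying with
    tau_s; negative amplitudes deflect V away from threshold.
    """
    if event.target_units.size and (
        event.target_units.min() < 0 or event.target_units.max() >= state.n_units
    ):
        raise ValueError("stimulus targets outside the unit range")
    state.v_slow[event.target_units] += event.amplitude
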