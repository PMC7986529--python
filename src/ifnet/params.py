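"""Scalar parameter containers for the integrate-and-fire conditioning model.

All membrane-potential quantities are stored internally in microvolts (uV);
configuration values quoted in millivolts are converted once at construction.
Temporal quantities are in milliseconds unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "SimulationParams",
    "PlasticityParams",
    "BiasConfig",
    "EpisodeSpec",
    "MV",
    "ALLOWED_STEPS",
]

#: conversion factor mV -> uV
MV = 1000.0

#: published step sizes (ms) accepted by default validation
ALLOWED_STEPS = (0.1, 0.05, 0.025, 0.02, 0.01)


@dataclass(frozen=True)
class SimulationParams:
    """Time base, membrane kinetics, thresholds and conduction delays.

    The unit potential is the difference of two leaky integrators sharing the
    same synaptic input and decaying with ``tau_s`` (slow) and ``tau_f``
    (fast); a spike is emitted when the difference strictly exceeds ``theta``
    and both integrators are reset to zero on the following step.
    """

    h: float = 0.1                 # time step (ms)
    theta: float = 5.0 * MV        # firing threshold (uV)
    tau_s: float = 3.2             # slow PSP decay constant (ms)
    tau_f: float = 0.8             # fast PSP decay constant (ms)
    d_cortical: float = 3.0        # cortex -> cortex conduction delay (ms)
    d_motor: float = 10.0          # cortex -> motoneuron conduction delay (ms)
    block_length: float = 10.0     # scheduling block (s)
    refractory: float = 0.0        # optional absolute refractory (ms), off by default
    strict_step_set: bool = True   # restrict h to ALLOWED_STEPS

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("h must be positive")
        if self.strict_step_set and not any(
            math.isclose(self.h, v, rel_tol=1e-9) for v in ALLOWED_STEPS
        ):
            raise ValueError(f"h={self.h} not in the validated set {ALLOWED_STEPS}")
        if not (self.tau_s > self.tau_f > 0):
            raise ValueError("require tau_s > tau_f > 0")
        if self.h >= self.tau_f:
            raise ValueError("Euler stability requires h < tau_f")
        for name in ("d_cortical", "d_motor"):
            d = getattr(self, name)
            steps = d / self.h
            if abs(steps - round(steps)) > 1e-9:
                raise ValueError(f"{name}={d} ms is not an integer multiple of h={self.h}")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")

    # --- derived step counts -------------------------------------------------
    @property
    def d_cortical_steps(self) -> int:
        return round(self.d_cortical / self.h)

    @property
    def d_motor_steps(self) -> int:
        return round(self.d_motor / self.h)

    @property
    def steps_per_block(self) -> int:
        return round(self.block_length * 1000.0 / self.h)

    def psp_peak(self) -> tuple[float, float]:
        """Peak time (ms) and peak amplitude per unit weight of the PSP kernel.

        The kernel ``g(t) = exp(-t/tau_s) - exp(-t/tau_f)`` is stationary at
        ``t* = tau_s*tau_f/(tau_s-tau_f) * ln(tau_s/tau_f)``; the returned
        ``k* = g(t*)`` converts a weight into a connection strength (the PSP
        maximum, in uV per unit weight).
        """
        ts, tf = self.tau_s, self.tau_f
        if ts <= tf:
            raise ValueError("degenerate PSP kernel: tau_s must exceed tau_f")
        t_star = ts * tf / (ts - tf) * math.log(ts / tf)
        k_star = math.exp(-t_star / ts) - math.exp(-t_star / tf)
        return t_star, k_star


@dataclass(frozen=True)
class PlasticityParams:
    """Trace-based STDP rule parameters.

    The asymmetric weight-change curve is
    ``r (exp(-dt/a_s) - exp(-dt/a_f))`` for pre-before-post (dt >= 0) and
    ``-c r (exp(dt/b_s) - exp(dt/b_f))`` for post-before-pre (dt < 0),
    accumulated through per-unit strengthening/weakening traces.  ``r`` and
    ``c`` scale the update only once, at weight-change time; the traces
    themselves integrate unit impulses.
    """

    r: float = 100.0               # training factor
    c: float = 0.55                # weakening factor
    a_s: float = 15.4              # strengthening trace slow decay (ms)
    a_f: float = 2.0               # strengthening trace fast decay (ms)
    b_s: float = 33.3              # weakening trace slow decay (ms)
    b_f: float = 2.0               # weakening trace fast decay (ms)
    w_min: float = 1.0             # minimum absolute weight (weight units)
    max_strength: float = 500.0    # maximum connection strength (uV), sets w_max
    squash_enabled: bool = False   # graded weight-change squashing hook (off)

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("training factor r must be positive")
        if self.c < 0:
            raise ValueError("weakening factor c must be >= 0")
        if not (self.a_s > self.a_f > 0):
            raise ValueError("require a_s > a_f > 0")
        if not (self.b_s > self.b_f > 0):
            raise ValueError("require b_s > b_f > 0")
        if self.w_min <= 0 or self.max_strength <= 0:
            raise ValueError("w_min and max_strength must be positive")
        if self.squash_enabled:
            raise NotImplementedError("graded squashing hook is provided but disabled")

    def w_max(self, sim: SimulationParams) -> float:
        """Maximum absolute weight derived from the maximum PSP strength."""
        _, k_star = sim.psp_peak()
        w = self.max_strength / k_star
        if not self.w_min < w:
            raise ValueError("w_min must be smaller than w_max")
        return w

    def strengthening_area(self) -> float:
        """Integral of the strengthening lobe of the STDP curve, r*(a_s - a_f)."""
        return self.r * (self.a_s - self.a_f)

    def weakening_area(self) -> float:
        """Integral magnitude of the weakening lobe, c*r*(b_s - b_f)."""
        return self.c * self.r * (self.b_s - self.b_f)


@dataclass(frozen=True)
class BiasConfig:
    """External excitatory bias drive to one cortical column.

    A fraction of the total per-unit rate arrives as column-wide *correlated*
    events: the column draws an event, and every unit receives one delivery at
    the event time plus Gaussian jitter.  The remainder arrives as independent
    *uncorrelated* per-unit events.  Every delivery evokes a standard PSP of
    peak amplitude ``event_strength`` uV.
    """

    total_rate: float = 1800.0       # events/s per unit
    correlated_fraction: float = 0.30
    jitter_sd: float = 3.0           # ms
    event_strength: float = 350.0    # PSP peak (uV)
    motoneuron_rate: float = 1000.0  # uncorrelated events/s per motoneuron

    def __post_init__(self) -> None:
        if self.total_rate < 0 or self.motoneuron_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.correlated_fraction <= 1.0:
            raise ValueError("correlated_fraction must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    def correlated_event_rate(self) -> float:
        """Column-level correlated event rate (events/s)."""
        return self.total_rate * self.correlated_fraction

    def uncorrelated_rate(self) -> float:
        """Per-unit uncorrelated event rate (events/s)."""
        return self.total_rate * (1.0 - self.correlated_fraction)

    def step_probabilities(self, sim: SimulationParams) -> tuple[float, float]:
        """Per-step Bernoulli probabilities (correlated column event, uncorrelated per unit)."""
        dt_s = sim.h * 1e-3
        p_c = self.correlated_event_rate() * dt_s
        p_u = self.uncorrelated_rate() * dt_s
        if p_c > 1.0 or p_u > 1.0:
            raise ValueError("event probability exceeds 1 at this h; lower the rate or h")
        return p_c, p_u


@dataclass(frozen=True)
class EpisodeSpec:
    """Oscillatory bias-modulation episodes (beta bursts) within each block."""

    frequency: float = 20.0        # Hz
    cycles: int = 6                # oscillation cycles per episode
    episodes_per_block: int = 4
    depth: float = 0.5             # modulation depth (fraction of baseline rate)
    column: str = "B"              # modulated column

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.depth < 0:
            raise ValueError("modulation depth must be >= 0")
        if self.episodes_per_block < 1:
            raise ValueError("episodes_per_block must be >= 1")

    @property
    def duration_ms(self) -> float:
        return self.cycles / self.frequency * 1000.0

    def onsets_ms(self, block_length_s: float) -> list[float]:
        """Episode onset times within a block, evenly spaced."""
        block_ms = block_length_s * 1000.0
        n = self.episodes_per_block
        return [block_ms * (2 * k + 1) / (2 * n) - self.duration_ms / 2.0 for k in range(n)]


def with_step(params: SimulationParams, h: float) -> SimulationParams:
    """Return a copy of ``params`` with a different time step."""
    return replace(params, h=h)
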