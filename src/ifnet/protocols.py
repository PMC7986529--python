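"""Conditioning protocols: trigger detection, calibration and scheduling.

Eight paradigms are supported.  Closed-loop variants (spike-, EMG-, gamma-
and cycle-triggered, and spike-triggered inhibition) detect triggers online
inside the simulation kernel; this module carries their declarative
specification, the offline (oracle) detectors used for analysis and testing,
threshold calibration, and the open-loop schedules (paired-pulse trains,
tetanic Poisson trains).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .params import MV, SimulationParams

__all__ = [
    "ProtocolSpec",
    "TriggerLog",
    "VARIANTS",
    "detect_spike_trigger",
    "detect_threshold_trigger",
    "detect_cycle_trigger",
    "calibrate_trigger_threshold",
    "schedule_tetanic",
    "deliver_conditioning",
    "design_trigger_filter",
    "preset",
]

VARIANTS = (
    "none",
    "spike_triggered",
    "spike_triggered_inhibition",
    "emg_triggered",
    "paired_pulse",
    "cycle_triggered",
    "gamma_triggered",
    "tetanic",
)


@dataclass(frozen=True)
class ProtocolSpec:
    """Declarative description of one conditioning paradigm."""

    variant: str = "none"
    trigger_unit: int = 0            # spike-triggered: unit index (Ae1 = 0)
    trigger_column: str = "A"        # column whose signal (EMG/LFP) is monitored
    target_column: str = "B"         # stimulated column
    delay: float = 10.0              # trigger -> stimulus delay (ms); paired: signed
    amplitude: float = 2.0 * MV      # stimulus amplitude (uV); negative = inhibition
    train: int = 1                   # pulses per stimulus
    train_interval: float = 33.0     # intra-train interval (ms)
    lockout: float = 0.0             # minimum inter-trigger interval (ms)
    band: tuple[float, float] | None = None   # trigger band edges (Hz)
    edge: str = "rising"             # threshold-crossing direction
    target_rate: float = 6.0         # calibrated trigger rate (1/s) for EMG/gamma
    phase: float = 0.0               # cycle-triggered stimulation phase (deg)
    rate: float = 10.0               # tetanic Poisson rate (Hz)
    refractory: float = 10.0         # tetanic refractory (ms)
    repetition_rate: float = 1.4     # paired-pulse repetitions (Hz)
    duty_cycle: float | None = None  # fraction of each block with triggering active

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown protocol variant {self.variant!r}")
        if self.train < 1:
            raise ValueError("train length must be >= 1")
        if self.delay < 0 and self.variant != "paired_pulse":
            raise ValueError("negative delays are only meaningful for paired_pulse")
        if self.edge not in ("rising", "falling"):
            raise ValueError("edge must be 'rising' or 'falling'")


@dataclass
class TriggerLog:
    """Trigger and stimulus bookkeeping for one run."""

    trigger_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    counts_per_period: list[int] = field(default_factory=list)
    truncated: int = 0


def design_trigger_filter(band: tuple[float, float], sim: SimulationParams) -> np.ndarray:
    """Causal second-order Butterworth band-pass (SOS) on the step grid.

    Second order per band edge.  The filter's group delay is part of the
    closed loop: triggers lag the underlying population event by roughly the
    inverse bandwidth, which is what places stimulus-evoked spikes after the
    presynaptic volley that generated the trigger.
    """
    fs = 1000.0 / sim.h
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError("band edge above Nyquist for the chosen h")
    return sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")


def detect_spike_trigger(
    spike_steps: np.ndarray, spec: ProtocolSpec, sim: SimulationParams
) -> np.ndarray:
    """Trigger steps from a unit's spike train, subject to the lockout."""
    lock = round(spec.lockout / sim.h)
    if lock <= 0:
        return np.asarray(spike_steps, dtype=np.int64)
    out = []
    last = -(1 << 60)
    for s in np.asarray(spike_steps, dtype=np.int64):
        if s - last >= lock:
            out.append(s)
            last = s
    return np.asarray(out, dtype=np.int64)


def detect_threshold_trigger(
    sig: np.ndarray,
    threshold: float,
    edge: str = "rising",
    lockout_steps: int = 0,
) -> np.ndarray:
    """Steps where ``sig`` crosses ``threshold`` in the given direction.

    Matches the online detector: a rising trigger fires where the previous
    sample is below and the current at-or-above threshold; crossings within
    ``lockout_steps`` of the previous trigger are suppressed.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    x = np.asarray(sig, dtype=float)
    if edge == "rising":
        hits = np.flatnonzero((x[:-1] < threshold) & (x[1:] >= threshold)) + 1
    else:
        hits = np.flatnonzero((x[:-1] > threshold) & (x[1:] <= threshold)) + 1
    if lockout_steps <= 0:
        return hits.astype(np.int64)
    out = []
    last = -(1 << 60)
    for s in hits:
        if s - last >= lockout_steps:
            out.append(s)
            last = s
    return np.asarray(out, dtype=np.int64)


def detect_cycle_trigger(
    filtered_lfp: np.ndarray,
    level: float,
    phase_deg: float,
    sim: SimulationParams,
    frequency: float = 20.0,
    arm_window_ms: float = 75.0,
    lockout_ms: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Offline cycle-phase triggers on a causally filtered beta-band LFP.

    After the filtered LFP exceeds ``level`` the signal is 'armed' for
    ``arm_window_ms``; while armed, zero crossings of the base type trigger.
    Phases in [0, 180) use the rising crossing as 0 deg, phases in [180, 360)
    the falling crossing as 180 deg; the stimulus is offset from the crossing
    by the remaining phase fraction of the oscillation period.  Returns
    (crossing steps, stimulus steps, edge, phase-offset steps).
    """
    phase = phase_deg % 360.0
    period_ms = 1000.0 / frequency
    if phase < 180.0:
        edge, offset_ms = +1, phase / 360.0 * period_ms
    else:
        edge, offset_ms = -1, (phase - 180.0) / 360.0 * period_ms
    offset = round(offset_ms / sim.h)
    arm = round(arm_window_ms / sim.h)
    lock = round(lockout_ms / sim.h)
    y = np.asarray(filtered_lfp, dtype=float)
    crossings = []
    armed_until = -1
    last = -(1 << 60)
    for t in range(1, y.shape[0]):
        if y[t] >= level:
            armed_until = t + arm
        if t < armed_until and t - last >= lock:
            if edge > 0 and y[t - 1] <= 0.0 < y[t]:
                crossings.append(t)
                last = t
            elif edge < 0 and y[t - 1] >= 0.0 > y[t]:
                crossings.append(t)
                last = t
    cr = np.asarray(crossings, dtype=np.int64)
    return cr, cr + offset, edge, offset


def calibrate_trigger_threshold(
    sig: np.ndarray,
    target_rate: float,
    sim: SimulationParams,
    edge: str = "rising",
    lockout_steps: int = 0,
    tol: float = 0.10,
    max_iter: int = 60,
) -> float:
    """Bisection on the empirical crossing rate of a recorded signal.

    Finds a threshold whose trigger rate is within ``tol`` (relative) of
    ``target_rate`` triggers/s.  A zero target returns a threshold above the
    signal maximum.  Raises if the target exceeds the achievable range.
    """
    x = np.asarray(sig, dtype=float)
    duration_s = x.shape[0] * sim.h / 1000.0
    if target_rate <= 0:
        return float(x.max()) + 1.0

    def rate(thr: float) -> float:
        return detect_threshold_trigger(x, thr, edge, lockout_steps).size / duration_s

    lo, hi = 0.0, float(np.abs(x).max())
    if rate(lo) < target_rate:
        raise ValueError(
            f"target rate {target_rate}/s unreachable; achievable <= {rate(lo):.2f}/s"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        rm = rate(mid)
        if abs(rm - target_rate) <= tol * target_rate:
            return mid
        if rm > target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def schedule_tetanic(
    rate_hz: float,
    refractory_ms: float,
    duration_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson stimulus times (ms) with an imposed refractory period.

    Exponential inter-stimulus intervals at the nominal rate are lengthened
    by the refractory period, with the exponential mean reduced so that the
    delivered rate stays at ``rate_hz``.
    """
    if rate_hz <= 0:
        return np.empty(0)
    if rate_hz * refractory_ms >= 1000.0:
        raise ValueError("rate * refractory must be < 1")
    # E[interval] = refractory + mean_exp = 1000/rate
    mean_exp = 1000.0 / rate_hz - refractory_ms
    times = []
    t = float(rng.exponential(mean_exp))
    while t < duration_ms:
        times.append(t)
        t += refractory_ms + float(rng.exponential(mean_exp))
    return np.asarray(times)


def deliver_conditioning(
    spec: ProtocolSpec,
    trigger_times_ms: np.ndarray,
    block_length_ms: float,
    sim: SimulationParams,
    col_of: dict[str, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Expand trigger times into open-loop stimulus events for one block.

    Returns sorted ``(steps, columns, amplitudes, truncated)``; events past
    the block end are dropped and counted.  For ``paired_pulse`` each trigger
    time yields an A-train and a B-train offset by the (signed) delay; other
    variants yield trains on the target column only.
    """
    from .topology import column_index

    steps: list[int] = []
    cols: list[int] = []
    amps: list[float] = []
    truncated = 0
    tgt = column_index(spec.target_column)
    src = column_index(spec.trigger_column)
    n_steps = round(block_length_ms / sim.h)

    def emit(t_ms: float, col: int, amp: float) -> None:
        nonlocal truncated
        s = round(t_ms / sim.h)
        if 0 <= s < n_steps:
            steps.append(s)
            cols.append(col)
            amps.append(amp)
        else:
            truncated += 1

    for t0 in np.asarray(trigger_times_ms, dtype=float):
        if spec.variant == "paired_pulse":
            for k in range(spec.train):
                emit(t0 + k * spec.train_interval, src, spec.amplitude)
                emit(t0 + spec.delay + k * spec.train_interval, tgt, spec.amplitude)
        else:
            for k in range(spec.train):
                emit(t0 + spec.delay + k * spec.train_interval, tgt, spec.amplitude)

    order = np.argsort(np.asarray(steps, dtype=np.int64), kind="stable")
    return (
        np.asarray(steps, dtype=np.int64)[order],
        np.asarray(cols, dtype=np.int8)[order],
        np.asarray(amps, dtype=float)[order],
        truncated,
    )


# --- named presets ----------------------------------------------------------

_PRESETS: dict[str, ProtocolSpec] = {
    "none": ProtocolSpec(variant="none"),
    "spike_triggered": ProtocolSpec(variant="spike_triggered", delay=10.0),
    "spike_triggered_inhibition": ProtocolSpec(
        variant="spike_triggered_inhibition", delay=10.0, amplitude=-2.0 * MV
    ),
    "emg_triggered": ProtocolSpec(
        variant="emg_triggered", delay=0.0, band=(100.0, 2500.0),
        edge="rising", lockout=20.0,
    ),
    "paired_pulse": ProtocolSpec(variant="paired_pulse", delay=10.0),
    "paired_triplet": ProtocolSpec(variant="paired_pulse", delay=10.0, train=3),
    "cycle_triggered": ProtocolSpec(
        variant="cycle_triggered", delay=0.0, band=(15.0, 25.0), phase=0.0,
        lockout=30.0, target_column="A", trigger_column="B",
    ),
    "gamma_triggered": ProtocolSpec(
        variant="gamma_triggered", delay=0.0, band=(50.0, 80.0),
        edge="falling", lockout=20.0,
    ),
    "tetanic": ProtocolSpec(variant="tetanic", rate=10.0, refractory=10.0),
}


def preset(name: str, **overrides) -> ProtocolSpec:
    """Named protocol preset, optionally with field overrides."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    spec = _PRESETS[name]
    return replace(spec, **overrides) if overrides else spec
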