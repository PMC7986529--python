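"""LFP/EMG synthesis and analysis: evoked potentials, histograms, weights.

The simulated local field potential of a column is the sum of all PSPs
arriving at the column's cortical units (including external-bias PSPs,
excluding direct stimulus steps, which are not synaptic events).  Evoked
potentials (EPs) are measured from test stimuli: the signed extremum of the
LFP in a post-stimulus window minus the pre-stimulus baseline mean.  EMG is
the sum of motor-unit potentials band-passed at 100-2500 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .params import SimulationParams
from .topology import MotorPool

__all__ = [
    "EPResult",
    "compute_lfp",
    "extract_segments",
    "ep_from_segments",
    "measure_ep",
    "ep_increase_percent",
    "synthesize_emg",
    "bandpass_causal",
    "bandpass_zero_phase",
    "trigger_aligned_histogram",
    "weight_summaries",
]

#: EP baseline window (ms relative to stimulus), mean over [-20, 0)
EP_BASELINE_MS = (-20.0, 0.0)
#: EP peak-search window (ms relative to stimulus), signed extremum over (3, 18]
EP_PEAK_MS = (3.0, 18.0)


@dataclass
class EPResult:
    """Evoked potentials for one directed column pair.

    ``amplitudes`` holds one single-trial EP per test stimulus; ``waveform``
    is the trial-averaged stimulus-locked LFP segment (baseline through peak
    window).  The headline EP (``mean``) is the amplitude of the *averaged*
    waveform — averaging before peak-picking avoids the upward bias that the
    extremum statistic acquires on single noisy trials.
    """

    amplitudes: np.ndarray      # uV, one entry per usable test stimulus
    waveform: np.ndarray | None = None   # trial-averaged segment (uV)
    h: float = 0.1
    baseline_ms: tuple[float, float] = EP_BASELINE_MS
    peak_ms: tuple[float, float] = EP_PEAK_MS

    @property
    def mean(self) -> float:
        if self.waveform is not None and self.waveform.size:
            return _segment_amplitude(
                self.waveform, self.h, self.baseline_ms, self.peak_ms
            )
        return float(self.amplitudes.mean()) if self.amplitudes.size else float("nan")

    @property
    def n(self) -> int:
        return int(self.amplitudes.size)


def _segment_amplitude(
    seg: np.ndarray,
    h: float,
    baseline_ms: tuple[float, float] = EP_BASELINE_MS,
    peak_ms: tuple[float, float] = EP_PEAK_MS,
) -> float:
    """Signed extremum minus baseline mean of one stimulus-locked segment.

    The segment starts at ``baseline_ms[0]`` relative to the stimulus and
    extends through ``peak_ms[1]``.
    """
    nb = round((baseline_ms[1] - baseline_ms[0]) / h)
    p0 = round((peak_ms[0] - baseline_ms[0]) / h)
    base = seg[:nb].mean()
    resp = seg[p0 + 1:] - base
    if resp.size == 0:
        return float("nan")
    return float(resp[np.argmax(np.abs(resp))])


def extract_segments(
    lfp: np.ndarray,
    stim_steps: np.ndarray,
    sim: SimulationParams,
    baseline_ms: tuple[float, float] = EP_BASELINE_MS,
    peak_ms: tuple[float, float] = EP_PEAK_MS,
) -> np.ndarray:
    """Stimulus-locked LFP segments (one row per usable stimulus)."""
    x = np.asarray(lfp, dtype=float)
    b0 = round(baseline_ms[0] / sim.h)
    p1 = round(peak_ms[1] / sim.h)
    rows = []
    for s in np.asarray(stim_steps, dtype=np.int64):
        if s + b0 < 0 or s + p1 + 1 > x.shape[0]:
            continue
        rows.append(x[s + b0: s + p1 + 1])
    return np.asarray(rows) if rows else np.empty((0, p1 - b0 + 1))


def ep_from_segments(
    segments: np.ndarray,
    sim: SimulationParams,
    baseline_ms: tuple[float, float] = EP_BASELINE_MS,
    peak_ms: tuple[float, float] = EP_PEAK_MS,
) -> EPResult:
    """EPResult from pre-extracted stimulus-locked segments."""
    segments = np.asarray(segments, dtype=float)
    if segments.size == 0:
        return EPResult(np.empty(0), None, sim.h, baseline_ms, peak_ms)
    amps = np.array(
        [_segment_amplitude(s, sim.h, baseline_ms, peak_ms) for s in segments]
    )
    return EPResult(amps, segments.mean(axis=0), sim.h, baseline_ms, peak_ms)


def compute_lfp(
    synaptic_input: np.ndarray, sim: SimulationParams
) -> np.ndarray:
    """Reference LFP: twin-integrator response to summed per-step column input.

    ``synaptic_input[t]`` is the summed synaptic weight delivered to the
    column's units at step ``t`` (spikes times weights, plus bias events).
    Equivalent to superposing the full signed PSP kernel of every delivery.
    """
    x = np.asarray(synaptic_input, dtype=float)
    cs = 1.0 - sim.h / sim.tau_s
    cf = 1.0 - sim.h / sim.tau_f
    # V_s(t+h) = cs V_s(t) + x(t); LFP(t) = V_s(t) - V_f(t)
    vs = sps.lfilter([0.0, 1.0], [1.0, -cs], x)
    vf = sps.lfilter([0.0, 1.0], [1.0, -cf], x)
    return vs - vf


def measure_ep(
    lfp: np.ndarray,
    stim_steps: np.ndarray,
    sim: SimulationParams,
    baseline_ms: tuple[float, float] = EP_BASELINE_MS,
    peak_ms: tuple[float, float] = EP_PEAK_MS,
) -> EPResult:
    """Evoked potential per test stimulus: signed extremum minus baseline mean.

    The baseline is the mean LFP over ``baseline_ms`` before the stimulus;
    the response is the sample of largest absolute deviation from baseline
    within ``peak_ms`` after it.  Stimuli whose windows fall outside the
    trace are skipped.
    """
    if baseline_ms[1] > peak_ms[0] + 1e-9 and baseline_ms[1] > 0:
        raise ValueError("baseline and peak windows overlap")
    segments = extract_segments(lfp, stim_steps, sim, baseline_ms, peak_ms)
    return ep_from_segments(segments, sim, baseline_ms, peak_ms)


def ep_increase_percent(pre_mean: float, post_mean: float) -> float:
    """Percent EP change, 100 (post - pre) / pre; NaN when pre is zero."""
    if pre_mean == 0 or not np.isfinite(pre_mean):
        return float("nan")
    return 100.0 * (post_mean - pre_mean) / pre_mean


def bandpass_causal(
    x: np.ndarray, band: tuple[float, float], sim: SimulationParams, order: int = 2
) -> np.ndarray:
    """Causal Butterworth band-pass on the step grid (closed-loop compatible)."""
    fs = 1000.0 / sim.h
    if band[1] >= fs / 2:
        raise ValueError("band edge above Nyquist for the chosen h")
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfilt(sos, np.asarray(x, dtype=float))


def bandpass_zero_phase(
    x: np.ndarray, band: tuple[float, float], sim: SimulationParams, order: int = 2
) -> np.ndarray:
    """Zero-phase band-pass for offline analysis only (non-causal)."""
    fs = 1000.0 / sim.h
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def synthesize_emg(
    mn_spike_steps: np.ndarray,
    mn_spike_units: np.ndarray,
    pool: MotorPool,
    n_steps: int,
    sim: SimulationParams,
    band: tuple[float, float] = (100.0, 2500.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Raw and band-passed multiunit EMG from a pool's spike log.

    Each motoneuron spike adds its motor-unit potential, a PSP-shaped kernel
    whose peak equals the unit's amplitude, to the raw trace.  Spike units
    are pool-relative (0..39).
    """
    _, k_star = sim.psp_peak()
    drive = np.zeros(n_steps)
    units = np.asarray(mn_spike_units, dtype=np.int64)
    steps = np.asarray(mn_spike_steps, dtype=np.int64)
    np.add.at(drive, steps, pool.muap_amplitudes[units] / k_star)
    raw = compute_lfp(drive, sim)
    return raw, bandpass_causal(raw, band, sim)


def trigger_aligned_histogram(
    spike_steps: np.ndarray,
    spike_units: np.ndarray,
    unit_set: np.ndarray,
    trigger_steps: np.ndarray,
    sim: SimulationParams,
    window_ms: float = 50.0,
    bin_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Population firing rate around triggers.

    Returns ``(bin_centers_ms, rate_hz)`` where the rate is spikes per second
    per population (summed over ``unit_set``), averaged over triggers.
    Empty trigger sets yield an empty histogram.
    """
    trigger_steps = np.asarray(trigger_steps, dtype=np.int64)
    edges = np.arange(-window_ms, window_ms + bin_ms / 2, bin_ms)
    centers = (edges[:-1] + edges[1:]) / 2.0
    if trigger_steps.size == 0:
        return centers, np.zeros(centers.shape)
    mask = np.isin(np.asarray(spike_units), np.asarray(unit_set))
    s = np.asarray(spike_steps, dtype=np.int64)[mask]
    counts = np.zeros(centers.shape[0])
    w = round(window_ms / sim.h)
    for t0 in trigger_steps:
        sel = s[(s >= t0 - w) & (s < t0 + w)]
        if sel.size:
            rel_ms = (sel - t0) * sim.h
            counts += np.histogram(rel_ms, bins=edges)[0]
    rate = counts / trigger_steps.size / (bin_ms * 1e-3)
    return centers, rate


def weight_summaries(network, exc_only: bool = True) -> np.ndarray:
    """3x3 mean intercolumn connection-strength matrix (uV).

    Entry [x, y] is the mean strength of existing connections from column x
    (excitatory sources by default) onto cortical units of column y.
    """
    from .topology import COLUMNS

    out = np.zeros((3, 3))
    for xi, x in enumerate(COLUMNS):
        for yi, y in enumerate(COLUMNS):
            out[xi, yi] = network.mean_strength(x, y, exc_only=exc_only)
    return out
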