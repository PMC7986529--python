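"""External bias spike streams: correlated column events and uncorrelated drive.

Each cortical column receives excitatory background events at a combined mean
per-unit rate (default 1800/s).  A configurable fraction arrives as
column-wide correlated events: the column draws a Bernoulli event per step
and every unit receives one delivery at the event time plus Gaussian jitter
(SD 3 ms, truncated at four SDs).  The rest are independent per-unit
Bernoulli events.  Rates may be modulated in time (oscillatory episodes,
behavioral activation) through a multiplicative envelope.
"""

from __future__ import annotations

import numpy as np

from .params import BiasConfig, EpisodeSpec, SimulationParams

__all__ = [
    "bias_event_stream",
    "oscillatory_envelope",
    "block_envelope",
    "JITTER_TRUNC_SD",
]

#: Gaussian jitter truncation, in SDs (also sets the delivery look-ahead)
JITTER_TRUNC_SD = 4.0


def bias_event_stream(
    config: BiasConfig,
    n_units: int,
    n_steps: int,
    sim: SimulationParams,
    rng: np.random.Generator,
    envelope: np.ndarray | None = None,
    dense: bool = False,
):
    """Generate the delivery stream for one column over ``n_steps`` steps.

    Returns ``(steps, units, counts)`` where ``steps``/``units`` are parallel
    arrays of delivery events (step index, unit index) and ``counts`` is the
    per-unit delivery total.  With ``dense=True`` an additional
    ``(n_steps, n_units)`` amplitude array (uV, weight units already applied
    by the caller) of per-step delivery counts is returned last.

    Correlated events are Bernoulli per step at probability
    ``rate * fraction * h * envelope``; each event delivers once to every
    unit at the event step plus rounded Gaussian jitter (deliveries jittered
    beyond the stream end are dropped, matching a finite recording window).
    Uncorrelated events are independent Bernoulli per unit per step.
    """
    p_c, p_u = config.step_probabilities(sim)
    env = np.ones(n_steps) if envelope is None else np.asarray(envelope, dtype=float)
    if env.shape[0] < n_steps:
        raise ValueError("envelope shorter than the step range")
    if (p_c * env.max() > 1.0) or (p_u * env.max() > 1.0):
        raise ValueError("event probability exceeds 1 at this h; lower the rate or h")

    jitter_steps_sd = config.jitter_sd / sim.h
    trunc = int(np.ceil(JITTER_TRUNC_SD * jitter_steps_sd))

    steps_out: list[np.ndarray] = []
    units_out: list[np.ndarray] = []

    # correlated column events
    if p_c > 0:
        ev = np.flatnonzero(rng.random(n_steps) < p_c * env[:n_steps])
        for t0 in ev:
            jit = rng.normal(0.0, jitter_steps_sd, size=n_units)
            jit = np.clip(jit, -trunc, trunc)
            t_del = t0 + np.rint(jit).astype(np.int64)
            keep = (t_del >= 0) & (t_del < n_steps)
            steps_out.append(t_del[keep])
            units_out.append(np.flatnonzero(keep).astype(np.int64))

    # uncorrelated per-unit events
    if p_u > 0:
        hits = rng.random((n_steps, n_units)) < p_u * env[:n_steps, None]
        t_u, u_u = np.nonzero(hits)
        steps_out.append(t_u.astype(np.int64))
        units_out.append(u_u.astype(np.int64))

    steps = np.concatenate(steps_out) if steps_out else np.empty(0, dtype=np.int64)
    units = np.concatenate(units_out) if units_out else np.empty(0, dtype=np.int64)
    order = np.argsort(steps, kind="stable")
    steps, units = steps[order], units[order]
    counts = np.bincount(units, minlength=n_units)

    if dense:
        amps = np.zeros((n_steps, n_units))
        np.add.at(amps, (steps, units), 1.0)
        return steps, units, counts, amps
    return steps, units, counts


def oscillatory_envelope(spec: EpisodeSpec, t_ms: np.ndarray, block_length_s: float) -> np.ndarray:
    """Rate multiplier ``1 + depth sin(2 pi f (t - onset))`` during episodes.

    ``t_ms`` are times within one block.  Episode onsets are evenly spaced in
    the block; outside episodes the multiplier is 1.  Floored at 0.
    """
    t = np.asarray(t_ms, dtype=float)
    env = np.ones_like(t)
    dur = spec.duration_ms
    for onset in spec.onsets_ms(block_length_s):
        mask = (t >= onset) & (t < onset + dur)
        env[mask] = 1.0 + spec.depth * np.sin(
            2.0 * np.pi * spec.frequency * (t[mask] - onset) * 1e-3
        )
    return np.maximum(env, 0.0)


def block_envelope(
    spec: EpisodeSpec | None,
    sim: SimulationParams,
    n_steps: int,
    margin_steps: int = 0,
) -> np.ndarray:
    """Per-step envelope for one block, extended ``margin_steps`` past its end.

    The extension repeats the periodic block pattern so that look-ahead
    correlated-event generation near a block boundary sees the correct rate.
    """
    total = n_steps + margin_steps
    if spec is None:
        return np.ones(total)
    block_ms = n_steps * sim.h
    t_ms = (np.arange(total) * sim.h) % block_ms
    return oscillatory_envelope(spec, t_ms, block_ms / 1000.0)
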