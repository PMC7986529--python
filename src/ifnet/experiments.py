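"""Preset experiment harnesses.

Convenience front-ends that assemble run configurations for each
conditioning paradigm, run matched intact/lesioned comparisons, sweep
stimulation phase or trigger delay, and measure bias-stream statistics.
Problem sizes default to a reduced schedule (60/40/100/40 s periods) that
preserves the full protocol structure while keeping multi-run sweeps cheap;
the full-scale 500-s periods remain available through ``schedule=``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .bias import bias_event_stream
from .params import BiasConfig, EpisodeSpec, PlasticityParams, SimulationParams
from .protocols import ProtocolSpec, preset
from .run import (
    PeriodSpec,
    RunConfig,
    RunResult,
    ScheduleSpec,
    run_schedule,
    standard_schedule,
)
from .topology import Network, TopologySpec, build_network, lesion_connections

__all__ = [
    "scaled_schedule",
    "conditioning_run",
    "cycle_phase_sweep",
    "measure_bias_rate",
    "disynaptic_comparison",
    "frozen_ep_run",
]


def scaled_schedule(
    precondition_s: float = 60.0,
    pretest_s: float = 40.0,
    condition_s: float = 100.0,
    posttest_s: float = 40.0,
    test_interval_s: float = 0.25,
    wtrack_interval_ms: float = 0.0,
) -> ScheduleSpec:
    """Reduced-duration four-period schedule for sweeps and test suites."""
    return ScheduleSpec(
        periods=standard_schedule(precondition_s, pretest_s, condition_s, posttest_s),
        test_interval_s=test_interval_s,
        wtrack_interval_ms=wtrack_interval_ms,
    )


def conditioning_run(
    protocol: ProtocolSpec | str,
    seed: int,
    schedule: ScheduleSpec | None = None,
    bias: BiasConfig | None = None,
    network: Network | None = None,
    episodes: EpisodeSpec | None = None,
    **config_overrides,
) -> RunResult:
    """One full conditioning run (preconditioning/test/conditioning/test)."""
    spec = preset(protocol) if isinstance(protocol, str) else protocol
    cfg = RunConfig(
        seed=seed,
        protocol=spec,
        schedule=schedule if schedule is not None else scaled_schedule(),
        bias=bias if bias is not None else BiasConfig(),
        episodes=episodes,
        **config_overrides,
    )
    return run_schedule(cfg, network=network)


def frozen_ep_run(
    network: Network,
    seed: int,
    duration_s: float = 30.0,
    test_interval_s: float = 1.0,
) -> RunResult:
    """Measure EPs of a frozen network (single testing period, plasticity off)."""
    cfg = RunConfig(
        seed=seed,
        schedule=ScheduleSpec(
            periods=(PeriodSpec("test", duration_s, False, False),),
            test_interval_s=test_interval_s,
        ),
    )
    return run_schedule(cfg, network=network)


def cycle_phase_sweep(
    phases_deg,
    seeds,
    schedule: ScheduleSpec | None = None,
) -> dict:
    """Cycle-triggered conditioning EP change as a function of stimulation phase.

    For every phase, runs the full cycle-triggered protocol (beta episodes in
    column B, stimuli to column A at that phase of the filtered LFP) for each
    seed and averages the A->B and B->A EP increases.  Returns a dict with
    ``phases``, ``ab`` and ``ba`` arrays plus the per-(phase, seed) table.
    """
    from .run import Simulation

    phases = np.asarray(list(phases_deg), dtype=float)
    seeds = list(seeds)
    schedule = schedule if schedule is not None else scaled_schedule()
    ab = np.zeros((phases.size, len(seeds)))
    ba = np.zeros((phases.size, len(seeds)))
    for k, seed in enumerate(seeds):
        # the preconditioning and pretest periods are phase-independent: run
        # them once per seed and branch the conditioning from a state snapshot
        base_cfg = RunConfig(
            seed=int(seed),
            protocol=preset("cycle_triggered", phase=float(phases[0])),
            schedule=schedule,
        )
        sim = Simulation(base_cfg)
        col = sim._new_collectors()
        periods = schedule.periods
        for p in periods[:-2]:
            sim._run_period(p, col)
        snap = sim.snapshot_state(col)
        for i, phase in enumerate(phases):
            col_b = sim.restore_state(snap)
            sim.config = replace(
                base_cfg, protocol=preset("cycle_triggered", phase=float(phase))
            )
            for p in periods[-2:]:
                sim._run_period(p, col_b)
            res = sim._finalize(col_b)
            ab[i, k] = res.ep_increase("A", "B")
            ba[i, k] = res.ep_increase("B", "A")
    ab_mean = np.nanmean(ab, axis=1)
    ba_mean = np.nanmean(ba, axis=1)

    def _argmax_phase(values: np.ndarray) -> float:
        phase = phases[int(np.nanargmax(values))]
        # report on (-90, 270]: keeps the A->B optimum near 0 and the B->A
        # optimum near 180 on a continuous axis
        return float((phase + 90.0) % 360.0 - 90.0)

    return {
        "phases": phases,
        "ab": ab_mean,
        "ba": ba_mean,
        "ab_table": ab,
        "ba_table": ba,
        "best_ab_phase": _argmax_phase(ab_mean),
        "best_ba_phase": _argmax_phase(ba_mean),
    }


def measure_bias_rate(
    seed: int,
    duration_s: float = 20.0,
    config: BiasConfig | None = None,
    sim: SimulationParams | None = None,
    n_units: int = 80,
) -> float:
    """Mean delivered external-bias rate per unit (events/s) for one column."""
    config = config if config is not None else BiasConfig()
    sim = sim if sim is not None else SimulationParams()
    n_steps = round(duration_s * 1000.0 / sim.h)
    rng = np.random.default_rng(seed)
    _, _, counts = bias_event_stream(config, n_units, n_steps, sim, rng)
    return float(counts.mean() / duration_s)


def disynaptic_comparison(
    seeds,
    schedule: ScheduleSpec | None = None,
    amplitude_uv: float = 2000.0,
    delay_ms: float = 10.0,
    probe_s: float = 300.0,
) -> dict:
    """Paired-triplet conditioning of matched intact and A<->B-lesioned twins.

    For each seed the same initial network is conditioned twice: intact, and
    with all direct A<->B connections deleted before conditioning.  The
    disynaptic (A->C->B) EP of the conditioned *intact* network is recovered
    by removing its A<->B connections for testing only.  Returns per-seed
    disynaptic EPs and their lesioned/intact ratio and regression slope.
    """
    spec = preset("paired_triplet", amplitude=amplitude_uv, delay=delay_ms)
    schedule = schedule if schedule is not None else scaled_schedule()
    sim = SimulationParams()
    plast = PlasticityParams()
    topo = TopologySpec()
    intact_ep, lesioned_ep = [], []
    for seed in seeds:
        seed = int(seed)
        base = build_network(topo, sim, plast, seed)
        res_int = conditioning_run(spec, seed, schedule=schedule, network=base.copy())
        res_les = conditioning_run(
            spec, seed, schedule=schedule,
            network=lesion_connections(base, "A", "B"),
        )
        # disynaptic EPs are small relative to the background LFP, so both
        # conditioned networks are probed with long plasticity-off testing
        # runs (the EP is stationary there, so averaging is limited only by
        # probe duration); the intact network's disynaptic component is
        # recovered by removing its A<->B connections for testing
        probe_int = lesion_connections(res_int.network, "A", "B")
        ep_i = frozen_ep_run(
            probe_int, seed, duration_s=probe_s, test_interval_s=0.25
        ).ep_periods[0][("A", "B")].mean
        ep_l = frozen_ep_run(
            res_les.network, seed, duration_s=probe_s, test_interval_s=0.25
        ).ep_periods[0][("A", "B")].mean
        intact_ep.append(ep_i)
        lesioned_ep.append(ep_l)
    intact_ep = np.asarray(intact_ep)
    lesioned_ep = np.asarray(lesioned_ep)
    slope = float(np.sum(intact_ep * lesioned_ep) / np.sum(intact_ep**2))
    return {
        "intact_disynaptic_ep": intact_ep,
        "lesioned_disynaptic_ep": lesioned_ep,
        "ratio": float(lesioned_ep.mean() / intact_ep.mean()),
        "slope": slope,
    }
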