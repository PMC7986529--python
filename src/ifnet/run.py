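"""Run scheduling and orchestration.

A run advances the network through a sequence of periods (default four:
preconditioning, preconditioning testing, conditioning, postconditioning
testing) in fixed-length blocks.  Plasticity is on during preconditioning
and conditioning and off during both testing periods; the conditioning
protocol is active only in the conditioning period.  Testing periods deliver
3-mV test stimuli and measure evoked potentials for every directed column
pair; weights are snapshotted at block boundaries.

The block loop marshals all state into the compiled kernel
(:mod:`ifnet.kernels`); a run is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .bias import JITTER_TRUNC_SD, block_envelope
from .kernels import PROTO_CYCLE, PROTO_NONE, PROTO_SPIKE, PROTO_THRESHOLD, run_block_kernel
from .params import MV, BiasConfig, EpisodeSpec, PlasticityParams, SimulationParams
from .protocols import (
    ProtocolSpec,
    calibrate_trigger_threshold,
    deliver_conditioning,
    design_trigger_filter,
    schedule_tetanic,
)
from .signals import (
    EPResult,
    ep_from_segments,
    ep_increase_percent,
    extract_segments,
)
from .topology import (
    COLUMNS,
    N_CORTICAL,
    N_UNITS,
    Network,
    TopologySpec,
    build_network,
    column_index,
    column_slice,
    exc_slice,
    motor_slice,
)

__all__ = ["PeriodSpec", "ScheduleSpec", "RunConfig", "RunResult", "Simulation", "run_schedule"]

TEST_AMPLITUDE = 3.0 * MV     # test stimulus (uV)
PAIRS = [(x, y) for x in COLUMNS for y in COLUMNS if x != y]


@dataclass(frozen=True)
class PeriodSpec:
    name: str
    duration_s: float
    plasticity: bool
    conditioning: bool


def standard_schedule(
    precondition_s: float = 500.0,
    pretest_s: float = 500.0,
    condition_s: float = 500.0,
    posttest_s: float = 500.0,
) -> tuple[PeriodSpec, ...]:
    return (
        PeriodSpec("preconditioning", precondition_s, True, False),
        PeriodSpec("pretest", pretest_s, False, False),
        PeriodSpec("conditioning", condition_s, True, True),
        PeriodSpec("posttest", posttest_s, False, False),
    )


@dataclass(frozen=True)
class ScheduleSpec:
    periods: tuple[PeriodSpec, ...] = field(default_factory=standard_schedule)
    test_interval_s: float = 2.0       # test-stimulus rotation cadence
    wtrack_interval_ms: float = 0.0    # fine-grained tracked-weight cadence (0 = off)

    def __post_init__(self) -> None:
        for p in self.periods:
            if not p.plasticity and p.conditioning:
                raise ValueError("testing periods must not run conditioning")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 1
    sim: SimulationParams = field(default_factory=SimulationParams)
    plast: PlasticityParams = field(default_factory=PlasticityParams)
    topo: TopologySpec = field(default_factory=TopologySpec)
    bias: BiasConfig = field(default_factory=BiasConfig)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    episodes: EpisodeSpec | None = None
    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)
    record_spikes: bool = False
    store_lfp: bool = False

    def __post_init__(self) -> None:
        if self.protocol.variant == "cycle_triggered" and self.episodes is None:
            object.__setattr__(self, "episodes", EpisodeSpec())


@dataclass
class RunResult:
    config: RunConfig
    ep_periods: list[dict[tuple[str, str], EPResult]]
    trigger_counts: list[int]
    snapshots: list[tuple[float, np.ndarray]]     # (time s, 3x3 mean strength uV)
    network: Network                              # final state
    wtrack: np.ndarray | None = None              # tracked mean strength (uV)
    wtrack_interval_ms: float = 0.0
    spikes: list[tuple[np.ndarray, np.ndarray]] | None = None
    lfp: list[np.ndarray] | None = None           # per-period concatenated (store_lfp)
    trigger_steps: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    manifest: dict = field(default_factory=dict)

    def _testing_indices(self) -> list[int]:
        return [i for i, p in enumerate(self.config.schedule.periods) if not p.plasticity]

    def ep_mean(self, period_index: int, src: str, dst: str) -> float:
        return self.ep_periods[period_index][(src, dst)].mean

    def ep_increase(self, src: str, dst: str) -> float:
        idx = self._testing_indices()
        pre, post = idx[0], idx[-1]
        return ep_increase_percent(
            self.ep_mean(pre, src, dst), self.ep_mean(post, src, dst)
        )


def _pow2_at_least(n: int) -> int:
    return 1 << max(1, math.ceil(math.log2(max(2, n))))


class Simulation:
    """Stateful driver owning all kernel arrays for one network."""

    def __init__(self, config: RunConfig, network: Network | None = None):
        self.config = config
        sim, plast = config.sim, config.plast
        self.network = network if network is not None else build_network(
            config.topo, sim, plast, config.seed
        )
        net = self.network
        self._k_star = net.k_star
        n = N_UNITS

        # kernel-layout copies (source-major)
        self.wt = np.ascontiguousarray(net.w.T)
        self.plastic = np.ascontiguousarray(net.plastic.T).astype(np.uint8)
        self.sign = net.sign.astype(np.int8)
        self.theta = net.thresholds.astype(np.float64)

        # membrane / trace state
        self.vs = np.zeros(n)
        self.vf = np.zeros(n)
        self.next_allowed = np.zeros(n, dtype=np.int64)
        ring_len = _pow2_at_least(sim.d_motor_steps + 1)
        self.ring = np.zeros((ring_len, n), dtype=np.uint8)
        self.s_slow = np.zeros(N_CORTICAL)
        self.s_fast = np.zeros(N_CORTICAL)
        self.t_slow = np.zeros(N_CORTICAL)
        self.t_fast = np.zeros(N_CORTICAL)

        # bias machinery
        bias = config.bias
        p_c_col, p_u_unit = bias.step_probabilities(sim)
        self.p_c = np.full(3, p_c_col)
        self.p_u = np.zeros(n)
        self.unit_col = np.full(n, -1, dtype=np.int64)
        for c in range(3):
            self.p_u[column_slice(c)] = p_u_unit
            self.unit_col[column_slice(c)] = c
            self.p_u[motor_slice(c)] = bias.motoneuron_rate * sim.h * 1e-3
        self.w_bias = bias.event_strength / self._k_star
        self.jitter_sd_steps = bias.jitter_sd / sim.h
        self.lookahead = int(math.ceil(JITTER_TRUNC_SD * self.jitter_sd_steps)) or 1
        self.corr_ring = np.zeros((_pow2_at_least(2 * self.lookahead + 2), N_CORTICAL))
        init_rng = np.random.default_rng([config.seed, 1])
        with np.errstate(divide="ignore"):
            self.uncorr_count = np.where(
                self.p_u > 0,
                init_rng.geometric(np.where(self.p_u > 0, self.p_u, 0.5)),
                1 << 60,
            ).astype(np.int64)
        self.bias_deliveries = np.zeros(n)

        # field potentials (lfp = all PSPs incl. bias; lfp_spk = spike-sourced only)
        self.lfp_s = np.zeros(3)
        self.lfp_f = np.zeros(3)
        self.lfp2_s = np.zeros(3)
        self.lfp2_f = np.zeros(3)
        self.emg_s = np.zeros(3)
        self.emg_f = np.zeros(3)
        self.muap_w = np.zeros(n)
        for pool in net.pools:
            self.muap_w[pool.unit_slice] = pool.muap_amplitudes / self._k_star

        # closed-loop machinery
        self.pend = np.zeros((kernels.PEND_LEN, 3))
        self.proto_state = np.array([-1e15, 0.0, -1e15])
        self._protocol_rng = np.random.default_rng([config.seed, 2])

        # recording buffers (reused per block)
        steps = sim.steps_per_block
        self.lfp_out = np.zeros((steps, 3), dtype=np.float32)
        self.lfp2_out = np.zeros((steps, 3), dtype=np.float32)
        self.emg_out = np.zeros((steps, 3), dtype=np.float32)
        self.spike_steps = np.zeros(2_000_000, dtype=np.int32)
        self.spike_units = np.zeros(2_000_000, dtype=np.int32)
        self.trig_log = np.zeros(200_000, dtype=np.int64)
        self._empty_f32 = np.zeros(1, dtype=np.float32)
        self._empty_i32 = np.zeros(0, dtype=np.int32)

        self.t_abs = 0
        self._block_index = 0

    # ------------------------------------------------------------------ helpers
    def _block_seed(self) -> int:
        return int((self.config.seed * 1_000_003 + self._block_index) % (2**31 - 1))

    def _episode_active(self) -> bool:
        return self.config.episodes is not None

    def _test_stims_standard(self, n_steps: int, test_counter: int) -> list[tuple[int, int, float]]:
        """Rotating per-column test stimuli within one block."""
        sim = self.config.sim
        interval = round(self.config.schedule.test_interval_s * 1000.0 / sim.h)
        out = []
        k = 0
        s = interval // 2
        while s < n_steps:
            out.append((s, (test_counter + k) % 3, TEST_AMPLITUDE))
            k += 1
            s += interval
        return out

    def _test_stims_episodes(self, n_steps: int) -> list[tuple[int, int, float]]:
        """Test pulses around oscillatory episodes (cycle-triggered runs).

        Two pulses before and two after each episode, alternating between the
        stimulated column (A) and column B so both directions are probed.
        """
        sim = self.config.sim
        ep = self.config.episodes
        block_s = n_steps * sim.h / 1000.0
        out = []
        dur = ep.duration_ms
        for onset in ep.onsets_ms(block_s):
            for t_ms, col in (
                (onset - 600.0, 0), (onset - 400.0, 1), (onset - 200.0, 0),
                (onset + dur + 200.0, 1), (onset + dur + 400.0, 0),
                (onset + dur + 600.0, 1),
            ):
                s = round(t_ms / sim.h)
                if 0 <= s < n_steps:
                    out.append((s, col, TEST_AMPLITUDE))
        return sorted(out)

    def _conditioning_schedule(self, n_steps: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Open-loop conditioning stimuli (paired-pulse / tetanic) for one block."""
        spec = self.config.protocol
        sim = self.config.sim
        block_ms = n_steps * sim.h
        if spec.variant == "paired_pulse":
            period = 1000.0 / spec.repetition_rate
            trig = np.arange(period / 2, block_ms - 100.0, period)
        elif spec.variant == "tetanic":
            trig = schedule_tetanic(spec.rate, spec.refractory, block_ms, self._protocol_rng)
        else:
            return (np.empty(0, np.int64), np.empty(0, np.int8), np.empty(0, float))
        steps, cols, amps, _ = deliver_conditioning(spec, trig, block_ms, sim)
        return steps, cols, amps

    def _proto_args(self, conditioning: bool) -> dict:
        """Closed-loop protocol parameters for the kernel."""
        spec = self.config.protocol
        sim = self.config.sim
        args = dict(
            proto_id=PROTO_NONE, trig_unit=0, trig_delay=0, stim_amp=0.0,
            train_n=1, train_interval=1, lockout=0, target_col=1, edge=1,
            thr_level=0.0, sos=np.zeros((1, 6)), src_kind=0, src_idx=0,
            phase_offset=0, arm_window=0,
        )
        if not conditioning:
            return args
        v = spec.variant
        if v in ("spike_triggered", "spike_triggered_inhibition"):
            args.update(
                proto_id=PROTO_SPIKE,
                trig_unit=spec.trigger_unit,
                trig_delay=round(spec.delay / sim.h),
                stim_amp=spec.amplitude,
                train_n=spec.train,
                train_interval=round(spec.train_interval / sim.h),
                lockout=round(spec.lockout / sim.h),
                target_col=column_index(spec.target_column),
            )
        elif v in ("emg_triggered", "gamma_triggered"):
            args.update(
                proto_id=PROTO_THRESHOLD,
                trig_delay=round(spec.delay / sim.h),
                stim_amp=spec.amplitude,
                train_n=spec.train,
                train_interval=round(spec.train_interval / sim.h),
                lockout=round(spec.lockout / sim.h),
                target_col=column_index(spec.target_column),
                edge=+1 if spec.edge == "rising" else -1,
                thr_level=self._trigger_threshold,
                sos=self._trigger_sos,
                src_kind=0 if v == "emg_triggered" else 2,
                src_idx=column_index(spec.trigger_column),
            )
        elif v == "cycle_triggered":
            phase = spec.phase % 360.0
            period_ms = 1000.0 / self.config.episodes.frequency
            if phase < 180.0:
                edge, offset_ms = +1, phase / 360.0 * period_ms
            else:
                edge, offset_ms = -1, (phase - 180.0) / 360.0 * period_ms
            args.update(
                proto_id=PROTO_CYCLE,
                trig_delay=round(spec.delay / sim.h),
                stim_amp=spec.amplitude,
                train_n=spec.train,
                train_interval=round(spec.train_interval / sim.h),
                lockout=round(spec.lockout / sim.h),
                target_col=column_index(spec.target_column),
                edge=edge,
                thr_level=self._trigger_threshold,
                sos=self._trigger_sos,
                src_kind=1,
                src_idx=column_index(spec.trigger_column),
                phase_offset=round(offset_ms / sim.h),
                arm_window=round(75.0 / sim.h),
            )
        return args

    # ------------------------------------------------------------------ blocks
    def run_block(
        self,
        plasticity: bool,
        conditioning: bool,
        stim_list: list[tuple[int, int, float]],
        proto_args: dict,
        zi: np.ndarray,
        cond_range: tuple[int, int] | None = None,
        wtrack: tuple[np.ndarray, np.ndarray, int, np.ndarray] | None = None,
        record_v_unit: int = -1,
        v_out: np.ndarray | None = None,
    ) -> dict:
        """Advance one block; returns block records."""
        cfg = self.config
        sim = cfg.sim
        n_steps = sim.steps_per_block
        env = np.ones((n_steps + self.lookahead, 3))
        if self._episode_active():
            col = column_index(cfg.episodes.column)
            env[:, col] = block_envelope(cfg.episodes, sim, n_steps, self.lookahead)
        env_max = env.max(axis=0)
        # effective per-unit uncorrelated sampling probability (thinned by env)
        p_eff = self.p_u.copy()
        for c in range(3):
            p_eff[self.unit_col == c] *= env_max[c]
        log1mp = np.where(p_eff > 0, np.log1p(-np.minimum(p_eff, 0.999999)), 0.0)

        if stim_list:
            order = sorted(stim_list)
            stim_steps = np.array([s for s, _, _ in order], dtype=np.int64)
            stim_cols = np.array([c for _, c, _ in order], dtype=np.int8)
            stim_amps = np.array([a for _, _, a in order], dtype=float)
        else:
            stim_steps = np.empty(0, np.int64)
            stim_cols = np.empty(0, np.int8)
            stim_amps = np.empty(0, float)

        if cond_range is None:
            cond_range = (0, n_steps) if conditioning else (0, 0)
        if wtrack is None:
            wj = np.zeros(1, dtype=np.int64)
            wi = np.zeros(1, dtype=np.int64)
            wint, wout = 0, self._empty_f32
        else:
            wj, wi, wint, wout = wtrack
        if v_out is None:
            v_out = self._empty_f32

        n_spikes, n_trigs = run_block_kernel(
            n_steps, self.t_abs, self._block_seed(),
            sim.h, 1.0 - sim.h / sim.tau_s, 1.0 - sim.h / sim.tau_f,
            self.theta, sim.d_cortical_steps, sim.d_motor_steps,
            round(sim.refractory / sim.h),
            self.wt, self.plastic, self.sign,
            cfg.plast.w_min, cfg.plast.w_max(sim), cfg.plast.r, cfg.plast.c,
            1 if plasticity else 0,
            1.0 - sim.h / cfg.plast.a_s, 1.0 - sim.h / cfg.plast.a_f,
            1.0 - sim.h / cfg.plast.b_s, 1.0 - sim.h / cfg.plast.b_f,
            self.vs, self.vf, self.ring, self.next_allowed,
            self.s_slow, self.s_fast, self.t_slow, self.t_fast,
            self.p_c, log1mp, self.unit_col, self.w_bias,
            self.jitter_sd_steps, self.lookahead, env, env_max,
            self.corr_ring, self.uncorr_count, self.bias_deliveries,
            self.lfp_s, self.lfp_f, self.lfp2_s, self.lfp2_f,
            self.emg_s, self.emg_f, self.muap_w,
            self.lfp_out, self.lfp2_out, self.emg_out,
            stim_steps, stim_cols, stim_amps,
            proto_args["proto_id"], proto_args["trig_unit"], proto_args["trig_delay"],
            proto_args["stim_amp"], proto_args["train_n"], proto_args["train_interval"],
            proto_args["lockout"], proto_args["target_col"], proto_args["edge"],
            proto_args["thr_level"], proto_args["sos"], zi,
            proto_args["src_kind"], proto_args["src_idx"], proto_args["phase_offset"],
            proto_args["arm_window"],
            cond_range[0], cond_range[1], self.proto_state,
            self.pend,
            self.spike_steps, self.spike_units, self.trig_log,
            record_v_unit, v_out,
            wj, wi, wint, wout,
        )
        self.t_abs += n_steps
        self._block_index += 1
        n_spikes = min(n_spikes, self.spike_steps.shape[0])
        n_trigs_kept = min(n_trigs, self.trig_log.shape[0])
        return {
            "n_spikes": n_spikes,
            "n_trigs": n_trigs,
            "trigger_steps": self.trig_log[:n_trigs_kept].copy(),
            "stims": list(zip(stim_steps.tolist(), stim_cols.tolist())),
        }

    # ------------------------------------------------------------------ full run
    def _new_collectors(self) -> dict:
        cfg = self.config
        spec = cfg.protocol
        self._trigger_threshold = 0.0
        self._conditioned = False
        self._trigger_sos = (
            design_trigger_filter(spec.band, cfg.sim)
            if spec.band is not None else np.zeros((1, 6))
        )
        wtrack_cfg = None
        if cfg.schedule.wtrack_interval_ms > 0:
            # tracked set: plastic excitatory A -> column-B cortical connections
            jj, ii = np.nonzero(self.plastic[exc_slice(0), column_slice(1)])
            wint = round(cfg.schedule.wtrack_interval_ms / cfg.sim.h)
            wtrack_cfg = (
                (jj + exc_slice(0).start).astype(np.int64),
                (ii + column_slice(1).start).astype(np.int64),
                wint,
            )
        return {
            "zi": np.zeros((self._trigger_sos.shape[0], 2)),
            "ep_periods": [], "trig_counts": [], "snapshots": [],
            "wtrack_all": [],
            "spikes_all": [] if cfg.record_spikes else None,
            "lfp_all": [] if cfg.store_lfp else None,
            "calib_signal": [], "test_counter": 0,
            "wtrack_cfg": wtrack_cfg, "trigger_steps": [],
        }

    def _run_period(self, period: PeriodSpec, col: dict) -> None:
        cfg = self.config
        sim = cfg.sim
        spec = cfg.protocol
        n_steps = sim.steps_per_block
        closed_loop = spec.variant in (
            "spike_triggered", "spike_triggered_inhibition",
            "emg_triggered", "gamma_triggered", "cycle_triggered",
        )
        needs_calibration = spec.variant in (
            "emg_triggered", "gamma_triggered", "cycle_triggered"
        )
        n_blocks = round(period.duration_s / sim.block_length)
        testing = not period.plasticity
        ep_acc: dict[tuple[str, str], list[np.ndarray]] = {p: [] for p in PAIRS}
        period_trigs = 0

        if period.conditioning and needs_calibration:
            sig = col["calib_signal"]
            self._calibrate(np.concatenate(sig) if sig else None)
            col["zi"][:] = 0.0

        proto_args = self._proto_args(period.conditioning and closed_loop)
        wtrack_cfg = col["wtrack_cfg"]

        for _ in range(n_blocks):
            stims: list[tuple[int, int, float]] = []
            if self._episode_active():
                if testing or period.conditioning:
                    stims.extend(self._test_stims_episodes(n_steps))
            elif testing:
                stims.extend(self._test_stims_standard(n_steps, col["test_counter"]))
                col["test_counter"] += len(stims)
            if period.conditioning and not closed_loop and spec.variant != "none":
                s2, c2, a2 = self._conditioning_schedule(n_steps)
                stims.extend(zip(s2.tolist(), c2.tolist(), a2.tolist()))

            cond_range = None
            if period.conditioning and spec.duty_cycle is not None:
                cond_range = (0, round(spec.duty_cycle * n_steps))

            wt_arrays = None
            if wtrack_cfg is not None and period.conditioning:
                n_snap = n_steps // wtrack_cfg[2]
                wout = np.zeros(n_snap, dtype=np.float32)
                wt_arrays = (*wtrack_cfg, wout)

            rec = self.run_block(
                period.plasticity, period.conditioning, stims, proto_args, col["zi"],
                cond_range=cond_range, wtrack=wt_arrays,
            )
            period_trigs += rec["n_trigs"]
            if rec["trigger_steps"].size:
                col["trigger_steps"].append(rec["trigger_steps"])

            if wt_arrays is not None:
                col["wtrack_all"].append(wt_arrays[3] * self._k_star)
            if cfg.record_spikes:
                ns = rec["n_spikes"]
                col["spikes_all"].append(
                    (self.spike_steps[:ns] + (self.t_abs - n_steps),
                     self.spike_units[:ns].copy())
                )
            if cfg.store_lfp:
                col["lfp_all"].append(self.lfp_out.copy())

            if testing:
                self._measure_block_eps(rec["stims"], ep_acc)
            if needs_calibration and not period.conditioning and not self._conditioned:
                src = column_index(spec.trigger_column)
                if spec.variant == "emg_triggered":
                    chan = self.emg_out[:, src]
                elif spec.variant == "gamma_triggered":
                    chan = self.lfp2_out[:, src]
                else:
                    chan = self.lfp_out[:, src]
                col["calib_signal"].append(chan.astype(np.float64))
            col["snapshots"].append((self.t_abs * sim.h / 1000.0, self._mean_strengths()))

        if period.conditioning:
            self._conditioned = True
        col["trig_counts"].append(period_trigs)
        col["ep_periods"].append({
            p: ep_from_segments(np.vstack(v) if v else np.empty((0, 0)), sim)
            for p, v in ep_acc.items()
        })

    def _finalize(self, col: dict) -> RunResult:
        cfg = self.config
        final = self.network.copy()
        final.w = np.ascontiguousarray(self.wt.T)
        manifest = {
            "seed": cfg.seed,
            "protocol": cfg.protocol.variant,
            "periods": [(p.name, p.duration_s) for p in cfg.schedule.periods],
            "trigger_counts": col["trig_counts"],
            "trigger_threshold": self._trigger_threshold,
            "bias_deliveries_mean_per_unit": float(self.bias_deliveries[:N_CORTICAL].mean()),
        }
        return RunResult(
            config=cfg, ep_periods=col["ep_periods"], trigger_counts=col["trig_counts"],
            snapshots=col["snapshots"], network=final,
            wtrack=(np.concatenate(col["wtrack_all"]) if col["wtrack_all"] else None),
            wtrack_interval_ms=cfg.schedule.wtrack_interval_ms,
            spikes=col["spikes_all"], lfp=col["lfp_all"],
            trigger_steps=(
                np.concatenate(col["trigger_steps"])
                if col["trigger_steps"] else np.empty(0, dtype=np.int64)
            ),
            manifest=manifest,
        )

    def run(self) -> RunResult:
        col = self._new_collectors()
        for period in self.config.schedule.periods:
            self._run_period(period, col)
        return self._finalize(col)

    # ------------------------------------------------------------------ branching
    _STATE_ARRAYS = (
        "wt", "vs", "vf", "ring", "next_allowed",
        "s_slow", "s_fast", "t_slow", "t_fast",
        "corr_ring", "uncorr_count", "bias_deliveries",
        "lfp_s", "lfp_f", "lfp2_s", "lfp2_f", "emg_s", "emg_f",
        "pend", "proto_state",
    )

    def snapshot_state(self, collectors: dict | None = None) -> dict:
        """Deep copy of the evolving simulation state (for matched branching).

        A snapshot taken after some periods can be restored repeatedly to run
        alternative continuations (e.g., different conditioning phases) from
        the identical preconditioned network and bias stream position.
        """
        import copy

        snap = {name: getattr(self, name).copy() for name in self._STATE_ARRAYS}
        snap["t_abs"] = self.t_abs
        snap["_block_index"] = self._block_index
        snap["_conditioned"] = self._conditioned
        snap["_trigger_threshold"] = self._trigger_threshold
        snap["_protocol_rng"] = copy.deepcopy(self._protocol_rng.bit_generator.state)
        if collectors is not None:
            snap["collectors"] = copy.deepcopy(collectors)
        return snap

    def restore_state(self, snap: dict) -> dict | None:
        """Restore a snapshot; returns the collectors copy if one was stored."""
        import copy

        for name in self._STATE_ARRAYS:
            getattr(self, name)[...] = snap[name]
        self.t_abs = snap["t_abs"]
        self._block_index = snap["_block_index"]
        self._conditioned = snap["_conditioned"]
        self._trigger_threshold = snap["_trigger_threshold"]
        self._protocol_rng.bit_generator.state = copy.deepcopy(snap["_protocol_rng"])
        return copy.deepcopy(snap.get("collectors"))

    # ------------------------------------------------------------------ internals
    def _calibrate(self, sig: np.ndarray | None) -> None:
        """Trigger threshold / episode level from pre-conditioning recordings."""
        from scipy.signal import sosfilt

        spec = self.config.protocol
        if sig is None or sig.size == 0:
            raise RuntimeError("no calibration window recorded before conditioning")
        filt = sosfilt(self._trigger_sos, sig)
        if spec.variant == "cycle_triggered":
            self._trigger_threshold = 2.0 * float(np.std(filt))
        else:
            lock = round(spec.lockout / self.config.sim.h)
            self._trigger_threshold = calibrate_trigger_threshold(
                filt, spec.target_rate, self.config.sim,
                edge=spec.edge, lockout_steps=lock,
            )

    def _measure_block_eps(self, stims: list, ep_acc: dict) -> None:
        sim = self.config.sim
        for s, col in stims:
            src = COLUMNS[col]
            for dst_i in range(3):
                if dst_i == col:
                    continue
                seg = extract_segments(self.lfp_out[:, dst_i], np.array([s]), sim)
                if seg.shape[0]:
                    ep_acc[(src, COLUMNS[dst_i])].append(seg)

    def _mean_strengths(self) -> np.ndarray:
        out = np.zeros((3, 3))
        for x in range(3):
            e = exc_slice(x)
            for y in range(3):
                dst = column_slice(y)
                sub = self.wt[e, dst]
                mask = self.plastic[e, dst].astype(bool)
                out[x, y] = np.abs(sub[mask]).mean() * self._k_star if mask.any() else 0.0
        return out


def run_schedule(config: RunConfig, network: Network | None = None) -> RunResult:
    """Execute one full run; deterministic given (config, seed)."""
    return Simulation(config, network=network).run()
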