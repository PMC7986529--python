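"""Construction of the three-column cortical network and motor pools.

The cortical sheet holds three columns (A, B, C) of 40 excitatory and 40
inhibitory units each.  Excitatory units connect sparsely to all other
cortical units in any column; inhibitory units connect, less sparsely, only
within their own column.  Each column drives a pool of 40 motoneurons
recruited by the size principle (thresholds 5-6 mV, motor unit potentials
0.5-1.5 mV, co-sorted).  Weight convention: ``w[i, j]`` is the signed weight
of the connection from source ``j`` onto target ``i``; non-existent
connections have weight zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MV, PlasticityParams, SimulationParams

__all__ = [
    "TopologySpec",
    "MotorPool",
    "Network",
    "COLUMNS",
    "build_network",
    "lesion_connections",
    "configure_fic",
    "save_network",
    "load_network",
]

COLUMNS = ("A", "B", "C")

N_E = 40          # excitatory units per column
N_I = 40          # inhibitory units per column
N_COL = N_E + N_I
N_CORTICAL = 3 * N_COL
N_MN = 40         # motoneurons per pool
N_UNITS = N_CORTICAL + 3 * N_MN


@dataclass(frozen=True)
class TopologySpec:
    """Declarative description of the random network draw."""

    n_excitatory: int = N_E
    n_inhibitory: int = N_I
    n_motoneurons: int = N_MN
    p_exc: float = 1.0 / 6.0        # excitatory cortical connection probability
    p_inh: float = 1.0 / 3.0        # within-column inhibitory probability
    p_cm: float = 1.0 / 3.0         # corticomotoneuronal probability
    init_strength_lo: float = 0.2   # initial strength range, fraction of max
    init_strength_hi: float = 0.6
    cm_strength: float = 350.0      # corticomotoneuronal PSP peak (uV), fixed
    mn_threshold_lo: float = 5.0 * MV   # uV
    mn_threshold_hi: float = 6.0 * MV
    muap_lo: float = 0.5 * MV       # motor unit potential peaks (uV)
    muap_hi: float = 1.5 * MV

    def __post_init__(self) -> None:
        for p in (self.p_exc, self.p_inh, self.p_cm):
            if not 0.0 <= p <= 1.0:
                raise ValueError("connection probabilities must lie in [0, 1]")
        if not 0.0 < self.init_strength_lo <= self.init_strength_hi <= 1.0:
            raise ValueError("initial strength range must satisfy 0 < lo <= hi <= 1")
        if (self.n_excitatory, self.n_inhibitory, self.n_motoneurons) != (N_E, N_I, N_MN):
            raise ValueError("non-default population sizes are not supported")


@dataclass
class MotorPool:
    """Size-principle motoneuron pool associated with one column."""

    column: int
    thresholds: np.ndarray      # uV, ascending
    muap_amplitudes: np.ndarray  # uV, ascending, co-sorted with thresholds

    def __post_init__(self) -> None:
        if not (np.all(np.diff(self.thresholds) >= 0)
                and np.all(np.diff(self.muap_amplitudes) >= 0)):
            raise ValueError("thresholds and amplitudes must be co-monotone increasing")

    @property
    def unit_slice(self) -> slice:
        return motor_slice(self.column)


def column_slice(col: int) -> slice:
    """Cortical units of column ``col`` (0=A, 1=B, 2=C)."""
    return slice(N_COL * col, N_COL * (col + 1))


def exc_slice(col: int) -> slice:
    return slice(N_COL * col, N_COL * col + N_E)


def inh_slice(col: int) -> slice:
    return slice(N_COL * col + N_E, N_COL * (col + 1))


def motor_slice(col: int) -> slice:
    return slice(N_CORTICAL + N_MN * col, N_CORTICAL + N_MN * (col + 1))


def column_index(name: str) -> int:
    try:
        return COLUMNS.index(name.upper())
    except ValueError:
        raise ValueError(f"unknown column {name!r}; expected one of {COLUMNS}") from None


@dataclass
class Network:
    """Weight matrix, unit roles and motor pools of one realized network."""

    w: np.ndarray               # float64 (N_UNITS, N_UNITS), w[i, j]: j -> i
    exists: np.ndarray          # bool mask, same shape
    plastic: np.ndarray         # bool mask, same shape
    sign: np.ndarray            # int8 per source unit: +1 excitatory, -1 inhibitory
    thresholds: np.ndarray      # uV per unit
    pools: list[MotorPool]
    spec: TopologySpec
    seed: int
    k_star: float               # PSP peak per unit weight (weight <-> uV strength)
    fic: bool = False           # fixed intracolumn connectivity variant

    def copy(self) -> "Network":
        return Network(
            w=self.w.copy(), exists=self.exists.copy(), plastic=self.plastic.copy(),
            sign=self.sign.copy(), thresholds=self.thresholds.copy(),
            pools=[MotorPool(p.column, p.thresholds.copy(), p.muap_amplitudes.copy())
                   for p in self.pools],
            spec=self.spec, seed=self.seed, k_star=self.k_star, fic=self.fic,
        )

    @property
    def n_units(self) -> int:
        return self.w.shape[0]

    def strengths(self) -> np.ndarray:
        """Absolute connection strengths (PSP maxima, uV)."""
        return np.abs(self.w) * self.k_star

    def mean_strength(self, src_col: str, dst_col: str, exc_only: bool = True) -> float:
        """Mean strength (uV) over existing plastic connections between columns."""
        src = exc_slice(column_index(src_col)) if exc_only else column_slice(column_index(src_col))
        dst = column_slice(column_index(dst_col))
        sub = self.w[dst, src]
        mask = self.exists[dst, src]
        if not mask.any():
            return 0.0
        return float(np.abs(sub[mask]).mean() * self.k_star)


def build_network(
    spec: TopologySpec,
    sim: SimulationParams,
    plast: PlasticityParams,
    seed: int,
) -> Network:
    """Draw one network: a pure function of (spec, seed).

    Each ordered cortical pair (excitatory source -> any other cortical unit)
    exists independently with ``p_exc``; (inhibitory source -> same-column
    cortical unit) with ``p_inh``.  Corticomotoneuronal edges run from a
    column's excitatory units to its pool with ``p_cm`` and a fixed,
    non-plastic strength.  Initial cortical strengths are uniform on
    [lo, hi] x max_strength with the source's sign.  Self-connections never
    exist.
    """
    rng = np.random.default_rng(seed)
    _, k_star = sim.psp_peak()
    n = N_UNITS

    w = np.zeros((n, n))
    exists = np.zeros((n, n), dtype=bool)
    plastic = np.zeros((n, n), dtype=bool)

    sign = np.ones(n, dtype=np.int8)
    for c in range(3):
        sign[inh_slice(c)] = -1

    # --- cortical connectivity ------------------------------------------------
    # excitatory sources: any cortical target, any column
    for c in range(3):
        e = exc_slice(c)
        mask = rng.random((N_CORTICAL, N_E)) < spec.p_exc
        exists[:N_CORTICAL, e] |= mask
        # inhibitory sources: same-column cortical targets only
        i = inh_slice(c)
        maski = rng.random((N_COL, N_I)) < spec.p_inh
        exists[column_slice(c), i] |= maski
    np.fill_diagonal(exists, False)

    cortical = exists[:N_CORTICAL, :N_CORTICAL]
    strengths = rng.uniform(
        spec.init_strength_lo * plast.max_strength,
        spec.init_strength_hi * plast.max_strength,
        size=cortical.shape,
    )
    wc = np.where(cortical, strengths / k_star, 0.0) * sign[:N_CORTICAL][None, :]
    w[:N_CORTICAL, :N_CORTICAL] = wc
    plastic[:N_CORTICAL, :N_CORTICAL] = cortical

    # --- corticomotoneuronal edges (fixed weights) ---------------------------
    pools: list[MotorPool] = []
    thresholds = np.full(n, sim.theta)
    k = np.arange(N_MN)
    for c in range(3):
        ms = motor_slice(c)
        e = exc_slice(c)
        cm = rng.random((N_MN, N_E)) < spec.p_cm
        exists[ms, e] = cm
        w[ms, e] = np.where(cm, spec.cm_strength / k_star, 0.0)
        thr = spec.mn_threshold_lo + k / (N_MN - 1) * (spec.mn_threshold_hi - spec.mn_threshold_lo)
        amp = spec.muap_lo + k / (N_MN - 1) * (spec.muap_hi - spec.muap_lo)
        thresholds[ms] = thr
        pools.append(MotorPool(column=c, thresholds=thr, muap_amplitudes=amp))

    return Network(
        w=w, exists=exists, plastic=plastic, sign=sign, thresholds=thresholds,
        pools=pools, spec=spec, seed=seed, k_star=k_star,
    )


def lesion_connections(network: Network, col_x: str, col_y: str) -> Network:
    """Remove all cortical connections between two columns, both directions.

    Returns a modified copy; all other edges and weights are untouched, so a
    lesioned twin shares every remaining weight with its intact sibling.
    Idempotent.
    """
    cx, cy = column_index(col_x), column_index(col_y)
    if cx == cy:
        raise ValueError("lesion requires two distinct columns")
    out = network.copy()
    for a, b in ((cx, cy), (cy, cx)):
        dst, src = column_slice(a), column_slice(b)
        out.w[dst, src] = 0.0
        out.exists[dst, src] = False
        out.plastic[dst, src] = False
    return out


def save_network(network: Network, path) -> None:
    """Persist a realized network as a compressed array snapshot.

    Captures weights, masks, thresholds, pools, seed and the variant flag so
    that intact/lesioned/conditioned twins round-trip exactly.
    """
    import dataclasses

    np.savez_compressed(
        path,
        w=network.w, exists=network.exists, plastic=network.plastic,
        sign=network.sign, thresholds=network.thresholds,
        pool_thresholds=np.stack([p.thresholds for p in network.pools]),
        pool_muaps=np.stack([p.muap_amplitudes for p in network.pools]),
        seed=np.int64(network.seed), k_star=np.float64(network.k_star),
        fic=np.uint8(network.fic),
        spec=np.array(
            [getattr(network.spec, f.name) for f in dataclasses.fields(TopologySpec)]
        ),
    )


def load_network(path) -> Network:
    """Inverse of :func:`save_network`; byte-exact round trip."""
    import dataclasses

    with np.load(path) as d:
        fields = dataclasses.fields(TopologySpec)
        spec = TopologySpec(**{
            f.name: type(f.default)(v) for f, v in zip(fields, d["spec"])
        })
        pools = [
            MotorPool(c, d["pool_thresholds"][c].copy(), d["pool_muaps"][c].copy())
            for c in range(3)
        ]
        return Network(
            w=d["w"].copy(), exists=d["exists"].copy(), plastic=d["plastic"].copy(),
            sign=d["sign"].copy(), thresholds=d["thresholds"].copy(),
            pools=pools, spec=spec, seed=int(d["seed"]), k_star=float(d["k_star"]),
            fic=bool(d["fic"]),
        )


def configure_fic(
    network: Network,
    strength_range: tuple[float, float] = (200.0, 300.0),
    seed: int | None = None,
) -> Network:
    """Fixed intracolumn connectivity (FIC) variant.

    Fully connects every within-column ordered cortical pair (no
    self-connections) with uniform strengths in ``strength_range`` uV, signed
    by the source type, and marks those connections non-plastic.  Intercolumn
    connections keep their weights and stay plastic.  FIC networks are
    normally run without correlated bias input; the caller zeroes the
    correlated fraction in the bias configuration.
    """
    lo, hi = strength_range
    if not 0 < lo <= hi:
        raise ValueError("strength range must be positive")
    out = network.copy()
    rng = np.random.default_rng(network.seed + 0x5F1C if seed is None else seed)
    for c in range(3):
        sl = column_slice(c)
        strengths = rng.uniform(lo, hi, size=(N_COL, N_COL))
        wcc = strengths / network.k_star * out.sign[sl][None, :]
        block = out.w[sl, sl]
        block[:, :] = wcc
        np.fill_diagonal(block, 0.0)
        out.w[sl, sl] = block
        ex = np.ones((N_COL, N_COL), dtype=bool)
        np.fill_diagonal(ex, False)
        out.exists[sl, sl] = ex
        out.plastic[sl, sl] = False
    out.fic = True
    return out
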