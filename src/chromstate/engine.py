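"""Event-based stochastic update loop.

Each update step draws four competing exponential clocks (recruitment with
rate 1, generic direct conversion with rate beta, direct deacetylation with
rate dn, direct deubiquitination with rate dp), advances raw time by the
minimum increment and attempts the corresponding move; attempted moves may
be rejected without changing the array.  Plotted time is raw time divided
by the number of half-nucleosomes N (i.e. recruitment attempts per half).
Optional replication resets each half to the unmodified state with
probability 1/2 whenever raw time since the previous replication reaches
generation_time * N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .rules import (
    ACTION_TABLE,
    DIRECT_TABLES,
    N_ENZYMES,
    RECRUIT_COUNTS,
    RECRUIT_LISTS,
    RECRUITED_BY,
    Enzyme,
)
from .states import CATEGORY_TABLE, N_HALF_STATES, UNMODIFIED_STATE

__all__ = [
    "RateModifiers",
    "SimulationConfig",
    "MoveDraw",
    "Trajectory",
    "apply_knob",
    "draw_move",
    "recruitment_step",
    "replicate",
    "run",
    "KNOB_NAMES",
]

INITIAL_CONDITIONS = ("all_unmodified", "all_active", "all_silent", "uniform_random")

CHANNEL_NAMES = ("recruitment", "beta", "nurd", "prdub")


@dataclass(frozen=True)
class RateModifiers:
    """Acceptance multipliers for the seven recruited complexes.

    An attempted recruited move by enzyme e is accepted with probability
    m_e / max(1, max_k m_k): lowering a multiplier below 1 thins that
    channel; raising one above 1 instead attenuates all the others.
    """

    trxg: float = 1.0
    trxg_utx: float = 1.0
    trxg_cbp: float = 1.0
    prc1: float = 1.0
    prc2: float = 1.0
    prc2_kdm: float = 1.0
    prc2_kdm_nurd: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v >= 0):
                raise ValueError(f"multiplier {f.name} must be >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.trxg,
                self.trxg_utx,
                self.trxg_cbp,
                self.prc1,
                self.prc2,
                self.prc2_kdm,
                self.prc2_kdm_nurd,
            ],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one simulation run.

    Defaults follow the reference setting: N = 20 halves, beta = 0.1,
    direct PR-DUB 0.15, all other rates 1.0, 50,000 plotted time units.
    """

    n: int = 20
    beta: float = 0.1
    nurd_direct: float = 1.0
    prdub_direct: float = 0.15
    multipliers: RateModifiers = field(default_factory=RateModifiers)
    replication_on: bool = False
    generation_time: float = 20.0
    duration: float = 50_000.0
    sample_interval: float = 1.0
    initial_condition: str = "all_unmodified"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.n % 2 != 0:
            raise ValueError(f"n must be even and >= 2, got {self.n}")
        for name in ("beta", "nurd_direct", "prdub_direct", "generation_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if self.initial_condition not in INITIAL_CONDITIONS:
            raise ValueError(
                f"initial_condition must be one of {INITIAL_CONDITIONS}, "
                f"got {self.initial_condition!r}"
            )

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["multipliers"] = {
            f.name: getattr(self.multipliers, f.name) for f in fields(RateModifiers)
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        mult = d.pop("multipliers", None)
        if mult is not None:
            d["multipliers"] = RateModifiers(**mult)
        return cls(**d)


#: Convenience knob names mapping the eight enzyme activities onto channels.
KNOB_NAMES = ("trxg", "utx", "cbp", "prc1", "prc2", "kdm", "nurd", "prdub")

_KNOB_TO_MULTIPLIER = {
    "trxg": "trxg",
    "utx": "trxg_utx",
    "cbp": "trxg_cbp",
    "prc1": "prc1",
    "prc2": "prc2",
    "kdm": "prc2_kdm",
    "nurd": "prc2_kdm_nurd",
}


def apply_knob(config: SimulationConfig, name: str, value) -> SimulationConfig:
    """Return a config with one named parameter set.

    Accepts enzyme knobs ("nurd" sets both the direct deacetylation rate
    and the recruited NURD-compound multiplier; "prdub" sets the direct
    deubiquitination rate), raw multiplier field names, and any
    SimulationConfig field name.
    """
    if name == "nurd":
        mult = replace(config.multipliers, prc2_kdm_nurd=value)
        return replace(config, nurd_direct=value, multipliers=mult)
    if name == "prdub":
        return replace(config, prdub_direct=value)
    if name in _KNOB_TO_MULTIPLIER:
        mult = replace(config.multipliers, **{_KNOB_TO_MULTIPLIER[name]: value})
        return replace(config, multipliers=mult)
    if name in {f.name for f in fields(RateModifiers)}:
        mult = replace(config.multipliers, **{name: value})
        return replace(config, multipliers=mult)
    if name in {f.name for f in fields(SimulationConfig)}:
        return replace(config, **{name: value})
    raise ValueError(f"unknown parameter name: {name!r}")


@dataclass(frozen=True)
class MoveDraw:
    """One draw of the four competing channel clocks."""

    t1: float
    t2: float
    t3: float
    t4: float
    chosen: int  # channel id, index into CHANNEL_NAMES
    dt: float


def draw_move(rng: np.random.Generator, beta: float, dn: float, dp: float) -> MoveDraw:
    """Draw the four channel clocks; consumes exactly four uniforms.

    The channel with the smallest increment wins.  A zero rate yields an
    infinite increment.  All rates zero is an error.
    """
    if beta == 0 and dn == 0 and dp == 0:
        # recruitment always has rate 1, so this only documents the contract
        pass
    u = [rng.random() for _ in range(4)]
    t1 = -math.log(u[0])
    t2 = -math.log(u[1]) / beta if beta > 0 else math.inf
    t3 = -math.log(u[2]) / dn if dn > 0 else math.inf
    t4 = -math.log(u[3]) / dp if dp > 0 else math.inf
    ts = (t1, t2, t3, t4)
    chosen = int(np.argmin(ts))
    return MoveDraw(t1, t2, t3, t4, chosen, ts[chosen])


def recruitment_step(
    array: np.ndarray, rng: np.random.Generator, multipliers: RateModifiers
) -> tuple[int, int, Enzyme] | None:
    """Attempt one recruited conversion, mutating ``array`` in place.

    Returns (target index, new state, enzyme) when a change was accepted,
    None otherwise.  Mirrors the kernel's RNG consumption order.
    """
    n = len(array)
    mult = multipliers.as_array()
    m_max = max(1.0, float(mult.max()))
    r = int(rng.integers(n))
    recruiters = RECRUITED_BY[int(array[r])]
    if not recruiters:
        return None
    if len(recruiters) == 1:
        e = recruiters[0]
    else:
        e = recruiters[int(rng.integers(len(recruiters)))]
    tgt = int(rng.integers(n - 1))
    if tgt >= r:
        tgt += 1
    new = int(ACTION_TABLE[e, int(array[tgt])])
    if new == 0:
        return None
    p = mult[e] / m_max
    if p < 1.0 and rng.random() >= p:
        return None
    array[tgt] = new
    return tgt, new, e


def replicate(array: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Reset each half independently to the unmodified state with prob. 1/2."""
    for k in range(len(array)):
        if rng.random() < 0.5:
            array[k] = UNMODIFIED_STATE
    return array


@dataclass
class Trajectory:
    """Time-stamped samples of the full array state.

    ``times`` are plotted time units (raw time / N); samples are evenly
    spaced at the configured sample interval, starting at time 0.
    """

    times: np.ndarray          # (S,), plotted units
    states: np.ndarray         # (S, n), int8, half-state indices 1..12
    replication_times: np.ndarray  # plotted units
    config: SimulationConfig
    stats: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def n_halves(self) -> int:
        return self.states.shape[1]

    def whole_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Half-state indices of (first, second) halves of each nucleosome."""
        return self.states[:, 0::2], self.states[:, 1::2]

    def category_counts(self) -> np.ndarray:
        """(S, 6) counts of whole nucleosomes per category at each sample."""
        first, second = self.whole_pairs()
        cats = CATEGORY_TABLE[first, second]  # (S, n/2), values 1..6
        counts = np.zeros((self.n_samples, 6), dtype=np.int64)
        for c in range(1, 7):
            counts[:, c - 1] = (cats == c).sum(axis=1)
        return counts

    def category_fractions(self) -> np.ndarray:
        """(S, 6) per-sample fractions of whole nucleosomes per category."""
        counts = self.category_counts()
        return counts / counts.sum(axis=1, keepdims=True)


def _initial_array(config: SimulationConfig) -> np.ndarray:
    if config.initial_condition == "all_unmodified":
        return np.full(config.n, UNMODIFIED_STATE, dtype=np.int8)
    if config.initial_condition == "all_active":
        return np.full(config.n, 1, dtype=np.int8)
    if config.initial_condition == "all_silent":
        return np.full(config.n, 11, dtype=np.int8)
    # uniform_random: drawn from a separate init stream so the kernel's
    # event stream is unchanged across initial conditions
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x1B17]))
    return rng.integers(1, N_HALF_STATES + 1, size=config.n).astype(np.int8)


def run(config: SimulationConfig) -> Trajectory:
    """Run one simulation; deterministic given ``config.seed``."""
    from ._kernel import simulate

    n = config.n
    dur_raw = config.duration * n
    samp_raw = config.sample_interval * n
    gen_raw = config.generation_time * n
    max_samples = int(math.floor(config.duration / config.sample_interval)) + 1
    max_reps = (int(dur_raw / gen_raw) + 2) if (config.replication_on and gen_raw > 0) else 1

    init = _initial_array(config)
    tabs = DIRECT_TABLES
    samples, n_samp, rep_times, n_rep, stats = simulate(
        int(config.seed) & 0xFFFFFFFF,
        init,
        float(config.beta),
        float(config.nurd_direct),
        float(config.prdub_direct),
        config.multipliers.as_array(),
        ACTION_TABLE,
        RECRUIT_LISTS,
        RECRUIT_COUNTS,
        tabs["k27_down"],
        tabs["k27_ac"],
        tabs["k27_me3"],
        tabs["k436_toggle"],
        tabs["h2a_toggle"],
        tabs["nurd"],
        tabs["prdub"],
        bool(config.replication_on),
        float(gen_raw),
        float(dur_raw),
        float(samp_raw),
        max_samples,
        max_reps,
    )
    times = np.arange(n_samp, dtype=np.float64) * config.sample_interval
    stats_dict = {
        "attempts": {CHANNEL_NAMES[i]: int(stats[i]) for i in range(4)},
        "executed": {CHANNEL_NAMES[i]: int(stats[4 + i]) for i in range(4)},
        "enzyme_chosen": {Enzyme(e).name: int(stats[8 + e]) for e in range(N_ENZYMES)},
        "enzyme_accepted": {Enzyme(e).name: int(stats[15 + e]) for e in range(N_ENZYMES)},
        "replications": int(stats[22]),
    }
    return Trajectory(
        times=times,
        states=samples[:n_samp].copy(),
        replication_times=(rep_times[: min(n_rep, len(rep_times))] / n).copy(),
        config=config,
        stats=stats_dict,
    )
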