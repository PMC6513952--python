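"""Parameter sweeps and phase diagrams.

Grids of simulations over one or two parameters, each cell classified into
an active / silent / bistable / other regime.  Cell seeds derive
independently from the base seed so cells can run in any order (or in
parallel) with identical results.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .analysis import BistabilityParams, RegimeCall, classify_regime
from .engine import SimulationConfig, apply_knob, run

__all__ = [
    "SweepAxis",
    "SweepSpec",
    "CellResult",
    "PhaseDiagram",
    "LadderResult",
    "log2_ladder",
    "grid_sweep",
    "boundary_scan",
    "cell_seed",
    "find_reference_regimes",
]

_REGIME_ORDER = ("active", "silent", "bistable", "other")


def log2_ladder(center: float = 1.0, low: int = -6, high: int = 6) -> list[float]:
    """2-fold spaced values center * 2**k for k in [low, high]."""
    return [center * 2.0**k for k in range(low, high + 1)]


@dataclass(frozen=True)
class SweepAxis:
    """One swept parameter: a knob/field name and its value list."""

    parameter: str
    values: tuple[float, ...]

    def __init__(self, parameter: str, values) -> None:
        object.__setattr__(self, "parameter", parameter)
        object.__setattr__(self, "values", tuple(values))


@dataclass(frozen=True)
class SweepSpec:
    base: SimulationConfig
    axes: tuple[SweepAxis, ...]
    seeds_per_cell: int = 3
    bistability: BistabilityParams = field(default_factory=BistabilityParams)

    def __post_init__(self) -> None:
        if not 1 <= len(self.axes) <= 2:
            raise ValueError("sweep requires one or two axes")
        for ax in self.axes:
            # validate the parameter name before any run
            apply_knob(self.base, ax.parameter, ax.values[0])
        if self.seeds_per_cell < 1:
            raise ValueError("seeds_per_cell must be >= 1")


@dataclass
class CellResult:
    values: tuple[float, ...]
    calls: list[RegimeCall]
    seeds: list[int]

    @property
    def regime(self) -> str:
        """Majority-vote regime over the cell's replicate seeds."""
        counts = Counter(c.regime for c in self.calls)
        best = max(counts.values())
        # deterministic tie-break by fixed regime order
        for r in _REGIME_ORDER:
            if counts.get(r, 0) == best:
                return r
        raise AssertionError("unreachable")

    @property
    def category_averages(self) -> np.ndarray:
        return np.mean([c.category_averages for c in self.calls], axis=0)


@dataclass
class PhaseDiagram:
    spec: SweepSpec
    cells: dict[tuple[int, ...], CellResult]

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(ax.values) for ax in self.spec.axes)

    def regime_grid(self) -> np.ndarray:
        grid = np.empty(self.shape, dtype=object)
        for idx, cell in self.cells.items():
            grid[idx] = cell.regime
        return grid


def cell_seed(base_seed: int, *indices: int) -> int:
    """Deterministic per-cell seed, independent of execution order."""
    ss = np.random.SeedSequence([int(base_seed) & 0xFFFFFFFF, *indices])
    return int(ss.generate_state(1)[0])


def _cell_indices(shape: tuple[int, ...]):
    if len(shape) == 1:
        for i in range(shape[0]):
            yield (i,)
    else:
        for i in range(shape[0]):
            for j in range(shape[1]):
                yield (i, j)


def grid_sweep(spec: SweepSpec) -> PhaseDiagram:
    """Run and classify every cell of the sweep grid."""
    shape = tuple(len(ax.values) for ax in spec.axes)
    cells: dict[tuple[int, ...], CellResult] = {}
    for idx in _cell_indices(shape):
        values = tuple(ax.values[k] for ax, k in zip(spec.axes, idx))
        config = spec.base
        for ax, v in zip(spec.axes, values):
            config = apply_knob(config, ax.parameter, v)
        calls, seeds = [], []
        for rep in range(spec.seeds_per_cell):
            seed = cell_seed(spec.base.seed, *idx, rep)
            traj = run(apply_knob(config, "seed", seed))
            calls.append(classify_regime(traj, spec.bistability))
            seeds.append(seed)
        cells[idx] = CellResult(values=values, calls=calls, seeds=seeds)
    return PhaseDiagram(spec=spec, cells=cells)


@dataclass
class LadderResult:
    """Regime calls along a 2-fold parameter ladder."""

    parameter: str
    values: list[float]
    calls: list[RegimeCall]
    first_silent: int | None  # index into values, or None if not found
    first_active: int | None

    @property
    def regimes(self) -> list[str]:
        return [c.regime for c in self.calls]


def boundary_scan(
    base: SimulationConfig,
    parameter: str,
    factor: float = 2.0,
    start: float = 1.0,
    max_steps: int = 8,
    params: BistabilityParams | None = None,
) -> LadderResult:
    """Scan a parameter up and down a geometric ladder from ``start``.

    Walks upward (multiplying by ``factor``) until a silent-dominant run is
    found and downward until an active-dominant run is found, classifying
    each run.  Missing switches are flagged by None indices, not an error.
    Ladder points reuse deterministic seeds derived from the base config
    seed and the ladder exponent.
    """
    apply_knob(base, parameter, start)  # validate name early
    if params is None:
        params = BistabilityParams()

    def call_at(k: int) -> RegimeCall:
        v = start * factor**k
        cfg = apply_knob(base, parameter, v)
        cfg = apply_knob(cfg, "seed", cell_seed(base.seed, 64 + k))
        return classify_regime(run(cfg), params)

    calls: dict[int, RegimeCall] = {0: call_at(0)}

    def is_silent(c: RegimeCall) -> bool:
        return c.regime == "silent"

    def is_active(c: RegimeCall) -> bool:
        return c.regime == "active"

    k = 0
    while not is_silent(calls[k]) and k < max_steps:
        k += 1
        calls[k] = call_at(k)
    k_hi = k

    k = 0
    while not is_active(calls[k]) and k > -max_steps:
        k -= 1
        calls[k] = call_at(k)
    k_lo = k

    exps = sorted(calls)
    values = [start * factor**e for e in exps]
    ordered = [calls[e] for e in exps]
    first_silent = exps.index(k_hi) if is_silent(calls[k_hi]) else None
    first_active = exps.index(k_lo) if is_active(calls[k_lo]) else None
    return LadderResult(
        parameter=parameter,
        values=values,
        calls=ordered,
        first_silent=first_silent,
        first_active=first_active,
    )


def find_reference_regimes(
    base: SimulationConfig | None = None,
    factor: float = 2.0,
    max_steps: int = 8,
    refine_steps: int = 4,
    params: BistabilityParams | None = None,
) -> dict[str, float]:
    """Locate active / bistable / silent deacetylation (NURD) settings.

    Scans the NURD knob on a 2-fold ladder from 1.0 for the first
    silent-dominant and first active-dominant rungs, then bisects
    geometrically between them on the sign of (avg cat1 - avg cat5) to
    find a *balanced* bistable setting: at 2-fold rung granularity a
    bistable run dwells mostly on one side, so the rungs themselves make
    poor landscape references.  Raises if no bistable point is found.
    """
    if base is None:
        base = SimulationConfig()
    ladder = boundary_scan(
        base, "nurd", factor=factor, start=1.0, max_steps=max_steps, params=params
    )
    if ladder.first_active is None or ladder.first_silent is None:
        raise RuntimeError(
            f"NURD ladder found no active/silent pair: {ladder.regimes}"
        )
    lo, hi = ladder.first_active, ladder.first_silent
    if "bistable" not in ladder.regimes[lo + 1 : hi]:
        raise RuntimeError(
            f"no bistable rung between active and silent: {ladder.regimes}"
        )

    if params is None:
        params = BistabilityParams()
    best_value = None
    best_imbalance = np.inf
    for k in range(lo + 1, hi):
        c = ladder.calls[k]
        if c.regime == "bistable" and abs(c.avg_cat1 - c.avg_cat5) < best_imbalance:
            best_imbalance = abs(c.avg_cat1 - c.avg_cat5)
            best_value = ladder.values[k]

    a, b = ladder.values[lo], ladder.values[hi]
    for step in range(refine_steps):
        v = float(np.sqrt(a * b))
        cfg = apply_knob(base, "nurd", v)
        # two replicate runs per bisection point: a single run's basin split
        # is too noisy to steer the bracket reliably
        calls = [
            classify_regime(
                run(apply_knob(cfg, "seed", cell_seed(base.seed, 128 + step, r))),
                params,
            )
            for r in range(2)
        ]
        balance = float(np.mean([c.avg_cat1 - c.avg_cat5 for c in calls]))
        if all(c.regime == "bistable" for c in calls) and abs(balance) < best_imbalance:
            best_imbalance = abs(balance)
            best_value = v
        if balance > 0:
            a = v
        else:
            b = v
    if best_value is None:
        raise RuntimeError("bisection found no bistable point")
    return {
        "active": ladder.values[lo],
        "bistable": best_value,
        "silent": ladder.values[hi],
    }
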