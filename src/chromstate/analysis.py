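"""Trajectory summary statistics.

Category occupancy time courses, 12x12 time-averaged whole-nucleosome
landscapes, regime classification (active / silent / bistable / other) and
co-occurrence statistics of opposing marks.  All time averages are plain
means over the evenly spaced trajectory samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Trajectory
from .states import (
    H2AUB_STATES,
    K27AC_STATES,
    K27ME3_STATES,
    K436ME_STATES,
    N_HALF_STATES,
)

__all__ = [
    "OccupancySeries",
    "BistabilityParams",
    "RegimeCall",
    "category_occupancy",
    "landscape",
    "classify_regime",
    "tail_coexistence",
    "pairwise_bivalent_fraction",
    "mark_ratio_in_double_marked",
    "MARK_STATES",
    "ACTIVE_MARKS",
    "SILENT_MARKS",
]

#: Half-state index sets carrying each of the four marks.
MARK_STATES = {
    "K27ac": K27AC_STATES,
    "K27me3": K27ME3_STATES,
    "K4/36me": K436ME_STATES,
    "H2Aub": H2AUB_STATES,
}
ACTIVE_MARKS = ("K27ac", "K4/36me")
SILENT_MARKS = ("K27me3", "H2Aub")


@dataclass
class OccupancySeries:
    """Per-sample category fractions plus their time averages."""

    times: np.ndarray        # (S,)
    fractions: np.ndarray    # (S, 6), rows sum to 1
    averages: np.ndarray     # (6,)


def _require_samples(traj: Trajectory) -> None:
    if traj.n_samples == 0:
        raise ValueError("trajectory has no samples")


def category_occupancy(traj: Trajectory) -> OccupancySeries:
    """Fraction of whole nucleosomes in each category over time."""
    _require_samples(traj)
    fractions = traj.category_fractions()
    return OccupancySeries(
        times=traj.times, fractions=fractions, averages=fractions.mean(axis=0)
    )


def landscape(traj: Trajectory) -> np.ndarray:
    """Time-averaged occupancy of the 144 whole-nucleosome states.

    Returns a 12x12 matrix L where L[i-1, j-1] is the probability that a
    whole nucleosome has first half in state i and second half in state j;
    entries sum to 1.
    """
    _require_samples(traj)
    first, second = traj.whole_pairs()
    flat = (first.astype(np.int64) - 1) * N_HALF_STATES + (second.astype(np.int64) - 1)
    counts = np.bincount(flat.ravel(), minlength=N_HALF_STATES**2)
    mat = counts.reshape(N_HALF_STATES, N_HALF_STATES).astype(np.float64)
    return mat / mat.sum()


@dataclass(frozen=True)
class BistabilityParams:
    """Thresholds for the regime classifier.

    A trajectory is bistable when it makes at least ``min_round_trips``
    transitions in each direction between epochs with more than
    ``dominance_threshold`` category-1 nucleosomes and epochs with more
    than that fraction of category-5 nucleosomes, and the mean epoch
    lifetime of both epoch types is at least ``min_mean_lifetime`` plotted
    time units.  Otherwise the call falls back to time-averaged dominance
    of category 1 (active) or 5 (silent) above ``dominance_avg_threshold``.
    """

    dominance_threshold: float = 0.6
    min_mean_lifetime: float = 40.0
    min_round_trips: int = 2
    dominance_avg_threshold: float = 0.5
    strict_epochs: bool = False

    def __post_init__(self) -> None:
        if not 0.5 < self.dominance_threshold <= 1.0:
            raise ValueError("dominance_threshold must be in (0.5, 1]")


@dataclass
class RegimeCall:
    """Outcome of regime classification with supporting statistics."""

    regime: str  # "active" | "silent" | "bistable" | "other"
    avg_cat1: float
    avg_cat5: float
    n_active_epochs: int = 0
    n_silent_epochs: int = 0
    transitions_to_silent: int = 0
    transitions_to_active: int = 0
    mean_active_lifetime: float = float("nan")
    mean_silent_lifetime: float = float("nan")
    category_averages: np.ndarray | None = None


def _segment_epochs(
    times: np.ndarray,
    cat1: np.ndarray,
    cat5: np.ndarray,
    threshold: float,
    strict: bool,
) -> list[tuple[str, float, float]]:
    """Segment the time series into active/silent dominance epochs.

    In the default (non-strict) mode, samples in neither dominance zone
    continue the current epoch, so brief excursions below threshold do not
    split an epoch.  In strict mode they terminate it.
    """
    epochs: list[tuple[str, float, float]] = []
    label: str | None = None
    start = 0.0
    last_time = times[0] if len(times) else 0.0
    for t, a, s in zip(times, cat1, cat5):
        if a > threshold:
            zone = "active"
        elif s > threshold:
            zone = "silent"
        else:
            zone = None
        if zone is None:
            if strict and label is not None:
                epochs.append((label, start, t))
                label = None
            last_time = t
            continue
        if label is None:
            label = zone
            start = t
        elif zone != label:
            epochs.append((label, start, t))
            label = zone
            start = t
        last_time = t
    if label is not None:
        epochs.append((label, start, max(last_time, times[-1])))
    return epochs


def classify_regime(
    traj: Trajectory, params: BistabilityParams | None = None
) -> RegimeCall:
    """Classify a trajectory as active, silent, bistable, or other."""
    _require_samples(traj)
    if params is None:
        params = BistabilityParams()
    occ = category_occupancy(traj)
    cat1 = occ.fractions[:, 0]
    cat5 = occ.fractions[:, 4]
    epochs = _segment_epochs(
        occ.times, cat1, cat5, params.dominance_threshold, params.strict_epochs
    )

    active_lifetimes = [e - s for lab, s, e in epochs if lab == "active"]
    silent_lifetimes = [e - s for lab, s, e in epochs if lab == "silent"]
    to_silent = sum(
        1
        for k in range(1, len(epochs))
        if epochs[k - 1][0] == "active" and epochs[k][0] == "silent"
    )
    to_active = sum(
        1
        for k in range(1, len(epochs))
        if epochs[k - 1][0] == "silent" and epochs[k][0] == "active"
    )

    mean_active = float(np.mean(active_lifetimes)) if active_lifetimes else float("nan")
    mean_silent = float(np.mean(silent_lifetimes)) if silent_lifetimes else float("nan")

    bistable = (
        to_silent >= params.min_round_trips
        and to_active >= params.min_round_trips
        and mean_active >= params.min_mean_lifetime
        and mean_silent >= params.min_mean_lifetime
    )
    if bistable:
        regime = "bistable"
    elif occ.averages[0] > params.dominance_avg_threshold:
        regime = "active"
    elif occ.averages[4] > params.dominance_avg_threshold:
        regime = "silent"
    else:
        regime = "other"

    return RegimeCall(
        regime=regime,
        avg_cat1=float(occ.averages[0]),
        avg_cat5=float(occ.averages[4]),
        n_active_epochs=len(active_lifetimes),
        n_silent_epochs=len(silent_lifetimes),
        transitions_to_silent=to_silent,
        transitions_to_active=to_active,
        mean_active_lifetime=mean_active,
        mean_silent_lifetime=mean_silent,
        category_averages=occ.averages,
    )


def _state_mask(mark: str) -> np.ndarray:
    if mark not in MARK_STATES:
        raise ValueError(f"unknown mark {mark!r}; expected one of {sorted(MARK_STATES)}")
    mask = np.zeros(N_HALF_STATES + 1, dtype=bool)
    for s in MARK_STATES[mark]:
        mask[s] = True
    return mask


def tail_coexistence(traj: Trajectory) -> float:
    """Fraction of K27me3-bearing halves that also carry K4/36 methylation.

    Returns NaN when no half ever carries K27me3.
    """
    _require_samples(traj)
    me3 = _state_mask("K27me3")[traj.states]
    both = (_state_mask("K27me3") & _state_mask("K4/36me"))[traj.states]
    denom = me3.sum()
    if denom == 0:
        return float("nan")
    return float(both.sum() / denom)


def pairwise_bivalent_fraction(traj: Trajectory, mark_a: str, mark_b: str) -> float:
    """Time-averaged fraction of whole nucleosomes carrying both marks.

    The marks must be an opposing (one active, one silent) pair; either
    half of the nucleosome may carry either mark.
    """
    _require_samples(traj)
    both_active = mark_a in ACTIVE_MARKS and mark_b in ACTIVE_MARKS
    both_silent = mark_a in SILENT_MARKS and mark_b in SILENT_MARKS
    if both_active or both_silent:
        raise ValueError(f"marks must be an opposing pair, got {mark_a!r}, {mark_b!r}")
    mask_a = _state_mask(mark_a)
    mask_b = _state_mask(mark_b)
    first, second = traj.whole_pairs()
    has_a = mask_a[first] | mask_a[second]
    has_b = mask_b[first] | mask_b[second]
    return float((has_a & has_b).mean())


def mark_ratio_in_double_marked(traj: Trajectory) -> float:
    """Ratio of K27me3-bearing to K4/36me-bearing halves among nucleosomes
    carrying both marks.

    Counts are pooled over all samples and qualifying nucleosomes.
    Returns NaN when no nucleosome ever carries both marks.
    """
    _require_samples(traj)
    me3_mask = _state_mask("K27me3")
    k4_mask = _state_mask("K4/36me")
    first, second = traj.whole_pairs()
    me3_halves = me3_mask[first].astype(np.int64) + me3_mask[second].astype(np.int64)
    k4_halves = k4_mask[first].astype(np.int64) + k4_mask[second].astype(np.int64)
    qualifying = (me3_halves > 0) & (k4_halves > 0)
    k4_total = k4_halves[qualifying].sum()
    if k4_total == 0:
        return float("nan")
    return float(me3_halves[qualifying].sum() / k4_total)
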