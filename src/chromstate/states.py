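"""Half- and whole-nucleosome modification states.

A half-nucleosome is one H3 tail plus one H2A tail.  Three sites can be
modified: H3K27 (unmodified, acetylated, or trimethylated — acetylation and
trimethylation are mutually exclusive on the same tail), the fused H3K4/K36
methylation site, and H2A ubiquitination.  That gives 3 x 2 x 2 = 12 half
states.  Two position-paired halves form a whole nucleosome, giving 144
ordered whole-nucleosome states, which are classified into six categories
by the balance of active (K27ac, K4/36me) versus silent (K27me3, H2Aub)
marks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "HalfState",
    "WholeNucleosome",
    "N_HALF_STATES",
    "N_WHOLE_STATES",
    "enumerate_half_states",
    "half_state_index",
    "half_state_from_index",
    "mark_counts",
    "classify_category",
    "classify_category_indices",
    "count_category_forms",
    "CATEGORY_TABLE",
    "ACTIVE_COUNT",
    "SILENT_COUNT",
    "K27AC_STATES",
    "K27ME3_STATES",
    "K436ME_STATES",
    "H2AUB_STATES",
    "UNMODIFIED_STATE",
]

K27_VALUES = ("none", "ac", "me3")
K436_VALUES = ("none", "me")
H2A_VALUES = ("none", "ub")

N_HALF_STATES = 12
N_WHOLE_STATES = 144

#: Index of the fully unmodified half state.
UNMODIFIED_STATE = 8

# Index layout (1..12): states 1-4 carry K27ac, 5-8 no K27 mark, 9-12 K27me3.
# Within each block of four the (K4/36, H2A) combination runs
# (me,-), (me,ub), (-,ub), (-,-).
_K27_BLOCK = {"ac": 0, "none": 1, "me3": 2}
_OFFSET = {("me", "none"): 0, ("me", "ub"): 1, ("none", "ub"): 2, ("none", "none"): 3}


@dataclass(frozen=True, order=True)
class HalfState:
    """Modification state of one half-nucleosome (one H3 + one H2A tail)."""

    k27: str
    k436: str
    h2a: str

    def __post_init__(self) -> None:
        if self.k27 not in K27_VALUES:
            raise ValueError(f"invalid k27 value: {self.k27!r}")
        if self.k436 not in K436_VALUES:
            raise ValueError(f"invalid k436 value: {self.k436!r}")
        if self.h2a not in H2A_VALUES:
            raise ValueError(f"invalid h2a value: {self.h2a!r}")

    @property
    def index(self) -> int:
        return half_state_index(self)

    @property
    def active_marks(self) -> int:
        """Number of active marks (K27ac, K4/36me) on this half."""
        return int(self.k27 == "ac") + int(self.k436 == "me")

    @property
    def silent_marks(self) -> int:
        """Number of silent marks (K27me3, H2Aub) on this half."""
        return int(self.k27 == "me3") + int(self.h2a == "ub")


@dataclass(frozen=True)
class WholeNucleosome:
    """An ordered pair of half-nucleosomes (ordered by array position)."""

    first: HalfState
    second: HalfState

    @classmethod
    def from_indices(cls, i: int, j: int) -> "WholeNucleosome":
        return cls(half_state_from_index(i), half_state_from_index(j))


def half_state_index(h: HalfState) -> int:
    """Return the 1..12 index of a half state."""
    return _K27_BLOCK[h.k27] * 4 + _OFFSET[(h.k436, h.h2a)] + 1


def half_state_from_index(i: int) -> HalfState:
    """Inverse of :func:`half_state_index`."""
    if not 1 <= i <= N_HALF_STATES:
        raise ValueError(f"half-state index out of range 1..12: {i}")
    return _STATES_BY_INDEX[i - 1]


def enumerate_half_states() -> tuple[HalfState, ...]:
    """All 12 allowed half-nucleosome states, in index order 1..12."""
    return _STATES_BY_INDEX


def _enumerate_raw() -> Iterator[HalfState]:
    for k27, k436, h2a in itertools.product(K27_VALUES, K436_VALUES, H2A_VALUES):
        yield HalfState(k27, k436, h2a)


_STATES_BY_INDEX: tuple[HalfState, ...] = tuple(
    sorted(_enumerate_raw(), key=half_state_index)
)

# Per-index mark counts, 1-indexed (slot 0 unused).
ACTIVE_COUNT = np.zeros(N_HALF_STATES + 1, dtype=np.int8)
SILENT_COUNT = np.zeros(N_HALF_STATES + 1, dtype=np.int8)
for _h in _STATES_BY_INDEX:
    ACTIVE_COUNT[_h.index] = _h.active_marks
    SILENT_COUNT[_h.index] = _h.silent_marks

K27AC_STATES = frozenset(h.index for h in _STATES_BY_INDEX if h.k27 == "ac")
K27ME3_STATES = frozenset(h.index for h in _STATES_BY_INDEX if h.k27 == "me3")
K436ME_STATES = frozenset(h.index for h in _STATES_BY_INDEX if h.k436 == "me")
H2AUB_STATES = frozenset(h.index for h in _STATES_BY_INDEX if h.h2a == "ub")


def mark_counts(w: WholeNucleosome) -> tuple[int, int]:
    """(active, silent) mark counts over both halves of a whole nucleosome."""
    active = w.first.active_marks + w.second.active_marks
    silent = w.first.silent_marks + w.second.silent_marks
    return active, silent


def classify_category(w: WholeNucleosome) -> int:
    """Classify a whole nucleosome into one of six categories.

    1: active only; 2: mostly-active bivalent; 3: balanced bivalent;
    4: mostly-silent bivalent; 5: silent only; 6: unmodified.
    """
    active, silent = mark_counts(w)
    if active == 0 and silent == 0:
        return 6
    if silent == 0:
        return 1
    if active == 0:
        return 5
    frac = silent / (active + silent)
    if frac < 0.5:
        return 2
    if frac == 0.5:
        return 3
    return 4


def _build_category_table() -> np.ndarray:
    table = np.zeros((N_HALF_STATES + 1, N_HALF_STATES + 1), dtype=np.int8)
    for i in range(1, N_HALF_STATES + 1):
        for j in range(1, N_HALF_STATES + 1):
            table[i, j] = classify_category(WholeNucleosome.from_indices(i, j))
    return table


#: 13x13 lookup (1-indexed on both axes): category of whole nucleosome (i, j).
CATEGORY_TABLE = _build_category_table()
CATEGORY_TABLE.setflags(write=False)


def classify_category_indices(i: int, j: int) -> int:
    """Category of the whole nucleosome with half-state indices (i, j)."""
    if not (1 <= i <= N_HALF_STATES and 1 <= j <= N_HALF_STATES):
        raise ValueError(f"half-state indices out of range: ({i}, {j})")
    return int(CATEGORY_TABLE[i, j])


def count_category_forms() -> dict[int, int]:
    """Number of the 144 ordered whole-nucleosome forms in each category."""
    counts = {c: 0 for c in range(1, 7)}
    for i in range(1, N_HALF_STATES + 1):
        for j in range(1, N_HALF_STATES + 1):
            counts[int(CATEGORY_TABLE[i, j])] += 1
    return counts
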