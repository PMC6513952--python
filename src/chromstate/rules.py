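"""Enzymatic conversion rules.

Seven recruited read-write / read-erase complexes act between half
nucleosomes: a reader binds marks on one half and its catalytic subunit
(the last-listed enzyme of a compound complex) writes or erases exactly one
mark on another half.  Three non-recruited channels also exist: the generic
direct-conversion channel (rate beta), direct deacetylation (NURD) and
direct deubiquitination (PR-DUB).

Inhibitions are encoded both on the reader side (which states recruit which
complexes) and on the writer side (which target states a complex can
change):

* H2Aub blocks K4/36 methylation of the carrying half, and K27ac+H2Aub
  states do not recruit the bare K4/36 methyltransferase.
* K4/36me blocks K27 trimethylation of the carrying half, and
  K27me3+K4/36me states do not recruit the bare trimethyltransferase.
* K27me3-carrying states never recruit the activating complexes.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

from .states import (
    N_HALF_STATES,
    HalfState,
    half_state_from_index,
    half_state_index,
)

__all__ = [
    "Enzyme",
    "N_ENZYMES",
    "RECRUITERS",
    "RECRUITED_BY",
    "ACTION_TABLE",
    "recruited_complexes",
    "apply_enzyme",
    "direct_conversion",
    "direct_nurd",
    "direct_prdub",
    "DIRECT_SITES",
]


class Enzyme(IntEnum):
    """The seven recruited complexes (compounds: last-listed part is catalytic)."""

    TRXG = 0
    TRXG_UTX = 1
    TRXG_CBP = 2
    PRC1 = 3
    PRC2 = 4
    PRC2_KDM = 5
    PRC2_KDM_NURD = 6


N_ENZYMES = len(Enzyme)

# Reader side: which half-nucleosome states recruit each complex.
# K27ac states (1-4) recruit the TrxG complexes, but H2Aub (states 2, 3)
# blocks recruitment of bare TRXG (its methyltransferase activity is the
# inhibited one; the compound complexes act through UTX/CBP instead).
# K4/36me without PRC1 recruitment (states 1, 2, 5, 6) recruits CBP-bearing
# complexes.  K27me3 states (9-12) recruit PRC1.  PRC2 is recruited by
# K27me3 (11, 12) and H2Aub (3, 7, 11) but not by K4/36me-carrying states
# (9, 10), whose mark inhibits its catalysis; the compound PRC2:KDM(:NURD)
# complexes bind any K27me3- or H2Aub-carrying state (2, 3, 6, 7, 9-12).
RECRUITERS: dict[Enzyme, frozenset[int]] = {
    Enzyme.TRXG: frozenset({1, 4}),
    Enzyme.TRXG_UTX: frozenset({1, 2, 3, 4}),
    Enzyme.TRXG_CBP: frozenset({1, 2, 3, 4, 5, 6}),
    Enzyme.PRC1: frozenset({9, 10, 11, 12}),
    Enzyme.PRC2: frozenset({3, 7, 11, 12}),
    Enzyme.PRC2_KDM: frozenset({2, 3, 6, 7, 9, 10, 11, 12}),
    Enzyme.PRC2_KDM_NURD: frozenset({2, 3, 6, 7, 9, 10, 11, 12}),
}

#: Per state 1..12, tuple of enzymes it recruits (state 8 recruits none).
RECRUITED_BY: tuple[tuple[Enzyme, ...], ...] = tuple(
    tuple(e for e in Enzyme if s in RECRUITERS[e])
    for s in range(0, N_HALF_STATES + 1)
)


def recruited_complexes(s: int) -> frozenset[Enzyme]:
    """Set of complexes recruited by a half-nucleosome in state ``s``."""
    if not 1 <= s <= N_HALF_STATES:
        raise ValueError(f"half-state index out of range 1..12: {s}")
    return frozenset(RECRUITED_BY[s])


def _enzyme_product(e: Enzyme, h: HalfState) -> HalfState | None:
    """Writer side: what ``e`` does to a target half in state ``h``.

    Returns None when the enzyme cannot act (target already carries the
    product, or carries a mark that inhibits the reaction).
    """
    if e is Enzyme.TRXG:
        # H2Aub on the target inhibits K4/36 methyltransferases.
        if h.k436 == "none" and h.h2a == "none":
            return HalfState(h.k27, "me", h.h2a)
    elif e is Enzyme.TRXG_UTX:
        if h.k27 == "me3":
            return HalfState("none", h.k436, h.h2a)
    elif e is Enzyme.TRXG_CBP:
        if h.k27 == "none":
            return HalfState("ac", h.k436, h.h2a)
    elif e is Enzyme.PRC1:
        if h.h2a == "none":
            return HalfState(h.k27, h.k436, "ub")
    elif e is Enzyme.PRC2:
        # K4/36me on the target inhibits PRC2 catalysis.
        if h.k27 == "none" and h.k436 == "none":
            return HalfState("me3", h.k436, h.h2a)
    elif e is Enzyme.PRC2_KDM:
        if h.k436 == "me":
            return HalfState(h.k27, "none", h.h2a)
    elif e is Enzyme.PRC2_KDM_NURD:
        if h.k27 == "ac":
            return HalfState("none", h.k436, h.h2a)
    return None


def _build_action_table() -> np.ndarray:
    table = np.zeros((N_ENZYMES, N_HALF_STATES + 1), dtype=np.int8)
    for e in Enzyme:
        for s in range(1, N_HALF_STATES + 1):
            product = _enzyme_product(e, half_state_from_index(s))
            table[e, s] = 0 if product is None else half_state_index(product)
    return table


#: (enzyme, state 1..12) -> product state, 0 meaning no-op.
ACTION_TABLE = _build_action_table()
ACTION_TABLE.setflags(write=False)


def apply_enzyme(e: Enzyme, target: int) -> int | None:
    """Product state of enzyme ``e`` acting on target state, or None (no-op)."""
    if not 1 <= target <= N_HALF_STATES:
        raise ValueError(f"half-state index out of range 1..12: {target}")
    result = int(ACTION_TABLE[e, target])
    return result if result else None


DIRECT_SITES = ("K27", "K436", "H2A")


def direct_conversion(s: int, site: str, u: float) -> int:
    """Non-recruited (beta-channel) conversion at one modification site.

    K27: a marked site (ac or me3) loses its mark; an unmarked site gains
    ac if ``u`` < 0.5 else me3.  K4/36 and H2A simply toggle (``u`` unused).
    """
    h = half_state_from_index(s)
    if site == "K27":
        if h.k27 != "none":
            out = HalfState("none", h.k436, h.h2a)
        else:
            out = HalfState("ac" if u < 0.5 else "me3", h.k436, h.h2a)
    elif site == "K436":
        out = HalfState(h.k27, "none" if h.k436 == "me" else "me", h.h2a)
    elif site == "H2A":
        out = HalfState(h.k27, h.k436, "none" if h.h2a == "ub" else "ub")
    else:
        raise ValueError(f"unknown modification site: {site!r}")
    return half_state_index(out)


def direct_nurd(s: int) -> int | None:
    """Non-recruited deacetylation: remove K27ac if present, else no-op."""
    h = half_state_from_index(s)
    if h.k27 == "ac":
        return half_state_index(HalfState("none", h.k436, h.h2a))
    return None


def direct_prdub(s: int) -> int | None:
    """Non-recruited deubiquitination: remove H2Aub if present, else no-op."""
    h = half_state_from_index(s)
    if h.h2a == "ub":
        return half_state_index(HalfState(h.k27, h.k436, "none"))
    return None


def _build_direct_tables() -> dict[str, np.ndarray]:
    """Flat 1-indexed lookup tables for the simulation kernel."""
    n = N_HALF_STATES + 1
    tabs = {
        "k27_down": np.zeros(n, dtype=np.int8),   # remove any K27 mark
        "k27_ac": np.zeros(n, dtype=np.int8),     # unmarked K27 -> ac
        "k27_me3": np.zeros(n, dtype=np.int8),    # unmarked K27 -> me3
        "k436_toggle": np.zeros(n, dtype=np.int8),
        "h2a_toggle": np.zeros(n, dtype=np.int8),
        "nurd": np.zeros(n, dtype=np.int8),
        "prdub": np.zeros(n, dtype=np.int8),
    }
    for s in range(1, n):
        h = half_state_from_index(s)
        if h.k27 == "none":
            tabs["k27_down"][s] = s
            tabs["k27_ac"][s] = direct_conversion(s, "K27", 0.0)
            tabs["k27_me3"][s] = direct_conversion(s, "K27", 1.0)
        else:
            tabs["k27_down"][s] = direct_conversion(s, "K27", 0.0)
            tabs["k27_ac"][s] = tabs["k27_me3"][s] = tabs["k27_down"][s]
        tabs["k436_toggle"][s] = direct_conversion(s, "K436", 0.0)
        tabs["h2a_toggle"][s] = direct_conversion(s, "H2A", 0.0)
        tabs["nurd"][s] = direct_nurd(s) or s
        tabs["prdub"][s] = direct_prdub(s) or s
    for t in tabs.values():
        t.setflags(write=False)
    return tabs


DIRECT_TABLES = _build_direct_tables()

# Dense recruiter lookup for the kernel: row s lists the enzymes state s
# recruits, padded with -1; RECRUIT_COUNTS[s] is the row length.
RECRUIT_LISTS = np.full((N_HALF_STATES + 1, N_ENZYMES), -1, dtype=np.int8)
RECRUIT_COUNTS = np.zeros(N_HALF_STATES + 1, dtype=np.int8)
for _s in range(1, N_HALF_STATES + 1):
    for _k, _e in enumerate(RECRUITED_BY[_s]):
        RECRUIT_LISTS[_s, _k] = int(_e)
    RECRUIT_COUNTS[_s] = len(RECRUITED_BY[_s])
RECRUIT_LISTS.setflags(write=False)
RECRUIT_COUNTS.setflags(write=False)
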