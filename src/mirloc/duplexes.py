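"""miRNA:miRNA* duplex derivation and structural-element summaries.

The duplex is the unit that gets featurized: a guide interval on the
pre-miRNA plus the star (passenger) interval read off the pair table. The
star spans the partners of the outermost paired guide bases, extended by a
2-nt 3' overhang where the sequence permits (the Dicer-product convention);
the extension is truncated at sequence and guide boundaries.

Element vocabulary (classic duplex anatomy): an unpaired run facing paired
bases on the other strand is a *bulge*; unpaired runs facing each other on
both strands form an *internal loop*; the unpaired apex of the hairpin is
the *terminal loop* and is never counted as an internal loop. Unpaired
overhangs outside the outermost duplex pair are neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoPairedBases
from .structure import UNPAIRED, FoldingEngine, PreMiRNA, surrogate_pair_energy

STAR_EXTENSION = 2  # nt of 3' overhang granted to the star strand

Interval = tuple[int, int]  # 0-based half-open


@dataclass(frozen=True)
class Duplex:
    """A guide/star strand pair on one pre-miRNA."""

    pre_ref: str
    guide: Interval
    star: Interval
    arm: str  # "5p" or "3p": which hairpin arm carries the guide
    guide_states: tuple[bool, ...]  # True where the guide position is paired
    star_states: tuple[bool, ...]

    @property
    def guide_length(self) -> int:
        return self.guide[1] - self.guide[0]


@dataclass(frozen=True)
class ElementSummary:
    """Structural elements of the duplex region."""

    bp_num: int  # paired guide positions
    num_loops: int  # internal loops (unpaired on both strands)
    num_bulges: int  # one-strand unpaired runs between duplex pairs
    ml_bulge: int  # longest run of consecutively paired guide bases
    dist_to_loop: int  # nt between the loop-proximal guide end and the terminal loop
    dist_to_helix: int  # nt between the base-proximal guide end and the stem's outermost pair


def derive_duplex(pre: PreMiRNA, guide: Interval) -> Duplex:
    """Derive the duplex for a guide interval by tracing the pair table.

    The star interval runs between the partners of the first and last paired
    guide bases (pairs closing back into the guide itself are ignored), plus
    the 3' extension.

    Raises
    ------
    NoPairedBases
        when no guide base pairs outside the guide (e.g. a candidate lying
        wholly inside the terminal loop).
    """
    gs, ge = guide
    n = len(pre)
    if not (0 <= gs < ge <= n):
        raise ValueError(f"guide interval {guide} outside sequence of length {n}")
    pt = pre.pair_table
    partners = [
        (i, int(pt[i]))
        for i in range(gs, ge)
        if pt[i] != UNPAIRED and not (gs <= pt[i] < ge)
    ]
    if not partners:
        raise NoPairedBases(f"{pre.id}: guide {guide} has no base pair outside itself")
    first_partner = partners[0][1]
    last_partner = partners[-1][1]
    ss, se = min(first_partner, last_partner), max(first_partner, last_partner) + 1

    # 2-nt 3' overhang on the star strand; its 3' end is the higher index.
    se = min(se + STAR_EXTENSION, n)
    if ss < gs:  # star 5' of the guide: do not run into the guide
        se = min(se, gs)

    loop = pre.terminal_loop()
    if loop is None:
        arm = "5p"
    else:
        loop_mid = (loop[0] + loop[1] - 1) / 2
        arm = "5p" if (gs + ge - 1) / 2 < loop_mid else "3p"

    return Duplex(
        pre_ref=pre.id,
        guide=(gs, ge),
        star=(ss, se),
        arm=arm,
        guide_states=tuple(bool(pt[i] != UNPAIRED) for i in range(gs, ge)),
        star_states=tuple(bool(pt[i] != UNPAIRED) for i in range(ss, se)),
    )


def _interior_elements(pre: PreMiRNA, duplex: Duplex) -> tuple[int, int, set[int]]:
    """(num_loops, num_bulges, bulge positions) from walking consecutive pairs."""
    gs, ge = duplex.guide
    pt = pre.pair_table
    paired = [i for i in range(gs, ge) if pt[i] != UNPAIRED and not (gs <= pt[i] < ge)]
    num_loops = 0
    num_bulges = 0
    bulge_positions: set[int] = set()
    for a, b in zip(paired, paired[1:]):
        guide_gap = list(range(a + 1, b))
        pa, pb = int(pt[a]), int(pt[b])
        lo, hi = min(pa, pb), max(pa, pb)
        star_gap = list(range(lo + 1, hi))
        if guide_gap and star_gap:
            num_loops += 1
        elif guide_gap:
            num_bulges += 1
            bulge_positions.update(guide_gap)
        elif star_gap:
            num_bulges += 1
            bulge_positions.update(star_gap)
    return num_loops, num_bulges, bulge_positions


def bulge_positions(pre: PreMiRNA, duplex: Duplex) -> set[int]:
    """Pre-miRNA positions inside one-strand (bulge) runs of the duplex."""
    return _interior_elements(pre, duplex)[2]


def structural_elements(pre: PreMiRNA, duplex: Duplex) -> ElementSummary:
    gs, ge = duplex.guide
    pt = pre.pair_table
    bp_num = sum(1 for i in range(gs, ge) if pt[i] != UNPAIRED)

    # longest consecutively paired guide run
    ml = run = 0
    for state in duplex.guide_states:
        run = run + 1 if state else 0
        ml = max(ml, run)

    num_loops, num_bulges, _ = _interior_elements(pre, duplex)

    loop = pre.terminal_loop()
    if loop is None:
        dist_to_loop = 0
    elif duplex.arm == "5p":
        dist_to_loop = max(0, loop[0] - ge)
    else:
        dist_to_loop = max(0, gs - loop[1])

    stem = pre.stem_span()
    if stem is None:
        dist_to_helix = 0
    elif duplex.arm == "5p":
        dist_to_helix = max(0, gs - stem[0])
    else:
        dist_to_helix = max(0, stem[1] - (ge - 1))

    return ElementSummary(
        bp_num=bp_num,
        num_loops=num_loops,
        num_bulges=num_bulges,
        ml_bulge=ml,
        dist_to_loop=dist_to_loop,
        dist_to_helix=dist_to_helix,
    )


def duplex_energy(
    pre: PreMiRNA, duplex: Duplex, engine: FoldingEngine | None = None
) -> float:
    """Free energy of the guide:star duplex in kcal/mol.

    Uses the engine's two-strand evaluation when available; otherwise the
    documented surrogate -(3*GC + 2*AU + 1*GU) summed over duplex pairs. A
    duplex with zero pairs scores 0.0 by convention.
    """
    gs, ge = duplex.guide
    if not any(duplex.guide_states):
        return 0.0
    if engine is not None and "duplex_energy" in engine.capabilities:
        guide_seq = pre.sequence[gs:ge]
        star_seq = pre.sequence[duplex.star[0] : duplex.star[1]]
        if not star_seq:
            return 0.0
        return engine.duplex_energy(guide_seq, star_seq)
    pt = pre.pair_table
    total = 0.0
    for i in range(gs, ge):
        j = int(pt[i])
        if j == UNPAIRED:
            continue
        if gs <= j < ge and j < i:
            continue  # intra-guide pair already counted once
        total += surrogate_pair_energy(pre.sequence[i], pre.sequence[j])
    return total
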