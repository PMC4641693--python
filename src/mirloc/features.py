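"""Fixed 440-dimensional sequence/structure encoding of a miRNA duplex.

The vector concatenates, in a fixed schema order:

* sequence properties (197): guide length, mono-/di-nucleotide frequencies,
  and one-hot nucleotide context in the [-5,+5] windows around the start and
  end of the duplex's 5p and 3p strands;
* structural properties (30): duplex free energy, base-pair counts and
  windowed densities, perfect-pair runs, bulge/loop counts, distances to the
  terminal loop and to the stem base, and bulge flags in the [-3,+3]
  windows around the guide start and end;
* positional entropy (22): H(i) in the [-5,+5] windows around the guide
  start and end;
* sequence-structure combinations (191): counts of nucleotide x structure
  symbol states (monoSSq), dinucleotide x symbol-pair states (diSS) and
  collapsed-bracket triplet states, each with an extra bucket for undefined
  combinations (N bases).

Every block writes a fixed number of columns; out-of-bounds context
positions encode as zeros. The schema is versioned so trained models refuse
features from a different layout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .duplexes import (
    Duplex,
    bulge_positions,
    duplex_energy,
    structural_elements,
)
from .errors import SchemaMismatch
from .structure import FoldingEngine, PreMiRNA

SCHEMA_VERSION = "mirloc-440-v1"

NUCLEOTIDES = "ACGU"
DINUCLEOTIDES = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2)]
SYMBOLS = "()."
SYMBOL_PAIRS = ["".join(p) for p in itertools.product(SYMBOLS, repeat=2)]
#: collapsed alphabet for triplets: any bracket counts as paired
TRIPLET_PATTERNS = ["".join(p) for p in itertools.product("(.", repeat=3)]
#: one-hot bit order: A=0001, C=0010, G=0100, U=1000 -> columns b3..b0 = U,G,C,A
NT_BIT_ORDER = "UGCA"

CONTEXT_OFFSETS = range(-5, 6)  # [-5, +5] windows
BULGE_OFFSETS = range(-3, 4)  # [-3, +3] windows
PERFECT_RUN_LENGTHS = (5, 10, 20)
BP_WINDOW_LENGTHS = (4, 6, 8)


def _offset_tag(off: int) -> str:
    return f"u{-off}" if off < 0 else (f"d{off}" if off > 0 else "0")


def _build_schema() -> tuple[list[str], list[str]]:
    names: list[str] = []
    groups: list[str] = []

    def add(group: str, *cols: str) -> None:
        names.extend(cols)
        groups.extend([group] * len(cols))

    add("miRNALen", "miRNALen")
    add("MNC", *(f"MNC_{n}" for n in NUCLEOTIDES))
    add("DNC", *(f"DNC_{d}" for d in DINUCLEOTIDES))
    for strand in ("5p", "3p"):
        for anchor in ("start", "end"):
            for off in CONTEXT_OFFSETS:
                add(
                    f"NT{strand}",
                    *(
                        f"NT{strand}_{anchor}_{_offset_tag(off)}_{nt}"
                        for nt in NT_BIT_ORDER
                    ),
                )
    add("MFE", "MFE")
    add("mlBulge", "mlBulge")
    add("bpNum", "bpNum")
    add("dist2Loop", "dist2Loop")
    add("dist2Helix", "dist2Helix")
    add("numLoop", "numLoop")
    add("numBulges", "numBulges")
    for k in PERFECT_RUN_LENGTHS:
        add("perfectBP", f"Persent_{k}mer", f"Persent_{k}mer_start")
    add("numBP_Win", *(f"numBP_Win{x}" for x in BP_WINDOW_LENGTHS))
    for anchor in ("Start", "End"):
        add(
            "Bulges",
            *(f"BulgeAt{anchor}_{_offset_tag(off)}" for off in BULGE_OFFSETS),
        )
    for anchor in ("start", "end"):
        add(
            "posEntropy",
            *(f"posEntropy_{anchor}_{_offset_tag(off)}" for off in CONTEXT_OFFSETS),
        )
    add(
        "monoSSq",
        *(f"monoSSq_{n}{s}" for n in NUCLEOTIDES for s in SYMBOLS),
        "monoSSq_undef",
    )
    add(
        "diSS",
        *(f"diSS_{d}{sp}" for d in DINUCLEOTIDES for sp in SYMBOL_PAIRS),
        "diSS_undef",
    )
    add(
        "triplets",
        *(f"triplet_{n}_{p}" for n in NUCLEOTIDES for p in TRIPLET_PATTERNS),
        "triplet_undef",
    )
    return names, groups


#: which schema group belongs to which top-level feature category
GROUP_CATEGORY = {
    "miRNALen": "sequence",
    "MNC": "sequence",
    "DNC": "sequence",
    "NT5p": "sequence",
    "NT3p": "sequence",
    "MFE": "structural",
    "mlBulge": "structural",
    "bpNum": "structural",
    "dist2Loop": "structural",
    "dist2Helix": "structural",
    "numLoop": "structural",
    "numBulges": "structural",
    "perfectBP": "structural",
    "numBP_Win": "structural",
    "Bulges": "structural",
    "posEntropy": "entropy",
    "monoSSq": "combination",
    "diSS": "combination",
    "triplets": "combination",
}


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, versioned catalogue of the 440 feature columns."""

    names: tuple[str, ...]
    groups: tuple[str, ...]
    version: str = SCHEMA_VERSION

    def __len__(self) -> int:
        return len(self.names)

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.groups:
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def category_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.groups:
            cat = GROUP_CATEGORY[g]
            sizes[cat] = sizes.get(cat, 0) + 1
        return sizes

    def index(self, name: str) -> int:
        return self.names.index(name)


_NAMES, _GROUPS = _build_schema()
SCHEMA = FeatureSchema(names=tuple(_NAMES), groups=tuple(_GROUPS))
N_FEATURES = len(SCHEMA)


@dataclass
class FeatureVector:
    """One encoded sample aligned to :data:`SCHEMA`."""

    values: np.ndarray
    sample_id: str
    label: str = "unlabeled"  # positive / negative / unlabeled
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise SchemaMismatch(
                f"feature vector has shape {self.values.shape}, expected ({N_FEATURES},)"
            )


# --------------------------------------------------------------------------
# block encoders
# --------------------------------------------------------------------------


def seq_composition(guide_seq: str) -> np.ndarray:
    """miRNALen + mononucleotide (4) + dinucleotide (16) frequencies."""
    L = len(guide_seq)
    mnc = np.array([guide_seq.count(n) / L for n in NUCLEOTIDES])
    pairs = [guide_seq[i : i + 2] for i in range(L - 1)]
    dnc = np.array([pairs.count(d) / (L - 1) for d in DINUCLEOTIDES]) if L > 1 else np.zeros(16)
    return np.concatenate([[float(L)], mnc, dnc])


def nt_context(pre: PreMiRNA, anchor: int) -> np.ndarray:
    """44 one-hot bits for the [-5,+5] window around one anchor position."""
    n = len(pre)
    out = np.zeros(44)
    for slot, off in enumerate(CONTEXT_OFFSETS):
        pos = anchor + off
        if 0 <= pos < n:
            nt = pre.sequence[pos]
            if nt in NT_BIT_ORDER:
                out[slot * 4 + NT_BIT_ORDER.index(nt)] = 1.0
    return out


def _paired_runs(states: tuple[bool, ...]) -> list[tuple[int, int]]:
    """(start, length) of maximal runs of paired positions along the guide."""
    runs = []
    i = 0
    L = len(states)
    while i < L:
        if states[i]:
            j = i
            while j < L and states[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def pairing_stats(duplex: Duplex) -> np.ndarray:
    """perfectBP presence/start (6) followed by numBP_Win 4/6/8 (3)."""
    states = duplex.guide_states
    runs = _paired_runs(states)
    out = []
    for k in PERFECT_RUN_LENGTHS:
        hit = next((r for r in runs if r[1] >= k), None)
        out.extend([1.0, float(hit[0])] if hit else [0.0, -1.0])
    L = len(states)
    arr = np.array(states, dtype=float)
    for x in BP_WINDOW_LENGTHS:
        if L <= x:
            out.append(float(arr.sum()))
        else:
            counts = np.convolve(arr, np.ones(x), mode="valid")
            out.append(float(counts.mean()))
    return np.array(out)


def bulge_context(pre: PreMiRNA, duplex: Duplex) -> np.ndarray:
    """14 flags: bulge membership at [-3,+3] around guide start and end."""
    bulges = bulge_positions(pre, duplex)
    gs, ge = duplex.guide
    out = np.zeros(14)
    for block, anchor in enumerate((gs, ge - 1)):
        for slot, off in enumerate(BULGE_OFFSETS):
            if (anchor + off) in bulges:
                out[block * 7 + slot] = 1.0
    return out


def entropy_context(pre: PreMiRNA, guide: tuple[int, int]) -> np.ndarray:
    """22 positional entropies at [-5,+5] around guide start and end."""
    n = len(pre)
    gs, ge = guide
    out = np.zeros(22)
    for block, anchor in enumerate((gs, ge - 1)):
        for slot, off in enumerate(CONTEXT_OFFSETS):
            pos = anchor + off
            if 0 <= pos < n:
                out[block * 11 + slot] = pre.entropy(pos)
    return out


def seq_struct_combos(pre: PreMiRNA, guide: tuple[int, int]) -> np.ndarray:
    """monoSSq (13) + diSS (145) + triplet (33) state counts over the guide."""
    gs, ge = guide
    seq = pre.sequence
    db = pre.structure

    mono = np.zeros(13)
    for i in range(gs, ge):
        if seq[i] in NUCLEOTIDES:
            mono[NUCLEOTIDES.index(seq[i]) * 3 + SYMBOLS.index(db[i])] += 1
        else:
            mono[12] += 1

    di = np.zeros(145)
    for i in range(gs, ge - 1):
        dn = seq[i : i + 2]
        if dn in DINUCLEOTIDES:
            di[DINUCLEOTIDES.index(dn) * 9 + SYMBOL_PAIRS.index(db[i : i + 2])] += 1
        else:
            di[144] += 1

    tri = np.zeros(33)
    for i in range(gs + 1, ge - 1):
        if seq[i] in NUCLEOTIDES:
            pattern = "".join("(" if db[p] != "." else "." for p in (i - 1, i, i + 1))
            tri[NUCLEOTIDES.index(seq[i]) * 8 + TRIPLET_PATTERNS.index(pattern)] += 1
        else:
            tri[32] += 1

    return np.concatenate([mono, di, tri])


def _guard(block: np.ndarray, width: int, name: str) -> np.ndarray:
    if block.shape != (width,):
        raise SchemaMismatch(f"block {name} returned width {block.shape}, expected {width}")
    return block


def featurize(
    pre: PreMiRNA,
    duplex: Duplex,
    engine: FoldingEngine | None = None,
    *,
    sample_id: str | None = None,
    label: str = "unlabeled",
) -> FeatureVector:
    """Encode one (pre-miRNA, duplex) pair as the 440-feature vector.

    Pure and deterministic for fixed inputs. ``engine`` supplies the duplex
    free energy; without one the documented pair-count surrogate is used.
    """
    gs, ge = duplex.guide
    strand5p = duplex.guide if duplex.arm == "5p" else duplex.star
    strand3p = duplex.star if duplex.arm == "5p" else duplex.guide

    elements = structural_elements(pre, duplex)
    blocks = [
        _guard(seq_composition(pre.sequence[gs:ge]), 21, "seq_composition"),
        _guard(
            np.concatenate(
                [
                    nt_context(pre, strand5p[0]),
                    nt_context(pre, strand5p[1] - 1),
                    nt_context(pre, strand3p[0]),
                    nt_context(pre, strand3p[1] - 1),
                ]
            ),
            176,
            "nt_context",
        ),
        _guard(
            np.array(
                [
                    duplex_energy(pre, duplex, engine),
                    float(elements.ml_bulge),
                    float(elements.bp_num),
                    float(elements.dist_to_loop),
                    float(elements.dist_to_helix),
                    float(elements.num_loops),
                    float(elements.num_bulges),
                ]
            ),
            7,
            "elements",
        ),
        _guard(pairing_stats(duplex), 9, "pairing_stats"),
        _guard(bulge_context(pre, duplex), 14, "bulge_context"),
        _guard(entropy_context(pre, duplex.guide), 22, "entropy_context"),
        _guard(seq_struct_combos(pre, duplex.guide), 191, "seq_struct_combos"),
    ]
    values = np.concatenate(blocks)
    return FeatureVector(
        values=values,
        sample_id=sample_id or f"{duplex.pre_ref}:{gs + 1}-{ge}",
        label=label,
    )
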