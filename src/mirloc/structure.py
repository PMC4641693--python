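"""Pre-miRNA secondary structure: parsing, folding engines, positional entropy.

A pre-miRNA is a hairpin-folded RNA. Its structure is held as a dot-bracket
string plus an equivalent pair table, optionally with the base-pair
probability matrix (bppm) from a partition-function fold. Positional entropy
H(i) quantifies how uncertain the pairing state of position i is: 0 when the
state is forced (one partner, or firmly unpaired, carries all probability)
and log2(n) when the probability is spread uniformly over n partners.

Coordinates are 0-based half-open throughout this package; user-facing
output converts to 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EngineUnavailable,
    InvalidCharacter,
    InvalidParams,
    InvalidProbability,
    MultiBranchStructure,
    UnbalancedStructure,
)

UNPAIRED = -1
RNA_ALPHABET = frozenset("ACGUN")
#: Watson-Crick plus wobble pairs admitted by the maximum-pairing engine.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)
MIN_LOOP = 3  # minimum unpaired bases inside a hairpin loop
_PROB_EPS = 1e-6


def normalize_sequence(seq: str) -> str:
    """Uppercase, convert DNA T to RNA U, and validate the alphabet."""
    out = seq.upper().replace("T", "U")
    bad = set(out) - RNA_ALPHABET
    if bad:
        raise InvalidCharacter(
            f"sequence contains characters outside ACGTUN: {sorted(bad)!r}"
        )
    return out


def parse_dotbracket(db: str) -> np.ndarray:
    """Parse a dot-bracket string into a pair table.

    Returns an int array ``pt`` of the same length where ``pt[i]`` is the
    partner of position ``i`` or ``UNPAIRED``. The table is an involution:
    ``pt[pt[i]] == i`` for every paired ``i``.
    """
    if not db:
        raise UnbalancedStructure("empty dot-bracket string")
    bad = set(db) - set("().")
    if bad:
        raise UnbalancedStructure(f"invalid dot-bracket characters: {sorted(bad)!r}")
    pt = np.full(len(db), UNPAIRED, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise UnbalancedStructure(f"unmatched ')' at position {i}")
            j = stack.pop()
            pt[j] = i
            pt[i] = j
    if stack:
        raise UnbalancedStructure(f"unmatched '(' at position {stack[-1]}")
    return pt


def serialize_pairtable(pt: np.ndarray) -> str:
    """Inverse of :func:`parse_dotbracket`."""
    out = []
    for i, j in enumerate(pt):
        if j == UNPAIRED:
            out.append(".")
        else:
            out.append("(" if i < j else ")")
    return "".join(out)


def positional_entropy(bppm: np.ndarray, i: int) -> float:
    """Shannon entropy (bits) of the pairing state of position ``i``.

    The outcome space is {pair with j, for every j} plus {unpaired}, the
    latter receiving the leftover mass ``1 - sum_j p_ij``. This form is 0 at
    a point mass and log2(n) when the mass is uniform over n partners.
    """
    row = np.asarray(bppm[i], dtype=float)
    if row.min() < -_PROB_EPS or row.max() > 1 + _PROB_EPS:
        raise InvalidProbability(f"probability outside [0,1] in row {i}")
    total = row.sum()
    if total > 1 + _PROB_EPS:
        raise InvalidProbability(f"pairing probabilities of position {i} sum to {total:.6f} > 1")
    q = np.append(row, max(0.0, 1.0 - total))
    q = np.clip(q, 0.0, 1.0)
    q = q[q > 0]
    if q.size == 0:
        return 0.0
    return float(-(q * np.log2(q)).sum() + 0.0)  # + 0.0 avoids IEEE -0.0


def entropy_profile(bppm: np.ndarray) -> np.ndarray:
    """Positional entropy at every position, as a vector."""
    return np.array([positional_entropy(bppm, i) for i in range(bppm.shape[0])])


def _validate_bppm(bppm: np.ndarray, n: int) -> None:
    if bppm.shape != (n, n):
        raise InvalidProbability(f"bppm shape {bppm.shape} does not match length {n}")
    if bppm.min() < -_PROB_EPS or bppm.max() > 1 + _PROB_EPS:
        raise InvalidProbability("bppm entries outside [0,1]")
    if not np.allclose(bppm, bppm.T, atol=1e-8):
        raise InvalidProbability("bppm is not symmetric")
    sums = bppm.sum(axis=1)
    if sums.max() > 1 + 1e-4:
        raise InvalidProbability("a bppm row sums above 1")


@dataclass
class PreMiRNA:
    """One folded pre-miRNA hairpin.

    Attributes
    ----------
    id : record identifier
    sequence : RNA string over {A,C,G,U,N}
    structure : dot-bracket string, same length as the sequence
    pair_table : partner index per position (``UNPAIRED`` where unpaired)
    mfe : free energy of the structure in kcal/mol
    bppm : optional symmetric base-pair probability matrix
    engine : name+version of the folding engine that produced the structure
    """

    id: str
    sequence: str
    structure: str
    pair_table: np.ndarray
    mfe: float
    bppm: np.ndarray | None = None
    engine: str = "precomputed"
    _entropy: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        n = len(self.sequence)
        if len(self.structure) != n:
            raise UnbalancedStructure(
                f"{self.id}: structure length {len(self.structure)} != sequence length {n}"
            )
        expected = parse_dotbracket(self.structure) if n else np.empty(0, dtype=np.int64)
        if self.pair_table is None:
            self.pair_table = expected
        else:
            self.pair_table = np.asarray(self.pair_table, dtype=np.int64)
            if not np.array_equal(self.pair_table, expected):
                raise UnbalancedStructure(f"{self.id}: pair table disagrees with dot-bracket")
        paired = np.nonzero(self.pair_table != UNPAIRED)[0]
        for i in paired:
            j = self.pair_table[i]
            if i < j and j - i < MIN_LOOP + 1:
                raise UnbalancedStructure(
                    f"{self.id}: pair ({i},{j}) violates the minimum loop of {MIN_LOOP}"
                )
        if self.bppm is not None:
            self.bppm = np.asarray(self.bppm, dtype=float)
            _validate_bppm(self.bppm, n)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dotbracket(
        cls,
        id: str,
        sequence: str,
        structure: str,
        mfe: float = 0.0,
        bppm: np.ndarray | None = None,
        engine: str = "precomputed",
    ) -> "PreMiRNA":
        return cls(
            id=id,
            sequence=sequence,
            structure=structure,
            pair_table=None,
            mfe=mfe,
            bppm=bppm,
            engine=engine,
        )

    # -- derived structure queries ------------------------------------------

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_pairs(self) -> int:
        return int((self.pair_table != UNPAIRED).sum()) // 2

    def effective_bppm(self) -> np.ndarray:
        """The bppm, or a degenerate point-mass matrix built from the MFE pairs.

        When only a single MFE structure is known, every pairing state is
        treated as certain, so all positional entropies collapse to zero. A
        warning flags that entropy features carry no signal in this mode.
        """
        if self.bppm is not None:
            return self.bppm
        warnings.warn(
            f"{self.id}: no base-pair probabilities available; using a degenerate "
            "point-mass matrix from the MFE structure (entropy features will be 0)",
            stacklevel=2,
        )
        n = len(self.sequence)
        m = np.zeros((n, n))
        for i, j in enumerate(self.pair_table):
            if j != UNPAIRED:
                m[i, j] = 1.0
        return m

    def entropy(self, i: int) -> float:
        """Positional entropy H(i) in bits (cached profile)."""
        if self._entropy is None:
            self._entropy = entropy_profile(self.effective_bppm())
        return float(self._entropy[i])

    def hairpin_loops(self) -> list[tuple[int, int]]:
        """Half-open spans of all hairpin loops (apex runs closed by a pair)."""
        loops = []
        for i, j in enumerate(self.pair_table):
            if j == UNPAIRED or j < i:
                continue
            inner = self.pair_table[i + 1 : j]
            if inner.size and (inner == UNPAIRED).all():
                loops.append((i + 1, j))
        return loops

    def terminal_loop(self) -> tuple[int, int] | None:
        """Span of the single terminal loop, or None for an unpaired structure.

        Raises
        ------
        MultiBranchStructure
            if the structure carries more than one hairpin loop.
        """
        loops = self.hairpin_loops()
        if len(loops) > 1:
            raise MultiBranchStructure(
                f"{self.id}: {len(loops)} hairpin loops; only single hairpins are supported"
            )
        return loops[0] if loops else None

    def stem_span(self) -> tuple[int, int] | None:
        """Indices of the outermost paired bases (start of the helix), or None."""
        paired = np.nonzero(self.pair_table != UNPAIRED)[0]
        if paired.size == 0:
            return None
        return int(paired[0]), int(paired[-1])


# --------------------------------------------------------------------------
# Folding engines
# --------------------------------------------------------------------------


class FoldingEngine:
    """Contract for pluggable secondary-structure engines.

    ``capabilities`` advertises {"mfe_structure", "partition_function",
    "duplex_energy"}. The determinism contract is: identical input sequence
    yields identical output within one engine version.
    """

    name: str = "abstract"
    version: str = "0"
    capabilities: frozenset[str] = frozenset()

    @property
    def signature(self) -> str:
        return f"{self.name}-{self.version}"

    def fold(self, sequence: str) -> tuple[str, float]:
        raise NotImplementedError

    def pair_probabilities(self, sequence: str) -> np.ndarray:
        raise NotImplementedError

    def duplex_energy(self, strand_a: str, strand_b: str) -> float:
        raise NotImplementedError


class ViennaEngine(FoldingEngine):
    """Thermodynamic engine backed by the ViennaRNA bindings."""

    def __init__(self) -> None:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - exercised only without ViennaRNA
            raise EngineUnavailable(
                "ViennaRNA python bindings are not importable"
            ) from exc
        self._rna = RNA
        self.name = "viennarna"
        self.version = getattr(RNA, "__version__", "unknown")
        self.capabilities = frozenset(
            {"mfe_structure", "partition_function", "duplex_energy"}
        )

    def fold(self, sequence: str) -> tuple[str, float]:
        fc = self._rna.fold_compound(sequence)
        db, mfe = fc.mfe()
        return db, float(mfe)

    def pair_probabilities(self, sequence: str) -> np.ndarray:
        fc = self._rna.fold_compound(sequence)
        _, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        fc.pf()
        raw = np.asarray(fc.bpp())[1:, 1:]  # drop the 1-based padding row/col
        return raw + raw.T

    def duplex_energy(self, strand_a: str, strand_b: str) -> float:
        d = self._rna.duplexfold(strand_a, strand_b)
        return float(d.energy)


#: Pair-count surrogate weights used when no thermodynamic engine exists.
_SURROGATE_WEIGHTS = {
    frozenset("GC"): 3.0,
    frozenset("AU"): 2.0,
    frozenset("GU"): 1.0,
}


def surrogate_pair_energy(base_a: str, base_b: str) -> float:
    """-3/-2/-1 kcal/mol-like score for GC/AU/GU pairs; 0 otherwise."""
    return -_SURROGATE_WEIGHTS.get(frozenset((base_a, base_b)), 0.0)


class MaxPairingEngine(FoldingEngine):
    """Maximum-base-pairing folder (Nussinov dynamic programme).

    Non-thermodynamic: it maximises the number of canonical pairs subject to
    the minimum-loop constraint and reports a documented surrogate energy
    (-3 GC, -2 AU, -1 GU per pair). Intended as a dependency-free test
    engine, not a substitute for a nearest-neighbour folder.
    """

    name = "maxpairing"
    version = "1"
    capabilities = frozenset({"mfe_structure"})

    def max_pairs(self, sequence: str) -> int:
        """Maximum number of canonical pairs (the DP objective)."""
        return self._table(normalize_sequence(sequence))[0, len(sequence) - 1] if sequence else 0

    def _table(self, seq: str) -> np.ndarray:
        n = len(seq)
        dp = np.zeros((n, n), dtype=np.int64)
        for span in range(MIN_LOOP + 1, n):
            for i in range(n - span):
                j = i + span
                best = dp[i, j - 1]
                for k in range(i, j - MIN_LOOP):
                    if (seq[k], seq[j]) in CANONICAL_PAIRS:
                        left = dp[i, k - 1] if k > i else 0
                        inner = dp[k + 1, j - 1] if k + 1 <= j - 1 else 0
                        best = max(best, left + inner + 1)
                dp[i, j] = best
        return dp

    def fold(self, sequence: str) -> tuple[str, float]:
        seq = normalize_sequence(sequence)
        n = len(seq)
        if n == 0:
            return "", 0.0
        dp = self._table(seq)
        pt = np.full(n, UNPAIRED, dtype=np.int64)

        def trace(i: int, j: int) -> None:
            while i < j:
                if dp[i, j] == (dp[i, j - 1] if j - 1 >= i else 0):
                    j -= 1
                    continue
                for k in range(i, j - MIN_LOOP):
                    if (seq[k], seq[j]) in CANONICAL_PAIRS:
                        left = dp[i, k - 1] if k > i else 0
                        inner = dp[k + 1, j - 1] if k + 1 <= j - 1 else 0
                        if dp[i, j] == left + inner + 1:
                            pt[k], pt[j] = j, k
                            trace(k + 1, j - 1)
                            j = k - 1
                            break
                else:  # pragma: no cover - DP and trace agree by construction
                    raise AssertionError("traceback failed")

        trace(0, n - 1)
        energy = sum(
            surrogate_pair_energy(seq[i], seq[int(j)])
            for i, j in enumerate(pt)
            if j != UNPAIRED and i < j
        )
        return serialize_pairtable(pt), float(energy)

    def duplex_energy(self, strand_a: str, strand_b: str) -> float:  # pragma: no cover
        raise NotImplementedError("maxpairing engine has no duplex energy")


def get_engine(name: str | None = "vienna") -> FoldingEngine:
    """Resolve an engine by name ('vienna' or 'maxpair')."""
    if name in (None, "vienna", "viennarna"):
        return ViennaEngine()
    if name in ("maxpair", "maxpairing", "nussinov"):
        return MaxPairingEngine()
    raise EngineUnavailable(f"unknown folding engine {name!r}")


def fold(
    sequence: str,
    engine: FoldingEngine | None,
    *,
    id: str = "seq",
    with_bppm: bool = True,
) -> PreMiRNA:
    """Fold a sequence into a :class:`PreMiRNA`.

    The bppm is attached iff the engine supports the partition function and
    ``with_bppm`` is set; otherwise entropy features fall back to the
    degenerate point-mass matrix.
    """
    seq = normalize_sequence(sequence)
    if engine is None:
        raise EngineUnavailable(
            "no folding engine configured and no precomputed structure supplied"
        )
    if len(seq) < 10:
        raise InvalidParams(f"sequence of length {len(seq)} is too short to fold (< 10 nt)")
    db, mfe = engine.fold(seq)
    bppm = None
    if with_bppm and "partition_function" in engine.capabilities:
        bppm = engine.pair_probabilities(seq)
        bppm[bppm < 1e-12] = 0.0
    return PreMiRNA.from_dotbracket(
        id=id, sequence=seq, structure=db, mfe=mfe, bppm=bppm, engine=engine.signature
    )
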