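"""Labeled training corpora and the synthetic hairpin generator.

Positives are duplexes anchored at experimentally annotated mature miRNAs
(one duplex per pre-miRNA even when both arms are annotated). Negatives are
pseudo-miRNA segments of the same length drawn at random from the same
hairpin, excluding starts within 2 nt of the true start, at a configurable
positive:negative ratio (RPNS, default 1:5).

The synthetic generator plants a guide strand in the 5' arm of a
random-sequence hairpin whose 3' arm is the reverse complement perturbed by
Bernoulli(bulge_rate) insertions/mismatches, so every pipeline stage is
testable without any external miRNA database.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .duplexes import Duplex, derive_duplex
from .errors import (
    EmptyPositiveSet,
    InvalidParams,
    NoPairedBases,
    TooFewSamples,
)
from .features import SCHEMA_VERSION, N_FEATURES, featurize
from .structure import UNPAIRED, FoldingEngine, PreMiRNA, fold, normalize_sequence

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGU", "UGCA")
#: negatives must not start within this many nt of the true miRNA start
NEGATIVE_START_EXCLUSION = 2


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Annotation:
    """One validated mature miRNA on a pre-miRNA.

    ``start``/``end`` are 0-based half-open (the TSV readers convert from the
    1-based inclusive convention). Either coordinates or ``mature_seq`` must
    be supplied; a sequence-only annotation is resolved against the folded
    pre-miRNA when the positive set is built.
    """

    premirna_id: str
    start: int | None = None
    end: int | None = None
    mature_seq: str | None = None
    arm: str | None = None

    def __post_init__(self) -> None:
        if self.mature_seq is None and (self.start is None or self.end is None):
            raise InvalidParams(
                f"{self.premirna_id}: annotation needs a mature sequence or coordinates"
            )
        if self.mature_seq is not None:
            object.__setattr__(self, "mature_seq", normalize_sequence(self.mature_seq))


def resolve_annotation(pre: PreMiRNA, ann: Annotation) -> tuple[int, int] | None:
    """Guide interval for an annotation, or None if it cannot be placed.

    A sequence given by the annotation may occur several times in the
    pre-miRNA; the occurrence whose interval carries the most base pairs
    wins, ties going to the leftmost occurrence.
    """
    if ann.start is not None and ann.end is not None:
        if 0 <= ann.start < ann.end <= len(pre):
            return (ann.start, ann.end)
        logger.warning("%s: annotated interval outside the pre-miRNA; skipped", pre.id)
        return None
    occurrences = []
    pos = pre.sequence.find(ann.mature_seq)
    while pos != -1:
        occurrences.append(pos)
        pos = pre.sequence.find(ann.mature_seq, pos + 1)
    if not occurrences:
        logger.warning(
            "%s: annotated mature sequence not found in the pre-miRNA; skipped", pre.id
        )
        return None
    L = len(ann.mature_seq)

    def bp_count(start: int) -> int:
        return int((pre.pair_table[start : start + L] != UNPAIRED).sum())

    best = max(occurrences, key=lambda s: (bp_count(s), -s))
    return (best, best + L)


@dataclass
class PositiveSample:
    pre: PreMiRNA
    duplex: Duplex
    annotation: Annotation


def build_positive_set(
    premirnas: dict[str, PreMiRNA], annotations: list[Annotation]
) -> list[PositiveSample]:
    """One guide duplex per pre-miRNA from its annotations.

    When both the 5' and 3' strands of the duplex are annotated as
    functional, only the 5p-anchored duplex is kept (its star covers the 3p
    annotation), avoiding redundant duplexes. Annotations that cannot be
    placed or whose guide has no base pair are skipped with a warning.
    """
    by_pre: dict[str, list[Annotation]] = {}
    for ann in annotations:
        if ann.premirna_id not in premirnas:
            logger.warning("%s: no such pre-miRNA loaded; annotation skipped", ann.premirna_id)
            continue
        by_pre.setdefault(ann.premirna_id, []).append(ann)

    samples: list[PositiveSample] = []
    for pre_id, anns in by_pre.items():
        pre = premirnas[pre_id]
        candidates: list[tuple[Annotation, Duplex]] = []
        for ann in anns:
            interval = resolve_annotation(pre, ann)
            if interval is None:
                continue
            try:
                dup = derive_duplex(pre, interval)
            except NoPairedBases:
                logger.warning("%s: annotated guide has no base pairs; skipped", pre_id)
                continue
            candidates.append((ann, dup))
        if not candidates:
            continue
        fivep = [c for c in candidates if c[1].arm == "5p"]
        ann, dup = fivep[0] if fivep else candidates[0]
        samples.append(PositiveSample(pre=pre, duplex=dup, annotation=ann))
    if not samples:
        raise EmptyPositiveSet("no annotation survived duplex derivation")
    return samples


def sample_negatives(
    pre: PreMiRNA,
    true_interval: tuple[int, int],
    count: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Pseudo-miRNA intervals of the true miRNA's length in the same hairpin.

    Starts are drawn uniformly without replacement from positions more than
    2 nt away from the true start; candidates whose duplex cannot be derived
    (no base pairs) are rejected and redrawn. A shortfall is logged, never
    raised.
    """
    ts, te = true_interval
    L = te - ts
    n = len(pre)
    valid = [p for p in range(0, n - L + 1) if abs(p - ts) > NEGATIVE_START_EXCLUSION]
    order = rng.permutation(len(valid))
    out: list[tuple[int, int]] = []
    for idx in order:
        p = valid[idx]
        try:
            derive_duplex(pre, (p, p + L))
        except NoPairedBases:
            continue
        out.append((p, p + L))
        if len(out) == count:
            break
    if len(out) < count:
        logger.warning(
            "%s: only %d/%d negative segments available", pre.id, len(out), count
        )
    return out


# --------------------------------------------------------------------------
# synthetic hairpins
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticHairpin:
    """A generated pre-miRNA with its planted ground-truth guide."""

    id: str
    sequence: str
    guide: tuple[int, int]  # 0-based half-open interval of the planted guide
    params: dict = field(hash=False)

    @property
    def annotation(self) -> Annotation:
        return Annotation(
            premirna_id=self.id, start=self.guide[0], end=self.guide[1], arm="5p"
        )


def generate_hairpin(
    stem_len: int = 40,
    loop_len: int = 8,
    guide_len: int = 21,
    bulge_rate: float = 0.05,
    seed: int | np.random.Generator = 0,
    id: str = "synth",
) -> SyntheticHairpin:
    """Generate one hairpin-structured sequence with a planted guide.

    The sequence is a random 5' arm, a random terminal loop, and the reverse
    complement of the arm perturbed per position by Bernoulli(bulge_rate)
    events (half mismatches, half single-nucleotide insertions). The guide is
    planted in the 5' arm with its 3' end 1-4 nt from the loop, mimicking the
    loop-proximal placement of real plant mature miRNAs. Deterministic for a
    fixed seed.
    """
    if not (stem_len >= guide_len >= 16):
        raise InvalidParams(f"need stem_len >= guide_len >= 16, got {stem_len}, {guide_len}")
    if loop_len < 3:
        raise InvalidParams(f"loop_len must be >= 3, got {loop_len}")
    if not (0 <= bulge_rate < 0.3):
        raise InvalidParams(f"bulge_rate must lie in [0, 0.3), got {bulge_rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    arm5 = "".join(rng.choice(list("ACGU"), size=stem_len))
    loop = "".join(rng.choice(list("ACGU"), size=loop_len))
    gap = int(rng.integers(1, 5))
    gap = min(gap, stem_len - guide_len)
    guide_start = stem_len - gap - guide_len

    arm3 = []
    for base in reverse_complement(arm5):
        if bulge_rate > 0 and rng.random() < bulge_rate:
            if rng.random() < 0.5:  # mismatch
                arm3.append(str(rng.choice([b for b in "ACGU" if b != base])))
            else:  # insertion
                arm3.append(base)
                arm3.append(str(rng.choice(list("ACGU"))))
        else:
            arm3.append(base)
    sequence = arm5 + loop + "".join(arm3)

    return SyntheticHairpin(
        id=id,
        sequence=sequence,
        guide=(guide_start, guide_start + guide_len),
        params={
            "stem_len": stem_len,
            "loop_len": loop_len,
            "guide_len": guide_len,
            "bulge_rate": bulge_rate,
        },
    )


def make_corpus(
    n: int,
    seed: int = 0,
    bulge_rate: float = 0.05,
    stem_range: tuple[int, int] = (35, 46),
    loop_range: tuple[int, int] = (6, 11),
    guide_range: tuple[int, int] = (20, 23),
) -> list[SyntheticHairpin]:
    """n synthetic hairpins with sizes drawn from realistic plant ranges."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(
            generate_hairpin(
                stem_len=int(rng.integers(*stem_range)),
                loop_len=int(rng.integers(*loop_range)),
                guide_len=int(rng.integers(*guide_range)),
                bulge_rate=bulge_rate,
                seed=rng,
                id=f"synth-{i:04d}",
            )
        )
    return out


# --------------------------------------------------------------------------
# labeled datasets
# --------------------------------------------------------------------------


@dataclass
class LabeledDataset:
    """Feature matrix with labels, per-sample provenance, and the RPNS used."""

    X: np.ndarray  # (n_samples, 440)
    y: np.ndarray  # 1 = positive, 0 = negative
    sample_ids: list[str]
    groups: list[str]  # pre-miRNA id per sample (grouped CV unit)
    rpns: int
    seed: int
    schema_version: str = SCHEMA_VERSION

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return int((self.y == 0).sum())

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            X=self.X[idx],
            y=self.y[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            groups=[self.groups[i] for i in idx],
            rpns=self.rpns,
            seed=self.seed,
            schema_version=self.schema_version,
        )


def build_dataset(
    premirnas: dict[str, PreMiRNA],
    annotations: list[Annotation],
    rpns: int = 5,
    engine: FoldingEngine | None = None,
    seed: int = 0,
) -> LabeledDataset:
    """Featurized positives plus ``rpns`` negatives per positive."""
    rng = np.random.default_rng(seed)
    positives = build_positive_set(premirnas, annotations)
    rows, labels, ids, groups = [], [], [], []
    for pos in positives:
        fv = featurize(pos.pre, pos.duplex, engine, label="positive")
        rows.append(fv.values)
        labels.append(1)
        ids.append(fv.sample_id)
        groups.append(pos.pre.id)
        for interval in sample_negatives(pos.pre, pos.duplex.guide, rpns, rng):
            dup = derive_duplex(pos.pre, interval)
            fv = featurize(pos.pre, dup, engine, label="negative")
            rows.append(fv.values)
            labels.append(0)
            ids.append(fv.sample_id)
            groups.append(pos.pre.id)
    return LabeledDataset(
        X=np.vstack(rows),
        y=np.array(labels, dtype=int),
        sample_ids=ids,
        groups=groups,
        rpns=rpns,
        seed=seed,
    )


def fold_corpus(
    hairpins: list[SyntheticHairpin],
    engine: FoldingEngine,
    with_bppm: bool = True,
) -> tuple[dict[str, PreMiRNA], list[Annotation]]:
    """Fold synthetic hairpins into PreMiRNAs plus their truth annotations."""
    premirnas = {
        hp.id: fold(hp.sequence, engine, id=hp.id, with_bppm=with_bppm)
        for hp in hairpins
    }
    return premirnas, [hp.annotation for hp in hairpins]


def split_folds(
    dataset: LabeledDataset, k: int, seed: int = 0
) -> list[np.ndarray]:
    """k disjoint index subsets, stratified by label and grouped by pre-miRNA.

    All samples of one pre-miRNA land in the same fold (a positive must
    never meet its sibling negatives across the train/test boundary). Within
    that constraint a greedy dealer balances positive counts first, then
    totals, so class sizes differ by at most one when groups are singletons.
    """
    if k < 2:
        raise InvalidParams(f"k must be >= 2, got {k}")
    group_ids = sorted(set(dataset.groups))
    group_idx: dict[str, list[int]] = {g: [] for g in group_ids}
    for i, g in enumerate(dataset.groups):
        group_idx[g].append(i)
    n_pos_total = dataset.n_pos
    if n_pos_total < k or dataset.n_neg < k:
        raise TooFewSamples(
            f"need at least {k} positives and {k} negatives for {k} folds"
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(group_ids))
    shuffled = [group_ids[i] for i in order]

    def group_pos(g: str) -> int:
        return int(dataset.y[group_idx[g]].sum())

    with_pos = sorted(
        (g for g in shuffled if group_pos(g) > 0),
        key=lambda g: -len(group_idx[g]),
    )
    without_pos = sorted(
        (g for g in shuffled if group_pos(g) == 0),
        key=lambda g: -len(group_idx[g]),
    )

    folds: list[list[int]] = [[] for _ in range(k)]
    fold_pos = [0] * k
    fold_tot = [0] * k
    for g in with_pos:
        f = min(range(k), key=lambda f: (fold_pos[f], fold_tot[f], f))
        folds[f].extend(group_idx[g])
        fold_pos[f] += group_pos(g)
        fold_tot[f] += len(group_idx[g])
    for g in without_pos:
        f = min(range(k), key=lambda f: (fold_tot[f], f))
        folds[f].extend(group_idx[g])
        fold_tot[f] += len(group_idx[g])
    return [np.array(sorted(f), dtype=int) for f in folds]


def dataset_params_json(hairpins: list[SyntheticHairpin], seed: int) -> str:
    """JSON provenance block written next to simulated corpora."""
    return json.dumps(
        {
            "n": len(hairpins),
            "seed": seed,
            "per_hairpin": [hp.params for hp in hairpins[:1]],
        },
        indent=2,
    )
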