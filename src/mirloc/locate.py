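"""Candidate enumeration, summed-score localisation, resolution evaluation.

The locator slides every candidate guide of length 16-30 nt over the folded
pre-miRNA, scores each candidate's duplex with a trained classifier, and
picks the start position maximising the summed score

    S(p) = sum over 16 <= L <= 30 of score(p, L),

then the length maximising score(p_pred, L). Candidates whose guide has no
base pair contribute nothing (their entry is absent from the grid). Starts
near the 3' end admit fewer lengths and therefore a downward-biased raw sum;
the sum is deliberately left unnormalised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .duplexes import derive_duplex
from .errors import EmptyGrid, MissingTruth, NoPairedBases, NoPrediction
from .features import featurize
from .models import TrainedModel
from .structure import FoldingEngine, PreMiRNA

logger = logging.getLogger(__name__)

LENGTH_MIN = 16
LENGTH_MAX = 30


def enumerate_candidates(
    n: int, lmin: int = LENGTH_MIN, lmax: int = LENGTH_MAX
) -> list[tuple[int, int]]:
    """All (start, length) with start+length <= n, ordered by start then length."""
    return [
        (p, L)
        for p in range(0, max(0, n - lmin + 1))
        for L in range(lmin, lmax + 1)
        if p + L <= n
    ]


@dataclass
class ScoreGrid:
    """Scores of all derivable candidates; absent keys were skipped."""

    scores: dict[tuple[int, int], float] = field(default_factory=dict)
    n: int = 0
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.scores)


def score_candidates(
    pre: PreMiRNA,
    model: TrainedModel,
    engine: FoldingEngine | None = None,
    lmin: int = LENGTH_MIN,
    lmax: int = LENGTH_MAX,
) -> ScoreGrid:
    """Featurize and score every derivable candidate on one pre-miRNA."""
    keys, rows = [], []
    skipped = 0
    for p, L in enumerate_candidates(len(pre), lmin, lmax):
        try:
            dup = derive_duplex(pre, (p, p + L))
        except NoPairedBases:
            skipped += 1
            continue
        keys.append((p, L))
        rows.append(featurize(pre, dup, engine).values)
    grid = ScoreGrid(n=len(pre), n_skipped=skipped)
    if rows:
        scores = model.predict_scores(np.vstack(rows))
        grid.scores = {k: float(s) for k, s in zip(keys, scores)}
    else:
        logger.warning("%s: every candidate was skipped (no pairable segment)", pre.id)
    return grid


def locate(grid: ScoreGrid) -> tuple[int, int]:
    """Two-stage argmax: position by summed score, then length at the winner.

    Ties break toward the smallest start, then the smallest length.
    """
    if not grid.scores:
        raise EmptyGrid("score grid is empty; nothing to locate")
    summed: dict[int, float] = {}
    for (p, _L), s in grid.scores.items():
        summed[p] = summed.get(p, 0.0) + s
    p_pred = min(p for p, v in summed.items() if v == max(summed.values()))
    at_p = {L: s for (p, L), s in grid.scores.items() if p == p_pred}
    l_pred = min(L for L, v in at_p.items() if v == max(at_p.values()))
    return p_pred, l_pred


@dataclass
class Prediction:
    """A located mature miRNA (1-based inclusive coordinates)."""

    premirna_id: str
    start: int
    end: int
    length: int
    arm: str
    mature_seq: str
    passenger_seq: str
    passenger_start: int
    passenger_end: int
    score: float  # score(p_pred, L_pred)
    summed_score: float  # S(p_pred)


def predict(
    pre: PreMiRNA,
    model: TrainedModel,
    engine: FoldingEngine | None = None,
    lmin: int = LENGTH_MIN,
    lmax: int = LENGTH_MAX,
) -> Prediction:
    """Locate the most probable mature miRNA and its passenger strand."""
    grid = score_candidates(pre, model, engine, lmin, lmax)
    try:
        p, L = locate(grid)
    except EmptyGrid as exc:
        raise NoPrediction(f"{pre.id}: {exc}") from exc
    dup = derive_duplex(pre, (p, p + L))
    summed = sum(s for (q, _), s in grid.scores.items() if q == p)
    return Prediction(
        premirna_id=pre.id,
        start=p + 1,
        end=p + L,
        length=L,
        arm=dup.arm,
        mature_seq=pre.sequence[p : p + L],
        passenger_seq=pre.sequence[dup.star[0] : dup.star[1]],
        passenger_start=dup.star[0] + 1,
        passenger_end=dup.star[1],
        score=grid.scores[(p, L)],
        summed_score=summed,
    )


def evaluate_resolution(
    predictions: dict[str, tuple[int, int]],
    truths: dict[str, tuple[int, int]],
    d_max: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative fraction of correct starts/ends at resolutions d = 0..d_max.

    ``predictions`` and ``truths`` map pre-miRNA id to (start, end) in any
    one consistent coordinate convention. A prediction counts as correct at
    resolution d when its start (end) lies within d nt of the true start
    (end). Both returned curves are non-decreasing in d.
    """
    missing = [k for k in predictions if k not in truths]
    if missing:
        raise MissingTruth(f"no truth for prediction id(s): {missing[:5]}")
    if not predictions:
        raise MissingTruth("no predictions to evaluate")
    start_off = np.array(
        [abs(predictions[k][0] - truths[k][0]) for k in predictions]
    )
    end_off = np.array([abs(predictions[k][1] - truths[k][1]) for k in predictions])
    ds = np.arange(d_max + 1)
    start_curve = np.array([(start_off <= d).mean() for d in ds])
    end_curve = np.array([(end_off <= d).mean() for d in ds])
    return start_curve, end_curve
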