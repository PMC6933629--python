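"""Precision-recall and ROC evaluation of a ranked edge list.

The precision-recall curve is built literally by prefix: for q = 1, 2, ...
over the candidate universe, the top-q edges are compared with the gold
standard and (recall, precision) recorded.  The AUPR is the step-wise area
(precision x recall increment at every rank where a true edge appears — no
interpolation), identical to average precision over the total order.

Pairs the method never scored (score 0) are appended after the ranked list
in ascending (regulator index, target index) order, so every quantity is a
deterministic function of the prediction and gold files.  AUROC is the
Mann-Whitney statistic on the scores over the full universe, counting tied
scores (including all appended zeros) as half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import ValidationError
from .io import GoldStandard, RankedEdgeList


@dataclass(frozen=True)
class EvalResult:
    """AUPR/AUROC plus the PR curve points (one per rank of a true edge)."""

    aupr: float
    auroc: float
    recall: np.ndarray
    precision: np.ndarray


def _extended_order(
    ranking: RankedEdgeList, gold: GoldStandard
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and scores over the whole candidate universe in rank order.

    The ranked pairs come first (their file order); all remaining admissible
    pairs follow in ascending (regulator index, target index) with score 0.
    """
    gene_idx = {g: i for i, g in enumerate(gold.gene_names)}
    reg_set = set(gold.regulator_names)
    ranked_pairs = ranking.pairs()
    seen = set()
    for reg, tgt in ranked_pairs:
        if reg not in reg_set:
            raise ValidationError(f"ranked regulator {reg!r} outside the TF set")
        if tgt not in gene_idx:
            raise ValidationError(f"ranked target {tgt!r} not a known gene")
        seen.add((reg, tgt))
    rest = sorted(
        (pair for pair in gold.candidate_universe() if pair not in seen),
        key=lambda p: (gene_idx[p[0]], gene_idx[p[1]]),
    )
    ordered = ranked_pairs + rest
    if len(ordered) != gold.n_candidates:
        raise ValidationError(
            f"{len(ordered)} ordered pairs but candidate universe has "
            f"{gold.n_candidates}"
        )
    labels = np.fromiter(
        (pair in gold.true_edges for pair in ordered), dtype=bool, count=len(ordered)
    )
    scores = np.zeros(len(ordered))
    scores[: len(ranked_pairs)] = [s for _, _, s in ranking.rows]
    return labels, scores


def confusion_at_q(
    ranking: RankedEdgeList, gold: GoldStandard, q: int
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) comparing the gold standard with the top-q edges."""
    labels, _ = _extended_order(ranking, gold)
    if not 1 <= q <= labels.size:
        raise ValidationError(f"q={q} outside 1..{labels.size}")
    tp = int(labels[:q].sum())
    fp = q - tp
    fn = int(labels.sum()) - tp
    tn = labels.size - q - fn
    return tp, fp, tn, fn


def aupr(ranking: RankedEdgeList, gold: GoldStandard) -> float:
    """Step-wise area under the precision-recall curve over the prefix sweep."""
    return evaluate(ranking, gold).aupr


def auroc(ranking: RankedEdgeList, gold: GoldStandard) -> float:
    """Probability a random true edge outranks a random false one (ties half)."""
    return evaluate(ranking, gold).auroc


def evaluate(ranking: RankedEdgeList, gold: GoldStandard) -> EvalResult:
    """Full evaluation: AUPR, AUROC and the PR curve."""
    labels, scores = _extended_order(ranking, gold)
    n_true = int(labels.sum())
    if n_true == 0:
        raise ValidationError("gold standard has no true edges; AUPR undefined")
    if n_true == labels.size:
        raise ValidationError("every candidate pair is true; AUROC undefined")

    q_hits = np.flatnonzero(labels) + 1  # ranks at which recall increases
    tp_at_hits = np.arange(1, n_true + 1)
    precision = tp_at_hits / q_hits
    recall = tp_at_hits / n_true
    area = float(np.sum(precision * (1.0 / n_true)))

    # Mann-Whitney U with average ranks: tied scores count one half
    ranks = scipy.stats.rankdata(scores)  # ascending: larger score = better
    n_false = labels.size - n_true
    u = ranks[labels].sum() - n_true * (n_true + 1) / 2.0
    roc = float(u / (n_true * n_false))
    return EvalResult(area, roc, recall, precision)


def pr_curve_table(
    ranking: RankedEdgeList, gold: GoldStandard
) -> list[tuple[int, float, float]]:
    """(q, precision, recall) at every prefix length over the universe."""
    labels, _ = _extended_order(ranking, gold)
    n_true = int(labels.sum())
    if n_true == 0:
        raise ValidationError("gold standard has no true edges")
    tp = np.cumsum(labels)
    q = np.arange(1, labels.size + 1)
    return list(zip(q.tolist(), (tp / q).tolist(), (tp / n_true).tolist()))
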