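import numpy as np
import pytest

from d3grn.errors import ValidationError
from d3grn.evaluation import aupr, auroc, confusion_at_q, evaluate, pr_curve_table
from d3grn.io import GoldStandard, RankedEdgeList

from .oracles import pairwise_auroc, prefix_sweep_aupr


def ranking_from_pairs(pairs, start=1.0, step=0.1):
    rows = tuple(
        (r, t, start - i * step) for i, (r, t) in enumerate(pairs)
    )
    return RankedEdgeList(rows)


def universe_gold(n_regs, n_genes, true_pairs):
    names = tuple(f"G{i}" for i in range(1, n_genes + 1))
    return GoldStandard(frozenset(true_pairs), names[:n_regs], names)


class TestConfusion:
    def test_full_prefix_recovers_everything(self, four_pair_gold):
        ranking = ranking_from_pairs(
            [("G1", "G2"), ("G1", "G3"), ("G2", "G1"), ("G2", "G3")]
        )
        tp, fp, tn, fn = confusion_at_q(ranking, four_pair_gold, q=4)
        assert (tp, fn) == (2, 0)
        assert tp + fn == four_pair_gold.n_true

    def test_perfect_first_edge(self, four_pair_gold):
        ranking = ranking_from_pairs(
            [("G1", "G2"), ("G1", "G3"), ("G2", "G1"), ("G2", "G3")]
        )
        tp, fp, _, _ = confusion_at_q(ranking, four_pair_gold, q=1)
        assert (tp, fp) == (1, 0)

    def test_six_pair_enumeration(self):
        gold = universe_gold(2, 4, {("G1", "G2"), ("G1", "G4")})
        ranking = ranking_from_pairs(
            [("G1", "G2"), ("G1", "G3"), ("G1", "G4")]
        )
        tp, fp, tn, fn = confusion_at_q(ranking, gold, q=3)
        assert (tp, fp, fn) == (2, 1, 0)
        assert tn == gold.n_candidates - 3

    def test_q_out_of_range(self, four_pair_gold):
        ranking = ranking_from_pairs([("G1", "G2")])
        with pytest.raises(ValidationError):
            confusion_at_q(ranking, four_pair_gold, q=99)


class TestAupr:
    def test_perfect_ranking_is_one(self, four_pair_gold):
        ranking = ranking_from_pairs(
            [("G1", "G2"), ("G2", "G1"), ("G1", "G3"), ("G2", "G3")]
        )
        assert aupr(ranking, four_pair_gold) == 1.0

    def test_four_pair_hand_swept_value(self, four_pair_gold):
        """Gold {e1, e3} with ranking e1,e2,e3,e4: area 1/2 + (1/2)(2/3) = 5/6."""
        ranking = ranking_from_pairs(
            [("G1", "G2"), ("G1", "G3"), ("G2", "G1"), ("G2", "G3")]
        )
        result = evaluate(ranking, four_pair_gold)
        assert result.aupr == pytest.approx(5 / 6, abs=1e-12)
        np.testing.assert_allclose(result.recall, [0.5, 1.0])
        np.testing.assert_allclose(result.precision, [1.0, 2 / 3])

    def test_random_ranking_scores_near_prevalence(self):
        """A random order scores at the prevalence scale, far below a real
        ranking, and the package value equals the independent prefix-sweep
        oracle on every shuffle.  (The exact expectation of average
        precision under shuffling exceeds prevalence by an O(1) factor on
        finite universes, so prevalence anchors the scale, not the value.)
        """
        rng = np.random.default_rng(99)
        names = tuple(f"G{i}" for i in range(1, 11))
        regs = names[:9]
        pairs = [(r, t) for r in regs for t in names if r != t]  # 81 pairs
        true = set(map(tuple, rng.choice(pairs, size=5, replace=False)))
        gold = universe_gold(9, 10, true)
        prevalence = len(true) / len(pairs)
        vals = []
        for _ in range(200):
            order = rng.permutation(len(pairs))
            ranking = ranking_from_pairs([pairs[i] for i in order], step=0.005)
            labels = np.array([pairs[i] in true for i in order])
            got = aupr(ranking, gold)
            assert got == pytest.approx(prefix_sweep_aupr(labels), abs=1e-12)
            vals.append(got)
        assert prevalence / 2 < np.mean(vals) < 3 * prevalence

    def test_empty_gold_rejected(self):
        gold = universe_gold(2, 3, set())
        ranking = ranking_from_pairs([("G1", "G2")])
        with pytest.raises(ValidationError):
            aupr(ranking, gold)

    def test_unranked_true_edges_still_counted(self):
        """Score-0 pairs are appended, so recall still reaches 1."""
        gold = universe_gold(2, 4, {("G1", "G2"), ("G2", "G4")})
        ranking = ranking_from_pairs([("G1", "G2")])  # one true edge unranked
        result = evaluate(ranking, gold)
        assert result.recall[-1] == 1.0


class TestAuroc:
    def test_perfect_and_reversed(self):
        gold = universe_gold(2, 3, {("G1", "G2")})
        pairs = [("G1", "G2"), ("G1", "G3"), ("G2", "G1"), ("G2", "G3")]
        assert auroc(ranking_from_pairs(pairs), gold) == 1.0
        assert auroc(ranking_from_pairs(pairs[::-1]), gold) == 0.0

    def test_six_pair_pairwise_oracle_value(self):
        """Gold {a, c} in ranking a,b,c,d,e,f -> (4 + 3)/(2*4) = 0.875."""
        gold = universe_gold(2, 4, {("G1", "G2"), ("G1", "G4")})
        ranking = ranking_from_pairs(
            [("G1", "G2"), ("G1", "G3"), ("G1", "G4"),
             ("G2", "G1"), ("G2", "G3"), ("G2", "G4")]
        )
        assert auroc(ranking, gold) == pytest.approx(0.875)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_pairwise_oracle(self, seed):
        """On every small universe the Mann-Whitney value equals the
        exhaustive true-vs-false comparison count (ties half)."""
        rng = np.random.default_rng(seed)
        names = ("G1", "G2", "G3", "G4")
        n_regs = int(rng.integers(1, 3))
        universe = [
            (r, t) for r in names[:n_regs] for t in names if r != t
        ]
        n_true = int(rng.integers(1, len(universe)))
        true = set(map(tuple, rng.choice(universe, size=n_true, replace=False)))
        if len(true) == len(universe):
            true.pop()
        # random scores with deliberate ties, a random subset left unranked
        scores = rng.choice([0.9, 0.5, 0.5, 0.2], size=len(universe))
        keep = rng.random(len(universe)) < 0.8
        ranked = sorted(
            (
                (universe[i], scores[i])
                for i in range(len(universe))
                if keep[i]
            ),
            key=lambda e: -e[1],
        )
        ranking = RankedEdgeList(
            tuple((r, t, s) for (r, t), s in ranked)
        )
        gold = universe_gold(n_regs, 4, true)
        got = auroc(ranking, gold)
        full_scores = np.array(
            [scores[i] if keep[i] else 0.0 for i in range(len(universe))]
        )
        labels = np.array([p in true for p in universe])
        assert got == pytest.approx(pairwise_auroc(labels, full_scores), abs=1e-12)


class TestOrderInvariance:
    def test_monotone_transform_leaves_metrics_unchanged(self):
        gold = universe_gold(3, 5, {("G1", "G2"), ("G2", "G5"), ("G3", "G1")})
        pairs = [(r, t) for r in ("G1", "G2", "G3") for t in
                 ("G1", "G2", "G3", "G4", "G5") if r != t]
        rng = np.random.default_rng(3)
        order = list(rng.permutation(len(pairs)))
        base = ranking_from_pairs([pairs[i] for i in order])
        squashed = RankedEdgeList(
            tuple((r, t, s**3 / 2) for r, t, s in base.rows)
        )
        assert aupr(base, gold) == aupr(squashed, gold)
        assert auroc(base, gold) == auroc(squashed, gold)

    def test_sklearn_cross_check_on_tie_free_instance(self):
        """Independent library check: with every pair scored distinctly the
        prefix-sweep AUPR equals average precision and the Mann-Whitney
        AUROC equals the ROC area."""
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(17)
        names = tuple(f"G{i}" for i in range(1, 7))
        universe = [(r, t) for r in names[:3] for t in names if r != t]
        true = set(map(tuple, rng.choice(universe, size=4, replace=False)))
        scores = rng.permutation(len(universe)) + 1.0
        order = np.argsort(-scores)
        ranking = RankedEdgeList(
            tuple((universe[i][0], universe[i][1], float(scores[i])) for i in order)
        )
        gold = universe_gold(3, 6, true)
        labels = np.array([p in true for p in universe])
        assert aupr(ranking, gold) == pytest.approx(
            sklearn_metrics.average_precision_score(labels, scores)
        )
        assert auroc(ranking, gold) == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores)
        )


def test_pr_curve_table_is_prefix_complete(four_pair_gold):
    ranking = ranking_from_pairs(
        [("G1", "G2"), ("G1", "G3"), ("G2", "G1"), ("G2", "G3")]
    )
    table = pr_curve_table(ranking, four_pair_gold)
    assert [q for q, _, _ in table] == [1, 2, 3, 4]
    assert table[-1][2] == 1.0  # recall complete at the full sweep
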