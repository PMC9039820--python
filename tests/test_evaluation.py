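from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from certcoder.evaluation import (
    MatchCounts,
    corpus_metrics,
    count_matches,
    per_chapter_rates,
    prf,
    rejection_curve,
    remove_shared_codes,
)
from certcoder.icd10 import parse_code
from certcoder.pipeline import metric_examples_check

TRUTH = ["I64", "G819"]

WORKED_EXAMPLES = [
    (["B189", "H155"], (0.0, 0.0, 0.0)),
    (["I64", "G81"], (0.5, 0.5, 0.5)),
    (["I64"], (1.0, 0.5, 2 / 3)),
    (["I64", "G819", "A338", "B87"], (0.5, 1.0, 2 / 3)),
    (["I64", "G819"], (1.0, 1.0, 1.0)),
    (["G819", "I64"], (1.0, 1.0, 1.0)),
]


def brute_force_tp(pred, truth):
    """Optimal one-to-one assignment where a pair scores iff codes are equal."""
    if not pred or not truth:
        return 0
    cost = -np.array([[int(p == t) for t in truth] for p in pred])
    ri, ci = linear_sum_assignment(cost)
    return int(-cost[ri, ci].sum())


class TestCountMatches:
    @pytest.mark.parametrize("pred,expected", WORKED_EXAMPLES)
    def test_worked_examples(self, pred, expected):
        p, r, f = prf(count_matches(pred, TRUTH))
        assert (p, r, f) == pytest.approx(expected, abs=1e-9)

    def test_worked_examples_via_pipeline_self_check(self):
        assert all(row["ok"] for row in metric_examples_check())

    def test_near_miss_counts_one_fp_and_one_fn(self):
        assert count_matches(["I64", "G81"], TRUTH) == MatchCounts(1, 1, 1)

    def test_repeated_codes_use_multiset_semantics(self):
        assert count_matches(["I10", "I10"], ["I10"]) == MatchCounts(1, 1, 0)
        assert count_matches(["I10"], ["I10", "I10"]) == MatchCounts(1, 0, 1)

    def test_agrees_with_assignment_oracle_on_random_pairs(self):
        rng = np.random.default_rng(8)
        pool = ["I64", "I10", "G819", "G81", "J189", "C349", "R092", "W19"]
        for _ in range(1000):
            pred = [pool[i] for i in rng.integers(0, len(pool), rng.integers(0, 8))]
            truth = [pool[i] for i in rng.integers(0, len(pool), rng.integers(0, 8))]
            counts = count_matches(pred, truth)
            assert counts.tp == brute_force_tp(pred, truth)
            assert counts.tp + counts.fp == len(pred)
            assert counts.tp + counts.fn == len(truth)

    def test_swapping_pred_and_truth_swaps_precision_and_recall(self):
        rng = np.random.default_rng(9)
        pool = ["I64", "I10", "G819", "A00"]
        for _ in range(200):
            pred = [pool[i] for i in rng.integers(0, 4, rng.integers(0, 6))]
            truth = [pool[i] for i in rng.integers(0, 4, rng.integers(0, 6))]
            p1, r1, f1 = prf(count_matches(pred, truth))
            p2, r2, f2 = prf(count_matches(truth, pred))
            assert (p1, r1) == (r2, p2) and f1 == pytest.approx(f2)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        pred=st.lists(st.sampled_from(["I64", "I10", "G819", "W19", "A00"]), max_size=8),
        truth=st.lists(st.sampled_from(["I64", "I10", "G819", "W19", "A00"]), max_size=8),
    )
    def test_count_conservation_and_oracle_equivalence_property(self, pred, truth):
        counts = count_matches(pred, truth)
        assert counts.tp + counts.fp == len(pred)
        assert counts.tp + counts.fn == len(truth)
        assert counts.tp == brute_force_tp(pred, truth)

    def test_order_invariance(self):
        rng = np.random.default_rng(10)
        pred, truth = ["I64", "G819", "I10", "I10"], ["I10", "G819", "W19"]
        base = count_matches(pred, truth)
        for _ in range(20):
            assert count_matches(rng.permutation(pred), rng.permutation(truth)) == base


class TestPrf:
    def test_empty_against_empty_is_perfect(self):
        assert prf(MatchCounts(0, 0, 0)) == (1.0, 1.0, 1.0)

    def test_zero_tp_with_errors_is_zero(self):
        assert prf(MatchCounts(0, 3, 2)) == (0.0, 0.0, 0.0)

    def test_f_is_harmonic_mean(self):
        p, r, f = prf(MatchCounts(7, 4, 3))
        assert f == pytest.approx(2 * p * r / (p + r))


class TestCorpusMetrics:
    def test_pooled_counts_over_worked_examples(self):
        preds = {f"c{i}": pred for i, (pred, _) in enumerate(WORKED_EXAMPLES)}
        truths = {f"c{i}": TRUTH for i in range(len(WORKED_EXAMPLES))}
        rep = corpus_metrics(preds, truths, B=100, seed=0)
        # hand-pooled: tp = 0+1+1+2+2+2 = 8 over 13 predicted / 12 true codes
        pooled = sum((count_matches(p, TRUTH) for p, _ in WORKED_EXAMPLES), MatchCounts(0, 0, 0))
        assert (pooled.tp, pooled.fp, pooled.fn) == (8, 5, 4)
        assert rep.precision == pytest.approx(8 / 13)
        assert rep.recall == pytest.approx(8 / 12)
        p, r = 8 / 13, 8 / 12
        assert rep.f_measure == pytest.approx(2 * p * r / (p + r))

    def test_perfect_corpus_has_degenerate_ci(self):
        preds = {"a": ["I64"], "b": ["G819", "I10"]}
        rep = corpus_metrics(preds, preds, B=200, seed=1)
        assert rep.f_measure == 1.0
        assert rep.ci["f_measure"] == (1.0, 1.0)

    def test_deterministic_under_seed(self):
        preds = {f"c{i}": pred for i, (pred, _) in enumerate(WORKED_EXAMPLES)}
        truths = {f"c{i}": TRUTH for i in range(len(WORKED_EXAMPLES))}
        a = corpus_metrics(preds, truths, B=500, seed=3)
        b = corpus_metrics(preds, truths, B=500, seed=3)
        assert a == b

    def _random_corpus(self, n, rng):
        pool = ["I64", "I10", "G819", "J189", "C349"]
        preds, truths = {}, {}
        for i in range(n):
            truth = [pool[j] for j in rng.integers(0, 5, rng.integers(1, 5))]
            pred = [c for c in truth if rng.random() > 0.15]
            if rng.random() < 0.2:
                pred.append(pool[rng.integers(5)])
            preds[f"c{i}"], truths[f"c{i}"] = pred, truth
        return preds, truths

    def test_more_replicates_leave_point_estimate_and_tighten_ci(self):
        preds, truths = self._random_corpus(250, np.random.default_rng(4))
        a = corpus_metrics(preds, truths, B=1000, seed=5)
        b = corpus_metrics(preds, truths, B=2000, seed=5)
        assert a.f_measure == b.f_measure
        for m in ("precision", "recall", "f_measure"):
            assert a.ci[m][0] == pytest.approx(b.ci[m][0], abs=0.005)
            assert a.ci[m][1] == pytest.approx(b.ci[m][1], abs=0.005)

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(6)
        widths = []
        for n in (100, 900):
            preds, truths = self._random_corpus(n, rng)
            rep = corpus_metrics(preds, truths, B=400, seed=7)
            widths.append(rep.ci["f_measure"][1] - rep.ci["f_measure"][0])
        assert widths[1] < 0.6 * widths[0]  # ~1/sqrt(9) ideally

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            corpus_metrics({"a": ["I64"]}, {"b": ["I64"]}, B=10, seed=0)


class TestPerChapterRates:
    def test_cross_chapter_confusion(self):
        report = per_chapter_rates({"c": ["I64"]}, {"c": ["G819"]})
        by_ch = {r.chapter: r for r in report.rows}
        assert by_ch[9].fp_rate == pytest.approx(100.0)
        assert by_ch[6].fn_rate == pytest.approx(100.0)
        assert by_ch[6].prevalence == pytest.approx(100.0)

    def test_correct_chapter_has_zero_fp_rate(self):
        report = per_chapter_rates(
            {"c": ["I64", "I10"], "d": ["J189"]}, {"c": ["I64", "I10"], "d": ["J450"]}
        )
        by_ch = {r.chapter: r for r in report.rows}
        assert by_ch[9].fp_rate == 0.0 and by_ch[9].fn_rate == 0.0
        assert by_ch[10].fp_rate == pytest.approx(100.0)

    def test_prevalence_sums_to_hundred(self):
        rng = np.random.default_rng(11)
        pool = ["I64", "G819", "J189", "C349", "W19", "S010", "F03"]
        preds = {f"c{i}": [pool[j] for j in rng.integers(0, 7, 3)] for i in range(50)}
        truths = {f"c{i}": [pool[j] for j in rng.integers(0, 7, 3)] for i in range(50)}
        report = per_chapter_rates(preds, truths)
        assert sum(r.prevalence for r in report.rows) == pytest.approx(100.0, abs=0.5)
        prevs = [r.prevalence for r in report.rows]
        assert prevs == sorted(prevs, reverse=True)


class TestRejectionCurve:
    def _fixture(self):
        preds = {"a": ["I64"], "b": ["I10"], "c": ["G819"]}
        truths = {"a": ["I64"], "b": ["J189"], "c": ["G819"]}
        scores = {"a": 0.9, "b": 0.3, "c": 0.7}
        return scores, preds, truths

    def test_zero_threshold_accepts_everything(self):
        scores, preds, truths = self._fixture()
        curve = rejection_curve(scores, preds, truths)
        first = curve.points[0]
        assert first.threshold == 0.0 and first.fraction_accepted == 1.0
        assert first.f_on_accepted == pytest.approx(2 / 3)

    def test_full_rejection_point_omitted(self):
        scores, preds, truths = self._fixture()
        curve = rejection_curve(scores, preds, truths)
        assert all(p.threshold < 0.9 for p in curve.points)

    def test_acceptance_fraction_non_increasing(self):
        scores, preds, truths = self._fixture()
        fracs = [p.fraction_accepted for p in rejection_curve(scores, preds, truths).points]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_rejecting_low_scores_raises_f_here(self):
        scores, preds, truths = self._fixture()
        curve = rejection_curve(scores, preds, truths)
        assert curve.at_acceptance(2 / 3).f_on_accepted == pytest.approx(1.0)

    def test_out_of_range_score_rejected(self):
        scores, preds, truths = self._fixture()
        scores["a"] = 1.5
        with pytest.raises(ValueError, match="outside"):
            rejection_curve(scores, preds, truths)


class TestRemoveSharedCodes:
    def test_worked_disagreement_example(self):
        pred = ["I259", "Z951", "I719", "C679", "I10", "R092"]
        db = ["I259", "I251", "I719", "C679", "I10", "R092"]
        expert = list(db)
        p, d, e = remove_shared_codes(pred, db, expert)
        assert (p, d, e) == (["Z951"], ["I251"], ["I251"])

    def test_identical_pred_and_db_empty_both(self):
        pred = ["I10", "I64"]
        expert = ["I10", "G819"]
        p, d, e = remove_shared_codes(pred, pred, expert)
        assert p == [] and d == [] and e == ["G819"]

    def test_disjoint_sequences_unchanged(self):
        p, d, e = remove_shared_codes(["I10"], ["I64"], ["G819"])
        assert (p, d, e) == (["I10"], ["I64"], ["G819"])

    def test_multiset_removal_respects_counts(self):
        p, d, e = remove_shared_codes(["I10", "I10"], ["I10"], ["I10", "I10"])
        assert (p, d, e) == (["I10"], [], ["I10"])
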