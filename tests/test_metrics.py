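import math

import numpy as np
import pytest

from ontoeval.annotations import BenchmarkSet
from ontoeval.metrics import (
    average_auc,
    coverage,
    evaluate,
    fmax,
    normalized_ru_mi_curve,
    precision_recall_curve,
    ru_mi_curve,
    smin,
    term_auc,
    top_terms_nonoverlapping,
    weighted_precision_recall_curve,
)
from ontoeval.ontology import InformationContentTable
from ontoeval.predictions import from_score_map

from _bruteforce import (
    brute_auc,
    brute_coverage,
    brute_fmax,
    brute_normalized_smin,
    brute_ru_mi,
    brute_smin,
    brute_weighted_fmax,
)
from _instances import random_instance


def _bench(truth):
    return BenchmarkSet("MFO", "NK", {p: frozenset(t) for p, t in truth.items()})


def _pred(scores):
    p = from_score_map("m", scores)
    p.validated = True
    p.propagated = True
    return p


def _ic(values, corpus_size=10):
    return InformationContentTable(dict(values), corpus_size)


def _at(curve, tau):
    i = int(round(tau * 100)) - 1
    return curve.coord1[i], curve.coord2[i]


class TestPrecisionRecall:
    def test_half_right_single_protein(self):
        curve = precision_recall_curve(
            _pred({"P1": {"a": 0.8, "c": 0.8}}), _bench({"P1": {"a", "b"}})
        )
        pr, rc = _at(curve, 0.5)
        assert pr == 0.5 and rc == 0.5

    def test_perfect_predictor_flat_curve(self):
        pred = _pred({"P1": {"a": 1.0, "b": 1.0}, "P2": {"c": 1.0}})
        curve = precision_recall_curve(pred, _bench({"P1": {"a", "b"}, "P2": {"c"}}))
        assert np.all(curve.coord1 == 1.0) and np.all(curve.coord2 == 1.0)
        assert fmax(curve) == (1.0, 0.01)

    def test_partial_mode_rescales_recall(self):
        pred = _pred({"P1": {"a": 0.6}})
        truth = {"P1": {"a"}, "P2": {"b"}}
        full = precision_recall_curve(pred, _bench(truth), mode="full")
        partial = precision_recall_curve(pred, _bench(truth), mode="partial")
        assert full.n_e == 2 and partial.n_e == 1
        # rc_partial = rc_full * n / m(0) at every threshold
        np.testing.assert_allclose(partial.coord2, full.coord2 * 2.0, atol=1e-15)
        # precision is identical in the two modes
        np.testing.assert_allclose(partial.coord1, full.coord1, atol=0)

    def test_undefined_precision_skipped_by_fmax(self):
        pred = _pred({"P1": {"a": 0.40}})
        curve = precision_recall_curve(pred, _bench({"P1": {"a"}}))
        assert np.isnan(curve.coord1[50])  # no predictions at tau=0.51
        value, tau = fmax(curve)
        assert value == 1.0 and tau == 0.01

    def test_no_predictions_fmax_zero(self):
        pred = _pred({})
        curve = precision_recall_curve(pred, _bench({"P1": {"a"}}))
        assert fmax(curve) == (0.0, None)

    def test_zero_true_positive_fmax_zero(self):
        pred = _pred({"P1": {"z": 0.9}})
        curve = precision_recall_curve(pred, _bench({"P1": {"a"}}))
        assert fmax(curve)[0] == 0.0

    def test_empty_benchmark_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_curve(_pred({}), _bench({}))


class TestRuMi:
    def test_hand_sum(self):
        ic = _ic({"a": 1.0, "b": 2.0, "c": 4.0})
        pred = _pred({"P1": {"a": 0.7, "c": 0.7}})
        curve = ru_mi_curve(pred, _bench({"P1": {"a", "b"}}), ic)
        ru, mi = _at(curve, 0.5)
        assert ru == 2.0 and mi == 4.0

    def test_perfect_predictor_zero_distance(self):
        ic = _ic({"a": 1.0, "b": 2.0})
        pred = _pred({"P1": {"a": 1.0, "b": 1.0}})
        curve = ru_mi_curve(pred, _bench({"P1": {"a", "b"}}), ic)
        assert smin(curve) == (0.0, 0.01)

    def test_empty_predictions_collapse(self):
        ic = _ic({"a": 1.0, "b": 2.0, "c": 3.0})
        pred = _pred({})
        truth = {"P1": {"a", "b"}, "P2": {"c"}}
        curve = ru_mi_curve(pred, _bench(truth), ic)
        assert np.all(curve.coord2 == 0.0)  # mi = 0 everywhere
        assert np.all(curve.coord1 == pytest.approx((3.0 + 3.0) / 2))
        value, _tau = smin(curve)
        assert value == pytest.approx(3.0)

    def test_three_four_five(self):
        ic = _ic({"a": 3.0, "b": 4.0})
        pred = _pred({"P1": {"b": 1.0}})
        curve = ru_mi_curve(pred, _bench({"P1": {"a"}}), ic)
        value, _ = smin(curve)
        assert value == 5.0


class TestSecondaryMetrics:
    def test_equal_ic_reduces_to_unweighted(self):
        truth = {"P1": {"a", "b"}, "P2": {"a", "c"}}
        pred = _pred({"P1": {"a": 0.8, "c": 0.3}, "P2": {"a": 0.6}})
        ic = _ic({t: 1.7 for t in "abc"})
        plain = precision_recall_curve(pred, _bench(truth))
        weighted = weighted_precision_recall_curve(pred, _bench(truth), ic)
        np.testing.assert_allclose(weighted.coord1, plain.coord1, atol=1e-12)
        np.testing.assert_allclose(weighted.coord2, plain.coord2, atol=1e-12)

    def test_weighted_hand_example(self):
        ic = _ic({"a": 1.0, "b": 2.0})
        pred = _pred({"P1": {"a": 0.9}})
        curve = weighted_precision_recall_curve(pred, _bench({"P1": {"a", "b"}}), ic)
        wpr, wrc = _at(curve, 0.5)
        assert wpr == 1.0
        assert wrc == pytest.approx(1.0 / 3.0)

    def test_normalized_perfect_predictor(self):
        ic = _ic({"a": 1.0, "b": 2.0})
        pred = _pred({"P1": {"a": 1.0, "b": 1.0}})
        curve = normalized_ru_mi_curve(pred, _bench({"P1": {"a", "b"}}), ic)
        assert smin(curve) == (0.0, 0.01)

    def test_normalized_coordinates_bounded(self):
        for seed in range(5):
            _ont, bench, pred, ic = random_instance(seed + 7000)
            curve = normalized_ru_mi_curve(pred, bench, ic)
            assert np.all(curve.coord1 <= 1.0 + 1e-12)
            assert np.all(curve.coord2 <= 1.0 + 1e-12)


class TestCoverage:
    def test_counts_predicted_fraction(self):
        truth = {f"P{i}": {"a"} for i in range(4)}
        pred = _pred({"P0": {"a": 0.5}, "P1": {"b": 0.2}, "P2": {"a": 0.9}})
        assert coverage(pred, _bench(truth)) == 0.75

    def test_extremes(self):
        truth = {"P1": {"a"}, "P2": {"a"}}
        assert coverage(_pred({}), _bench(truth)) == 0.0
        assert coverage(_pred({"P1": {"a": 1.0}, "P2": {"a": 0.5}}), _bench(truth)) == 1.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_instances_match_brute_force(self, seed):
        """Curve machinery agrees with explicit set materialization at all
        100 thresholds, for every scalar metric, in both modes."""
        _ont, bench, pred, ic = random_instance(seed)
        truth = dict(bench.proteins)
        scores = pred.scores
        for mode in ("full", "partial"):
            if mode == "partial" and not any(scores.get(p) for p in truth):
                continue
            f = fmax(precision_recall_curve(pred, bench, mode=mode))[0]
            assert f == pytest.approx(brute_fmax(scores, truth, mode), abs=1e-12)
            s = smin(ru_mi_curve(pred, bench, ic, mode=mode))[0]
            assert s == pytest.approx(brute_smin(scores, truth, ic, mode), abs=1e-12)
            wf = fmax(weighted_precision_recall_curve(pred, bench, ic, mode=mode))[0]
            assert wf == pytest.approx(
                brute_weighted_fmax(scores, truth, ic, mode), abs=1e-12
            )
            ns = smin(normalized_ru_mi_curve(pred, bench, ic, mode=mode))[0]
            assert ns == pytest.approx(
                brute_normalized_smin(scores, truth, ic, mode), abs=1e-12
            )
        assert coverage(pred, bench) == pytest.approx(
            brute_coverage(scores, truth), abs=1e-12
        )

    def test_ru_monotone_mi_antitone(self):
        for seed in range(5):
            _ont, bench, pred, ic = random_instance(seed + 500)
            curve = ru_mi_curve(pred, bench, ic)
            assert np.all(np.diff(curve.coord1) >= -1e-12)  # ru non-decreasing
            assert np.all(np.diff(curve.coord2) <= 1e-12)  # mi non-increasing


class TestTermAUC:
    def test_perfect_separation(self):
        truth = {"P1": {"f"}, "P2": {"f"}, "P3": set("x"), "P4": set("x")}
        pred = _pred({"P1": {"f": 0.9}, "P2": {"f": 0.8},
                      "P3": {"f": 0.1}, "P4": {"f": 0.2}})
        assert term_auc(pred, _bench(truth), "f").auc == 1.0

    def test_constant_scores_give_half(self):
        truth = {"P1": {"f"}, "P2": set("x")}
        pred = _pred({"P1": {"f": 0.5}, "P2": {"f": 0.5}})
        assert term_auc(pred, _bench(truth), "f").auc == 0.5

    def test_three_of_four_concordant(self):
        truth = {"P1": {"f"}, "P2": {"f"}, "P3": set("x"), "P4": set("x")}
        pred = _pred({"P1": {"f": 0.8}, "P2": {"f": 0.3},
                      "P3": {"f": 0.5}, "P4": {"f": 0.1}})
        assert term_auc(pred, _bench(truth), "f").auc == 0.75

    def test_unpredicted_proteins_score_zero(self):
        truth = {"P1": {"f"}, "P2": set("x")}
        pred = _pred({"P1": {"f": 0.2}})
        assert term_auc(pred, _bench(truth), "f").auc == 1.0

    def test_no_positives_is_error(self):
        with pytest.raises(ValueError):
            term_auc(_pred({}), _bench({"P1": {"a"}}), "zzz")

    def test_invariant_under_monotone_transform_and_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(4, 12))
            labels = np.zeros(n, dtype=bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            if labels.all():
                labels[0] = False
            scores = rng.integers(0, 101, size=n) / 100.0
            truth = {
                f"P{i}": ({"f"} if labels[i] else {"x"}) for i in range(n)
            }
            pred = _pred({f"P{i}": {"f": scores[i]} for i in range(n) if scores[i] > 0})
            got = term_auc(pred, _bench(truth), "f").auc
            expect = brute_auc(scores[labels], scores[~labels])
            assert got == pytest.approx(expect, abs=1e-12)
            squashed = _pred(
                {f"P{i}": {"f": scores[i] ** 3} for i in range(n) if scores[i] > 0}
            )
            assert term_auc(squashed, _bench(truth), "f").auc == pytest.approx(
                got, abs=1e-12
            )

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        n = 30
        labels = rng.random(n) < 0.4
        labels[0], labels[1] = True, False
        scores = rng.integers(0, 101, size=n) / 100.0
        truth = {f"P{i}": ({"f"} if labels[i] else {"x"}) for i in range(n)}
        pred = _pred({f"P{i}": {"f": scores[i]} for i in range(n) if scores[i] > 0})
        assert term_auc(pred, _bench(truth), "f").auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestAverageAUC:
    def test_min_positives_rule(self):
        truth = {}
        for i in range(10):
            truth[f"P{i}"] = {"common"}  # 10 positives
        for i in range(10, 19):
            truth[f"P{i}"] = {"rare"}  # 9 positives
        pred = _pred({f"P{i}": {"common": 0.9, "rare": 0.9} for i in range(19)})
        result = average_auc(pred, _bench(truth), min_positives=10)
        assert [r.term for r in result.records] == ["common"]

    def test_single_term_zero_se(self):
        truth = {f"P{i}": ({"f"} if i < 10 else {"x"}) for i in range(12)}
        pred = _pred({f"P{i}": {"f": 0.9 if i < 10 else 0.1} for i in range(12)})
        result = average_auc(pred, _bench(truth), min_positives=10)
        assert result.mean == 1.0 and result.se == 0.0

    def test_mean_of_two_terms(self):
        truth = {}
        pred_scores = {}
        # term g: perfect separation; term h: constant scores -> 0.5
        for i in range(10):
            truth[f"A{i}"] = {"g"}
            pred_scores[f"A{i}"] = {"g": 0.9, "h": 0.5}
        for i in range(10):
            truth[f"B{i}"] = {"h"}
            pred_scores[f"B{i}"] = {"g": 0.1, "h": 0.5}
        result = average_auc(_pred(pred_scores), _bench(truth), min_positives=10)
        assert result.mean == pytest.approx((1.0 + 0.5) / 2)

    def test_no_qualifying_term_is_error(self):
        truth = {"P1": {"a"}, "P2": {"b"}}
        with pytest.raises(ValueError):
            average_auc(_pred({}), _bench(truth), min_positives=10)


class TestTopTermsNonoverlapping:
    def test_chain_keeps_only_best(self, chain_ontology):
        out = top_terms_nonoverlapping(
            {"T:b": 0.9, "T:a": 0.8}, chain_ontology, k=5
        )
        assert out == [("T:b", 0.9)]

    def test_disjoint_subtrees_all_kept(self, diamond_ontology):
        # d (under a) and b are ancestrally disjoint once c is excluded
        out = top_terms_nonoverlapping(
            {"T:d": 0.9, "T:b": 0.8}, diamond_ontology, k=2
        )
        assert out == [("T:d", 0.9), ("T:b", 0.8)]

    def test_k_zero(self, chain_ontology):
        assert top_terms_nonoverlapping({"T:b": 0.9}, chain_ontology, k=0) == []


class TestEvaluateSummary:
    def test_summary_fields_consistent(self):
        for seed in (3, 4):
            _ont, bench, pred, ic = random_instance(seed)
            summary = evaluate(pred, bench, ic=ic, mode="full")
            assert summary.n == bench.n
            assert summary.n_e == summary.n
            assert summary.coverage == pytest.approx(summary.m0 / summary.n)
            assert 0.0 <= summary.fmax <= 1.0
            assert summary.smin >= 0.0
            partial = evaluate(pred, bench, ic=ic, mode="partial")
            if 0 < summary.m0:
                assert partial.n_e == summary.m0
                assert partial.fmax >= summary.fmax - 1e-12
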