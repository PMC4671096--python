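"""Precision/recall, PR curves, APR, variance decomposition, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import average_precision_score

from vcbench.matchclass import Category, ConfusionCounts, ErrorClass, MatchResult
from vcbench.metrics import (
    PRCurve,
    aligner_caller_variation,
    apr,
    error_probabilities,
    het_hom_depth_ratio,
    pr_curve,
    precision,
    recall,
)
from vcbench.variant_model import HET, HOM_ALT

from conftest import make_prim


def result(qual, category, *, depth=None, gt=HET, error=ErrorClass.NONE, snp=True, pos=100):
    ref, alt = ("A", "G") if snp else ("AT", "A")
    call = make_prim(pos=pos, ref=ref, alt=alt, qual=qual, gt=gt, depth=depth)
    truth = make_prim(pos=pos, ref=ref, alt=alt, gt=HET if gt is HOM_ALT else HOM_ALT)
    if category is Category.TP:
        return MatchResult(call, make_prim(pos=pos, ref=ref, alt=alt, gt=gt), category)
    if category is Category.FP:
        return MatchResult(call, None, category)
    if category is Category.FN:
        return MatchResult(None, truth, category)
    return MatchResult(call, truth, category, error)


class TestPrecisionRecall:
    def test_direct_formula(self):
        c = ConfusionCounts(tp=3, fp=1, fn=1, genotype_errors=0, tn_universe=0)
        assert precision(c) == 0.75 and recall(c) == 0.75

    def test_zero_call_precision_convention(self):
        c = ConfusionCounts(tp=0, fp=0, fn=2, genotype_errors=0, tn_universe=0)
        assert precision(c) == 1.0

    def test_perfect_callset(self):
        c = ConfusionCounts(tp=5, fp=0, fn=0, genotype_errors=0, tn_universe=0)
        assert precision(c) == 1.0 and recall(c) == 1.0

    def test_genotype_errors_hurt_both(self):
        c = ConfusionCounts(tp=3, fp=0, fn=0, genotype_errors=1, tn_universe=0)
        assert precision(c) == 0.75 and recall(c) == 0.75

    def test_empty_truth_recall_is_error(self):
        c = ConfusionCounts(tp=0, fp=2, fn=0, genotype_errors=0, tn_universe=0)
        with pytest.raises(ValueError):
            recall(c)


class TestPRCurve:
    def test_three_threshold_example(self):
        results = [result(50.0, Category.TP), result(40.0, Category.FP), result(30.0, Category.TP)]
        curve = pr_curve(results, truth_size=2)
        assert curve.points == ((0.5, 1.0), (0.5, 0.5), (1.0, 2 / 3))
        assert curve.apr == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_perfect_callset_ends_at_one_one(self):
        results = [result(50.0, Category.TP), result(50.0, Category.TP)]
        curve = pr_curve(results, truth_size=2)
        assert curve.points[-1] == (1.0, 1.0) and curve.apr == 1.0

    def test_equal_qual_ties_form_one_group(self):
        results = [result(40.0, Category.TP), result(40.0, Category.FP)]
        curve = pr_curve(results, truth_size=1)
        assert curve.points == ((1.0, 0.5),)

    def test_all_fp_curve_has_zero_apr(self):
        results = [result(q, Category.FP) for q in (50.0, 30.0)]
        curve = pr_curve(results, truth_size=3)
        assert curve.apr == 0.0

    def test_empty_truth_is_error(self):
        with pytest.raises(ValueError):
            pr_curve([result(50.0, Category.FP)], truth_size=0)

    def test_recall_is_non_decreasing(self):
        rng = np.random.default_rng(5)
        results = [
            result(float(rng.integers(0, 30)), Category.TP if rng.random() < 0.7 else Category.FP)
            for _ in range(200)
        ]
        n_tp = sum(1 for r in results if r.category is Category.TP)
        curve = pr_curve(results, truth_size=n_tp + 5)
        recalls = [r for r, _ in curve.points]
        assert recalls == sorted(recalls)

    def test_matches_average_precision_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(5, 500))
            labels = rng.random(n) < 0.6
            if not labels.any():
                labels[0] = True
            scores = np.round(rng.uniform(0, 60, n), 1)
            results = [
                result(float(s), Category.TP if l else Category.FP)
                for s, l in zip(scores, labels)
            ]
            mine = pr_curve(results, truth_size=int(labels.sum())).apr
            ref = average_precision_score(labels.astype(int), scores)
            assert mine == pytest.approx(ref, abs=1e-9)


class TestAPRIntegration:
    def test_stepwise_sum(self):
        curve = PRCurve(points=((0.5, 1.0), (0.5, 0.5), (1.0, 2 / 3)), thresholds=(50, 40, 30), apr=0.0)
        assert apr(curve) == pytest.approx(0.8333333333333)

    def test_clamped_to_unit_interval(self):
        assert apr(PRCurve(points=(), thresholds=(), apr=0.0)) == 0.0


class TestAlignerCallerVariation:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["dataset_id", "aligner_id", "caller_id", "apr"])

    def test_all_equal_gives_zero(self):
        rows = [("d1", a, c, 0.9) for a in "xy" for c in "pq"]
        assert aligner_caller_variation(self.table(rows)) == (0.0, 0.0)

    def test_hand_computed_sample_sd(self):
        # APR differs across aligners only: sd = sd({0.8, 0.9}) = 0.0707...
        rows = [("d1", "x", c, 0.8) for c in "pq"] + [("d1", "y", c, 0.9) for c in "pq"]
        sd_al, sd_ca = aligner_caller_variation(self.table(rows))
        assert sd_al == pytest.approx(np.std([0.8, 0.9], ddof=1))
        assert sd_ca == 0.0

    def test_invariant_to_dataset_order(self):
        rows = [(d, a, c, hash((d, a, c)) % 100 / 100) for d in ("d1", "d2") for a in "xy" for c in "pq"]
        fwd = aligner_caller_variation(self.table(rows))
        rev = aligner_caller_variation(self.table(rows[::-1]))
        assert fwd == pytest.approx(rev)

    def test_small_groups_raise_when_nothing_left(self):
        with pytest.raises(ValueError):
            aligner_caller_variation(self.table([("d1", "x", "p", 0.5)]))


class TestErrorProbabilities:
    def test_direct_ratio(self):
        results = (
            [result(50.0, Category.GENOTYPE_ERROR, gt=HOM_ALT, error=ErrorClass.IR)]
            + [result(50.0, Category.GENOTYPE_ERROR, gt=HET, error=ErrorClass.AR)]
            + [result(50.0, Category.TP) for _ in range(8)]
        )
        prof = error_probabilities(results, 0.0)
        assert prof.p_ir == prof.p_ar == 0.1
        assert prof.n_calls == 10 and prof.n_other == 0

    def test_no_errors_gives_zero(self):
        prof = error_probabilities([result(50.0, Category.TP)] * 4, 0.0)
        assert prof.p_ir == prof.p_ar == 0.0

    def test_indel_calls_excluded(self):
        results = [result(50.0, Category.TP), result(50.0, Category.TP, snp=False)]
        assert error_probabilities(results, 0.0).n_calls == 1

    def test_no_snp_calls_is_error(self):
        with pytest.raises(ValueError):
            error_probabilities([result(50.0, Category.TP, snp=False)], 0.0)


class TestHetHomDepthRatio:
    def test_equal_depths_give_one(self):
        results = [result(50.0, Category.TP, depth=20, gt=HET),
                   result(50.0, Category.TP, depth=20, gt=HOM_ALT)]
        assert het_hom_depth_ratio(results) == 1.0

    def test_direct_computation(self):
        results = [result(50.0, Category.TP, depth=10, gt=HET),
                   result(50.0, Category.TP, depth=20, gt=HET),
                   result(50.0, Category.TP, depth=30, gt=HOM_ALT)]
        assert het_hom_depth_ratio(results) == pytest.approx(0.5)

    def test_missing_group_is_error(self):
        with pytest.raises(ValueError):
            het_hom_depth_ratio([result(50.0, Category.TP, depth=10, gt=HET)])

    def test_poisson_simulation_recovers_ratio(self):
        rng = np.random.default_rng(23)
        results = [result(50.0, Category.TP, depth=int(rng.poisson(15)), gt=HET, pos=p)
                   for p in range(4000)]
        results += [result(50.0, Category.TP, depth=int(rng.poisson(30)), gt=HOM_ALT, pos=p)
                    for p in range(4000)]
        se = 0.5 * math.sqrt(1 / (4000 * 15) + 1 / (4000 * 30))
        assert het_hom_depth_ratio(results) == pytest.approx(0.5, abs=3 * se)
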