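"""Precision/recall, QUAL-ranked PR curves, APR, and diagnostic summaries.

The summary score is the area under the precision-recall curve (APR),
integrated step-wise (average precision): APR = sum_i (R_i - R_{i-1}) * P_i
over curve points at descending QUAL thresholds.  No interpolation is applied
between points — linear interpolation in PR space is known to flatter a
classifier.  Calls sharing a QUAL are inseparable and enter as one threshold
group.  APR is 1.0 exactly when every truth variant is recovered with the
correct genotype and nothing else is called.

Genotyping errors are folded into FP for precision and into FN for recall
(see :mod:`vcbench.matchclass`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .matchclass import Category, ConfusionCounts, ErrorClass, MatchResult

logger = logging.getLogger("vcbench")


@dataclass(frozen=True)
class PRCurve:
    """(recall, precision) points at descending QUAL thresholds, plus APR."""

    points: tuple[tuple[float, float], ...]
    thresholds: tuple[float, ...]
    apr: float


@dataclass(frozen=True)
class ErrorProfile:
    """SNP genotyping-error composition of one callset."""

    n_ir: int
    n_ar: int
    n_other: int
    n_calls: int  # all classified SNP calls at the threshold (TP+FP+errors)
    p_ir: float
    p_ar: float


def precision(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp + c.genotype_errors
    if denom == 0:
        return 1.0  # zero-call limit: nothing asserted, nothing wrong
    return c.tp / denom


def recall(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn + c.genotype_errors
    if denom == 0:
        raise ValueError("recall undefined: empty truth set")
    return c.tp / denom


def pr_curve(results: Sequence[MatchResult], truth_size: int) -> PRCurve:
    """QUAL-ranked precision-recall curve over a matched callset.

    *truth_size* is the number of truth primitives in the territory; recall is
    measured against it, so truth never recovered at any threshold still
    penalizes recall.  Calls with missing QUAL fail every numeric threshold
    and never enter the curve.
    """
    if truth_size <= 0:
        raise ValueError("pr_curve requires a non-empty truth set")
    scored = [
        (r.qual, 1 if r.category is Category.TP else 0)
        for r in results
        if r.call is not None and r.qual is not None
    ]
    scored.sort(key=lambda t: -t[0])
    points: list[tuple[float, float]] = []
    thresholds: list[float] = []
    cum_tp = 0
    cum_calls = 0
    i = 0
    n = len(scored)
    while i < n:
        q = scored[i][0]
        while i < n and scored[i][0] == q:  # equal-QUAL ties form one group
            cum_tp += scored[i][1]
            cum_calls += 1
            i += 1
        points.append((cum_tp / truth_size, cum_tp / cum_calls))
        thresholds.append(q)
    curve = PRCurve(tuple(points), tuple(thresholds), 0.0)
    return PRCurve(curve.points, curve.thresholds, apr(curve))


def apr(curve: PRCurve) -> float:
    """Step-wise average-precision integral of a PR curve, clamped to [0, 1]."""
    total = 0.0
    prev_r = 0.0
    for r, p in curve.points:
        total += (r - prev_r) * p
        prev_r = r
    return min(1.0, max(0.0, total))


def aligner_caller_variation(
    table: pd.DataFrame, value: str = "apr"
) -> tuple[float, float]:
    """Average APR spread attributable to the aligner vs the caller.

    For each (dataset, caller[, variant class]) group, the sample standard
    deviation of APR across aligners; and symmetrically across callers for
    each (dataset, aligner[, ...]) group.  Returns the two means.  Groups
    with fewer than two members are skipped with a warning.
    """

    def _mean_sd(df: pd.DataFrame, vary: str) -> float:
        fixed = [c for c in df.columns if c not in (vary, value)]
        sds = []
        for keys, grp in df.groupby(fixed, dropna=False):
            if len(grp) < 2:
                logger.warning("variation: group %s has <2 %s levels, skipped", keys, vary)
                continue
            sds.append(grp[value].std(ddof=1))
        if not sds:
            raise ValueError(f"no group has >=2 {vary} levels")
        return float(sum(sds) / len(sds))

    return _mean_sd(table, "aligner_id"), _mean_sd(table, "caller_id")


def error_probabilities(
    results: Sequence[MatchResult], qual_min: float = 0.0
) -> ErrorProfile:
    """IR/AR probabilities among all classified SNP calls at the threshold.

    The denominator is every SNP call surviving the QUAL filter (TP + FP +
    genotyping errors); the raw counts are reported so any alternative
    denominator can be recomputed.
    """
    n_ir = n_ar = n_other = n_calls = 0
    for r in results:
        if r.call is None or not r.call.is_snp:
            continue
        if r.qual is None or r.qual < qual_min:
            continue
        n_calls += 1
        if r.category is Category.GENOTYPE_ERROR:
            if r.error_class is ErrorClass.IR:
                n_ir += 1
            elif r.error_class is ErrorClass.AR:
                n_ar += 1
            else:
                n_other += 1
    if n_calls == 0:
        raise ValueError("no SNP calls at or above the QUAL threshold")
    return ErrorProfile(n_ir, n_ar, n_other, n_calls, n_ir / n_calls, n_ar / n_calls)


def het_hom_depth_ratio(results: Sequence[MatchResult]) -> float:
    """Mean depth of correctly called het variants over that of hom-alt ones.

    A coverage diagnostic: on deeply sequenced data the ratio sits above 1
    (both alleles must be sampled for a confident het call); a ratio below 1
    flags depth-starved calling.
    """
    het: list[int] = []
    hom: list[int] = []
    for r in results:
        if r.category is not Category.TP or r.call is None or r.call.depth is None:
            continue
        (het if r.call.genotype.is_het else hom).append(r.call.depth)
    if not het or not hom:
        raise ValueError("need depth-bearing TP calls in both genotype groups")
    return (sum(het) / len(het)) / (sum(hom) / len(hom))


def build_apr_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble per-pipeline APR rows into the crossed-design table."""
    df = pd.DataFrame(rows)
    expected = {"dataset_id", "aligner_id", "caller_id", "vclass", "apr"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"APR table missing columns: {sorted(missing)}")
    return df
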