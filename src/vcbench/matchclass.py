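"""Genotype-aware classification of query calls against the gold standard.

A call is a true positive only if locus, alleles *and* diploid genotype all
agree with the truth record.  A call matching a truth site but with the wrong
genotype is a genotyping error, typed by how the reference allele was handled:

* IR (ignoring the reference allele): truth is het ref/alt, call is hom-alt;
* AR (adding the reference allele): truth is hom-alt, call is het ref/alt;
* OTHER: any remaining disagreement (including a different ALT at the site).

Genotyping errors count against both precision (the emitted call is wrong)
and recall (the truth genotype was not produced); that is the strictest
treatment consistent with the genotype-aware TP definition.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .normalize import PrimitiveVariant
from .regions import RegionSet
from .variant_model import VariantClass

logger = logging.getLogger("vcbench")


class Category(enum.Enum):
    TP = "TP"
    FP = "FP"
    FN = "FN"
    GENOTYPE_ERROR = "GENOTYPE_ERROR"


class ErrorClass(enum.Enum):
    IR = "IR"
    AR = "AR"
    OTHER = "OTHER"
    NONE = "NONE"


@dataclass(frozen=True)
class MatchResult:
    """Per-call (or per-missed-truth) classification outcome."""

    call: Optional[PrimitiveVariant]
    truth: Optional[PrimitiveVariant]
    category: Category
    error_class: ErrorClass = ErrorClass.NONE

    def __post_init__(self) -> None:
        if self.category in (Category.TP, Category.GENOTYPE_ERROR):
            if self.call is None or self.truth is None:
                raise ValueError(f"{self.category} requires both call and truth")
        elif self.category is Category.FP and self.truth is not None:
            raise ValueError("FP must have no truth")
        elif self.category is Category.FN and self.call is not None:
            raise ValueError("FN must have no call")
        if (self.error_class is not ErrorClass.NONE) != (
            self.category is Category.GENOTYPE_ERROR
        ):
            raise ValueError("error_class set iff category is GENOTYPE_ERROR")

    @property
    def qual(self) -> Optional[float]:
        return self.call.qual if self.call is not None else None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    genotype_errors: int
    tn_universe: int


def classify_error(
    call_gt: Sequence[str], truth_gt: Sequence[str], ref: str
) -> ErrorClass:
    """Type a genotype disagreement at one SNP site.

    Genotypes are unordered pairs of allele sequences; *ref* is the reference
    allele at the site.  IR and AR are specific reference-allele mistakes on
    the *same* alternative allele; everything else is OTHER.
    """
    call = tuple(sorted(call_gt))
    truth = tuple(sorted(truth_gt))
    if call == truth:
        raise ValueError("classify_error requires call_gt != truth_gt")
    # IR: call hom-alt {A,A}, truth het {R,A} with the same A
    if call[0] == call[1] != ref and truth == tuple(sorted((ref, call[0]))):
        return ErrorClass.IR
    # AR: call het {R,A}, truth hom-alt {A,A} with the same A
    if truth[0] == truth[1] != ref and call == tuple(sorted((ref, truth[0]))):
        return ErrorClass.AR
    return ErrorClass.OTHER


def _dedupe(prims: Iterable[PrimitiveVariant], what: str) -> dict[tuple, PrimitiveVariant]:
    """Collapse duplicate (chrom,pos,ref,alt) keys, keeping the highest QUAL."""
    best: dict[tuple, PrimitiveVariant] = {}
    for p in prims:
        old = best.get(p.key)
        if old is None:
            best[p.key] = p
        else:
            logger.warning("%s: duplicate key %s, keeping highest QUAL", what, p.key)
            old_q = -1.0 if old.qual is None else old.qual
            new_q = -1.0 if p.qual is None else p.qual
            if new_q > old_q:
                best[p.key] = p
    return best


def _site_genotype(prims: Sequence[PrimitiveVariant], ref: str) -> tuple[str, str]:
    """Joint diploid genotype over all primitives at one site.

    Two het primitives with different ALTs form an alt/alt het (the AB class);
    remaining chromosome copies carry the reference allele.
    """
    alts: list[str] = []
    for p in prims:
        copies = 2 if p.genotype.is_hom_alt else 1
        alts.extend([str(p.alt)] * copies)
    if len(alts) > 2:
        logger.warning("inconsistent site genotype (>2 alt copies) at %s", prims[0].site)
        alts = alts[:2]
    while len(alts) < 2:
        alts.append(ref)
    return tuple(sorted(alts))  # type: ignore[return-value]


def match_callset(
    calls: Iterable[PrimitiveVariant], truth: Iterable[PrimitiveVariant]
) -> list[MatchResult]:
    """Join calls and truth on (chrom, pos, ref, alt); classify every record.

    Same key and genotype -> TP; same key, different genotype -> genotyping
    error; a SNP call whose key is absent but whose site holds an unmatched
    truth SNP with a different ALT -> genotyping error (OTHER family); other
    unmatched calls -> FP; unmatched truth -> FN.  Every call and every truth
    primitive appears in exactly one result.
    """
    call_map = _dedupe(calls, "callset")
    truth_map = _dedupe(truth, "truth set")
    truth_by_site: dict[tuple, list[PrimitiveVariant]] = {}
    call_by_site: dict[tuple, list[PrimitiveVariant]] = {}
    for t in truth_map.values():
        truth_by_site.setdefault(t.site, []).append(t)
    for c in call_map.values():
        call_by_site.setdefault(c.site, []).append(c)

    results: list[MatchResult] = []
    consumed_truth: set[tuple] = set()
    deferred_snps: list[PrimitiveVariant] = []

    for key, call in call_map.items():
        t = truth_map.get(key)
        if t is not None:
            consumed_truth.add(key)
            if call.genotype == t.genotype:
                results.append(MatchResult(call, t, Category.TP))
            else:
                if call.is_snp and t.is_snp:
                    cls = classify_error(
                        _site_genotype(call_by_site[call.site], str(call.ref)),
                        _site_genotype(truth_by_site[t.site], str(t.ref)),
                        str(call.ref),
                    )
                else:
                    cls = ErrorClass.OTHER  # indel genotype mismatch: not IR/AR-typed
                results.append(MatchResult(call, t, Category.GENOTYPE_ERROR, cls))
        elif call.is_snp:
            deferred_snps.append(call)
        else:
            results.append(MatchResult(call, None, Category.FP))

    # second pass: SNP calls with a different ALT at a truth SNP site
    for call in deferred_snps:
        site_truth = [
            t
            for t in truth_by_site.get(call.site, [])
            if t.is_snp and t.key not in consumed_truth
        ]
        if site_truth:
            t = site_truth[0]
            consumed_truth.add(t.key)
            cls = classify_error(
                _site_genotype(call_by_site[call.site], str(call.ref)),
                _site_genotype(truth_by_site[t.site], str(t.ref)),
                str(call.ref),
            )
            results.append(MatchResult(call, t, Category.GENOTYPE_ERROR, cls))
        else:
            results.append(MatchResult(call, None, Category.FP))

    for key, t in truth_map.items():
        if key not in consumed_truth:
            results.append(MatchResult(None, t, Category.FN))
    return results


def tabulate(
    results: Sequence[MatchResult], qual_min: float, territory: RegionSet
) -> ConfusionCounts:
    """Confusion counts over calls with QUAL >= *qual_min*.

    A truth site whose only call falls below the threshold (or carries a
    missing QUAL, which fails every numeric threshold) counts as FN.  The TN
    universe is the covered territory minus truth-variant sites.
    """
    tp = fp = fn = ge = n_truth = 0
    for r in results:
        if r.truth is not None:
            n_truth += 1
        if r.category is Category.FN:
            fn += 1
            continue
        q = r.qual
        if q is None or q < qual_min:
            if r.truth is not None:
                fn += 1
            continue
        if r.category is Category.TP:
            tp += 1
        elif r.category is Category.FP:
            fp += 1
        else:
            ge += 1
    return ConfusionCounts(
        tp=tp,
        fp=fp,
        fn=fn,
        genotype_errors=ge,
        tn_universe=territory.covered_length() - n_truth,
    )


def results_to_rows(results: Sequence[MatchResult]) -> list[dict]:
    """Flatten results for TSV/DataFrame output, one row per MatchResult."""
    rows = []
    for r in results:
        v = r.call if r.call is not None else r.truth
        assert v is not None
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": str(v.ref),
                "alt": str(v.alt),
                "call_gt": "." if r.call is None else str(r.call.genotype),
                "truth_gt": "." if r.truth is None else str(r.truth.genotype),
                "qual": "" if r.qual is None else r.qual,
                "category": r.category.value,
                "error_class": r.error_class.value,
            }
        )
    return rows
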