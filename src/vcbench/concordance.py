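"""Multi-caller concordance (Venn partition of high-confidence calls).

For each caller, callsets produced with different read aligners are merged
(union over call identity, keeping the best QUAL); the merged callsets are
filtered at a QUAL threshold (default 20) and every surviving call is assigned
to exactly one Venn region — the exact subset of callers that produced it.
Region sizes are reported as percentages of the union, and summarized as
mean ± sd across datasets.

Call identity includes the genotype by default: a site called het by one
caller and hom-alt by another is discordant, consistent with the
genotype-aware TP definition used throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

from .normalize import PrimitiveVariant

DEFAULT_QUAL_MIN = 20.0


class CallsetKey(NamedTuple):
    """Identity of one normalized call for set algebra."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gt: str  # "0/1" or "1/1"; "" when genotype-blind


Callset = dict[CallsetKey, Optional[float]]  # key -> best QUAL


def callset_of(
    prims: Iterable[PrimitiveVariant], *, genotype_aware: bool = True
) -> Callset:
    out: Callset = {}
    for p in prims:
        key = CallsetKey(
            p.chrom, p.pos, str(p.ref), str(p.alt), str(p.genotype) if genotype_aware else ""
        )
        old = out.get(key, None)
        if key not in out or _q(p.qual) > _q(old):
            out[key] = p.qual
    return out


def _q(qual: Optional[float]) -> float:
    return -1.0 if qual is None else qual


def merge_aligners(callsets: Sequence[Callset]) -> Callset:
    """Union of per-aligner callsets for one caller; colliding keys keep the
    maximum QUAL."""
    merged: Callset = {}
    for cs in callsets:
        for key, qual in cs.items():
            if key not in merged or _q(qual) > _q(merged[key]):
                merged[key] = qual
    return merged


@dataclass(frozen=True)
class VennResult:
    """Venn partition of one dataset's filtered union of calls."""

    region_counts: dict[frozenset, int]
    union_size: int

    @property
    def percentages(self) -> dict[frozenset, float]:
        return {r: 100.0 * n / self.union_size for r, n in self.region_counts.items()}


def venn(
    callsets: Mapping[str, Callset], qual_min: float = DEFAULT_QUAL_MIN
) -> VennResult:
    """Partition the union of QUAL-filtered callsets into exclusive Venn regions.

    Missing QUAL fails the threshold.  Every non-empty caller subset appears
    in the result (possibly with count 0), so percentages over datasets align.
    """
    if not 2 <= len(callsets) <= 4:
        raise ValueError("venn supports 2-4 callers")
    names = sorted(callsets)
    filtered: dict[str, set[CallsetKey]] = {
        name: {k for k, q in cs.items() if q is not None and q >= qual_min}
        for name, cs in callsets.items()
    }
    union: set[CallsetKey] = set().union(*filtered.values())
    if not union:
        raise ValueError("empty union after QUAL filtering")
    counts: dict[frozenset, int] = {}
    for r in range(1, 1 << len(names)):
        region = frozenset(n for i, n in enumerate(names) if r >> i & 1)
        counts[region] = 0
    for key in union:
        region = frozenset(n for n in names if key in filtered[n])
        counts[region] += 1
    return VennResult(counts, len(union))


@dataclass(frozen=True)
class ConcordanceSummary:
    """Mean ± sd of Venn-region percentages across datasets."""

    mean: dict[frozenset, float]
    sd: dict[frozenset, float]
    per_dataset: tuple[dict[frozenset, float], ...]


def summarize_venn(per_dataset: Sequence[VennResult]) -> ConcordanceSummary:
    if not per_dataset:
        raise ValueError("no datasets to summarize")
    regions = set()
    for v in per_dataset:
        regions |= set(v.region_counts)
    pcts = [v.percentages for v in per_dataset]
    mean: dict[frozenset, float] = {}
    sd: dict[frozenset, float] = {}
    n = len(pcts)
    for region in regions:
        vals = [p.get(region, 0.0) for p in pcts]
        m = sum(vals) / n
        mean[region] = m
        sd[region] = (
            math.sqrt(sum((v - m) ** 2 for v in vals) / (n - 1)) if n > 1 else 0.0
        )
    return ConcordanceSummary(mean, sd, tuple(pcts))


def region_name(region: frozenset) -> str:
    return " ∩ ".join(sorted(region)) if len(region) > 1 else next(iter(region))
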