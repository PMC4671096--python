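"""Synthetic benchmark inputs with known ground-truth labels.

Emulates the study design the package evaluates: a diploid gold-standard set
of SNPs and short indels confined to high-confidence regions intersected with
an exome-capture territory, plus degraded query callsets with controlled
false-negative, false-positive and genotyping-error structure.  Because every
emitted call carries its intended label, the matcher and the metrics can be
tested against an exact oracle, and injected error rates can be recovered
statistically.

What the generator emulates — and what it does not: sites are independent and
placed on a sparse grid (>=10 bp apart), so there is no linkage, no clustered
error structure, no homopolymer-driven indel bias and no reference context
beyond each record's own alleles.  QUAL separates true from erroneous calls as
two truncated normals, a deliberately clean version of the score/accuracy
relationship that makes threshold filtering and PR ranking meaningful.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .variant_model import (
    HET,
    HOM_ALT,
    Allele,
    GenomicInterval,
    Genotype,
    SourceLabels,
    VariantRecord,
)
from .regions import RegionSet, intersect

_BASES = np.array(list("ACGT"))

#: minimum spacing between simulated truth sites (keeps primitives disjoint)
SITE_SPACING = 10
#: margin kept clear of interval ends so any ref span (<=6 bp) stays contained
_EDGE_MARGIN = 6


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    Defaults sketch a deeply covered exome-like experiment: a few thousand
    mostly heterozygous truth variants on one contig, a confident territory
    covering ~70% of it, a capture territory ~50%, low error rates, and QUAL
    distributions that separate true calls (N(45,5), truncated at 0) from
    erroneous ones (N(15,5)) so the conventional QUAL>=20 filter bites.
    Depth means (het 80x, hom 49x) echo the coverage asymmetry of confident
    het vs hom calls on high-depth short-read data.
    """

    contig: str = "chr1"
    contig_length: int = 1_500_000
    n_snp: int = 4000
    n_indel: int = 400
    het_fraction: float = 0.6
    confident_fraction: float = 0.7
    capture_fraction: float = 0.5
    fn_rate: float = 0.03
    fp_rate: float = 0.02
    ir_rate: float = 0.01
    ar_rate: float = 0.015
    other_rate: float = 0.005
    qual_true: tuple[float, float] = (45.0, 5.0)  # (location, scale)
    qual_false: tuple[float, float] = (15.0, 5.0)
    depth_het_mean: float = 80.0
    depth_hom_mean: float = 49.0
    seed: int = 0
    window: int = 5000  # tiling window for BED construction

    def validate(self) -> None:
        for name in ("het_fraction", "confident_fraction", "capture_fraction",
                     "fn_rate", "fp_rate", "ir_rate", "ar_rate", "other_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ir_rate + self.ar_rate + self.other_rate + self.fn_rate > 1.0:
            raise ValueError("fn_rate + ir_rate + ar_rate + other_rate must be <= 1")
        if self.n_snp < 0 or self.n_indel < 0:
            raise ValueError("negative truth counts")
        if (self.n_snp + self.n_indel) * SITE_SPACING > self.contig_length:
            raise ValueError("site spacing guarantee violated: too many sites for contig")
        if self.qual_true[1] < 0 or self.qual_false[1] < 0:
            raise ValueError("negative QUAL scale")
        if self.depth_het_mean < 0 or self.depth_hom_mean < 0:
            raise ValueError("negative depth mean")


@dataclass(frozen=True)
class TruthSet:
    """Gold-standard callset plus the territory it lives in."""

    records: tuple[VariantRecord, ...]
    confident: RegionSet
    capture: RegionSet
    territory: RegionSet
    ref_map: Mapping[int, str]  # pos -> REF string at each truth site
    fp_candidates: tuple[int, ...]  # grid positions inside territory, unused by truth
    config: SimulationConfig


LABEL_COLUMNS = ("chrom", "pos", "ref", "alt", "category", "error_class", "qual")


def _tiled_regions(
    rng: np.random.Generator, chrom: str, length: int, fraction: float, window: int
) -> RegionSet:
    """Cover ~fraction of the contig with one sub-interval per tiling window."""
    intervals = []
    for w_start in range(0, length, window):
        w_len = min(window, length - w_start)
        cover = int(round(w_len * fraction))
        if cover <= 0:
            continue
        offset = int(rng.integers(0, w_len - cover + 1))
        intervals.append(GenomicInterval(chrom, w_start + offset, w_start + offset + cover))
    return RegionSet(intervals)


def simulate_truth(cfg: SimulationConfig) -> TruthSet:
    """Draw the gold standard: genotyped SNP/indel sites inside confident ∩ capture.

    Sites sit on a 10 bp grid inside the territory (with a 6 bp margin from
    interval ends) so reference spans never straddle a region edge and
    neighbouring primitives never interact.  Deterministic given cfg.seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    confident = _tiled_regions(rng, cfg.contig, cfg.contig_length, cfg.confident_fraction, cfg.window)
    capture = _tiled_regions(rng, cfg.contig, cfg.contig_length, cfg.capture_fraction, cfg.window)
    territory = intersect(confident, capture)

    candidates: list[int] = []
    for iv in territory.intervals:
        # 1-based positions p with [p-1, p-1+6) inside [start, end)
        candidates.extend(range(iv.start + 1, iv.end - _EDGE_MARGIN + 2, SITE_SPACING))
    n_sites = cfg.n_snp + cfg.n_indel
    if n_sites > len(candidates):
        raise ValueError(
            f"cannot place {n_sites} sites: only {len(candidates)} grid positions in territory"
        )
    chosen = rng.choice(len(candidates), size=n_sites, replace=False)
    positions = sorted(int(candidates[i]) for i in chosen)
    is_indel = np.zeros(n_sites, dtype=bool)
    is_indel[rng.choice(n_sites, size=cfg.n_indel, replace=False)] = True

    records: list[VariantRecord] = []
    ref_map: dict[int, str] = {}
    for pos, indel in zip(positions, is_indel):
        anchor = str(rng.choice(_BASES))
        if not indel:
            ref, alt = anchor, str(rng.choice(_BASES[_BASES != anchor]))
        else:
            extra = "".join(rng.choice(_BASES, size=int(rng.integers(1, 5))))
            if rng.random() < 0.5:  # insertion
                ref, alt = anchor, anchor + extra
            else:  # deletion
                ref, alt = anchor + extra, anchor
        gt = HET if rng.random() < cfg.het_fraction else HOM_ALT
        records.append(
            VariantRecord(
                chrom=cfg.contig,
                pos=pos,
                ref=Allele(ref),
                alts=(Allele(alt),),
                genotype=gt,
                qual=100.0,
                labels=SourceLabels(dataset_id="truth"),
            )
        )
        ref_map[pos] = ref

    used = set(positions)
    fp_candidates = tuple(p for p in candidates if p not in used)
    return TruthSet(
        records=tuple(records),
        confident=confident,
        capture=capture,
        territory=territory,
        ref_map=ref_map,
        fp_candidates=fp_candidates,
        config=cfg,
    )


def _stream_seed(base_seed: int, stream: str) -> list[int]:
    return [int(base_seed) & 0x7FFFFFFF, zlib.crc32(stream.encode()) & 0x7FFFFFFF]


def _draw_qual(rng: np.random.Generator, loc_scale: tuple[float, float]) -> float:
    loc, scale = loc_scale
    return round(max(0.0, float(rng.normal(loc, scale))), 2)


def simulate_callset(
    truth: TruthSet,
    caller_profile: Optional[Mapping[str, float]] = None,
    *,
    stream: str = "query",
    labels: SourceLabels = SourceLabels(),
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Degrade the truth into a query callset with known per-call labels.

    Per truth site, independently: dropped with probability ``fn_rate``;
    an emitted het becomes hom-alt with probability ``ir_rate`` (the IR
    pattern); an emitted hom-alt becomes het with probability ``ar_rate``
    (AR); an emitted SNP otherwise has its ALT swapped with probability
    ``other_rate`` (the remaining error family).  ``round(fp_rate * |truth|)``
    novel SNP calls land on unused grid positions.  True calls draw QUAL from
    ``qual_true``, erroneous ones from ``qual_false``; depth is Poisson with
    the mean matching the *emitted* genotype.

    ``caller_profile`` overrides individual config fields (typically rates),
    emulating callers with different error biases.  ``stream`` names the
    callset's RNG stream so several callsets from one truth are independent
    but reproducible.

    Returns the records and a label table with one row per emitted call
    (category TP/FP/GENOTYPE_ERROR + error class) plus one FN row per dropped
    truth site.
    """
    cfg = truth.config
    if caller_profile:
        cfg = replace(cfg, **dict(caller_profile))
        cfg.validate()
    rng = np.random.default_rng(_stream_seed(truth.config.seed, stream))

    records: list[VariantRecord] = []
    rows: list[tuple] = []
    for t in truth.records:
        ref, alt = str(t.ref), str(t.alts[0])
        is_snp = len(ref) == 1 and len(alt) == 1
        if rng.random() < cfg.fn_rate:
            rows.append((t.chrom, t.pos, ref, alt, "FN", "NONE", np.nan))
            continue
        gt = t.genotype
        err = None
        if gt.is_het and rng.random() < cfg.ir_rate:
            gt, err = HOM_ALT, ("IR" if is_snp else "OTHER")
        elif gt.is_hom_alt and rng.random() < cfg.ar_rate:
            gt, err = HET, ("AR" if is_snp else "OTHER")
        elif is_snp and rng.random() < cfg.other_rate:
            alt = str(rng.choice(_BASES[(_BASES != ref) & (_BASES != alt)]))
            err = "OTHER"
        qual = _draw_qual(rng, cfg.qual_true if err is None else cfg.qual_false)
        depth = int(rng.poisson(cfg.depth_het_mean if gt.is_het else cfg.depth_hom_mean))
        records.append(
            VariantRecord(
                chrom=t.chrom, pos=t.pos, ref=Allele(ref), alts=(Allele(alt),),
                genotype=gt, qual=qual, depth=depth, labels=labels,
            )
        )
        rows.append(
            (t.chrom, t.pos, ref, alt, "TP" if err is None else "GENOTYPE_ERROR",
             err or "NONE", qual)
        )

    n_fp = int(round(cfg.fp_rate * len(truth.records)))
    if n_fp > len(truth.fp_candidates):
        raise ValueError(f"cannot place {n_fp} FP calls: only {len(truth.fp_candidates)} free positions")
    if n_fp:
        fp_pos = sorted(
            int(truth.fp_candidates[i])
            for i in rng.choice(len(truth.fp_candidates), size=n_fp, replace=False)
        )
        for pos in fp_pos:
            ref = str(rng.choice(_BASES))
            alt = str(rng.choice(_BASES[_BASES != ref]))
            gt = HET if rng.random() < cfg.het_fraction else HOM_ALT
            qual = _draw_qual(rng, cfg.qual_false)
            depth = int(rng.poisson(cfg.depth_het_mean if gt.is_het else cfg.depth_hom_mean))
            records.append(
                VariantRecord(
                    chrom=cfg.contig, pos=pos, ref=Allele(ref), alts=(Allele(alt),),
                    genotype=gt, qual=qual, depth=depth, labels=labels,
                )
            )
            rows.append((cfg.contig, pos, ref, alt, "FP", "NONE", qual))

    label_table = pd.DataFrame(rows, columns=LABEL_COLUMNS)
    return records, label_table
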