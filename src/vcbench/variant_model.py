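"""Core data model and VCF/BED I/O.

The package scores diploid variant calls against a gold-standard callset, so
the model is deliberately small: a variant is a locus, a REF allele, one or
more ALT alleles, an unordered diploid genotype, a Phred-scaled quality and an
optional read depth.  Phase is discarded on ingestion because every downstream
classification (genotype concordance, IR/AR error typing) is phase-free.

Coordinates follow the native conventions of each format: VCF positions are
1-based, BED intervals are 0-based half-open.  Conversion happens exactly once,
in :mod:`vcbench.regions`.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam

logger = logging.getLogger("vcbench")

_VALID_BASES = frozenset("ACGT")

#: QUAL values are stored at milli-Phred precision so that a written value
#: survives a float32 round-trip through pysam bit-exactly.
QUAL_DECIMALS = 3


class VcfParseError(ValueError):
    """A VCF record could not be parsed or violates the model invariants."""


class BedParseError(ValueError):
    """A BED line could not be parsed or has start >= end."""


class UnsupportedInputError(ValueError):
    """Structurally valid input outside the supported subset (e.g. multi-sample VCF)."""


class Allele(str):
    """A non-empty uppercase DNA string over {A, C, G, T}.

    Case is normalized on construction; ambiguity codes and symbolic alleles
    are rejected.
    """

    __slots__ = ()

    def __new__(cls, sequence: str) -> "Allele":
        seq = str(sequence).upper()
        if not seq:
            raise VcfParseError("empty allele sequence")
        if not set(seq) <= _VALID_BASES:
            raise VcfParseError(f"allele {sequence!r} contains non-ACGT characters")
        return super().__new__(cls, seq)

    @property
    def sequence(self) -> str:
        return str(self)


@dataclass(frozen=True, order=True)
class Genotype:
    """Unordered diploid genotype as a sorted pair of allele indices.

    Index 0 is the REF allele, 1..k the ALT alleles of the owning record.
    Phase is discarded: ``1|0`` and ``0/1`` are the same genotype.
    """

    indices: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.indices) != 2:
            raise ValueError("genotype must be diploid (exactly two allele indices)")
        a, b = self.indices
        if a < 0 or b < 0:
            raise ValueError("negative allele index")
        if a > b:
            object.__setattr__(self, "indices", (b, a))

    @classmethod
    def of(cls, a: int, b: int) -> "Genotype":
        return cls((a, b))

    @property
    def is_het(self) -> bool:
        return self.indices[0] != self.indices[1]

    @property
    def is_hom(self) -> bool:
        return self.indices[0] == self.indices[1]

    @property
    def is_hom_ref(self) -> bool:
        return self.indices == (0, 0)

    @property
    def is_hom_alt(self) -> bool:
        a, b = self.indices
        return a == b and a > 0

    def allele_sequences(self, ref: str, alts: Sequence[str]) -> tuple[str, str]:
        """Genotype expressed as the pair of allele sequences it carries."""
        alleles = (ref, *alts)
        pair = tuple(sorted(alleles[i] for i in self.indices))
        return pair  # type: ignore[return-value]

    def __str__(self) -> str:
        return f"{self.indices[0]}/{self.indices[1]}"


HET = Genotype.of(0, 1)
HOM_ALT = Genotype.of(1, 1)


class VariantClass(enum.Enum):
    """SNP / insertion / deletion, assigned per allelic primitive."""

    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


def classify_alleles(ref: str, alt: str) -> VariantClass:
    if len(ref) == len(alt) == 1:
        return VariantClass.SNP
    if len(alt) > len(ref):
        return VariantClass.INS
    if len(alt) < len(ref):
        return VariantClass.DEL
    raise ValueError(f"equal-length multi-base pair {ref}>{alt} is not a primitive")


@dataclass(frozen=True)
class SourceLabels:
    """Provenance of a callset: which caller/aligner/dataset produced it."""

    caller_id: Optional[str] = None
    aligner_id: Optional[str] = None
    dataset_id: Optional[str] = None


@dataclass(frozen=True)
class VariantRecord:
    """One called or truth variant (possibly multi-allelic, pre-normalization)."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: Allele
    alts: tuple[Allele, ...]
    genotype: Genotype
    qual: Optional[float] = None
    depth: Optional[int] = None
    filter_status: str = "PASS"
    labels: SourceLabels = field(default_factory=SourceLabels)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfParseError(f"position {self.pos} < 1")
        if not self.alts:
            raise VcfParseError("record has no ALT allele")
        alleles = (str(self.ref), *map(str, self.alts))
        if len(set(alleles)) != len(alleles):
            raise VcfParseError(f"REF and ALT alleles not pairwise distinct: {alleles}")
        if max(self.genotype.indices) > len(self.alts):
            raise VcfParseError(
                f"genotype {self.genotype} references allele beyond ALT list of length {len(self.alts)}"
            )
        if self.qual is not None:
            if self.qual < 0:
                raise VcfParseError(f"negative QUAL {self.qual}")
            object.__setattr__(self, "qual", round(float(self.qual), QUAL_DECIMALS))
        if self.depth is not None and self.depth < 0:
            raise VcfParseError(f"negative DP {self.depth}")

    @property
    def passes_filter(self) -> bool:
        return self.filter_status in ("PASS", ".")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, joined alts) — identifies the source record."""
        return (self.chrom, self.pos, str(self.ref), ",".join(map(str, self.alts)))

    def with_labels(self, labels: SourceLabels) -> "VariantRecord":
        return replace(self, labels=labels)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on one contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise BedParseError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadStats:
    """Per-file ingestion bookkeeping so denominators stay auditable."""

    n_records: int = 0
    n_half_calls_skipped: int = 0
    n_filtered_excluded: int = 0
    n_hom_ref_skipped: int = 0


# ---------------------------------------------------------------------------
# VCF reading (pysam) and writing
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    labels: SourceLabels | None = None,
    *,
    include_filtered: bool = False,
    stats: ReadStats | None = None,
) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a single-sample VCF in file order.

    Half-calls (``./1``) and non-diploid genotypes are skipped with a warning
    and counted in *stats*; FILTER-failing records are excluded unless
    *include_filtered* is set. Missing QUAL stays missing (never coerced to 0).
    """
    labels = labels or SourceLabels()
    stats = stats if stats is not None else ReadStats()
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot open as VCF: {exc}") from exc
    with vf:
        if len(vf.header.samples) != 1:
            raise UnsupportedInputError(
                f"{path}: expected exactly one sample column, found {len(vf.header.samples)}"
            )
        for i, rec in enumerate(vf, start=1):
            try:
                parsed = _record_from_pysam(rec, labels)
            except VcfParseError as exc:
                raise VcfParseError(f"{path}: record {i} ({rec.chrom}:{rec.pos}): {exc}") from exc
            if parsed is None:
                stats.n_half_calls_skipped += 1
                logger.warning("%s: record %d skipped (half-call or non-diploid GT)", path, i)
                continue
            if parsed.genotype.is_hom_ref:
                stats.n_hom_ref_skipped += 1
                continue
            if not include_filtered and not parsed.passes_filter:
                stats.n_filtered_excluded += 1
                continue
            stats.n_records += 1
            yield parsed


def _record_from_pysam(rec: "pysam.VariantRecord", labels: SourceLabels) -> Optional[VariantRecord]:
    if rec.alts is None:
        raise VcfParseError("missing ALT")
    sample = rec.samples[0]
    gt = sample.get("GT")
    if gt is None or len(gt) != 2 or any(a is None for a in gt):
        return None
    depth = sample.get("DP")
    filters = list(rec.filter)
    filter_status = ";".join(filters) if filters else "."
    qual = None if rec.qual is None else round(float(rec.qual), QUAL_DECIMALS)
    return VariantRecord(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=Allele(rec.ref),
        alts=tuple(Allele(a) for a in rec.alts),
        genotype=Genotype.of(*gt),
        qual=qual,
        depth=None if depth is None else int(depth),
        filter_status=filter_status,
        labels=labels,
    )


_VCF_HEADER_LINES = (
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
)


def _format_qual(qual: Optional[float]) -> str:
    if qual is None:
        return "."
    q = round(float(qual), QUAL_DECIMALS)
    if q == int(q):
        return str(int(q))
    return f"{q:.{QUAL_DECIMALS}f}".rstrip("0")


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    *,
    sample_name: str = "SAMPLE",
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write records as a single-sample VCF, sorted by (chrom, pos).

    Round-trips losslessly through :func:`read_vcf` for all modeled fields.
    """
    recs = sorted(records, key=lambda r: (r.chrom, r.pos, str(r.ref), ",".join(r.alts)))
    contigs: dict[str, int | None] = {}
    for r in recs:
        span_end = r.pos + len(r.ref) - 1
        if contig_lengths and r.chrom in contig_lengths:
            contigs[r.chrom] = contig_lengths[r.chrom]
        else:
            contigs[r.chrom] = max(contigs.get(r.chrom) or 0, span_end)
    with open(path, "w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        for chrom in sorted(contigs):
            fh.write(f"##contig=<ID={chrom},length={contigs[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name + "\n")
        for r in recs:
            has_dp = r.depth is not None
            fmt = "GT:DP" if has_dp else "GT"
            sample = str(r.genotype) + (f":{r.depth}" if has_dp else "")
            fh.write(
                "\t".join(
                    (
                        r.chrom,
                        str(r.pos),
                        ".",
                        str(r.ref),
                        ",".join(map(str, r.alts)),
                        _format_qual(r.qual),
                        r.filter_status,
                        ".",
                        fmt,
                        sample,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED reading
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Parse a 3+ column BED file into raw (unmerged) intervals.

    Merging and sorting happen in :class:`vcbench.regions.RegionSet`; use
    :func:`vcbench.regions.read_bed` for the merged set.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end))
            except BedParseError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return intervals
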