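"""Decomposition of complex REF/ALT pairs into allelic primitives.

Different callers represent the same haplotype change in different ways
(an MNP vs a run of SNPs, a complex substitution vs SNP+indel).  Before any
comparison, every record is regularized into *allelic primitives*: single-base
substitutions (SNPs) and simple anchored insertions/deletions, obtained from a
global pairwise alignment of REF against each called ALT.

Alignment scoring is fixed (match +1, mismatch -1, gap open -2, gap extend -1)
and the traceback is deterministic, preferring a substitution column over a
gap and placing gaps leftmost among ties, so decomposition is reproducible.
Indels are left-aligned within the record's own REF string; no external
reference genome is consulted, which keeps the normalization self-contained at
the cost of not shifting indels across record boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .variant_model import (
    HET,
    HOM_ALT,
    Allele,
    Genotype,
    SourceLabels,
    VariantClass,
    VariantRecord,
    classify_alleles,
)

logger = logging.getLogger("vcbench")

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_OPEN = -2
GAP_EXTEND = -1

_NEG = float("-inf")


@dataclass(frozen=True)
class PrimitiveVariant:
    """A minimal biallelic variant: one SNP or one anchored simple indel."""

    chrom: str
    pos: int  # 1-based
    ref: Allele
    alt: Allele
    vclass: VariantClass
    genotype: Genotype
    qual: Optional[float] = None
    depth: Optional[int] = None
    parent_key: str = ""
    labels: SourceLabels = field(default_factory=SourceLabels)

    def __post_init__(self) -> None:
        if str(self.ref) == str(self.alt):
            raise ValueError(f"primitive with ref == alt at {self.chrom}:{self.pos}")
        if max(self.genotype.indices) > 1:
            raise ValueError("primitive genotype must be expressed over {0, 1}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, str(self.ref), str(self.alt))

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, str(self.ref))

    @property
    def is_snp(self) -> bool:
        return self.vclass is VariantClass.SNP

    def genotype_sequences(self) -> tuple[str, str]:
        return self.genotype.allele_sequences(str(self.ref), (str(self.alt),))

    def as_record(self) -> VariantRecord:
        return VariantRecord(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alts=(self.alt,),
            genotype=self.genotype,
            qual=self.qual,
            depth=self.depth,
            labels=self.labels,
        )


# ---------------------------------------------------------------------------
# Global alignment (Gotoh affine-gap) with deterministic traceback
# ---------------------------------------------------------------------------

def align_global(ref: str, alt: str) -> tuple[str, str]:
    """Globally align two sequences, returning the gapped strings.

    Affine gap penalties; ties resolved by preferring a substitution column
    over opening a gap, deletions over insertions, which places gaps leftmost
    among co-optimal layouts.
    """
    n, m = len(ref), len(alt)
    # three-state Gotoh: M = column consumes both, D = gap in alt (deletion),
    # I = gap in ref (insertion)
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    D = [[_NEG] * (m + 1) for _ in range(n + 1)]
    I = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        D[i][0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        I[0][j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, n + 1):
        Mi, Di, Ii = M[i], D[i], I[i]
        Mp, Dp, Ip = M[i - 1], D[i - 1], I[i - 1]
        ri = ref[i - 1]
        for j in range(1, m + 1):
            s = MATCH_SCORE if ri == alt[j - 1] else MISMATCH_SCORE
            Mi[j] = max(Mp[j - 1], Dp[j - 1], Ip[j - 1]) + s
            Di[j] = max(Mp[j] + GAP_OPEN, Dp[j] + GAP_EXTEND, Ip[j] + GAP_OPEN)
            Ii[j] = max(Mi[j - 1] + GAP_OPEN, Ii[j - 1] + GAP_EXTEND, Di[j - 1] + GAP_OPEN)

    out_ref: list[str] = []
    out_alt: list[str] = []
    i, j = n, m
    # preference order M > D > I applies at every tie
    state = max(("M", "D", "I"), key=lambda st: {"M": M, "D": D, "I": I}[st][i][j])
    best = {"M": M, "D": D, "I": I}[state][i][j]
    for st in ("M", "D", "I"):
        if {"M": M, "D": D, "I": I}[st][i][j] == best:
            state = st
            break
    while i > 0 or j > 0:
        if state == "M":
            out_ref.append(ref[i - 1])
            out_alt.append(alt[j - 1])
            s = MATCH_SCORE if ref[i - 1] == alt[j - 1] else MISMATCH_SCORE
            target = M[i][j] - s
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("D", D), ("I", I)):
                if mat[i][j] == target:
                    state = st
                    break
        elif state == "D":
            out_ref.append(ref[i - 1])
            out_alt.append("-")
            here = D[i][j]
            i -= 1
            if M[i][j] + GAP_OPEN == here:
                state = "M"
            elif D[i][j] + GAP_EXTEND == here:
                state = "D"
            else:
                state = "I"
        else:  # I
            out_ref.append("-")
            out_alt.append(alt[j - 1])
            here = I[i][j]
            j -= 1
            if M[i][j] + GAP_OPEN == here:
                state = "M"
            elif I[i][j] + GAP_EXTEND == here:
                state = "I"
            else:
                state = "D"
        if i == 0 and j > 0:
            state = "I"
        elif j == 0 and i > 0:
            state = "D"
    return "".join(reversed(out_ref)), "".join(reversed(out_alt))


def alignment_score(gapped_ref: str, gapped_alt: str) -> float:
    """Score of an alignment under the module's fixed scheme (for cross-checks)."""
    score = 0.0
    prev_gap = None
    for r, a in zip(gapped_ref, gapped_alt):
        if r == "-" or a == "-":
            gap_side = "r" if r == "-" else "a"
            score += GAP_EXTEND if prev_gap == gap_side else GAP_OPEN
            prev_gap = gap_side
        else:
            score += MATCH_SCORE if r == a else MISMATCH_SCORE
            prev_gap = None
    return score


# ---------------------------------------------------------------------------
# Event extraction and primitive construction
# ---------------------------------------------------------------------------

@dataclass
class _Event:
    kind: str  # "SNP" | "DEL" | "INS"
    offset: int  # 0-based offset into the record's REF string
    payload: str  # SNP: alt base; DEL: deleted bases; INS: inserted bases


def _alignment_events(ref: str, alt: str, base_offset: int) -> list[_Event]:
    gr, ga = align_global(ref, alt)
    events: list[_Event] = []
    r_off = base_offset
    k = 0
    ncol = len(gr)
    while k < ncol:
        r, a = gr[k], ga[k]
        if r != "-" and a != "-":
            if r != a:
                events.append(_Event("SNP", r_off, a))
            r_off += 1
            k += 1
        elif a == "-":  # deletion run
            start = r_off
            run: list[str] = []
            while k < ncol and ga[k] == "-":
                run.append(gr[k])
                r_off += 1
                k += 1
            events.append(_Event("DEL", start, "".join(run)))
        else:  # insertion run
            run = []
            while k < ncol and gr[k] == "-":
                run.append(ga[k])
                k += 1
            events.append(_Event("INS", r_off, "".join(run)))
    return events


def _events_for_pair(ref: str, alt: str) -> list[_Event]:
    """Events describing ref -> alt, after common prefix/suffix stripping."""
    p = 0
    while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
        p += 1
    s = 0
    while (
        s < len(ref) - p
        and s < len(alt) - p
        and ref[len(ref) - 1 - s] == alt[len(alt) - 1 - s]
    ):
        s += 1
    core_ref = ref[p : len(ref) - s]
    core_alt = alt[p : len(alt) - s]
    if not core_ref and not core_alt:
        return []
    if not core_ref:
        return [_Event("INS", p, core_alt)]
    if not core_alt:
        return [_Event("DEL", p, core_ref)]
    return _alignment_events(core_ref, core_alt, p)


def _primitive_alleles(ref: str, events: list[_Event]) -> list[tuple[int, str, str]]:
    """Render events as (ref_offset, p_ref, p_alt) primitives.

    Indels are left-aligned within *ref* and anchored on the preceding base;
    an indel at the very start of the record (no left anchor) absorbs an
    adjacent substitution or falls back to a right anchor.
    """
    snp_at = {e.offset: e for e in events if e.kind == "SNP"}
    consumed_snps: set[int] = set()
    prims: list[tuple[int, str, str]] = []
    for e in events:
        if e.kind == "SNP":
            if e.offset not in consumed_snps:
                prims.append((e.offset, ref[e.offset], e.payload))
        elif e.kind == "DEL":
            i, seq = e.offset, e.payload
            L = len(seq)
            while i > 1 and ref[i - 1] == ref[i + L - 1]:
                i -= 1
            seq = ref[i : i + L]
            if i > 0:
                prims.append((i - 1, ref[i - 1 : i + L], ref[i - 1]))
            else:
                # deletion at record start: anchor on the following base,
                # folding in a substitution there if the alignment made one
                anchor_off = L
                if anchor_off >= len(ref):
                    raise ValueError("deletion consumes the entire REF with no anchor")
                snp = snp_at.get(anchor_off)
                if snp is not None:
                    consumed_snps.add(anchor_off)
                    anchor = snp.payload
                else:
                    anchor = ref[anchor_off]
                prims.append((0, ref[0 : L + 1], anchor))
        else:  # INS
            i, seq = e.offset, e.payload
            while i > 1 and seq[-1] == ref[i - 1]:
                seq = ref[i - 1] + seq[:-1]
                i -= 1
            if i > 0:
                prims.append((i - 1, ref[i - 1], ref[i - 1] + seq))
            else:
                snp = snp_at.get(0)
                if snp is not None:
                    consumed_snps.add(0)
                    prims.append((0, ref[0], seq + snp.payload))
                else:
                    prims.append((0, ref[0], seq + ref[0]))
    prims.sort(key=lambda t: (t[0], len(t[1])))
    return prims


def apply_primitives(
    ref: str, record_pos: int, primitives: Sequence["PrimitiveVariant | tuple[int, str, str]"]
) -> str:
    """Substitute primitives into *ref*, reconstructing the ALT haplotype.

    Primitives may overlap on an anchor base that another primitive rewrote
    (e.g. a SNP at a deletion's anchor); a cursor-based sweep emits each base
    exactly once, applying shorter spans first at equal positions.
    """
    triples: list[tuple[int, str, str]] = []
    for p in primitives:
        if isinstance(p, PrimitiveVariant):
            triples.append((p.pos - record_pos, str(p.ref), str(p.alt)))
        else:
            triples.append(p)
    triples.sort(key=lambda t: (t[0], len(t[1])))
    out: list[str] = []
    cursor = 0
    for off, p_ref, p_alt in triples:
        if off > cursor:
            out.append(ref[cursor:off])
            cursor = off
        if off < cursor:
            overlap = cursor - off
            out.append(p_alt[overlap:])
        else:
            out.append(p_alt)
        cursor = max(cursor, off + len(p_ref))
    out.append(ref[cursor:])
    return "".join(out)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def split_multiallelic(record: VariantRecord) -> list[VariantRecord]:
    """One biallelic record per ALT carried by the genotype.

    Genotype indices are remapped to {0, 1}; an ALT present in no genotype
    allele is dropped.
    """
    out: list[VariantRecord] = []
    for j in range(1, len(record.alts) + 1):
        copies = sum(1 for idx in record.genotype.indices if idx == j)
        if copies == 0:
            continue
        out.append(
            replace(
                record,
                alts=(record.alts[j - 1],),
                genotype=HOM_ALT if copies == 2 else HET,
            )
        )
    return out


def decompose(record: VariantRecord) -> list[PrimitiveVariant]:
    """Decompose a record into allelic primitives with re-expressed genotypes.

    Each called ALT is aligned to REF independently; a primitive carried by
    both genotype alleles becomes homozygous-alt, by one allele heterozygous.
    """
    parent = "{}:{}:{}>{}".format(record.chrom, record.pos, record.ref, ",".join(record.alts))
    carriers: dict[tuple[int, str, str], int] = {}
    order: list[tuple[int, str, str]] = []
    for sub in split_multiallelic(record):
        ref, alt = str(sub.ref), str(sub.alts[0])
        if ref == alt:  # defensive: the record model already forbids this
            logger.warning("%s: ref == alt, nothing to decompose", parent)
            continue
        n_copies = 2 if sub.genotype.is_hom_alt else 1
        for prim in _primitive_alleles(ref, _events_for_pair(ref, alt)):
            if prim not in carriers:
                order.append(prim)
                carriers[prim] = 0
            carriers[prim] = min(2, carriers[prim] + n_copies)
    out: list[PrimitiveVariant] = []
    for off, p_ref, p_alt in sorted(order, key=lambda t: (t[0], len(t[1]))):
        out.append(
            PrimitiveVariant(
                chrom=record.chrom,
                pos=record.pos + off,
                ref=Allele(p_ref),
                alt=Allele(p_alt),
                vclass=classify_alleles(p_ref, p_alt),
                genotype=HOM_ALT if carriers[(off, p_ref, p_alt)] == 2 else HET,
                qual=record.qual,
                depth=record.depth,
                parent_key=parent,
                labels=record.labels,
            )
        )
    return out


def normalize_records(records: Iterable[VariantRecord]) -> list[PrimitiveVariant]:
    """Decompose a record stream into a flat list of primitives."""
    out: list[PrimitiveVariant] = []
    for rec in records:
        out.extend(decompose(rec))
    return out
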