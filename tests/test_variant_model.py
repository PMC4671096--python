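"""VCF/BED ingestion, the diploid genotype model, and round-trip fidelity."""

import pytest
from hypothesis import given, settings, strategies as st

from vcbench.regions import read_bed
from vcbench.variant_model import (
    HET,
    Allele,
    BedParseError,
    Genotype,
    ReadStats,
    UnsupportedInputError,
    VcfParseError,
    read_vcf,
    write_vcf,
)

from conftest import make_record

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    "##contig=<ID=chr1,length=100000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1\n"
)


def write_text_vcf(path, body):
    path.write_text(VCF_HEADER + body)
    return str(path)


class TestAlleleAndGenotype:
    def test_allele_uppercased_and_validated(self):
        assert Allele("acgt") == "ACGT"
        with pytest.raises(VcfParseError):
            Allele("AN")
        with pytest.raises(VcfParseError):
            Allele("")

    def test_genotype_is_unordered(self):
        assert Genotype.of(1, 0) == Genotype.of(0, 1)
        assert Genotype.of(1, 0).indices == (0, 1)
        assert Genotype.of(0, 1).is_het and not Genotype.of(1, 1).is_het
        assert Genotype.of(1, 1).is_hom_alt and not Genotype.of(0, 0).is_hom_alt

    def test_genotype_allele_sequences(self):
        assert Genotype.of(1, 0).allele_sequences("A", ("G",)) == ("A", "G")
        assert Genotype.of(2, 2).allele_sequences("A", ("G", "T")) == ("T", "T")


class TestReadVcf:
    def test_basic_field_mapping(self, tmp_path):
        path = write_text_vcf(tmp_path / "a.vcf", "chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP\t0/1:30\n")
        (rec,) = list(read_vcf(path))
        assert (rec.chrom, rec.pos, str(rec.ref), [str(a) for a in rec.alts]) == ("chr1", 100, "A", ["G"])
        assert rec.genotype == HET and rec.qual == 50 and rec.depth == 30

    def test_phase_is_dropped(self, tmp_path):
        path = write_text_vcf(tmp_path / "a.vcf", "chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t1|0\n")
        (rec,) = list(read_vcf(path))
        assert rec.genotype.indices == (0, 1)

    def test_missing_qual_stays_missing(self, tmp_path):
        path = write_text_vcf(tmp_path / "a.vcf", "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n")
        (rec,) = list(read_vcf(path))
        assert rec.qual is None

    def test_multi_sample_rejected(self, tmp_path):
        text = VCF_HEADER.replace("\tNA1\n", "\tNA1\tNA2\n") + "chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/1\t0/1\n"
        path = tmp_path / "multi.vcf"
        path.write_text(text)
        with pytest.raises(UnsupportedInputError):
            list(read_vcf(str(path)))

    def test_half_call_skipped_and_counted(self, tmp_path):
        body = "chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t./1\nchr1\t200\t.\tC\tT\t50\tPASS\t.\tGT\t0/1\n"
        path = write_text_vcf(tmp_path / "a.vcf", body)
        stats = ReadStats()
        recs = list(read_vcf(path, stats=stats))
        assert len(recs) == 1 and recs[0].pos == 200
        assert stats.n_half_calls_skipped == 1

    def test_filter_failing_records_excluded_by_default(self, tmp_path):
        body = "chr1\t100\t.\tA\tG\t50\tq10\t.\tGT\t0/1\nchr1\t200\t.\tC\tT\t50\tPASS\t.\tGT\t0/1\n"
        text = VCF_HEADER.replace("##contig", '##FILTER=<ID=q10,Description="low">\n##contig')
        path = tmp_path / "f.vcf"
        path.write_text(text + body)
        stats = ReadStats()
        recs = list(read_vcf(str(path), stats=stats))
        assert [r.pos for r in recs] == [200]
        assert stats.n_filtered_excluded == 1
        both = list(read_vcf(str(path), include_filtered=True))
        assert [r.pos for r in both] == [100, 200]


qual_values = st.one_of(st.none(), st.integers(0, 20000).map(lambda q: q / 100))
allele_st = st.text(alphabet="ACGT", min_size=1, max_size=6)


@st.composite
def records_st(draw):
    ref = draw(allele_st)
    alts = draw(st.lists(allele_st.filter(lambda a: a != ref), min_size=1, max_size=2, unique=True))
    gt = draw(st.tuples(st.integers(0, len(alts)), st.integers(0, len(alts))))
    if gt == (0, 0):
        gt = (0, 1)
    return make_record(
        chrom=draw(st.sampled_from(["chr1", "chr2"])),
        pos=draw(st.integers(1, 10_000)),
        ref=ref,
        alts=tuple(alts),
        gt=Genotype(gt),
        qual=draw(qual_values),
        depth=draw(st.one_of(st.none(), st.integers(0, 500))),
    )


class TestRoundTrip:
    @settings(max_examples=50, deadline=None)
    @given(st.lists(records_st(), min_size=1, max_size=12))
    def test_vcf_round_trip_is_lossless(self, tmp_path_factory, recs):
        path = tmp_path_factory.mktemp("rt") / "rt.vcf"
        write_vcf(recs, path)
        back = list(read_vcf(path))
        key = lambda r: (r.chrom, r.pos, str(r.ref), tuple(map(str, r.alts)))
        for orig, got in zip(sorted(recs, key=key), sorted(back, key=key)):
            assert key(orig) == key(got)
            assert orig.genotype == got.genotype
            assert orig.qual == got.qual
            assert orig.depth == got.depth

    def test_records_written_in_coordinate_order(self, tmp_path):
        recs = [make_record(pos=500), make_record(pos=10, ref="C", alts=("T",))]
        path = tmp_path / "sorted.vcf"
        write_vcf(recs, path)
        assert [r.pos for r in read_vcf(path)] == [10, 500]

    def test_missing_qual_written_as_dot(self, tmp_path):
        path = tmp_path / "q.vcf"
        write_vcf([make_record(qual=None)], path)
        data_line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        assert data_line.split("\t")[5] == "."


class TestReadBed:
    def test_overlap_and_adjacency_merge(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\nchr1\t15\t30\nchr1\t30\t35\n")
        rs = read_bed(p)
        assert [(iv.start, iv.end) for iv in rs.intervals] == [(10, 35)]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0 and read_bed(p).covered_length() == 0

    def test_invalid_interval_reports_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t20\t10\n")
        with pytest.raises(BedParseError, match="line 1"):
            read_bed(p)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 200), st.integers(1, 40)), min_size=1, max_size=20), st.randoms())
    def test_merged_output_invariant_under_shuffling(self, tmp_path_factory, raw, rnd):
        intervals = [("chr1", s, s + ln) for s, ln in raw]
        d = tmp_path_factory.mktemp("bed")
        a, b = d / "a.bed", d / "b.bed"
        a.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in intervals))
        shuffled = list(intervals)
        rnd.shuffle(shuffled)
        b.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in shuffled))
        ra, rb = read_bed(a), read_bed(b)
        assert ra.intervals == rb.intervals
        # disjoint and sorted
        prev_end = -1
        for iv in ra.intervals:
            assert iv.start > prev_end  # merged intervals cannot touch
            prev_end = iv.end
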