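import pytest

from vcbench.normalize import PrimitiveVariant
from vcbench.regions import RegionSet
from vcbench.variant_model import (
    HET,
    HOM_ALT,
    Allele,
    GenomicInterval,
    Genotype,
    VariantClass,
    VariantRecord,
    classify_alleles,
)


def make_record(chrom="chr1", pos=100, ref="A", alts=("G",), gt=HET, qual=50.0,
                depth=None, **kw):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=Allele(ref), alts=tuple(Allele(a) for a in alts),
        genotype=gt, qual=qual, depth=depth, **kw,
    )


def make_prim(chrom="chr1", pos=100, ref="A", alt="G", gt=HET, qual=50.0, depth=None):
    return PrimitiveVariant(
        chrom=chrom, pos=pos, ref=Allele(ref), alt=Allele(alt),
        vclass=classify_alleles(ref, alt), genotype=gt, qual=qual, depth=depth,
    )


def regions(*triples, label=""):
    return RegionSet([GenomicInterval(c, s, e) for c, s, e in triples], label=label)


@pytest.fixture
def het():
    return HET


@pytest.fixture
def hom_alt():
    return HOM_ALT
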