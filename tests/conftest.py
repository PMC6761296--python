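import numpy as np
import pysam
import pytest

from asebias.catalog import GeneModel, VariantCatalog, VariantSite


@pytest.fixture
def toy_header():
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "chr1", "LN": 100_000}, {"SN": "chr2", "LN": 100_000}],
    })


@pytest.fixture
def make_read(toy_header):
    """Factory for aligned segments on the toy header."""

    def _make(name, chrom, pos, seq, cigar=None, mapq=60, flag=0, quals=None):
        seg = pysam.AlignedSegment(toy_header)
        seg.query_name = name
        seg.query_sequence = seq
        seg.reference_name = chrom
        seg.reference_start = pos
        seg.mapping_quality = mapq
        seg.cigarstring = cigar or f"{len(seq)}M"
        seg.flag = flag
        if quals is None:
            quals = "I" * len(seq)
        seg.query_qualities = pysam.qualitystring_to_array(quals)
        return seg

    return _make


@pytest.fixture
def two_exon_gene():
    return GeneModel(gene_id="gA", chrom="chr1", span=(1000, 2000),
                     exons=[(1000, 1200), (1800, 2000)])


@pytest.fixture
def small_catalog():
    sites = [
        VariantSite("chr1", 1050, "A", "G"),
        VariantSite("chr1", 1100, "C", "T"),
        VariantSite("chr1", 1900, "G", "A"),
        VariantSite("chr2", 500, "T", "C"),
    ]
    return VariantCatalog(sites)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
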