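import pytest

from txweld.io import CdsFeature, PafAlignment, SequenceRecord
from txweld.synthetic import generate_truth


def make_paf(qname="t1", qlen=100, qstart=0, qend=100, strand="+", tname="c1",
             tlen=1000, tstart=0, tend=100, matches=None, block_len=None,
             mapq=60, cg=None, tp=None):
    """Compact PAF record builder for fixtures."""
    block = block_len if block_len is not None else max(qend - qstart,
                                                        tend - tstart)
    tags = {}
    if tp is not None:
        tags["tp"] = ("A", tp)
    if cg is not None:
        tags["cg"] = ("Z", cg)
    return PafAlignment(qname=qname, qlen=qlen, qstart=qstart, qend=qend,
                        strand=strand, tname=tname, tlen=tlen, tstart=tstart,
                        tend=tend,
                        matches=matches if matches is not None else block,
                        block_len=block, mapq=mapq, tags=tags)


@pytest.fixture(scope="session")
def community():
    """Error-free synthetic community with all four artifact classes.

    Coverage of every expressed CDS is at least 60%, so the default 50%
    selection threshold admits every expressed gene.
    """
    return generate_truth(n_genomes=5, genome_len=50_000, n_cds=20,
                          partial_cov=(0.6, 0.95), seed=11)


@pytest.fixture
def simple_cds():
    return CdsFeature(contig_id="c1", start=100, end=200, strand="+",
                      feature_id="g1")


@pytest.fixture
def record():
    return SequenceRecord(id="s1", description="demo", seq="ACGT" * 30)
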