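"""Alignment filtering, CDS projection and union coverage."""

import numpy as np
import pytest

from conftest import make_paf
from txweld.coverage import (compute_cds_coverage, filter_alignments,
                             parse_cigar, partition_transcripts,
                             per_base_query_offsets, project_to_cds,
                             select_covered_cds)
from txweld.errors import IntegrityError
from txweld.io import CdsFeature


def cigar_walk_pairs(cigar, tstart, qspan_start=0):
    """Oracle: explicit CIGAR expansion to (target_pos, query_off) pairs.

    Query offsets are on the aligned strand; deletions yield None.
    """
    pairs = []
    t, q = tstart, qspan_start
    for length, op in parse_cigar(cigar):
        if op in "M=X":
            for _ in range(length):
                pairs.append((t, q))
                t += 1
                q += 1
        elif op in "DN":
            for _ in range(length):
                pairs.append((t, None))
                t += 1
        elif op in "IS":
            q += length
    return dict(pairs)


class TestFilter:
    def test_empty(self):
        assert filter_alignments([]) == []

    def test_block_threshold(self):
        a = make_paf(qend=50, tend=50)
        assert filter_alignments([a], min_block=100) == []
        assert filter_alignments([a], min_block=50) == [a]

    def test_secondary_dropped(self):
        recs = [make_paf(qname=f"t{i}", tp="P" if i % 2 else "S")
                for i in range(6)]
        kept = filter_alignments(recs)
        assert len(kept) == 3 and all(r.tp == "P" for r in kept)
        assert len(filter_alignments(recs, primary_only=False)) == 6

    def test_identity_threshold(self):
        a = make_paf(matches=80)  # identity 0.8
        assert filter_alignments([a], min_identity=0.9) == []
        assert filter_alignments([a], min_identity=0.8) == [a]


class TestProjection:
    def test_disjoint(self):
        aln = make_paf(tstart=50, tend=150)
        cds = CdsFeature("c1", 0, 40, "+", "g")
        assert project_to_cds(aln, cds) is None

    def test_gapless_intersection(self):
        aln = make_paf(tstart=50, tend=150)
        cds = CdsFeature("c1", 100, 200, "+", "g")
        seg = project_to_cds(aln, cds)
        assert (seg.t_lo, seg.t_hi) == (100, 150)
        # last 50 query bases of the block on + strand
        assert (seg.q_lo, seg.q_hi) == (50, 100)

    def test_minus_strand_query_interval(self):
        aln = make_paf(strand="-", tstart=50, tend=150)
        cds = CdsFeature("c1", 100, 200, "+", "g")
        seg = project_to_cds(aln, cds)
        # aligned-strand tail maps to the head of the original query
        assert (seg.q_lo, seg.q_hi) == (0, 50)

    def test_contig_mismatch(self):
        with pytest.raises(IntegrityError):
            project_to_cds(make_paf(tname="c1"),
                           CdsFeature("c2", 0, 50, "+", "g"))

    @pytest.mark.parametrize("lo,hi", [(100, 210), (120, 200), (100, 155),
                                       (150, 160), (155, 205)])
    def test_cigar_deletion_matches_per_base_walk(self, lo, hi):
        aln = make_paf(qend=100, tstart=100, tend=210, block_len=110,
                       matches=100, cg="50M10D50M")
        cds = CdsFeature("c1", lo, hi, "+", "g")
        oracle = cigar_walk_pairs("50M10D50M", 100)
        seg = project_to_cds(aln, cds, 0)
        mapped = [oracle[t] for t in range(lo, hi) if oracle[t] is not None]
        if not mapped:
            assert seg is None
            return
        assert (seg.q_lo, seg.q_hi) == (min(mapped), max(mapped) + 1)
        offs = per_base_query_offsets(aln, seg.t_lo, seg.t_hi)
        assert offs == [oracle[t] for t in range(seg.t_lo, seg.t_hi)]

    def test_monotone_in_cds_extent(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ts = int(rng.integers(0, 400))
            te = int(rng.integers(ts + 10, ts + 200))
            aln = make_paf(qlen=te - ts, qend=te - ts, tstart=ts, tend=te)
            lo = int(rng.integers(0, 500))
            hi = int(rng.integers(lo + 1, 700))
            small = project_to_cds(aln, CdsFeature("c1", lo, hi, "+", "g"))
            big = project_to_cds(
                aln, CdsFeature("c1", max(lo - 20, 0), hi + 20, "+", "g"))
            if small is not None:
                assert big is not None
                assert big.t_lo <= small.t_lo and big.t_hi >= small.t_hi


class TestCoverage:
    def test_no_overlap_zero(self):
        cds = CdsFeature("c1", 0, 100, "+", "g")
        aln = make_paf(tstart=500, tend=600)
        cov = compute_cds_coverage([aln], cds)
        assert cov.fraction == 0.0 and cov.covered_bases == 0

    def test_disjoint_union(self):
        cds = CdsFeature("c1", 0, 100, "+", "g")
        alns = [make_paf(qname="a", qlen=30, qend=30, tstart=0, tend=30),
                make_paf(qname="b", qlen=40, qend=40, tstart=50, tend=90)]
        cov = compute_cds_coverage(alns, cds)
        assert cov.covered_bases == 70 and cov.fraction == pytest.approx(0.7)

    def test_union_equals_boolean_oracle(self):
        rng = np.random.default_rng(17)
        cds = CdsFeature("c1", 0, 1000, "+", "g")
        for _ in range(50):
            alns = []
            mask = np.zeros(1000, dtype=bool)
            for i in range(int(rng.integers(1, 50))):
                ts = int(rng.integers(0, 990))
                te = int(rng.integers(ts + 1, min(ts + 300, 1000)))
                alns.append(make_paf(qname=f"t{i}", qlen=te - ts, qend=te - ts,
                                     tstart=ts, tend=te, tlen=1000))
                mask[ts:te] = True
            cov = compute_cds_coverage(alns, cds)
            assert cov.covered_bases == int(mask.sum())

    def test_fraction_order_invariant(self):
        cds = CdsFeature("c1", 0, 100, "+", "g")
        alns = [make_paf(qname="a", qlen=60, qend=60, tstart=10, tend=70),
                make_paf(qname="b", qlen=50, qend=50, tstart=40, tend=90)]
        assert compute_cds_coverage(alns, cds).fraction == \
            compute_cds_coverage(alns[::-1], cds).fraction


class TestSelection:
    def test_inclusive_boundary(self):
        cds = CdsFeature("c1", 0, 1000, "+", "g")

        def cov_at(f):
            n = int(f * 1000)
            return compute_cds_coverage(
                [make_paf(qlen=n, qend=n, tstart=0, tend=n, tlen=1000)], cds)

        covs = [cov_at(0.49), cov_at(0.50), cov_at(0.51)]
        kept = select_covered_cds(covs, threshold=0.5)
        assert [round(c.fraction, 2) for c in kept] == [0.50, 0.51]

    def test_threshold_zero_keeps_all(self):
        cds = CdsFeature("c1", 0, 100, "+", "g")
        covs = [compute_cds_coverage([], cds)]
        assert select_covered_cds(covs, threshold=0.0) == covs

    @pytest.mark.parametrize("bad", [-0.1, 1.01])
    def test_threshold_domain(self, bad):
        with pytest.raises(ValueError):
            select_covered_cds([], threshold=bad)

    def test_matches_naive_filter(self):
        rng = np.random.default_rng(3)
        cds = CdsFeature("c1", 0, 100, "+", "g")
        covs = []
        for _ in range(40):
            n = int(rng.integers(1, 101))
            covs.append(compute_cds_coverage(
                [make_paf(qlen=n, qend=n, tstart=0, tend=n, tlen=100)], cds))
        thr = float(rng.uniform(0, 1))
        naive = [c for c in covs if c.fraction >= thr]
        assert select_covered_cds(covs, threshold=thr) == naive


class TestPartition:
    def test_no_alignments(self):
        aligned, unaligned = partition_transcripts([], ["a", "b"])
        assert aligned == [] and unaligned == ["a", "b"]

    def test_all_aligned(self):
        alns = [make_paf(qname="a"), make_paf(qname="b")]
        aligned, unaligned = partition_transcripts(alns, ["a", "b"])
        assert unaligned == [] and set(aligned) == {"a", "b"}

    def test_partition_property(self):
        rng = np.random.default_rng(9)
        ids = [f"t{i}" for i in range(30)]
        alns = [make_paf(qname=f"t{int(rng.integers(0, 30))}")
                for _ in range(15)]
        aligned, unaligned = partition_transcripts(alns, ids)
        assert set(aligned) | set(unaligned) == set(ids)
        assert set(aligned) & set(unaligned) == set()
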