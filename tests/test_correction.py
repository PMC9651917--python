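"""Consensus welding: gap fill, variant preservation, splitting, trimming."""

import numpy as np
import pytest

from conftest import make_paf
from txweld.correction import (build_consensus, correct_assembly,
                               resolve_overlap_winner)
from txweld.coverage import project_to_cds
from txweld.errors import IntegrityError
from txweld.io import CdsFeature, SequenceRecord, revcomp
from txweld.synthetic import generate_truth


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def genome_and_cds():
    rng = np.random.default_rng(23)
    genome = _random_dna(rng, 400)
    cds = CdsFeature("c1", 150, 250, "+", "g1")
    return genome, cds


class TestBuildConsensus:
    def test_gap_fill_provenance(self, genome_and_cds):
        genome, cds = genome_and_cds
        # two exact fragments leaving CDS positions 40..59 uncovered
        frags = []
        for i, (a, b) in enumerate([(0, 40), (60, 100)]):
            q = genome[cds.start + a:cds.start + b]
            aln = make_paf(qname=f"f{i}", qlen=b - a, qend=b - a,
                           tstart=cds.start + a, tend=cds.start + b, tlen=400,
                           cg=f"{b - a}M")
            frags.append((q, aln))
        segs = [project_to_cds(a, cds, i) for i, (_, a) in enumerate(frags)]
        out = build_consensus(cds, genome, segs,
                              {f"f{i}": s for i, (s, _) in enumerate(frags)})
        assert out.provenance == "T" * 40 + "G" * 20 + "T" * 40
        assert out.seq == genome[150:250]
        assert len(out.seq) == len(cds)

    def test_variant_preserved(self, genome_and_cds):
        genome, cds = genome_and_cds
        q = list(genome[150:250])
        q[30] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[30]]
        aln = make_paf(qname="v", qlen=100, qend=100, tstart=150, tend=250,
                       tlen=400, matches=99, cg="100M")
        seg = project_to_cds(aln, cds, 0)
        out = build_consensus(cds, genome, [seg], {"v": "".join(q)})
        assert out.seq[30] == q[30] != genome[180]
        assert out.provenance == "T" * 100

    def test_overlapping_fragments_reconstruct_exactly(self, genome_and_cds):
        genome, cds = genome_and_cds
        seqs, segs = {}, []
        for i, (a, b) in enumerate([(0, 55), (45, 100)]):  # 10 bp overlap
            seqs[f"f{i}"] = genome[cds.start + a:cds.start + b]
            aln = make_paf(qname=f"f{i}", qlen=b - a, qend=b - a,
                           tstart=cds.start + a, tend=cds.start + b, tlen=400,
                           cg=f"{b - a}M")
            segs.append(project_to_cds(aln, cds, i))
        out = build_consensus(cds, genome, segs, seqs)
        # oracle: direct substring of the ground-truth genome
        assert out.seq == genome[150:250]

    def test_minus_strand_is_revcomp_of_plus_consensus(self, genome_and_cds):
        genome, _ = genome_and_cds
        plus = CdsFeature("c1", 150, 250, "+", "g1")
        minus = CdsFeature("c1", 150, 250, "-", "g1")
        out_p = build_consensus(plus, genome, [], {})
        out_m = build_consensus(minus, genome, [], {})
        assert out_m.seq == revcomp(out_p.seq)
        assert out_m.provenance == out_p.provenance[::-1]

    def test_insertion_dropped_length_locked(self, genome_and_cds):
        genome, cds = genome_and_cds
        # transcript carries a 5 bp insertion after 50 aligned bases
        q = genome[150:200] + "AAAAA" + genome[200:250]
        aln = make_paf(qname="ins", qlen=105, qend=105, tstart=150, tend=250,
                       tlen=400, matches=100, block_len=105, cg="50M5I50M")
        seg = project_to_cds(aln, cds, 0)
        out = build_consensus(cds, genome, [seg], {"ins": q})
        assert len(out.seq) == 100
        assert out.seq == genome[150:250]

    def test_bad_transcript_length_is_integrity_error(self, genome_and_cds):
        genome, cds = genome_and_cds
        aln = make_paf(qname="x", qlen=100, qend=100, tstart=150, tend=250,
                       tlen=400)
        seg = project_to_cds(aln, cds, 0)
        with pytest.raises(IntegrityError):
            build_consensus(cds, genome, [seg], {"x": "ACGT"})


class TestOverlapWinner:
    def test_single(self, genome_and_cds):
        genome, cds = genome_and_cds
        seg = project_to_cds(make_paf(tstart=150, tend=250, tlen=400), cds)
        assert resolve_overlap_winner([seg]) is seg

    def test_matches_win(self, genome_and_cds):
        _, cds = genome_and_cds
        s1 = project_to_cds(make_paf(qname="a", matches=90, tstart=150,
                                     tend=250, tlen=400), cds)
        s2 = project_to_cds(make_paf(qname="b", matches=80, tstart=150,
                                     tend=250, tlen=400), cds)
        assert resolve_overlap_winner([s2, s1]) is s1

    def test_full_tie_smallest_qname_deterministic(self, genome_and_cds):
        _, cds = genome_and_cds
        segs = [project_to_cds(make_paf(qname=n, tstart=150, tend=250,
                                        tlen=400), cds)
                for n in ["zz", "aa", "mm"]]
        rng = np.random.default_rng(0)
        for _ in range(10):
            order = list(rng.permutation(3))
            assert resolve_overlap_winner([segs[i] for i in order]).aln.qname \
                == "aa"


class TestCorrectAssembly:
    def test_intergenic_flanks_trimmed(self):
        """One contig = CDS plus 50 bp flanks: output is flank-free, all-T."""
        rng = np.random.default_rng(7)
        genome = _random_dna(rng, 500)
        cds = CdsFeature("c1", 200, 300, "+", "g1")
        contig = genome[150:350]
        aln = make_paf(qname="ext", qlen=200, qend=200, tstart=150, tend=350,
                       tlen=500, cg="200M")
        res = correct_assembly([SequenceRecord("ext", "", contig)],
                               [SequenceRecord("c1", "", genome)],
                               [cds], [aln])
        (out,) = res.transcripts
        assert out.seq == genome[200:300]
        assert len(out.seq) == 100
        assert out.provenance == "T" * 100

    def test_operon_contig_split_into_two(self):
        rng = np.random.default_rng(13)
        genome = _random_dna(rng, 1000)
        a = CdsFeature("c1", 100, 280, "+", "gA")
        b = CdsFeature("c1", 320, 520, "+", "gB")
        contig = genome[100:520]
        aln = make_paf(qname="op", qlen=420, qend=420, tstart=100, tend=520,
                       tlen=1000, cg="420M")
        res = correct_assembly([SequenceRecord("op", "", contig)],
                               [SequenceRecord("c1", "", genome)],
                               [a, b], [aln])
        assert len(res.transcripts) == 2
        by_cds = {t.cds_ref: t.seq for t in res.transcripts}
        assert by_cds == {"gA": genome[100:280], "gB": genome[320:520]}

    def test_unknown_ids_are_integrity_errors(self):
        g = [SequenceRecord("c1", "", "ACGT" * 100)]
        t = [SequenceRecord("t1", "", "ACGT" * 50)]
        cds = [CdsFeature("c1", 0, 120, "+", "g1")]
        bad_q = make_paf(qname="ghost", qlen=200, qend=200, tend=200)
        with pytest.raises(IntegrityError, match="ghost"):
            correct_assembly(t, g, cds, [bad_q])
        bad_t = make_paf(qname="t1", qlen=200, qend=200, tname="nowhere",
                         tend=200)
        with pytest.raises(IntegrityError, match="nowhere"):
            correct_assembly(t, g, cds, [bad_t])

    def test_threshold_monotonicity(self, community):
        tr = community
        lo = correct_assembly(tr.contigs, tr.genomes, tr.cds, tr.truth_paf,
                              threshold=0.3)
        hi = correct_assembly(tr.contigs, tr.genomes, tr.cds, tr.truth_paf,
                              threshold=0.7)
        lo_ids = {c.cds_ref for c in lo.selected_cds}
        hi_ids = {c.cds_ref for c in hi.selected_cds}
        assert hi_ids <= lo_ids

    def test_synthetic_community_exact_recovery(self, community):
        """Every expressed CDS yields one output equal to the true CDS."""
        tr = community
        res = correct_assembly(tr.contigs, tr.genomes, tr.cds, tr.truth_paf)
        expressed = {c.feature_id for c in tr.expressed_cds()}
        got = {t.cds_ref: t for t in res.transcripts}
        assert set(got) == expressed
        assert len(res.transcripts) == len(got), "duplicate outputs"
        truth_seq = {c.feature_id: tr.cds_sequence(c) for c in tr.cds}
        for cid, t in got.items():
            assert t.seq == truth_seq[cid]
            assert len(t.seq) % 3 == 0
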