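"""Consensus reconstruction of full-length, single-CDS transcripts.

For every CDS with sufficient transcript coverage the module builds one
output sequence of exactly the annotated CDS length: positions covered by
transcript alignments take the transcript base (preserving variants seen
in the RNA evidence), uncovered positions are filled from the genomic
contig, and the result is reported in coding-sense orientation.  Operon
splitting and intergenic trimming are emergent: a contig spanning k CDS
contributes to k outputs, and bases mapping outside every CDS never enter
any output because the output length is locked to the CDS.

Transcript insertions relative to the genome are dropped (counted in
``CorrectionResult.dropped_insertions``) so the annotated reading frame is
never disrupted; substitutions are transferred verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .coverage import (CdsCoverage, CdsSegment, compute_cds_coverage,
                       filter_alignments, parse_cigar, partition_transcripts,
                       per_base_query_offsets, select_covered_cds)
from .errors import IntegrityError
from .io import CdsFeature, PafAlignment, SequenceRecord, revcomp

__all__ = [
    "CorrectedTranscript",
    "CorrectionResult",
    "build_consensus",
    "resolve_overlap_winner",
    "correct_assembly",
    "corrected_to_records",
    "write_correction_tsv",
]


@dataclass
class CorrectedTranscript:
    """One reconstructed mRNA containing a single complete coding region.

    ``provenance`` labels every base ``T`` (transcript-derived) or ``G``
    (genome-filled); ``seq`` is in coding-sense (5'→3' mRNA) orientation.
    """

    id: str
    seq: str
    cds_ref: str
    provenance: str
    status: str = "aligned"
    source_contigs: list[str] = field(default_factory=list)

    @property
    def transcript_fraction(self) -> float:
        return self.provenance.count("T") / len(self.provenance)


@dataclass
class CorrectionResult:
    transcripts: list[CorrectedTranscript]
    selected_cds: list[CdsCoverage]
    skipped_cds: list[CdsCoverage]
    unaligned_ids: list[str]
    dropped_insertions: int = 0


def resolve_overlap_winner(segments_at_p: list[CdsSegment]) -> CdsSegment:
    """Deterministic winner among segments covering one position.

    Greatest alignment ``matches`` wins; ties fall to greater ``mapq``,
    then to the lexicographically smallest query name.
    """
    return min(segments_at_p, key=_segment_priority)


def _segment_priority(seg: CdsSegment) -> tuple:
    return (-seg.aln.matches, -seg.aln.mapq, seg.aln.qname, seg.aln_ref)


def _count_insertions_in_window(aln: PafAlignment, t_lo: int, t_hi: int) -> int:
    cg = aln.cigar
    if cg is None:
        return 0
    events = 0
    t = aln.tstart
    for length, op in parse_cigar(cg):
        if op == "I" and t_lo < t < t_hi:
            events += 1
        if op in "MDN=X":
            t += length
    return events


def build_consensus(cds: CdsFeature, genome_seq: str,
                    segments: list[CdsSegment],
                    transcript_seqs: dict[str, str]) -> CorrectedTranscript:
    """Assemble the single-CDS consensus for one coding region.

    Walks genome-forward coordinates ``cds.start .. cds.end-1``; each
    position covered by ≥1 segment takes the winning segment's query base
    (the per-position winner is the segment with the best alignment score,
    see :func:`resolve_overlap_winner`), everything else is filled from
    ``genome_seq``.  A ``-``-strand CDS is reverse-complemented at the end
    so the output reads in coding sense.
    """
    n = len(cds)
    seq = list(genome_seq[cds.start:cds.end])
    prov = ["G"] * n
    winners_used: set[str] = set()
    dropped = 0

    # Best segment first: later (worse) segments only fill still-unclaimed
    # positions, which realises the per-position winner rule in O(total
    # segment length).
    claimed = [False] * n
    for seg in sorted(segments, key=_segment_priority):
        if seg.cds_ref != cds.feature_id:
            raise IntegrityError(
                f"segment for {seg.cds_ref!r} passed to CDS {cds.feature_id!r}")
        tseq = transcript_seqs.get(seg.aln.qname)
        if tseq is None or len(tseq) != seg.aln.qlen:
            raise IntegrityError(
                f"transcript {seg.aln.qname!r}: sequence missing or length "
                f"inconsistent with alignment qlen")
        # Orient the query the way the aligner walked it (target-forward).
        if seg.aln.strand == "+":
            oriented = tseq
            block_q0 = seg.aln.qstart
        else:
            oriented = revcomp(tseq)
            block_q0 = seg.aln.qlen - seg.aln.qend
        offsets = per_base_query_offsets(seg.aln, seg.t_lo, seg.t_hi)
        contributed = False
        for i, off in enumerate(offsets):
            p = seg.t_lo - cds.start + i
            if claimed[p] or off is None:
                continue
            seq[p] = oriented[block_q0 + off]
            prov[p] = "T"
            claimed[p] = True
            contributed = True
        if contributed:
            winners_used.add(seg.aln.qname)
            dropped += _count_insertions_in_window(seg.aln, seg.t_lo, seg.t_hi)

    out_seq = "".join(seq)
    out_prov = "".join(prov)
    if cds.strand == "-":
        out_seq = revcomp(out_seq)
        out_prov = out_prov[::-1]
    t = CorrectedTranscript(
        id=f"{cds.feature_id}|corrected", seq=out_seq, cds_ref=cds.feature_id,
        provenance=out_prov, status="aligned",
        source_contigs=sorted(winners_used))
    t._dropped_insertions = dropped  # consumed by correct_assembly
    return t


def correct_assembly(transcripts: list[SequenceRecord],
                     genomes: list[SequenceRecord],
                     cds_list: list[CdsFeature],
                     alignments: list[PafAlignment],
                     threshold: float = 0.5,
                     min_block: int = 100,
                     primary_only: bool = True,
                     min_identity: float = 0.0) -> CorrectionResult:
    """Full correction pipeline: filter → project → cover → select → weld.

    Emits exactly one :class:`CorrectedTranscript` per CDS whose covered
    fraction reaches ``threshold``; CDS with evidence below threshold (or
    none) are reported in ``skipped_cds`` for auditability.
    """
    tseqs = {r.id: r.seq for r in transcripts}
    gseqs = {r.id: r.seq for r in genomes}

    for aln in alignments:
        if aln.qname not in tseqs:
            raise IntegrityError(f"alignment references unknown transcript "
                                 f"{aln.qname!r}")
        if aln.tname not in gseqs:
            raise IntegrityError(f"alignment references unknown genomic contig "
                                 f"{aln.tname!r}")
    for cds in cds_list:
        g = gseqs.get(cds.contig_id)
        if g is None:
            raise IntegrityError(f"CDS {cds.feature_id!r} references unknown "
                                 f"contig {cds.contig_id!r}")
        if cds.end > len(g):
            raise IntegrityError(f"CDS {cds.feature_id!r} extends past contig end")

    kept = filter_alignments(alignments, min_block=min_block,
                             primary_only=primary_only,
                             min_identity=min_identity)
    by_contig: dict[str, list[PafAlignment]] = {}
    for a in kept:
        by_contig.setdefault(a.tname, []).append(a)

    coverages = [compute_cds_coverage(by_contig.get(cds.contig_id, []), cds)
                 for cds in cds_list]
    selected = select_covered_cds(coverages, threshold=threshold)
    selected_ids = {c.cds_ref for c in selected}
    skipped = [c for c in coverages if c.cds_ref not in selected_ids]

    outputs: list[CorrectedTranscript] = []
    dropped = 0
    for cov in selected:
        t = build_consensus(cov.cds, gseqs[cov.cds.contig_id], cov.segments,
                            tseqs)
        dropped += getattr(t, "_dropped_insertions", 0)
        outputs.append(t)

    _, unaligned = partition_transcripts(kept, [r.id for r in transcripts])
    return CorrectionResult(transcripts=outputs, selected_cds=selected,
                            skipped_cds=skipped, unaligned_ids=unaligned,
                            dropped_insertions=dropped)


def corrected_to_records(result: CorrectionResult) -> list[SequenceRecord]:
    """FASTA-ready records; headers carry cds id, status and provenance fraction."""
    return [SequenceRecord(
        id=t.id,
        description=(f"cds={t.cds_ref} status={t.status} "
                     f"provenance_T={t.transcript_fraction:.3f}"),
        seq=t.seq) for t in result.transcripts]


def write_correction_tsv(result: CorrectionResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tcds_id\tcontig\tstart\tend\tstrand\t"
                 "coverage_fraction\tsupporting_contigs\n")
        cov_by_id = {c.cds_ref: c for c in result.selected_cds}
        for t in result.transcripts:
            c = cov_by_id[t.cds_ref]
            fh.write("\t".join([
                t.id, t.cds_ref, c.cds.contig_id, str(c.cds.start),
                str(c.cds.end), c.cds.strand, f"{c.fraction:.4f}",
                ",".join(t.source_contigs) or "-"]) + "\n")
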