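"""Projection of transcript-to-genome alignments onto annotated CDS.

The selection machinery of the correction step: filter raw alignments,
intersect each alignment's target interval with each CDS on the same
genomic contig, and accumulate per-CDS union coverage.  A CDS whose
covered fraction reaches the user threshold (default 50%, inclusive)
becomes a target for consensus reconstruction.

Query coordinates of a projected segment are exact when the alignment
carries a ``cg`` CIGAR tag, and proportionally interpolated over the
block otherwise (the standard coordinate-only approximation for a
collinear gapless mapping).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .errors import IntegrityError
from .io import CdsFeature, PafAlignment

__all__ = [
    "CdsSegment",
    "CdsCoverage",
    "parse_cigar",
    "filter_alignments",
    "project_to_cds",
    "compute_cds_coverage",
    "select_covered_cds",
    "partition_transcripts",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_T_CONSUMING = frozenset("MDN=X")
_Q_CONSUMING = frozenset("MIS=X")


def parse_cigar(cg: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) pairs.

    Raises :class:`IntegrityError` on unparseable text.
    """
    ops = _CIGAR_RE.findall(cg)
    if "".join(f"{n}{o}" for n, o in ops) != cg:
        raise IntegrityError(f"malformed CIGAR string {cg!r}")
    return [(int(n), o) for n, o in ops]


@dataclass
class CdsSegment:
    """The piece of one alignment that falls inside one CDS.

    ``t_lo``/``t_hi`` are genome coordinates clipped to the CDS interval;
    ``q_lo``/``q_hi`` are the corresponding query (transcript) coordinates
    on the original query strand.  ``aln`` keeps the source alignment so the
    consensus step can recover per-base query positions.
    """

    cds_ref: str
    aln_ref: int
    t_lo: int
    t_hi: int
    q_lo: int
    q_hi: int
    aln: PafAlignment

    def __post_init__(self) -> None:
        if not self.t_lo < self.t_hi:
            raise ValueError("empty target interval")
        if not self.q_lo < self.q_hi:
            raise ValueError("empty query interval")


@dataclass
class CdsCoverage:
    """Union coverage of one CDS by projected alignment segments."""

    cds: CdsFeature
    covered_bases: int
    fraction: float
    segments: list[CdsSegment] = field(default_factory=list)

    @property
    def cds_ref(self) -> str:
        return self.cds.feature_id


def filter_alignments(alignments: list[PafAlignment], min_block: int = 100,
                      primary_only: bool = True,
                      min_identity: float = 0.0) -> list[PafAlignment]:
    """Drop short, secondary and low-identity alignments; order is stable.

    ``min_block`` guards against spurious micro-hits below read length;
    ``primary_only`` drops records tagged ``tp:A:S`` so a single transcript
    copy supports each locus (re-admit secondaries for paralog-rich data).
    """
    out = []
    for a in alignments:
        if a.block_len < min_block:
            continue
        if primary_only and a.tp == "S":
            continue
        if a.identity < min_identity:
            continue
        out.append(a)
    return out


def _aligned_query_offsets(aln: PafAlignment, t_lo: int, t_hi: int) -> tuple[int, int]:
    """Aligned-strand query offsets corresponding to target window [t_lo, t_hi).

    Offsets are measured from the start of the aligned block on the strand
    the alignment was computed on (i.e. the reverse complement of the query
    for '-' records, per PAF/minimap2 convention where the CIGAR advances
    along the target).
    """
    cg = aln.cigar
    if cg is None:
        tspan = aln.tend - aln.tstart
        qspan = aln.qend - aln.qstart
        lo = (t_lo - aln.tstart) * qspan // tspan
        hi = (t_hi - aln.tstart) * qspan // tspan if t_hi < aln.tend else qspan
        return lo, hi

    ops = parse_cigar(cg)
    return (_query_offset_at(ops, t_lo - aln.tstart, left=True),
            _query_offset_at(ops, t_hi - aln.tstart, left=False))


def _query_offset_at(ops: list[tuple[int, str]], target_off: int,
                     left: bool) -> int:
    """Query bases consumed before target offset ``target_off`` in the block.

    When the boundary coincides with an insertion, a left boundary is
    placed after the inserted bases and a right boundary before them, so
    insertions at segment edges never leak into the query interval.
    """
    t = q = 0
    for length, op in ops:
        dt = length if op in _T_CONSUMING else 0
        dq = length if op in _Q_CONSUMING else 0
        if not left and t == target_off:
            return q
        if dt and t + dt > target_off:
            return q + (target_off - t if dq else 0)
        t += dt
        q += dq
    return q


def per_base_query_offsets(aln: PafAlignment, t_lo: int,
                           t_hi: int) -> list[int | None]:
    """Aligned-strand query offset for every target position in [t_lo, t_hi).

    ``None`` marks positions inside a transcript deletion (no query base).
    Without a CIGAR the block is treated as collinear and gapless, with
    proportional interpolation when query and target spans differ.
    """
    n = t_hi - t_lo
    cg = aln.cigar
    if cg is None:
        tspan = aln.tend - aln.tstart
        qspan = aln.qend - aln.qstart
        base = t_lo - aln.tstart
        return [min((base + i) * qspan // tspan, qspan - 1) for i in range(n)]
    out: list[int | None] = [None] * n
    t = q = 0
    for length, op in parse_cigar(cg):
        dt = length if op in _T_CONSUMING else 0
        dq = length if op in _Q_CONSUMING else 0
        if dt:
            lo = max(t, t_lo - aln.tstart)
            hi = min(t + dt, t_hi - aln.tstart)
            for pos in range(lo, hi):
                out[pos - (t_lo - aln.tstart)] = q + (pos - t) if dq else None
        t += dt
        q += dq
        if t >= t_hi - aln.tstart:
            break
    return out


def project_to_cds(aln: PafAlignment, cds: CdsFeature,
                   aln_index: int = 0) -> CdsSegment | None:
    """Clip an alignment to a CDS interval on the same genomic contig.

    Returns ``None`` when the alignment does not overlap the CDS, or when
    the overlap has an empty query image (it lies entirely inside a
    transcript deletion).
    """
    if aln.tname != cds.contig_id:
        raise IntegrityError(
            f"alignment target {aln.tname!r} does not match CDS contig "
            f"{cds.contig_id!r}")
    t_lo = max(aln.tstart, cds.start)
    t_hi = min(aln.tend, cds.end)
    if t_lo >= t_hi:
        return None
    aq_lo, aq_hi = _aligned_query_offsets(aln, t_lo, t_hi)
    if aq_lo >= aq_hi:
        return None
    if aln.strand == "+":
        q_lo, q_hi = aln.qstart + aq_lo, aln.qstart + aq_hi
    else:
        q_lo, q_hi = aln.qend - aq_hi, aln.qend - aq_lo
    return CdsSegment(cds_ref=cds.feature_id, aln_ref=aln_index,
                      t_lo=t_lo, t_hi=t_hi, q_lo=q_lo, q_hi=q_hi, aln=aln)


def compute_cds_coverage(alignments: list[PafAlignment],
                         cds: CdsFeature) -> CdsCoverage:
    """Union coverage of one CDS by all overlapping (pre-filtered) alignments."""
    segments = []
    for i, aln in enumerate(alignments):
        if aln.tname != cds.contig_id:
            continue
        seg = project_to_cds(aln, cds, aln_index=i)
        if seg is not None:
            segments.append(seg)
    if segments:
        tree = IntervalTree.from_tuples((s.t_lo, s.t_hi) for s in segments)
        tree.merge_overlaps()
        covered = sum(iv.end - iv.begin for iv in tree)
    else:
        covered = 0
    return CdsCoverage(cds=cds, covered_bases=covered,
                       fraction=covered / len(cds), segments=segments)


def select_covered_cds(coverages: list[CdsCoverage],
                       threshold: float = 0.5) -> list[CdsCoverage]:
    """Keep CDS whose covered fraction is at least ``threshold`` (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return [c for c in coverages if c.fraction >= threshold]


def partition_transcripts(alignments: list[PafAlignment],
                          transcript_ids: list[str]) -> tuple[list[str], list[str]]:
    """Split transcript ids into (aligned, unaligned) by surviving alignments.

    Transcripts absent from the metagenome (e.g. dietary mRNA in gut
    samples) end up unaligned and are handled by the orphan path.
    """
    hit = {a.qname for a in alignments}
    aligned = [t for t in transcript_ids if t in hit]
    unaligned = [t for t in transcript_ids if t not in hit]
    return aligned, unaligned
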