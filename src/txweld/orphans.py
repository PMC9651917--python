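"""Handling of transcripts with no genomic alignment.

Gut metatranscriptomes capture mRNA the community itself never encoded
(dietary material, transient organisms), so contigs that fail to align to
the metagenome are not discarded outright.  Two stages mirror the usual
practice: (1) keep only contigs carrying a long open reading frame — a
crude but effective coding-potential screen; (2) greedy centroid
clustering against the corrected transcript set so a duplicate of an
already-reconstructed mRNA is absorbed rather than reported twice.

All coordinates returned by :func:`find_orfs` are on the coding-sense
strand after frame resolution (frames 3–5 index into the reverse
complement).
"""

from __future__ import annotations

import edlib
from Bio.Data import CodonTable

from .io import SequenceRecord, revcomp

__all__ = ["OrfCall", "find_orfs", "select_coding", "cluster_dedup"]

from dataclasses import dataclass

_DEFAULT_STARTS = frozenset({"ATG", "GTG", "TTG"})


@dataclass
class OrfCall:
    """A candidate open reading frame on one transcript.

    ``start``/``end`` are 0-based half-open on the strand the ORF reads
    from; ``end`` includes the stop codon when one is present.  ``aa_len``
    counts residues including the initiator, excluding the stop.
    """

    transcript_id: str
    frame: int          # 0-2 forward, 3-5 reverse-complement
    start: int
    end: int
    aa_len: int


def _stop_codons(table: int) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[table].stop_codons)


def find_orfs(seq: str, min_aa: int = 100,
              starts: frozenset[str] = _DEFAULT_STARTS,
              table: int = 11,
              transcript_id: str = "") -> list[OrfCall]:
    """Six-frame scan for maximal ORFs of at least ``min_aa`` residues.

    An ORF runs from the first accepted start codon after the previous
    in-frame stop to the next stop codon; an ORF hitting the sequence end
    without a stop is kept (3'-partial).  Results are sorted by ``aa_len``
    descending.
    """
    stops = _stop_codons(table)
    calls: list[OrfCall] = []
    for frame in range(6):
        s = seq if frame < 3 else revcomp(seq)
        off = frame % 3
        start_pos: int | None = None
        for i in range(off, len(s) - 2, 3):
            codon = s[i:i + 3]
            if start_pos is None and codon in starts:
                start_pos = i
            if codon in stops:
                if start_pos is not None:
                    aa = (i - start_pos) // 3
                    if aa >= min_aa:
                        calls.append(OrfCall(transcript_id, frame,
                                             start_pos, i + 3, aa))
                start_pos = None
        if start_pos is not None:
            # 3'-partial: runs off the end of the transcript
            last = off + ((len(s) - off) // 3) * 3
            aa = (last - start_pos) // 3
            if aa >= min_aa:
                calls.append(OrfCall(transcript_id, frame, start_pos, last, aa))
    calls.sort(key=lambda c: (-c.aa_len, c.frame, c.start))
    return calls


def select_coding(unaligned_records: list[SequenceRecord],
                  min_aa: int = 100) -> list[SequenceRecord]:
    """Keep unaligned contigs with at least one long ORF; label them unaligned."""
    out = []
    for rec in unaligned_records:
        if find_orfs(rec.seq, min_aa=min_aa, transcript_id=rec.id):
            out.append(SequenceRecord(id=rec.id, description="status=unaligned",
                                      seq=rec.seq))
    return out


def _kmer_set(seq: str, k: int, stride: int) -> set[str]:
    return {seq[i:i + k] for i in range(0, len(seq) - k + 1, stride)}


def _pair_identity(a: str, b: str) -> float:
    """Identity of the shorter sequence aligned as an infix of the longer.

    Both orientations of the shorter sequence are tried; identity is
    1 − edits/|shorter| with the whole shorter sequence consumed, so the
    coverage of the shorter sequence is complete by construction.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0.0
    for query in (short, revcomp(short)):
        d = edlib.align(query, long_, mode="HW", task="distance")["editDistance"]
        if d >= 0:
            best = max(best, 1.0 - d / len(short))
    return best


def cluster_dedup(corrected: list[SequenceRecord],
                  orphan_candidates: list[SequenceRecord],
                  min_identity: float = 0.95,
                  min_cov: float = 0.9,
                  k: int = 15) -> list[SequenceRecord]:
    """Greedy length-sorted centroid clustering for output deduplication.

    Corrected transcripts are seeded as centroids first (every one of them
    appears in the output exactly once); each orphan candidate, longest
    first, is absorbed by the first centroid reaching ``min_identity`` over
    at least ``min_cov`` of the shorter sequence, else becomes a new
    centroid labelled ``unaligned``.  A k-mer prefilter skips hopeless
    pairs.
    """
    centroids: list[SequenceRecord] = []
    kmer_index: list[set[str]] = []

    def seed(rec: SequenceRecord, status: str) -> None:
        desc = f"status={status}" if "status=" not in rec.description \
            else rec.description
        centroids.append(SequenceRecord(id=rec.id, description=desc, seq=rec.seq))
        kmer_index.append(_kmer_set(rec.seq, k, stride=1)
                          | _kmer_set(revcomp(rec.seq), k, stride=1))

    for rec in sorted(corrected, key=len, reverse=True):
        seed(rec, "aligned")

    for rec in sorted(orphan_candidates, key=len, reverse=True):
        probe = _kmer_set(rec.seq, k, stride=k)
        absorbed = False
        for cseq, ckmers in zip(centroids, kmer_index):
            if probe and not (probe & ckmers):
                continue
            # Infix alignment consumes the whole shorter sequence, so the
            # min_cov requirement on the shorter sequence holds whenever
            # the identity test is reached (see _pair_identity).
            if _pair_identity(rec.seq, cseq.seq) >= min_identity:
                absorbed = True
                break
        if not absorbed:
            seed(rec, "unaligned")
    return centroids
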