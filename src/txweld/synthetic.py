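"""Ground-truth microbial community and assembly-artifact simulator.

Everything the correction/evaluation machinery consumes can be generated
here without any download: random bacterial-like genomes with framed,
non-overlapping CDS; log-normal species abundances; per-gene log-normal
expression multiplied by the abundance of the carrying species (so the
effective transcript pool mixes community structure and regulation, as in
real metatranscriptomes); transcript contigs exhibiting the canonical
de-novo assembly artifact classes — fragmented, partially assembled,
fragmented-and-partial, and intergenic-extended contigs — plus
operon-spanning, chimeric and clean contigs for splitting/misassembly
tests; exact truth alignments (PAF with CIGAR) for every contig; and
error-free reads for quantification.

Every operation is deterministic under a fixed seed; the global seed fans
out to per-operation streams via a CRC32 hash of the operation name, so
each generator is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .io import CdsFeature, PafAlignment, SequenceRecord, revcomp

__all__ = [
    "SyntheticTruth",
    "generate_community",
    "assign_abundances",
    "assign_expression",
    "make_artifact_contigs",
    "simulate_reads",
    "reads_to_paf",
    "generate_truth",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOPS]

DEFAULT_MIX = {
    "fragmented": 0.25,
    "partial": 0.25,
    "fragmented_partial": 0.25,
    "intergenic_extended": 0.25,
}


def _rng(seed: int, op: str) -> np.random.Generator:
    """Per-operation stream: global seed + CRC32 of the operation name."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(op.encode())])


@dataclass
class SyntheticTruth:
    """Complete ground truth for one simulated community."""

    genomes: list[SequenceRecord]
    cds: list[CdsFeature]
    abundance: dict[str, float]
    expression: dict[str, float]
    effective_tpm: dict[str, float]
    contigs: list[SequenceRecord] = field(default_factory=list)
    artifact_labels: dict[str, str] = field(default_factory=dict)
    truth_paf: list[PafAlignment] = field(default_factory=list)
    seed: int = 0

    def cds_sequence(self, feature: CdsFeature) -> str:
        """Coding-sense (mRNA) sequence of one CDS."""
        g = next(r for r in self.genomes if r.id == feature.contig_id)
        s = g.seq[feature.start:feature.end]
        return s if feature.strand == "+" else revcomp(s)

    def expressed_cds(self) -> list[CdsFeature]:
        return [c for c in self.cds if self.effective_tpm.get(c.feature_id, 0) > 0]

    def transcript_records(self) -> list[SequenceRecord]:
        """True mRNA set (one record per CDS, coding sense)."""
        return [SequenceRecord(id=c.feature_id, description="",
                               seq=self.cds_sequence(c)) for c in self.cds]


def _random_cds_seq(rng: np.random.Generator, length: int) -> str:
    """A framed coding sequence: start codon, sense codons, one stop."""
    n_body = length // 3 - 2
    body = "".join(rng.choice(_SENSE_CODONS, size=n_body))
    stop = _STOPS[rng.integers(3)]
    return "ATG" + body + stop


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Substitute bases at ``rate``; returns (sequence, substitution count)."""
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr), len(hits)


def generate_community(n_genomes: int = 5, genome_len: int = 50_000,
                       n_cds: int = 20,
                       cds_len_range: tuple[int, int] = (300, 900),
                       seed: int = 0,
                       homolog_pairs: int = 0,
                       homolog_identity: float = 0.95,
                       gap_range: tuple[int, int] = (60, 150)
                       ) -> tuple[list[SequenceRecord], list[CdsFeature]]:
    """Random genomes with ``n_cds`` non-overlapping framed CDS each.

    CDS are laid down left to right with intergenic gaps drawn from
    ``gap_range`` (leaving room for intergenic-extension flanks and operon
    adjacency); lengths are drawn from ``cds_len_range`` and rounded down
    to a codon multiple; strands are random.  ``homolog_pairs`` CDS per
    genome (beyond the first) are mutated copies of a CDS from the
    previous genome at ``homolog_identity``, emulating closely related
    strains.
    """
    lo, hi = cds_len_range
    if lo < 60 or hi < lo:
        raise ValueError("cds_len_range must satisfy 60 ≤ lo ≤ hi")
    if n_cds * hi + (n_cds + 1) * gap_range[1] > genome_len:
        raise ValueError(
            f"cannot pack {n_cds} CDS of up to {hi} bp plus gaps into a "
            f"{genome_len} bp genome")
    rng = _rng(seed, "generate_community")
    genomes: list[SequenceRecord] = []
    features: list[CdsFeature] = []
    prev_coding: list[str] = []
    for gi in range(n_genomes):
        gid = f"genome_{gi + 1:02d}"
        seq = list("".join(rng.choice(_BASES, size=genome_len)))
        pos = int(rng.integers(gap_range[0], gap_range[1] + 1))
        coding_seqs: list[str] = []
        for ci in range(n_cds):
            if gi > 0 and prev_coding and ci < homolog_pairs:
                src = prev_coding[ci]
                coding, _ = _mutate(rng, src, 1.0 - homolog_identity)
                # keep the copy translatable: restore frame integrity
                body = [coding[k:k + 3] for k in range(3, len(coding) - 3, 3)]
                body = [_SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
                        if b in _STOPS else b for b in body]
                coding = "ATG" + "".join(body) + coding[-3:]
                if coding[-3:] not in _STOPS:
                    coding = coding[:-3] + src[-3:]
                length = len(coding)
            else:
                length = int(rng.integers(lo, hi + 1)) // 3 * 3
                coding = _random_cds_seq(rng, length)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = coding if strand == "+" else revcomp(coding)
            seq[pos:pos + length] = placed
            features.append(CdsFeature(
                contig_id=gid, start=pos, end=pos + length, strand=strand,
                feature_id=f"{gid}_cds_{ci + 1:02d}"))
            coding_seqs.append(coding)
            pos += length + int(rng.integers(gap_range[0], gap_range[1] + 1))
        prev_coding = coding_seqs
        genomes.append(SequenceRecord(id=gid, description="synthetic genome",
                                      seq="".join(seq)))
    return genomes, features


def assign_abundances(genome_ids: list[str], sigma: float = 1.5,
                      seed: int = 0) -> dict[str, float]:
    """Log-normal relative species abundances, normalised to sum 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = _rng(seed, "assign_abundances")
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=len(genome_ids))
    raw /= raw.sum()
    return {gid: float(v) for gid, v in zip(genome_ids, raw)}


def assign_expression(cds: list[CdsFeature], abundance: dict[str, float],
                      sigma: float = 1.0, zero_fraction: float = 0.1,
                      seed: int = 0
                      ) -> tuple[dict[str, float], dict[str, float]]:
    """Per-gene expression and the community-effective TPM it implies.

    Expression is log-normal with a ``zero_fraction`` of silent genes; the
    effective transcript fraction of gene *i* is proportional to
    expression_i × abundance(species of *i*), scaled to sum to 10^6.
    """
    rng = _rng(seed, "assign_expression")
    expr: dict[str, float] = {}
    for c in cds:
        if rng.random() < zero_fraction:
            expr[c.feature_id] = 0.0
        else:
            expr[c.feature_id] = float(rng.lognormal(mean=0.0, sigma=sigma))
    weighted = {c.feature_id: expr[c.feature_id] * abundance[c.contig_id]
                for c in cds}
    total = sum(weighted.values())
    tpm = {fid: (1e6 * w / total if total > 0 else 0.0)
           for fid, w in weighted.items()}
    return expr, tpm


def _piece(cds: CdsFeature, tlen: int, a: int, b: int, contig_id: str,
           transcript: str, rng: np.random.Generator,
           error_rate: float) -> tuple[SequenceRecord, PafAlignment]:
    """One contig covering transcript coords [a, b) of a CDS, plus truth PAF."""
    seq = transcript[a:b]
    seq, n_err = _mutate(rng, seq, error_rate)
    if cds.strand == "+":
        t_lo, t_hi = cds.start + a, cds.start + b
    else:
        t_lo, t_hi = cds.end - b, cds.end - a
    rec = SequenceRecord(id=contig_id, description="", seq=seq)
    paf = PafAlignment(
        qname=contig_id, qlen=b - a, qstart=0, qend=b - a, strand=cds.strand,
        tname=cds.contig_id, tlen=tlen, tstart=t_lo, tend=t_hi,
        matches=b - a - n_err, block_len=b - a, mapq=60,
        tags={"tp": ("A", "P"), "cg": ("Z", f"{b - a}M")})
    return rec, paf


def make_artifact_contigs(genomes: list[SequenceRecord],
                          cds: list[CdsFeature],
                          effective_tpm: dict[str, float],
                          mix: dict[str, float] | None = None,
                          error_rate: float = 0.0,
                          seed: int = 0,
                          flank_len: int = 50,
                          partial_cov: tuple[float, float] = (0.5, 0.95),
                          frag_overlap: int = 10,
                          min_piece: int = 100
                          ) -> tuple[list[SequenceRecord], dict[str, str],
                                     list[PafAlignment]]:
    """Emit assembly-artifact contigs for every expressed CDS.

    Each expressed CDS draws one artifact class from ``mix`` and produces
    contigs accordingly (see module docstring for the classes).  Every
    piece's exact genomic placement is recorded as a truth PAF record with
    a full-length CIGAR.  ``operon_span`` falls back to ``clean`` (with a
    warning label preserved as ``clean``) when the genome offers no
    adjacent same-strand partner CDS.
    """
    mix = dict(DEFAULT_MIX) if mix is None else dict(mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("artifact class proportions must sum to 1")
    rng = _rng(seed, "make_artifact_contigs")
    gseq = {g.id: g.seq for g in genomes}
    glen = {g.id: len(g.seq) for g in genomes}
    by_contig: dict[str, list[CdsFeature]] = {}
    for c in cds:
        by_contig.setdefault(c.contig_id, []).append(c)
    for feats in by_contig.values():
        feats.sort(key=lambda f: f.start)

    def mrna(c: CdsFeature) -> str:
        s = gseq[c.contig_id][c.start:c.end]
        return s if c.strand == "+" else revcomp(s)

    classes = sorted(mix)
    probs = np.array([mix[k] for k in classes])
    expressed = [c for c in cds if effective_tpm.get(c.feature_id, 0) > 0]

    contigs: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    paf: list[PafAlignment] = []

    for c in expressed:
        cls = classes[int(rng.choice(len(classes), p=probs))]
        L = len(c)
        tlen = glen[c.contig_id]
        tx = mrna(c)
        emitted: list[tuple[SequenceRecord, PafAlignment]] = []

        if cls == "fragmented":
            cut = int(rng.integers(min_piece, L - min_piece + 1))
            half = frag_overlap // 2
            emitted.append(_piece(c, tlen, 0, min(cut + half, L),
                                  f"{c.feature_id}.frag.1", tx, rng, error_rate))
            emitted.append(_piece(c, tlen, max(cut - half, 0), L,
                                  f"{c.feature_id}.frag.2", tx, rng, error_rate))
        elif cls == "partial":
            lo, hi = partial_cov
            cov = float(rng.uniform(max(lo, min_piece / L), hi))
            pl = max(min_piece, int(round(cov * L)))
            a = int(rng.integers(0, L - pl + 1))
            emitted.append(_piece(c, tlen, a, a + pl,
                                  f"{c.feature_id}.part.1", tx, rng, error_rate))
        elif cls == "fragmented_partial":
            cov_lo = max(0.6, (2 * min_piece + 2) / L)
            cov = float(rng.uniform(cov_lo, min(0.95, (L - 1) / L)))
            total = int(round(cov * L))
            l1 = int(rng.integers(min_piece, total - min_piece + 1))
            l2 = total - l1
            emitted.append(_piece(c, tlen, 0, l1,
                                  f"{c.feature_id}.fp.1", tx, rng, error_rate))
            emitted.append(_piece(c, tlen, L - l2, L,
                                  f"{c.feature_id}.fp.2", tx, rng, error_rate))
        elif cls == "intergenic_extended":
            f5 = min(flank_len, c.start if c.strand == "+" else tlen - c.end)
            f3 = min(flank_len, tlen - c.end if c.strand == "+" else c.start)
            if c.strand == "+":
                g_lo, g_hi = c.start - f5, c.end + f3
            else:
                g_lo, g_hi = c.start - f3, c.end + f5
            raw = gseq[c.contig_id][g_lo:g_hi]
            seq = raw if c.strand == "+" else revcomp(raw)
            seq, n_err = _mutate(rng, seq, error_rate)
            cid = f"{c.feature_id}.ext.1"
            contigs_rec = SequenceRecord(id=cid, description="", seq=seq)
            emitted.append((contigs_rec, PafAlignment(
                qname=cid, qlen=g_hi - g_lo, qstart=0, qend=g_hi - g_lo,
                strand=c.strand, tname=c.contig_id, tlen=tlen,
                tstart=g_lo, tend=g_hi, matches=g_hi - g_lo - n_err,
                block_len=g_hi - g_lo, mapq=60,
                tags={"tp": ("A", "P"), "cg": ("Z", f"{g_hi - g_lo}M")})))
        elif cls == "operon_span":
            partner = _adjacent_same_strand(by_contig[c.contig_id], c)
            if partner is None:
                cls = "clean"
                emitted.append(_piece(c, tlen, 0, L, f"{c.feature_id}.clean.1",
                                      tx, rng, error_rate))
            else:
                a, b = (c, partner) if c.start < partner.start else (partner, c)
                raw = gseq[c.contig_id][a.start:b.end]
                seq = raw if c.strand == "+" else revcomp(raw)
                seq, n_err = _mutate(rng, seq, error_rate)
                span = b.end - a.start
                cid = f"{c.feature_id}.op.1"
                emitted.append((SequenceRecord(id=cid, description="", seq=seq),
                                PafAlignment(
                    qname=cid, qlen=span, qstart=0, qend=span, strand=c.strand,
                    tname=c.contig_id, tlen=tlen, tstart=a.start, tend=b.end,
                    matches=span - n_err, block_len=span, mapq=60,
                    tags={"tp": ("A", "P"), "cg": ("Z", f"{span}M")})))
        elif cls == "chimeric":
            other = _other_genome_cds(cds, c, rng)
            l1 = max(min_piece, L // 2)
            tx2 = mrna(other)
            l2 = max(min_piece, len(other) // 2)
            cid = f"{c.feature_id}.chim.1"
            seq = tx[:l1] + tx2[len(other) - l2:]
            seq, _ = _mutate(rng, seq, error_rate)
            qlen = l1 + l2
            p1 = PafAlignment(
                qname=cid, qlen=qlen, qstart=0, qend=l1, strand=c.strand,
                tname=c.contig_id, tlen=tlen,
                tstart=c.start if c.strand == "+" else c.end - l1,
                tend=c.start + l1 if c.strand == "+" else c.end,
                matches=l1, block_len=l1, mapq=60,
                tags={"tp": ("A", "P"), "cg": ("Z", f"{l1}M")})
            o_lo = (other.end - l2 if other.strand == "+"
                    else other.start)
            p2 = PafAlignment(
                qname=cid, qlen=qlen, qstart=l1, qend=qlen,
                strand=other.strand, tname=other.contig_id,
                tlen=glen[other.contig_id], tstart=o_lo, tend=o_lo + l2,
                matches=l2, block_len=l2, mapq=60,
                tags={"tp": ("A", "P"), "cg": ("Z", f"{l2}M")})
            emitted.append((SequenceRecord(id=cid, description="", seq=seq), p1))
            paf.append(p2)
        elif cls == "clean":
            emitted.append(_piece(c, tlen, 0, L, f"{c.feature_id}.clean.1",
                                  tx, rng, error_rate))
        else:
            raise ValueError(f"unknown artifact class {cls!r}")

        for rec, p in emitted:
            contigs.append(rec)
            labels[rec.id] = cls
            paf.append(p)
    return contigs, labels, paf


def _adjacent_same_strand(feats: list[CdsFeature],
                          c: CdsFeature) -> CdsFeature | None:
    idx = feats.index(c)
    for j in (idx + 1, idx - 1):
        if 0 <= j < len(feats) and feats[j].strand == c.strand:
            return feats[j]
    return None


def _other_genome_cds(cds: list[CdsFeature], c: CdsFeature,
                      rng: np.random.Generator) -> CdsFeature:
    others = [f for f in cds if f.contig_id != c.contig_id]
    if not others:
        raise ValueError("chimeric contigs require at least two genomes")
    return others[int(rng.integers(len(others)))]


def simulate_reads(transcripts: list[SequenceRecord],
                   effective_tpm: dict[str, float],
                   n_reads: int = 10_000, read_len: int = 100,
                   seed: int = 0, error_rate: float = 0.0
                   ) -> tuple[list[SequenceRecord], dict[str, tuple[str, int]]]:
    """Fragment-sample reads from the expressed transcript pool.

    A transcript is chosen with probability ∝ effective TPM × number of
    read start positions (length weighting of fragment sampling); the
    start is uniform.  Returns the reads and a truth table
    read_id → (source transcript, start).
    """
    pool = [t for t in transcripts if effective_tpm.get(t.id, 0) > 0]
    if not pool:
        raise ValueError("no expressed transcripts to sample from")
    if read_len > min(len(t) for t in pool):
        raise ValueError("read_len exceeds shortest expressed transcript")
    rng = _rng(seed, "simulate_reads")
    weights = np.array([effective_tpm[t.id] * (len(t) - read_len + 1)
                        for t in pool], dtype=float)
    weights /= weights.sum()
    idx = rng.choice(len(pool), size=n_reads, p=weights)
    reads: list[SequenceRecord] = []
    truth: dict[str, tuple[str, int]] = {}
    for i, src_i in enumerate(idx):
        src = pool[src_i]
        start = int(rng.integers(0, len(src) - read_len + 1))
        seq = src.seq[start:start + read_len]
        seq, _ = _mutate(rng, seq, error_rate)
        rid = f"read_{i + 1:06d}"
        reads.append(SequenceRecord(id=rid, description="", seq=seq))
        truth[rid] = (src.id, start)
    return reads, truth


def reads_to_paf(reads: list[SequenceRecord],
                 truth: dict[str, tuple[str, int]],
                 transcripts: list[SequenceRecord],
                 multimap: bool = False) -> list[PafAlignment]:
    """PAF of reads against the transcript set.

    By default each read maps to its truth source at the truth position
    (exact, unique).  With ``multimap`` every exact forward occurrence of
    the read in every transcript is reported, which exercises the
    fractional counting path on homolog-rich communities.
    """
    tlen = {t.id: len(t) for t in transcripts}
    out: list[PafAlignment] = []
    for r in reads:
        placements: list[tuple[str, int]] = []
        if multimap:
            for t in transcripts:
                at = t.seq.find(r.seq)
                while at != -1:
                    placements.append((t.id, at))
                    at = t.seq.find(r.seq, at + 1)
        else:
            placements.append(truth[r.id])
        for tid, start in placements:
            n = len(r.seq)
            out.append(PafAlignment(
                qname=r.id, qlen=n, qstart=0, qend=n, strand="+", tname=tid,
                tlen=tlen[tid], tstart=start, tend=start + n, matches=n,
                block_len=n, mapq=60 if len(placements) == 1 else 1,
                tags={"tp": ("A", "P"), "cg": ("Z", f"{n}M")}))
    return out


def generate_truth(n_genomes: int = 5, genome_len: int = 50_000,
                   n_cds: int = 20,
                   cds_len_range: tuple[int, int] = (300, 900),
                   mix: dict[str, float] | None = None,
                   abundance_sigma: float = 1.5,
                   expression_sigma: float = 1.0,
                   zero_fraction: float = 0.1,
                   error_rate: float = 0.0,
                   seed: int = 0,
                   partial_cov: tuple[float, float] = (0.5, 0.95),
                   homolog_pairs: int = 0) -> SyntheticTruth:
    """One-call community: genomes, annotation, abundances, expression, contigs."""
    genomes, cds = generate_community(
        n_genomes=n_genomes, genome_len=genome_len, n_cds=n_cds,
        cds_len_range=cds_len_range, seed=seed, homolog_pairs=homolog_pairs)
    abundance = assign_abundances([g.id for g in genomes],
                                  sigma=abundance_sigma, seed=seed)
    expression, tpm = assign_expression(cds, abundance,
                                        sigma=expression_sigma,
                                        zero_fraction=zero_fraction, seed=seed)
    contigs, labels, paf = make_artifact_contigs(
        genomes, cds, tpm, mix=mix, error_rate=error_rate, seed=seed,
        partial_cov=partial_cov)
    return SyntheticTruth(genomes=genomes, cds=cds, abundance=abundance,
                          expression=expression, effective_tpm=tpm,
                          contigs=contigs, artifact_labels=labels,
                          truth_paf=paf, seed=seed)
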