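"""Readers and writers for FASTA, GFF3 (Prokka dialect) and PAF.

All coordinates are 0-based half-open internally.  Conversions from the
1-based inclusive GFF convention happen here and nowhere else; PAF is
natively half-open and passes through unchanged.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import ParseError

__all__ = [
    "SequenceRecord",
    "CdsFeature",
    "PafAlignment",
    "read_fasta",
    "write_fasta",
    "read_gff_cds",
    "write_gff_cds",
    "read_paf",
    "write_paf",
    "read_expression_tsv",
    "write_expression_tsv",
]

_DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named DNA sequence (transcript contig, genome contig, or read).

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``description`` holds the remainder of the header line.
    """

    id: str
    description: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CdsFeature:
    """An annotated coding region on a genomic contig.

    ``start``/``end`` are 0-based half-open genome coordinates regardless of
    strand; ``feature_id`` comes from the GFF ``ID`` attribute, else
    ``locus_tag``, else is synthesized.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    feature_id: str
    product: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"CDS {self.feature_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"CDS {self.feature_id!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PafAlignment:
    """One PAF record (query → target alignment, 0-based half-open).

    ``tags`` maps tag name → (type char, value string); the ``cg`` (CIGAR)
    and ``tp`` (primary/secondary) tags get convenience accessors, all other
    tags are carried opaquely and round-trip unchanged.
    """

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    block_len: int
    mapq: int
    tags: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(f"{self.qname}: bad query interval")
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(f"{self.qname}: bad target interval")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.qname}: bad strand {self.strand!r}")
        if self.matches > self.block_len:
            raise ValueError(f"{self.qname}: matches exceed block length")
        if not (0 <= self.mapq <= 255):
            raise ValueError(f"{self.qname}: mapq out of range")

    @property
    def tp(self) -> str | None:
        t = self.tags.get("tp")
        return t[1] if t else None

    @property
    def cigar(self) -> str | None:
        t = self.tags.get("cg")
        return t[1] if t else None

    @property
    def identity(self) -> float:
        return self.matches / self.block_len if self.block_len else 0.0


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Sequences are uppercased; characters outside {A,C,G,T,N} and duplicated
    ids are errors, as is sequence text before the first header.
    """
    path = os.fspath(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError("sequence data before first '>' header", path, lineno)
            break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise ParseError(
                f"record {rec.id!r}: invalid sequence characters {sorted(bad)}", path
            )
        if rec.id in seen:
            raise ParseError(f"duplicated sequence id {rec.id!r}", path)
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, description=desc, seq=seq))
    return records


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike,
                line_width: int = 60) -> None:
    """Write records as wrapped FASTA; round-trips through :func:`read_fasta`."""
    bio_records = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=line_width)
        writer.write_file(bio_records)


# ---------------------------------------------------------------------------
# GFF3 (Prokka dialect)

def read_gff_cds(path: str | os.PathLike) -> list[CdsFeature]:
    """Extract CDS rows from a GFF3 file.

    Only rows of type ``CDS`` are returned; the 1-based inclusive GFF
    interval becomes 0-based half-open.  Everything after a ``##FASTA``
    pragma (Prokka appends the contig sequences there) is ignored.
    """
    path = os.fspath(path)
    features: list[CdsFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ParseError(f"expected ≥8 tab-separated columns, got {len(cols)}",
                                 path, lineno)
            contig_id, _src, ftype, start_s, end_s, _score, strand = cols[:7]
            if ftype != "CDS":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError("non-integer coordinate", path, lineno) from None
            if end1 < start1:
                raise ParseError(f"end < start ({end1} < {start1})", path, lineno)
            if strand not in ("+", "-"):
                raise ParseError(f"unknown strand symbol {strand!r}", path, lineno)
            attrs: dict[str, str] = {}
            if len(cols) >= 9:
                for item in cols[8].split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        attrs[k.strip()] = v.strip()
            feature_id = attrs.get("ID") or attrs.get("locus_tag") \
                or f"{contig_id}:{start1 - 1}-{end1}"
            features.append(CdsFeature(
                contig_id=contig_id, start=start1 - 1, end=end1, strand=strand,
                feature_id=feature_id, product=attrs.get("product")))
    return features


def write_gff_cds(features: list[CdsFeature], path: str | os.PathLike) -> None:
    """Write CDS features as GFF3 (internal half-open → 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.feature_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write("\t".join([
                f.contig_id, "txweld", "CDS", str(f.start + 1), str(f.end),
                ".", f.strand, "0", attrs]) + "\n")


# ---------------------------------------------------------------------------
# PAF

def _parse_tag(token: str, path: str, lineno: int) -> tuple[str, str, str]:
    parts = token.split(":", 2)
    if len(parts) != 3:
        raise ParseError(f"malformed tag {token!r}", path, lineno)
    return parts[0], parts[1], parts[2]


def read_paf(path: str | os.PathLike) -> list[PafAlignment]:
    """Parse a PAF file (≥12 mandatory columns plus optional typed tags)."""
    path = os.fspath(path)
    records: list[PafAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(f"expected ≥12 columns, got {len(cols)}", path, lineno)
            try:
                rec = PafAlignment(
                    qname=cols[0], qlen=int(cols[1]), qstart=int(cols[2]),
                    qend=int(cols[3]), strand=cols[4], tname=cols[5],
                    tlen=int(cols[6]), tstart=int(cols[7]), tend=int(cols[8]),
                    matches=int(cols[9]), block_len=int(cols[10]),
                    mapq=int(cols[11]),
                    tags={name: (typ, val)
                          for name, typ, val in
                          (_parse_tag(t, path, lineno) for t in cols[12:])},
                )
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None
            records.append(rec)
    return records


def write_paf(records: list[PafAlignment], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [r.qname, str(r.qlen), str(r.qstart), str(r.qend), r.strand,
                    r.tname, str(r.tlen), str(r.tstart), str(r.tend),
                    str(r.matches), str(r.block_len), str(r.mapq)]
            cols += [f"{name}:{typ}:{val}" for name, (typ, val) in r.tags.items()]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Expression tables (feature_id, TPM)

def read_expression_tsv(path: str | os.PathLike) -> dict[str, float]:
    path = os.fspath(path)
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("feature_id"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError("expected ≥2 tab-separated columns", path, lineno)
            try:
                table[cols[0]] = float(cols[1])
            except ValueError:
                raise ParseError(f"non-numeric TPM {cols[1]!r}", path, lineno) from None
    return table


def write_expression_tsv(table: dict[str, float], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\ttpm\n")
        for fid, tpm in table.items():
            fh.write(f"{fid}\t{tpm:.6g}\n")
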