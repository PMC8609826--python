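"""Sequence and table I/O helpers (Bio.SeqIO-backed)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profiling import MarkerSet, ProteinFamilyDB, ProteinRecord

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_reads",
    "write_family_fasta",
    "read_family_fasta",
    "write_marker_fasta",
]


def _records(pairs: Iterable[tuple[str, str]], quality: int | None = None):
    for seq_id, seq in pairs:
        rec = SeqRecord(Seq(seq), id=seq_id, description="")
        if quality is not None:
            rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        yield rec


def write_fasta(pairs: Iterable[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at 60 columns."""
    SeqIO.write(_records(pairs), str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fastq(pairs: Iterable[tuple[str, str]], path, quality: int = 40) -> None:
    """Write reads as FASTQ (Phred+33) with a constant quality."""
    SeqIO.write(_records(pairs, quality=quality), str(path), "fastq")


def read_reads(path) -> list[tuple[str, str]]:
    """Read a FASTA or FASTQ read set (format sniffed from suffix)."""
    p = Path(path)
    fmt = "fastq" if p.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(p), fmt)]


def write_family_fasta(db: ProteinFamilyDB, path) -> None:
    """FASTA with the family label carried in the description."""
    recs = (
        SeqRecord(Seq(r.sequence), id=r.seq_id, description=f"family={r.family}")
        for r in db.records
    )
    SeqIO.write(recs, str(path), "fasta")


def read_family_fasta(path) -> ProteinFamilyDB:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        family = ""
        for token in rec.description.split():
            if token.startswith("family="):
                family = token.removeprefix("family=")
        records.append(
            ProteinRecord(seq_id=rec.id, family=family, sequence=str(rec.seq))
        )
    return ProteinFamilyDB(records=records)


def write_marker_fasta(markers: MarkerSet, path) -> None:
    pairs = ((m.marker_id, m.peptide) for m in markers.markers)
    write_fasta(pairs, path)
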