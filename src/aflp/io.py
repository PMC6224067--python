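"""Readers and writers for the standard formats this toolkit touches.

Thin wrappers around Biopython's SeqIO: multi-record FASTA (wrapped
lines, CRLF tolerated) and FASTQ/FASTA reads, plain or gzip-compressed.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

from .ngs import Read

__all__ = ["read_fasta", "write_fasta", "read_reads", "read_groups"]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> dict[str, str]:
    """FASTA records as an ordered ``{id: sequence}`` dict."""
    with _open_text(path) as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in sequences.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_reads(path) -> list[Read]:
    """Sequencing reads from FASTQ or FASTA (by extension), gzip-tolerant."""
    path = Path(path)
    stem = path.name[:-3] if path.suffix == ".gz" else path.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        reads = []
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            reads.append(Read(rec.id, str(rec.seq).upper(), qual))
    return reads


def read_groups(path) -> dict[str, str]:
    """Two-column sample_id / label TSV (header optional)."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"groups file needs two columns, got {line!r}")
            if fields[0] == "sample_id":
                continue
            groups[fields[0]] = fields[1]
    return groups
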