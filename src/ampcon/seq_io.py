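"""Sequence containers and FASTQ/FASTA input/output.

Every other stage of the pipeline moves data through the two small types
defined here: :class:`SequenceRead` (a basecalled read with per-base Phred
scores) and :class:`ReferenceSequence` (a primer, index, or reference
barcode).  Phred encoding is fixed at ASCII offset 33, the dialect modern
nanopore basecallers emit.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Union

from Bio import SeqIO

__all__ = [
    "SequenceRead",
    "ReferenceSequence",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
]

PHRED_OFFSET = 33

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SequenceRead:
    """One basecalled read with per-base quality.

    ``orientation`` is ``"unknown"`` until demultiplexing or clustering
    assigns a strand; it is metadata only and never serialised to FASTQ.
    """

    read_id: str
    bases: str
    quals: List[int]
    orientation: str = "unknown"

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: bases ({len(self.bases)}) and quality "
                f"({len(self.quals)}) lengths differ"
            )
        if not set(self.bases) <= _DNA:
            bad = sorted(set(self.bases) - _DNA)
            raise ValueError(f"read {self.read_id!r}: non-DNA characters {bad}")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complemented(self) -> "SequenceRead":
        flipped = {"forward": "reverse", "reverse": "forward"}.get(
            self.orientation, "unknown"
        )
        return SequenceRead(
            self.read_id,
            reverse_complement(self.bases),
            list(reversed(self.quals)),
            orientation=flipped,
        )


@dataclass
class ReferenceSequence:
    """A named DNA sequence acting as amplicon reference, primer, or index."""

    name: str
    bases: str
    role: str = "amplicon_reference"

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        if not self.bases:
            raise ValueError(f"reference {self.name!r}: empty sequence")
        allowed = _DNA if self.role == "amplicon_reference" else set("ACGT")
        if not set(self.bases) <= allowed:
            raise ValueError(
                f"reference {self.name!r} (role {self.role}): invalid characters"
            )
        if self.role in ("primer", "index") and len(self.bases) >= 50:
            raise ValueError(f"{self.role} {self.name!r} must be < 50 nt")


def reverse_complement(bases: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}.

    A length-preserving involution: ``rc(rc(s)) == s``.
    """
    if not set(bases) <= _DNA:
        bad = sorted(set(bases) - _DNA)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return bases.translate(_COMPLEMENT)[::-1]


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: Union[str, Path]) -> List[SequenceRead]:
    """Read a FASTQ file (plain or gzipped) into a list of reads.

    Phred scores are decoded at ASCII offset 33 (the Sanger/modern
    dialect).  Order is preserved.  A record whose quality line does not
    match its sequence length raises ``ValueError`` naming the offending
    read.
    """
    reads: List[SequenceRead] = []
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fastq"):
            reads.append(
                SequenceRead(
                    record.id,
                    str(record.seq),
                    list(record.letter_annotations["phred_quality"]),
                )
            )
    return reads


def write_fastq(reads: Iterable[SequenceRead], path: Union[str, Path]) -> Path:
    """Write reads as offset-33 FASTQ; round-trips bit-exactly with read_fastq."""
    path = Path(path)
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.quals)
            handle.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")
    return path


def read_fasta(
    path: Union[str, Path], role: str = "amplicon_reference"
) -> List[ReferenceSequence]:
    """Read FASTA (wrapped or unwrapped); duplicate names are a hard error."""
    records: List[ReferenceSequence] = []
    seen = set()
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seen:
                raise ValueError(f"duplicate FASTA record name: {record.id!r}")
            seen.add(record.id)
            records.append(ReferenceSequence(record.id, str(record.seq), role=role))
    return records


def write_fasta(
    records: Sequence[ReferenceSequence], path: Union[str, Path], width: int = 0
) -> Path:
    """Write FASTA; ``width=0`` writes each sequence on a single line."""
    path = Path(path)
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.name}\n")
            if width and width > 0:
                for i in range(0, len(rec.bases), width):
                    handle.write(rec.bases[i : i + width] + "\n")
            else:
                handle.write(rec.bases + "\n")
    return path
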