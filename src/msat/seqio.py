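"""Reading FASTA/FASTQ read sets, transparently gzipped."""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

_GZIP_MAGIC = b"\x1f\x8b"


class SequenceInputError(ValueError):
    """Raised when a read file cannot be parsed as FASTA or FASTQ."""


def _open_text(path: Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "r")


def _detect_format(first_char: str, path: Path) -> str:
    if first_char == ">":
        return "fasta"
    if first_char == "@":
        return "fastq"
    raise SequenceInputError(f"{path}: not FASTA or FASTQ (starts with {first_char!r})")


def read_seqs(path) -> Iterator[tuple[str, str]]:
    """Yield ``(seq_id, sequence)`` pairs; id is taken up to first whitespace."""
    path = Path(path)
    with _open_text(path) as fh:
        head = fh.read(1)
        if not head:
            return
        fmt = _detect_format(head, path)
        fh.seek(0)
        for record in SeqIO.parse(fh, fmt):
            yield record.id, str(record.seq)


def write_fasta(reads, path, line_width: int = 80) -> None:
    """Write ``(seq_id, sequence)`` pairs as FASTA (gzipped if path ends .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for seq_id, seq in reads:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
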