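"""Streaming FASTA/FASTQ input and contig FASTA output.

Format is sniffed from the first byte of the (possibly gzipped)
content; records are parsed by Bio.SeqIO and yielded one at a time so
memory stays constant per record.  Qualities are carried through but
ignored downstream.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator, Optional, Sequence

from Bio import SeqIO


class SequenceFormatError(ValueError):
    pass


def _open_text(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic[:2] == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path) -> Iterator[tuple[str, str, Optional[str]]]:
    """Yield (id, sequence, quality-or-None) for each record of a FASTA
    or FASTQ file, plain or gzipped.  Wrapped FASTA lines are
    concatenated; an empty file yields nothing."""
    path = Path(path)
    fh = _open_text(path)
    try:
        first = fh.read(1)
        if first == "":
            return
        fh.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise SequenceFormatError(
                f"{path}: cannot determine format (starts with {first!r})"
            )
        try:
            for rec in SeqIO.parse(fh, fmt):
                qual = None
                if fmt == "fastq":
                    qual = rec.letter_annotations.get("phred_quality")
                yield rec.id, str(rec.seq).upper(), qual
        except ValueError as exc:
            raise SequenceFormatError(f"{path}: malformed {fmt} record: {exc}") from exc
    finally:
        fh.close()


def read_sequence_strings(path) -> Iterator[str]:
    """Just the nucleotide strings (what k-mer counting consumes)."""
    for _, seq, _ in read_sequences(path):
        yield seq


def write_contigs(contigs: Sequence, path, width: int = 80) -> None:
    """Write contigs as FASTA, 80-column wrapped, headers
    ``>contig_<i> len=<L>``; deterministic order as given."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, c in enumerate(contigs):
            fh.write(f">contig_{i} len={c.length}\n")
            for j in range(0, c.length, width):
                fh.write(c.sequence[j : j + width] + "\n")


def write_reads_fastq(reads: Sequence[str], path) -> None:
    """Write simulated reads as FASTQ (constant quality), gzipped if
    the path ends in .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@read_{i}\n{r}\n+\n{'I' * len(r)}\n")


def write_fasta(records: Sequence[tuple[str, str]], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for j in range(0, len(seq), width):
                fh.write(seq[j : j + width] + "\n")
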