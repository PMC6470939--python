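"""Shared sequence helpers: alphabet normalization, reverse complement, light I/O.

All sequences are stored internally in the DNA alphabet (U -> T, uppercase).
RNA input is accepted everywhere and normalized on entry.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA2DNA = str.maketrans("acgtuU", "ACGTTT")

DNA_BASES = "ACGT"


def normalize(seq: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet."""
    return seq.translate(_RNA2DNA)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content of *seq* on a 0-100 scale."""
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def check_alphabet(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"empty {what}")
    if set(seq) - set(DNA_BASES):
        bad = sorted(set(seq) - set(DNA_BASES))
        raise ValueError(f"{what} contains non-ACGT characters: {bad}")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (header, sequence) pairs; sequence normalized to DNA alphabet."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.description, normalize(str(rec.seq))


def read_fastq_seqs(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (fast path, qualities ignored)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield normalize(seq)


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str | Path, reads: Iterable[str], prefix: str = "read") -> None:
    """Write reads with constant Phred+33 quality 'I' (Q40)."""
    with open(path, "w") as fh:
        chunk: list[str] = []
        for i, seq in enumerate(reads, start=1):
            chunk.append(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
            if len(chunk) >= 100_000:
                fh.write("".join(chunk))
                chunk = []
        fh.write("".join(chunk))
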