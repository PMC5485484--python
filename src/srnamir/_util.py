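"""Shared helpers: sequence ops, half-up rounding, FASTA/FASTQ io."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

_COMP = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA output; U treated as T)."""
    return seq.translate(_COMP)[::-1]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, as printed in the summary tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    if whole == 0:
        raise ValueError("cannot take a percentage of a zero total")
    return round_half_up(100.0 * part / whole, ndigits)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, sequence, quality-string) triples as Sanger FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality-string); raises on malformed records."""
    with open(path) as fh:
        for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
            if len(seq) != len(qual):
                raise ValueError(f"FASTQ record {i} ({title}): seq/qual length mismatch")
            yield title.split()[0], seq.upper(), qual
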