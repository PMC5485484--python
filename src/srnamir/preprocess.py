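"""Raw FASTQ to clean, length-selected, collapsed unique tags.

Cleaning policy (documented defaults, exposed as parameters):

* high-quality = mean Phred >= ``quality_floor`` (default 20);
* the 3' adapter is trimmed at the leftmost position where its prefix
  matches with at most one mismatch over an overlap of >= 6 nt; reads
  with no adapter hit are kept only if already within the size range;
* reads containing ambiguous N bases are discarded;
* poly(A) reads — a run of >= 8 consecutive A, or >= 80% A content after
  trimming — are discarded;
* insert length must fall in [min_len, max_len] (default 18-30 nt).

Every removal reason is counted so raw = clean + sum(removals) holds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from ._util import percent, read_fastq

__all__ = [
    "UniqueTag",
    "CleaningStats",
    "clean_reads",
    "collapse_tags",
    "length_distribution",
]

REMOVAL_REASONS = ("low_quality", "no_adapter", "ambiguous", "poly_a", "too_short", "too_long")


@dataclass
class UniqueTag:
    """A distinct small-RNA sequence with per-library raw counts."""

    sequence: str
    count_control: int = 0
    count_treated: int = 0

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGTU"):
            raise ValueError(f"tag has non-nucleotide symbols: {self.sequence!r}")
        if self.count_control < 0 or self.count_treated < 0:
            raise ValueError("negative tag count")

    @property
    def total(self) -> int:
        return self.count_control + self.count_treated


@dataclass
class CleaningStats:
    """Per-library read-cleaning accounting."""

    raw_reads: int = 0
    removed: Counter = field(default_factory=Counter)
    length_histogram: Counter = field(default_factory=Counter)

    @property
    def high_quality_reads(self) -> int:
        return self.raw_reads - self.removed["low_quality"]

    @property
    def clean_reads(self) -> int:
        return self.raw_reads - sum(self.removed.values())

    @property
    def clean_fraction_of_high_quality(self) -> float:
        """Clean / high-quality reads as a percentage, 2 decimals half-up."""
        return percent(self.clean_reads, self.high_quality_reads)

    def validate(self) -> None:
        assert self.clean_reads <= self.high_quality_reads <= self.raw_reads
        assert sum(self.length_histogram.values()) == self.clean_reads

    def __add__(self, other: "CleaningStats") -> "CleaningStats":
        return CleaningStats(
            self.raw_reads + other.raw_reads,
            self.removed + other.removed,
            self.length_histogram + other.length_histogram,
        )


def _find_adapter(seq: str, adapter: str, min_overlap: int = 6, max_mismatch: int = 1) -> int:
    """Leftmost 3'-adapter start in ``seq``; -1 if absent.

    Fast path: exact match of the (possibly truncated) adapter prefix;
    positions left of the exact hit are then rescanned allowing one
    mismatch, so the reported position is the true leftmost match.
    """
    n = len(seq)
    limit = n - min_overlap
    exact = seq.find(adapter[: min(len(adapter), n)])
    if exact < 0:
        # the adapter may be truncated by the read end
        for i in range(max(0, n - len(adapter) + 1), limit + 1):
            if seq[i:] == adapter[: n - i]:
                exact = i
                break
    hi = exact if exact >= 0 else limit + 1
    for i in range(0, min(hi, limit + 1)):
        overlap = min(len(adapter), n - i)
        mism = 0
        for a, b in zip(seq[i : i + overlap], adapter):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return i
    return exact


def clean_reads(
    reads: str | Path | Iterable[tuple[str, str, str]],
    adapter: str,
    min_len: int = 18,
    max_len: int = 30,
    quality_floor: float = 20.0,
) -> tuple[list[str], CleaningStats]:
    """Clean one library; returns (clean insert sequences, stats).

    ``reads`` is a FASTQ path or an iterable of (id, seq, qual) triples.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    it: Iterator[tuple[str, str, str]]
    it = read_fastq(reads) if isinstance(reads, (str, Path)) else iter(reads)
    stats = CleaningStats()
    clean: list[str] = []
    for _name, seq, qual in it:
        stats.raw_reads += 1
        q = np.frombuffer(qual.encode(), dtype=np.uint8)
        if q.size == 0 or q.mean() - 33.0 < quality_floor:
            stats.removed["low_quality"] += 1
            continue
        pos = _find_adapter(seq, adapter)
        if pos < 0:
            if len(seq) > max_len:
                stats.removed["no_adapter"] += 1
                continue
            insert = seq
        else:
            insert = seq[:pos]
        if "N" in insert:
            stats.removed["ambiguous"] += 1
            continue
        n = len(insert)
        if n and ("A" * 8 in insert or insert.count("A") / n >= 0.8):
            stats.removed["poly_a"] += 1
            continue
        if n < min_len:
            stats.removed["too_short"] += 1
            continue
        if n > max_len:
            stats.removed["too_long"] += 1
            continue
        clean.append(insert)
        stats.length_histogram[n] += 1
    stats.validate()
    return clean, stats


def collapse_tags(clean_control: Iterable[str], clean_treated: Iterable[str]) -> list[UniqueTag]:
    """Collapse cleaned reads of the two libraries into unique tags.

    Sum of tag counts per library equals that library's clean-read total.
    Tags are ordered by pooled abundance (desc), then sequence.
    """
    cw = Counter(clean_control)
    ct = Counter(clean_treated)
    tags = [
        UniqueTag(seq, cw.get(seq, 0), ct.get(seq, 0))
        for seq in set(cw) | set(ct)
    ]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def length_distribution(tags: list[UniqueTag], min_len: int = 18, max_len: int = 30) -> pd.DataFrame:
    """Per-length unique/total tag counts and percentages for each library."""
    if not tags:
        raise ValueError("no tags to summarize")
    rows = []
    totals = {
        "unique_control": sum(1 for t in tags if t.count_control),
        "total_control": sum(t.count_control for t in tags),
        "unique_treated": sum(1 for t in tags if t.count_treated),
        "total_treated": sum(t.count_treated for t in tags),
    }
    for L in range(min_len, max_len + 1):
        sub = [t for t in tags if len(t.sequence) == L]
        row = {"length": L}
        for key, val in (
            ("unique_control", sum(1 for t in sub if t.count_control)),
            ("total_control", sum(t.count_control for t in sub)),
            ("unique_treated", sum(1 for t in sub if t.count_treated)),
            ("total_treated", sum(t.count_treated for t in sub)),
        ):
            row[key] = val
            row[f"{key}_pct"] = percent(val, totals[key]) if totals[key] else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
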