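"""Hierarchical tag annotation and conserved-miRNA identification.

Tags are assigned exactly one category with precedence
miRNA > rRNA > tRNA > snRNA > snoRNA > unannotated.  A tag is a
conserved miRNA if an ungapped, 5'-flush comparison against some known
mature (length difference <= 2 nt, overhangs free) shows at most
``max_mismatch`` substitutions; noncoding families are matched by exact
substring only.  scRNA entries, if present in the reference, are folded
into the snRNA bucket.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from ._util import percent, revcomp
from .preprocess import UniqueTag

__all__ = [
    "ConservedMirnaCall",
    "AnnotationRecord",
    "match_known_mirnas",
    "classify_noncoding",
    "annotate_tags",
    "category_table",
    "CATEGORIES",
]

CATEGORIES = ("miRNA", "rRNA", "snRNA", "snoRNA", "tRNA", "unann")
_NONCODING_PRECEDENCE = ("rRNA", "tRNA", "snRNA", "snoRNA")
_FAMILY_RE = re.compile(r"(miR[0-9]+)", re.IGNORECASE)


@dataclass
class ConservedMirnaCall:
    """A tag identified as a known (conserved) mature miRNA."""

    mature: str
    known_id: str
    family: str
    mismatches: int
    has_star: bool
    count_control: int = 0
    count_treated: int = 0

    def __post_init__(self) -> None:
        if self.mismatches > 2:
            raise ValueError("conserved call with > 2 mismatches")
        if not 18 <= len(self.mature) <= 30:
            raise ValueError("mature length outside 18-30 nt")


@dataclass
class AnnotationRecord:
    tag: UniqueTag
    category: str
    matched_reference: str | None = None
    mismatches: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _flush5_mismatches(tag: str, ref: str, max_len_diff: int = 2) -> int | None:
    """Substitutions over the 5'-flush overlap, or None if lengths differ > 2."""
    if abs(len(tag) - len(ref)) > max_len_diff:
        return None
    n = min(len(tag), len(ref))
    return sum(1 for a, b in zip(tag[:n], ref[:n]) if a != b)


def _family(known_id: str) -> str:
    m = _FAMILY_RE.search(known_id)
    return m.group(1) if m else known_id


def _looks_like_star(candidate: str, mature: str, max_shift: int = 2, max_mismatch: int = 4) -> bool:
    """Does ``candidate`` look like the duplex partner (miRNA*) of ``mature``?

    The reverse complement of a star overlays the mature up to the 2-nt
    3' overhangs of the duplex, so we slide it within +-``max_shift`` nt
    and accept <= ``max_mismatch`` substitutions over the overlap.
    """
    if candidate == mature or abs(len(candidate) - len(mature)) > 4:
        return False
    rc = revcomp(candidate)
    for shift in range(-max_shift, max_shift + 1):
        mism = 0
        overlap = 0
        for i, c in enumerate(rc):
            j = i + shift
            if 0 <= j < len(mature):
                overlap += 1
                if c != mature[j]:
                    mism += 1
        if overlap >= len(mature) - 2 * max_shift and mism <= max_mismatch:
            return True
    return False


def match_known_mirnas(
    tags: list[UniqueTag],
    known_matures: dict[str, str],
    max_mismatch: int = 2,
) -> list[ConservedMirnaCall]:
    """Identify conserved miRNAs among the tags.

    Ties are broken by fewest mismatches, then lexicographically smallest
    reference id.  Star presence is flagged when some other tag looks
    like the duplex partner of the called mature.
    """
    if not known_matures:
        raise ValueError("known-mature reference is empty")
    calls: list[ConservedMirnaCall] = []
    ref_ids = sorted(known_matures)
    for tag in tags:
        if not 18 <= len(tag.sequence) <= 30:
            continue
        best: tuple[int, str] | None = None
        for kid in ref_ids:
            mism = _flush5_mismatches(tag.sequence, known_matures[kid])
            if mism is not None and mism <= max_mismatch:
                if best is None or (mism, kid) < best:
                    best = (mism, kid)
        if best is not None:
            calls.append(
                ConservedMirnaCall(
                    mature=tag.sequence,
                    known_id=best[1],
                    family=_family(best[1]),
                    mismatches=best[0],
                    has_star=False,
                    count_control=tag.count_control,
                    count_treated=tag.count_treated,
                )
            )
    sequences = [t.sequence for t in tags]
    for call in calls:
        call.has_star = any(_looks_like_star(s, call.mature) for s in sequences)
    return calls


def classify_noncoding(tag_sequence: str, noncoding: dict[str, dict[str, str]]) -> tuple[str, str] | None:
    """First (family, reference id) whose sequence contains the tag, or None.

    Families are checked in the fixed precedence order
    rRNA > tRNA > snRNA > snoRNA (scRNA references count as snRNA).
    """
    for fam in _NONCODING_PRECEDENCE:
        members = dict(noncoding.get(fam, {}))
        if fam == "snRNA":
            members.update(noncoding.get("scRNA", {}))
        for rid in sorted(members):
            if tag_sequence in members[rid]:
                return fam, rid
    return None


def annotate_tags(
    tags: list[UniqueTag],
    known_matures: dict[str, str],
    noncoding: dict[str, dict[str, str]],
    max_mismatch: int = 2,
) -> tuple[list[AnnotationRecord], list[ConservedMirnaCall]]:
    """Assign every tag exactly one category; returns (records, conserved calls)."""
    calls = match_known_mirnas(tags, known_matures, max_mismatch=max_mismatch)
    by_seq = {c.mature: c for c in calls}
    records: list[AnnotationRecord] = []
    for tag in tags:
        call = by_seq.get(tag.sequence)
        if call is not None:
            records.append(AnnotationRecord(tag, "miRNA", call.known_id, call.mismatches))
            continue
        hit = classify_noncoding(tag.sequence, noncoding)
        if hit is not None:
            records.append(AnnotationRecord(tag, hit[0], hit[1]))
        else:
            records.append(AnnotationRecord(tag, "unann"))
    return records, calls


def category_table(records: list[AnnotationRecord]) -> pd.DataFrame:
    """Per-library unique/total counts and percentages by category.

    Columns mirror the standard sRNA summary table: unique and total tag
    counts for each library with percentages of the library total,
    rounded half-up to two decimals; the Total row closes the table.
    """
    if not records:
        raise ValueError("no annotation records")
    counts = {cat: {"uc": 0, "tc": 0, "ut": 0, "tt": 0} for cat in CATEGORIES}
    for rec in records:
        c = counts[rec.category]
        if rec.tag.count_control:
            c["uc"] += 1
            c["tc"] += rec.tag.count_control
        if rec.tag.count_treated:
            c["ut"] += 1
            c["tt"] += rec.tag.count_treated
    tot = {k: sum(counts[cat][k] for cat in CATEGORIES) for k in ("uc", "tc", "ut", "tt")}
    rows = []
    for cat in CATEGORIES + ("Total",):
        c = tot if cat == "Total" else counts[cat]
        rows.append(
            {
                "category": cat,
                "unique_control": c["uc"],
                "unique_control_pct": percent(c["uc"], tot["uc"]) if tot["uc"] else 0.0,
                "total_control": c["tc"],
                "total_control_pct": percent(c["tc"], tot["tc"]) if tot["tc"] else 0.0,
                "unique_treated": c["ut"],
                "unique_treated_pct": percent(c["ut"], tot["ut"]) if tot["ut"] else 0.0,
                "total_treated": c["tt"],
                "total_treated_pct": percent(c["tt"], tot["tt"]) if tot["tt"] else 0.0,
            }
        )
    return pd.DataFrame(rows)
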