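"""Degradome tag classification, miRNA target alignment and t-plot categories.

Tags (collapsed sequence/count pairs) are annotated with precedence
rRNA > tRNA > snRNA > snoRNA > poly(N) > cDNA_sense > cDNA_antisense >
other; sense-mapped tags build per-transcript 5'-end abundance profiles.
miRNAs are aligned antiparallel to transcripts with the standard plant
target penalty scheme (mismatch 1, G:U wobble 0.5, doubled over miRNA
positions 2-13, cutoff 4.5; the search is over gapless duplexes).  A
candidate duplex becomes a target hit when degradome tags start exactly
opposite miRNA positions 10-11, and the hit is ranked by the t-plot
category of that site within the transcript profile:

    4  exactly one raw read at the site;
    0  the site is the unique profile maximum;
    1  the site ties the maximum with >= 2 positions;
    2  below the maximum but above the median (of positions with >= 1 read);
    3  at or below the median, more than one read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import percent, revcomp

__all__ = [
    "DegradomeTag",
    "TargetHit",
    "classify_degradome_tags",
    "degradome_table",
    "align_mirna_targets",
    "call_cleavage",
    "tplot_table",
]

DEGRADOME_CATEGORIES = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "polyN",
    "cDNA_sense",
    "cDNA_antisense",
    "other",
)


@dataclass
class DegradomeTag:
    sequence: str
    count: int
    annotation: str
    transcript_id: str | None = None
    position: int | None = None     # 5'-end, 0-based, sense strand

    def __post_init__(self) -> None:
        if self.annotation not in DEGRADOME_CATEGORIES:
            raise ValueError(f"unknown degradome annotation {self.annotation!r}")


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    score: float
    alignment: str
    cleavage_pos: int
    site_abundance: int
    profile: dict[int, int] = field(repr=False)
    category: int = -1
    transcript_length: int = 0

    def __post_init__(self) -> None:
        if self.category not in (-1, 0, 1, 2, 3, 4):
            raise ValueError("category must be 0-4")


def _is_polyn(seq: str) -> bool:
    return "N" * 5 in seq or (len(seq) > 0 and seq.count("N") / len(seq) >= 0.10)


def _position_index(transcripts: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        for p in range(len(seq) - k + 1):
            index.setdefault(seq[p : p + k], []).append((tid, p))
    return index


def classify_degradome_tags(
    tags: list[tuple[str, int]],
    noncoding: dict[str, dict[str, str]],
    transcripts: dict[str, str],
    map_length: int = 20,
) -> list[DegradomeTag]:
    """Annotate one degradome library of (sequence, count) pairs.

    Tags are truncated to their first ``map_length`` nt for transcript
    mapping; the first sense occurrence assigns transcript and position.
    """
    index = _position_index(transcripts, map_length)
    fam_concat = {
        fam: "|".join(noncoding.get(fam, {}).values()) for fam in ("rRNA", "tRNA", "snRNA", "snoRNA")
    }
    out: list[DegradomeTag] = []
    for seq, count in tags:
        seq = seq.upper()
        head = seq[:map_length]
        ann, tid, pos = None, None, None
        for fam in ("rRNA", "tRNA", "snRNA", "snoRNA"):
            if seq in fam_concat[fam] and "|" not in seq:
                ann = fam
                break
        if ann is None and _is_polyn(seq):
            ann = "polyN"
        if ann is None:
            hit = index.get(head)
            if hit:
                ann, (tid, pos) = "cDNA_sense", hit[0]
            elif index.get(revcomp(head)):
                ann = "cDNA_antisense"
            else:
                ann = "other"
        out.append(DegradomeTag(seq, count, ann, tid, pos))
    return out


def degradome_table(libraries: dict[str, list[DegradomeTag]]) -> pd.DataFrame:
    """Unique/total tag counts and percentages per category and library."""
    if not libraries:
        raise ValueError("no degradome libraries")
    rows = []
    per_lib: dict[str, dict[str, dict[str, int]]] = {}
    for lib, tags in libraries.items():
        cat = {c: {"unique": 0, "total": 0} for c in DEGRADOME_CATEGORIES}
        for t in tags:
            cat[t.annotation]["unique"] += 1
            cat[t.annotation]["total"] += t.count
        per_lib[lib] = cat
    for c in DEGRADOME_CATEGORIES + ("Total",):
        row = {"category": c if c != "other" else "Other"}
        for lib, cat in per_lib.items():
            uu = sum(v["unique"] for v in cat.values())
            tt = sum(v["total"] for v in cat.values())
            u = uu if c == "Total" else cat[c]["unique"]
            t = tt if c == "Total" else cat[c]["total"]
            row[f"unique_{lib}"] = u
            row[f"unique_{lib}_pct"] = percent(u, uu) if uu else 0.0
            row[f"total_{lib}"] = t
            row[f"total_{lib}_pct"] = percent(t, tt) if tt else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# penalty lookup: rows = miRNA base (ACGT; U as T), cols = transcript base
_PEN = np.ones((4, 4), dtype=float)
_ORD = {"A": 0, "C": 1, "G": 2, "T": 3}
for _m, _t in (("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")):
    _PEN[_ORD[_m], _ORD[_t]] = 0.0
_PEN[_ORD["G"], _ORD["T"]] = 0.5   # G:U wobble
_PEN[_ORD["T"], _ORD["G"]] = 0.5


def _encode_dna(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().replace("U", "T").encode(), dtype=np.uint8)


def align_mirna_targets(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    max_score: float = 4.5,
) -> list[dict]:
    """Score every gapless antiparallel miRNA/transcript duplex.

    Penalties per miRNA position (1-based from the miRNA 5' end):
    mismatch 1, G:U 0.5, doubled over the seed-to-cleavage core 2-13.
    Candidates scoring <= ``max_score`` are returned with the duplex
    window and an alignment rendering (target 5'->3' on top).
    """
    lut = np.zeros((256, 256), dtype=float)
    bytes_of = {b: ord(b) for b in "ACGT"}
    for mb, mi in _ORD.items():
        for tb, ti in _ORD.items():
            lut[bytes_of[mb], bytes_of[tb]] = _PEN[mi, ti]
    out: list[dict] = []
    for mid in sorted(mirnas):
        mseq = mirnas[mid].upper().replace("U", "T")
        L = len(mseq)
        if not 18 <= L <= 30:
            raise ValueError(f"miRNA {mid} length {L} outside 18-30 nt")
        menc = _encode_dna(mseq)
        weights = np.where((np.arange(1, L + 1) >= 2) & (np.arange(1, L + 1) <= 13), 2.0, 1.0)
        for tid in sorted(transcripts):
            tenc = _encode_dna(transcripts[tid])
            if len(tenc) < L:
                continue
            win = np.lib.stride_tricks.sliding_window_view(tenc, L)[:, ::-1]
            # win[p, q-1] pairs miRNA position q with transcript base p+L-q
            pen = lut[menc[None, :], win]
            scores = pen @ weights
            for p in np.nonzero(scores <= max_score)[0]:
                out.append(
                    {
                        "mirna_id": mid,
                        "transcript_id": tid,
                        "window_start": int(p),
                        "score": float(scores[p]),
                        "alignment": _render_alignment(mseq, transcripts[tid][p : p + L]),
                    }
                )
    out.sort(key=lambda h: (h["score"], h["mirna_id"], h["transcript_id"], h["window_start"]))
    return out


def score_duplex(mirna: str, target_window: str) -> float:
    """Reference scorer for a single gapless duplex (same scheme)."""
    mseq = mirna.upper().replace("U", "T")
    tseq = target_window.upper().replace("U", "T")
    if len(mseq) != len(tseq):
        raise ValueError("window length must equal miRNA length")
    L = len(mseq)
    total = 0.0
    for q in range(1, L + 1):
        pen = _PEN[_ORD[mseq[q - 1]], _ORD[tseq[L - q]]]
        total += pen * (2.0 if 2 <= q <= 13 else 1.0)
    return total


def _render_alignment(mirna: str, window: str) -> str:
    L = len(mirna)
    bonds = []
    for q in range(1, L + 1):
        pen = _PEN[_ORD[mirna[q - 1]], _ORD[window[L - q]]]
        bonds.append("|" if pen == 0 else "o" if pen == 0.5 else " ")
    return (
        f"target 5' {window} 3'\n"
        f"          {''.join(reversed(bonds))}\n"
        f"miRNA  3' {mirna[::-1]} 5'"
    )


def call_cleavage(
    candidates: list[dict],
    tags: list[DegradomeTag],
    transcripts: dict[str, str],
    mirna_lengths: dict[str, int] | None = None,
) -> list[TargetHit]:
    """Turn candidate duplexes into categorized cleavage-site hits.

    Site abundance sums the counts of sense-mapped tags whose 5' end sits
    opposite miRNA positions 10-11; duplexes with no tag at the site are
    dropped.  Categories follow the module docstring; the median is taken
    over positions with at least one read.
    """
    profiles: dict[str, dict[int, int]] = {}
    for t in tags:
        if t.annotation == "cDNA_sense" and t.transcript_id is not None:
            prof = profiles.setdefault(t.transcript_id, {})
            prof[t.position] = prof.get(t.position, 0) + t.count
    hits: list[TargetHit] = []
    for cand in candidates:
        tid = cand["transcript_id"]
        prof = profiles.get(tid, {})
        L = (
            mirna_lengths[cand["mirna_id"]]
            if mirna_lengths is not None
            else len(cand["alignment"].splitlines()[0].split()[2])
        )
        site = cand["window_start"] + L - 10
        abundance = prof.get(site, 0)
        if abundance == 0:
            continue
        values = np.array(list(prof.values()))
        vmax = values.max()
        median = float(np.median(values))
        if abundance == 1:
            category = 4
        elif abundance == vmax:
            category = 0 if (values == vmax).sum() == 1 else 1
        elif abundance > median:
            category = 2
        else:
            category = 3
        hits.append(
            TargetHit(
                mirna_id=cand["mirna_id"],
                transcript_id=tid,
                score=cand["score"],
                alignment=cand["alignment"],
                cleavage_pos=site,
                site_abundance=int(abundance),
                profile=dict(sorted(prof.items())),
                category=category,
                transcript_length=len(transcripts[tid]),
            )
        )
    return hits


def tplot_table(hit: TargetHit) -> pd.DataFrame:
    """Per-position abundance table of a hit's transcript (t-plot data)."""
    if not hit.profile:
        raise ValueError("hit has an empty tag profile")
    n = hit.transcript_length or max(hit.profile) + 1
    rows = [
        {
            "position": p,
            "abundance": hit.profile.get(p, 0),
            "is_cleavage_site": p == hit.cleavage_pos,
        }
        for p in range(n)
    ]
    return pd.DataFrame(rows)
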