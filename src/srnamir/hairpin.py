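"""Novel miRNA prediction from unannotated tags.

Unannotated tags are placed on the reference transcripts by exact match,
candidate precursor windows are excised around each placement (the tag
plus a 150 nt flank on either side), folded, and accepted as novel
miRNAs under plant-annotation hairpin criteria:

i.   the structure around the mature is a single stem-loop (exactly one
     terminal loop on the path covering the mature);
ii.  the mature lies entirely in one arm, at least 2 nt from the loop;
iii. at most 4 mature bases are unpaired against the star region, and
     bulges inside the duplex are at most 2 nt asymmetric;
iv.  precursor MFE <= -18 kcal/mol;
v.   mature read count >= 5 summed over the libraries.

All five thresholds are parameters.  A star is flagged when some tag
occupies the expected miRNA* position (2-nt duplex offset, +-2 nt
tolerance).  Overlapping windows that yield the same mature are
deduplicated, keeping the lowest-energy precursor.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fold import HairpinStructure, fold, structure_energy
from .preprocess import UniqueTag

__all__ = [
    "CandidateWindow",
    "NovelMirnaCall",
    "extract_precursors",
    "call_novel",
    "predict_novel",
]


@dataclass
class CandidateWindow:
    tag: UniqueTag
    transcript_id: str
    tag_start: int          # position of the tag on the transcript
    window_start: int       # 0-based half-open window on the transcript
    window_end: int
    sequence: str

    @property
    def mature_offset(self) -> int:
        return self.tag_start - self.window_start


@dataclass
class NovelMirnaCall:
    mature: str
    star: str | None
    precursor: HairpinStructure
    arm: str                      # "5p" | "3p"
    count_control: int
    count_treated: int
    transcript_id: str
    precursor_start: int          # on the transcript

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be 5p or 3p, got {self.arm!r}")

    @property
    def precursor_length(self) -> int:
        return len(self.precursor.sequence)

    @property
    def mfe(self) -> float:
        return self.precursor.mfe


def _occurrences(needle: str, haystack: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i >= 0:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def extract_precursors(
    tags: list[UniqueTag],
    transcripts: dict[str, str],
    flank: int = 150,
) -> list[CandidateWindow]:
    """Candidate precursor windows around exact tag placements.

    For every exact (ungapped, mismatch-free) occurrence of a tag on a
    transcript, two windows are emitted: one extending ``flank`` nt
    upstream of the tag and one extending downstream, both clipped to
    the transcript bounds.  Tags mapping nowhere are skipped.
    """
    windows: list[CandidateWindow] = []
    for tag in tags:
        for tid in sorted(transcripts):
            seq = transcripts[tid]
            for s in _occurrences(tag.sequence, seq):
                e = s + len(tag.sequence)
                for ws, we in ((max(0, s - flank), e), (s, min(len(seq), e + flank))):
                    windows.append(CandidateWindow(tag, tid, s, ws, we, seq[ws:we]))
    return windows


def _enclosing_pair(pairs: dict[int, int], a: int, b: int) -> tuple[int, int] | None:
    """Outermost pair (i, j) spanning the paired portion of the mature [a, b).

    The stem-loop path covering the mature is defined by its paired
    bases: unpaired dangles at the mature ends (budgeted separately by
    the max-unpaired criterion) do not have to be enclosed, and the stem
    may begin exactly on the first paired mature base — the candidate
    windows place the tag flush against one window edge.  Ties prefer
    the widest span.
    """
    anchored = [p for p in range(a, b) if p in pairs]
    if not anchored:
        return None
    lo, hi = anchored[0], anchored[-1]
    best = None
    for i, j in pairs.items():
        if i < j and i <= lo and j >= hi:
            if best is None or (i, -j) < (best[0], -best[1]):
                best = (i, j)
    return best


def _duplex_geometry_ok(pairs: dict[int, int], a: int, b: int, max_unpaired: int, max_bulge: int) -> bool:
    """Criterion iii on the mature span [a, b)."""
    paired = [p for p in range(a, b) if p in pairs]
    if (b - a) - len(paired) > max_unpaired:
        return False
    for p, q in zip(paired, paired[1:]):
        dp = q - p
        dq = pairs[p] - pairs[q]
        if dq <= 0:  # partners must run antiparallel through one duplex
            return False
        if abs(dp - dq) > max_bulge:
            return False
    return True


def call_novel(
    windows: list[CandidateWindow],
    all_tags: list[UniqueTag] | None = None,
    mfe_max: float = -18.0,
    max_unpaired_mature: int = 4,
    max_bulge: int = 2,
    min_count: int = 5,
    min_loop_distance: int = 2,
) -> list[NovelMirnaCall]:
    """Apply the hairpin criteria to candidate windows.

    ``all_tags`` (defaulting to the window tags) supplies the tag pool
    searched for miRNA* evidence.
    """
    tag_pool = all_tags if all_tags is not None else [w.tag for w in windows]
    calls: dict[str, NovelMirnaCall] = {}
    fold_cache: dict[str, HairpinStructure] = {}
    seen: set[tuple[str, str]] = set()
    for w in windows:
        if w.tag.total < min_count:
            continue
        key = (w.sequence, w.tag.sequence)
        if key in seen:
            continue
        seen.add(key)
        if w.sequence not in fold_cache:
            fold_cache[w.sequence] = fold(w.sequence)
        st = fold_cache[w.sequence]
        a, b = w.mature_offset, w.mature_offset + len(w.tag.sequence)
        outer = _enclosing_pair(st.pairs, a, b)
        if outer is None:
            continue
        oi, oj = outer
        loops = [sp for sp in st.hairpin_loops() if oi < sp[0] and sp[1] <= oj]
        if len(loops) != 1:
            continue
        ls, le = loops[0]
        if b <= ls - min_loop_distance:
            arm = "5p"
        elif a >= le + min_loop_distance:
            arm = "3p"
        else:
            continue
        if not _duplex_geometry_ok(st.pairs, a, b, max_unpaired_mature, max_bulge):
            continue
        # excised precursor always covers the whole mature, including any
        # unpaired dangle outside the outermost stem pair
        oi, oj = min(oi, a), max(oj, b - 1)
        sub_pairs = [
            (i - oi, j - oi) for i, j in st.pairs.items() if i < j and oi <= i and j <= oj
        ]
        prec_seq = w.sequence[oi : oj + 1]
        prec_mfe = structure_energy(prec_seq, sub_pairs)
        if prec_mfe > mfe_max:
            continue
        db = ["."] * len(prec_seq)
        for i, j in sub_pairs:
            db[i], db[j] = "(", ")"
        prec = HairpinStructure(
            prec_seq, "".join(db), prec_mfe, {k - oi: v - oi for k, v in st.pairs.items() if oi <= min(k, v) and max(k, v) <= oj}
        )
        star = _find_star(w, st, a, b, tag_pool)
        call = NovelMirnaCall(
            mature=w.tag.sequence,
            star=star,
            precursor=prec,
            arm=arm,
            count_control=w.tag.count_control,
            count_treated=w.tag.count_treated,
            transcript_id=w.transcript_id,
            precursor_start=w.window_start + oi,
        )
        old = calls.get(call.mature)
        if old is None or call.mfe < old.mfe:
            calls[call.mature] = call
    return sorted(calls.values(), key=lambda c: c.mature)


def _find_star(
    w: CandidateWindow,
    st: HairpinStructure,
    a: int,
    b: int,
    tag_pool: list[UniqueTag],
    tolerance: int = 2,
) -> str | None:
    """Tag sitting at the expected miRNA* position (+-2 nt), if any."""
    paired = [p for p in range(a, b) if p in st.pairs]
    if not paired:
        return None
    expected_start = st.pairs[paired[-1]] + 2
    for tag in tag_pool:
        if tag.sequence == w.tag.sequence or abs(len(tag.sequence) - (b - a)) > 4:
            continue
        for s in _occurrences(tag.sequence, w.sequence):
            if abs(s - expected_start) <= tolerance:
                return tag.sequence
    return None


def predict_novel(
    unann_tags: list[UniqueTag],
    transcripts: dict[str, str],
    flank: int = 150,
    **criteria,
) -> list[NovelMirnaCall]:
    """Convenience wrapper: extract windows, fold, and call."""
    windows = extract_precursors(unann_tags, transcripts, flank=flank)
    return call_novel(windows, all_tags=unann_tags, **criteria)
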