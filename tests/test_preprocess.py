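"""Read cleaning, tag collapsing and the length distribution."""

from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from srnamir import preprocess
from srnamir.preprocess import CleaningStats, UniqueTag, clean_reads, collapse_tags

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
HQ = "I"


def _read(seq, qual_char=HQ, name="r"):
    return (name, seq, qual_char * len(seq))


def test_exact_adapter_is_trimmed_and_insert_kept():
    insert = "ACGTACGTACGTACGTACGTA"  # 21 nt
    clean, stats = clean_reads([_read(insert + ADAPTER)], ADAPTER)
    assert clean == [insert]
    assert stats.clean_reads == 1 and stats.length_histogram[21] == 1


def test_one_mismatch_in_adapter_still_trims():
    insert = "ACGTACGTACGTACGTACGTA"
    mutated = "A" + ADAPTER[1:]
    clean, _ = clean_reads([_read(insert + mutated)], ADAPTER)
    assert clean == [insert]


@pytest.mark.parametrize(
    "insert,reason",
    [
        ("ACGTACGTACGTACGT", "too_short"),              # 16 nt
        ("ACGTACGTNACGTACGTACGT", "ambiguous"),
        ("ACGCACGCAAAAAAAACGCAC", "poly_a"),            # run of 8 A
        ("A" * 17 + "CGT", "poly_a"),                   # >= 80% A content
    ],
)
def test_removal_reasons(insert, reason):
    clean, stats = clean_reads([_read(insert + ADAPTER)], ADAPTER)
    assert clean == []
    assert stats.removed[reason] == 1


def test_low_quality_read_gates_before_everything_else():
    insert = "ACGTACGTACGTACGTACGTA"
    clean, stats = clean_reads([_read(insert + ADAPTER, qual_char="+")], ADAPTER)
    assert clean == []
    assert stats.high_quality_reads == 0
    assert stats.removed["low_quality"] == 1


def test_adapterless_read_kept_only_if_within_size_range():
    short = "ACGTACGTACGTACGTACGTACG"     # 23 nt, no adapter -> kept
    long = "ACGTACGTACGTACGTACGTACGTACGTACGTACG"  # 35 nt -> removed
    clean, stats = clean_reads([_read(short), _read(long)], ADAPTER)
    assert clean == [short]
    assert stats.removed["no_adapter"] == 1


def test_clean_fraction_matches_printed_precision():
    """The high-quality -> clean percentage is reported half-up to 2 dp."""
    stats = CleaningStats(raw_reads=23_221_177)
    stats.removed["low_quality"] = 23_221_177 - 23_168_277
    stats.removed["poly_a"] = 23_168_277 - 23_040_002
    stats.length_histogram[21] = stats.clean_reads
    assert stats.high_quality_reads == 23_168_277
    assert stats.clean_reads == 23_040_002
    assert stats.clean_fraction_of_high_quality == 99.45


def test_collapse_counts_per_library():
    a, c = "A" * 21, "C" * 21
    tags = collapse_tags([a, a, a, c], [])
    assert [(t.sequence, t.count_control, t.count_treated) for t in tags] == [
        (a, 3, 0),
        (c, 1, 0),
    ]


def test_collapse_disjoint_libraries_have_zero_counts():
    tags = collapse_tags(["A" * 20], ["C" * 20])
    by_seq = {t.sequence: t for t in tags}
    assert by_seq["A" * 20].count_treated == 0
    assert by_seq["C" * 20].count_control == 0


def test_unique_tag_validation():
    with pytest.raises(ValueError):
        UniqueTag("ACGTX")
    with pytest.raises(ValueError):
        UniqueTag("ACGT", count_control=-1)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.text(alphabet="ACGTN", min_size=1, max_size=60),
            st.integers(min_value=2, max_value=40),
        ),
        min_size=1,
        max_size=30,
    )
)
def test_cleaning_conservation_and_length_bounds(raw):
    """raw = clean + removals, and every kept read is 18-30 nt."""
    reads = [(f"r{i}", seq, chr(33 + q) * len(seq)) for i, (seq, q) in enumerate(raw)]
    clean, stats = clean_reads(reads, ADAPTER)
    assert stats.raw_reads == len(reads)
    assert stats.raw_reads == stats.clean_reads + sum(stats.removed.values())
    assert all(18 <= len(s) <= 30 for s in clean)
    assert sum(stats.length_histogram.values()) == len(clean)


def test_collapse_round_trip_preserves_multiset():
    reads = ["ACGT" * 5, "ACGT" * 5, "TTTTGGGGCCCCAAAATTTT"]
    tags = collapse_tags(reads, reads[:1])
    expanded = Counter()
    for t in tags:
        expanded[t.sequence] += t.count_control
    assert expanded == Counter(reads)


def test_length_distribution_single_length_is_total():
    tags = [UniqueTag("A" * 10 + "C" * 11, 5, 2)]
    df = preprocess.length_distribution(tags)
    row = df[df["length"] == 21].iloc[0]
    assert row["total_control_pct"] == 100.0 and row["unique_treated_pct"] == 100.0
    assert df["total_control"].sum() == 5


def test_length_distribution_mode_follows_planted_matures(pipeline, default_config):
    df = preprocess.length_distribution(pipeline.tags)
    mode = df.loc[df["total_control"].idxmax(), "length"]
    lo, hi = default_config.mature_len_range
    assert lo <= mode <= hi


def test_length_distribution_requires_tags():
    with pytest.raises(ValueError):
        preprocess.length_distribution([])
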