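"""Degradome classification, duplex scoring and t-plot categories."""

import pytest

from srnamir import degradome
from srnamir._util import revcomp
from srnamir.degradome import (
    DegradomeTag,
    TargetHit,
    align_mirna_targets,
    call_cleavage,
    classify_degradome_tags,
    degradome_table,
    score_duplex,
    tplot_table,
)

TX = {"t1": "ACGGTTACGTTGACCGTATCGATCGGATTCAGCTAAGGTCCAGATTGCGCTACCGGTAACGT" * 4}
NC = {"rRNA": {"r1": "CCGGAATTCCGGAATTCCGGAATTCC"}, "tRNA": {}, "snRNA": {}, "snoRNA": {}}


def test_sense_tag_gets_transcript_and_position():
    tag = TX["t1"][30:50]
    out = classify_degradome_tags([(tag, 3)], NC, TX)
    assert out[0].annotation == "cDNA_sense"
    assert out[0].transcript_id == "t1" and out[0].position == 30


def test_antisense_only_match_is_antisense():
    tag = revcomp(TX["t1"][40:60])
    out = classify_degradome_tags([(tag, 1)], NC, TX)
    assert out[0].annotation == "cDNA_antisense"


def test_noncoding_precedence_beats_transcript_match():
    tag = NC["rRNA"]["r1"][2:22]
    tx = {"t1": "AAAA" + tag + "GGGG"}  # also a perfect sense match
    out = classify_degradome_tags([(tag, 1)], NC, tx)
    assert out[0].annotation == "rRNA"


@pytest.mark.parametrize(
    "seq", ["ACGTANNNNNACGTACGTAC", "NNACGTACGTACGTACGTAC"]  # run >= 5 / >= 10% N
)
def test_polyn_rule(seq):
    out = classify_degradome_tags([(seq, 1)], NC, TX)
    assert out[0].annotation == "polyN"


def test_unmatched_tag_is_other():
    out = classify_degradome_tags([("TTTTTTTTTTAAAAAAAAAA", 1)], NC, TX)
    assert out[0].annotation == "other"


def test_degradome_table_partitions_and_percentages():
    tags = {
        "control": classify_degradome_tags(
            [(TX["t1"][0:20], 9), (revcomp(TX["t1"][40:60]), 1)], NC, TX
        )
    }
    df = degradome_table(tags).set_index("category")
    assert df.loc["cDNA_sense", "total_control"] == 9
    assert df.loc["cDNA_sense", "total_control_pct"] == 90.0
    assert df.loc["Total", "unique_control"] == 2
    assert df.drop("Total")["total_control"].sum() == df.loc["Total", "total_control"]


def test_perfect_site_scores_zero_and_wobble_rules():
    mirna = "TGACAGAAGAGAGTGAGCACA"
    assert score_duplex(mirna, revcomp(mirna)) == 0.0
    # G:U wobble inside the doubled core (positions 2-13): 0.5 * 2 -> 1.0
    window = list(revcomp(mirna))
    q = next(i + 1 for i, b in enumerate(mirna) if b == "G" and 2 <= i + 1 <= 13)
    window[len(mirna) - q] = "T"
    assert score_duplex(mirna, "".join(window)) == 1.0
    # mismatch at position 1 (outside the core) costs 1.0
    window = list(revcomp(mirna))
    window[len(mirna) - 1] = "C" if window[len(mirna) - 1] != "C" else "G"
    assert score_duplex(mirna, "".join(window)) == 1.0


def test_alignment_search_agrees_with_sliding_window_oracle():
    mirna = "TGACAGAAGAGAGTGAGCACA"
    tx = {"t1": "AAGGTT" + revcomp(mirna) + TX["t1"][:80]}
    cands = align_mirna_targets({"m1": mirna}, tx, max_score=4.5)
    # oracle: rescore every window explicitly
    oracle = [
        (p, score_duplex(mirna, tx["t1"][p : p + len(mirna)]))
        for p in range(len(tx["t1"]) - len(mirna) + 1)
    ]
    expected = {(p, s) for p, s in oracle if s <= 4.5}
    assert {(c["window_start"], c["score"]) for c in cands} == expected
    assert any(c["window_start"] == 6 and c["score"] == 0.0 for c in cands)


def _hit_for_profile(profile, site, mirna_len=21):
    cand = {
        "mirna_id": "m1",
        "transcript_id": "t1",
        "window_start": site - mirna_len + 10,
        "score": 0.0,
        "alignment": "",
    }
    tags = [
        DegradomeTag("A" * 20, count, "cDNA_sense", "t1", pos)
        for pos, count in profile.items()
    ]
    hits = call_cleavage([cand], tags, {"t1": "A" * 300}, mirna_lengths={"m1": mirna_len})
    return hits


@pytest.mark.parametrize(
    "profile,site,category",
    [
        ({100: 1}, 100, 4),                                  # single raw read
        ({100: 50, 10: 1, 20: 1, 30: 1}, 100, 0),            # unique maximum
        ({100: 50, 40: 50, 20: 1}, 100, 1),                  # tied maximum
        ({100: 10, 40: 50, 10: 1, 20: 1, 30: 1}, 100, 2),    # above the median
        ({100: 2, 40: 50, 30: 20, 20: 8, 10: 6}, 100, 3),    # at/below median, > 1 read
    ],
)
def test_tplot_categories(profile, site, category):
    hits = _hit_for_profile(profile, site)
    assert len(hits) == 1
    assert hits[0].category == category


def test_site_without_reads_is_dropped():
    assert _hit_for_profile({50: 3}, 100) == []


def test_planted_fixture_sites_all_category_zero(pipeline, bundle):
    planted = {(t.transcript_id, t.cleavage_pos) for t in bundle.truth.targets}
    found = {(h.transcript_id, h.cleavage_pos): h for h in pipeline.target_hits}
    assert planted <= set(found)
    assert all(found[s].category == 0 for s in planted)
    assert all(found[s].score == 0.0 for s in planted)


def test_tplot_table_conserves_abundance(pipeline):
    hit = pipeline.target_hits[0]
    df = tplot_table(hit)
    assert len(df) == hit.transcript_length
    assert df["abundance"].sum() == sum(hit.profile.values())
    assert df.loc[df["is_cleavage_site"], "position"].iloc[0] == hit.cleavage_pos


def test_tplot_table_requires_profile():
    hit = TargetHit("m", "t", 0.0, "", 10, 1, profile={}, category=4, transcript_length=50)
    with pytest.raises(ValueError):
        tplot_table(hit)
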