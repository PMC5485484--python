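"""Synthetic-data generator: determinism, truth bookkeeping, count model."""

import numpy as np
import pytest
from scipy import stats as sps

from srnamir import hairpin, preprocess, simulate
from srnamir.simulate import ConfigurationError, SimulationConfig


def test_config_invariants_enforced():
    with pytest.raises(ConfigurationError):
        SimulationConfig(mature_len_range=(16, 24))
    with pytest.raises(ConfigurationError):
        SimulationConfig(de_fraction=1.5)
    with pytest.raises(ConfigurationError):
        SimulationConfig(depth_per_library=0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(adapter_seq="")


def test_ground_truth_bookkeeping(small_config):
    cfg = simulate.SimulationConfig(
        n_conserved_mirnas=5, n_novel_mirnas=3, n_transcripts=30, seed=3
    )
    bundle = simulate.make_reference(cfg)
    truth = bundle.truth
    assert len(truth.mirnas) == 8
    assert sum(m.is_conserved for m in truth.mirnas.values()) == 5
    # every planted miRNA appears in exactly one hairpin at its recorded locus
    for m in truth.mirnas.values():
        host = bundle.transcripts[m.host_transcript]
        assert host[m.precursor_pos : m.precursor_pos + len(m.precursor)] == m.precursor
        assert m.precursor.count(m.mature) >= 1
    # targets carry the reverse complement of the mature at the recorded spot
    for t in truth.targets:
        m = truth.mirnas[t.mirna_id]
        seq = bundle.transcripts[t.transcript_id]
        from srnamir._util import revcomp

        assert seq[t.site_start : t.site_start + len(m.mature)] == revcomp(m.mature)
        assert t.cleavage_pos == t.site_start + len(m.mature) - 10
        assert 0 <= t.cleavage_pos < len(seq)


def test_all_matures_conserved_when_no_novel_class():
    cfg = SimulationConfig(n_conserved_mirnas=6, n_novel_mirnas=0, n_transcripts=30, seed=4)
    bundle = simulate.make_reference(cfg)
    assert all(m.is_conserved and m.known_id for m in bundle.truth.mirnas.values())
    # each planted mature is within 2 substitutions of its database entry
    for m in bundle.truth.mirnas.values():
        ref = bundle.known_matures[m.known_id]
        assert sum(a != b for a, b in zip(m.mature, ref)) <= 2


def test_same_seed_is_byte_identical(tmp_path, small_config):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    for d in (d1, d2):
        simulate.write_bundle(simulate.make_reference(small_config), d)
    for name in ("transcripts.fasta", "reads_control.fastq", "reads_treated.fastq",
                 "degradome_control.fasta", "ground_truth.tsv", "ct_table.tsv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_true_counts_within_depth(bundle, default_config):
    for attr in ("count_control", "count_treated"):
        total = sum(getattr(m, attr) for m in bundle.truth.mirnas.values())
        assert 0 < total <= default_config.depth_per_library


def test_zero_dispersion_matches_poisson_moments():
    """The gamma-Poisson sampler degenerates to Poisson as dispersion -> 0."""
    rng = np.random.default_rng(11)
    mu = np.full(10_000, 40.0)
    draws = simulate._nb_draw(rng, mu, 0.0)
    ref = sps.poisson(40.0)
    assert draws.mean() == pytest.approx(ref.mean(), rel=0.02)
    assert draws.var() == pytest.approx(ref.var(), rel=0.05)
    # overdispersed draws must exceed the Poisson variance
    over = simulate._nb_draw(rng, mu, 0.2)
    assert over.var() > 1.5 * ref.var()


def test_null_model_log_ratios_concentrate_near_zero():
    df = simulate.draw_library_counts(
        400, de_fraction=0.0, mean_range=(200, 400), dispersion=0.01, seed=5
    )
    ratio = np.log2((df["count_treated"] + 0.5) / (df["count_control"] + 0.5))
    assert abs(ratio.mean()) < 0.05
    assert (np.abs(ratio) < 1).mean() > 0.99


def test_planted_precursors_pass_hairpin_criteria(bundle):
    """Self-consistency: the generator's hairpins satisfy the caller's rules."""
    truth = bundle.truth
    matures = [
        preprocess.UniqueTag(m.mature, 10, 10) for m in truth.mirnas.values()
    ]
    calls = hairpin.predict_novel(matures, bundle.transcripts)
    called = {c.mature: c for c in calls}
    arm_ok = sum(1 for m in truth.mirnas.values() if m.mature in called and called[m.mature].arm == m.arm)
    assert len(called) == len(truth.mirnas)
    assert arm_ok == len(truth.mirnas)


def test_degradome_truth_sites_dominate_with_quiet_background(small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, degradome_background=0, degradome_decoy=0)
    bundle = simulate.make_reference(cfg)
    tags = simulate.simulate_degradome(bundle, cfg)
    assert set(tags) == {"control", "treated"}
    for t in bundle.truth.targets:
        seq = bundle.transcripts[t.transcript_id]
        planted = seq[t.cleavage_pos : t.cleavage_pos + 20]
        counts = dict(tags["control"])
        assert counts.get(planted, 0) >= cfg.degradome_site_count


def test_degradome_without_targets_holds_only_background(small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, target_fraction=0.0)
    bundle = simulate.make_reference(cfg)
    assert bundle.truth.targets == []
    tags = simulate.simulate_degradome(bundle, cfg)
    assert all(count == 1 for _seq, count in tags["control"])
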