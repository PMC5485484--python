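"""Synthetic two-condition small-RNA + degradome study with known truth.

Builds every input the pipeline consumes: a reference transcript set
("unigenes") with miRNA hairpin loci and target sites planted at recorded
positions, a known-mature miRNA database, noncoding RNA family databases,
two small-RNA FASTQ libraries (control and drought-treated) whose
per-miRNA counts follow a negative-binomial model with known log2 fold
changes, two degradome tag libraries with cleavage-site signal, and a
qPCR Ct table consistent with the planted fold changes.

Hairpin loci are built constructively — a stem arm, a terminal loop and
the mutated reverse complement of the arm — so every planted precursor
satisfies the hairpin-calling criteria by construction.  The generator is
fully deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import revcomp, write_fasta, write_fastq

__all__ = [
    "SimulationConfig",
    "MirnaTruth",
    "TargetTruth",
    "GroundTruth",
    "ReferenceBundle",
    "make_reference",
    "simulate_sra_reads",
    "simulate_degradome",
    "simulate_ct_table",
    "write_bundle",
]

_NT = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Raised for self-contradictory simulation settings."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the simulated experiment.

    Defaults describe a scaled-down two-library drought experiment: tens
    of transcripts, a few dozen planted miRNA loci, and libraries of a
    few tens of thousands of 18-30 nt reads with a 3' sequencing adapter.
    """

    n_transcripts: int = 60
    transcript_len_range: tuple[int, int] = (600, 1200)
    n_conserved_mirnas: int = 10
    n_novel_mirnas: int = 15
    n_noncoding: int = 4              # sequences per noncoding family
    mature_len_range: tuple[int, int] = (20, 24)
    depth_per_library: int = 60_000
    de_fraction: float = 0.4
    true_lfc_values: tuple[float, ...] = (-2.0, 2.0, -1.5, 1.5)
    dispersion: float = 0.05          # NB: var = mu + dispersion * mu^2
    adapter_seq: str = "TGGAATTCTCGGGTGCCAAGG"
    seed: int = 0
    # secondary knobs (fractions of depth_per_library)
    noncoding_read_fraction: float = 0.10
    background_read_fraction: float = 0.05
    decoy_read_fraction: float = 0.05
    star_fraction: float = 0.4        # miRNAs with detectable star reads
    target_fraction: float = 0.6      # miRNAs with a planted cleavage target
    degradome_site_count: int = 50    # degradome tags at each true site
    degradome_background: int = 300   # background singleton tags per library
    degradome_decoy: int = 40         # noncoding/poly(N) degradome decoys
    read_length: int = 36

    def __post_init__(self) -> None:
        for name in (
            "n_transcripts",
            "n_conserved_mirnas",
            "n_novel_mirnas",
            "n_noncoding",
            "depth_per_library",
            "read_length",
        ):
            if getattr(self, name) < 0 or (
                name in ("n_transcripts", "depth_per_library", "read_length")
                and getattr(self, name) <= 0
            ):
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.mature_len_range
        if not (18 <= lo <= hi <= 30):
            raise ConfigurationError("mature_len_range must lie within 18-30 nt")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError("de_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if not self.adapter_seq or set(self.adapter_seq) - set("ACGT"):
            raise ConfigurationError("adapter_seq must be a nonempty ACGT string")
        if self.transcript_len_range[0] < 200:
            raise ConfigurationError("transcripts must be >= 200 nt to host hairpins")
        if self.mature_len_range[1] + 10 > self.read_length:
            raise ConfigurationError("read_length too short for mature + adapter overlap")


@dataclass
class MirnaTruth:
    mirna_id: str
    mature: str                 # DNA alphabet, as sequenced
    precursor: str
    arm: str                    # "5p" | "3p"
    star: str
    has_star_reads: bool
    is_conserved: bool
    known_id: str | None
    host_transcript: str
    precursor_pos: int          # 0-based start of precursor in host
    count_control: int = 0
    count_treated: int = 0
    true_lfc: float = 0.0

    @property
    def is_de(self) -> bool:
        return abs(self.true_lfc) >= 1.0


@dataclass
class TargetTruth:
    mirna_id: str
    transcript_id: str
    site_start: int      # 0-based start of the target duplex on the transcript
    cleavage_pos: int    # 0-based 5' position of the diagnostic degradome tag


@dataclass
class GroundTruth:
    mirnas: dict[str, MirnaTruth]
    targets: list[TargetTruth]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mirna_id": m.mirna_id,
                "mature": m.mature,
                "arm": m.arm,
                "is_conserved": m.is_conserved,
                "known_id": m.known_id or "",
                "has_star_reads": m.has_star_reads,
                "host_transcript": m.host_transcript,
                "precursor_pos": m.precursor_pos,
                "count_control": m.count_control,
                "count_treated": m.count_treated,
                "true_lfc": m.true_lfc,
                "is_de": m.is_de,
            }
            for m in self.mirnas.values()
        ]
        return pd.DataFrame(rows)


@dataclass
class ReferenceBundle:
    transcripts: dict[str, str]
    known_matures: dict[str, str]
    noncoding: dict[str, dict[str, str]]   # family -> id -> sequence
    truth: GroundTruth
    config: SimulationConfig = field(repr=False)


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, n_subs: int, forbidden: range | None = None) -> str:
    """Apply ``n_subs`` substitutions, avoiding positions in ``forbidden``."""
    allowed = [i for i in range(len(seq)) if forbidden is None or i not in forbidden]
    if n_subs > len(allowed):
        raise ConfigurationError("more substitutions requested than available positions")
    pos = rng.choice(len(allowed), size=n_subs, replace=False) if n_subs else []
    out = list(seq)
    for p in pos:
        i = allowed[int(p)]
        out[i] = str(rng.choice([c for c in "ACGT" if c != out[i]]))
    return "".join(out)


def _hamming_flush5(a: str, b: str) -> int:
    n = min(len(a), len(b))
    return sum(1 for x, y in zip(a[:n], b[:n]) if x != y)


def _build_hairpin(
    rng: np.random.Generator, mature_len: int, arm: str
) -> tuple[str, str, str, int]:
    """Return (precursor, mature, star, mature_offset_in_precursor).

    The precursor is stem5 + loop + revcomp(stem5) with 0-2 substitutions
    injected opposite the flanking context only, never opposite the
    mature, so the mature/star duplex stays near-perfect.
    """
    outer = int(rng.integers(18, 28))
    inner = int(rng.integers(4, 9))     # distance from mature to the loop
    loop_len = int(rng.integers(10, 16))
    source = _rand_seq(rng, mature_len)
    stem5 = _rand_seq(rng, outer) + source + _rand_seq(rng, inner)
    loop = _rand_seq(rng, loop_len)
    stem3 = revcomp(stem5)
    n = 2 * len(stem5) + loop_len
    if arm == "5p":
        a = outer
    else:
        # mature sits on the 3' arm, opposite the source region
        a = n - (outer + mature_len)
    b = a + mature_len
    # substitutions only opposite the flanking context: in stem3-local
    # coordinates the mature (3p) or its complement (5p) both occupy
    # [S - outer - mature_len, S - outer), which stays untouched
    n_subs = int(rng.integers(0, 3))
    protected = range(len(stem5) - outer - mature_len, len(stem5) - outer)
    stem3 = _mutate(rng, stem3, n_subs, forbidden=protected)
    precursor = stem5 + loop + stem3
    mature = precursor[a:b]
    star = precursor[max(0, n - b + 2) : n - a + 2]
    return precursor, mature, star, a


def make_reference(config: SimulationConfig) -> ReferenceBundle:
    """Construct transcripts, reference databases and the ground truth.

    Hairpin loci for every planted miRNA (conserved and novel) are
    embedded in host transcripts; conserved matures are copied into the
    known-mature database with up to two substitutions; each targeted
    miRNA gets the reverse complement of its mature planted in a distinct
    target transcript at a recorded position.
    """
    rng = np.random.default_rng(config.seed)
    lens = rng.integers(*config.transcript_len_range, size=config.n_transcripts)
    transcripts = {f"Unigene{i + 1}": _rand_seq(rng, int(L)) for i, L in enumerate(lens)}
    tx_ids = list(transcripts)

    n_mirnas = config.n_conserved_mirnas + config.n_novel_mirnas
    if n_mirnas > config.n_transcripts:
        raise ConfigurationError("need at least one transcript per planted miRNA")

    known_matures: dict[str, str] = {}
    mirnas: dict[str, MirnaTruth] = {}
    n_star = round(config.star_fraction * n_mirnas)
    star_flags = np.zeros(n_mirnas, dtype=bool)
    star_flags[rng.choice(n_mirnas, size=n_star, replace=False)] = True

    for i in range(n_mirnas):
        conserved = i < config.n_conserved_mirnas
        mlen = int(rng.integers(config.mature_len_range[0], config.mature_len_range[1] + 1))
        arm = "5p" if rng.random() < 0.5 else "3p"
        for _attempt in range(50):
            precursor, mature, star, _ = _build_hairpin(rng, mlen, arm)
            # novel matures must stay >2 mismatches from every known mature
            if conserved or all(
                _hamming_flush5(mature, k) > 2 or abs(len(mature) - len(k)) > 2
                for k in known_matures.values()
            ):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise ConfigurationError("could not draw a distinct novel mature")
        if conserved:
            mid = f"ptf-miR{151 + i}"
            known_id = f"ath-miR{151 + i}"
            known_matures[known_id] = _mutate(rng, mature, int(rng.integers(0, 3)))
        else:
            mid = f"ptf-M{i - config.n_conserved_mirnas + 1}"
            known_id = None
        host = tx_ids[i]
        seq = transcripts[host]
        pos = int(rng.integers(30, len(seq) - len(precursor) - 30))
        transcripts[host] = seq[:pos] + precursor + seq[pos + len(precursor):]
        mirnas[mid] = MirnaTruth(
            mirna_id=mid,
            mature=mature,
            precursor=precursor,
            arm=arm,
            star=star,
            has_star_reads=bool(star_flags[i]),
            is_conserved=conserved,
            known_id=known_id,
            host_transcript=host,
            precursor_pos=pos,
        )

    # a few known matures that are not planted (database realism)
    for j in range(3):
        known_matures[f"ath-miR{900 + j}"] = _rand_seq(rng, 21)

    # planted cleavage targets, each on a transcript with no hairpin locus
    targets: list[TargetTruth] = []
    free_tx = tx_ids[n_mirnas:]
    target_ids = [m for m in mirnas][: round(config.target_fraction * n_mirnas)]
    if target_ids and not free_tx:
        raise ConfigurationError("no transcripts left to host target sites")
    for k, mid in enumerate(target_ids):
        m = mirnas[mid]
        tid = free_tx[k % len(free_tx)]
        seq = transcripts[tid]
        site = revcomp(m.mature)
        pos = int(rng.integers(40, len(seq) - len(site) - 60))
        transcripts[tid] = seq[:pos] + site + seq[pos + len(site):]
        targets.append(
            TargetTruth(
                mirna_id=mid,
                transcript_id=tid,
                site_start=pos,
                cleavage_pos=pos + len(site) - 10,
            )
        )

    fam_lens = {"rRNA": 150, "tRNA": 75, "snRNA": 110, "snoRNA": 95}
    noncoding = {
        fam: {f"{fam}_{j + 1}": _rand_seq(rng, L) for j in range(config.n_noncoding)}
        for fam, L in fam_lens.items()
    }

    # true counts from the NB model (drawn here so GroundTruth is complete)
    _draw_counts(rng, config, mirnas)
    return ReferenceBundle(transcripts, known_matures, noncoding, GroundTruth(mirnas, targets), config)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts via the gamma-Poisson mixture.

    var = mu + dispersion * mu^2; dispersion 0 reduces to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _draw_counts(rng: np.random.Generator, config: SimulationConfig, mirnas: dict[str, MirnaTruth]) -> None:
    ids = list(mirnas)
    n = len(ids)
    if n == 0:
        return
    budget = config.depth_per_library * (
        1.0
        - config.noncoding_read_fraction
        - config.background_read_fraction
        - config.decoy_read_fraction
    )
    weights = np.exp(rng.uniform(math.log(0.3), math.log(3.0), size=n))
    mu_control = budget * weights / weights.sum()
    n_de = round(config.de_fraction * n)
    lfc = np.zeros(n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    for j, idx in enumerate(de_idx):
        lfc[idx] = config.true_lfc_values[j % len(config.true_lfc_values)]
    mu_treated = mu_control * np.power(2.0, lfc)
    cw = _nb_draw(rng, mu_control, config.dispersion)
    ct = _nb_draw(rng, mu_treated, config.dispersion)
    for counts in (cw, ct):  # keep the depth invariant deterministic
        excess = counts.sum() - config.depth_per_library
        if excess > 0:  # pragma: no cover - requires extreme dispersion
            counts[np.argmax(counts)] -= excess
    for i, mid in enumerate(ids):
        mirnas[mid].count_control = int(cw[i])
        mirnas[mid].count_treated = int(ct[i])
        mirnas[mid].true_lfc = float(lfc[i])


_HIGH_Q = "I"  # Phred 40
_LOW_Q = "+"   # Phred 10


def _as_read(config: SimulationConfig, rng: np.random.Generator, insert: str, qual_char: str = _HIGH_Q) -> tuple[str, str]:
    full = insert + config.adapter_seq
    if len(full) < config.read_length:
        full += _rand_seq(rng, config.read_length - len(full))
    full = full[: config.read_length]
    return full, qual_char * len(full)


def simulate_sra_reads(
    bundle: ReferenceBundle, config: SimulationConfig | None = None
) -> dict[str, list[tuple[str, str, str]]]:
    """Simulate the two adapter-ligated small-RNA libraries.

    Returns ``{"control": reads, "treated": reads}`` where each read is an
    (id, sequence, quality) triple.  Reads comprise planted mature (and
    star) miRNA tags at their NB-drawn counts, noncoding-derived
    fragments, random background tags, and decoys that the cleaning stage
    must remove: too-short/too-long inserts, poly(A) inserts, and
    low-quality reads.
    """
    config = config or bundle.config
    if config.depth_per_library <= 0:
        raise ConfigurationError("depth_per_library must be > 0")
    rng = np.random.default_rng(config.seed + 1)
    nc_pool = [s for fam in bundle.noncoding.values() for s in fam.values()]
    out: dict[str, list[tuple[str, str, str]]] = {}
    for lib, attr in (("control", "count_control"), ("treated", "count_treated")):
        inserts: list[tuple[str, str]] = []
        for m in bundle.truth.mirnas.values():
            inserts += [(m.mature, _HIGH_Q)] * getattr(m, attr)
            if m.has_star_reads:
                # stars are detectable but far below mature abundance
                inserts += [(m.star, _HIGH_Q)] * int(rng.integers(1, 3))
        n_nc = round(config.noncoding_read_fraction * config.depth_per_library)
        for _ in range(n_nc):
            src = nc_pool[int(rng.integers(len(nc_pool)))]
            ln = int(rng.integers(18, 31))
            start = int(rng.integers(0, len(src) - ln + 1))
            inserts.append((src[start : start + ln], _HIGH_Q))
        n_bg = round(config.background_read_fraction * config.depth_per_library)
        for _ in range(n_bg):
            inserts.append((_rand_seq(rng, int(rng.integers(18, 31))), _HIGH_Q))
        n_decoy = round(config.decoy_read_fraction * config.depth_per_library)
        for d in range(n_decoy):
            kind = d % 4
            if kind == 0:      # too short after trimming
                inserts.append((_rand_seq(rng, int(rng.integers(8, 17))), _HIGH_Q))
            elif kind == 1:    # too long: adapter overlap pushed past the read end
                inserts.append((_rand_seq(rng, int(rng.integers(31, 41))), _HIGH_Q))
            elif kind == 2:    # poly(A) insert
                inserts.append(("A" * int(rng.integers(20, 27)), _HIGH_Q))
            else:              # low quality
                inserts.append((_rand_seq(rng, int(rng.integers(18, 31))), _LOW_Q))
        order = rng.permutation(len(inserts))
        reads = []
        for ridx, oi in enumerate(order):
            ins, q = inserts[int(oi)]
            seq, qual = _as_read(config, rng, ins, q)
            reads.append((f"{lib}_{ridx + 1}", seq, qual))
        out[lib] = reads
    return out


def simulate_degradome(
    bundle: ReferenceBundle, config: SimulationConfig | None = None
) -> dict[str, list[tuple[str, int]]]:
    """Simulate the two degradome tag libraries as (sequence, count) pairs.

    Each planted cleavage site yields an abundant ~20 nt tag whose 5' end
    sits exactly at the recorded cleavage position (opposite miRNA
    positions 10-11); uniform singleton background tags and noncoding /
    poly(N) decoys are added on top.
    """
    config = config or bundle.config
    rng = np.random.default_rng(config.seed + 2)
    tx = bundle.transcripts
    tx_ids = list(tx)
    nc_pool = [s for fam in bundle.noncoding.values() for s in fam.values()]
    out: dict[str, list[tuple[str, int]]] = {}
    for lib in ("control", "treated"):
        tags: list[tuple[str, int]] = []
        for t in bundle.truth.targets:
            seq = tx[t.transcript_id]
            tag = seq[t.cleavage_pos : t.cleavage_pos + 20]
            count = config.degradome_site_count + int(rng.integers(0, 11))
            tags.append((tag, count))
        for _ in range(config.degradome_background):
            tid = tx_ids[int(rng.integers(len(tx_ids)))]
            seq = tx[tid]
            pos = int(rng.integers(0, len(seq) - 20))
            tags.append((seq[pos : pos + 20], 1))
        for d in range(config.degradome_decoy):
            if d % 2 == 0 and nc_pool:
                src = nc_pool[int(rng.integers(len(nc_pool)))]
                pos = int(rng.integers(0, len(src) - 20))
                tags.append((src[pos : pos + 20], 1))
            else:
                base = _rand_seq(rng, 20)
                k = int(rng.integers(0, 5))
                tags.append((base[:k] + "N" * 6 + base[k + 6 :], 1))
        out[lib] = tags
    return out


def simulate_ct_table(
    bundle: ReferenceBundle,
    mirna_ids: list[str] | None = None,
    n_replicates: int = 3,
    noise_sd: float = 0.12,
) -> pd.DataFrame:
    """qPCR Ct table consistent with the planted fold changes.

    One endogenous reference (U6) plus the chosen miRNAs, ``n_replicates``
    biological replicates per condition; a unit change in expression
    corresponds to one PCR cycle, so Ct_treated = Ct_control - true_lfc
    up to replicate noise.
    """
    config = bundle.config
    rng = np.random.default_rng(config.seed + 3)
    if mirna_ids is None:
        de = [m.mirna_id for m in bundle.truth.mirnas.values() if m.is_de]
        mirna_ids = de[:4] or list(bundle.truth.mirnas)[:4]
    rows = []
    for cond in ("control", "treated"):
        for rep in range(1, n_replicates + 1):
            rows.append(("U6", "reference", cond, rep, 19.0 + rng.normal(0, noise_sd)))
    for mid in mirna_ids:
        m = bundle.truth.mirnas[mid]
        base = float(rng.uniform(22, 27))
        for rep in range(1, n_replicates + 1):
            rows.append((mid, "target", "control", rep, base + rng.normal(0, noise_sd)))
        for rep in range(1, n_replicates + 1):
            rows.append((mid, "target", "treated", rep, base - m.true_lfc + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=["gene", "role", "condition", "replicate", "ct"])


def write_bundle(bundle: ReferenceBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the full simulated study to ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": outdir / "transcripts.fasta",
        "known_matures": outdir / "known_matures.fasta",
        "noncoding": outdir / "noncoding.fasta",
        "truth": outdir / "ground_truth.tsv",
        "fastq_control": outdir / "reads_control.fastq",
        "fastq_treated": outdir / "reads_treated.fastq",
        "degradome_control": outdir / "degradome_control.fasta",
        "degradome_treated": outdir / "degradome_treated.fasta",
        "ct_table": outdir / "ct_table.tsv",
    }
    write_fasta(bundle.transcripts.items(), paths["transcripts"])
    write_fasta(bundle.known_matures.items(), paths["known_matures"])
    write_fasta(
        ((f"{fam}|{name}", seq) for fam, fams in bundle.noncoding.items() for name, seq in fams.items()),
        paths["noncoding"],
    )
    bundle.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    reads = simulate_sra_reads(bundle)
    write_fastq(reads["control"], paths["fastq_control"])
    write_fastq(reads["treated"], paths["fastq_treated"])
    deg = simulate_degradome(bundle)
    for lib in ("control", "treated"):
        write_fasta(
            ((f"dtag{i + 1}_x{count}", seq) for i, (seq, count) in enumerate(deg[lib])),
            paths[f"degradome_{lib}"],
        )
    simulate_ct_table(bundle).to_csv(paths["ct_table"], sep="\t", index=False)
    return paths


def draw_library_counts(
    n_mirnas: int,
    depth: int = 60_000,
    dispersion: float = 0.05,
    de_fraction: float = 0.0,
    true_lfc_values: tuple[float, ...] = (-2.0, 2.0),
    mean_range: tuple[float, float] = (50.0, 500.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-miRNA two-library counts from the NB count model alone.

    A counts-only view of the generator (no sequences), for null and
    power studies of the exact test: control means uniform over
    ``mean_range``, treated means scaled by 2^lfc for the DE subset.
    Returns columns mirna_id, count_control, count_treated, true_lfc,
    plus ``.attrs['totals']`` with per-library totals including a
    non-miRNA remainder so totals reflect the configured depth.
    """
    if n_mirnas <= 0 or depth <= 0:
        raise ConfigurationError("n_mirnas and depth must be > 0")
    rng = np.random.default_rng(seed)
    mu = rng.uniform(*mean_range, size=n_mirnas)
    lfc = np.zeros(n_mirnas)
    n_de = round(de_fraction * n_mirnas)
    for j, idx in enumerate(rng.choice(n_mirnas, size=n_de, replace=False)):
        lfc[idx] = true_lfc_values[j % len(true_lfc_values)]
    cw = _nb_draw(rng, mu, dispersion)
    ct = _nb_draw(rng, mu * np.power(2.0, lfc), dispersion)
    df = pd.DataFrame(
        {
            "mirna_id": [f"mir{i + 1}" for i in range(n_mirnas)],
            "count_control": cw.astype(int),
            "count_treated": ct.astype(int),
            "true_lfc": lfc,
        }
    )
    rest = max(0, depth - int(mu.sum()))
    df.attrs["totals"] = {
        "control": int(cw.sum()) + rest,
        "treated": int(ct.sum()) + rest,
    }
    return df


def null_config(**overrides) -> SimulationConfig:
    """A no-differential-expression configuration (all true lfc = 0)."""
    base = SimulationConfig(de_fraction=0.0)
    return replace(base, **overrides)
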