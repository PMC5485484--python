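"""End-of-run summaries, cross-stage consistency checks and orchestration.

``build_summary`` aggregates every stage's output into a ``RunSummary``
and asserts the identities that tie the stages together (total miRNAs =
conserved + novel, DE = up + down, cleavage sites = sum over t-plot
categories, the novel-prediction input is exactly the unannotated pool).
``run_all`` executes the whole pipeline — simulate, preprocess, annotate,
novel-miRNA prediction, differential expression, degradome target
calling, qPCR — from one configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import degradome as _degradome
from . import diffexpr as _diffexpr
from . import hairpin as _hairpin
from . import preprocess as _preprocess
from . import qpcr as _qpcr
from . import simulate as _simulate

__all__ = ["ConsistencyError", "RunSummary", "build_summary", "render_tables", "run_all", "PipelineResult"]


class ConsistencyError(AssertionError):
    """A cross-table identity failed; the message names the identity."""


@dataclass
class RunSummary:
    cleaning: dict[str, _preprocess.CleaningStats]
    category_table: pd.DataFrame
    degradome_table: pd.DataFrame | None
    n_conserved: int
    n_novel: int
    n_conserved_with_star: int
    n_novel_with_star: int
    arm_5p: int
    arm_3p: int
    precursor_length_mean: float
    mfe_mean: float
    de_tallies: dict[str, int]
    n_targets: int
    n_sites: int
    sites_per_category: dict[int, int]
    unann_pool_size: int
    novel_input_size: int
    qpcr: dict[str, float] = field(default_factory=dict)   # gene -> fold

    @property
    def n_total(self) -> int:
        return self.n_conserved + self.n_novel

    def to_dict(self) -> dict:
        pooled = sum(self.cleaning.values(), _preprocess.CleaningStats())
        d = {
            "raw_reads": pooled.raw_reads,
            "high_quality_reads": pooled.high_quality_reads,
            "clean_reads": pooled.clean_reads,
            "clean_pct_of_high_quality": pooled.clean_fraction_of_high_quality,
            "n_conserved": self.n_conserved,
            "n_novel": self.n_novel,
            "n_total_mirnas": self.n_total,
            "n_conserved_with_star": self.n_conserved_with_star,
            "n_novel_with_star": self.n_novel_with_star,
            "arm_5p": self.arm_5p,
            "arm_3p": self.arm_3p,
            "precursor_length_mean": self.precursor_length_mean,
            "mfe_mean": self.mfe_mean,
            "n_targets": self.n_targets,
            "n_sites": self.n_sites,
            "unann_pool_size": self.unann_pool_size,
        }
        d.update(self.de_tallies)
        for cat in range(5):
            d[f"sites_category_{cat}"] = self.sites_per_category.get(cat, 0)
        return d


def build_summary(
    cleaning: dict[str, _preprocess.CleaningStats] | None,
    category_table: pd.DataFrame | None,
    conserved_calls: list[_annotate.ConservedMirnaCall] | None,
    novel_calls: list[_hairpin.NovelMirnaCall] | None,
    de_tallies: dict[str, int] | None,
    target_hits: list[_degradome.TargetHit] | None,
    unann_pool_size: int | None,
    novel_input_size: int | None,
    degradome_table: pd.DataFrame | None = None,
    qpcr: dict[str, float] | None = None,
) -> RunSummary:
    """Aggregate stage outputs, asserting every cross-stage identity."""
    stages = {
        "preprocess": cleaning,
        "annotate": category_table,
        "conserved": conserved_calls,
        "novel": novel_calls,
        "diffexpr": de_tallies,
        "degradome": target_hits,
        "unann_pool": unann_pool_size,
        "novel_input": novel_input_size,
    }
    for name, value in stages.items():
        if value is None:
            raise ConsistencyError(f"missing stage output: {name}")
    if not conserved_calls and not novel_calls:
        raise ConsistencyError("empty inputs: no miRNAs identified in any class")

    sites: dict[tuple[str, int], _degradome.TargetHit] = {}
    for h in sorted(target_hits, key=lambda h: h.score):
        sites.setdefault((h.transcript_id, h.cleavage_pos), h)
    per_cat: dict[int, int] = {}
    for h in sites.values():
        per_cat[h.category] = per_cat.get(h.category, 0) + 1

    summary = RunSummary(
        cleaning=cleaning,
        category_table=category_table,
        degradome_table=degradome_table,
        n_conserved=len({c.mature for c in conserved_calls}),
        n_novel=len(novel_calls),
        n_conserved_with_star=len({c.mature for c in conserved_calls if c.has_star}),
        n_novel_with_star=sum(1 for c in novel_calls if c.star is not None),
        arm_5p=sum(1 for c in novel_calls if c.arm == "5p"),
        arm_3p=sum(1 for c in novel_calls if c.arm == "3p"),
        precursor_length_mean=float(np.mean([c.precursor_length for c in novel_calls])) if novel_calls else 0.0,
        mfe_mean=float(np.mean([c.mfe for c in novel_calls])) if novel_calls else 0.0,
        de_tallies=dict(de_tallies),
        n_targets=len({h.transcript_id for h in target_hits}),
        n_sites=len(sites),
        sites_per_category=per_cat,
        unann_pool_size=int(unann_pool_size),
        novel_input_size=int(novel_input_size),
        qpcr=dict(qpcr or {}),
    )

    if summary.n_total != summary.n_conserved + summary.n_novel:  # pragma: no cover
        raise ConsistencyError("n_total != n_conserved + n_novel")
    t = summary.de_tallies
    if t["n_de"] != t["n_up"] + t["n_down"]:
        raise ConsistencyError("n_de != n_up + n_down")
    if t["n_sig"] != t["n_sig_up"] + t["n_sig_down"]:
        raise ConsistencyError("n_sig != n_sig_up + n_sig_down")
    if summary.n_sites != sum(per_cat.values()):
        raise ConsistencyError("n_sites != sum of per-category site counts")
    if summary.arm_5p + summary.arm_3p != summary.n_novel:
        raise ConsistencyError("arm_5p + arm_3p != n_novel")
    if summary.unann_pool_size != summary.novel_input_size:
        raise ConsistencyError("novel-prediction input differs from the unannotated pool")
    return summary


def _fmt(value, pretty: bool):
    if pretty and isinstance(value, (int, np.integer)):
        return f"{value:,}"
    return value


def render_tables(summary: RunSummary, outdir: str | Path, pretty: bool = False) -> dict[str, Path]:
    """Write the category table, degradome table and run summary as TSV.

    Machine TSVs carry plain numbers with a fixed decimal point; with
    ``pretty=True`` integer cells gain thousands separators, mirroring
    the human-readable table style.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    suffix = "_pretty" if pretty else ""

    cat = summary.category_table.copy()
    if pretty:
        for col in cat.columns:
            if cat[col].dtype.kind in "iu":
                cat[col] = cat[col].map(lambda v: f"{v:,}")
    paths["category_table"] = outdir / f"table_srna_categories{suffix}.tsv"
    cat.to_csv(paths["category_table"], sep="\t", index=False, float_format="%.2f")

    if summary.degradome_table is not None:
        deg = summary.degradome_table.copy()
        if pretty:
            for col in deg.columns:
                if deg[col].dtype.kind in "iu":
                    deg[col] = deg[col].map(lambda v: f"{v:,}")
        paths["degradome_table"] = outdir / f"table_degradome_categories{suffix}.tsv"
        deg.to_csv(paths["degradome_table"], sep="\t", index=False, float_format="%.2f")

    rows = [(k, _fmt(v, pretty)) for k, v in summary.to_dict().items()]
    paths["summary"] = outdir / f"run_summary{suffix}.tsv"
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(paths["summary"], sep="\t", index=False)
    return paths


@dataclass
class PipelineResult:
    bundle: _simulate.ReferenceBundle
    cleaning: dict[str, _preprocess.CleaningStats]
    tags: list[_preprocess.UniqueTag]
    records: list[_annotate.AnnotationRecord]
    conserved_calls: list[_annotate.ConservedMirnaCall]
    novel_calls: list[_hairpin.NovelMirnaCall]
    expression: pd.DataFrame
    de_tallies: dict[str, int]
    degradome_tags: dict[str, list[_degradome.DegradomeTag]]
    target_hits: list[_degradome.TargetHit]
    qpcr: dict[str, _qpcr.RelativeExpression]
    summary: RunSummary


def run_all(
    config: _simulate.SimulationConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Simulate a study and run every pipeline stage on it."""
    config = config or _simulate.SimulationConfig()
    bundle = _simulate.make_reference(config)
    reads = _simulate.simulate_sra_reads(bundle)

    clean, stats = {}, {}
    for lib in ("control", "treated"):
        clean[lib], stats[lib] = _preprocess.clean_reads(reads[lib], config.adapter_seq)
    tags = _preprocess.collapse_tags(clean["control"], clean["treated"])

    records, conserved_calls = _annotate.annotate_tags(tags, bundle.known_matures, bundle.noncoding)
    cat_table = _annotate.category_table(records)

    unann = [r.tag for r in records if r.category == "unann"]
    novel_calls = _hairpin.predict_novel(unann, bundle.transcripts)

    mature_counts: list[tuple[str, int, int]] = []
    mirna_seqs: dict[str, str] = {}
    for c in conserved_calls:
        mid = f"cons:{c.known_id}:{c.mature[:6]}"
        mature_counts.append((mid, c.count_treated, c.count_control))
        mirna_seqs[mid] = c.mature
    for i, c in enumerate(novel_calls):
        mid = f"novel:{i + 1}"
        mature_counts.append((mid, c.count_treated, c.count_control))
        mirna_seqs[mid] = c.mature
    n1 = stats["treated"].clean_reads
    n2 = stats["control"].clean_reads
    expr = _diffexpr.expression_table(mature_counts, total_treated=n1, total_control=n2)
    expr, tallies = _diffexpr.call_de(expr)

    deg_raw = _simulate.simulate_degradome(bundle)
    deg_tags = {
        lib: _degradome.classify_degradome_tags(deg_raw[lib], bundle.noncoding, bundle.transcripts)
        for lib in ("control", "treated")
    }
    deg_table = _degradome.degradome_table(deg_tags)
    candidates = _degradome.align_mirna_targets(mirna_seqs, bundle.transcripts)
    merged = deg_tags["control"] + deg_tags["treated"]
    lengths = {mid: len(seq) for mid, seq in mirna_seqs.items()}
    hits = _degradome.call_cleavage(candidates, merged, bundle.transcripts, mirna_lengths=lengths)

    ct = _simulate.simulate_ct_table(bundle)
    qpcr_results = {
        gene: _qpcr.ddct(ct, gene, "U6")
        for gene in sorted(ct.loc[ct["role"] == "target", "gene"].unique())
    }

    summary = build_summary(
        cleaning=stats,
        category_table=cat_table,
        conserved_calls=conserved_calls,
        novel_calls=novel_calls,
        de_tallies=tallies,
        target_hits=hits,
        unann_pool_size=len(unann),
        novel_input_size=len(unann),
        degradome_table=deg_table,
        qpcr={g: r.fold_mean for g, r in qpcr_results.items()},
    )
    result = PipelineResult(
        bundle=bundle,
        cleaning=stats,
        tags=tags,
        records=records,
        conserved_calls=conserved_calls,
        novel_calls=novel_calls,
        expression=expr,
        de_tallies=tallies,
        degradome_tags=deg_tags,
        target_hits=hits,
        qpcr=qpcr_results,
        summary=summary,
    )
    if outdir is not None:
        outdir = Path(outdir)
        render_tables(summary, outdir)
        expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    return result
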