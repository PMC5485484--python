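# srnamir

A small-RNA-seq + degradome analysis pipeline for plant miRNA discovery,
of the kind used to study stress-responsive miRNAs (e.g. drought) in
non-model trees such as *Paulownia*: two sRNA libraries (control vs
treated) are cleaned and collapsed to unique tags, tags are annotated
against known matures and noncoding families, novel miRNAs are predicted
from hairpin structure, expression differences are tested per miRNA,
cleavage targets are called from degradome tags, and selected miRNAs are
validated by qPCR. A synthetic-data generator with full ground truth
makes the entire chain testable offline.

## What it computes

* **Cleaning / collapsing** — adapter trimming (≤ 1 mismatch, ≥ 6 nt
  overlap), quality / N / poly(A) / size filters with full removal
  accounting; unique tags with per-library counts; length distributions.
* **Annotation** — conserved miRNA = ungapped match to a known mature
  with ≤ 2 substitutions; noncoding by exact substring with precedence
  rRNA > tRNA > snRNA > snoRNA; the remainder ("unann") feeds novel
  prediction. Category tables with unique/total counts and percentages.
* **Novel miRNAs** — unannotated tags are placed on transcripts, ±150 nt
  windows folded with a Zuker-style dynamic program (reduced
  nearest-neighbor energy model, authored here), and accepted under
  plant hairpin criteria: single stem-loop, mature in one arm ≥ 2 nt
  from the loop, ≤ 4 unpaired mature bases, ≤ 2 nt bulge asymmetry,
  MFE ≤ −18 kcal/mol, count ≥ 5; miRNA* evidence flagged.
* **Differential expression** — RPM = count/total × 10⁶;
  FC = log₂(RPM_T/RPM_W); exact conditional tag-count test
  P(y|x) = (N₂/N₁)^y (x+y)!/(x!y!) (1+N₂/N₁)^−(x+y+1) with tails C, D
  and p = min(1, 2·min(C, D)); DE at p ≤ 0.05 & |log₂FC| ≥ 1,
  "significant" at p ≤ 0.01.
* **Degradome targets** — tag annotation (Rfam-style precedence, poly(N),
  cDNA sense/antisense), gapless miRNA–transcript alignment (mismatch 1,
  G:U 0.5, ×2 over positions 2–13, cutoff 4.5), cleavage site opposite
  miRNA positions 10–11, t-plot categories 0–4.
* **qPCR** — 2^−ΔΔCt with an endogenous reference, control rescaled to
  mean 1, Welch t-test across replicates.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate a study and run every stage (seeds make everything
reproducible, byte-for-byte):

```bash
srnamir run-all --seed 1 --outdir demo
```

prints, on this seed:

```json
{
  "raw_reads": 127318,
  "high_quality_reads": 125818,
  "clean_reads": 121321,
  "clean_pct_of_high_quality": 96.43,
  "n_conserved": 10,
  "n_novel": 15,
  "n_total_mirnas": 25,
  "arm_5p": 7,
  "arm_3p": 8,
  "n_de": 9,
  "n_up": 4,
  "n_down": 5,
  "n_targets": 15,
  "n_sites": 15,
  "sites_category_0": 15,
  ...
}
```

Reading it: of 127,318 simulated raw reads, 121,321 survive cleaning
(96.43 % of the high-quality reads); all 10 planted conserved and all 15
planted novel miRNAs are identified (7 on the 5' arm, 8 on the 3' arm of
their hairpins); 9 miRNAs pass the DE thresholds (4 up, 5 down, matching
the planted fold changes the test had power to see); and all 15 planted
cleavage sites are recovered as category 0 — the site is the unique
abundance maximum on its transcript, the strongest degradome evidence
class. `demo/` holds the category tables (sRNA and degradome), the
per-miRNA expression table with x, y, RPM, log₂FC, C, D and p, and the
run summary.

Each stage is also a library function (`srnamir.preprocess.clean_reads`,
`srnamir.diffexpr.ac_pvalue`, `srnamir.degradome.call_cleavage`, ...) and
a CLI subcommand (`simulate`, `preprocess`, `annotate`, `novel`,
`diffexpr`, `degradome`, `qpcr`) for running on your own files.

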