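# Methods

`srnamir` re-implements, as one tested toolkit, the analysis chain used in
two-condition plant small-RNA studies: read cleaning, tag annotation,
conserved/novel miRNA identification from hairpin structure, exact-test
differential expression on tag counts, degradome-based cleavage-site
calling, and qPCR 2^-ΔΔCt validation. Because studies of this design are
frequently published without deposited raw reads, the package ships a
synthetic-data generator that reproduces the statistical structure the
analysis assumes, with full ground truth; every stage is exercised and
validated against that truth.

## Read cleaning

Reads are filtered in a fixed order, and every removal is counted so that
`raw = clean + Σ(removals)` holds exactly:

1. **Quality**: mean Phred < 20 → removed (`low_quality`). Reads passing
   are the "high-quality" pool.
2. **Adapter**: the 3' adapter is trimmed at the leftmost position where
   its prefix matches with ≤ 1 mismatch over ≥ 6 nt of overlap. Reads
   with no hit are kept only if already within the size range.
3. **Ambiguity**: any remaining `N` → removed.
4. **Poly(A)**: a run of ≥ 8 A, or ≥ 80 % A content, after trimming →
   removed.
5. **Size**: insert length outside [18, 30] nt → removed
   (`too_short`/`too_long`).

The quality floor, adapter-match rule and poly(A) thresholds are
documented defaults of this package, exposed as parameters — published
pipelines of this kind rarely state theirs.

## Tag annotation

Cleaned reads are collapsed to unique tags with per-library counts. A tag
is a **conserved miRNA** when an ungapped, 5'-flush comparison against a
known-mature database entry (length difference ≤ 2 nt; overhangs free)
shows ≤ 2 substitutions; ties prefer fewer mismatches, then the
lexicographically smallest reference id. Noncoding families are matched
by exact substring with precedence rRNA > tRNA > snRNA > snoRNA (scRNA
entries count as snRNA, since the summary-table layout has no scRNA
row); overall category precedence is miRNA > noncoding > unannotated, so
each tag receives exactly one category and category counts partition each
library total. miRNA* ("star") evidence for a conserved call is a second
tag whose reverse complement overlays the mature within a ± 2 nt shift
(the 2-nt 3' overhang geometry of the miRNA/miRNA* duplex) with ≤ 4
mismatches.

## RNA folding

Hairpin structures are predicted with a Zuker-style dynamic program over
a reduced nearest-neighbor model authored for this package: Watson–Crick
plus G:U pairs with a 6 × 6 stacking table, size-dependent hairpin /
bulge / interior-loop penalties (logarithmic extrapolation beyond the
tabulated sizes, interior asymmetry penalized at 0.5 kcal/mol/nt capped
at 3), a linear multibranch model (3.4 kcal/mol closing + 0.4 per
branch, unpaired free), terminal loops ≥ 3 nt, bulge/interior loops
capped at 30 unpaired nt, no pseudoknots. All arithmetic is in integer
tenths of kcal/mol, so the dynamic program, the loop-decomposition
scorer `structure_energy`, and the exhaustive enumerator used as an
exact reference (`brute_force_mfe`, all nested structures, feasible to
~18 nt) agree bit-for-bit with no floating-point ties; ties between
co-optimal structures are broken by a fixed traceback order.

Absolute MFE values under this reduced parameter set are model-dependent:
they are comparable within the package and suitable for thresholding, but
not interchangeable with values from full Turner-parameter engines.

## Novel miRNA prediction

Unannotated tags are placed on the reference transcripts by exact match
(novel loci require unambiguous placement). Around each placement two
candidate windows are excised — tag plus 150 nt upstream, and tag plus
150 nt downstream, clipped to the transcript — folded, and accepted when:

1. the structure around the mature is a single stem-loop: exactly one
   terminal loop inside the outermost pair spanning the mature's paired
   bases. Enclosure is defined over the *paired* portion of the mature
   because the windows place the tag flush against one window edge, where
   a 1–2 nt unpaired dangle is routine; dangles are budgeted by rule 3;
2. the mature sits entirely on one arm, ≥ 2 nt from the loop (arm 5p/3p
   assigned by which side of the loop it occupies);
3. ≤ 4 mature bases are unpaired and duplex bulges are ≤ 2 nt
   asymmetric;
4. precursor MFE ≤ −18 kcal/mol (energy of the excised stem-loop, which
   always covers the whole mature);
5. mature tag count ≥ 5 summed over libraries.

These five thresholds follow standard plant miRNA annotation practice
and are all configurable. Star presence is flagged when another tag maps
within ± 2 nt of the expected miRNA* start (partner of the mature's last
paired base, offset by the canonical 2-nt overhang). Calls from
overlapping windows are deduplicated per mature, keeping the
lowest-energy precursor.

## Differential expression

Counts are normalized to reads per million, RPM = count / clean-read
total × 10⁶. The fold change is log₂(RPM_treated / RPM_control), with
zero RPM replaced by 0.01 *only* inside the ratio (never in reports);
both-zero is defined as 0. The test is the classic conditional tag-count
(Audic–Claverie) probability

    P(y | x) = (N₂/N₁)^y · (x+y)! / (x! y!) · (1 + N₂/N₁)^-(x+y+1),

equivalently y | x ~ NB(x + 1, N₁/(N₁+N₂)), with x the treated count
(library total N₁) and y the control count (N₂); a swap flag flips the
binding. Tails C = P(Y ≤ y | x) and D = P(Y ≥ y | x) are accumulated in
log space via log-gamma (D through the complement of the lower tail,
never an infinite sum), and the reported p is min(1, 2·min(C, D));
doubling the smaller tail is the standard two-sided convention and a
one-sided variant is available. Flags are raw-p thresholds combined with
|log₂FC| ≥ 1 (p ≤ 0.05 "DE", p ≤ 0.01 "significant"); a
Benjamini–Hochberg column is emitted for reference but never gates the
flags, matching the raw-threshold convention of this study design.
Correctness is verified against an exact-rational oracle
(`fractions.Fraction`) over x, y ≤ 200 and N₂/N₁ ∈ {½, 1, 2}.

## Degradome analysis

Degradome tags are annotated with precedence rRNA > tRNA > snRNA >
snoRNA > poly(N) (≥ 10 % N or a run of ≥ 5) > cDNA_sense >
cDNA_antisense > other; tags are truncated to their first 20 nt for
transcript mapping, and sense-mapped 5' ends accumulate per-transcript
abundance profiles. miRNAs are aligned antiparallel to transcripts with
the standard plant penalty scheme — mismatch 1, G:U 0.5, doubled over
miRNA positions 2–13, cutoff 4.5. The search is restricted to gapless
duplexes: with the core doubled, a single gap (penalty 2, doubled to 4
in positions 2–13, and disallowed opposite positions 10–11) leaves
almost no scoring room under the 4.5 cutoff, and the gapless search is
exactly rescorable by a sliding-window oracle.

A candidate duplex becomes a target hit when tags start exactly at the
position opposite miRNA positions 10–11 (window start + miRNA length −
10). Hits are ranked by t-plot category within the transcript profile:
**4** exactly one raw read; **0** unique maximum; **1** tied maximum;
**2** above the median; **3** at/below the median with > 1 read. The
singleton rule is evaluated first, and the median is computed over
positions with ≥ 1 read only — over all positions, zero-inflation would
force nearly every site above the median.

## qPCR

ΔCt = Ct_gene − Ct_reference paired by replicate index (same RNA
preparation); ΔΔCt = ΔCt_treated − mean(ΔCt_control); fold = 2^−ΔΔCt
with control folds rescaled to mean exactly 1 (per-mean scaling; the
alternative per-replicate normalization was an open choice). Conditions
are compared with Welch's unequal-variance two-sided t-test on
per-replicate folds — the safer default when only "independent t-test"
is specified; the degenerate all-equal case returns p = 1.

## Synthetic data generator

The generator emulates a two-library (control vs drought-treated)
experiment plus two degradome libraries and a qPCR plate:

* **Hairpin loci** are built constructively — stem arm (18–28 nt outer
  context + mature + 4–8 nt inner spacer), a 10–15 nt terminal loop, and
  the reverse complement of the arm with 0–2 substitutions injected only
  opposite the flanking context — and embedded in host transcripts. This
  guarantees every planted precursor satisfies the caller's criteria
  (asserted by a self-consistency test). Conserved matures are copied
  into the known-mature database with ≤ 2 substitutions; novel matures
  are kept > 2 mismatches from every database entry.
* **Counts** follow a negative binomial via the gamma–Poisson mixture,
  var = μ + φμ² (φ = 0.05 by default; φ → 0 recovers Poisson), with
  control means proportional to library depth and treated means scaled
  by 2^lfc. Planted log₂ fold changes default to ±1.5/±2 balanced in
  sign so library totals stay comparable; 40 % of miRNAs are DE by
  default. The study itself gives no distributional statement for
  counts — NB is this package's stand-in.
* **Reads** are 36 nt: insert + 3' adapter + random fill, Phred 40, at a
  default depth of 60,000 per library, with ~10 % noncoding-derived
  fragments, 5 % random background, and 5 % decoys (too-short, too-long,
  poly(A), low-quality) exercising every cleaning rule. Star reads are
  planted at 1–2 copies per library — detectable as miRNA* evidence but
  below the novel-call count threshold, as befits their much lower
  biological abundance.
* **Degradome tags** of 20 nt start exactly at each planted cleavage
  position (opposite miRNA positions 10–11 of a target site that is the
  reverse complement of the mature) at ~50–60 copies, over uniform
  singleton background and noncoding/poly(N) decoys.
* **Ct values** encode the planted fold changes at one PCR cycle per
  doubling with 0.12-cycle replicate noise.

Everything is deterministic for a fixed seed, byte-for-byte.

The default problem size (60 transcripts of 0.6–1.2 kb, 10 conserved +
15 novel miRNAs, 60 k reads/library) is chosen so a full pipeline run
takes seconds while every code path — including all decoy classes and
both hairpin arms — is exercised; it is a scaled-down study, not a
read-for-read emulation of a production sequencing run.

**What passing on synthetic data does not show:** the generator draws
uniform random transcripts (no repeats, paralogy or compositional bias),
plants exact-match matures (no isomiR ladders or sequencing errors), and
its degradome background is uniform (real degradation is structured).
Recovery rates here demonstrate correctness of the algorithms under the
model's assumptions, not expected sensitivity on real libraries.

## Numerical and design choices

* Integer deci-kcal energies: exact DP/oracle agreement, no float ties.
* Exact-test tails via `logsumexp`; absolute agreement with the rational
  oracle is ~10⁻¹³ over the tested grid.
* Percentages in rendered tables use decimal half-up rounding to two
  decimals, reproducing printed summary-table cells bit-exactly from
  their integers; machine TSVs never carry thousands separators (a
  `--pretty` variant does).
* Cleavage sites shared by several miRNAs are counted once (best-scoring
  hit) in the per-category site tallies.
* Type-I error of the DE caller on null fixtures runs ~4 % at the
  nominal 5 % p-threshold combined with the fold-change gate; the NB
  overdispersion (φ = 0.05) makes the Poisson-family exact test slightly
  anticonservative, which the |log₂FC| ≥ 1 gate offsets.

## Known limitations

* Folding ignores dangling ends, terminal-mismatch and special-hairpin
  bonuses; coaxial stacking and pseudoknots are out of scope.
* Target search is transcript-based (sense strand) and gapless.
* No replicate-aware DE model (no dispersion estimation); the exact test
  conditions on single library pairs, as in the study design it mirrors.
* Annotation uses exact-substring noncoding matching, not covariance
  models; genomic context (exon/intron/intergenic) is not modeled.
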