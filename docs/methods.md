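# Methods

## The screen

The core procedure correlates every transcription factor (TF) with
every structural gene (SG) of a biosynthetic pathway across an ordered
developmental axis (default: 7, 14, 21, 28, 35, 42, 49 days after
flowering).  For each (TF, SG) pair in one genotype:

1. both series must clear the expression floor (RPKM ≥ `min_rpkm`,
   default 5.0, in at least `min_stages_expressed` stages, default 1);
2. Pearson *r* is computed on the chosen scale (raw RPKM by default —
   the screen was historically run on RPKM tables directly — or
   log2(RPKM + pseudocount));
3. the pair is *significant* iff |*r*| ≥ `r_threshold` (default 0.8)
   **and** *t* = *r*√(*n*−2)/√(1−*r*²) exceeds the two-sided Student-*t*
   critical value at level `alpha` (default 0.05) with *n*−2 degrees of
   freedom.  For *n* = 7 and α = 0.05 the *t*-rule is |*r*| > 0.754, so
   at the default 0.8 cut the double condition is conservative but
   harmless; it matters when the user lowers `r_threshold`.

Requiring both conditions rather than choosing one is deliberate: the
two published statements of the rule (a 0.8 screening cut, and
*t*-test significance equivalent to r > 0.754 at n = 7) are both
honored, and each remains individually configurable.

Genotypes are screened independently at *n* = 7 each, never pooled to
*n* = 14: the two cultivars ripen on different schedules, so pooling
would mix distinct stage-to-physiology mappings and inflate *n*.

A series with zero variance after filtering has no defined correlation.
Such pairs are **excluded with a recorded reason**, never scored as
*r* = 0 — scoring them as zero would silently deflate per-TF counts
with a number that has no statistical meaning.

Note that at exactly r = 0.754 the *t* statistic evaluates to 2.567;
the exact α = 0.05 threshold is r = 0.75449…, whose *t* is the critical
2.5706.  The implementation always uses the exact inversion
(`significance_threshold_r`), quoting 0.754 only as a display value.

Per TF, `n_correlated` counts significant SGs and `n_positive` the
subset with r > 0 (rendered `N(P)`).  Candidate selection keeps TFs
with `n_correlated ≥ min_count` in every genotype (`require_both`) or
in at least one; defaults per pathway are ascorbate ≥ 15 (either
genotype), carotenoid ≥ 5 (both), flavonoid ≥ 2 (either) — the
published inclusion rules are not fully stated, so these are
configurable.  No multiple-testing correction is applied by default
(matching the published screening convention); a Benjamini–Hochberg helper is
provided as a clearly optional extension.

## Quantification and fold-change conventions

RPKM = 10⁹·count/(library_size·gene_length).  Stage-over-stage tables
carry four record kinds, driven by a detection floor (default exactly
0): RATIO (both stages detected; value = later/earlier), FROM_ZERO
(switch-on; the value carried is the later-stage RPKM itself, rendered
`value/0`), TO_ZERO (switch-off, rendered `0`) and NOT_DETECTED
(neither stage detected, rendered `-`).  TO_ZERO exists because a
switch-off cell cannot be a RATIO (a ratio of 0 is not a positive fold
change) yet must render distinctly from `-`.  Differential-expression
calls take an externally supplied p-value (typically produced by a
dedicated count-model tool such as edgeR, which is not reimplemented
here): |log2 ratio| > 2.0 and p < 0.01 by
default, degrading to a fold-change-only rule when no p-value is given.
FROM_ZERO records are excluded from log2-based calls unless explicitly
flagged as infinite fold changes.

## Temporal clustering

Clustering operates on log2(RPKM + 1) without per-gene standardization:
the grouping is meant to separate abundance courses, and the published
pattern groups were formed on log2 values with no mention of z-scoring.
K-means uses Euclidean distance and Lloyd iterations with `n_init`
restarts (default 10), split between k-means++ seeding and
random-partition seeding, and each restart is finished with a Hartigan
single-point polish (accept the best single reassignment counting the
centroid shift it causes, repeat until stable, cap 200 moves).  The
mixed scheme exists because k-means++ seeds centroids at data points,
and on small instances the global optimum's basin sometimes contains
no data-point seed pair; random-partition seeds and Hartigan moves
both reach such optima.  On 6-point instances this combination matches
the exhaustively enumerated optimal bipartition in 100/100 random
trials.  Group labels are renumbered 1..k by descending size so reruns
and genotypes give comparable, stable numbering; ties break by original
centroid order.  Genes are filtered for expression before clustering;
the two genotypes are clustered separately by default (joint clustering
over 14 columns is available in the CLI by concatenating inputs).

The stage correlation matrix is plain Pearson over the common gene set
for every pair of genotype × stage columns, with zero-variance columns
rejected by name.  The grid is symmetrized and its diagonal pinned to
exactly 1 to absorb float round-off.

## Metabolite association

A metabolite's stage course is correlated against structural genes and
TFs through the *same* code path as the TF screen (the metabolite takes
the source role), so the significance rule cannot drift between the two
analyses.  The metabolite enters on its measured concentration scale —
no transform is applied, as the screening convention it follows states
none — while genes follow the configured scale.  Ascorbate is
carried as three distinct series (total, reduced AsA, oxidized DHA).

## The synthetic generator

`simulate_experiment` emulates the statistical structure the screen
assumes, at a realistic fruit-transcriptome scale by default: 2 genotypes × 7 stages,
823 TFs, pathway sizes 46/18/14, 25,000 background genes, 20 temporal
archetypes, 50 planted signed TF→target links (30/12/8 per pathway,
allocated roughly proportionally to pathway size).

* **Archetypes** are unit-scaled canonical shapes (monotone rise/fall,
  peaks and valleys at varying positions, high-low-high, near-flat
  high, late induction, …).  Candidates correlating at r ≥ 0.95 with an
  accepted shape are skipped; beyond the base family, parameterized
  variants are generated, so any k is served without duplicates.  The
  check is on signed r: mirror-image shapes (r = −1) are distinct
  patterns, not duplicates.
* **Expression**: each gene's log2 profile is baseline + amplitude ×
  (centered archetype) + N(0, `noise_sd`) per stage.  Noise is
  log-normal on the RPKM scale (additive on log2), keeping values
  positive and matching multiplicative biological variability.
  Baselines span log2 ∈ [2.5, 7.5] for TFs and structural genes (the
  expressed range the screen operates on) and [−1.5, 7.5] for
  background genes, so the RPKM ≥ 5 floor removes a realistic fraction
  (~25%) of the universe.
* **Planted links** set the target's log2 profile to baseline +
  `effect_size` × sign × (regulator's realized log2 profile, centered)
  + independent noise.  Each target has exactly one regulator — two
  conflicting parents cannot both be reproduced — so per-pathway link
  counts may not exceed the pathway size.  With `noise_sd = 0` every
  planted pair correlates at exactly ±1 on the log2 scale; recovery is
  therefore *scored* with a log2-scale screen (pseudocount 0), where
  the planted relation is affine.  On the raw scale a negative link is
  y ∝ 1/x, which is not affine, so raw-scale |r| would be slightly
  below 1 even without noise.
* **Second genotype** reuses the same truth but lags ripening-linked
  archetypes by one stage (edge-held shift), emulating an early- vs
  late-maturing cultivar pair.
* **Metabolites** accumulate as the cumulative stage-sum of their
  pathway's mean expression times a rate, with multiplicative noise —
  a modeling choice (metabolites integrate upstream enzyme activity),
  not a claim about the original measurements.  Declining metabolite
  courses (e.g. chlorogenic acid in real fruit) are not reproduced.
* **Counts** (optional): negative-binomial reads at a given dispersion
  and library size (5 × 10⁶ by default, a typical per-sample depth of
  uniquely mapped reads), with RPKM recomputed from the draws;
  dispersion 0 falls back to Poisson, under which recomputed RPKM
  converges to the intended profile as the library deepens.
* All randomness flows from a single `numpy` Generator seeded by
  `seed`; identical configs give bit-identical output.

What the generator does **not** emulate: read-level artifacts (mapping
bias, multi-mapping, coverage non-uniformity), gene-gene correlation
beyond archetype sharing and planted links, genotype-specific
regulatory rewiring, and compositional effects of library
normalization.  Passing recovery tests therefore demonstrates that the
screen's statistics behave as designed under its own assumptions — not
that the screen is robust to everything real RNA-seq does.

## Null calibration

Type-I error of the r > 0.754 rule is measured on archetype-free flat
profiles (log2 values iid Gaussian per stage), where the correlation
t-test is exact; the significant fraction over 22,500 pairs sits within
3 standard errors of α = 0.05.  Pairs built from 150 source × 150
target series share rows and are not strictly independent, which
slightly inflates the spread of the estimate but not its mean.

## Problem sizes and runtime choices

The test suite and the acceptance script run the full-scale default
simulation where a single run suffices (planted-link recovery:
25,901 genes, 823 TFs) and a reduced generator (150 TFs, 200 background
genes — background genes play no role in the screen) for the
20-replicate noise-monotonicity sweep, keeping the whole suite around
ten seconds.  The clustering global-optimum check uses 6-profile
instances because 2-part partitions (31) can be enumerated exactly.

## Known limitations

* The screen is pairwise correlation only: no partial correlation,
  no network deconvolution, no causality.  A TF sharing a target's
  temporal archetype is indistinguishable from its regulator — the
  high false-discovery proportion against planted truth quantifies
  exactly this ambiguity.
* The published per-group gene counts and differential-expression
  totals of the source dataset depend on the real sequencing data and
  on edgeR internals, and are intentionally not reproduction targets;
  reproduction of the published per-TF candidate counts requires the
  study's supplementary RPKM tables exported as TSV under
  `data/supplementary/` (see `tests/test_acceptance.py`), and the
  suite passes without them.
* `expression_filter` treats missing values as impermissible by design;
  upstream absence must be encoded as 0.
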