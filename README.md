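# stagescreen

Stage-course co-expression screening of transcription factors against
biosynthetic pathway genes in developing fruit.

## The problem

During tomato fruit development and ripening, the enzymes of the
ascorbate (vitamin C), carotenoid and flavonoid biosynthetic pathways
are transcriptionally regulated, but the transcription factors (TFs)
doing the regulating are largely unknown.  A classic way to nominate
candidates from a developmental RNA-seq time course is a *co-expression
screen*: correlate every annotated TF with every pathway structural
gene (SG) across the sampled stages, call a pair co-expressed when the
correlation clears a significance rule, and rank TFs by how many
pathway genes they track.  `stagescreen` implements that screen as a
tested, reusable pipeline — quantification and filtering, temporal
pattern clustering, the TF screen itself, metabolite–transcript
correlation — together with a synthetic data generator that plants
known TF→target links so every stage of the analysis can be validated
against ground truth without access to the original sequencing data.

It is aimed at computational biologists who want either the screen
itself (the `stagescreen` library/CLI) or a calibrated testbed for
time-course co-expression methods (the `stagescreen.synthetic_data`
generator plus recovery scoring).

## The statistics at the core

* **Expression**: RPKM = 10⁹ · *reads* / (*library size* · *gene
  length*), with an expression floor (RPKM ≥ 5 in at least one of the
  seven stages, 7–49 days after flowering sampled weekly) applied to
  both TFs and structural genes before screening.
* **Correlation significance**: Pearson *r* over the *n* = 7 stage
  points, tested with *t* = *r*·√(*n*−2)/√(1−*r*²) against the
  two-sided Student-*t* critical value with *n*−2 = 5 degrees of
  freedom.  At α = 0.05 the critical *t* is 2.571, equivalently
  |*r*| > 0.754.  A pair is called significant when **both** the
  screening cut |*r*| ≥ 0.8 and the *t*-test hold; genotypes are always
  screened separately (never pooled to *n* = 14).
* **Candidate table**: per TF and pathway, `N(P)` = number of
  significantly correlated structural genes (`N`) and the positively
  correlated subset (`P`), per genotype; candidates are selected by
  per-pathway count thresholds.
* **Temporal patterns**: K-means (Lloyd + k-means++/random-partition
  restarts, finished with a Hartigan single-point polish) on
  log2(RPKM + 1) profiles, *k* = 20 groups.
* **Fold-change conventions**: stage-over-stage tables use the
  published cell codes — a numeric ratio, `-` (no expression in either
  stage), `12.29/0` (switched on; the value is the later-stage RPKM)
  and `0` (switched off).

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic dataset (two genotypes × 7 stages, ~25,900 genes, 823
TFs, pathway sizes 46/18/14, 50 planted TF→target links, seed 1):

```
$ python analysis/01_simulate.py
AC: 25901 genes x 7 stages -> expression_AC.tsv
HG6-61: 25901 genes x 7 stages -> expression_HG6-61.tsv
50 planted links recorded in truth.json; 20 metabolite series written

$ python analysis/02_filter_foldchange.py
AC: 19065/25901 genes at RPKM >= 5.0 in >= 1 stage(s)
...

$ python analysis/03_cluster.py
AC: k=20, SSE=60817, largest groups [1384, 1251, 1247]
HG6-61: k=20, SSE=59011, largest groups [1508, 1437, 1236]
between-genotype same-stage correlation: 0.992 0.993 0.991 0.987 0.910 0.923 0.848

$ python analysis/04_screen.py
ascorbate: 12862 significant TF-gene pairs, 143 candidate TFs (>= 15 correlated genes, either genotype)
  top candidate TF0005 (AUX/IAA): AC=13(9), HG6-61=19(15)
...
planted-link recovery: sensitivity 0.98, FDP 1.00, sign accuracy 1.00 (49/50 links; ...)
```

Reading the output: ~74% of simulated genes clear the expression floor
(real tomato fruit data keep about 76%); the same-stage correlation between the
early- and late-maturing genotype declines toward ripening (0.992 →
0.848) because ripening-linked expression programs are lagged in the
second genotype; the screen recovers 49 of the 50 planted regulatory
links with every recovered sign correct.  The high false-discovery
proportion is expected and informative: with 823 TFs sharing 20
temporal archetypes, many TF–gene pairs are genuinely co-expressed
without being the planted regulator — exactly the ambiguity a real
co-expression screen faces.

The same stages are available as CLI subcommands
(`stagescreen simulate|filter|cluster|screen|metab-corr|run`), e.g.:

```
stagescreen run --config configs/demo.json --out-dir out/
```

which executes all five stages from a JSON config and writes a
`manifest.json` with SHA-256 digests of every output for byte-exact
reproducibility.

## Layout

```
src/stagescreen/        the library (data model, quantification,
                        clustering, co-expression screen, metabolite
                        association, synthetic data, pipeline, CLI)
analysis/               numbered narrative drivers over the library
tests/                  pytest suite (unit, property and end-to-end)
scripts/acceptance.py   headline-number reproduction
configs/demo.json       small demo pipeline config
docs/methods.md         models, assumptions, parameter choices
```
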