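# Methods

`circsponge` implements a circRNA–miRNA–mRNA "sponge network" analysis for
case/control bulk RNA-seq cohorts, together with a synthetic-study generator
that plants a known ground truth through the whole chain. This note records
the models, the defaults and why, the numerical choices, and what the
synthetic data do and do not demonstrate.

## Consensus circRNA calling

Back-spliced junctions (BSJs) are identified by `(chrom, start, end)` in
1-based inclusive coordinates; the canonical ID string is `chrom:start|end`.
Strand is carried but excluded from junction identity: the two caller
families occasionally disagree on strand for the same event, and the ID
format used throughout omits it.

Two caller-output dialects are read: a CIRI2-style table (1-based inclusive,
with an ID column) and a CIRCexplorer2-style BED-derived table (0-based
half-open). Only the CIRCexplorer2-style output is filtered for read
support (≥ 2 junction-spanning reads by default); the CIRI2-style output is
taken as published. Bona fide circRNAs are the exact intersection of the
two pooled candidate lists (a per-sample intersection mode is available
behind a flag). Consensus counts per junction and sample are the
arithmetic mean of the two callers' junction read counts, with a junction
absent from one caller in a given sample contributing 0 on that side —
consensus membership is decided at the junction level, not per sample.
Averaged counts are kept fractional; all downstream work is on log-CPM, so
integrality is never needed.

"Detected in a condition" means present with a positive count in at least
one sample of that condition; the detection summary then reports
case/control/common/unique cardinalities per tissue by inclusion–exclusion.

## Filtering, normalization, differential expression

* **Expression filter.** A feature is kept if its CPM is at least
  `min_cpm` (default 10) in at least `min_samples` samples (default 9; an
  alternative rule `ceil(0.7 × smallest tissue dataset)` is available via
  `use_auto_min_samples`).
* **TMM.** The reference sample is the column whose upper-quartile CPM is
  closest to the mean upper-quartile. For each other sample, log-ratios
  `M = log2((x/N)/(x_r/N_r))` and abundances `A = ½·log2((x/N)(x_r/N_r))`
  are computed over features nonzero in both; the extreme 30 % of M and
  5 % of A are trimmed on each side (rank-based); the factor is
  `2^(Σ M/v / Σ 1/v)` with delta-method variances
  `v = (N−x)/(Nx) + (N_r−x_r)/(N_r x_r)`; factors are rescaled to geometric
  mean exactly 1. A sample with no common nonzero features gets factor 1
  with a warning. Note the trimmed set is depth-invariant but the
  precision weights are not, so scaling one column's depth changes the
  factors at the ~1 % level; pure depth-replicate columns give factors of
  exactly 1. The implementation is verified against edgeR's
  `calcNormFactors` to 1e-6 in the test suite.
* **log-CPM.** `log2((x + p) / (N·f + 2p) × 1e6)` with prior count
  `p = 0.5`; finite for zero counts.
* **Moderated t.** Per feature, OLS of log-CPM on an intercept + case
  indicator (+ optional covariates). Residual variances `s²_g` with `d`
  degrees of freedom are shrunk toward a prior `(d₀, s₀²)` estimated by
  matching the first two moments of `log s²_g` through digamma/trigamma
  identities (Newton inversion of the trigamma function). The posterior
  variance is `s̃² = (d₀s₀² + d s²)/(d₀ + d)`; the statistic
  `t = β̂ / (se_unit · s̃)` is referred to a t distribution with
  `min(d₀ + d, G·d)` degrees of freedom (the cap is the complete-pooling
  limit). If the trigamma equation has no positive solution, `d₀ = ∞` and
  `s₀²` is the mean of the `s²_g`. `d₀ = 0` reproduces the ordinary
  two-sample t exactly; the whole path is verified against limma's
  `eBayes` in the tests.
* **Multiple testing.** Benjamini–Hochberg step-up, reported in input
  order; the procedure is stated explicitly because downstream significant-
  feature counts depend on it.
* **Per-tissue analysis.** DE is always computed within a tissue, never
  pooled across tissues.

## Covariate variance assessment

For each feature, the fixed-effects model
`log-CPM ~ RIN + PMI + sex + group` is decomposed into per-covariate R²
fractions by the order-averaged sequential sum of squares (the LMG/Shapley
decomposition over all covariate orderings), plus a residual fraction;
fractions sum to 1 per feature. The median fraction per covariate across
features is the decision statistic: with `auto_covariates` enabled,
covariates at or above `variance_threshold` (default 4.5 %) are retained in
the DE design; by default quality covariates are excluded from the design,
matching the observed-data regime in which their median contribution falls
below that threshold. This fixed-effects partition deliberately replaces a
mixed-effects/variance-stabilizing-transform treatment: it keeps the
decision rule while avoiding heavy machinery, and is testable by recovery
of planted variance fractions. Constant covariates get fraction 0 with a
warning.

## Seed-site scanning on circular sequences

The seed is miRNA nucleotides 2–7; a target site is an occurrence of the
reverse complement of the seed, classified canonically:

| class   | requirement                                         | span |
|---------|-----------------------------------------------------|------|
| 6mer    | seed match only                                     | 6    |
| 7mer-A1 | seed match + A on the target 3′ of the hexamer      | 7    |
| 7mer-m8 | seed match + pairing of miRNA nt 8 5′ of the hexamer| 7    |
| 8mer    | both the m8 pair and the A1 adenine                 | 8    |

Each hexamer match yields exactly one site of its best class (an 8mer is
never double-reported as a weaker class). `start` is the 1-based position
of the first nucleotide of the full span (the m8 position for m8-containing
classes), a convention that makes planting and recovery positions coincide
for every class. Because circRNAs are covalently closed, circular scanning
wraps matches across the sequence end (the BSJ) and flags them with
`wraps_junction = start + span − 1 > length`. Overlapping sites of one
miRNA at distinct starts are counted separately — averages such as "sites
per circRNA" are raw occurrence counts. All four classes are counted by
default (`site_classes` restricts them).

miRNA selection is two-staged: keep miRNAs with sites in at least
`min_circ` (default 10) distinct DE circRNAs in some tissue, then rank by
total site count over upregulated DE circRNAs pooled across tissues
(descending, ties broken lexicographically by ID — determinism) and take
the top `top_k` (default 12). "Upregulated across tissues" is the union of
per-tissue upregulated sets. Affected genes are the targets of selected
miRNAs that are significantly upregulated (`adj_p < α`, `log2fc > 0`);
context-score filtering is off by default (no published cutoff) and
available via `max_context_score`. The tripartite network has
circRNA→miRNA edges where a selected miRNA has a positive site count on an
upregulated DE circRNA and miRNA→mRNA edges where a selected miRNA targets
an affected gene; node size is `log2(degree)`.

## Enrichment

One-sided hypergeometric upper tail `P(X ≥ k)` per gene set, BH across the
collection. The universe is the set of genes present in the analysed
(filtered) gene matrix, not the whole annotation — standard
over-representation practice. Both raw and adjusted p-values are reported.

## The synthetic-study generator

The generator emulates a three-region spinal-cord cohort: tissues SCC, SCT,
SCL with 18/7, 16/6 and 16/6 case/control samples (the roughly 2.6:1 design
of the motivating cohort), RIN higher in cases (7–9.5 vs 3.5–7.3) and PMI
shorter (2–15 h vs 5–25 h).

* **Counts.** Negative binomial with a single common dispersion
  (default 0.1) and per-feature log2 baselines `N(5, 1.5)` (circRNA
  baselines floored at 4 counts so every consensus junction is detectable
  in both callers). DE features get a ±`lfc_magnitude` (default 2.0)
  condition offset; the planted DE sets are disjoint across tissues
  (matching the observed absence of cross-tissue overlap), with 70 % of
  each tissue's share upregulated. Defaults: 300 circRNAs (240 shared
  between callers at `caller_overlap = 0.8`), 2 000 genes, 20 % DE
  circRNAs, 10 % DE genes. The gene count is deliberately desk-scale; the
  motivating study tested ~60 000 StringTie gene rows, and nothing in the
  machinery depends on the feature count.
* **Covariate effects** enter as linear terms on the log2 mean with a
  random sign per feature — a shift common to all features would be
  absorbed into the library size and erased by CPM normalization — with
  coefficients calibrated against the approximate NB log-scale variance so
  that a requested variance fraction is recovered by the partition stage.
  All fractions default to 0.
* **Caller tables.** Shared junctions get both callers' counts as the
  underlying NB count times independent ±20 % multiplicative jitter
  (exercising the count-averaging rule); each caller additionally gets its
  own unique junctions at lower abundance. The two tables share exactly
  `round(caller_overlap × n_circ)` junctions.
* **Sequences and planted sites.** Background circRNA sequence (400 nt) is
  drawn from a first-order chain that never emits C after C, and every
  panel miRNA seed contains GG — so every target hexamer contains CC and
  the background is provably seed-free for the whole panel. The 12
  "sponge" miRNAs (the plantable subset) additionally satisfy a
  shifted-occurrence exclusion: no panel hexamer may match a sponge motif
  padded with wildcard flanks at any offset, which removes the dominant
  source of spurious sites at motif boundaries. Sites (default one per
  sponge miRNA per upregulated DE circRNA, cycling through the four
  classes, ~20 % wrapping the junction) are planted as exact motifs with
  flank bases adjusted so the planted class is exactly what a scanner
  recovers; each sequence is then verified by scanning against the full
  panel, with a randomized local repair of any residual boundary artefact
  and position re-draws as a fallback. The result is exact:
  planted-site recall and precision are 1.0 by construction, and the tests
  assert it.
* **Targets and gene sets.** Sponge miRNAs target a chosen subset
  (default 30) of upregulated DE genes from the two scanned tissues
  (the planted "affected" set) plus non-DE decoys; background miRNAs get
  unconstrained decoy targets. The GMT contains one term holding the
  affected genes (plus padding) and 19 random background terms, so the
  planted term must attain the smallest enrichment p.
* **Determinism.** All randomness flows from one `SeedSequence` spawned
  into per-component streams; identical configuration and seed give
  byte-identical files.

### What passing on synthetic data does and does not show

The generator produces clean NB counts with a common dispersion, exact
planted effects, a seed-free background and noiseless metadata. Passing
the recovery tests therefore demonstrates that the *machinery* is correct
(coordinate handling, normalization, moderation, scanning, selection,
intersection, graph assembly), not that the biological pipeline would make
the same calls on real tissue: real data have per-feature dispersions,
batch structure, mapping artefacts, incomplete caller concordance beyond a
simple overlap fraction, and miRNA seeds without convenient forbidden
dinucleotides. The sponge-triple recovery in particular relies on the
seed-free background and large planted effects; it is a correctness check,
not a power analysis.

## Numerical choices and degenerate inputs

* Trigamma inversion by Newton iteration on the asymptotic-scale start
  point, tolerance 1e-10; inputs ≤ 0 map to `d₀ = ∞`.
* BH is vectorised step-up with a stable mergesort, so tied p-values are
  handled identically in any input order.
* `detection_summary` validates `common ≤ min(case, control)` and derives
  unique counts rather than accepting them.
* Percentages in DE summaries round half away from zero.
* Zero-TSS (constant) features get residual fraction 1 and zero covariate
  fractions; constant covariates get fraction 0 with a warning.
* A significant feature with `log2fc == 0` counts as neither up nor down
  (warned) — it cannot occur with continuous data but is defined anyway.
* The empty network writes header-only files; GraphML export goes through
  networkx.

## Problem sizes

Defaults throughout (and in the verification script) are the synthetic
cohort above: 69 samples, 300 circRNAs, 2 000 genes, 150 panel miRNAs.
A full simulated run of every stage completes in a few seconds on one CPU;
the calibration checks (null type-I error at 2 000 features, FDR/
sensitivity over 20 replicates) run in well under a minute.

## Known limitations

* No read-level simulation or alignment; caller behaviour is modelled only
  at the candidate-table level.
* No thermodynamic duplex scoring, conservation, or context++ computation;
  target strengths are consumed as input scores.
* The variance partition is fixed-effects only; repeated donors (the same
  patient contributing several tissues) are not modelled as random effects.
* Exact NB tests, quasi-likelihood F tests and voom-style precision
  weights are intentionally out of scope; DE is plain moderated t on
  log-CPM.
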