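# Methods

`mirpair` discovers miRNA–mRNA interaction pairs that are conserved across
tumour types. It chains six statistical stages over per-tumour count
matrices and validates all of them end to end on a synthetic cohort
generator with planted ground truth. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not show.

## Cohort inclusion

A tumour type enters the analysis only if it has at least 10 healthy
(control) samples and controls make up at least 5% of its samples
(`validate_cohort`). Both bounds are inclusive; exclusions are reported
with their reasons.

## Differential expression (`mirpair.de`)

Counts are modelled as negative binomial with the mean–dispersion
parameterisation `var = mu + phi * mu^2`, one common `phi` across features.

1. **Filtering.** Features with CPM < 1 are removed; a feature is kept if
   CPM >= 1 in at least `min_samples` samples (default: the smaller group
   size). The threshold is inclusive, reading the removal rule "CPM < 1"
   literally.
2. **TMM normalisation.** For sample *k* against a reference *r* (the
   column whose upper CPM quartile is closest to the mean upper quartile),
   over features positive in both: `M_g = log2((y_gk/N_k)/(y_gr/N_r))`,
   `A_g = 0.5*log2((y_gk/N_k)(y_gr/N_r))`. Features are doubly trimmed
   (30% on M, 5% on A, rank-based) and the factor is
   `2^(sum w_g M_g / sum w_g)` with inverse asymptotic-variance weights
   `w_g = (N_k - y_gk)/(N_k y_gk) + (N_r - y_gr)/(N_r y_gr)`; factors are
   rescaled to geometric mean 1. If trimming removes every feature the
   factor falls back to 1 with a warning.
3. **Dispersion.** Effective libraries (library size x TMM factor) are
   equalised to their geometric mean by a quantile mapping of counts
   between NB distributions (average of a variance-matched linear map and
   a gamma quantile–quantile map). The common dispersion maximises the
   conditional log-likelihood of these pseudo-counts given the group sums,
   optimised over `delta = phi/(1+phi)`; two equalise/optimise rounds are
   used. If the optimisation fails a method-of-moments estimate (median
   across features of `(s^2 - m)/m^2` on library-scaled counts) is the
   fallback. Numerical identity with any particular reference
   implementation is not claimed; the test suite checks the engine by
   simulation calibration instead (type-I error within [0.035, 0.065] at
   nominal 0.05; power >= 0.9 at log2FC 2, mean count 100, 10 vs 10).
4. **Exact test.** Conditional on the per-feature total of the rounded
   pseudo-counts, group sums are NB with means proportional to group sizes
   and dispersions `phi/n_group`. The two-sided p-value is the total
   conditional probability of splits at most as probable as the observed
   one (no tail doubling; float ties are absorbed with a relative 1e-10
   tolerance). At `phi = 0` this reduces exactly to a conditional binomial
   test, which is what the enumeration oracle in the tests checks. For
   totals above 10,000 a beta approximation to the split distribution
   (shape parameters `n_group/phi`, continuity-corrected, doubled tails)
   replaces the enumeration; this only engages far from the discrete
   regime.
5. **Selection.** log2 fold changes are tumour vs control with a prior
   count of 0.125 added to each group mean; BH-adjusted p-values; DE means
   `fdr < 0.05` AND `|log2FC| > 1`, both strict.

## Pathway enrichment (`mirpair.enrichment`)

Per tumour type, DE genes are crossed with each curated pathway over the
universe of genes expressed (CPM-filtered) in that type:
`[[DE&P, DE\P], [nonDE&P, nonDE\P]]`, two-sided Fisher exact test, BH
across the seven pathways. The odds ratio `ad/bc` is the effect measure;
OR > 1 means the pathway is enriched in altered genes, OR < 1 depleted
(the pathway behaves like healthy tissue). Two-sidedness here is a design
choice: both directions are biologically reportable, whereas the
recurrence-threshold and specificity tests below are right-tailed because
only enrichment is meaningful there. When a cell is zero the *reported* OR
uses the Haldane–Anscombe 0.5 correction; inference always uses the
uncorrected table. A size-matched random-gene-set control
(`random_control`) provides a null OR distribution for comparison.

## Cross-tumour recurrence (`mirpair.integration`)

A feature's recurrence is the number of distinct tumour types where it is
DE, counting both directions (a gene may be up in some types, down in
others; both are retained). The recurrence cut-off is chosen by scanning
T = 5..10: at each T, features with recurrence >= T are crossed with a
known cancer gene/miRNA list over the expressed universe (right-tailed
Fisher, BH across the scanned thresholds) and the chosen T maximises the
odds ratio among thresholds with fdr < 0.05. Ties break toward the smaller
T (more features retained); zero-cell tables are ranked by the
Haldane-corrected OR so that fully-contained known lists still order the
scan; empty selections are excluded. Gene and miRNA thresholds are
optimised independently against their own known lists.

## Pairing (`mirpair.pairing`)

Candidate interactions come from a predicted-target catalogue carrying a
genomic-agreement count (distinct prediction methods at the same 3'UTR
position); only edges with agreement >= 2 qualify. A pair instance is one
(tumour type, edge) where the miRNA and gene are DE in opposite
directions, with genes restricted to the pathway universe. miRNA names are
matched case-insensitively with the `hsa-` prefix stripped.

* **Conserved pairs** keep instances whose both members passed the
  recurrence cut-off, aggregated per pair with their tumour-type lists.
* **Exclusive pairs** occur in exactly one tumour type; a group query
  (e.g. the two lung types) returns pairs whose full support is inside the
  group and spans more than one of its members.
* **Specificity.** For each distinct pair (m, g) over all instances the
  table `[[#(m,g), #(m,-g)], [#(-m,g), #(-m,-g)]]` is tested right-tailed
  and BH-adjusted over all pairs; a small p marks a pair that recurs
  across tumours while both partners have few co-interactors. The pooled
  single-table layout was chosen over two one-sided (per-miRNA /
  per-gene) analyses; the counting helpers are small and separable so the
  marginal variants can be built from the same instance multiset. Adding
  co-interactors for a pair's miRNA can only make its right-tailed p
  larger, a property the tests verify over randomized instance sets.
* **Novelty.** Pairs present in the validated-pair list are flagged
  `validated`, the rest `novel`.
* Instances are counted once per (pair, tumour type); samples are never
  weighted, since the unit of recurrence is the tumour type.

## Covariate-adjusted regression (`mirpair.regression`)

For every candidate pair, gene expression is regressed on miRNA expression
in tumour samples, adjusting for copy number and methylation:

* Expression is `log2(RPKM + 1)`; RPKM = count x 1e9 / (library x
  length_bp). The pseudo-count guards zeros; base and pseudo-count are
  parameters of `log_expression`.
* CNA enters as an unordered categorical factor over its observed levels
  (−2..2). The source coding is ordered, but with Type-III sums of squares
  orderedness only changes the contrast basis, not the term's SS; plain
  categorical keeps the design transparent.
* Every methylation probe mapping to the gene enters as its own M-value
  covariate, `M = log2(beta/(1-beta))` with beta clamped to
  [1e-6, 1-1e-6]. Constant (variance < 1e-12) or aliased columns are
  dropped with a warning; incomplete cases are excluded.
* The joint model over all tumour types adds cancer type and the cancer
  type x miRNA interaction. Cancer type uses sum-to-zero contrasts so the
  miRNA main effect is the average within-type slope and its Type-III SS
  remains interpretable under the interaction.
* The pair correlation is `sign(beta_mir) * sqrt(SS_mir / SS_total)` where
  `SS_mir` is the miRNA term's Type-III sum of squares (for a 1-df term,
  `t^2 * s^2`). With no covariates this equals the Pearson r exactly, an
  identity the tests assert to 1e-10.
* A dataset where a member is undetected is recorded as `nonexistent`
  (correlation treated as 0, excluded from the FDR family). BH runs
  globally over every fitted (pair x dataset) test — with 15 tumour types
  plus the joint fit, 16 datasets per pair; a per-pair family is available
  as an option. The final selection keeps pairs with **negative** joint
  correlation at joint fdr < 0.05.
* Fewer than (columns + 2) complete cases also yields `nonexistent`.

## Survival (`mirpair.survival`)

Tumour stage is collapsed to binary prognosis: stages I/II (any
sub-letter) good; III/IV/X bad; for the prostate-like type, Gleason 6–7
good, >= 8 bad; unparseable records are excluded with a warning. Cox
proportional hazards with Efron tie handling (lifelines, Newton precision
1e-14) is fitted per tumour type with prognosis and `log2(RPKM+1)`
expression as covariates, so the expression Wald p is stage-independent by
construction. If prognosis has one level the covariate is dropped with a
warning; constant expression or non-convergent fits are flagged and
excluded from the BH family, which spans all (feature x tumour type)
tests. A (pair, type) cell is **supported** when the pair's per-type
correlation fdr and the gene's survival fdr are both < 0.05; pairs
supported in >= 2 types form the strongest stratum.

## Synthetic cohort generator (`mirpair.simulate`)

The generator emulates the data the pipeline consumes, with planted truth:

* **Counts.** NB (`var = mu + phi mu^2`, default `phi = 0.1`) around
  log-linear means. Per-feature baselines are `Normal(6, 1.5)` in log2
  relative abundance; per-sample depth factors are log-normal (sigma 0.3)
  around a nominal library of 1e6, so CPM/TMM steps are non-trivial.
* **Planted DE.** A fraction (default 0.2) of genes and miRNAs is shifted
  by ±2 log2 units in tumour samples of a random subset of
  `planted_recurrence` (default 10 of 15) tumour types.
* **Planted pairs.** 30 (miRNA, gene) pairs, alternating orientation
  (miR-up/gene-down and the reverse), sharing their planted type sets. The
  gene's log2 mean additionally moves by `pair_slope` (default −0.5) times
  the partner miRNA's realised log2(RPKM+1), centred on the miRNA's
  control-sample mean so baselines stay in range.
* **Confounding.** CNA levels are drawn per (gene, tumour sample) with
  probabilities (.02, .08, .80, .08, .02) for −2..2 and shift expression
  by `cna_effect` (0.5) per level. Methylation M-values are
  `Normal(probe baseline, 0.7)` per probe (3 probes/gene), beta =
  logistic(M); the gene mean moves by `met_effect` (−0.25) per unit of the
  gene's mean M, centred on the probe baselines. Controls carry no
  CNA/methylation, mirroring tumour-only molecular profiling; the
  regression stage operates on tumour samples.
* **Survival.** Exponential times with log hazard = log(1/1000) +
  0.8·bad_stage + 0.7·z(log2 expression) for each of 5 hazard-carrying
  genes (genes of the first 5 planted pairs). Five carriers is deliberate:
  every additional carrier acts as unmodelled frailty in the single-gene
  Cox fits and attenuates all estimates. Censoring is an independent
  exponential calibrated so the expected censored fraction equals
  `censor_rate` (0.3). Bad stage has probability 0.4; one tumour type
  carries Gleason grades instead of stages to exercise that coding path.
* **Catalogue and lists.** Planted edges get agreement 2–5. Decoys are 10x
  the planted edges: half agreement-1 (preferentially between inversely DE
  planted features, so the agreement filter — not the DE filter — rejects
  them), half agreement >= 2 between random, uncoupled features (the null
  pairs that exercise FDR control). Known-gene/miRNA lists are half of the
  planted features plus an equal number of background features; 40% of
  planted pairs form the validated-pair list. Seven pathways cover ~60% of
  genes including every pair gene.
* **Determinism.** One master stream keyed by the seed fixes cohort-level
  structure; per-type substreams fix samples. The same config and seed
  reproduce byte-identical cohort directories.

The CNA/methylation generators are independent across samples and of each
other; the joint distribution of these alterations in real tumours is not
modelled, nor are isoforms, reads, or sequence-level miRNA binding. Passing
the synthetic recovery tests therefore shows that the statistical machinery
recovers the assumed data-generating structure at realistic effect sizes
and sample counts — not that real TCGA-scale data would yield any
particular gene list.

## Validation summary

The test suite checks, among others: Fisher p-values against exact-integer
enumeration for every table with total <= 50 (1e-12); BH against an
independent step-up oracle (exact); TMM against a literal-formula oracle
(1e-8) and depth-invariance (1e-9); exact-test type-I calibration and
power; the Pearson-r identity (1e-10) and the beta/M closed forms;
recurrence-threshold recovery of a designed cut-off in >= 9/10 seeds;
specificity-p monotonicity over 200 randomized instance sets; >= 90%
planted-pair recovery with false-discovery proportion <= 0.10 over 10
default-cohort seeds and a null pass rate at the nominal level when
`pair_slope = 0`; Cox null-permutation uniformity (KS), ±0.15 recovery of
a 0.7 log HR, and 1e-6 agreement with a small-n partial-likelihood oracle.
Problem sizes in the recovery studies (15 types x 65 samples, 500 genes,
150 miRNAs, 180 candidate pairs) match the generator defaults.

`scripts/acceptance.py --seed <s> --out <json>` re-runs the full pipeline
on a fresh default cohort and reports the recovery fractions, thresholds
and calibration numbers it computes.
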