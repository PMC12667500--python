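# Methods

`crossdeg` re-creates, at desk scale and with planted ground truth, the
analysis chain used to compare cochlear transcriptional responses to
intense noise between a noise-damaged rodent model and a noise-resistant
echolocating bat: per-species differential expression from counts,
cross-species concordance of the shared DEGs through a one-to-one
ortholog map, term enrichment against an explicit background, hub scoring
on an interaction network built over the species-specific DEGs, and the
quantification formulas of the downstream validation assays.

## Count model and differential expression

Counts are modelled as gamma-Poisson (negative binomial): for gene *i* in
sample *j*,

    y_ij ~ NB(mean = s_j * q_i(g(j)),  Var = mu + alpha_i * mu^2)

with sample size factor `s_j`, per-condition mean `q_i(g)` and gene
dispersion `alpha_i`.

**Size factors** are median-of-ratios: the median over all-positive genes
of `y_ij / geomean_i(y_i.)`, rescaled so their geometric mean is 1.  With
no all-positive gene the estimator is undefined; an optional fallback
takes per-gene geometric means over positive entries only (used by the
orchestrator so sparse simulated matrices never abort a run).

**Dispersion.**  The first-stage estimator is per-gene method of moments
on normalized counts, `alpha_i = max(floor, (v_i - m_i) / m_i^2)` with the
within-group pooled variance `v_i`, grand mean `m_i` and a floor of 1e-8.
At the 3-vs-3 replication this pipeline targets, that estimate has ~4
degrees of freedom, and plugging it directly into a normal-reference Wald
test inflates the type-I error roughly two-fold (we measured 11-13% at
nominal 5% on null simulations).  The default therefore fits the
parametric mean-dispersion trend

    alpha(mu) = a0 + a1 / mu

to the gene-wise estimates by least squares with three rounds of
trimming (genes whose ratio to the current fit leaves [1e-4, 10] are
excluded), and the Wald test uses the fitted trend values.  On the same
null simulations this restores calibration (4-6% at nominal 5%).  The
trend requires a reasonable number of genes; below 100 usable genes the
`auto` method falls back to the gene-wise estimates.  Both estimators are
exposed (`method="trend" | "genewise" | "auto"`).  No empirical-Bayes
shrinkage of individual genes toward the trend is applied: with so few
degrees of freedom per gene, any weight on the gene-wise value re-inflates
the tails, and per-gene dispersion heterogeneity is not part of what the
synthetic study conditions exercise.

**Wald test.**  Per gene and condition group, the NB mean `q` is fitted by
Newton iterations on `log q` (score `sum (y - mu)/(1 + alpha*mu)`,
information `sum mu/(1 + alpha*mu)`, relative tolerance 1e-8, at most 50
iterations, steps clipped to +-5 log units; the closed-form weighted mean
`sum y / sum s` initializes).  The log2 fold change is
`beta = log2(q_treated / q_control)`; its standard error comes from the
inverse information of the two group fits, and `beta/SE` is referred to
the standard normal.  Genes with zero counts in both groups get NA
p-values; genes all-zero in exactly one group get a +-30 log2FC sentinel
with NA p and never enter DEG calls.

**DEG rule.**  `adjusted p < alpha` (strict) and `|log2FC| >= log2(min_fc)`,
defaults `alpha = 0.05`, `min_fc = 1.5`, applied two-sided on the
fold-change scale so both up- and down-regulated sets exist.  Adjustment
is Benjamini-Hochberg step-up with monotonicity enforcement; NA p-values
propagate and are excluded from the number of tests.

**Sample clustering** uses distance `1 - Pearson r` on
`log2(normalized count + 1)`, average linkage.  Samples are sorted
lexicographically before the distance computation so the tree is invariant
to input column order; trees serialize to Newick.  A zero-variance sample
makes the correlation undefined and is reported by name instead of being
silently dropped.

## Cross-species concordance

DEG sets of the two species are joined through a strictly one-to-one
ortholog map; only pairs significant in both species enter the overlap
(unmapped DEGs and singly-significant pairs are counted and logged).  Each
overlap pair is classified by its direction pair: Q1 up/up, Q2
A-down/B-up, Q3 down/down, Q4 A-up/B-down.  Directions come from the DEG
call itself, so a quadrant label can never contradict the called
direction.  The four quadrants are asserted disjoint and exhaustive on
every run.  Species-specific DEGs are those whose ortholog partner is not
a DEG in the other species; genes without any one-to-one partner are
included in the specific set (the induced network is built over specific
DEGs, and orphan genes are specific by any reading).

## Enrichment

One-sided over-representation per term: with universe size N, term size K
(within the universe), query size n and overlap k, p = P(X >= k) for
hypergeometric X, computed by `scipy.stats.hypergeom.sf`.  k = 0 gives
p = 1 exactly.  Terms annotating fewer than 2 universe genes are
untestable and skipped; query genes outside the background are dropped
with a logged count.  FDR is BH across the terms tested in one run;
ranking is FDR, then raw p, then term id.  No ontology-hierarchy
propagation or bias correction is attempted.

## Network hubs

The graph is undirected, simple and unweighted (edge confidence scores,
if present in the input, are ignored); it is induced on the gene set of
interest, dropping genes with no retained edge unless `keep_isolated` is
set.  Closeness is component-restricted: `c(v) = |R(v)| / sum of BFS
distances to R(v)` over the reachable set R(v), i.e. the reciprocal of
the mean distance to reachable nodes; isolated nodes get 0.  The hub
statistic is `score = log2(degree + 1) * closeness`, so degree-0 nodes
score exactly 0, a 2-node edge scores 1.0 at both ends, and the center of
a star on n+1 nodes scores log2(n+1).  Hubs are ranked within each
regulation direction (up/down, inherited from the DEG sets) by descending
score, ties broken by degree then node id.  Centralities are computed once
on the combined network and only the ranking is direction-stratified.

## Assay quantification

* **2^-ddCt**: per sample `dCt = Ct_target - Ct_reference`;
  `ddCt = dCt - mean(dCt of the calibrator group)`; `RQ = 2^-ddCt`.
  Group means +- SD are reported.  Using the calibrator group mean (rather
  than per-replicate pairing) makes the calibrator group's geometric mean
  RQ exactly 1.
* **Viability**: `100 * (OD - mean OD_positive) / (mean OD_negative -
  mean OD_positive)`; values are deliberately not clipped to [0, 100], and
  equal control means are a degenerate-input error.  The statistic is
  invariant to adding a constant to every OD.
* **ABR threshold**: on the 5-90 dB SPL grid in 5 dB steps, the lowest
  intensity above which every detectability flag is true; 90 dB when no
  waveform is detectable at any intensity (the reporting ceiling).
  Non-monotone flag patterns — possible under visual scoring — are
  resolved by that persistence rule and logged.  Threshold shifts are
  post minus pre per frequency; a shift whose post threshold sits at the
  ceiling is flagged censored rather than adjusted.

## Synthetic study conditions

The generator's defaults are the study conditions every test and the
acceptance script run under: 2000 genes per species, 1500 one-to-one
orthologs, 2 conditions x 3 replicates, baseline means log-uniform on
[20, 500] counts, common dispersion 0.1, size factors log-uniform on
[0.7, 1.4], planted |log2FC| = 1.5 (the DEG fold-change threshold), and a
planted quadrant structure of (43, 41, 51, 69) ortholog pairs — the
concordance split the analysis is expected to recover — plus
species-specific planted DEGs (160/170 up/down in species A, 50/80 in
species B) so the specific-DEG network stage has structure to find.
Annotations are 50 random terms of 20-100 genes with one term covering
the planted DEG set at rate 0.8; the interaction graph has 300 nodes and
600 random edges with one hub given 60 extra edges.  Assay defaults:
Ct noise SD 0.2 cycles with true ddCt = -1 (a 2-fold change), a plate at
55% true viability, and pre-exposure ABR thresholds of 40/30/25/35/45 dB
at 4/8/16/24/32 kHz with persistent 45/40 dB elevations at 2 and 14 days
post exposure.

Where exact recovery rather than statistical power is being demonstrated
(the quadrant worked example, the end-to-end hub/term recovery), the
conditions use stronger effects (log2FC 2.5-4), lower dispersion (0.05)
and means >= 100 so that every planted gene clears the thresholds with
probability ~1; those choices are stated at the call sites.

What the generator does **not** emulate: per-gene dispersion
heterogeneity and mean-dispersion trends of real tissue, correlated genes
(counts are independent given the size factors), library-size extremes,
ortholog-mapping errors, annotation redundancy/hierarchy, and the degree
distribution of curated interaction databases.  Passing tests therefore
demonstrate correctness of the computations and calibration under the
stated model, not pipeline performance on the real accessions; in
particular the real studies' headline DEG/ortholog/network counts depend
on external data snapshots and are out of scope here.

## Numerical and design choices

* Gene identifiers are opaque strings; species are compared only through
  the ortholog map.  Tests shuffle identifiers to keep order exploits out.
* Output tables are TSV with "NA" for missing and 6 significant digits;
  DE tables are written sorted by adjusted p then gene id, enrichment by
  FDR then p then term id, so runs are diffable.
* All generators derive their streams from a single integer seed
  (per-stage substreams via `default_rng([seed, stage])`); identical
  configs give byte-identical outputs, which the test suite asserts on
  whole output directories.
* The pipeline's simulated network draws its nodes from the planted
  species-B-specific DEGs (capped at the configured node count) because
  the network stage consumes exactly that gene set; the designated hub is
  drawn from the planted up-regulated genes.
* Degenerate inputs are errors, not warnings: no usable genes for size
  factors (without fallback), equal plate controls, constant samples in
  clustering, off-grid ABR intensities, p-values outside [0, 1].

## Limitations

* Two-group designs only; no covariates, interaction terms, outlier
  handling, independent filtering or LFC shrinkage.
* The dispersion trend assumes a shared mean-dispersion relationship; on
  data with strong per-gene dispersion outliers the Wald test will be
  anti-conservative for those genes.
* DEG counts on real data are not expected to match tools with
  empirical-Bayes dispersion machinery gene for gene.
* Enrichment treats terms independently (no hierarchy), and the ABR rule
  models the printed thresholding convention, not waveform analysis.
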