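# Methods

This note documents the statistical model behind `cssig`, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not demonstrate.

## Statistics

**Correlation Module Score (CMS).** For a module of *m* genes in one
dataset, the intra-correlation table is the full m × m matrix of pairwise
Pearson correlations between gene expression profiles over the chosen
samples (a 150-gene module gives 150 · 150 = 22,500 cells). The CMS is the
mean of the off-diagonal cells; the per-gene MGCS is the mean of one gene's
row excluding the diagonal, so the MGCS average equals the CMS exactly (an
identity the tests assert to 1e-12). Genes with zero variance have no
defined correlation; they are dropped from the table with a warning and
recorded, rather than being assigned r = 0. All correlations are plain
Pearson on the values as loaded — the pipeline never re-normalizes
expression matrices; they are assumed log-scale and producer-normalized.

**Shuffle null and lognormal tail.** Significance of an observed CMS is
assessed by permuting the anchor metabolite profile across samples,
re-deriving a fresh top-k module per permutation and recording its CMS on
the same samples (default 100 permutations, seeded generator owned by the
call). A note on the two possible nulls: "random modules" could also mean
uniformly sampled gene sets; both are implemented
(`permutation_null` and `random_module_null`) and the shuffle null is the
default because it preserves the selection step of the observed statistic.
The null CMS values are positive in practice (genes selected for
correlation with a common profile are mutually correlated), and a lognormal
is fitted by maximum likelihood on the logs — mu = mean(log), sigma =
population standard deviation of the logs, location fixed at zero — with
p = 1 − F(observed). Degenerate inputs (non-positive nulls, zero sigma)
raise rather than returning a value.

**Refinement.** Stage 1 computes per-dataset MGCS for every initial gene on
cancer-class samples; a gene absent from a dataset's platform receives that
dataset's missing-gene constant, 0.5 × the dataset's module CMS. Stage 2
correlates every union-universe gene against the per-dataset module-average
profile (elementwise mean over present initial genes), substituting the
constant for absences and for zero-variance candidates. Stage 3 takes the
k candidates with the highest average correlation (initial genes excluded),
computes their per-dataset MGCS against the initial module, stacks the 2k
rows and keeps the k genes with the highest unweighted average MGCS across
datasets. Design points resolved here: all datasets including the anchor
participate in the stages (a flag excludes the anchor); datasets are not
weighted by sample size; candidate MGCS is computed against the *initial*
module as specified by the stepwise procedure, not against an updated
module; exactly one refinement pass is made; and every top-k selection
breaks ties lexicographically by gene id so results are identical across
platforms and input orderings.

**ssGSEA.** For one sample the genes of the universe are ranked by
descending expression, ties broken lexicographically. With in-set weights
w_i = (N − i + 1)^alpha at rank position i (N = universe size), the score is

  score = Σ_i [ P_in(i) − P_out(i) ],

where P_in is the weighted in-set ECDF and P_out the unweighted out-of-set
ECDF. alpha defaults to 0.25; alpha = 0 gives equal steps and hand-checkable
values (universe of 5, set = top 2 → exactly +2.5). Raw per-sample ranking
is the default — secretion and stroma content are strong absolute signals —
and a `centered` mode z-scores each gene across samples before ranking for
sparse per-pixel data. Scores are not divided by the number of positions;
cross-universe comparability is handled by adapted scoring (restricting
both datasets and the module to the shared gene universe) plus optional
min–max rescaling to [0, 1]. The statistic is invariant to any strictly
increasing transform of a sample's expression, which the suite
property-tests.

**Networks and hubs.** Per cohort, the signature genes present form nodes;
each node keeps directed edges to the k = 20 genes with the largest
absolute Pearson correlation (cancer-class samples). Degree is the number
of distinct neighbours in the union of in- and out-links — a reciprocal
pair counts once; an `in_out` mode counts it twice for users who prefer
link-count semantics. Hubs are the 10 genes with the highest mean degree
across cohorts; genes absent from a cohort contribute degree 0 there, so
hubs must be broadly measured (`present_only` averaging is available).

**Group comparisons.** Enrichment-score differences between two sample
groups use a Welch two-sample t-test; this is deliberately ordinary
plumbing, not a moderated differential-expression model, and no
multiple-testing correction is applied (raw per-cohort p-values are
reported). Ordered-stage trends use Spearman rank correlation of scores
against the class index; per-dataset centering and min–max scaling support
cross-cohort displays.

## Synthetic data model

The generator emulates a multi-cohort bulk-tissue study. Per sample, a
latent secretion activity a_s ∈ [0, 1] is drawn around class means
(normal 0.9, low-grade 0.6, high-grade 0.3, metastasis 0.1, stroma 0.0;
jitter sd 0.15, clipped), and a stroma fraction f_s around class means
(normal 0.45, low 0.30, high 0.20, metastasis 0.10, stroma 0.90; jitter sd
0.10). Planted genes respond to the *diluted* activity,
x = mu_g + beta · a_s(1 − f_s) + N(0, sigma), because bulk epithelial
signal is diluted by stroma — this single multiplicative coupling produces
both the progression trajectory and the stroma anti-correlation seen in
real cohorts. Stroma-module genes follow beta · f_s; background genes are
pure noise; decoy genes are coupled to the activity only inside their host
dataset. All decoys are hosted in the anchor: only there can a
dataset-specific artefact leak into a metabolite-correlated module, which
is precisely the failure mode refinement exists to remove. Baselines mu_g
are N(5, 1) per dataset (they cancel in every correlation-based statistic).
Each non-anchor cohort drops a random 5% of genes to mimic platform
differences. Defaults: 12 cohorts × 2000 genes × 100 samples
(20/30/30/10/10 per class), planted module 150, stroma module 100,
30 decoys.

**Effect size.** The per-gene effect defaults to beta = 3.0 noise-sd units
per unit of diluted activity. With the class structure above this puts the
planted module's intra-correlation in the ~0.2–0.3 range on cancer samples
— the module-integrity regime reported for real secretion signatures — and
makes single-cohort selection good but imperfect (initial recall ~0.75 at
defaults), leaving refinement meaningful work to do. Substantially smaller
beta values make the planted module's mutual correlations indistinguishable
from sampling noise at n ≈ 60 cancer samples, which would model a signal
the original strategy could not have found.

**Metabolites.** Citrate and spermine are both
baseline 1.0 + kappa · a_s(1 − f_s) + independent Gaussian noise,
kappa = 2.0. The noise sd is calibrated analytically as
tau = kappa · sd(a(1−f)) · sqrt((1 − r)/r) so the realized mutual
correlation matches the target r = 0.95 (the empirical mean over 20 seeds
lands within ±0.01). When kappa = 0 (the null collection used for
significance calibration) the calibration is undefined and the configured
metabolite noise sd (0.15) is used; expression draws are bit-identical
between a collection and its null twin at the same seed, so the null
isolates exactly the metabolite coupling.

**What passing tests show — and don't.** The generator is Gaussian with a
single latent factor per module and exact class labels. Real cohorts add
platform/batch effects, probe-level noise, label noise, non-Gaussian
expression and correlated confounders beyond stroma fraction. Recovery and
calibration results on this generator therefore validate the *procedure*
(selection, substitution rules, ranking, determinism, type-I error under
the intended null), not the biological accuracy of any particular real
signature.

## Problem sizes and numerical choices

- Refinement recovery runs 20 seeded studies at full default scale; the
  significance calibration runs 200 replicates on anchor-only collections
  at 500 genes (the shuffle null never touches the non-anchor cohorts, so
  generating them would only add cost, not information). Trajectory and
  stroma mirrors likewise evaluate the anchor cohort, whose draws are
  identical whether or not the other cohorts are generated.
- The pipeline determinism check uses a reduced configuration (3 cohorts ×
  400 genes); determinism is a property of the code path, not of the
  problem size.
- Duplicate probe ids collapse to the row with the highest mean expression
  (deterministic and standard); missing values are rejected at load time;
  expression files round-trip at full float precision (`%.17g` writing,
  round-trip float parsing).
- All RNGs are `numpy.random.default_rng` generators owned by the calling
  function — no global state; identical (config, seed) pairs reproduce
  collections, refinements and written files byte-for-byte.

## Known limitations

- One refinement pass only; the procedure's fixed-point behaviour under
  iteration is deliberately out of scope.
- The adapted-ssGSEA stability reported for real cohort pairs cannot be
  checked here; only the procedure is validated.
- The Welch comparison stands in for moderated models; with very small
  groups its p-values are approximate.
- `in+out` degree counting and `present_only` hub averaging are provided
  but unexercised by the headline analyses.
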