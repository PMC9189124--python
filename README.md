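# cssig — metabolite-anchored gene signatures across expression cohorts

Normal prostate epithelium secretes large amounts of citrate and spermine;
aggressive prostate cancer loses this function. The genes behind it are
largely unknown, but they can be found indirectly: in a cohort where
metabolite concentrations and gene expression were measured on the same
tissue samples, genes whose expression tracks the citrate–spermine
concentration profile are candidates for the secretion machinery.

`cssig` implements that strategy as a reusable pipeline for anyone who has
one *anchor* cohort with paired metabolite + expression data and any number
of expression-only cohorts:

1. **Anchor** (`cssig.anchor`) — normalize each anchoring metabolite profile
   to unit sum, average them into a per-sample activity proxy, Pearson-correlate
   every gene against it, and keep the top *k* (150 by default) as the
   *initial module*.
2. **Module integrity** (`cssig.module_score`) — the **Correlation Module
   Score** of a module *M* in a dataset is the mean off-diagonal entry of the
   pairwise Pearson table over its gene expression profiles,

   CMS = (1 / (m(m−1))) · Σ_{g≠h∈M} r(x_g, x_h),

   and the per-gene **Module Gene Contribution Score**
   MGCS(g) = (1/(m−1)) · Σ_{h≠g} r(x_g, x_h), with mean(MGCS) = CMS exactly.
   Significance: shuffle the metabolite profile across samples, re-select a
   fresh top-*k* module per permutation (100 by default), fit a lognormal to
   the null CMS values and report the upper-tail probability of the observed
   CMS.
3. **Refinement** (`cssig.refinement`) — a three-stage procedure pools all
   cohorts: per-dataset MGCS for every initial gene (absent genes get the
   dataset's *missing-gene constant*, 0.5 × that dataset's CMS); correlation
   of every union-universe gene to the module-average profile; then the top
   *k* candidates and the *k* initial genes are re-ranked together by average
   MGCS across datasets and the top *k* become the refined signature.
4. **Per-sample scoring** (`cssig.ssgsea`) — single-sample GSEA: rank a
   sample's genes by descending expression and sum, over all positions, the
   weighted in-set ECDF minus the out-of-set ECDF. Cross-dataset comparisons
   restrict both datasets to their shared gene universe (adapted scoring),
   optionally min–max rescaled to [0, 1].
5. **Networks** (`cssig.network_hubs`) — per cohort, each signature gene
   keeps its 20 strongest outgoing |Pearson r| links; hub genes are those
   with the highest mean degree across cohorts.
6. **Synthetic studies** (`cssig.synthetic_data`) — a generator that plants
   a latent secretion activity, a stroma-fraction confounder, a co-expressed
   module, decoy genes and calibrated metabolite profiles across 12 cohorts,
   so the whole chain can be validated against known ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (each accepts `--seed`, default 1):

```sh
cd analysis
python 01_simulate.py        # writes scratch/sim/, 12 cohorts x 100 samples
python 02_derive_initial.py  # initial 150-gene module + shuffle-null test
python 03_refine.py          # cross-cohort refinement + CMS report
python 04_score_signature.py # ssGSEA, grade comparison, stroma correlation
python 05_network_hubs.py    # hub ranking
```

With seed 1 this prints (abridged):

```
anchor citrate-spermine correlation: r = 0.951
initial module: 150 genes (top correlation 0.639, rank-150 correlation 0.292)
anchor cancer CMS = 0.182, shuffle-null mean = 0.062, lognormal p = 2.77e-34
36/150 genes replaced (24.0%)
CMS improved on normal samples in 12/12 cohorts, on cancer samples in 11/12
high- vs low-grade Welch p < 0.05 in 12/12 cohorts
ordinal trend rho (mean over cohorts): -0.674
signature-vs-stroma correlation in normal samples (mean): -0.768
```

Reading this: the two anchoring metabolites are almost perfectly mutually
correlated (r = 0.95), so their unit-sum average is a stable activity
proxy. The initial module is highly coherent compared with the shuffle
null (CMS 0.182 vs 0.062). Refinement replaces about a quarter of the
genes and improves module integrity in *normal* samples of every cohort —
samples never used to build the signature — which is the key evidence that
refinement removes anchor-specific noise. Per-sample scores then fall from
normal through low-grade and high-grade cancer to metastasis (negative
trend rho), and anti-correlate with stroma content in normal tissue, the
expected confounder in bulk samples.

The same workflow is exposed as a CLI (`cssig simulate|derive|score-module|
null-test|refine|score|adapt|network|compare|pipeline`) for use on real
tabular data (TSV/CSV/GCT expression, TSV metabolite tables, GMT gene sets).

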