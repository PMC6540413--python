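# Methods

## The analysis model

The pipeline treats a localized-ccRCC cohort as a probe × sample count
matrix from a targeted immune panel (endogenous genes, housekeeping genes,
spiked-in positive and negative controls), a registry of marker-gene
signatures, and a per-sample clinical annotation (recurrence status,
pathologic covariates, per-slide TIL foci counts). Its claims are
comparative: whether signature scores, individual genes and morphologic TIL
levels differ between patients who recur after nephrectomy and those who do
not.

Deconvolution here is deconvolution-by-signature: the relative abundance of
a cell type is proxied by the mean log2 expression of its marker genes, not
by a constrained regression against purified reference profiles. This
assumes marker genes are expressed predominantly by their cell type and
that the mean over a handful of markers is a stable ordinal proxy; it makes
no claim to absolute cell fractions. One consequence is embraced rather
than hidden: the Treg "signature" is a single gene (FOXP3), so its score
inherits single-gene noise.

## NanoString processing

Stages run floor → positive-control scale → log2 → quantile, each recorded
in the matrix provenance.

- **Background floor.** Per sample, the limit of detection is `m + 2s`
  where `m`, `s` are the mean and sample SD (ddof = 1) of negative-control
  counts; endogenous/housekeeping counts below it become `m`. The SD
  convention is a package choice (the convention is not dictated by the
  procedure itself); it is configurable in effect by editing negatives, and
  recorded. Requiring ≥ 2 negative probes makes the SD defined.
- **Positive-control scaling.** Factor `f_j = mean_k(geomean_k)/geomean_j`
  over positive-control counts, applied to the biological probes only. After
  scaling, every sample's positive-control geometric mean equals the cohort
  mean — the invariant the tests assert. Zero positive counts are an error
  by default; a pseudo-count escape hatch exists but is off, because a zero
  positive control indicates a failed lane rather than a value to patch.
- **Quantile normalization.** Classical sort/average: rank-r values are
  replaced by the mean of the r-th order statistics across samples. Ties
  within a column receive the mean of the normalized values over their tied
  ranks, which is deterministic, permutation-equivariant, and conserves
  each column's total. With integer count input ties are common, so the
  "identical column multisets" identity holds exactly only tie-free;
  untied entries always land on the shared reference distribution.
- **Ordering.** Whether flooring precedes positive-control scaling is not
  fixed by the science; the default order (floor first) is recorded in the
  provenance so a run is self-describing.

Housekeeping genes are carried through and retained in the gene space but
not used for an extra normalization step; only positive-control scaling is
applied by default.

## RNA-seq unit conversions

`counts_to_fpkm` (`c·1e9 / (len · depth)`), `fpkm_to_tpm` (rescale columns
to 1e6) and `log2_fpkm` (offset 1 by default) support the RNA-seq
validation arm. Alignment and read counting are out of scope; the package
starts from gene-level counts or FPKM. CYT is defined on TPM with the 0.01
offset; Teff/Treg on the RNA-seq platform uses anti-logged scores, on the
NanoString platform the ratio of log2 scores (both are implemented and the
platform tag is carried in the result, since the NanoString convention is
ambiguous in the field; rank-based tests downstream are unaffected by the
choice for any monotone transform).

## Association statistics

- **Wilcoxon rank-sum.** W is the rank sum of the first group with
  midranks. For `n+m ≤ 12` tie-free, the null is enumerated exactly over
  all C(n+m, n) labelings; otherwise a normal approximation with tie
  correction and a 0.5 continuity correction. The cutoff balances exactness
  against the O(C(n+m, n)) enumeration cost. "less" means recurrent group
  tends lower.
- **Moderated t.** Pooled two-group variances on `d_g = n1+n2−2` df are
  shrunk toward a scaled inverse-chi-square prior fitted by method of
  moments on `log s²` (digamma/trigamma moment matching, Newton inversion
  of the trigamma function). When the observed spread of `log s²` does not
  exceed its sampling noise the prior df is infinite and the prior variance
  is the plain mean of the `s²`. Total df are capped at the pooled residual
  df. Forcing `d0 = 0` recovers the ordinary pooled t exactly — the limit
  case the tests pin — and the full fit agrees with the R/limma eBayes
  implementation to ~1e-8 relative on a shared fixture, which the suite
  verifies through an Rscript oracle.
- **DEG reporting.** Fold change is the ratio of group means of anti-logged
  expression (a log-scale alternative sits behind a flag); a gene is
  reported iff `max(FC, 1/FC) > 1.5` and BH `q < 0.3`, both strict.
- **Multiplicity.** BH q-values are reported alongside raw p for the 28
  signature tests, but raw p drives the headline outputs, matching how such
  panels are conventionally read.
- **Clustering.** Response-category genes minus any gene occurring in ≥ 2
  categories, gene-wise Z-scored, then agglomerative clustering of rows and
  columns with Euclidean distance and complete linkage. Tie-breaking among
  equidistant merges follows scipy's deterministic nearest-neighbor-chain
  implementation rather than an explicit lowest-index rule: it is O(n²),
  reproducible across runs, and coincides with any tie rule on tie-free
  data, which is where the brute-force O(n³) oracle checks it. Only orders,
  heights and flat labels are produced; heatmap rendering is out of scope.

## Morphology statistics

TIL score = max foci over slides, capped at 4; `cut2` (≥ 2 high) and `cut3`
(≥ 3 high) dichotomizations. Odds ratios use the cross-product with Woolf
CIs; the CI method is informational — published CIs for these tables were
evidently computed by a different method, so only the ORs themselves are
treated as reproducible. Three published univariate ORs recompute exactly
from the bundled cross-tabulation counts (FCCC lymphocytes under both
cut-offs, UAB necrosis); the remaining printed ORs do not follow from the
printed marginal counts (likely different analytic subsets) and are bundled
for reference only, excluded from validation targets. Comparisons against
printed values accept one unit in the last printed digit, since printed
values mix rounding and truncation (e.g. 2.2958 printed as 2.29).

Logistic regression is Newton/IRLS maximum likelihood; complete separation
is detected as a diverging coefficient (|β| > 15) and raised explicitly.
VIF is `1/(1−R²)` per covariate with a flag at ≥ 5; perfect collinearity
yields an infinite, flagged sentinel.

## Synthetic cohort generator

The generator reproduces the statistical skeleton the analysis assumes,
with defaults mirroring the discovery design: 127 samples with recurrence
probability 24/127, 730 endogenous + 40 housekeeping genes, 6 positive and
8 negative spike-in controls.

- **Counts.** Endogenous/housekeeping counts are negative binomial
  (gamma-Poisson, variance `μ + φμ²`, φ = 0.05 by default) around
  `lib_j · base_g · 2^(effect_g·rec_j + t_j·[g ∈ T-cell])`: log-normal
  per-gene baselines (log2 mean 6, SD 1.5 — tens to thousands of counts),
  log-normal library factors (log2 SD 0.15), planted log2 fold-changes from
  `effect_map` (keyed by signature name, additive for genes in several
  named signatures), and a latent per-sample T-cell level `t_j ~ N(0, 1)`
  scaling all T-cell signature genes. NanoString counts are overdispersed,
  hence the NB choice; the true count law of the platform is not published,
  so this is an explicit modeling assumption. Positive controls follow the
  platform's 4-fold concentration ladder (128 … 0.125 units) at 200
  counts/unit — putting the top control in the tens of thousands and the
  lowest around 25 counts, as on real lanes — scaled by the library factor,
  Poisson. Negative controls are Poisson(4), independent of biology and
  library size.
- **Panel.** Each of the 24 cell types gets a disjoint gene block (4–24
  extra genes beyond a seed marker; Treg is exactly FOXP3); canonical
  effector markers (GZMA, PRF1, CD8A, GZMB, IFNG, EOMES, CXCL9, CXCL10,
  TBX21) are placed in the gene space and their intersection with it forms
  the Teff signature. The four response categories partition all endogenous
  genes with ~10% assigned to a second category, so the clustering
  overlap-exclusion rule always has genes to remove.
- **Morphology.** 1–10 slides per sample (uniform — centered near the ~6
  slides typical of central review); per-slide foci are
  Poisson(`0.5 · 2^(λ·t_j)`) with link strength λ (default 1), so λ = 0
  decouples TILs from expression and λ = 2 produces the strong
  TIL-versus-T-cell-score correlation seen in real cohorts. Grade, necrosis
  and stage indicators are drawn conditional on the recurrence label with
  probabilities matching the published cohort marginals.
- **Randomness.** One global seed is stream-split (SeedSequence children:
  panel / counts+covariates / foci), so any stage reruns independently and
  byte-identically.

What the generator does **not** emulate: batch/lot effects, probe-specific
hybridization efficiency, spatial or histologic structure behind the foci
counts, correlated gene modules beyond the single latent T-cell factor, and
missingness. Passing tests therefore demonstrate the statistical machinery
recovers planted structure under a faithful noise model — not that the
biological conclusions transfer to any particular real cohort.

## Study sizes used by the test suite

Power and calibration are exercised at the sizes the analysis design
implies: planted-effect recovery at n = 125, recurrence fraction 0.2, over
200 seeds (observed recovery ≈ 99% against the ≥ 90% requirement), and null
calibration over 36 cohorts × 28 signatures = 1,008 draws (rejection rate
required within 5% ± 2%). Unit fixtures use 24–120-gene panels; the default
770-probe panel is exercised in the panel-structure and pipeline tests. A
full default pipeline run takes well under a minute on one CPU.

## Known limitations

- The exact Teff gene list of the published reference is not public; the
  registry treats Teff as user-supplied input, and the synthetic panel uses
  a canonical effector-marker stand-in.
- ESTIMATE immune/stromal scores are not re-implemented; the score-table
  interface is the adapter slot for an external implementation.
- Expression-side published p-values depend on unpublished patient-level
  data and are not reproduction targets; the acceptance surface for
  expression is property-based (oracle equivalence, limit cases, planted
  effect recovery, null calibration) rather than value matching.
- Quantile normalization's multiset identity is exact only without ties
  (see above); with counts, tie blocks are averaged.
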