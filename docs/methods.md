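# Methods

`multicia` re-implements, as a tested and reusable pipeline, a multi-omics
integration analysis for classifying relapsing–remitting multiple sclerosis
(RRMS) from multi-compartment molecular profiles: small-RNA count matrices
(Small-seq-style UMI counts and MINTmap-style tRNA-fragment counts) from
plasma, PBMCs, CSF cells and cell-free CSF, together with a smoothed
CSF-cell methylome (beta values in [0, 1]). This note documents the model,
its assumptions, the parameters that matter, the numerical conventions, and
what the synthetic cohorts do and do not show about real data.

## The decomposition

Multiple co-inertia analysis (MCIA) is a multi-block latent decomposition of
K datasets X_1 … X_K measured on the same n samples. Each block is

1. column-centered,
2. divided column-wise by the sample standard deviation (n − 1 denominator),
3. divided block-wise by the square root of its total sum of squares, so
   every block enters with **unit inertia**.

The standardized blocks are concatenated and decomposed one component at a
time:

- the leading singular triplet (u, σ, v) of the concatenated matrix gives
  the **global score** t = uσ and the concatenated weight vector v;
- the segment of v belonging to block k, renormalized to unit length, is
  that block's **loading** v_k; the **partial score** is t_k = X_k v_k;
- each block is deflated by the rank-1 residual X_k ← X_k (I − v_k v_kᵀ)
  ("blockLoading" deflation), which makes the loadings of successive
  components exactly orthogonal within every block;
- the sign of each component is fixed so the largest-magnitude entry of the
  concatenated weight vector is positive.

The **contribution** of block k to component j is
c_kj = ((t_kjᵀ t_j)/(t_jᵀ t_j))² · (t_jᵀ t_j), reported as per-component
fractions c_kj / Σ_k' c_k'j, which sum to one.

Numerical choices:

- the leading triplet is taken from a dense SVD of the concatenated matrix
  (n and p are modest at desk scale); a power-iteration path is not needed;
- when a block is deflated to numerical zero (all its variance extracted),
  its weight segment is noise; we assign a zero loading rather than
  renormalizing noise, and the reference oracle used in the tests adopts the
  same convention;
- the inertia divisor uses the square root of the total sum of squares so
  the standardized block has unit inertia, the testable, conventional
  choice; a raw-sum variant is available (`inertia="raw"`) and differs only
  by per-block scale factors.

### Projection of unseen samples

Held-out samples (the progressive, SPMS-like group) are standardized with
the **training** column means, SDs and inertia divisor and multiplied by the
raw concatenated singular vectors. Using the raw vectors (not the per-block
renormalized loadings) makes self-projection exact for component 1:
projecting the training data reproduces the stored L1 global scores, which
is both the natural contract and a structural test. For later components the
two conventions differ because deflation intervenes; we keep the raw-vector
convention for all components. Standardization of new samples always uses
training statistics — pooling would leak the held-out group into the model.

## Preprocessing

Per-assay filter chains, applied to the fitting samples only:

- **smallseq** (UMI counts): drop features with a summed count below 100
  across all samples (the boundary is inclusive: exactly 100 stays), drop
  zero-SD features, TMM-normalize to CPM;
- **mintmap** (tRF counts): drop features covered (count > 0) in less than
  2/3 of samples in either diagnosis group — keeping a feature requires
  coverage ≥ 2/3 in *both* groups; an "any" mode is available — then
  zero-SD filter and TMM;
- **methylome** (beta values): keep features whose robust coefficient of
  variation, RCV = median(|x − median(x)|)/median(x), is at least 1 and
  whose SD is positive. Features with median 0 have an undefined RCV and are
  excluded with a logged reason.

A fact worth stating because it shapes both the filter and the generator:
for strictly positive data **RCV < 1 always** (at least half of the
deviations |x − median| are below the median because x > 0, so their median
is too). RCV = 1 is attained exactly when a site is zero in about half the
samples and clearly positive in the rest. A threshold-1 RCV filter is
therefore a *bimodality* filter: it retains sparse sites whose smoothed
estimate collapses to zero in a subset of samples — a realistic signature of
low-input whole-genome bisulfite data — and removes every well-covered,
smoothly varying site.

**TMM** (trimmed mean of M-values) follows the standard formulation: the
reference is the sample whose upper-quartile count fraction is closest to
the mean upper-quartile; M (log2 ratio) and A (mean log2 abundance) values
are computed on features nonzero in both libraries; values surviving a
double trim (30% on M, 5% on A, rank-based) are combined by a weighted mean
with inverse delta-method variances; factors are normalized to geometric
mean 1 and values reported as counts per million. The worked examples in the
tests were verified against an independent step-by-step computation to 1e-6.
Held-out samples are normalized against the frozen training reference and
geometric-mean correction. Normalized count matrices are log2(x+1)
transformed before standardization (variance stabilization for the linear
latent model; switchable with `log_transform=False`).

## Evaluation

k-means with k = 2 on a single latent variable is solved **exactly** by
enumerating the n − 1 split points of the sorted scores, which removes all
seed sensitivity from the headline metric. Partition agreement with the
diagnosis labels uses the split-join distance
d = (n − Σ_i max_j |A_i ∩ B_j|) + (n − Σ_j max_i |B_j ∩ A_i|).

The ROC curve is built by relocation: starting from the exact two-cluster
partition, the true-positive cluster is the one holding the larger fraction
of the positive class; samples are then moved one at a time — always the
move that minimally increases the live k-means objective, with cluster means
recomputed after every move and ties broken by the smaller sample position —
until the source cluster empties, recording (FPR, TPR) after each move. The
sweep runs in both directions from the reinstated clustering; the curve is
the union of recorded points plus (0, 0) and (1, 1), sorted by (FPR, TPR),
with trapezoidal AUC. The metric is invariant under positive affine
transforms of the scores and under sign flips.

Group differences on a latent variable use the unpaired Mann-Whitney
rank-sum test (the groups are independent, so a signed-rank pairing would be
inappropriate): exact enumeration when m + n ≤ 12 without ties, otherwise
the normal approximation with tie and continuity correction. At m = n = 6
the continuity-corrected approximation tracks the exact law to about 0.015
in the worst case.

The positive class defaults to {RRMS, CIS, RIS}; the held-out class to
{SPMS}.

## Feature reduction

The component-1 global score is regressed on all standardized features with
an L1 penalty (coordinate descent). The penalty is chosen by 5-fold
cross-validation, stratified by the binary diagnosis label and seeded for
reproducibility; the default rule is λ_min (the CV-error minimizer), with
λ_1se available. Coefficients are reported on the standardized-predictor
scale so they are comparable across blocks. Features with β = 0 are
dropped; blocks losing all features are removed entirely; the decomposition
is then re-fitted on the reduced blocks (re-standardization only — the
count filters and TMM factors are not recomputed, since the reduced model
should see the same normalized data the full model saw). An optional
post-selection magnitude filter (keep |β| above one SD of the nonzero-|β|
distribution, applied within each block) is off by default because its
published description is ambiguous.

Full and reduced models are compared by ranking all features by absolute
component-1 loading in each model and computing Spearman's rho over the
shared (reduced) feature set; with fewer than three shared features rho is
undefined and flagged rather than computed.

## The synthetic cohort

The generator emulates the study conditions: 22 fitting-positive,
14-control-style cohorts are configurable, with defaults set to 15 positives
(13 RRMS split relapse/remission plus one CIS and one RIS), 15 controls
(NINDC/INDC in roughly 2:1), and 15 held-out progressive (SPMS) samples.
Five blocks total 2000 features, mirroring the real design's very uneven
block sizes at desk scale: PBMC small-RNA 800, methylome 600, plasma 250,
CSF-cell small-RNA 200, cell-free-CSF tRF 150.

One shared latent factor f is planted: f ~ N(effect_size, 1) for positives,
N(0, 1) for controls, and N(effect_size/2, 1) for the progressive group
(intermediate by construction, configurable). `effect_size` defaults to 2 —
in factor-SD units, so the population AUROC of the factor itself is
Φ(2/√2) ≈ 0.92. Loading strength is block-specific: 0.8 in the three
plasma/CSF small-RNA blocks and 0.2 in PBMC and methylome, so the methylome
and PBMC blocks contribute weakly to the recovered component, as in the
motivating data. 10% of each block's features are informative, with random
effect signs.

Counts are negative-binomial on a log-linear model: heavy-tailed relative
abundances (gamma, shape 0.3), log-normal library sizes with CV 0.3 around a
mean depth of 25 counts per feature, per-feature log-mean shifted by
loading_strength × f for informative features, and NB size (dispersion
parameter) 5, so variance = μ + μ²/5; large size recovers the Poisson
limit. Methylation is beta-distributed with a logistic mean in the planted
factor (baseline logit ~ N(−2.5, 1.6), precision 8) plus structural
zero-inflation: 35% of sites receive a per-site dropout probability in
[0.40, 0.50] under which a sample's value is exactly 0. The zero-inflation
is what gives the RCV filter a realistic retained subset (see above).

Randomness is organized as spawned substreams — one child stream per block
and per generation step — so the fitting samples are bit-identical whatever
the held-out group size and whichever blocks are requested. This is what
makes the pipeline's no-leakage property testable by exact comparison.

What the generator does **not** emulate: read-level sequencing artifacts,
batch effects, correlated feature blocks (features are conditionally
independent given the factor), multiple shared factors, and
compartment-specific biology. Passing tests therefore show that the
pipeline recovers a single planted shared factor under realistic noise and
sparsity — not that it would rank biological features correctly in any real
cohort.

## Pipeline and reproducibility

The orchestrated run executes simulate/load → preprocess → fit → evaluate →
select → refit → project → report. The held-out group never enters filter
computation, the TMM reference choice, the fit, or the Lasso
cross-validation; this is verified by re-running the fit without the
held-out samples and comparing reports exactly. Every run writes a JSON
report (deterministically serialized), TSV intermediates, and a manifest
with a configuration hash (analysis-relevant settings only) and all seeds;
two runs with the same configuration are byte-identical.

Problem sizes in the test-suite Monte-Carlo runs are 15 + 15 samples and
~2000 features per cohort, with 50 replicates for null calibration and 20
for effect-size recovery; these sizes make the planted-factor recovery
checks sharp while keeping each replicate's decomposition a fraction of a
second.

## Known limitations

- The relocation AUROC is upward-biased under the null (≈ 0.55 on average
  at n = 15 + 15) because the true-positive cluster is chosen to favor the
  positive class; the null-calibration test accounts for this.
- At effect size 2 and n = 15 per group, the sampling spread of any
  empirical AUROC is ≈ 0.05 around the 0.92 population value, which bounds
  how consistently any classifier — including one scoring samples by the
  true factor — can clear a 0.9 threshold.
- The exact 1-D k-means and relocation ROC are quadratic/cubic in n; they
  are intended for cohort-scale n (tens to low hundreds), not thousands.
- `filter_rcv` with threshold 1 removes every strictly positive feature by
  construction; thresholds below 1 behave as a conventional robust
  variation filter.
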