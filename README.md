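# multicia

Multi-omics integration for multiple-sclerosis classification with multiple
co-inertia analysis (MCIA): per-assay filtering and TMM normalization of
small-RNA count and methylome blocks, a multi-block latent decomposition
with projection of held-out samples, a clustering-derived AUROC, and
Lasso-based feature reduction — exercised end-to-end on synthetic
multi-compartment cohorts.

## Who this is for

Researchers integrating several omics matrices measured on the same
samples — e.g. small-RNA counts from plasma, PBMCs, CSF cells and cell-free
CSF plus a CSF-cell methylome — who want an unsupervised shared latent
variable, a label-free-but-evaluable classification score, and a reduced
feature panel, with every step reproducible and testable without access to
patient data.

## The model

Each block X_k (samples × features) is centered, scaled to unit column SD
and divided by the square root of its total sum of squares (unit block
inertia). Components are extracted one at a time from the concatenated
matrix X = [X_1 … X_K]:

    X = U Σ Vᵀ                      leading singular triplet (u, σ, v)
    t = uσ                          global latent score (L1, L2, …)
    v_k = v[block k] / ‖v[block k]‖  block loading
    t_k = X_k v_k                   partial score
    X_k ← X_k (I − v_k v_kᵀ)        blockLoading deflation

Block k's share of component j is ((t_kjᵀt_j)/(t_jᵀt_j))²·(t_jᵀt_j),
normalized to fractions. Held-out samples are standardized with training
statistics and projected with the stored singular vectors. L1 is scored
against the diagnosis labels with an exact two-cluster k-means, the
split-join distance, and an ROC curve built by minimal-cost sample
relocation between the two clusters; features are then reduced by Lasso
regression of L1 on all features (5-fold CV, λ_min) and the model re-fitted
on the selected set. See `docs/methods.md` for the full account.

## Worked example

Run the full pipeline on the default synthetic cohort (15 positives, 15
controls, 15 held-out progressive samples; 5 blocks, 2000 features, planted
effect size 2 with weak loadings in the PBMC and methylome blocks):

```bash
$ multicia run --seed 1 --out demo_run
L1 AUROC: 0.911   split-join: 14
reduced L1 AUROC: 0.911   split-join: 14   features: 28
report written to demo_run/report.json
```

The first latent variable classifies the positive group with AUROC 0.911
and needs 14 split-join moves to match the label partition; Lasso reduces
973 post-filter features to 28 with no loss of discrimination here (the
drop is bounded by ~0.05 in the replicate tests). The same fit from Python:

```python
from multicia import SyntheticConfig, generate_cohort, preprocess_block, fit_mcia

blocks, meta, truth = generate_cohort(SyntheticConfig(seed=1))
groups = meta["group"]
fit_ids = meta.index[groups != "SPMS"]
binary = groups.loc[fit_ids].isin(["RRMS", "CIS", "RIS"]).map(
    {True: "positive", False: "control"})
proc = {name: preprocess_block(b.subset_samples(fit_ids), binary).block
        for name, b in blocks.items()}
res = fit_mcia(proc, 10, labels=groups.loc[fit_ids])
print(res.summary())
```

```
Multiple co-inertia analysis
============================================================
samples: 30    components: 10
blocks: pbmc_smallseq (457), csf_cells_methylome (155), plasma_smallseq (142), csf_cells_smallseq (113), csf_free_mintmap (106)

component   eigenvalue   var.fraction
       L1     0.417336         0.1887
       L2     0.233067         0.1054
       ...
      L10     0.171245         0.0774

block contribution fractions (L1):
  pbmc_smallseq              0.1279
  csf_cells_methylome        0.0891
  plasma_smallseq            0.3262
  csf_cells_smallseq         0.2703
  csf_free_mintmap           0.1864
```

L1 carries the most variance (18.9%), and the three plasma/CSF small-RNA
blocks dominate its contribution while the PBMC transcripts and the
methylome contribute least — the planted pattern. `res.project(...)` places
the held-out progressive samples on the same axes;
`evaluate_components(res)` tabulates AUROC and split-join for L1–L10;
`select_features(res)` and `reduce_and_refit(...)` produce the reduced
model; `compare_ranks(full, reduced)` reports the Spearman agreement of the
loading ranks.

CLI stages are also available individually: `multicia simulate`,
`preprocess`, `fit`, `evaluate`, and `run` (all stages, YAML-configurable
via `--config`).

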