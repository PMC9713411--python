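"""Lasso-based feature reduction against the top latent variable.

The component-1 global score of the fitted decomposition is regressed on
all (standardized, concatenated) features with an L1 penalty; the penalty
is chosen by k-fold cross-validation (lambda_min rule by default) and
features with a zero coefficient at the chosen penalty are dropped.  Blocks
losing all features are removed entirely and the decomposition is re-fitted
on the reduced feature set, after which the full and reduced models are
compared by the Spearman correlation of their loading ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold, StratifiedKFold

from .blocks import OmicsBlock
from .model import MCIA, MCIAResults


@dataclass
class SelectionResult:
    """Outcome of the penalized reduction.

    ``selected`` maps block name to a Series of nonzero coefficients (on the
    standardized predictor scale); ``cv_curve`` tabulates the cross-validation
    error over the penalty grid; ``dropped_blocks`` lists blocks that lost
    every feature.
    """

    selected: dict[str, pd.Series]
    lambda_chosen: float
    cv_curve: pd.DataFrame  # columns: lam, mean_cv_error, se
    dropped_blocks: list[str]
    seed: int
    reduced_model: MCIAResults | None = field(default=None, repr=False)

    @property
    def n_selected(self) -> int:
        return sum(len(s) for s in self.selected.values())

    def selected_features(self) -> list[tuple[str, str]]:
        return [(b, str(f)) for b, s in self.selected.items() for f in s.index]

    def to_dict(self) -> dict:
        return {
            "lambda_chosen": self.lambda_chosen,
            "seed": self.seed,
            "n_selected": self.n_selected,
            "dropped_blocks": self.dropped_blocks,
            "selected": {b: {str(f): float(v) for f, v in s.items()}
                         for b, s in self.selected.items()},
        }


def lasso_select(
    features: pd.DataFrame,
    response,
    folds: int = 5,
    seed: int = 0,
    *,
    labels: pd.Series | None = None,
    lambda_rule: str = "min",
    n_lambdas: int = 100,
    lambdas=None,
    post_sd_filter: bool = False,
) -> SelectionResult:
    """L1-penalized regression of a latent score on all features.

    ``features`` is the samples x features design matrix with two-level
    columns (block, feature); predictors are standardized internally and the
    coefficients reported on that scale.  Folds are stratified by ``labels``
    when given, otherwise shuffled with ``seed``.  ``lambda_rule`` is
    ``"min"`` (CV-error minimizer) or ``"1se"``.
    """
    y = np.asarray(response, dtype=float)
    if len(y) != len(features):
        raise ValueError("response length must equal the sample count")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(features) < folds:
        raise ValueError(f"fewer samples ({len(features)}) than folds ({folds})")
    if not isinstance(features.columns, pd.MultiIndex):
        features = features.copy()
        features.columns = pd.MultiIndex.from_tuples(
            [("all", str(c)) for c in features.columns], names=["block", "feature"])

    x = features.to_numpy(dtype=float)
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    xs = (x - mu) / sd

    if labels is not None:
        cv = list(StratifiedKFold(folds, shuffle=True, random_state=seed)
                  .split(xs, np.asarray(labels)))
    else:
        cv = list(KFold(folds, shuffle=True, random_state=seed).split(xs))

    grid = np.sort(np.asarray(lambdas, float))[::-1] if lambdas is not None else n_lambdas
    lcv = LassoCV(alphas=grid, cv=cv, max_iter=50000, tol=1e-6)
    lcv.fit(xs, y)
    mse_mean = lcv.mse_path_.mean(axis=1)
    mse_se = lcv.mse_path_.std(axis=1, ddof=1) / np.sqrt(lcv.mse_path_.shape[1])
    curve = pd.DataFrame({"lam": lcv.alphas_, "mean_cv_error": mse_mean, "se": mse_se})

    if lambda_rule == "min":
        lam = float(lcv.alpha_)
        coefs = lcv.coef_
    elif lambda_rule == "1se":
        i_min = int(np.argmin(mse_mean))
        bound = mse_mean[i_min] + mse_se[i_min]
        ok = np.flatnonzero(mse_mean <= bound)
        lam = float(lcv.alphas_[ok.min()])  # alphas_ descend: smallest index = largest penalty
        refit = Lasso(alpha=lam, max_iter=50000, tol=1e-6)
        refit.fit(xs, y)
        coefs = refit.coef_
    else:
        raise ValueError("lambda_rule must be 'min' or '1se'")

    beta = pd.Series(coefs, index=features.columns)
    nz = beta[beta != 0]
    if post_sd_filter and len(nz):
        # keep features whose |beta| exceeds one SD of the nonzero-|beta|
        # distribution within their own block
        kept = []
        for block in nz.index.get_level_values(0).unique():
            sub = nz.xs(block, level=0, drop_level=False)
            cut = sub.abs().std(ddof=1) if len(sub) > 1 else 0.0
            kept.append(sub[sub.abs() > (cut if np.isfinite(cut) else 0.0)])
        nz = pd.concat(kept) if kept else nz.iloc[:0]

    selected: dict[str, pd.Series] = {}
    for block in features.columns.get_level_values(0).unique():
        if block in nz.index.get_level_values(0):
            s = nz.xs(block, level=0)
            if len(s):
                selected[str(block)] = s.astype(float)
    all_blocks = [str(b) for b in features.columns.get_level_values(0).unique()]
    dropped = [b for b in all_blocks if b not in selected]
    return SelectionResult(selected=selected, lambda_chosen=lam, cv_curve=curve,
                           dropped_blocks=dropped, seed=seed)


def design_matrix(results: MCIAResults) -> pd.DataFrame:
    """Concatenated standardized design matrix of a fitted decomposition."""
    frames = []
    for name in results.block_names:
        sb = results.model.blocks[name]
        frames.append(pd.DataFrame(
            sb.values, index=sb.sample_ids,
            columns=pd.MultiIndex.from_product([[name], sb.feature_ids],
                                               names=["block", "feature"]),
        ))
    return pd.concat(frames, axis=1)


def select_features(results: MCIAResults, folds: int = 5, seed: int = 0,
                    **kwargs) -> SelectionResult:
    """Run :func:`lasso_select` on a fitted model's own design and L1 score."""
    labels = kwargs.pop("labels", results.labels)
    return lasso_select(design_matrix(results), results.global_scores["L1"],
                        folds=folds, seed=seed, labels=labels, **kwargs)


def reduce_and_refit(
    blocks: Mapping[str, OmicsBlock],
    selection: SelectionResult,
    n_components: int | str = 10,
    *,
    labels: pd.Series | None = None,
    inertia: str = "root",
) -> MCIAResults:
    """Refit the decomposition on the selected features only.

    Blocks are restricted to the selected feature ids; blocks with no
    selected feature are removed entirely; the reduced blocks are then
    re-standardized and the model re-fitted.
    """
    if selection.n_selected == 0:
        raise ValueError("selection is empty: no features to refit on")
    reduced: dict[str, OmicsBlock] = {}
    for name, block in blocks.items():
        if name not in selection.selected:
            continue
        feats = [str(f) for f in selection.selected[name].index]
        reduced[name] = block.with_data(block.data.loc[:, feats])
    n = len(next(iter(reduced.values())).sample_ids)
    p = sum(b.n_features for b in reduced.values())
    if n_components != "all":
        n_components = min(int(n_components), n - 1, p)
    res = MCIA(reduced, n_components, inertia=inertia, labels=labels).fit()
    selection.reduced_model = res
    return res


def compare_ranks(full: MCIAResults, reduced: MCIAResults,
                  component: int = 1) -> tuple[pd.DataFrame, float]:
    """Spearman agreement of |loading| ranks between full and reduced models.

    Features are ranked by descending absolute component loading in each
    model; the correlation is computed over the shared (reduced) feature set.
    Returns the per-feature rank table and Spearman's rho.
    """
    rf = full.rank_features(component).set_index(["block", "feature"])
    rr = reduced.rank_features(component).set_index(["block", "feature"])
    shared = rr.index.intersection(rf.index)
    if len(shared) < len(rr):
        missing = list(rr.index.difference(rf.index))[:5]
        raise ValueError(f"reduced features not contained in full model: {missing}")
    table = pd.DataFrame({
        "rank_full": rf.loc[shared, "rank"],
        "rank_reduced": rr.loc[shared, "rank"],
        "loading_full": rf.loc[shared, "loading"],
        "loading_reduced": rr.loc[shared, "loading"],
    })
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared features: rank correlation undefined")
    rho = float(stats.spearmanr(table["rank_full"], table["rank_reduced"]).statistic)
    return table.reset_index(), rho
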