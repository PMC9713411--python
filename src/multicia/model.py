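"""Multiple co-inertia analysis (MCIA) as a model/results pair.

MCIA is a multi-block latent decomposition for several datasets measured on
the same samples.  Each block is column-centered, column-scaled and divided
by the square root of its total inertia so every block enters with unit sum
of squares; the blocks are then concatenated and decomposed one component at
a time: the leading singular triplet of the concatenated matrix gives the
global score (u * sigma) and a concatenated weight vector, whose per-block
segments (renormalized to unit length) are the block loadings.  Each block is
deflated by the rank-1 projection onto its own loading ("blockLoading"
deflation, X_k <- X_k (I - v_k v_k^T)), which makes loadings of successive
components mutually orthogonal within every block.

Unseen samples are projected onto the latent space by standardizing them
with the *training* column means/SDs and inertia and multiplying by the raw
concatenated singular vectors, so projecting the training data itself
reproduces the component-1 global scores.

Usage follows the statsmodels convention::

    model = MCIA(blocks, n_components=10)
    res = model.fit()
    res.global_scores          # samples x components, "L1".."LK"
    res.contribution_fractions # block x component share of each component
    res.project(new_blocks)    # held-out samples onto the same space
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .blocks import OmicsBlock


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizedBlock:
    """A processed block plus the parameters needed to reproduce the transform.

    ``values`` has column means ~0 and (with the default root-inertia
    convention) total sum of squares 1.  ``col_means``, ``col_sds`` and
    ``inertia_norm`` are stored so unseen samples can be pushed through the
    identical transform at projection time.
    """

    values: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    inertia_norm: float
    name: str
    sample_ids: list[str]
    feature_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        """Standardize new rows with the stored training parameters."""
        x = data.to_numpy(dtype=float)
        return (x - self.col_means) / self.col_sds / self.inertia_norm


def standardize_block(
    block: OmicsBlock | pd.DataFrame,
    *,
    inertia: str = "root",
    name: str = "",
) -> StandardizedBlock:
    """Center, scale to unit column SD, then divide by the block inertia.

    With ``inertia="root"`` the divisor is the square root of the total sum
    of squares of the column-standardized block, so the output block has unit
    inertia (total SS = 1).  ``inertia="raw"`` divides by the raw sum of
    squares instead (scale-only difference when blocks differ in size).

    Column SDs use the n-1 denominator.  The composed transform is invariant
    to that choice: rescaling all SDs by a constant is cancelled by the
    inertia divisor.
    """
    if isinstance(block, OmicsBlock):
        df = block.data
        name = name or block.name
    else:
        df = block
        name = name or "block"
    x = df.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("standardization needs at least 2 samples")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        bad = [str(df.columns[j]) for j in zero[:5]]
        raise ValueError(
            f"block {name!r}: zero-SD feature(s) {bad} — apply the zero-SD filter first"
        )
    z = (x - means) / sds
    ss = float((z**2).sum())
    if inertia == "root":
        divisor = np.sqrt(ss)
    elif inertia == "raw":
        divisor = ss
    else:
        raise ValueError("inertia must be 'root' or 'raw'")
    return StandardizedBlock(
        values=z / divisor,
        col_means=means,
        col_sds=sds,
        inertia_norm=divisor,
        name=name,
        sample_ids=list(df.index.astype(str)),
        feature_ids=list(df.columns.astype(str)),
    )


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProjectedScores:
    """Latent coordinates of samples that were not part of the fit."""

    scores: pd.DataFrame
    projected: bool = True


class MCIA:
    """Multiple co-inertia model over a set of omics blocks.

    Parameters
    ----------
    blocks : mapping of name -> OmicsBlock, or sequence of OmicsBlock /
        StandardizedBlock.  All blocks must share the identical ordered
        sample ids.  OmicsBlocks are standardized internally.
    n_components : int or "all"
        Number of latent variables to extract; "all" takes min(n-1, p).
    inertia : "root" or "raw"
        Block inertia convention (see :func:`standardize_block`).
    labels : optional pandas Series of per-sample diagnosis labels, stored on
        the results for downstream evaluation.
    """

    def __init__(self, blocks, n_components: int | str = 10, *,
                 inertia: str = "root", labels: pd.Series | None = None):
        std_blocks: dict[str, StandardizedBlock] = {}
        if isinstance(blocks, Mapping):
            items = list(blocks.items())
        else:
            items = [(getattr(b, "name", f"block{i}") or f"block{i}", b)
                     for i, b in enumerate(blocks)]
        if not items:
            raise ValueError("no blocks supplied")
        for name, b in items:
            if isinstance(b, StandardizedBlock):
                std_blocks[name] = b
            else:
                std_blocks[name] = standardize_block(b, inertia=inertia, name=name)
        ref = std_blocks[items[0][0]].sample_ids
        for name, sb in std_blocks.items():
            if sb.sample_ids != ref:
                raise ValueError(f"sample ids of block {name!r} do not match the first block")
        self.blocks = std_blocks
        self.sample_ids = ref
        self.inertia = inertia
        self.labels = labels.reindex(ref) if labels is not None else None
        n = len(ref)
        p_total = sum(sb.n_features for sb in std_blocks.values())
        k_max = min(n - 1, p_total)
        if n_components == "all":
            n_components = k_max
        n_components = int(n_components)
        if not 1 <= n_components <= k_max:
            raise ValueError(f"n_components must be in [1, {k_max}], got {n_components}")
        self.n_components = n_components

    def fit(self) -> "MCIAResults":
        names = list(self.blocks)
        segs: dict[str, slice] = {}
        stop = 0
        for name in names:
            start, stop = stop, stop + self.blocks[name].n_features
            segs[name] = slice(start, stop)
        p_total = stop
        n = len(self.sample_ids)
        K = self.n_components

        current = {name: self.blocks[name].values.copy() for name in names}
        global_scores = np.zeros((n, K))
        eigenvalues = np.zeros(K)
        weights = np.zeros((p_total, K))           # raw concatenated singular vectors
        loadings = {name: np.zeros((self.blocks[name].n_features, K)) for name in names}
        partial = {name: np.zeros((n, K)) for name in names}

        for c in range(K):
            x = np.concatenate([current[name] for name in names], axis=1)
            u, s, vt = np.linalg.svd(x, full_matrices=False)
            u1, s1, v1 = u[:, 0], s[0], vt[0]
            # sign convention: largest-|weight| entry positive
            if v1[np.argmax(np.abs(v1))] < 0:
                u1, v1 = -u1, -v1
            global_scores[:, c] = u1 * s1
            eigenvalues[c] = s1**2
            weights[:, c] = v1
            for name in names:
                w = v1[segs[name]]
                norm = np.linalg.norm(w)
                # an exhausted block (deflated to numerical zero) keeps a
                # zero loading instead of a renormalized noise direction
                vk = w / norm if norm > 1e-10 else np.zeros_like(w)
                loadings[name][:, c] = vk
                partial[name][:, c] = current[name] @ vk
                # blockLoading deflation: rank-1 residual within the block
                current[name] = current[name] - np.outer(current[name] @ vk, vk)

        comp_names = [f"L{j + 1}" for j in range(K)]
        return MCIAResults(
            model=self,
            global_scores=pd.DataFrame(global_scores, index=self.sample_ids, columns=comp_names),
            eigenvalues=pd.Series(eigenvalues, index=comp_names, name="eigenvalue"),
            block_loadings={
                name: pd.DataFrame(loadings[name], index=self.blocks[name].feature_ids,
                                   columns=comp_names)
                for name in names
            },
            partial_scores={
                name: pd.DataFrame(partial[name], index=self.sample_ids, columns=comp_names)
                for name in names
            },
            projection_weights=pd.DataFrame(
                weights,
                index=pd.MultiIndex.from_tuples(
                    [(name, f) for name in names for f in self.blocks[name].feature_ids],
                    names=["block", "feature"],
                ),
                columns=comp_names,
            ),
        )


class MCIAResults:
    """Fitted MCIA decomposition: scores, loadings, eigenvalues, contributions."""

    def __init__(self, model: MCIA, global_scores, eigenvalues, block_loadings,
                 partial_scores, projection_weights):
        self.model = model
        self.global_scores = global_scores
        self.eigenvalues = eigenvalues
        self.block_loadings = block_loadings
        self.partial_scores = partial_scores
        self.projection_weights = projection_weights
        self.sample_ids = model.sample_ids
        self.labels = model.labels
        self.n_components = model.n_components
        self.block_names = list(model.blocks)

    # -- contributions ---------------------------------------------------------

    def contributions(self) -> pd.DataFrame:
        """Absolute block contributions c_kj = cos^2(t_kj, scaled) * |t_j|^2.

        For block k and component j, with t_kj the partial score and t_j the
        global score: c_kj = ((t_kj' t_j) / (t_j' t_j))^2 * (t_j' t_j).
        """
        out = {}
        for name in self.block_names:
            row = []
            for comp in self.global_scores.columns:
                tj = self.global_scores[comp].to_numpy()
                tkj = self.partial_scores[name][comp].to_numpy()
                denom = float(tj @ tj)
                if denom == 0:
                    raise ZeroDivisionError(f"degenerate global score on {comp}")
                row.append((float(tkj @ tj) / denom) ** 2 * denom)
            out[name] = row
        return pd.DataFrame(out, index=self.global_scores.columns).T

    @property
    def contribution_fractions(self) -> pd.DataFrame:
        """Per-component contribution shares; each column sums to 1."""
        c = self.contributions()
        return c / c.sum(axis=0)

    # -- projection ------------------------------------------------------------

    def project(self, new_blocks: Mapping[str, OmicsBlock | pd.DataFrame]) -> ProjectedScores:
        """Project unseen samples onto the fitted latent space.

        Every model block must be supplied with the identical feature set;
        new samples are standardized with the stored training parameters and
        multiplied by the concatenated singular-vector matrix.
        """
        missing = set(self.block_names) - set(new_blocks)
        if missing:
            raise ValueError(f"missing block(s) for projection: {sorted(missing)}")
        frames = []
        sample_ids = None
        for name in self.block_names:
            nb = new_blocks[name]
            df = nb.data if isinstance(nb, OmicsBlock) else nb
            sb = self.model.blocks[name]
            got, want = list(df.columns.astype(str)), sb.feature_ids
            if got != want:
                extra = sorted(set(got) - set(want))[:5]
                lacking = sorted(set(want) - set(got))[:5]
                raise ValueError(
                    f"feature mismatch in block {name!r}: unexpected {extra}, missing {lacking}"
                )
            ids = list(df.index.astype(str))
            if sample_ids is None:
                sample_ids = ids
            elif ids != sample_ids:
                raise ValueError(f"sample ids of new block {name!r} do not match")
            frames.append(sb.transform(df))
        x = np.concatenate(frames, axis=1)
        scores = x @ self.projection_weights.to_numpy()
        return ProjectedScores(
            scores=pd.DataFrame(scores, index=sample_ids, columns=self.global_scores.columns)
        )

    # -- feature ranking -------------------------------------------------------

    def rank_features(self, component: int = 1) -> pd.DataFrame:
        """All features ordered by |loading| on one component (descending).

        Ties are broken lexicographically by (block name, feature id).
        Returns a frame with block, feature, loading and 1-based rank.
        """
        if not 1 <= component <= self.n_components:
            raise ValueError(f"component must be in [1, {self.n_components}]")
        comp = f"L{component}"
        rows = []
        for name in self.block_names:
            lo = self.block_loadings[name][comp]
            for feat, val in lo.items():
                rows.append((name, str(feat), float(val)))
        df = pd.DataFrame(rows, columns=["block", "feature", "loading"])
        df["abs_loading"] = df["loading"].abs()
        df = df.sort_values(
            by=["abs_loading", "block", "feature"], ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    # -- reporting -------------------------------------------------------------

    @property
    def variance_fractions(self) -> pd.Series:
        return self.eigenvalues / self.eigenvalues.sum()

    def summary(self) -> str:
        lines = ["Multiple co-inertia analysis", "=" * 60]
        lines.append(f"samples: {len(self.sample_ids)}    components: {self.n_components}")
        lines.append("blocks: " + ", ".join(
            f"{n} ({self.model.blocks[n].n_features})" for n in self.block_names))
        lines.append("")
        lines.append("component   eigenvalue   var.fraction")
        for comp in self.global_scores.columns:
            lines.append(
                f"{comp:>9}   {self.eigenvalues[comp]:10.6f}   {self.variance_fractions[comp]:12.4f}"
            )
        lines.append("")
        lines.append("block contribution fractions (L1):")
        frac = self.contribution_fractions["L1"]
        for name, v in frac.items():
            lines.append(f"  {name:<24} {v:8.4f}")
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------------

    def save(self, outdir) -> None:
        """Serialize as JSON metadata plus TSV matrices under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "n_components": self.n_components,
            "inertia": self.model.inertia,
            "sample_ids": self.sample_ids,
            "block_names": self.block_names,
            "labels": (self.labels.astype(str).to_dict() if self.labels is not None else None),
            "blocks": {
                name: {
                    "feature_ids": self.model.blocks[name].feature_ids,
                    "col_means": self.model.blocks[name].col_means.tolist(),
                    "col_sds": self.model.blocks[name].col_sds.tolist(),
                    "inertia_norm": self.model.blocks[name].inertia_norm,
                }
                for name in self.block_names
            },
        }
        (outdir / "model.json").write_text(json.dumps(meta, indent=1))
        self.global_scores.to_csv(outdir / "global_scores.tsv", sep="\t")
        self.eigenvalues.to_csv(outdir / "eigenvalues.tsv", sep="\t")
        self.projection_weights.to_csv(outdir / "projection_weights.tsv", sep="\t")
        for name in self.block_names:
            self.block_loadings[name].to_csv(outdir / f"loadings_{name}.tsv", sep="\t")
            self.partial_scores[name].to_csv(outdir / f"partial_scores_{name}.tsv", sep="\t")


def fit_mcia(blocks, n_components: int | str = 10, *, inertia: str = "root",
             labels: pd.Series | None = None) -> MCIAResults:
    """Convenience wrapper: build an :class:`MCIA` model and fit it."""
    return MCIA(blocks, n_components, inertia=inertia, labels=labels).fit()
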