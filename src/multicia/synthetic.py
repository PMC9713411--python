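"""Synthetic multi-omics cohorts with a planted group-separating factor.

Emulates a multi-compartment small-RNA + methylome study of relapsing-remitting
multiple sclerosis (RRMS): five data blocks with very different feature counts
— overdispersed UMI/tRF count matrices with library-size variation from plasma,
PBMCs, CSF cells and cell-free CSF, plus a smoothed beta-value methylome block —
measured on the same samples.  A single shared latent factor separates the
positive (RRMS/CIS/RIS) from the control (NINDC/INDC) group, with block-specific
loading strength (weak in the PBMC and methylome blocks).  A held-out
"progressive" (SPMS) group is drawn with an intermediate factor mean; it is
generated for projection only and must never enter fitting.

Counts are negative-binomial on a log-linear mean model; methylation values are
beta-distributed with a mean that is a logistic function of the factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .blocks import OmicsBlock, write_matrix

#: default block layout: name -> (assay, source, n_features).
#: Feature counts mirror the relative sizes of a real multi-compartment design
#: (cellular blocks large, biofluid blocks small) at desk scale.
DEFAULT_BLOCKS: dict[str, tuple[str, str, int]] = {
    "pbmc_smallseq": ("smallseq", "pbmc", 800),
    "csf_cells_methylome": ("methylome", "csf_cells", 600),
    "plasma_smallseq": ("smallseq", "plasma", 250),
    "csf_cells_smallseq": ("smallseq", "csf_cells", 200),
    "csf_free_mintmap": ("mintmap", "csf_free", 150),
}

#: planted loading strength per block: strong in the plasma/CSF small-RNA
#: blocks, weak in PBMC transcripts and the CSF-cell methylome.
DEFAULT_LOADING_STRENGTH: dict[str, float] = {
    "pbmc_smallseq": 0.2,
    "csf_cells_methylome": 0.2,
    "plasma_smallseq": 0.8,
    "csf_cells_smallseq": 0.8,
    "csf_free_mintmap": 0.8,
}

GROUPS = ("positive", "control", "progressive")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a generated cohort.

    ``n_per_group`` is the number of samples in each diagnosis group
    (positives, controls and the held-out progressive group); pass a mapping
    to size the groups differently.  ``effect_size`` is the standardized mean
    shift of the planted latent factor between positives and controls, in
    factor-SD units.  ``count_dispersion`` is the negative-binomial size
    (shape) parameter: variance = mu + mu^2 / size, so larger values approach
    the Poisson limit.  ``library_size_cv`` is the coefficient of variation of
    the log-normal per-sample sequencing depth.
    """

    n_per_group: int | Mapping[str, int] = 15
    features_per_block: Mapping[str, int] = field(
        default_factory=lambda: {k: v[2] for k, v in DEFAULT_BLOCKS.items()}
    )
    effect_size: float = 2.0
    block_loading_strength: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOADING_STRENGTH)
    )
    count_dispersion: float = 5.0
    library_size_cv: float = 0.3
    informative_fraction: float = 0.10
    progressive_position: float = 0.5  # factor mean of SPMS, as fraction of effect_size
    mean_depth_per_feature: float = 25.0
    seed: int = 0

    def group_sizes(self) -> dict[str, int]:
        if isinstance(self.n_per_group, Mapping):
            sizes = {g: int(self.n_per_group.get(g, 0)) for g in GROUPS}
        else:
            sizes = {g: int(self.n_per_group) for g in GROUPS}
        for g in ("positive", "control"):
            if sizes[g] <= 0:
                raise ValueError(f"group {g!r} must have a positive size, got {sizes[g]}")
        if sizes["progressive"] < 0:
            raise ValueError("progressive group size must be non-negative")
        return sizes

    def validate(self) -> None:
        self.group_sizes()
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be > 0")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be >= 0")
        for name in self.features_per_block:
            if name not in DEFAULT_BLOCKS:
                raise ValueError(
                    f"unknown block name {name!r}; known blocks: {sorted(DEFAULT_BLOCKS)}"
                )
        for name, s in self.block_loading_strength.items():
            if name not in DEFAULT_BLOCKS:
                raise ValueError(f"unknown block name {name!r} in block_loading_strength")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"loading strength for {name!r} must be in [0, 1], got {s}")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: the factor, the labels, and the informative features."""

    latent_factor_values: pd.Series
    group_labels: pd.Series
    informative_feature_ids: dict[str, list[str]]


def _check_informative(informative_idx, n_features: int) -> np.ndarray:
    idx = np.asarray(informative_idx, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n_features):
        raise IndexError(
            f"informative feature index out of range [0, {n_features}): "
            f"{idx[(idx < 0) | (idx >= n_features)].tolist()}"
        )
    return idx


def generate_count_block(
    n_samples: int,
    n_features: int,
    informative_idx,
    factor_values,
    loading_strength: float,
    dispersion: float,
    library_size_cv: float,
    rng: np.random.Generator,
    *,
    assay: str = "smallseq",
    source: str = "plasma",
    sample_ids=None,
    feature_prefix: str = "feat",
    mean_depth_per_feature: float = 25.0,
) -> OmicsBlock:
    """Overdispersed count matrix with a log-linear planted effect.

    The log-mean of each informative feature shifts linearly with the latent
    factor, scaled by ``loading_strength`` and a random per-feature sign.
    Library sizes are log-normal with the stated coefficient of variation.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    factor = np.asarray(factor_values, dtype=float)
    if factor.shape != (n_samples,):
        raise ValueError("factor_values must have length n_samples")
    idx = _check_informative(informative_idx, n_features)
    # independent substreams per step so appending samples (e.g. a held-out
    # group drawn after the fitting groups) never perturbs earlier rows
    rng_abund, rng_signs, rng_lib, rng_counts = rng.spawn(4)

    # heavy-tailed relative abundances: many rare features, a few dominant ones
    abundance = rng_abund.gamma(shape=0.3, scale=1.0, size=n_features)
    abundance /= abundance.sum()

    target_library = mean_depth_per_feature * n_features
    if library_size_cv > 0:
        sigma2 = np.log1p(library_size_cv**2)
        lib = np.exp(rng_lib.normal(np.log(target_library) - sigma2 / 2.0,
                                    np.sqrt(sigma2), n_samples))
    else:
        lib = np.full(n_samples, target_library)

    signs = rng_signs.choice([-1.0, 1.0], size=idx.size)
    eta = np.zeros((n_samples, n_features))
    eta[:, idx] = loading_strength * np.outer(factor, signs)
    mu = lib[:, None] * abundance[None, :] * np.exp(eta)

    p = dispersion / (dispersion + mu)
    counts = rng_counts.negative_binomial(dispersion, p).astype(float)

    if sample_ids is None:
        sample_ids = [f"s{i + 1:03d}" for i in range(n_samples)]
    df = pd.DataFrame(
        counts,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"{feature_prefix}{j + 1:04d}" for j in range(n_features)],
    )
    return OmicsBlock(data=df, assay=assay, source=source)


def generate_methylation_block(
    n_samples: int,
    n_features: int,
    informative_idx,
    factor_values,
    loading_strength: float,
    rng: np.random.Generator,
    *,
    source: str = "csf_cells",
    sample_ids=None,
    feature_prefix: str = "cpg",
    base_logit_mean: float = -2.5,
    base_logit_sd: float = 1.6,
    precision: float = 8.0,
    zero_inflated_fraction: float = 0.35,
    dropout_range: tuple[float, float] = (0.40, 0.50),
) -> OmicsBlock:
    """Beta-valued methylome block; informative sites shift on the logit scale.

    Baseline methylation is skewed low (most smoothed sites near-unmethylated
    with a long tail of intermediate sites) and per-site beta precision is
    deliberately low: smoothed low-input methylomes are noisy across samples.

    A ``zero_inflated_fraction`` of sites is additionally bimodal: each
    sample independently reads exactly 0 with a per-site dropout probability
    drawn from ``dropout_range``, emulating sparsely covered regions whose
    smoothed estimate collapses to fully-unmethylated in a subset of
    samples.  For strictly positive data the robust coefficient of variation
    (MAD/median) is provably below 1, so only such part-zero bimodal sites
    can reach an RCV of 1 and survive a threshold-1 robust-variation filter.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    factor = np.asarray(factor_values, dtype=float)
    if factor.shape != (n_samples,):
        raise ValueError("factor_values must have length n_samples")
    idx = _check_informative(informative_idx, n_features)
    rng_base, rng_signs, rng_beta, rng_sparse, rng_drop = rng.spawn(5)

    base = rng_base.normal(base_logit_mean, base_logit_sd, n_features)
    signs = rng_signs.choice([-1.0, 1.0], size=idx.size)
    shift = np.zeros((n_samples, n_features))
    shift[:, idx] = loading_strength * np.outer(factor, signs)
    mean = expit(base[None, :] + shift)

    a = np.clip(mean * precision, 1e-6, None)
    b = np.clip((1.0 - mean) * precision, 1e-6, None)
    beta = rng_beta.beta(a, b)
    beta = np.clip(beta, 1e-9, 1.0 - 1e-9)

    if zero_inflated_fraction > 0:
        n_sparse = int(round(zero_inflated_fraction * n_features))
        sparse = rng_sparse.choice(n_features, size=n_sparse, replace=False)
        dropout = rng_sparse.uniform(*dropout_range, size=n_sparse)
        drop = rng_drop.random((n_samples, n_sparse)) < dropout[None, :]
        beta[:, sparse] = np.where(drop, 0.0, beta[:, sparse])

    if sample_ids is None:
        sample_ids = [f"s{i + 1:03d}" for i in range(n_samples)]
    df = pd.DataFrame(
        beta,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"{feature_prefix}{j + 1:05d}" for j in range(n_features)],
    )
    return OmicsBlock(data=df, assay="methylome", source=source)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[dict[str, OmicsBlock], pd.DataFrame, GroundTruth]:
    """Generate all blocks, the sample metadata table and the ground truth.

    Returns blocks sharing an identical sample ordering (positives, controls,
    then the held-out progressive group), a metadata frame with ``group``
    (RRMS/CIS/RIS/NINDC/INDC/SPMS) and ``phase`` columns, and a
    :class:`GroundTruth` with the planted factor and informative feature ids.
    """
    config.validate()
    # one child stream per potential block (plus one for the factor), so the
    # cohort's fitting samples are bit-identical whatever the held-out group
    # size and whichever blocks are requested
    children = np.random.default_rng(config.seed).spawn(1 + len(DEFAULT_BLOCKS))
    rng_factor = children[0]
    block_rngs = dict(zip(DEFAULT_BLOCKS, children[1:]))
    sizes = config.group_sizes()
    n_pos, n_ctl, n_prog = sizes["positive"], sizes["control"], sizes["progressive"]
    n_total = n_pos + n_ctl + n_prog

    means = np.concatenate(
        [
            np.full(n_pos, config.effect_size),
            np.zeros(n_ctl),
            np.full(n_prog, config.progressive_position * config.effect_size),
        ]
    )
    factor = rng_factor.normal(0.0, 1.0, n_total) + means

    sample_ids = [f"s{i + 1:03d}" for i in range(n_total)]
    labels, phases = [], []
    for i in range(n_pos):
        # mirror a clinical cohort: mostly RRMS with one CIS and one RIS case
        if i == n_pos - 1 and n_pos >= 3:
            labels.append("CIS"), phases.append("na")
        elif i == n_pos - 2 and n_pos >= 4:
            labels.append("RIS"), phases.append("na")
        else:
            labels.append("RRMS")
            phases.append("relapse" if i % 2 == 0 else "remission")
    for i in range(n_ctl):
        labels.append("INDC" if i % 3 == 2 else "NINDC")
        phases.append("na")
    labels += ["SPMS"] * n_prog
    phases += ["na"] * n_prog

    metadata = pd.DataFrame(
        {"group": labels, "phase": phases},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    blocks: dict[str, OmicsBlock] = {}
    informative: dict[str, list[str]] = {}
    for name in DEFAULT_BLOCKS:  # fixed order => reproducible rng consumption
        if name not in config.features_per_block:
            continue
        assay, source, _ = DEFAULT_BLOCKS[name]
        rng = block_rngs[name]
        p = int(config.features_per_block[name])
        strength = float(config.block_loading_strength.get(name, 0.0))
        n_inf = int(round(config.informative_fraction * p))
        idx = np.sort(rng.choice(p, size=n_inf, replace=False))
        if assay == "methylome":
            block = generate_methylation_block(
                n_total, p, idx, factor, strength, rng,
                source=source, sample_ids=sample_ids, feature_prefix=f"{name}_cpg",
            )
        else:
            block = generate_count_block(
                n_total, p, idx, factor, strength,
                config.count_dispersion, config.library_size_cv, rng,
                assay=assay, source=source, sample_ids=sample_ids,
                feature_prefix=f"{name}_f",
                mean_depth_per_feature=config.mean_depth_per_feature,
            )
        blocks[name] = block
        informative[name] = [block.feature_ids[j] for j in idx]

    truth = GroundTruth(
        latent_factor_values=pd.Series(factor, index=metadata.index, name="factor"),
        group_labels=metadata["group"].copy(),
        informative_feature_ids=informative,
    )
    return blocks, metadata, truth


def write_cohort(blocks: Mapping[str, OmicsBlock], metadata: pd.DataFrame, outdir) -> None:
    """Write every block and the metadata table as TSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, block in blocks.items():
        write_matrix(block, outdir / f"{name}.tsv")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t")
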