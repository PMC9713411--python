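"""Per-assay feature filters and TMM normalization.

Each assay kind gets its published filter chain:

* ``smallseq`` UMI counts — drop features with fewer than 100 total counts
  across all samples, drop zero-SD features, then TMM-normalize to CPM.
* ``mintmap`` tRF counts — drop features covered (count > 0) in less than
  2/3 of samples in either diagnosis group, drop zero-SD features, then TMM.
* ``methylome`` beta values — keep features whose robust coefficient of
  variation (median absolute deviation / median) is at least 1 and whose SD
  is positive.

TMM (trimmed mean of M-values) computes one scaling factor per sample
against a reference library, doubly trimming log-ratios (M) and log
abundances (A) and weighting the surviving M values by their inverse
asymptotic (delta-method) variance.  Factors are normalized to geometric
mean 1 and normalized values reported as counts-per-million.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import OmicsBlock


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for one filter application."""

    rule: str
    n_before: int
    n_after: int
    pass_flags: pd.Series  # bool per input feature
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if int(self.pass_flags.sum()) != self.n_after:
            raise ValueError("n_after inconsistent with pass flags")

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "n_before": self.n_before,
            "n_after": self.n_after,
            "removed": [str(f) for f, ok in self.pass_flags.items() if not ok],
            "notes": self.notes,
        }


def _apply(block: OmicsBlock, keep: pd.Series, rule: str, notes: dict | None = None):
    keep = keep.astype(bool)
    report = FilterReport(
        rule=rule,
        n_before=block.n_features,
        n_after=int(keep.sum()),
        pass_flags=keep,
        notes=notes or {},
    )
    return block.with_data(block.data.loc[:, keep[keep].index]), report


def filter_min_total_count(block: OmicsBlock, min_total: int = 100):
    """Keep features whose summed count across all samples is >= ``min_total``.

    The boundary is inclusive: a feature with exactly ``min_total`` counts
    stays ("less than ``min_total``" is removed).
    """
    if not block.is_count_assay:
        raise ValueError(f"min-total-count filter applies to count assays, not {block.assay!r}")
    totals = block.data.sum(axis=0)
    return _apply(block, totals >= min_total, "min_total_count",
                  {"min_total": min_total})


def filter_group_coverage(block: OmicsBlock, group_labels, fraction: float = 2 / 3,
                          *, mode: str = "both"):
    """Keep features covered (count > 0) in >= ``fraction`` of samples per group.

    ``mode="both"`` (default) requires the coverage threshold in both groups
    — i.e. a feature falling below it in either group is removed;
    ``mode="any"`` requires it in at least one group.
    """
    labels = pd.Series(group_labels, index=block.data.index)
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {list(groups)}")
    covs = []
    for g in groups:
        members = labels[labels == g].index
        if len(members) == 0:
            raise ValueError(f"group {g!r} has zero members")
        covs.append((block.data.loc[members] > 0).mean(axis=0))
    if mode == "both":
        keep = (covs[0] >= fraction) & (covs[1] >= fraction)
    elif mode == "any":
        keep = (covs[0] >= fraction) | (covs[1] >= fraction)
    else:
        raise ValueError("mode must be 'both' or 'any'")
    return _apply(block, keep, "group_coverage", {"fraction": fraction, "mode": mode})


def filter_zero_sd(block: OmicsBlock):
    """Remove features with zero sample standard deviation (n-1 denominator)."""
    if block.n_features == 0:
        return _apply(block, pd.Series(dtype=bool), "zero_sd")
    sds = block.data.std(axis=0, ddof=1)
    return _apply(block, sds > 0, "zero_sd")


def rcv(values: np.ndarray) -> float:
    """Robust coefficient of variation: median(|x - median(x)|) / median(x)."""
    med = float(np.median(values))
    if med == 0:
        return math.nan
    return float(np.median(np.abs(values - med))) / med


def filter_rcv(block: OmicsBlock, threshold: float = 1.0):
    """Keep methylome features with RCV >= ``threshold`` and positive SD.

    Features whose median is zero have an undefined RCV and are excluded,
    with their ids recorded in the report notes.
    """
    if block.assay != "methylome":
        raise ValueError(f"RCV filter applies to methylome blocks, not {block.assay!r}")
    vals = block.data.to_numpy(dtype=float)
    med = np.median(vals, axis=0)
    mad = np.median(np.abs(vals - med), axis=0)
    sds = vals.std(axis=0, ddof=1) if vals.shape[0] > 1 else np.zeros(vals.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        rcvs = np.where(med != 0, mad / np.where(med != 0, med, 1.0), np.nan)
    undefined = [str(f) for f, m in zip(block.data.columns, med) if m == 0]
    keep = pd.Series((med != 0) & (rcvs >= threshold) & (sds > 0), index=block.data.columns)
    return _apply(block, keep, "rcv", {"threshold": threshold, "undefined_median": undefined})


# --------------------------------------------------------------------------
# TMM normalization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TMMParams:
    """Frozen normalization state, sufficient to normalize unseen samples."""

    factors: pd.Series            # per training sample, geometric mean 1
    reference_sample: str
    reference_counts: pd.Series   # reference library on the filtered feature set
    geomean: float                # raw-factor geometric mean divided out
    m_trim: float
    a_trim: float


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, m_trim: float, a_trim: float) -> float:
    """log2 scaling factor of one library against the reference."""
    n_obs, n_ref = obs.sum(), ref.sum()
    both = (obs > 0) & (ref > 0)
    o, r = obs[both], ref[both]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # inverse asymptotic variance of M under the delta method
    w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    if m.size == 0:
        return 0.0
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = math.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank(method="average").to_numpy()
    rank_a = pd.Series(a).rank(method="average").to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


def tmm_factors(counts: pd.DataFrame, ref_counts: np.ndarray,
                m_trim: float = 0.30, a_trim: float = 0.05) -> pd.Series:
    """Raw (un-normalized) TMM factors of each row against ``ref_counts``."""
    ref = np.asarray(ref_counts, dtype=float)
    out = {}
    for sid, row in counts.iterrows():
        out[sid] = 2.0 ** _tmm_pair_factor(row.to_numpy(dtype=float), ref, m_trim, a_trim)
    return pd.Series(out, name="tmm_factor")


def tmm_normalize(block: OmicsBlock, m_trim: float = 0.30, a_trim: float = 0.05):
    """TMM-normalize a count block to CPM.

    Returns ``(normalized_block, params)`` where ``params`` is a
    :class:`TMMParams` carrying the per-sample factors (geometric mean 1),
    the chosen reference sample and the correction needed to normalize
    unseen samples consistently.  Normalized values are
    counts / (library size x factor) x 1e6.
    """
    if not block.is_count_assay:
        raise ValueError(f"TMM applies to count assays, not {block.assay!r}")
    if block.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    counts = block.data.astype(float)
    lib = counts.sum(axis=1)
    if (lib == 0).any():
        bad = list(lib[lib == 0].index)
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    # reference: sample whose upper-quartile (of count fractions) is closest
    # to the mean upper-quartile
    q75 = (counts.div(lib, axis=0)).quantile(0.75, axis=1)
    ref_id = (q75 - q75.mean()).abs().idxmin()
    ref = counts.loc[ref_id].to_numpy()

    raw = tmm_factors(counts, ref, m_trim, a_trim)
    geomean = float(np.exp(np.mean(np.log(raw))))
    factors = raw / geomean

    cpm = counts.div(lib * factors, axis=0) * 1e6
    params = TMMParams(
        factors=factors, reference_sample=str(ref_id),
        reference_counts=counts.loc[ref_id].copy(), geomean=geomean,
        m_trim=m_trim, a_trim=a_trim,
    )
    return block.with_data(cpm), params


def tmm_apply(block: OmicsBlock, params: TMMParams) -> OmicsBlock:
    """Normalize unseen samples against a frozen TMM state (training reference)."""
    counts = block.data.astype(float)
    if list(counts.columns) != list(params.reference_counts.index):
        raise ValueError("feature set does not match the TMM reference")
    lib = counts.sum(axis=1)
    if (lib == 0).any():
        raise ValueError("sample with all-zero counts cannot be normalized")
    raw = tmm_factors(counts, params.reference_counts.to_numpy(), params.m_trim, params.a_trim)
    factors = raw / params.geomean
    return block.with_data(counts.div(lib * factors, axis=0) * 1e6)


# --------------------------------------------------------------------------
# per-assay dispatcher
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessResult:
    """Processed block plus the filter chain reports and frozen transforms."""

    block: OmicsBlock
    reports: list[FilterReport]
    tmm: TMMParams | None = None
    log_transform: bool = True

    def __iter__(self):  # allow (block, reports) unpacking
        return iter((self.block, self.reports))

    def apply_to_new(self, block: OmicsBlock) -> OmicsBlock:
        """Push unseen samples through the identical frozen preprocessing."""
        sub = block.with_data(block.data.loc[:, self.block.feature_ids])
        if self.tmm is not None:
            sub = tmm_apply(sub, self.tmm)
            if self.log_transform:
                sub = sub.with_data(np.log2(sub.data + 1.0))
        return sub


def preprocess_block(
    block: OmicsBlock,
    group_labels=None,
    *,
    min_total: int = 100,
    coverage_fraction: float = 2 / 3,
    coverage_mode: str = "both",
    rcv_threshold: float = 1.0,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
    log_transform: bool = True,
) -> PreprocessResult:
    """Run the published per-assay filter chain and normalization.

    smallseq: min-total-count, zero-SD, TMM; mintmap: group coverage,
    zero-SD, TMM; methylome: RCV (which subsumes the zero-SD rule).  Count
    blocks are log2(x+1)-transformed after TMM when ``log_transform`` is on.
    """
    reports: list[FilterReport] = []
    tmm: TMMParams | None = None
    if block.assay == "smallseq":
        block, rep = filter_min_total_count(block, min_total)
        reports.append(rep)
        block, rep = filter_zero_sd(block)
        reports.append(rep)
        block, tmm = tmm_normalize(block, m_trim, a_trim)
    elif block.assay == "mintmap":
        if group_labels is None:
            raise ValueError("mintmap preprocessing needs group labels for the coverage filter")
        block, rep = filter_group_coverage(block, group_labels, coverage_fraction,
                                           mode=coverage_mode)
        reports.append(rep)
        block, rep = filter_zero_sd(block)
        reports.append(rep)
        block, tmm = tmm_normalize(block, m_trim, a_trim)
    elif block.assay == "methylome":
        block, rep = filter_rcv(block, rcv_threshold)
        reports.append(rep)
    else:
        raise ValueError(f"unknown assay {block.assay!r}")
    if tmm is not None and log_transform:
        block = block.with_data(np.log2(block.data + 1.0))
    return PreprocessResult(block=block, reports=reports, tmm=tmm, log_transform=log_transform)
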