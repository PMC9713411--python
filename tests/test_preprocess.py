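"""Filter chain and TMM normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multicia.preprocess import (
    filter_group_coverage,
    filter_min_total_count,
    filter_rcv,
    filter_zero_sd,
    preprocess_block,
    rcv,
    tmm_apply,
    tmm_normalize,
)

from conftest import make_count_block, make_methyl_block


# ---- min total count --------------------------------------------------------

def test_min_total_boundary_inclusive():
    # feature totals 99, 100, 101 over three samples
    block = make_count_block([[33, 30, 41], [33, 30, 30], [33, 40, 30]])
    out, rep = filter_min_total_count(block, 100)
    assert out.feature_ids == ["g1", "g2"]
    assert (rep.n_before, rep.n_after) == (3, 2)


def test_all_zero_feature_removed():
    block = make_count_block([[0, 5], [0, 200]])
    out, _ = filter_min_total_count(block, 100)
    assert out.feature_ids == ["g1"]


def test_zero_threshold_is_identity():
    block = make_count_block([[0, 1], [2, 3]])
    out, rep = filter_min_total_count(block, 0)
    assert out.feature_ids == block.feature_ids
    assert rep.n_after == rep.n_before


def test_min_total_rejects_methylome():
    block = make_methyl_block([[0.1, 0.2], [0.3, 0.4]])
    with pytest.raises(ValueError, match="count assay"):
        filter_min_total_count(block)


# ---- group coverage ---------------------------------------------------------

def _coverage_block(cov_a, n_a, cov_b, n_b):
    """One feature, covered in cov_a of n_a group-A and cov_b of n_b group-B."""
    col = [1] * cov_a + [0] * (n_a - cov_a) + [1] * cov_b + [0] * (n_b - cov_b)
    counts = np.array(col, dtype=float)[:, None]
    block = make_count_block(counts, assay="mintmap")
    labels = ["A"] * n_a + ["B"] * n_b
    return block, labels


def test_coverage_boundary_exactly_two_thirds_kept():
    block, labels = _coverage_block(6, 9, 8, 12)
    out, _ = filter_group_coverage(block, labels)
    assert out.n_features == 1


def test_full_coverage_kept():
    block, labels = _coverage_block(9, 9, 12, 12)
    out, _ = filter_group_coverage(block, labels)
    assert out.n_features == 1


def test_low_coverage_in_one_group_removed():
    block, labels = _coverage_block(9, 9, 7, 12)  # 7/12 < 2/3
    out, _ = filter_group_coverage(block, labels)
    assert out.n_features == 0


def test_coverage_any_mode_keeps_single_group_coverage():
    block, labels = _coverage_block(9, 9, 7, 12)
    out, _ = filter_group_coverage(block, labels, mode="any")
    assert out.n_features == 1


def test_coverage_requires_two_groups():
    block = make_count_block([[1], [1]], assay="mintmap")
    with pytest.raises(ValueError, match="two groups"):
        filter_group_coverage(block, ["A", "A"])


# ---- zero SD ----------------------------------------------------------------

def test_constant_feature_removed_single_difference_kept():
    block = make_count_block([[5, 5], [5, 6], [5, 5]])
    out, _ = filter_zero_sd(block)
    assert out.feature_ids == ["g1"]


def test_zero_sd_on_empty_block():
    block = make_count_block(np.zeros((3, 0)))
    out, rep = filter_zero_sd(block)
    assert rep.n_before == 0 and out.n_features == 0


# ---- RCV --------------------------------------------------------------------

@pytest.mark.parametrize(
    "values,expected",
    [
        ([0.1, 0.2, 0.9], 0.5),
        ([0.01, 0.5, 0.99], 0.98),
        ([0.01, 0.4, 0.99], 0.975),
        ([0.01, 0.2, 0.99], 0.95),
    ],
)
def test_rcv_hand_computations(values, expected):
    assert rcv(np.array(values)) == pytest.approx(expected, abs=1e-12)


def test_rcv_filter_removes_low_variation_and_constant():
    block = make_methyl_block(np.column_stack([
        [0.1, 0.2, 0.9],     # RCV 0.5 -> removed
        [0.5, 0.5, 0.5],     # constant -> removed
        [0.0, 0.35, 0.7],    # median 0.35, MAD 0.35 -> RCV 1.0 -> kept
    ]))
    out, rep = filter_rcv(block, threshold=1.0)
    assert out.feature_ids == ["cpg2"]
    assert rep.n_after == 1


def test_rcv_median_zero_excluded_with_reason():
    block = make_methyl_block(np.column_stack([[0.0, 0.0, 0.4]]))
    out, rep = filter_rcv(block)
    assert out.n_features == 0
    assert rep.notes["undefined_median"] == ["cpg0"]


def test_rcv_strictly_below_one_for_positive_data():
    """MAD/median < 1 is a theorem for strictly positive values."""
    rng = np.random.default_rng(0)
    for _ in range(200):
        x = rng.lognormal(0, 2, size=rng.integers(2, 30))
        assert rcv(x) < 1.0


def test_rcv_rejects_count_assay():
    with pytest.raises(ValueError, match="methylome"):
        filter_rcv(make_count_block([[1, 2], [3, 4]]))


# ---- filter properties ------------------------------------------------------

@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_filters_idempotent_and_shrinking(seed):
    rng = np.random.default_rng(seed)
    counts = rng.negative_binomial(2, 0.05, size=(8, 40)).astype(float)
    block = make_count_block(counts)
    once, _ = filter_min_total_count(block, 100)
    twice, _ = filter_min_total_count(once, 100)
    assert once.feature_ids == twice.feature_ids
    assert once.n_features <= block.n_features
    assert once.sample_ids == block.sample_ids
    z1, _ = filter_zero_sd(block)
    z2, _ = filter_zero_sd(z1)
    assert z1.feature_ids == z2.feature_ids


# ---- TMM --------------------------------------------------------------------

def test_tmm_identical_samples_unit_factors():
    block = make_count_block([[10, 20, 30, 40], [10, 20, 30, 40]])
    _, params = tmm_normalize(block)
    np.testing.assert_allclose(params.factors.to_numpy(), [1.0, 1.0], atol=1e-12)


def test_tmm_scale_equivariance():
    rng = np.random.default_rng(5)
    a = rng.negative_binomial(5, 0.1, size=40).astype(float) + 1
    block = make_count_block(np.vstack([a, 2 * a]))
    norm, _ = tmm_normalize(block)
    np.testing.assert_allclose(norm.values[0], norm.values[1], rtol=1e-10)


def test_tmm_worked_examples_match_independent_computation():
    """Factors frozen from an independent step-by-step reference computation."""
    block6 = make_count_block(np.array([
        [100, 200, 50, 400, 80, 120],
        [210, 380, 110, 820, 150, 260],
        [95, 205, 48, 410, 85, 115],
    ], float))
    _, params = tmm_normalize(block6)
    np.testing.assert_allclose(
        params.factors.to_numpy(),
        [0.9974495830, 0.9996104870, 1.0029475994], atol=1e-6)

    block4 = make_count_block(np.array([
        [500, 100, 300, 60],
        [1000, 250, 560, 140],
        [480, 90, 310, 55],
    ], float))
    _, params4 = tmm_normalize(block4)
    np.testing.assert_allclose(
        params4.factors.to_numpy(),
        [1.007750579283, 1.001619577449, 0.990704507509], atol=1e-6)


def test_tmm_factor_geometric_mean_one_and_rescale_invariance():
    rng = np.random.default_rng(9)
    counts = rng.negative_binomial(3, 0.02, size=(6, 200)).astype(float)
    block = make_count_block(counts)
    norm1, params = tmm_normalize(block)
    assert np.exp(np.mean(np.log(params.factors))) == pytest.approx(1.0, abs=1e-12)
    # rescaling every sample by the same constant leaves CPM output unchanged
    norm2, params2 = tmm_normalize(make_count_block(counts * 4))
    np.testing.assert_allclose(norm1.values, norm2.values, rtol=1e-9)


def test_tmm_all_zero_sample_rejected():
    block = make_count_block([[0, 0, 0], [1, 2, 3]])
    with pytest.raises(ValueError, match="all-zero"):
        tmm_normalize(block)


def test_tmm_apply_consistent_with_training_reference():
    rng = np.random.default_rng(17)
    counts = rng.negative_binomial(3, 0.02, size=(8, 150)).astype(float)
    block = make_count_block(counts)
    norm, params = tmm_normalize(block)
    renorm = tmm_apply(block, params)
    np.testing.assert_allclose(renorm.values, norm.values, rtol=1e-12)


# ---- dispatcher -------------------------------------------------------------

def test_methylome_never_normalized(default_cohort):
    blocks, metadata, _ = default_cohort
    res = preprocess_block(blocks["csf_cells_methylome"])
    assert res.tmm is None
    assert all(r.rule == "rcv" for r in res.reports)


def test_report_chain_consistency(default_cohort):
    blocks, metadata, _ = default_cohort
    groups = metadata["group"]
    fit = metadata.index[~groups.eq("SPMS")]
    binary = groups.loc[fit].isin(["RRMS", "CIS", "RIS"]).map(
        {True: "positive", False: "control"})
    for name, block in blocks.items():
        res = preprocess_block(block.subset_samples(fit), binary)
        assert res.reports[-1].n_after == res.block.n_features
        for prev, nxt in zip(res.reports, res.reports[1:]):
            assert nxt.n_before == prev.n_after


def test_smallseq_filter_count_matches_bookkeeping(default_cohort):
    blocks, _, _ = default_cohort
    block = blocks["plasma_smallseq"]
    expected = int((block.data.sum(axis=0) >= 100).sum())
    out, rep = filter_min_total_count(block, 100)
    assert rep.n_after == expected == out.n_features


def test_unknown_assay_rejected():
    block = make_count_block([[1, 2], [3, 4]])
    object.__setattr__(block, "assay", "proteome")
    with pytest.raises(ValueError, match="unknown assay|proteome"):
        preprocess_block(block)
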