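"""Co-inertia decomposition: standardization, fit, projection, contributions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multicia.model import MCIA, StandardizedBlock, fit_mcia, standardize_block
from multicia.preprocess import preprocess_block

from oracles import mcia_reference


def _std_from_values(x, name="b"):
    df = pd.DataFrame(np.asarray(x, float),
                      index=[f"s{i}" for i in range(len(x))],
                      columns=[f"f{j}" for j in range(np.asarray(x).shape[1])])
    return standardize_block(df, name=name)


def _random_std_blocks(rng, n, sizes):
    return {f"b{i}": _std_from_values(rng.normal(size=(n, p)), name=f"b{i}")
            for i, p in enumerate(sizes)}


# ---- standardization --------------------------------------------------------

def test_standardize_worked_example():
    sb = _std_from_values([[0, 2], [2, 0]])
    np.testing.assert_allclose(sb.values, [[-0.5, 0.5], [0.5, -0.5]], atol=1e-12)
    assert (sb.values**2).sum() == pytest.approx(1.0, abs=1e-12)


def test_standardize_centers_columns():
    rng = np.random.default_rng(2)
    sb = _std_from_values(rng.lognormal(1, 1, size=(9, 14)))
    assert np.abs(sb.values.mean(axis=0)).max() < 1e-10
    assert (sb.values**2).sum() == pytest.approx(1.0, abs=1e-10)


def test_standardize_idempotent_on_standardized_values():
    rng = np.random.default_rng(4)
    sb = _std_from_values(rng.normal(size=(7, 5)))
    again = _std_from_values(sb.values)
    np.testing.assert_allclose(again.values, sb.values, atol=1e-12)


def test_zero_sd_column_raises_with_feature_name():
    x = np.array([[1.0, 3.0], [1.0, 4.0], [1.0, 5.0]])
    with pytest.raises(ValueError, match="f0"):
        _std_from_values(x)


def test_raw_inertia_variant_scales_only():
    rng = np.random.default_rng(6)
    df = pd.DataFrame(rng.normal(size=(6, 4)))
    root = standardize_block(df, inertia="root")
    raw = standardize_block(df, inertia="raw")
    ratio = root.values / raw.values
    assert np.allclose(ratio, ratio.flat[0])


def test_training_transform_reproduces_stored_values(default_cohort):
    blocks, metadata, _ = default_cohort
    res = preprocess_block(blocks["csf_cells_methylome"])
    sb = standardize_block(res.block)
    np.testing.assert_allclose(sb.transform(res.block.data), sb.values, atol=1e-12)


# ---- fit: reductions and oracle --------------------------------------------

def test_single_block_fit_equals_svd():
    rng = np.random.default_rng(10)
    sb = _std_from_values(rng.normal(size=(8, 6)))
    k = 5
    res = MCIA({"b": sb}, n_components=k).fit()
    u, s, vt = np.linalg.svd(sb.values, full_matrices=False)
    for j in range(k):
        score = res.global_scores.iloc[:, j].to_numpy()
        ref = u[:, j] * s[j]
        sign = np.sign(score @ ref)
        np.testing.assert_allclose(score, sign * ref, atol=1e-8)
        np.testing.assert_allclose(
            res.block_loadings["b"].iloc[:, j].to_numpy(), sign * vt[j], atol=1e-8)
        assert res.eigenvalues.iloc[j] == pytest.approx(s[j] ** 2, rel=1e-10)


def test_duplicated_block_contributions_half_half():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(7, 5))
    blocks = {"a": _std_from_values(x, "a"), "b": _std_from_values(x, "b")}
    res = MCIA(blocks, n_components=3).fit()
    frac = res.contribution_fractions
    np.testing.assert_allclose(frac.loc["a"], 0.5, atol=1e-10)
    np.testing.assert_allclose(frac.loc["b"], 0.5, atol=1e-10)


def test_fit_matches_reference_oracle():
    """6-sample, (4+3)-feature two-block instances vs the literal oracle."""
    for seed in (0, 1, 2, 3, 4):
        rng = np.random.default_rng(seed)
        blocks = _random_std_blocks(rng, 6, [4, 3])
        res = MCIA(blocks, n_components=4).fit()
        ref_scores, ref_loadings, ref_eigs, _ = mcia_reference(
            [blocks["b0"].values, blocks["b1"].values], 4)
        np.testing.assert_allclose(res.global_scores.to_numpy(), ref_scores, atol=1e-8)
        np.testing.assert_allclose(res.eigenvalues.to_numpy(), ref_eigs, atol=1e-8)
        np.testing.assert_allclose(
            res.block_loadings["b0"].to_numpy(), ref_loadings[0], atol=1e-8)
        np.testing.assert_allclose(
            res.block_loadings["b1"].to_numpy(), ref_loadings[1], atol=1e-8)


def test_eigenvalues_non_increasing():
    rng = np.random.default_rng(13)
    blocks = _random_std_blocks(rng, 10, [6, 8, 4])
    res = MCIA(blocks, n_components=9).fit()
    eigs = res.eigenvalues.to_numpy()
    assert (np.diff(eigs) <= 1e-10).all()


def test_block_loadings_unit_norm_and_orthogonal():
    rng = np.random.default_rng(14)
    blocks = _random_std_blocks(rng, 12, [9, 7])
    res = MCIA(blocks, n_components=6).fit()
    for name in blocks:
        v = res.block_loadings[name].to_numpy()
        np.testing.assert_allclose(np.linalg.norm(v, axis=0), 1.0, atol=1e-10)
        gram = v.T @ v
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8


def test_contribution_fractions_sum_to_one():
    rng = np.random.default_rng(15)
    blocks = _random_std_blocks(rng, 9, [5, 6, 3])
    res = MCIA(blocks, n_components=4).fit()
    frac = res.contribution_fractions
    assert ((frac >= 0) & (frac <= 1)).all().all()
    np.testing.assert_allclose(frac.sum(axis=0), 1.0, atol=1e-10)


def test_block_order_invariance_up_to_sign():
    rng = np.random.default_rng(16)
    blocks = _random_std_blocks(rng, 8, [5, 4, 6])
    res1 = MCIA(blocks, n_components=3).fit()
    reordered = {k: blocks[k] for k in ["b2", "b0", "b1"]}
    res2 = MCIA(reordered, n_components=3).fit()
    for j in range(3):
        a = res1.global_scores.iloc[:, j].to_numpy()
        b = res2.global_scores.iloc[:, j].to_numpy()
        sign = np.sign(a @ b)
        np.testing.assert_allclose(a, sign * b, atol=1e-8)


def test_k_too_large_rejected():
    rng = np.random.default_rng(17)
    blocks = _random_std_blocks(rng, 5, [3])
    with pytest.raises(ValueError, match="n_components"):
        MCIA(blocks, n_components=5)


def test_mismatched_sample_ids_rejected():
    rng = np.random.default_rng(18)
    a = _std_from_values(rng.normal(size=(5, 3)), "a")
    b = StandardizedBlock(
        values=a.values, col_means=a.col_means, col_sds=a.col_sds,
        inertia_norm=a.inertia_norm, name="b",
        sample_ids=[f"t{i}" for i in range(5)], feature_ids=a.feature_ids)
    with pytest.raises(ValueError, match="sample ids"):
        MCIA({"a": a, "b": b})


# ---- projection -------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_two_block():
    rng = np.random.default_rng(20)
    raw = {name: pd.DataFrame(
        rng.normal(size=(9, p)), index=[f"s{i}" for i in range(9)],
        columns=[f"{name}_f{j}" for j in range(p)])
        for name, p in [("a", 6), ("b", 4)]}
    blocks = {name: standardize_block(df, name=name) for name, df in raw.items()}
    return raw, MCIA(blocks, n_components=5).fit()


def test_self_projection_reproduces_component1(fitted_two_block):
    raw, res = fitted_two_block
    proj = res.project(raw)
    np.testing.assert_allclose(
        proj.scores["L1"].to_numpy(), res.global_scores["L1"].to_numpy(), atol=1e-8)


def test_projection_of_feature_means_scores_zero(fitted_two_block):
    raw, res = fitted_two_block
    new = {name: pd.DataFrame(df.mean(axis=0).to_frame().T.values,
                              index=["mean_sample"], columns=df.columns)
           for name, df in raw.items()}
    proj = res.project(new)
    np.testing.assert_allclose(proj.scores.to_numpy(), 0.0, atol=1e-10)


def test_projection_copy_consistency(fitted_two_block):
    raw, res = fitted_two_block
    i = 3
    new = {name: df.iloc[[i]].rename(index={df.index[i]: "copy"})
           for name, df in raw.items()}
    proj = res.project(new)
    assert proj.scores["L1"].iloc[0] == pytest.approx(
        res.global_scores["L1"].iloc[i], abs=1e-8)
    assert proj.projected


def test_projection_feature_mismatch_lists_differences(fitted_two_block):
    raw, res = fitted_two_block
    bad = {name: df.copy() for name, df in raw.items()}
    bad["a"] = bad["a"].rename(columns={"a_f0": "rogue"})
    with pytest.raises(ValueError, match="rogue"):
        res.project(bad)


def test_projection_missing_block_rejected(fitted_two_block):
    raw, res = fitted_two_block
    with pytest.raises(ValueError, match="missing block"):
        res.project({"a": raw["a"]})


# ---- feature ranking --------------------------------------------------------

def test_rank_features_absolute_ordering():
    df = pd.DataFrame({"L1": [0.9, -0.95, 0.1]}, index=["a", "b", "c"])
    rng = np.random.default_rng(23)
    blocks = _random_std_blocks(rng, 5, [3])
    res = MCIA(blocks, n_components=1).fit()
    res.block_loadings["b0"] = df
    ranked = res.rank_features(1)
    assert list(ranked["feature"]) == ["b", "a", "c"]
    assert list(ranked["rank"]) == [1, 2, 3]


def test_rank_features_tie_breaks_by_block_then_feature():
    rng = np.random.default_rng(24)
    blocks = _random_std_blocks(rng, 5, [2, 2])
    res = MCIA(blocks, n_components=1).fit()
    res.block_loadings["b0"] = pd.DataFrame({"L1": [0.5, -0.5]}, index=["x", "y"])
    res.block_loadings["b1"] = pd.DataFrame({"L1": [-0.5, 0.5]}, index=["a", "b"])
    ranked = res.rank_features(1)
    assert list(zip(ranked["block"], ranked["feature"])) == [
        ("b0", "x"), ("b0", "y"), ("b1", "a"), ("b1", "b")]


def test_rank_list_covers_all_features(default_cohort):
    blocks, metadata, _ = default_cohort
    fit_ids = metadata.index[metadata["group"] != "SPMS"]
    proc = {}
    for name, b in blocks.items():
        if b.assay == "methylome":
            proc[name] = preprocess_block(b.subset_samples(fit_ids)).block
    res = fit_mcia(proc, n_components=2)
    ranked = res.rank_features(1)
    assert len(ranked) == sum(res.model.blocks[n].n_features for n in res.block_names)


# ---- planted-factor recovery ------------------------------------------------

def test_component1_tracks_planted_factor(default_cohort):
    blocks, metadata, truth = default_cohort
    groups = metadata["group"]
    fit_ids = metadata.index[groups != "SPMS"]
    binary = groups.loc[fit_ids].isin(["RRMS", "CIS", "RIS"]).map(
        {True: "positive", False: "control"})
    proc = {name: preprocess_block(b.subset_samples(fit_ids), binary).block
            for name, b in blocks.items()}
    res = fit_mcia(proc, n_components=2)
    rho = stats.spearmanr(res.global_scores["L1"],
                          truth.latent_factor_values.loc[fit_ids]).statistic
    assert abs(rho) >= 0.8
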