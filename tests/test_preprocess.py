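"""Filtering, imputation, normalization and the two-step differential test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omnitide.omics import OmicsMatrix, sample_name
from omnitide.preprocess import log2fc_profile, preprocess, select_differential
from .conftest import make_matrix


def test_low_valid_fraction_feature_removed():
    rng = np.random.default_rng(0)
    vals = rng.normal(10, 1, size=(3, 30))
    vals[0, 6:] = np.nan  # 6/30 observed < 70%
    m = make_matrix(vals)
    out = preprocess(m, min_valid_fraction=0.7, impute_method="half_minimum")
    assert "f0000" not in out.feature_ids
    assert set(out.feature_ids) == {"f0001", "f0002"}


def test_half_minimum_subtracts_one_log2_unit():
    vals = np.full((1, 30), 9.5)
    vals[0, 0] = 8.0  # observed minimum
    vals[0, 5] = np.nan
    m = make_matrix(vals)
    out = preprocess(m, min_valid_fraction=0.5, impute_method="half_minimum")
    assert out.values.iloc[0, 5] == pytest.approx(7.0)


def test_lls_imputation_uses_correlated_features():
    rng = np.random.default_rng(1)
    base = rng.normal(0, 1, size=30)
    vals = np.vstack([10 + base + rng.normal(0, 0.01, size=30) for _ in range(12)])
    vals[0, 3] = np.nan
    m = make_matrix(vals)
    out = preprocess(m, impute_method="lls", lls_k=5)
    assert out.values.iloc[0, 3] == pytest.approx(10 + base[3], abs=0.1)


def test_lls_falls_back_to_half_minimum_when_too_few_complete(caplog):
    rng = np.random.default_rng(2)
    vals = rng.normal(10, 1, size=(4, 30))
    vals[:, 0] = np.nan  # no complete feature at all
    m = make_matrix(vals)
    with caplog.at_level("WARNING"):
        out = preprocess(m, min_valid_fraction=0.5, impute_method="lls")
    assert "half-minimum" in caplog.text
    assert not out.values.isna().any().any()


def test_zero_centering_removes_replicate_block_means():
    rng = np.random.default_rng(3)
    vals = rng.normal(10, 1, size=(5, 30))
    m = make_matrix(vals)
    out = preprocess(m, zero_center=True)
    for _, cols in out.replicate_blocks().items():
        np.testing.assert_allclose(out.values[cols].mean(axis=1), 0.0, atol=1e-12)


def test_quantile_normalization_aligns_sample_distributions():
    rng = np.random.default_rng(4)
    vals = rng.normal(10, 1, size=(200, 30)) + rng.normal(0, 2, size=30)
    m = make_matrix(vals)
    out = preprocess(m, quantile_normalize=True)
    meds = out.values.median(axis=0)
    assert meds.max() - meds.min() < 0.05


def test_all_missing_feature_dropped_never_imputed():
    vals = np.full((2, 30), 10.0)
    vals[0, :] = np.nan
    m = make_matrix(vals)
    out = preprocess(m, min_valid_fraction=0.0, impute_method="half_minimum")
    assert "f0000" not in out.feature_ids


def test_log2fc_profile_is_mean_difference_vs_control():
    vals = np.full((1, 30), 10.0)
    m = make_matrix(vals)
    m.values.loc["f0000", m.columns_at(3)] = 11.2
    lfc = log2fc_profile(m)
    assert lfc.loc["f0000", "t3"] == pytest.approx(1.2)
    assert (lfc.loc["f0000"].drop("t3") == 0).all()
    with pytest.raises(ValueError):
        log2fc_profile(m, reference_timepoint=99)


def test_constant_feature_has_zero_profile_and_is_not_selected():
    m = make_matrix(np.full((3, 30), 10.0))
    res = select_differential(m, r2_min=0.0, lfc_min=0.0)
    assert (res.lfc.to_numpy() == 0).all()
    assert (res.table["p_value"] == 1.0).all()
    assert not res.table["selected"].any()


def test_planted_switch_selected_with_standard_thresholds():
    rng = np.random.default_rng(5)
    vals = 10 + rng.normal(0, 0.25, size=(40, 30))
    step = np.where(np.repeat(np.arange(10), 3) >= 2, 2.0, 0.0)
    vals[0] += step
    m = make_matrix(vals)
    res = select_differential(m, alpha=0.05, r2_min=0.6, lfc_min=1.0)
    assert bool(res.table.loc["f0000", "selected"])
    assert res.table.loc["f0000", "r_squared"] > 0.6
    assert res.table.loc["f0000", "max_abs_log2fc"] == pytest.approx(2.0, abs=0.3)


def test_bh_adjustment_bounds_and_selection_invariants():
    rng = np.random.default_rng(6)
    vals = 10 + rng.normal(0, 0.3, size=(100, 30))
    vals[:5] += np.where(np.repeat(np.arange(10), 3) >= 4, 1.5, 0.0)
    m = make_matrix(vals)
    res = select_differential(m, r2_min=0.0, lfc_min=0.0)
    t = res.table
    assert (t["adj_p"] >= t["p_value"] - 1e-15).all()
    assert (t["adj_p"] <= 1.0).all()
    # adj_p non-decreasing in p rank
    s = t.sort_values("p_value")
    assert (np.diff(s["adj_p"].to_numpy()) >= -1e-12).all()
    # nothing selected at infinite lfc threshold
    res_inf = select_differential(m, lfc_min=np.inf)
    assert not res_inf.table["selected"].any()
    # everything with finite F selected at the permissive corner
    res_all = select_differential(m, alpha=1.0, r2_min=0.0, lfc_min=0.0)
    assert res_all.table["selected"].all()


def test_selection_invariant_to_location_shift_and_column_order():
    rng = np.random.default_rng(7)
    vals = 10 + rng.normal(0, 0.3, size=(30, 30))
    vals[0] += np.where(np.repeat(np.arange(10), 3) >= 3, 2.0, 0.0)
    m = make_matrix(vals)
    res = select_differential(m)
    shifted = make_matrix(vals + 5.0)
    res_shift = select_differential(shifted)
    pd.testing.assert_series_equal(res.table["selected"], res_shift.table["selected"])
    perm = rng.permutation(m.values.shape[1])
    mp = OmicsMatrix("TEST", m.values.iloc[:, perm])
    res_perm = select_differential(mp)
    pd.testing.assert_series_equal(res.table["selected"], res_perm.table["selected"])


def test_too_few_timepoints_for_degree_rejected():
    m = make_matrix(np.random.default_rng(8).normal(10, 1, (3, 12)), n_timepoints=4)
    with pytest.raises(ValueError, match="timepoints"):
        select_differential(m, degree=3)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_replicate_outlier_masking_never_invents_values(seed):
    rng = np.random.default_rng(seed)
    vals = rng.normal(10, 1, size=(6, 30))
    m = make_matrix(vals)
    out = preprocess(
        m, min_valid_fraction=0.0, impute_method="half_minimum", metab_sd_outlier=True
    )
    # every surviving value existed in the input (imputed cells are min-1)
    for fid in out.feature_ids:
        orig = set(np.round(vals[int(fid[1:])], 9))
        allowed = orig | {round(v - 1.0, 9) for v in orig}
        assert set(np.round(out.values.loc[fid].to_numpy(), 9)) <= allowed
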