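"""Regulatory class assignment, persistence, concordance, kinase activity."""

import numpy as np
import pandas as pd
import pytest

from omnitide import classes as cl


def test_class_rule_examples():
    assert cl.assign_class([0.8, 0.6, 0.9]) == "I"
    assert cl.assign_class([0.8, -0.5]) == "II-B"
    assert cl.assign_class([0.1, 0.3]) == "II-A"


def test_anticorrelation_takes_precedence_over_class_I():
    # one strong negative pair must never yield Class I
    assert cl.assign_class([0.9, 0.9, -0.41]) == "II-B"
    assert cl.assign_class({("A", "B"): 0.41, ("A", "C"): -0.4}) == "II-B"


def test_class_invariant_to_pair_order_and_na_excluded():
    vals = [0.5, 0.45, 0.7]
    assert cl.assign_class(vals) == cl.assign_class(vals[::-1])
    assert cl.assign_class([np.nan, 0.5]) == "I"
    with pytest.raises(ValueError):
        cl.assign_class([np.nan, np.nan])


def test_boundary_values_of_class_rule():
    assert cl.assign_class([0.4]) == "I"  # r >= 0.4 inclusive
    assert cl.assign_class([-0.4]) == "II-B"  # r <= -0.4 inclusive
    assert cl.assign_class([0.39]) == "II-A"
    assert cl.assign_class([-0.39]) == "II-A"


def test_class_persistence_identity_and_permutation_expectation():
    genes = [f"g{i}" for i in range(3000)]
    rng = np.random.default_rng(0)
    labels = pd.Series(rng.choice(["I", "II-A", "II-B"], size=3000), index=genes)
    res = cl.class_persistence(labels, labels)
    assert res["overall"] == 1.0
    shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=genes)
    res_p = cl.class_persistence(labels, shuffled)
    assert res_p["overall"] == pytest.approx(1 / 3, abs=0.03)
    with pytest.raises(ValueError):
        cl.class_persistence(labels.iloc[:5], labels.iloc[10:15].rename(lambda s: s + "x"))


def test_concordance_fraction_extremes_and_monotonicity():
    genes = [f"g{i}" for i in range(100)]
    all_one = pd.Series(1.0, index=genes)
    all_zero = pd.Series(0.0, index=genes)
    assert cl.concordance_fraction(genes, all_one, r_cut=0.1) == 0.0
    assert cl.concordance_fraction(genes, all_zero, r_cut=0.1) == 1.0
    rng = np.random.default_rng(1)
    mixed = pd.Series(rng.uniform(-1, 1, size=100), index=genes)
    f1 = cl.concordance_fraction(genes, mixed, r_cut=0.1)
    f2 = cl.concordance_fraction(genes, mixed, r_cut=0.5)
    assert 0.0 <= f1 <= f2 <= 1.0
    with pytest.raises(ValueError):
        cl.concordance_fraction([], mixed)


def test_concordance_fraction_on_planted_uncorrelated_subset():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(100)]
    pcc = pd.Series(1.0, index=genes)
    pcc.iloc[:30] = 0.0  # planted: 30/100 uncorrelated with reference
    assert cl.concordance_fraction(genes, pcc, r_cut=0.1) == pytest.approx(0.30)


def test_protein_phospho_concordance_counts_both_cutoffs():
    cols = [f"t{i}" for i in range(1, 10)]
    prof = np.arange(9.0)
    protein = pd.DataFrame([prof], index=["P1"], columns=cols)
    sites = pd.DataFrame(
        [prof, -prof, np.r_[prof[1:], 0.0]],
        index=["P1_S1", "P1_S2", "ORPHAN_S9"],
        columns=cols,
    )
    res = cl.protein_phospho_concordance(sites, protein)
    assert res["n_unmapped"] == 1
    assert res["pcc"]["P1_S1"] == pytest.approx(1.0)
    assert res["pcc"]["P1_S2"] == pytest.approx(-1.0)
    assert res["fraction_poor"] == pytest.approx(0.5)  # only the flipped site
    assert res["fraction_opposite"] == pytest.approx(0.5)


def test_protein_phospho_planted_mixture_fraction():
    rng = np.random.default_rng(3)
    cols = [f"t{i}" for i in range(1, 10)]
    prots, sites, site_rows = [], [], []
    for i in range(200):
        prof = rng.normal(size=9)
        prots.append(prof)
        coupled = i < 100
        site_rows.append(prof if coupled else rng.normal(size=9))
        sites.append(f"P{i}_S1")
    protein = pd.DataFrame(prots, index=[f"P{i}" for i in range(200)], columns=cols)
    psite = pd.DataFrame(site_rows, index=sites, columns=cols)
    res = cl.protein_phospho_concordance(psite, protein)
    # coupled sites have r = 1; independent sites are mostly below 0.4
    assert res["fraction_poor"] == pytest.approx(0.5, abs=0.1)


def test_kinase_activity_null_and_shift_invariance():
    rng = np.random.default_rng(4)
    n = 2000
    lfc = pd.DataFrame(
        {"t1": rng.normal(0, 1, n), "t3": rng.normal(0, 1, n)},
        index=[f"s{i}" for i in range(n)],
    )
    subs = [f"s{i}" for i in range(20)]  # drawn from the same null
    acts = cl.kinase_activity(lfc, {"K": subs}, m_min=3)
    assert abs(acts[0].z_by_timepoint["t1"]) < 3.5
    shifted = cl.kinase_activity(lfc + 7.0, {"K": subs}, m_min=3)
    np.testing.assert_allclose(
        acts[0].z_by_timepoint.to_numpy(),
        shifted[0].z_by_timepoint.to_numpy(),
        atol=1e-9,
    )


def test_kinase_stage_bins_route_timepoints():
    rng = np.random.default_rng(5)
    n = 500
    cols = [f"t{i}" for i in range(1, 10)]
    lfc = pd.DataFrame(rng.normal(0, 1, size=(n, 9)),
                       index=[f"s{i}" for i in range(n)], columns=cols)
    acts = cl.kinase_activity(lfc, {"K": [f"s{i}" for i in range(10)]}, m_min=3)
    z = acts[0].z_by_timepoint.abs()
    sums = acts[0].stage_sums
    assert sums["E"] == pytest.approx(z[["t1", "t2"]].sum())
    assert sums["E/M"] == pytest.approx(z[["t3", "t4", "t5"]].sum())
    assert sums["M"] == pytest.approx(z[["t6", "t7", "t8", "t9"]].sum())


def test_kinase_below_substrate_minimum_skipped_and_zero_sd_errors():
    lfc = pd.DataFrame({"t1": [0.0, 0.0, 0.0]}, index=["a", "b", "c"])
    with pytest.raises(ValueError, match="sd"):
        cl.kinase_activity(lfc, {"K": ["a", "b", "c"]}, m_min=3)
    lfc2 = pd.DataFrame({"t1": [0.1, 0.5, -0.3, 0.2]}, index=list("abcd"))
    assert cl.kinase_activity(lfc2, {"K": ["a", "b"]}, m_min=3) == []


def test_classify_genes_recovers_planted_labels(zero_noise_sim):
    from omnitide.preprocess import log2fc_profile

    cfg, layers, truth = zero_noise_sim
    proteomic = [s.name for s in cfg.layers if s.proteomic]
    lfc = {n: log2fc_profile(layers[n]) for n in proteomic}
    table = cl.classify_genes(lfc)
    covered = [g for g in truth.class_label if g in table.index]
    assert len(covered) > 50
    mismatch = [
        g for g in covered if table.loc[g, "class"] != truth.class_label[g]
    ]
    assert mismatch == []
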