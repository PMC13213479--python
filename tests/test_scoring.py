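"""Scale scores, Hedges' g, weighted statistics, pairwise comparison reports."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdsmeq.mnlfa import fit_mnlfa
from pdsmeq.scoring import (
    build_score_table,
    categorize_effect,
    comparison_matrix,
    hedges_g,
    pairwise_compare,
    pre_post_report,
    unadjusted_scale_score,
    weighted_group_stats,
)
from pdsmeq.synthetic import default_true_params

from conftest import make_dataset


# --- unadjusted scores ----------------------------------------------------


def test_unadjusted_score_is_item_mean(toy_table):
    t = toy_table.copy()
    t.loc[0, [f"item_{j}" for j in range(1, 8)]] = [1, 2, 3, 4, 5, 1, 2]
    s = unadjusted_scale_score(t)
    assert s.iloc[0] == pytest.approx(18 / 7)
    t2 = toy_table.copy()
    t2[[f"item_{j}" for j in range(1, 8)]] = 5
    assert (unadjusted_scale_score(t2) == 5.0).all()


def test_unadjusted_score_missing_item_excludes_person(toy_table):
    t = toy_table.copy()
    t.loc[2, "item_4"] = np.nan
    s = unadjusted_scale_score(t)
    assert np.isnan(s.iloc[2]) and np.isfinite(s.drop(index=2)).all()


# --- Hedges' g ------------------------------------------------------------


def test_hedges_g_zero_for_equal_means():
    assert hedges_g(1.2, 0.5, 100, 1.2, 0.7, 80) == 0.0


def test_hedges_g_antisymmetric():
    g12 = hedges_g(0.36, 0.81, 1488, -0.15, 0.53, 5773)
    g21 = hedges_g(-0.15, 0.53, 5773, 0.36, 0.81, 1488)
    assert g12 == pytest.approx(-g21)


def test_hedges_g_small_sample_correction():
    # n1=n2=5: J = 1 - 3/31
    g = hedges_g(1.0, 1.0, 5, 0.0, 1.0, 5)
    assert g == pytest.approx((1 - 3 / 31) * 1.0)


def test_hedges_g_invalid_inputs():
    with pytest.raises(ValueError):
        hedges_g(1, 1, 1, 0, 1, 5)
    with pytest.raises(ValueError):
        hedges_g(1, 0, 5, 0, 0, 5)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    st.floats(-5, 5), st.floats(0.1, 3), st.integers(5, 500),
    st.floats(-5, 5), st.floats(0.1, 3), st.integers(5, 500),
    st.floats(-10, 10), st.floats(0.1, 10),
)
def test_hedges_g_affine_invariance(m1, s1, n1, m2, s2, n2, shift, scale):
    g = hedges_g(m1, s1, n1, m2, s2, n2)
    g2 = hedges_g(scale * m1 + shift, scale * s1, n1, scale * m2 + shift, scale * s2, n2)
    assert g2 == pytest.approx(g, abs=1e-9)


# --- effect-size categories -----------------------------------------------


@pytest.mark.parametrize(
    "g,cat",
    [(0.403, "small"), (0.515, "medium"), (0.893, "large"), (0.19, "below-small"),
     (-0.85, "large"), (0.2, "small"), (0.5, "medium"), (0.8, "large")],
)
def test_categorize_effect_bins(g, cat):
    assert categorize_effect(g) == cat


# --- weighted statistics --------------------------------------------------


def test_unit_weights_reduce_to_classical_stats():
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    m, sd, n = weighted_group_stats(x, np.ones(200))
    assert m == pytest.approx(x.mean())
    assert sd == pytest.approx(x.std(ddof=1))
    assert n == 200


def test_duplicating_equals_doubling_weight():
    x = np.array([1.0, 2.0, 5.0])
    m_dup, _, _ = weighted_group_stats(np.array([1.0, 1.0, 2.0, 5.0]), np.ones(4))
    m_w, _, _ = weighted_group_stats(x, np.array([2.0, 1.0, 1.0]))
    assert m_w == pytest.approx(m_dup)


def test_weighted_stats_match_definition_oracle():
    rng = np.random.default_rng(1)
    x = rng.normal(size=50)
    w = rng.uniform(0.2, 3.0, size=50)
    m, sd, n = weighted_group_stats(x, w)
    m_o = np.sum(w * x) / np.sum(w)
    sd_o = np.sqrt(np.sum(w * (x - m_o) ** 2) / (np.sum(w) - 1))
    assert m == pytest.approx(m_o) and sd == pytest.approx(sd_o) and n == 50


def test_weighted_stats_errors():
    with pytest.raises(ValueError, match="empty group"):
        weighted_group_stats(np.array([]), np.array([]))
    with pytest.raises(ValueError, match="positive"):
        weighted_group_stats(np.array([1.0]), np.array([-1.0]))


# --- pairwise comparisons --------------------------------------------------


@pytest.fixture(scope="module")
def scored_cohort():
    table, design = make_dataset("final_model", n=8000, seed=81, continuous=False)
    truth = default_true_params("final_model")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_mnlfa(table, design, active=truth.active)
    return build_score_table(table, fit, design)


def test_pairwise_report_structure_and_families(scored_cohort):
    rep = pairwise_compare(scored_cohort, "unadjusted")
    counts = rep.groupby("family").size()
    assert counts["sex"] == 1 and counts["race"] == 3 and counts["intersectional"] == 15
    # internal consistency: g recomputes from the printed summaries
    for _, r in rep.iterrows():
        assert r["g"] == pytest.approx(
            hedges_g(r["mean1"], r["sd1"], r["n1"], r["mean2"], r["sd2"], r["n2"])
        )


def test_adjustment_removes_dif_induced_sex_artifact(scored_cohort):
    """The injected sex intercept DIF leaks into unadjusted scale scores as a
    spurious sex gap; the bias-adjusted factor scores remove it, while the real
    race/ethnicity differences are flagged under both scorings."""
    adj = pairwise_compare(scored_cohort, "adjusted")
    sex_adj = adj[adj["family"] == "sex"].iloc[0]
    assert not sex_adj["significant"]
    unadj = pairwise_compare(scored_cohort, "unadjusted")
    sex_unadj = unadj[unadj["family"] == "sex"].iloc[0]
    # adjustment shrinks the standardized sex gap
    assert abs(sex_adj["g"]) < abs(sex_unadj["g"])
    for rep in (adj, unadj):
        race = rep[rep["family"] == "race"].set_index(["group1", "group2"])
        assert race.loc[("Black", "White"), "significant"]
        assert race.loc[("Black", "White"), "g"] > 0


def test_adjusted_scores_center_at_model_implied_mean(scored_cohort):
    """Posterior scores average to the sample mean of the fitted alpha(x): with
    uncentred Helmert codes and race mean effects this is nonzero, and the sex
    groups stay essentially level (the structural pattern of the study's
    adjusted-score table)."""
    rep = pairwise_compare(scored_cohort, "adjusted")
    sex = rep[rep["family"] == "sex"].iloc[0]
    assert abs(sex["mean1"] - sex["mean2"]) < 0.05
    race = rep[rep["family"] == "race"].set_index(["group1", "group2"])
    assert race.loc[("Black", "White"), "mean1"] > 0 > race.loc[("Black", "White"), "mean2"]


def test_identical_populations_mostly_ns(null_cohort):
    table, design = null_cohort
    fit_params = default_true_params("null")
    scores = build_score_table(table, fit_params, design)
    rep = pairwise_compare(scores, "unadjusted")
    assert rep["significant"].sum() <= 2  # FDR keeps false flags rare


def test_swapping_groups_flips_g_sign(scored_cohort):
    rep = pairwise_compare(scored_cohort, "adjusted")
    r = rep[rep["family"] == "race"].iloc[0]
    assert hedges_g(r["mean2"], r["sd2"], r["n2"], r["mean1"], r["sd1"], r["n1"]) == pytest.approx(-r["g"])


def test_pre_post_report_flags_category_shifts(scored_cohort):
    ua = pairwise_compare(scored_cohort, "unadjusted")
    ad = pairwise_compare(scored_cohort, "adjusted")
    rep = pre_post_report(ua, ad)
    assert set(rep.columns) >= {"g_unadjusted", "g_adjusted", "delta_g", "category_shift"}
    same = pre_post_report(ua, ua)
    assert (same["delta_g"] == 0).all() and (same["category_shift"] == "").all()


def test_comparison_matrix_layout(scored_cohort):
    ua = pairwise_compare(scored_cohort, "unadjusted")
    ad = pairwise_compare(scored_cohort, "adjusted")
    M = comparison_matrix(ua, ad)
    assert M.shape == (6, 6)
    assert all(M.loc[g, g].startswith("n=") for g in M.index)
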