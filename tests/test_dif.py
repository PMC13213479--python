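"""Staged DIF selection: pairing, screens, BH-FDR, trimming, trace."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdsmeq.dif import (
    EffectKey,
    SelectionConfig,
    UnitKey,
    all_units,
    bh_fdr,
    conditional_step,
    impact_step,
    item_dif_step,
    pair_groups,
    run_pipeline,
)
from pdsmeq.mnlfa import ActiveSet
from pdsmeq.synthetic import GeneratorConfig, default_true_params, simulate_dataset
from pdsmeq.contrasts import build_design

from conftest import make_dataset


# --- retention units ------------------------------------------------------


def test_pair_groups_partition():
    units = pair_groups()
    assert units == {
        "sex": ("sex",),
        "race": ("race1", "race2"),
        "sex_race": ("sex_race1", "sex_race2"),
    }
    flat = [c for covs in units.values() for c in covs]
    assert sorted(flat) == sorted(["sex", "race1", "race2", "sex_race1", "sex_race2"])


def test_unit_members_expand_pairs():
    u = UnitKey("intercept", 3, "race")
    assert [str(m) for m in u.members()] == ["intercept[3]~race1", "intercept[3]~race2"]
    assert len(all_units("loading")) == 21  # 7 items x 3 units


def test_effect_key_validation():
    with pytest.raises(ValueError, match="item index"):
        EffectKey("intercept", 9, "sex")
    with pytest.raises(ValueError, match="no item index"):
        EffectKey("mean", 1, "sex")
    with pytest.raises(ValueError, match="unknown covariate"):
        EffectKey("mean", None, "age")


def test_selection_config_rejects_bad_thresholds():
    with pytest.raises(ValueError, match="impact_threshold"):
        SelectionConfig(impact_threshold=1.5).validate()


# --- BH-FDR ---------------------------------------------------------------


def bh_oracle(p, q):
    """Definitional step-up rule: largest k with p_(k) <= q k/m, reject 1..k."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def test_bh_worked_example():
    p = [0.001, 0.01, 0.02, 0.04, 0.2]
    assert list(bh_fdr(p, q=0.05)) == [True, True, True, True, False]


def test_bh_edge_cases():
    assert not bh_fdr([1.0, 1.0, 1.0], q=0.05).any()
    assert bh_fdr([0.04], q=0.05).all()
    assert bh_fdr([], q=0.05).size == 0
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2], q=0.05)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
       st.sampled_from([0.01, 0.05, 0.1, 0.25]))
def test_bh_matches_definitional_oracle(pvals, q):
    assert np.array_equal(bh_fdr(pvals, q=q), bh_oracle(pvals, q))


# --- screening stages on data with known truth ----------------------------


@pytest.fixture(scope="module")
def race_impact_cohort():
    truth = default_true_params("null").copy()
    truth.beta[1] = 0.5  # race1 effect on the factor mean
    cfg = GeneratorConfig(n=5000, true_params=truth, seed=61, continuous=True)
    table = simulate_dataset(cfg)
    return table, build_design(table)


def test_impact_step_retains_race_pair_on_mean(race_impact_cohort):
    table, design = race_impact_cohort
    retained, _ = impact_step(table, design)
    assert UnitKey("mean", None, "race") in retained


def test_variance_moderation_detected():
    truth = default_true_params("null").copy()
    truth.delta[0] = 0.4  # sex effect on the factor variance
    cfg = GeneratorConfig(n=5000, true_params=truth, seed=63, continuous=True)
    table = simulate_dataset(cfg)
    design = build_design(table)
    retained, _ = impact_step(table, design)
    assert UnitKey("variance", None, "sex") in retained


def test_item_step_detects_injected_intercept_and_loading_dif():
    truth = default_true_params("null").copy()
    truth.kappa[0, 0] = -0.21  # item-1 sex intercept
    truth.omega_mod[1, 0] = 0.30  # item-2 sex loading
    cfg = GeneratorConfig(n=9360, true_params=truth, seed=65, continuous=True)
    table = simulate_dataset(cfg)
    design = build_design(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        retained, _ = item_dif_step(table, design, impact_units=[])
    assert UnitKey("intercept", 1, "sex") in retained
    assert UnitKey("loading", 2, "sex") in retained


def test_conditional_step_empty_carried_set_returns_invariant_fit(null_cohort):
    table, design = null_cohort
    structural, measurement, fit = conditional_step(table, design, carried=[])
    assert structural == [] and measurement == []
    assert fit.converged
    assert fit.params.active.n_active == 0


# --- full pipeline --------------------------------------------------------


def test_pipeline_trace_is_deterministic_and_complete():
    table, design = make_dataset("final_model", n=2500, seed=67)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r1 = run_pipeline(table, design)
        r2 = run_pipeline(table, design)
    pd.testing.assert_frame_equal(r1.trace, r2.trace)
    assert [str(u) for u in r1.final_units] == [str(u) for u in r2.final_units]
    # every tested effect appears exactly once per screening stage
    impact = r1.trace[r1.trace["stage"] == "impact"]
    assert len(impact) == 10 and impact["effect"].is_unique
    for j in range(1, 8):
        stage = r1.trace[r1.trace["stage"] == f"item_{j}"]
        assert len(stage) == 10 and stage["effect"].is_unique


def test_final_set_reconstructible_from_trace():
    table, design = make_dataset("final_model", n=2500, seed=69)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = run_pipeline(table, design)
    trace = res.trace
    last = trace.groupby("effect").tail(1)
    kept = set(last.loc[last["retained"], "effect"])
    assert kept == {str(e) for e in res.final_effects}


def test_paired_retention_closed_in_final_set():
    table, design = make_dataset("final_model", n=2500, seed=71)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = run_pipeline(table, design)
    effects = {str(e) for e in res.final_effects}
    for e in effects:
        if "race1" in e:
            assert e.replace("race1", "race2") in effects
        if "race2" in e:
            assert e.replace("race2", "race1") in effects


def test_trim_carried_only_family_is_more_permissive():
    """BH over only the carried p-values (all below the screen threshold) keeps
    essentially everything the screens passed; the all-tested family is the
    conservative default."""
    table, design = make_dataset("final_model", n=9360, seed=73)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res_default = run_pipeline(table, design, SelectionConfig())
        res_carried = run_pipeline(table, design, SelectionConfig(trim_family="carried"))
    assert len(res_carried.measurement_effects) >= len(res_default.measurement_effects)
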