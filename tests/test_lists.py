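"""List-experiment endpoint: prevalence estimator, DiD OLS, effect decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from listrct import (ListCellSummary, cell_summaries, prevalence, fit_did,
                     fit_three_arm, linear_combination, effect_decomposition,
                     analyze_lists, SimulationConfig, generate_trial,
                     TrialDataset, ContractError)
from listrct.schema import ARMS

from conftest import cell_dataset, make_record


def _summary(t_mean, c_mean, arm="covideo", idx=1, n=100, var=1.0):
    return ListCellSummary(arm=arm, experiment_index=idx, control_mean=c_mean,
                           treatment_mean=t_mean, control_n=n, treatment_n=n,
                           control_var=var, treatment_var=var)


# -- cell summaries ------------------------------------------------------------

def test_cell_summary_hand_arithmetic():
    ds = cell_dataset({
        ("covideo", "treatment"): [2, 2, 3, 2],
        ("covideo", "control"): [2, 2, 2, 2],
        ("apc", "treatment"): [1], ("apc", "control"): [1],
        ("do_nothing", "treatment"): [1], ("do_nothing", "control"): [1],
    })
    s = cell_summaries(ds, 1)["covideo"]
    assert s.treatment_mean == pytest.approx(2.25)
    assert s.control_mean == pytest.approx(2.00)
    assert (s.treatment_n, s.control_n) == (4, 4)
    assert s.treatment_var == pytest.approx(0.25)  # ddof=1: 3*(0.25²)+0.75² over 3


def test_all_zero_counts_give_zero_means():
    ds = cell_dataset({(a, g): [0, 0] for a in ARMS
                       for g in ("control", "treatment")})
    for s in cell_summaries(ds, 1).values():
        assert s.control_mean == 0.0 and s.treatment_mean == 0.0


def test_empty_cell_named_in_error():
    ds = TrialDataset.from_records(
        [make_record("P1", arm="covideo", list_group="control")])
    with pytest.raises(ContractError, match=r"empty design cell: arm=\w+, list_group=\w+"):
        cell_summaries(ds, 1)


def test_invalid_experiment_index_rejected(six_cell_dataset):
    with pytest.raises(ContractError):
        cell_summaries(six_cell_dataset, 6)


# -- difference-in-means prevalence -------------------------------------------

def test_prevalence_is_hundred_times_mean_difference():
    est = prevalence(_summary(2.25, 2.00))
    assert est.prevalence == pytest.approx(25.0, abs=1e-12)
    est = prevalence(_summary(2.372, 2.2))
    assert est.prevalence == pytest.approx(17.2, abs=1e-10)


def test_equal_means_give_zero_prevalence():
    est = prevalence(_summary(2.0, 2.0))
    assert est.prevalence == 0.0
    assert est.ci_low < 0 < est.ci_high


def test_prevalence_se_from_analytic_variances():
    est = prevalence(_summary(2.5, 2.0, n=400, var=1.21))
    expected_se = 100 * np.sqrt(1.21 / 400 + 1.21 / 400)
    assert est.se == pytest.approx(expected_se, abs=1e-12)
    assert est.ci_high - est.ci_low == pytest.approx(2 * 1.959964 * est.se, abs=1e-3)


def test_negative_prevalence_not_truncated():
    est = prevalence(_summary(1.8, 2.0))
    assert est.prevalence == pytest.approx(-20.0)


# -- DiD OLS -------------------------------------------------------------------

def test_eight_row_fixture_reproduces_cell_means():
    """Saturated 2×2 OLS: b0 = ref-control mean, b0+b1 = comparison-control,
    b0+b2 = ref-treatment, b0+b1+b2+b3 = comparison-treatment."""
    ds = cell_dataset({
        ("do_nothing", "control"): [1, 2],    # mean 1.5
        ("do_nothing", "treatment"): [2, 3],  # mean 2.5
        ("covideo", "control"): [0, 1],       # mean 0.5
        ("covideo", "treatment"): [3, 4],     # mean 3.5
        ("apc", "control"): [1], ("apc", "treatment"): [1],
    })
    fit = fit_did(ds, 1, ("do_nothing", "covideo"))
    b0, b1, b2, b3 = fit.params
    assert b0 == pytest.approx(1.5, abs=1e-10)
    assert b0 + b1 == pytest.approx(0.5, abs=1e-10)
    assert b0 + b2 == pytest.approx(2.5, abs=1e-10)
    assert b0 + b1 + b2 + b3 == pytest.approx(3.5, abs=1e-10)
    assert b3 == pytest.approx((3.5 - 0.5) - (2.5 - 1.5), abs=1e-10)
    assert fit.df_resid == 4


def test_interaction_equals_cell_mean_did_on_random_datasets():
    """Saturated-model identity: b3 equals the cell-mean
    difference-in-difference on any dataset, to 1e-10."""
    rng = np.random.default_rng(7)
    for _ in range(30):
        n = int(rng.integers(2, 120))
        cells = {(a, g): rng.integers(0, 6, size=n)
                 for a in ARMS for g in ("control", "treatment")}
        ds = cell_dataset(cells)
        for cmp_arm in ("apc", "covideo"):
            fit = fit_did(ds, 1, ("do_nothing", cmp_arm))
            s = cell_summaries(ds, 1)
            did = ((s[cmp_arm].treatment_mean - s[cmp_arm].control_mean)
                   - (s["do_nothing"].treatment_mean - s["do_nothing"].control_mean))
            assert fit.params[3] == pytest.approx(did, abs=1e-10)


def test_identical_cell_distributions_give_null_coefficients():
    vals = list(range(6)) * 40
    ds = cell_dataset({(a, g): vals for a in ARMS
                       for g in ("control", "treatment")})
    fit = fit_did(ds, 1, ("do_nothing", "covideo"))
    assert np.allclose(fit.params[1:], 0.0, atol=1e-10)


def test_empty_design_cell_rejected():
    ds = cell_dataset({
        ("do_nothing", "control"): [1, 2], ("do_nothing", "treatment"): [2, 3],
        ("covideo", "control"): [0, 1],
        ("apc", "control"): [1], ("apc", "treatment"): [1],
    })
    with pytest.raises(ContractError):
        fit_did(ds, 1, ("do_nothing", "covideo"))


# -- linear combinations -------------------------------------------------------

@pytest.fixture(scope="module")
def small_did_fit():
    ds = generate_trial(SimulationConfig(n_per_cell=250, seed=300,
                                         attrition_rate=0.0))
    return ds, fit_did(ds, 1, ("do_nothing", "covideo"))


def test_unit_weight_reproduces_interaction(small_did_fit):
    _, fit = small_did_fit
    lc = linear_combination(fit, [0, 0, 0, 1])
    assert lc.estimate == pytest.approx(fit.params[3], abs=1e-14)
    assert lc.se == pytest.approx(np.sqrt(fit.cov[3, 3]), abs=1e-14)


def test_zero_weights_give_zero_estimate_and_se(small_did_fit):
    _, fit = small_did_fit
    lc = linear_combination(fit, [0, 0, 0, 0])
    assert lc.estimate == 0.0 and lc.se == 0.0
    assert np.isnan(lc.p_value)


def test_dimension_mismatch_rejected(small_did_fit):
    _, fit = small_did_fit
    with pytest.raises(ContractError):
        linear_combination(fit, [0, 0, 1])


def test_classical_se_agrees_with_bootstrap(small_did_fit):
    """SE of b2+b3 (the comparison-arm treatment-list effect) checked against
    a nonparametric bootstrap; agreement within 10%."""
    ds, fit = small_did_fit
    lc = linear_combination(fit, [0, 0, 1, 1])
    rng = np.random.default_rng(301)
    frame = ds.frame[ds.frame["arm"].isin(["do_nothing", "covideo"])]
    boot = []
    for _ in range(1000):
        resampled = frame.sample(n=len(frame), replace=True, random_state=rng)
        sub = TrialDataset(resampled.assign(
            participant_id=[f"B{i}" for i in range(len(resampled))]))
        bfit = fit_did(sub, 1, ("do_nothing", "covideo"))
        boot.append(bfit.params[2] + bfit.params[3])
    boot_se = np.std(boot, ddof=1)
    assert lc.se == pytest.approx(boot_se, rel=0.10)


# -- effect decomposition ------------------------------------------------------

def test_content_effect_from_reported_prevalences():
    """Prevalences 17.2 (intervention) and 29.4 (APC) imply a content effect
    of −12.2 percentage points (−0.122 on the proportion scale); the joint
    fit reproduces exactly this arithmetic on data with those cell means."""
    assert (17.2 - 29.4) / 100 == pytest.approx(-0.122, abs=1e-12)
    # counts engineered so (T̄ − C̄) is 0.172 (intervention) and 0.294 (APC):
    # 1000 participants per cell, sensitive item endorsed by 172 / 294 / 217
    base = [2] * 1000
    ds = cell_dataset({
        ("do_nothing", "control"): base,
        ("do_nothing", "treatment"): [3] * 217 + [2] * 783,
        ("apc", "control"): base,
        ("apc", "treatment"): [3] * 294 + [2] * 706,
        ("covideo", "control"): base,
        ("covideo", "treatment"): [3] * 172 + [2] * 828,
    })
    effects = effect_decomposition(ds, 1)
    assert effects["content"].estimate == pytest.approx(-0.122, abs=1e-10)
    assert effects["total"].estimate == pytest.approx(-0.045, abs=1e-10)
    assert effects["content"].estimate == pytest.approx(
        effects["total"].estimate - effects["attention"].estimate, abs=1e-12)


def test_decomposition_matches_prevalence_differences():
    ds = generate_trial(SimulationConfig(n_per_cell=500, seed=302,
                                         attrition_rate=0.0))
    for i in (1, 4):
        s = cell_summaries(ds, i)
        prev = {a: prevalence(s[a]).prevalence for a in ARMS}
        effects = effect_decomposition(ds, i)
        assert effects["total"].estimate * 100 == pytest.approx(
            prev["covideo"] - prev["do_nothing"], abs=1e-8)
        assert effects["attention"].estimate * 100 == pytest.approx(
            prev["apc"] - prev["do_nothing"], abs=1e-8)
        assert effects["content"].estimate * 100 == pytest.approx(
            prev["covideo"] - prev["apc"], abs=1e-8)


def test_pairwise_fits_agree_with_joint_fit():
    ds = generate_trial(SimulationConfig(n_per_cell=300, seed=303,
                                         attrition_rate=0.0))
    joint = fit_three_arm(ds, 2)
    for arm, coef_idx in (("apc", 4), ("covideo", 5)):
        pairwise = fit_did(ds, 2, ("do_nothing", arm))
        assert pairwise.params[3] == pytest.approx(joint.params[coef_idx],
                                                   abs=1e-10)


def test_equal_prevalences_give_null_effects():
    prev = np.full((3, 5), 0.4)
    ds = generate_trial(SimulationConfig(n_per_cell=4000, seed=304,
                                         attrition_rate=0.0,
                                         sensitive_prevalence=prev))
    effects = effect_decomposition(ds, 3)
    for eff in effects.values():
        assert abs(eff.estimate) < 3 * eff.se


def test_analyze_lists_covers_all_experiments():
    ds = generate_trial(SimulationConfig(n_per_cell=300, seed=305))
    out = analyze_lists(ds)
    assert set(out.prevalences) == {1, 2, 3, 4, 5}
    for i, by_arm in out.prevalences.items():
        assert set(by_arm) == set(ARMS)
        for est in by_arm.values():
            assert est.ci_low <= est.prevalence <= est.ci_high
        total = out.effects[i]["total"].estimate
        assert out.effects[i]["content"].estimate + \
            out.effects[i]["attention"].estimate == pytest.approx(total, abs=1e-12)
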