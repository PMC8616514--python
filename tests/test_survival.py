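"""Cox modeling stage: fits, screening, elimination, comparison, stratification."""

import numpy as np
import pandas as pd
import pytest

from wltb import survival as surv
from wltb.estimators import (
    BackwardEliminationCox,
    CoxPHModel,
    MedianRiskStratifier,
    UnivariableCoxScreen,
)
from wltb.phantom import SurvivalSimConfig, simulate_clinical, simulate_survival


def make_cohort(n, beta, seed, censor_rate=0.1, extra_features=None):
    """Simulated feature table + survival with known log-hazard structure."""
    rng = np.random.default_rng(seed)
    table = pd.DataFrame({name: rng.normal(size=n) for name in beta} if beta else {})
    if extra_features:
        for name in extra_features:
            table[name] = rng.normal(size=n)
    if table.empty:
        table = pd.DataFrame(index=range(n))
    out = simulate_survival(table, SurvivalSimConfig(beta=beta, censor_rate=censor_rate, seed=seed))
    return table, out["time_months"].values, out["event"].values


# ---------------------------------------------------------------------------
# fit_cox
# ---------------------------------------------------------------------------

def test_null_effect_hr_near_one():
    x, t, e = make_cohort(800, {}, seed=0, extra_features=["noise"])
    res = surv.fit_cox(x[["noise"]], t, e)
    assert abs(res.summary.loc["noise", "coef"]) < 0.1
    assert res.summary.loc["noise", "hr"] == pytest.approx(1.0, abs=0.1)


def test_known_coefficient_recovered():
    x, t, e = make_cohort(500, {"f": 0.5}, seed=3)
    xs = (x - x.mean()) / x.std()
    res = surv.fit_cox(xs, t, e)
    assert res.summary.loc["f", "coef"] == pytest.approx(0.5, abs=0.1)
    # result invariants
    assert res.summary.loc["f", "hr"] == pytest.approx(np.exp(res.summary.loc["f", "coef"]))
    assert res.aic == pytest.approx(2 * 1 - 2 * res.log_partial_likelihood)
    assert 0 <= res.c_index <= 1


def test_perfectly_concordant_score_has_c_index_one():
    n = 60
    t = np.linspace(1, 60, n)
    x = pd.DataFrame({"risk": -t + 0.0})  # higher risk -> earlier death, no ties
    res = surv.fit_cox(x, t, np.ones(n, int))
    assert res.c_index == pytest.approx(1.0)


def test_constant_covariate_rejected():
    x = pd.DataFrame({"c": np.ones(50)})
    with pytest.raises(ValueError, match="constant"):
        surv.fit_cox(x, np.arange(1, 51), np.ones(50, int))


def test_too_few_events_rejected():
    x = pd.DataFrame({"a": np.random.default_rng(0).normal(size=20)})
    with pytest.raises(ValueError, match="events"):
        surv.fit_cox(x, np.arange(1, 21), np.zeros(20, int))


def test_permuting_subjects_changes_nothing():
    x, t, e = make_cohort(200, {"f": 0.4}, seed=5)
    res1 = surv.fit_cox(x, t, e)
    perm = np.random.default_rng(1).permutation(len(x))
    res2 = surv.fit_cox(x.iloc[perm].reset_index(drop=True), t[perm], e[perm])
    assert res1.summary.loc["f", "coef"] == pytest.approx(res2.summary.loc["f", "coef"], rel=1e-8)
    assert res1.c_index == pytest.approx(res2.c_index, rel=1e-12)


# ---------------------------------------------------------------------------
# univariable screen
# ---------------------------------------------------------------------------

def test_duplicated_feature_screens_identically():
    x, t, e = make_cohort(150, {"f": 0.5}, seed=7)
    x = x.assign(f_copy=x["f"])
    candidates, report = surv.univariable_screen(x, t, e)
    assert report.loc["f", "wald_p"] == pytest.approx(report.loc["f_copy", "wald_p"])
    assert ("f" in candidates) == ("f_copy" in candidates)


def test_screen_reports_all_features_and_flags_candidates():
    x, t, e = make_cohort(250, {"strong": 0.8}, seed=8, extra_features=["junk"])
    candidates, report = surv.univariable_screen(x, t, e)
    assert set(report.index) == {"strong", "junk"}
    assert "strong" in candidates
    assert report.loc["strong", "candidate"]


def test_screen_excludes_failing_feature_without_crash():
    x, t, e = make_cohort(100, {"f": 0.5}, seed=9)
    x = x.assign(constant=1.0)
    candidates, report = surv.univariable_screen(x, t, e)
    assert "constant" not in report.index
    assert "f" in report.index


# ---------------------------------------------------------------------------
# clinical baseline designs
# ---------------------------------------------------------------------------

def test_haas_design_log_identities():
    clin = pd.DataFrame(
        {
            "ecog": [0, 2],
            "crp_mg_dl": [np.e**2, 1.0],
            "bilirubin_mg_dl": [np.e, 1.0],
        }
    )
    d = surv.haas_design(clin)
    assert d.loc[0, "ecog_1plus"] == 0.0
    assert d.loc[1, "ecog_1plus"] == 1.0  # ECOG 2 pools into >= 1
    assert d.loc[0, "log_crp"] == pytest.approx(2.0)
    assert d.loc[0, "log_bilirubin"] == pytest.approx(1.0)


def test_haas_nonpositive_labs_clipped_not_crashed():
    clin = pd.DataFrame({"ecog": [0, 1], "crp_mg_dl": [0.0, 1.0], "bilirubin_mg_dl": [0.5, -1.0]})
    d = surv.haas_design(clin)
    assert np.isfinite(d.values).all()


def test_xue_design_boundaries():
    clin = pd.DataFrame(
        {
            "ecog": [1, 2],
            "ca19_9_u_ml": [1000.0, 999.9],
            "crp_mg_dl": [5.0, 4.9],
        }
    )
    d = surv.xue_design(clin)
    assert d.loc[0, "ecog_2plus"] == 0.0  # ECOG 1 is low-risk in this model
    assert d.loc[1, "ecog_2plus"] == 1.0
    assert d.loc[0, "ca19_9_ge_1000"] == 1.0  # threshold is inclusive
    assert d.loc[1, "ca19_9_ge_1000"] == 0.0
    assert d.loc[0, "crp_ge_threshold"] == 1.0
    assert d.loc[1, "crp_ge_threshold"] == 0.0


def test_degenerate_all_zero_indicators_flagged():
    clin = simulate_clinical(60, seed=1).assign(ecog=0, ca19_9_u_ml=1.0, crp_mg_dl=0.1)
    t = np.arange(1.0, 61.0)
    with pytest.raises(ValueError, match="constant"):
        surv.baseline_model_xue(clin, t, np.ones(60, int))


def test_baseline_haas_recovers_log_crp_effect():
    """Hazard driven only by ln(CRP): the fitted coefficient recovers it."""
    clin = simulate_clinical(500, seed=4)
    clin["log_crp"] = np.log(clin["crp_mg_dl"].clip(lower=0.01))
    sd = clin["log_crp"].std()
    out = simulate_survival(clin, SurvivalSimConfig(beta={"log_crp": 0.4 * sd}, censor_rate=0.05, seed=4))
    res = surv.baseline_model_haas(clin, out["time_months"], out["event"])
    assert res.summary.loc["log_crp", "coef"] == pytest.approx(0.4, abs=0.1)


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

def test_zero_candidates_returns_baseline_identically():
    x, t, e = make_cohort(150, {"a": 0.5, "b": 0.3}, seed=11)
    baseline_fit = surv.fit_cox(x, t, e)
    fit, trace, design = surv.extend_model(x, pd.DataFrame(index=x.index), t, e)
    assert trace.empty
    assert fit.terms == baseline_fit.terms
    assert fit.log_partial_likelihood == pytest.approx(baseline_fit.log_partial_likelihood)
    assert list(design.columns) == list(x.columns)


def test_pure_noise_candidate_elimination_follows_aic_rule():
    """A single null candidate is removed exactly when its LR gain is < 2.

    The 2-unit AIC penalty dominates the null deviance in most cohorts
    (P(chi2_1 < 2) ~ 0.84), so over seeds the noise feature is usually
    dropped; per seed the removal decision must coincide with the LR rule.
    """
    removed = 0
    for seed in range(12):
        x, t, e = make_cohort(400, {"signal": 0.6}, seed=seed, extra_features=["noise"])
        full = surv.fit_cox(x[["signal", "noise"]], t, e)
        reduced = surv.fit_cox(x[["signal"]], t, e)
        lr = 2 * (full.log_partial_likelihood - reduced.log_partial_likelihood)
        fit, trace, _ = surv.extend_model(x[["signal"]], x[["noise"]], t, e)
        assert ("noise" not in fit.terms) == (lr < 2.0)
        if "noise" not in fit.terms:
            removed += 1
            assert (trace["aic_after"] < trace["aic_before"]).all()
    assert removed >= 7  # AIC drops the null feature in the clear majority


def test_forced_terms_never_removed_even_if_null():
    x, t, e = make_cohort(300, {"signal": 0.6}, seed=13, extra_features=["forced_null", "junk"])
    fit, _, _ = surv.extend_model(x[["forced_null"]], x[["signal", "junk"]], t, e)
    assert "forced_null" in fit.terms
    assert "signal" in fit.terms


def test_elimination_is_locally_aic_optimal():
    """Final AIC <= start AIC and <= AIC after removing any retained candidate."""
    x, t, e = make_cohort(250, {"a": 0.5, "b": 0.4}, seed=14, extra_features=["n1", "n2"])
    baseline = x[["a"]]
    cands = x[["b", "n1", "n2"]]
    start = surv.fit_cox(pd.concat([baseline, cands], axis=1), t, e)
    fit, _, design = surv.extend_model(baseline, cands, t, e)
    assert fit.aic <= start.aic + 1e-9
    retained = [c for c in design.columns if c != "a"]
    for c in retained:
        reduced = surv.fit_cox(design.drop(columns=[c]), t, e)
        assert fit.aic <= reduced.aic + 1e-9


def test_candidate_overlapping_baseline_rejected():
    x, t, e = make_cohort(100, {"a": 0.5}, seed=15)
    with pytest.raises(ValueError, match="duplicate"):
        surv.extend_model(x[["a"]], x[["a"]], t, e)


# ---------------------------------------------------------------------------
# nested comparison
# ---------------------------------------------------------------------------

def test_identical_models_lr_zero_p_one():
    x, t, e = make_cohort(150, {"a": 0.5}, seed=16)
    fit = surv.fit_cox(x, t, e)
    cmp = surv.compare_nested(fit, fit)
    assert cmp.lr_statistic == pytest.approx(0.0, abs=1e-9)
    assert cmp.p_value == 1.0
    assert cmp.df == 0


def test_non_nested_models_hard_error():
    x, t, e = make_cohort(150, {"a": 0.5, "b": 0.4}, seed=17)
    fit_a = surv.fit_cox(x[["a"]], t, e)
    fit_b = surv.fit_cox(x[["b"]], t, e)
    with pytest.raises(ValueError, match="not nested"):
        surv.compare_nested(fit_a, fit_b)


def test_strong_added_effect_detected_with_small_p():
    x, t, e = make_cohort(500, {"clin": 0.3, "img": 0.8}, seed=18)
    base = surv.fit_cox(x[["clin"]], t, e)
    ext = surv.fit_cox(x, t, e)
    cmp = surv.compare_nested(base, ext)
    assert cmp.df == 1
    assert cmp.p_value < 0.003
    assert cmp.extended_c_index > cmp.baseline_c_index


# ---------------------------------------------------------------------------
# risk stratification
# ---------------------------------------------------------------------------

def test_two_group_exponential_km_medians():
    """Exponential hazards lam vs 2*lam, no censoring: KM medians ~ ln2/lam."""
    lam = 0.08
    rng = np.random.default_rng(19)
    n = 500
    grp = np.repeat([0.0, 1.0], n // 2)
    t = np.where(grp == 1, rng.exponential(1 / (2 * lam), n), rng.exponential(1 / lam, n))
    e = np.ones(n, int)
    x = pd.DataFrame({"grp": grp})
    fit = surv.fit_cox(x, t, e)
    strat = surv.stratify_risk(fit, x, t, e)
    assert strat.logrank_p < 1e-6
    assert strat.median_survival_months["low"] == pytest.approx(np.log(2) / lam, rel=0.15)
    assert strat.median_survival_months["high"] == pytest.approx(np.log(2) / (2 * lam), rel=0.15)
    # the high-risk group is the one dying faster
    assert strat.median_survival_months["high"] < strat.median_survival_months["low"]


def test_non_informative_risk_score_errors():
    x, t, e = make_cohort(100, {"a": 0.5}, seed=20)
    fit = surv.fit_cox(x, t, e)
    constant = pd.DataFrame({"a": np.zeros(len(x))})
    with pytest.raises(ValueError, match="non-informative"):
        surv.stratify_risk(fit, constant, t, e)


def test_median_survival_split_mode_runs():
    x, t, e = make_cohort(300, {"a": 0.8}, seed=22, censor_rate=0.05)
    fit = surv.fit_cox(x, t, e)
    strat = surv.stratify_risk(fit, x, t, e, split="median_survival")
    assert set(strat.group_assignment.unique()) == {"high", "low"}
    assert strat.logrank_p < 0.05


# ---------------------------------------------------------------------------
# correlation report
# ---------------------------------------------------------------------------

def test_correlation_self_and_monotone_transform():
    rng = np.random.default_rng(23)
    table = pd.DataFrame({"f": rng.normal(size=75)})
    table["g"] = np.exp(table["f"])  # monotone transform: Spearman rho = 1
    table["h"] = rng.normal(size=75)
    rep = surv.correlation_report(table, method="spearman")
    assert rep.matrix.loc["f", "f"] == pytest.approx(1.0)
    assert rep.matrix.loc["f", "g"] == pytest.approx(1.0)
    assert abs(rep.matrix.loc["f", "h"]) < 0.4
    assert sorted(rep.leaf_order) == ["f", "g", "h"]
    # monotone pair clusters together
    i, j = rep.leaf_order.index("f"), rep.leaf_order.index("g")
    assert abs(i - j) == 1


def test_correlation_constant_column_masked():
    table = pd.DataFrame(
        {"a": np.arange(10.0), "b": np.ones(10), "c": np.arange(10.0) ** 2}
    )
    rep = surv.correlation_report(table)
    assert np.isnan(rep.matrix.loc["a", "b"])
    assert rep.matrix.loc["b", "b"] == 1.0


def test_pearson_option():
    rng = np.random.default_rng(24)
    table = pd.DataFrame({"a": rng.normal(size=50)})
    table["b"] = 2 * table["a"] + 1
    rep = surv.correlation_report(table, method="pearson")
    assert rep.matrix.loc["a", "b"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# sklearn estimator wrappers
# ---------------------------------------------------------------------------

def test_estimators_follow_sklearn_conventions():
    from sklearn.base import clone

    x, t, e = make_cohort(200, {"f": 0.6}, seed=25, extra_features=["g"])
    y = pd.DataFrame({"time_months": t, "event": e})
    model = CoxPHModel().fit(x, y)
    assert hasattr(model, "result_")
    assert model.predict(x).shape == (200,)
    assert 0.5 < model.score(x, y) <= 1.0

    screen = UnivariableCoxScreen(alpha=0.2)
    assert clone(screen).get_params()["alpha"] == 0.2
    screen.fit(x, y)
    assert "f" in screen.candidates_
    assert list(screen.transform(x).columns) == screen.candidates_

    strat = MedianRiskStratifier().fit(x, y)
    assert set(strat.groups_.unique()) == {"high", "low"}
    preds = strat.predict(x)
    assert set(preds) <= {"high", "low"}


def test_backward_elimination_estimator_nesting():
    x, t, e = make_cohort(300, {"clin": 0.4, "img": 0.6}, seed=26, extra_features=["noise"])
    y = (t, e)
    est = BackwardEliminationCox(forced=["clin"]).fit(x, y)
    assert "clin" in est.result_.terms
    cmp = est.compare_to_baseline()
    assert cmp.df == len(est.result_.terms) - 1
    assert cmp.p_value <= 1.0
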