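"""Cox survival modeling: screening, baseline models, AIC selection, risk groups.

Implements the statistical stage of the biomarker pipeline:

* univariable Cox proportional-hazards (CPH) screening of imaging features
  with a liberal Wald threshold (p < 0.2) to nominate candidates;
* two established clinical baseline models for metastatic pancreatic
  cancer — a three-term model on ECOG (0 vs >=1), log CRP and log bilirubin,
  and a three-indicator model on ECOG >= 2, CA 19-9 >= 1000 U/ml and an
  elevated-CRP threshold;
* extension of a baseline by screened imaging candidates with backward
  elimination on the Akaike information criterion (AIC), keeping every
  clinical term so the models stay nested;
* nested model comparison by likelihood-ratio test, Harrell's C-index;
* risk stratification by median split of the linear predictor, with
  Kaplan-Meier curves and the log-rank test;
* a rank-correlation report (heatmap ordering by hierarchical clustering).

Fitting is delegated to ``lifelines`` (Efron tie handling); this module owns
model construction, selection and comparison logic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

__all__ = [
    "CoxFitResult",
    "ModelComparison",
    "RiskStratification",
    "CoxNotConvergedError",
    "fit_cox",
    "univariable_screen",
    "haas_design",
    "xue_design",
    "baseline_model_haas",
    "baseline_model_xue",
    "extend_model",
    "compare_nested",
    "stratify_risk",
    "correlation_report",
]


class CoxNotConvergedError(RuntimeError):
    """Partial-likelihood maximisation failed (carries the lifelines trace)."""


@dataclass
class CoxFitResult:
    """Summary of one Cox proportional-hazards fit.

    ``summary`` is indexed by term name with columns coef, se, hr,
    hr_ci_lower, hr_ci_upper, wald_p.  ``aic`` is the partial-likelihood AIC
    2k - 2*log PL; ``c_index`` is Harrell's concordance over usable pairs.
    """

    summary: pd.DataFrame
    log_partial_likelihood: float
    aic: float
    c_index: float
    n: int
    n_events: int
    warnings_: list[str] = field(default_factory=list)

    @property
    def terms(self) -> list[str]:
        return list(self.summary.index)

    def coefficients(self) -> pd.Series:
        return self.summary["coef"]


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of two nested Cox models."""

    lr_statistic: float
    df: int
    p_value: float
    baseline_c_index: float
    extended_c_index: float


@dataclass
class RiskStratification:
    """Median-split risk groups with Kaplan-Meier summaries."""

    group_assignment: pd.Series  # "high" / "low" per subject
    threshold: float
    km_high: KaplanMeierFitter
    km_low: KaplanMeierFitter
    logrank_p: float
    median_survival_months: dict[str, float]


def _validate_inputs(X: pd.DataFrame, time, event) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    X = pd.DataFrame(X).astype(float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(X) != len(time) or len(X) != len(event):
        raise ValueError("covariates, time and event must have equal length")
    if np.any(time < 0):
        raise ValueError("survival times must be non-negative")
    if event.sum() < 2:
        raise ValueError(f"need at least 2 events, got {int(event.sum())}")
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValueError(f"constant covariate {col!r} cannot enter a Cox model")
        if not np.all(np.isfinite(X[col])):
            raise ValueError(f"non-finite values in covariate {col!r}")
    return X, time, event


def fit_cox(X: pd.DataFrame, time, event) -> CoxFitResult:
    """Maximum-partial-likelihood Cox fit with Efron tie handling.

    Raises :class:`CoxNotConvergedError` on non-convergence; convergence
    warnings (e.g. hints of complete separation) are collected on the result
    rather than silently dropped.
    """
    X, time, event = _validate_inputs(X, time, event)
    df = X.copy()
    df["_time"] = time
    df["_event"] = event
    fitter = CoxPHFitter()
    collected: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fitter.fit(df, duration_col="_time", event_col="_event")
        except ConvergenceError as exc:
            raise CoxNotConvergedError(f"Cox fit did not converge: {exc}") from exc
        for w in caught:
            if "convergence" in str(w.message).lower() or "separation" in str(w.message).lower():
                collected.append(str(w.message))
    s = fitter.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "hr_ci_lower": s["exp(coef) lower 95%"],
            "hr_ci_upper": s["exp(coef) upper 95%"],
            "wald_p": s["p"],
        }
    )
    summary.index.name = "term"
    ll = float(fitter.log_likelihood_)
    return CoxFitResult(
        summary=summary,
        log_partial_likelihood=ll,
        aic=2.0 * len(summary) - 2.0 * ll,
        c_index=float(fitter.concordance_index_),
        n=len(df),
        n_events=int(event.sum()),
        warnings_=collected,
    )


def univariable_screen(
    feature_table: pd.DataFrame, time, event, alpha: float = 0.2
) -> tuple[list[str], pd.DataFrame]:
    """One unadjusted Cox fit per feature; keep those with Wald p < ``alpha``.

    Returns the candidate list and a per-feature report (HR, CI, p) in the
    style of a univariable biomarker table.  A feature whose fit fails is
    excluded with a logged warning, never a crash.
    """
    rows = []
    candidates: list[str] = []
    for name in feature_table.columns:
        try:
            res = fit_cox(feature_table[[name]], time, event)
        except (ValueError, CoxNotConvergedError) as exc:
            log.warning("univariable screen: feature %r excluded (%s)", name, exc)
            continue
        term = res.summary.iloc[0]
        passed = bool(term["wald_p"] < alpha)
        rows.append(
            {
                "feature": name,
                "hr": term["hr"],
                "hr_ci_lower": term["hr_ci_lower"],
                "hr_ci_upper": term["hr_ci_upper"],
                "wald_p": term["wald_p"],
                "candidate": passed,
            }
        )
        if passed:
            candidates.append(name)
    report = pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame()
    return candidates, report


# ---------------------------------------------------------------------------
# clinical baseline models
# ---------------------------------------------------------------------------

_EPS_LOG = 0.01  # mg/dl offset for nonpositive lab values entering a log


def haas_design(clinical: pd.DataFrame) -> pd.DataFrame:
    """Design matrix of the ECOG / log(CRP) / log(bilirubin) baseline model.

    ECOG is dichotomized 0 vs >= 1; CRP and bilirubin (mg/dl) enter on the
    natural-log scale.  Nonpositive lab values are clipped to a small
    positive offset and logged.
    """
    crp = clinical["crp_mg_dl"].astype(float)
    bili = clinical["bilirubin_mg_dl"].astype(float)
    n_clipped = int((crp <= 0).sum() + (bili <= 0).sum())
    if n_clipped:
        log.warning("haas design: %d nonpositive lab value(s) clipped to %.2g", n_clipped, _EPS_LOG)
    return pd.DataFrame(
        {
            "ecog_1plus": (clinical["ecog"].astype(int) >= 1).astype(float),
            "log_crp": np.log(crp.clip(lower=_EPS_LOG)),
            "log_bilirubin": np.log(bili.clip(lower=_EPS_LOG)),
        },
        index=clinical.index,
    )


def xue_design(clinical: pd.DataFrame, crp_threshold_mg_dl: float = 5.0) -> pd.DataFrame:
    """Design matrix of the three-indicator prognostic-index baseline model.

    Indicators: ECOG >= 2; CA 19-9 >= 1000 U/ml (inclusive); CRP at or above
    ``crp_threshold_mg_dl`` (the published threshold is quoted as 5 —
    stored here in mg/dl and configurable because sources disagree on the
    unit).
    """
    return pd.DataFrame(
        {
            "ecog_2plus": (clinical["ecog"].astype(int) >= 2).astype(float),
            "ca19_9_ge_1000": (clinical["ca19_9_u_ml"].astype(float) >= 1000.0).astype(float),
            "crp_ge_threshold": (clinical["crp_mg_dl"].astype(float) >= crp_threshold_mg_dl).astype(float),
        },
        index=clinical.index,
    )


def baseline_model_haas(clinical: pd.DataFrame, time=None, event=None) -> CoxFitResult:
    """Fit the Haas-style clinical baseline Cox model."""
    if time is None:
        time = clinical["time_months"]
    if event is None:
        event = clinical["event"]
    return fit_cox(haas_design(clinical), time, event)


def baseline_model_xue(
    clinical: pd.DataFrame, time=None, event=None, crp_threshold_mg_dl: float = 5.0
) -> CoxFitResult:
    """Fit the Xue-style clinical baseline Cox model."""
    if time is None:
        time = clinical["time_months"]
    if event is None:
        event = clinical["event"]
    return fit_cox(xue_design(clinical, crp_threshold_mg_dl), time, event)


# ---------------------------------------------------------------------------
# model extension by AIC backward elimination
# ---------------------------------------------------------------------------

def extend_model(
    baseline_X: pd.DataFrame,
    candidate_X: pd.DataFrame,
    time,
    event,
) -> tuple[CoxFitResult, pd.DataFrame, pd.DataFrame]:
    """Extend a clinical baseline with imaging candidates, pruned by AIC.

    Starts from baseline + all candidates and repeatedly removes the single
    candidate whose removal most decreases the AIC, stopping when no removal
    decreases it.  Clinical (baseline) terms are never removed, so the final
    model stays nested above the baseline.  Ties in AIC are broken by
    removing the candidate with the larger Wald p in the current model.

    Returns ``(final_fit, trace, final_design)`` where ``trace`` records one
    row per elimination step (feature removed, AIC before/after).
    """
    baseline_X = pd.DataFrame(baseline_X)
    candidate_X = pd.DataFrame(candidate_X)
    overlap = set(baseline_X.columns) & set(candidate_X.columns)
    if overlap:
        raise ValueError(f"candidates duplicate baseline terms: {sorted(overlap)}")
    current = list(candidate_X.columns)
    trace_rows: list[dict] = []

    def design(cands: list[str]) -> pd.DataFrame:
        return pd.concat([baseline_X, candidate_X[cands]], axis=1)

    if not current:
        fit = fit_cox(baseline_X, time, event)
        return fit, pd.DataFrame(trace_rows), baseline_X

    def try_fit(cands: list[str]) -> CoxFitResult | None:
        try:
            return fit_cox(design(cands), time, event)
        except (ValueError, CoxNotConvergedError) as exc:
            log.debug("backward elimination: fit with %d candidate(s) failed (%s)", len(cands), exc)
            return None

    # the full starting model can be unfittable at small n (collinear or
    # separating candidates); shed candidates until a model converges
    current_fit = try_fit(current)
    if current_fit is None:
        log.warning(
            "backward elimination: full starting model with %d candidate(s) is unfittable "
            "(collinear or separating); shedding candidates until a model converges",
            len(current),
        )
    while current_fit is None and current:
        best_name, best_fit = None, None
        for name in current:
            fit = try_fit([c for c in current if c != name])
            if fit is not None and (best_fit is None or fit.aic < best_fit.aic):
                best_name, best_fit = name, fit
        if best_fit is None:
            dropped = current.pop()
            trace_rows.append({"removed": dropped, "aic_before": np.nan, "aic_after": np.nan})
            continue
        trace_rows.append({"removed": best_name, "aic_before": np.nan, "aic_after": best_fit.aic})
        current.remove(best_name)
        current_fit = best_fit
    if current_fit is None:
        fit = fit_cox(baseline_X, time, event)
        return fit, pd.DataFrame(trace_rows), baseline_X

    while current:
        best_name, best_fit = None, None
        for name in current:
            reduced = [c for c in current if c != name]
            try:
                fit = fit_cox(design(reduced), time, event)
            except (ValueError, CoxNotConvergedError) as exc:
                log.warning("backward elimination: removal of %r skipped (%s)", name, exc)
                continue
            if best_fit is None or fit.aic < best_fit.aic - 1e-12:
                best_name, best_fit = name, fit
            elif abs(fit.aic - best_fit.aic) <= 1e-12:
                # AIC tie: prefer dropping the term with the larger Wald p
                p_this = current_fit.summary.loc[name, "wald_p"]
                p_best = current_fit.summary.loc[best_name, "wald_p"]
                if p_this > p_best:
                    best_name, best_fit = name, fit
        if best_fit is None or best_fit.aic >= current_fit.aic:
            break
        trace_rows.append(
            {
                "removed": best_name,
                "aic_before": current_fit.aic,
                "aic_after": best_fit.aic,
            }
        )
        current.remove(best_name)
        current_fit = best_fit
    return current_fit, pd.DataFrame(trace_rows), design(current)


def compare_nested(baseline: CoxFitResult, extended: CoxFitResult) -> ModelComparison:
    """Likelihood-ratio test of nested Cox models: LR = 2(l_ext - l_base).

    Refuses non-nested inputs (baseline terms must be a subset of extended
    terms, fitted on the same subjects).
    """
    if not set(baseline.terms) <= set(extended.terms):
        raise ValueError(
            "models are not nested: baseline terms "
            f"{sorted(set(baseline.terms) - set(extended.terms))} missing from the extended model"
        )
    if baseline.n != extended.n or baseline.n_events != extended.n_events:
        raise ValueError("nested comparison requires identical subjects and events")
    df = len(extended.terms) - len(baseline.terms)
    lr = 2.0 * (extended.log_partial_likelihood - baseline.log_partial_likelihood)
    lr = max(lr, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(lr, df))
    return ModelComparison(
        lr_statistic=lr,
        df=df,
        p_value=p,
        baseline_c_index=baseline.c_index,
        extended_c_index=extended.c_index,
    )


def stratify_risk(
    fit: CoxFitResult, X: pd.DataFrame, time, event, split: str = "linear_predictor"
) -> RiskStratification:
    """Median-split risk groups from a fitted Cox model, with KM and log-rank.

    ``split='linear_predictor'`` (default) thresholds the per-subject linear
    predictor at its median, giving two equal-sized groups.  The alternative
    ``split='median_survival'`` classifies each subject by whether their
    predicted survival curve (cohort Kaplan-Meier raised to exp of the
    centred linear predictor) stays above 0.5 at the cohort's median
    survival time — group sizes are then data-driven rather than equal.
    """
    X = pd.DataFrame(X).astype(float)
    missing = set(fit.terms) - set(X.columns)
    if missing:
        raise ValueError(f"covariate table lacks fitted terms: {sorted(missing)}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lp = X[fit.terms].values @ fit.coefficients().values
    if np.ptp(lp) == 0:
        raise ValueError("non-informative risk score: identical linear predictor for all subjects")
    if split == "linear_predictor":
        threshold = float(np.median(lp))
        high = lp > threshold
    elif split == "median_survival":
        km_all = KaplanMeierFitter().fit(time, event)
        cohort_median = float(km_all.median_survival_time_)
        if not np.isfinite(cohort_median):
            raise ValueError("cohort KM median undefined; cannot split by median survival")
        s0 = float(km_all.predict(cohort_median))
        # predicted S(t | x) ~= S_km(t) ^ exp(lp - mean lp); high risk if it
        # has already fallen below 0.5 at the cohort median survival time
        surv_at_median = s0 ** np.exp(lp - lp.mean())
        threshold = 0.5
        high = surv_at_median < threshold
    else:
        raise ValueError(f"unknown split mode {split!r}")
    low = ~high
    if high.sum() < 2 or low.sum() < 2:
        raise ValueError("median split leaves fewer than 2 subjects in a group")
    km_high = KaplanMeierFitter(label="high risk").fit(time[high], event[high])
    km_low = KaplanMeierFitter(label="low risk").fit(time[low], event[low])
    lr = logrank_test(time[high], time[low], event[high], event[low])
    groups = pd.Series(np.where(high, "high", "low"), index=X.index, name="risk_group")
    return RiskStratification(
        group_assignment=groups,
        threshold=threshold,
        km_high=km_high,
        km_low=km_low,
        logrank_p=float(lr.p_value),
        median_survival_months={
            "high": float(km_high.median_survival_time_),
            "low": float(km_low.median_survival_time_),
        },
    )


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    matrix: pd.DataFrame
    leaf_order: list[str]
    method: str

    def ordered_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[self.leaf_order, self.leaf_order]

    def plot_heatmap(self, path=None):
        """Render the clustered correlation heatmap; save if a path is given."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        mat = self.ordered_matrix()
        fig, ax = plt.subplots(figsize=(0.45 * len(mat) + 2.5,) * 2)
        im = ax.imshow(mat.values, cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_xticks(range(len(mat)), mat.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(mat)), mat.index, fontsize=7)
        fig.colorbar(im, ax=ax, label=f"{self.method} correlation")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def correlation_report(
    table: pd.DataFrame, method: str = "spearman"
) -> CorrelationReport:
    """Pairwise rank (or Pearson) correlations with dendrogram leaf ordering.

    Hierarchical clustering uses average linkage on the distance 1 - |rho|.
    Constant columns have undefined correlations; they are masked (NaN) and
    logged, and enter the clustering at maximal distance.
    """
    if len(table) < 3:
        raise ValueError("correlation report needs at least 3 subjects")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be 'spearman' or 'pearson': {method!r}")
    table = pd.DataFrame(table).astype(float)
    constant = [c for c in table.columns if table[c].nunique() <= 1]
    if constant:
        log.warning("correlation report: constant column(s) masked: %s", constant)
    corr = table.corr(method=method)
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = 1.0
    dist = 1.0 - corr.abs().fillna(0.0).values
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [table.columns[i] for i in hierarchy.leaves_list(linkage)]
    return CorrelationReport(matrix=corr, leaf_order=order, method=method)
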