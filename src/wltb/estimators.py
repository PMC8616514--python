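"""scikit-learn-style estimators wrapping the feature and survival stages.

These classes follow the sklearn conventions (``fit``/``transform``/
``predict``, ``get_params``/``set_params``, fitted attributes with a trailing
underscore) so the pipeline composes with sklearn model selection.  Survival
targets ``y`` are passed as a DataFrame with ``time_months`` and ``event``
columns, a ``(time, event)`` tuple, or a 2-column array.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import survival as surv
from .features import FEATURE_COLUMNS, extract_features
from .radiomics import DiscretizationConfig, WaveletConfig

__all__ = [
    "WLTBFeatureExtractor",
    "CoxPHModel",
    "UnivariableCoxScreen",
    "BackwardEliminationCox",
    "MedianRiskStratifier",
    "split_survival_target",
]


def split_survival_target(y) -> tuple[np.ndarray, np.ndarray]:
    """Normalise a survival target into (time, event) arrays."""
    if isinstance(y, pd.DataFrame):
        return np.asarray(y["time_months"], float), np.asarray(y["event"], int)
    if isinstance(y, tuple) and len(y) == 2:
        return np.asarray(y[0], float), np.asarray(y[1], int)
    arr = np.asarray(y)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0].astype(float), arr[:, 1].astype(int)
    raise ValueError("survival target must provide time and event")


class WLTBFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform (ImageVolume, SegmentationSet) pairs into biomarker rows.

    Stateless per subject; ``fit`` only validates the configuration.

    Parameters mirror the extraction configuration: fixed-bin-width gray-level
    discretization (HU), run-matrix aggregation over the 13 directions,
    wavelet family and sub-band, lesion-diameter convention for the tumor
    burden score, spread convention (voxel union vs centroids) and surface
    method (marching-cubes mesh vs voxel faces).
    """

    def __init__(
        self,
        bin_width: float = 25.0,
        aggregation: str = "merge",
        wavelet: str = "coif1",
        subband: str = "HLH",
        diameter_mode: str = "3d",
        spread_mode: str = "voxels",
        surface_method: str = "mesh",
    ):
        self.bin_width = bin_width
        self.aggregation = aggregation
        self.wavelet = wavelet
        self.subband = subband
        self.diameter_mode = diameter_mode
        self.spread_mode = spread_mode
        self.surface_method = surface_method

    def _configs(self) -> tuple[DiscretizationConfig, WaveletConfig]:
        disc = DiscretizationConfig(bin_width=self.bin_width, aggregation=self.aggregation)
        wcfg = WaveletConfig(family=self.wavelet, subband=self.subband)
        disc.validate()
        wcfg.validate()
        return disc, wcfg

    def fit(self, X=None, y=None):
        self._configs()
        self.feature_names_out_ = list(FEATURE_COLUMNS)
        return self

    def transform(self, X) -> pd.DataFrame:
        """X: iterable of (ImageVolume, SegmentationSet) pairs."""
        check_is_fitted(self, "feature_names_out_")
        disc, wcfg = self._configs()
        rows = [
            extract_features(
                image,
                seg,
                disc=disc,
                wcfg=wcfg,
                diameter_mode=self.diameter_mode,
                spread_mode=self.spread_mode,
                surface_method=self.surface_method,
            )
            for image, seg in X
        ]
        return pd.DataFrame(rows, columns=FEATURE_COLUMNS)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_out_")
        return np.asarray(self.feature_names_out_, dtype=object)


class CoxPHModel(BaseEstimator):
    """Cox proportional-hazards regression (Efron ties, lifelines backend).

    Fitted attributes: ``result_`` (:class:`~wltb.survival.CoxFitResult`),
    ``coef_``, ``feature_names_in_``.  ``predict`` returns the linear
    predictor (log relative hazard); ``score`` returns Harrell's C-index.
    """

    def fit(self, X: pd.DataFrame, y):
        time, event = split_survival_target(y)
        X = pd.DataFrame(X)
        self.result_ = surv.fit_cox(X, time, event)
        self.feature_names_in_ = list(X.columns)
        self.coef_ = self.result_.coefficients().values
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "result_")
        X = pd.DataFrame(X)
        return X[self.result_.terms].values.astype(float) @ self.coef_

    def score(self, X, y) -> float:
        from lifelines.utils import concordance_index

        time, event = split_survival_target(y)
        return float(concordance_index(time, -self.predict(X), event))


class UnivariableCoxScreen(TransformerMixin, BaseEstimator):
    """Screen features by unadjusted Cox Wald tests; keep p < ``alpha``.

    Fitted attributes: ``candidates_`` (selected feature names) and
    ``report_`` (per-feature HR, CI and p, a univariable biomarker table).
    ``transform`` restricts a table to the selected candidates.
    """

    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y):
        time, event = split_survival_target(y)
        self.candidates_, self.report_ = surv.univariable_screen(
            pd.DataFrame(X), time, event, alpha=self.alpha
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "candidates_")
        return pd.DataFrame(X)[self.candidates_]


class BackwardEliminationCox(BaseEstimator):
    """Cox model with AIC backward elimination over non-forced covariates.

    ``forced`` names the clinical columns that are never eliminated (they
    keep the final model nested above the clinical baseline).  Fitted
    attributes: ``result_``, ``trace_`` (one row per removal), ``design_``
    (the final design matrix columns), ``baseline_result_``.
    """

    def __init__(self, forced: list[str] | None = None):
        self.forced = forced

    def fit(self, X: pd.DataFrame, y):
        time, event = split_survival_target(y)
        X = pd.DataFrame(X)
        forced = list(self.forced or [])
        missing = set(forced) - set(X.columns)
        if missing:
            raise ValueError(f"forced columns absent from design: {sorted(missing)}")
        baseline_X = X[forced]
        candidate_X = X[[c for c in X.columns if c not in forced]]
        self.baseline_result_ = surv.fit_cox(baseline_X, time, event) if forced else None
        self.result_, self.trace_, design = surv.extend_model(baseline_X, candidate_X, time, event)
        self.design_columns_ = list(design.columns)
        self.retained_candidates_ = [c for c in self.design_columns_ if c not in forced]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "result_")
        X = pd.DataFrame(X)
        return X[self.result_.terms].values.astype(float) @ self.result_.coefficients().values

    def compare_to_baseline(self) -> surv.ModelComparison:
        check_is_fitted(self, "result_")
        if self.baseline_result_ is None:
            raise ValueError("no forced baseline terms; nothing to compare against")
        return surv.compare_nested(self.baseline_result_, self.result_)


class MedianRiskStratifier(BaseEstimator):
    """Median-split risk groups from a Cox linear predictor.

    Fits the supplied Cox estimator (default :class:`CoxPHModel`) and splits
    subjects at the median of the resulting risk score.  Fitted attributes:
    ``stratification_`` (KM curves, log-rank p, medians), ``groups_``.
    """

    def __init__(self, estimator=None, split: str = "linear_predictor"):
        self.estimator = estimator
        self.split = split

    def fit(self, X: pd.DataFrame, y):
        from sklearn.base import clone

        time, event = split_survival_target(y)
        X = pd.DataFrame(X)
        est = clone(self.estimator) if self.estimator is not None else CoxPHModel()
        est.fit(X, y)
        self.estimator_ = est
        self.stratification_ = surv.stratify_risk(est.result_, X, time, event, split=self.split)
        self.groups_ = self.stratification_.group_assignment
        self.logrank_p_ = self.stratification_.logrank_p
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "stratification_")
        lp = self.estimator_.predict(X)
        if self.split != "linear_predictor":
            raise ValueError("predict is only defined for the linear-predictor split")
        return np.where(lp > self.stratification_.threshold, "high", "low")
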