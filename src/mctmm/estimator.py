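"""Scikit-learn style estimator facade over the mixed-effects Markov model.

:class:`MinimalCTMM` wraps model fitting and per-patient prediction behind
the familiar ``fit`` / ``predict`` / ``predict_proba`` surface so the model
can be configured with ``get_params`` / ``set_params`` and dropped into
generic tooling.  Input is either a long-format dataframe (see
:mod:`mctmm.io`) or a sequence of :class:`~mctmm.data.PatientRecord`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import PatientRecord
from .estimation import fit as _fit, marginal_ofv
from .model_core import CovariateSpec, PopulationParams
from .prediction import ppv_npv, prediction_table

__all__ = ["MinimalCTMM"]


def _as_records(X) -> list[PatientRecord]:
    if isinstance(X, pd.DataFrame):
        from .io import records_from_frame
        return records_from_frame(X)
    records = list(X)
    if not all(isinstance(r, PatientRecord) for r in records):
        raise TypeError(
            "X must be a long-format DataFrame or a sequence of PatientRecord")
    return records


class MinimalCTMM(BaseEstimator):
    """Minimal continuous-time Markov model for ordinal toxicity grades.

    Parameters
    ----------
    dose_effect : bool, default True
        Include the linear daily-dose effect on the logit intercepts
        (the final model); False fits the base model.
    dose_center : float, default 3000.0
        Centering dose (mg) of the linear dose effect.
    method : {"laplace", "agq"}, default "laplace"
        Marginal-likelihood approximation.
    start : PopulationParams or None
        Starting values; None uses a neutral default.
    compute_se : bool, default False
        Compute standard errors after the fit (adds a numerical Hessian).
    maxiter : int, default 300
        Outer optimizer iteration cap.

    Attributes
    ----------
    params_ : PopulationParams
        Estimated population parameters.
    ofv_ : float
        Objective function value (-2 log marginal likelihood) at the
        estimates.
    result_ : FitResult
        Full fit diagnostics.
    standard_errors_ : dict
        Per-parameter standard errors (empty when ``compute_se=False``).
    """

    def __init__(self, dose_effect: bool = True, dose_center: float = 3000.0,
                 method: str = "laplace", start: PopulationParams | None = None,
                 compute_se: bool = False, maxiter: int = 300):
        self.dose_effect = dose_effect
        self.dose_center = dose_center
        self.method = method
        self.start = start
        self.compute_se = compute_se
        self.maxiter = maxiter

    def _spec(self) -> CovariateSpec:
        return (CovariateSpec.final(self.dose_center) if self.dose_effect
                else CovariateSpec.base(self.dose_center))

    def fit(self, X, y=None) -> "MinimalCTMM":
        """Fit the model to a longitudinal toxicity dataset.

        ``y`` is ignored; the grades live inside ``X`` (DV column or
        record observations), as is natural for longitudinal data.
        """
        records = _as_records(X)
        start = self.start or PopulationParams(
            alpha1=1.0, b2=-1.0, b3=-1.0, met=1.0, theta_dose=1e-4,
            omega_alpha=0.5, omega_met=0.5)
        result = _fit(records, start, self._spec(), method=self.method,
                      compute_se=self.compute_se, maxiter=self.maxiter)
        self.result_ = result
        self.params_ = result.estimates
        self.ofv_ = result.ofv
        self.standard_errors_ = result.standard_errors
        self.n_subjects_ = result.n_subjects
        self.n_observations_ = result.n_observations
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise AttributeError("this MinimalCTMM instance is not fitted yet")

    def predict_table(self, X, cycles=range(2, 7)) -> pd.DataFrame:
        """Predicted-vs-observed modal grades (cycles 2..6 by default),
        using empirical-Bayes random effects from each patient's earlier
        cycles."""
        self._check_fitted()
        return prediction_table(_as_records(X), self.params_, self._spec(),
                                cycles=cycles)

    def predict(self, X) -> np.ndarray:
        """Predicted next-cycle modal grade for every predictable
        observation in X (ordered by cycle, then subject)."""
        return self.predict_table(X).predicted.to_numpy()

    def score(self, X, y=None) -> float:
        """Average marginal log-likelihood per observation (higher is
        better)."""
        self._check_fitted()
        records = [r for r in _as_records(X) if r.n_observations > 0]
        n_obs = sum(r.n_observations for r in records)
        ofv = marginal_ofv(records, self.params_, self._spec(),
                           method=self.method)
        return -0.5 * ofv / n_obs

    def ppv_npv(self, X) -> tuple[float, float]:
        """Positive/negative predictive value of the grade >= 2 grouping
        over cycles 2..6."""
        return ppv_npv(self.predict_table(X))
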