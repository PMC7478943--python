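"""Marginal maximum-likelihood estimation, likelihood-ratio testing, and
the non-parametric bootstrap.

The objective function value (OFV) is -2 times the log marginal likelihood,
with the subject-level random effects integrated out by a Laplace
approximation (default) or adaptive Gauss-Hermite quadrature.  Fixed
effects are optimized on a transformed scale that enforces the domain
constraints: log(-b) for the negative intercept increments, log for MET and
the random-effect SDs, and a per-gram rescaling of the dose slope for
conditioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .data import PackedData, PatientRecord, pack
from .likelihood import (
    agq_subject_loglik,
    laplace_subject_loglik,
    population_loglik,
)
from .model_core import CovariateSpec, EtaPair, PopulationParams

__all__ = [
    "FitResult",
    "LrtDecision",
    "BootstrapResult",
    "individual_loglik",
    "marginal_ofv",
    "fit",
    "likelihood_ratio_test",
    "bootstrap",
    "LRT_THRESHOLD_DF1",
]

logger = logging.getLogger(__name__)

#: Chi-square 0.01 critical value at one degree of freedom: the OFV must
#: drop by at least this much for one extra parameter at p <= 0.01.
LRT_THRESHOLD_DF1 = float(chi2.ppf(0.99, 1))  # 6.63


# ---------------------------------------------------------------------------
# Parameter transform

_OMEGA_FLOOR = 1e-3
_DOSE_SCALE = 1e3  # optimize theta_dose per gram instead of per mg


class _Transform:
    """Bijection between PopulationParams (+ extra covariate coefficients)
    and the unconstrained optimization vector."""

    def __init__(self, spec: CovariateSpec):
        self.spec = spec
        self.names = ["alpha1", "b2", "b3", "met"]
        if spec.dose_on_intercept:
            self.names.append("theta_dose")
        self.names += ["omega_alpha", "omega_met"]
        self.extra_names = [f"beta_{e.covariate}_{e.target}" for e in spec.extra]

    @property
    def all_names(self) -> list[str]:
        return self.names + self.extra_names

    def encode(self, params: PopulationParams) -> np.ndarray:
        x = [params.alpha1, np.log(-params.b2), np.log(-params.b3),
             np.log(params.met)]
        if self.spec.dose_on_intercept:
            x.append(params.theta_dose * _DOSE_SCALE)
        x += [np.log(max(params.omega_alpha, _OMEGA_FLOOR)),
              np.log(max(params.omega_met, _OMEGA_FLOOR))]
        for eff in self.spec.extra:
            coef = eff.coef
            if eff.covariate == "daily_dose":
                coef *= _DOSE_SCALE
            x.append(coef)
        return np.asarray(x, dtype=float)

    def decode(self, x: np.ndarray) -> tuple[PopulationParams, CovariateSpec]:
        i = 4
        theta = 0.0
        if self.spec.dose_on_intercept:
            theta = x[4] / _DOSE_SCALE
            i = 5
        params = PopulationParams(
            alpha1=x[0], b2=-np.exp(x[1]), b3=-np.exp(x[2]), met=np.exp(x[3]),
            theta_dose=theta,
            omega_alpha=np.exp(x[i]), omega_met=np.exp(x[i + 1]))
        effects = []
        for j, eff in enumerate(self.spec.extra):
            coef = x[i + 2 + j]
            if eff.covariate == "daily_dose":
                coef /= _DOSE_SCALE
            effects.append(replace(eff, coef=coef))
        spec = replace(self.spec, extra=tuple(effects))
        return params, spec

    def bounds(self) -> list[tuple[float, float]]:
        b = [(-15.0, 15.0), (-6.0, 4.0), (-6.0, 4.0), (-5.0, 5.0)]
        if self.spec.dose_on_intercept:
            b.append((-20.0, 20.0))
        b += [(np.log(_OMEGA_FLOOR), 3.0), (np.log(_OMEGA_FLOOR), 3.0)]
        b += [(-20.0, 20.0)] * len(self.spec.extra)
        return b


# ---------------------------------------------------------------------------
# Result containers

@dataclass
class FitResult:
    """Estimates and diagnostics of one marginal-likelihood fit.

    ``standard_errors`` follow the convention SE = sqrt(diag(2 H^-1)) with
    H the numerical Hessian of the OFV (= -2 log L) at the estimates, so
    that 2 H^-1 approximates the parameter covariance.
    """

    estimates: PopulationParams
    spec: CovariateSpec
    ofv: float
    standard_errors: dict = field(default_factory=dict)
    convergence: dict = field(default_factory=dict)
    n_subjects: int = 0
    n_observations: int = 0
    method: str = "laplace"
    eta_modes: np.ndarray | None = None

    def parameter_table(self) -> pd.DataFrame:
        """Estimate and RSE% per parameter, in the conventional layout."""
        tf = _Transform(self.spec)
        values = _param_values(self.estimates, self.spec)
        rows = []
        for name in tf.all_names:
            est = values[name]
            se = self.standard_errors.get(name, np.nan)
            rse = 100 * abs(se / est) if est and np.isfinite(se) else np.nan
            rows.append({"parameter": name, "estimate": est, "rse_percent": rse})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class LrtDecision:
    """Outcome of a likelihood-ratio test between nested models at the
    p <= 0.01 inclusion threshold."""

    delta_ofv: float
    df: int
    p_value: float
    significant: bool


@dataclass
class BootstrapResult:
    """Percentile summaries over bootstrap replicate refits."""

    medians: dict
    ci_lower: dict
    ci_upper: dict
    estimates: pd.DataFrame
    n_replicates: int
    n_failed: int
    high_failure_warning: bool = False

    def table(self) -> pd.DataFrame:
        rows = [{"parameter": k, "bootstrap_median": self.medians[k],
                 "ci95_lower": self.ci_lower[k], "ci95_upper": self.ci_upper[k]}
                for k in self.medians]
        return pd.DataFrame(rows)


def _param_values(params: PopulationParams, spec: CovariateSpec) -> dict:
    values = {"alpha1": params.alpha1, "b2": params.b2, "b3": params.b3,
              "met": params.met, "omega_alpha": params.omega_alpha,
              "omega_met": params.omega_met}
    if spec.dose_on_intercept:
        values["theta_dose"] = params.theta_dose
    for eff in spec.extra:
        values[f"beta_{eff.covariate}_{eff.target}"] = eff.coef
    return values


# ---------------------------------------------------------------------------
# Public operations

def individual_loglik(record: PatientRecord, params: PopulationParams,
                      eta: EtaPair | None = None,
                      spec: CovariateSpec | None = None) -> float:
    """Conditional log-likelihood of one subject at fixed random effects:
    the sum over consecutive observation pairs (starting from the grade-0
    baseline) of log transition probabilities."""
    eta = eta or EtaPair()
    spec = spec or CovariateSpec.final()
    packed = pack([record])
    ll = population_loglik(packed, params, spec,
                           np.array([eta.eta_alpha]), np.array([eta.eta_met]))
    return float(ll[0])


def marginal_ofv(data, params: PopulationParams,
                 spec: CovariateSpec | None = None,
                 method: str = "laplace", n_nodes: int = 21) -> float:
    """-2 log marginal likelihood of the cohort.

    ``method`` is ``"laplace"`` (per-subject mode + curvature) or ``"agq"``
    (adaptive Gauss-Hermite quadrature with ``n_nodes`` per dimension).
    """
    spec = spec or CovariateSpec.final()
    packed = data if isinstance(data, PackedData) else pack(data)
    if method == "laplace":
        ll, _ = laplace_subject_loglik(packed, params, spec)
    elif method == "agq":
        ll = agq_subject_loglik(packed, params, spec, n_nodes=n_nodes)
    else:
        raise ValueError(f"unknown method {method!r}; use 'laplace' or 'agq'")
    return float(-2.0 * ll.sum())


def fit(data, start: PopulationParams,
        spec: CovariateSpec | None = None, method: str = "laplace",
        compute_se: bool = True, maxiter: int = 300,
        ftol: float = 1e-8, gtol: float = 5e-4) -> FitResult:
    """Maximize the marginal likelihood over the population parameters.

    L-BFGS-B on the transformed scale with finite-difference gradients;
    standard errors (optional) from the central-difference Hessian of the
    OFV at the optimum on the natural scale.
    """
    spec = spec or CovariateSpec.final()
    records = None
    if isinstance(data, PackedData):
        packed = data
    else:
        records = [r for r in data if r.n_observations > 0]
        dropped = len(list(data)) - len(records)
        if dropped:
            logger.info("dropped %d subject(s) observed only at baseline", dropped)
        packed = pack(records)
    tf = _Transform(spec)
    x0 = tf.encode(start)

    def objective(x):
        params_x, spec_x = tf.decode(x)
        ll, _ = (laplace_subject_loglik(packed, params_x, spec_x)
                 if method == "laplace"
                 else (agq_subject_loglik(packed, params_x, spec_x), None))
        value = -2.0 * float(np.sum(ll))
        # a finite penalty keeps line searches alive at numerically
        # degenerate trial points
        return value if np.isfinite(value) else 1e10

    res = optimize.minimize(
        objective, x0, method="L-BFGS-B", bounds=tf.bounds(),
        options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol,
                 "eps": 1e-5, "maxfun": 20000})
    est_params, est_spec = tf.decode(res.x)
    ll, eta_modes = laplace_subject_loglik(packed, est_params, est_spec)
    ofv = -2.0 * float(ll.sum())

    ses: dict = {}
    if compute_se:
        ses = _standard_errors(packed, est_params, est_spec, method, ofv)

    return FitResult(
        estimates=est_params, spec=est_spec, ofv=ofv,
        standard_errors=ses,
        convergence={
            "converged": bool(res.success), "message": str(res.message),
            "n_iterations": int(res.nit), "n_ofv_evaluations": int(res.nfev),
            "gradient_norm": float(np.max(np.abs(res.jac)))
            if res.jac is not None else np.nan,
            "se_convention": "SE = sqrt(diag(2 * H_OFV^-1)), H_OFV the "
                             "central-difference Hessian of the OFV at the "
                             "estimates on the natural scale",
        },
        n_subjects=packed.n_subjects, n_observations=packed.n_observations,
        method=method, eta_modes=eta_modes)


def _standard_errors(packed, params, spec, method, ofv0) -> dict:
    """Central-difference Hessian of the OFV on the natural scale;
    SE = sqrt(diag(2 H^-1)).  Non-PD Hessians yield NaN entries."""
    values = _param_values(params, spec)
    names = list(values)
    x0 = np.array([values[n] for n in names])
    steps = np.maximum(np.abs(x0) * 1e-3, 1e-8)

    def f(x):
        vals = dict(zip(names, x))
        try:
            p = PopulationParams(
                alpha1=vals["alpha1"], b2=vals["b2"], b3=vals["b3"],
                met=vals["met"], theta_dose=vals.get("theta_dose", 0.0),
                omega_alpha=max(vals["omega_alpha"], 0.0),
                omega_met=max(vals["omega_met"], 0.0))
        except ValueError:
            return np.nan
        effects = tuple(replace(e, coef=vals[f"beta_{e.covariate}_{e.target}"])
                        for e in spec.extra)
        s = replace(spec, extra=effects)
        return marginal_ofv(packed, p, s, method=method)

    k = len(x0)
    hess = np.full((k, k), np.nan)
    fp = np.zeros(k)
    fm = np.zeros(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = steps[i]
        fp[i] = f(x0 + e)
        fm[i] = f(x0 - e)
        hess[i, i] = (fp[i] - 2 * ofv0 + fm[i]) / steps[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            hij = (f(x0 + ei + ej) - f(x0 + ei - ej)
                   - f(x0 - ei + ej) + f(x0 - ei - ej)) / (4 * steps[i] * steps[j])
            hess[i, j] = hess[j, i] = hij
    ses = {}
    try:
        cov = 2.0 * np.linalg.inv(hess)
        diag = np.diag(cov)
        for n, v in zip(names, diag):
            ses[n] = float(np.sqrt(v)) if v > 0 else np.nan
    except np.linalg.LinAlgError:
        ses = {n: np.nan for n in names}
    return ses


def likelihood_ratio_test(ofv_reduced: float, ofv_full: float,
                          df: int) -> LrtDecision:
    """Nested-model test on the OFV difference.

    ``delta_ofv = ofv_full - ofv_reduced`` (negative when the larger model
    improves the fit); the p-value refers -delta_ofv to chi-square with
    ``df`` degrees of freedom, and significance is declared at p <= 0.01
    (a drop of at least 6.64 units for one extra parameter).
    """
    if df not in (1, 2):
        raise ValueError(f"df must be 1 or 2, got {df}")
    delta = ofv_full - ofv_reduced
    p = float(chi2.sf(max(-delta, 0.0), df))
    return LrtDecision(delta_ofv=delta, df=df, p_value=p,
                       significant=p <= 0.01)


def bootstrap(data, start: PopulationParams,
              spec: CovariateSpec | None = None,
              n_replicates: int = 1000, seed: int | None = None,
              method: str = "laplace", maxiter: int = 200) -> BootstrapResult:
    """Non-parametric bootstrap without stratification.

    Subjects are resampled with replacement to the original cohort size;
    each replicate is refit from ``start`` (conventionally the original
    estimates).  Reports per-parameter 2.5/50/97.5 percentiles over the
    replicates that converged; failed replicates are excluded and counted,
    with a hard warning flag above 20% failures.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    spec = spec or CovariateSpec.final()
    records = [r for r in data if r.n_observations > 0]
    rng = np.random.default_rng(seed)
    n = len(records)
    rows = []
    n_failed = 0
    for rep in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        sample = [records[i] for i in idx]
        try:
            res = fit(sample, start, spec, method=method,
                      compute_se=False, maxiter=maxiter)
            if not np.isfinite(res.ofv):
                raise RuntimeError("non-finite OFV")
            rows.append(_param_values(res.estimates, res.spec))
        except Exception as exc:  # refit failures are logged, not fatal
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %s", rep, exc)
    est = pd.DataFrame(rows)
    med, lo, hi = {}, {}, {}
    for col in est.columns:
        med[col] = float(est[col].median())
        lo[col] = float(np.percentile(est[col], 2.5))
        hi[col] = float(np.percentile(est[col], 97.5))
    return BootstrapResult(
        medians=med, ci_lower=lo, ci_upper=hi, estimates=est,
        n_replicates=n_replicates, n_failed=n_failed,
        high_failure_warning=n_failed > 0.2 * n_replicates)
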