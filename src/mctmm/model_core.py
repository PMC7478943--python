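"""Proportional-odds probability machinery for ordered toxicity grades.

The severity of hand-foot syndrome (HFS) is recorded on the ordinal CTCAE
scale 0-3.  At any moment the model assigns each grade a probability through
a proportional-odds construction: the three cumulative probabilities
``P(grade >= n)`` share a single linear predictor on the logit scale and
differ only through ordered intercepts,

    logit P(grade >= n) = alpha_n + g(x) + eta,

where ``g(x)`` carries covariate effects (in the final model a linear effect
of the absolute daily capecitabine dose, centred on 3000 mg) and ``eta`` is a
subject-level normal random effect shared by all three cumulative logits.
The ordering alpha_1 > alpha_2 > alpha_3 is enforced by parametrizing the
intercepts as alpha_{n+1} = alpha_n + b_{n+1} with b strictly negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "PopulationParams",
    "EtaPair",
    "CovariateVector",
    "GradeDistribution",
    "CovariateEffect",
    "CovariateSpec",
    "cumulative_logits",
    "grade_distribution",
    "covariate_model",
    "PROB_FLOOR",
    "N_GRADES",
]

N_GRADES = 4

#: Floor applied to each grade probability before transition rates are built
#: from it; keeps the generator matrix finite when a grade is numerically
#: impossible.
PROB_FLOOR = 1e-12


class InvalidParameterError(ValueError):
    """A population parameter violates its domain constraint."""


class OrderingViolationError(ValueError):
    """Cumulative logits are not strictly decreasing in grade."""


@dataclass(frozen=True)
class PopulationParams:
    """Fixed effects and random-effect standard deviations of the model.

    Parameters
    ----------
    alpha1 : float
        Logit-scale intercept for grade >= 1.
    b2, b3 : float
        Strictly negative increments giving alpha2 = alpha1 + b2 and
        alpha3 = alpha2 + b3.
    met : float
        Mean equilibration time in treatment cycles (> 0); the single time
        scale of all adjacent-grade transition rates.
    theta_dose : float
        Slope of the linear daily-dose effect on the logit scale (per mg).
    omega_alpha : float
        SD of the additive intercept random effect (>= 0).
    omega_met : float
        SD of the log-MET random effect (>= 0).
    """

    alpha1: float
    b2: float
    b3: float
    met: float
    theta_dose: float = 0.0
    omega_alpha: float = 0.0
    omega_met: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.alpha1, self.b2, self.b3, self.met, self.theta_dose,
                self.omega_alpha, self.omega_met)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite parameter in {self}")
        if self.b2 >= 0 or self.b3 >= 0:
            raise InvalidParameterError(
                f"b2 and b3 must be strictly negative, got b2={self.b2}, b3={self.b3}")
        if self.met <= 0:
            raise InvalidParameterError(f"met must be > 0, got {self.met}")
        if self.omega_alpha < 0 or self.omega_met < 0:
            raise InvalidParameterError("omega values must be >= 0")

    @property
    def alpha2(self) -> float:
        return self.alpha1 + self.b2

    @property
    def alpha3(self) -> float:
        return self.alpha1 + self.b2 + self.b3

    @property
    def intercepts(self) -> np.ndarray:
        """The three ordered logit intercepts (alpha1, alpha2, alpha3)."""
        return np.array([self.alpha1, self.alpha2, self.alpha3])

    def replace(self, **kwargs) -> "PopulationParams":
        return replace(self, **kwargs)

    @classmethod
    def reference(cls) -> "PopulationParams":
        """Reference estimates for capecitabine-induced HFS.

        The defaults are the final-model estimates from the 150-patient
        observational capecitabine cohort this model family was developed
        on; they serve as the default simulation truth throughout.
        """
        return cls(alpha1=1.81, b2=-1.80, b3=-2.08, met=1.09,
                   theta_dose=8.33e-4, omega_alpha=1.12, omega_met=0.542)


@dataclass(frozen=True)
class EtaPair:
    """Subject-level random effects: additive on the logit intercepts
    (``eta_alpha``) and additive on log MET (``eta_met``)."""

    eta_alpha: float = 0.0
    eta_met: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.eta_alpha) and math.isfinite(self.eta_met)):
            raise InvalidParameterError("eta values must be finite")


@dataclass(frozen=True)
class CovariateVector:
    """Covariates of one subject at one dosing interval.

    ``daily_dose`` is the absolute daily dose in mg (0 after treatment
    discontinuation).  The remaining fields are the baseline covariates
    screened during model development; they carry no effect in the final
    model but are retained so covariate screens can be exercised.
    """

    daily_dose: float = 3000.0
    age: float = 62.0
    sex: str = "female"
    entity: str = "colorectal"
    monotherapy: bool = True
    adherence_group: str = ">100%"

    SEXES = ("male", "female")
    ENTITIES = ("colorectal", "breast", "other")
    ADHERENCE = (">100%", "90-100%", "<90%")

    def __post_init__(self) -> None:
        if not 0 <= self.daily_dose <= 6000:
            raise InvalidParameterError(
                f"daily_dose must be in [0, 6000] mg, got {self.daily_dose}")
        if self.sex not in self.SEXES:
            raise InvalidParameterError(f"unknown sex {self.sex!r}")
        if self.entity not in self.ENTITIES:
            raise InvalidParameterError(f"unknown entity {self.entity!r}")
        if self.adherence_group not in self.ADHERENCE:
            raise InvalidParameterError(
                f"unknown adherence group {self.adherence_group!r}")


class GradeDistribution:
    """Probability vector over grades 0..3."""

    __slots__ = ("p",)

    def __init__(self, p):
        p = np.asarray(p, dtype=float)
        if p.shape != (N_GRADES,):
            raise ValueError(f"expected {N_GRADES} probabilities, got shape {p.shape}")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError(f"probabilities outside [0, 1]: {p}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
        self.p = p

    def cumulative(self) -> np.ndarray:
        """P(grade >= n) for n = 0..3 (first entry is 1)."""
        return self.p[::-1].cumsum()[::-1]

    def floored(self, floor: float = PROB_FLOOR) -> np.ndarray:
        """Probabilities with the numerical floor applied (not renormalized)."""
        return np.maximum(self.p, floor)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GradeDistribution({np.array2string(self.p, precision=4)})"


# ---------------------------------------------------------------------------
# Covariate model

#: Covariates resolvable by name in a covariate effect.  Each maps a
#: CovariateVector (plus the interval time, for the time screen) to one or
#: more numeric regressors.
_COVARIATE_VALUES = {
    "daily_dose": lambda cov, t: cov.daily_dose,      # centring handled below
    "age": lambda cov, t: cov.age - 62.0,
    "sex_female": lambda cov, t: 1.0 if cov.sex == "female" else 0.0,
    "monotherapy": lambda cov, t: 1.0 if cov.monotherapy else 0.0,
    "entity_breast": lambda cov, t: 1.0 if cov.entity == "breast" else 0.0,
    "entity_colorectal": lambda cov, t: 1.0 if cov.entity == "colorectal" else 0.0,
    "entity_other": lambda cov, t: 1.0 if cov.entity == "other" else 0.0,
    "adherence_90_100": lambda cov, t: 1.0 if cov.adherence_group == "90-100%" else 0.0,
    "adherence_lt90": lambda cov, t: 1.0 if cov.adherence_group == "<90%" else 0.0,
    "time": lambda cov, t: t,
}

_TARGETS = ("intercept", "met")


class CovariateConfigurationError(ValueError):
    """A covariate effect references an unknown covariate or target."""


@dataclass(frozen=True)
class CovariateEffect:
    """One screened covariate effect: additive on the logit intercepts or
    multiplicative (exp of a linear term) on MET."""

    covariate: str
    target: str
    coef: float = 0.0

    def __post_init__(self) -> None:
        if self.covariate not in _COVARIATE_VALUES:
            raise CovariateConfigurationError(
                f"unknown covariate {self.covariate!r}; "
                f"known: {sorted(_COVARIATE_VALUES)}")
        if self.target not in _TARGETS:
            raise CovariateConfigurationError(
                f"unknown target {self.target!r}; known: {_TARGETS}")


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate-effect configuration of a model variant.

    ``dose_on_intercept`` switches the final model's linear daily-dose
    effect (coefficient ``PopulationParams.theta_dose``) on the logit
    intercepts; the base model sets it to False.  ``extra`` holds screened
    effects with their own coefficients, enabling the covariate screen on
    top of either model.
    """

    dose_on_intercept: bool = True
    extra: tuple[CovariateEffect, ...] = ()
    dose_center: float = 3000.0

    def __post_init__(self) -> None:
        if self.dose_center <= 0:
            raise InvalidParameterError(
                f"dose_center must be > 0, got {self.dose_center}")

    @classmethod
    def base(cls, dose_center: float = 3000.0) -> "CovariateSpec":
        """The base model: no covariate effects."""
        return cls(dose_on_intercept=False, dose_center=dose_center)

    @classmethod
    def final(cls, dose_center: float = 3000.0) -> "CovariateSpec":
        """The final model: linear daily-dose effect on the intercepts."""
        return cls(dose_on_intercept=True, dose_center=dose_center)

    def with_effect(self, covariate: str, target: str,
                    coef: float = 0.0) -> "CovariateSpec":
        return replace(self, extra=self.extra
                       + (CovariateEffect(covariate, target, coef),))


def covariate_model(spec: CovariateSpec, cov: CovariateVector,
                    params: PopulationParams | None = None,
                    time: float = 0.0) -> tuple[float, float]:
    """Evaluate covariate adjustments under a configuration.

    Returns ``(logit_shift, met_multiplier)``: the additive adjustment to
    all three cumulative logits and the multiplicative adjustment to MET.
    """
    logit_shift = 0.0
    log_met = 0.0
    if spec.dose_on_intercept:
        theta = params.theta_dose if params is not None else 0.0
        logit_shift += theta * (cov.daily_dose - spec.dose_center)
    for eff in spec.extra:
        value = _COVARIATE_VALUES[eff.covariate](cov, time)
        if eff.covariate == "daily_dose":
            value -= spec.dose_center
        if eff.target == "intercept":
            logit_shift += eff.coef * value
        else:
            log_met += eff.coef * value
    return logit_shift, math.exp(log_met)


def cumulative_logits(params: PopulationParams,
                      eta: EtaPair | None = None,
                      cov: CovariateVector | None = None,
                      spec: CovariateSpec | None = None,
                      time: float = 0.0) -> np.ndarray:
    """The three cumulative logits for one subject at one dosing interval.

    Returns ``(logit P(>=1), logit P(>=2), logit P(>=3))``, a strictly
    decreasing triple.  With the final-model spec the linear predictor is
    ``theta_dose * (daily_dose - dose_center)`` plus the intercept random
    effect; additional screened effects from ``spec.extra`` are included.
    """
    eta = eta or EtaPair()
    cov = cov or CovariateVector()
    spec = spec or CovariateSpec.final()
    shift, _ = covariate_model(spec, cov, params, time)
    return params.intercepts + shift + eta.eta_alpha


def individual_met(params: PopulationParams,
                   eta: EtaPair | None = None,
                   cov: CovariateVector | None = None,
                   spec: CovariateSpec | None = None,
                   time: float = 0.0) -> float:
    """Subject-level mean equilibration time MET * exp(eta_met) times any
    screened multiplicative covariate adjustment."""
    eta = eta or EtaPair()
    cov = cov or CovariateVector()
    spec = spec or CovariateSpec.final()
    _, met_mult = covariate_model(spec, cov, params, time)
    return params.met * math.exp(eta.eta_met) * met_mult


def grade_distribution(logits) -> GradeDistribution:
    """Grade probabilities from the three cumulative logits.

    ``p(grade n) = expit(logit_n) - expit(logit_{n+1})`` with the
    conventions ``expit(logit_0) = 1`` and ``expit(logit_4) = 0``.
    """
    logits = np.asarray(logits, dtype=float)
    if logits.shape != (3,):
        raise ValueError(f"expected 3 logits, got shape {logits.shape}")
    if not np.all(np.diff(logits) < 0):
        raise OrderingViolationError(
            f"cumulative logits must be strictly decreasing, got {logits}")
    cum = np.empty(N_GRADES + 1)
    cum[0] = 1.0
    cum[1:4] = expit(logits)
    cum[4] = 0.0
    return GradeDistribution(-np.diff(cum))


def linear_predictors(params: PopulationParams, spec: CovariateSpec,
                      daily_dose, time=0.0, regressors: dict | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized fixed-effect linear predictors (excluding random effects).

    Returns ``(logit_shift, log_met)`` broadcast over ``daily_dose`` /
    ``time`` / the regressor arrays.  ``regressors`` maps covariate names
    (as in covariate effects) to numeric arrays for any screened effects.
    """
    daily_dose = np.asarray(daily_dose, dtype=float)
    time = np.asarray(time, dtype=float)
    shift = np.zeros(np.broadcast(daily_dose, time).shape)
    log_met = np.full_like(shift, math.log(params.met))
    if spec.dose_on_intercept:
        shift = shift + params.theta_dose * (daily_dose - spec.dose_center)
    for eff in spec.extra:
        if eff.covariate == "daily_dose":
            value = daily_dose - spec.dose_center
        elif eff.covariate == "time":
            value = time
        else:
            if regressors is None or eff.covariate not in regressors:
                raise CovariateConfigurationError(
                    f"no regressor values supplied for {eff.covariate!r}")
            value = np.asarray(regressors[eff.covariate], dtype=float)
        if eff.target == "intercept":
            shift = shift + eff.coef * value
        else:
            log_met = log_met + eff.coef * value
    return shift, log_met


def grade_probabilities_batch(logits: np.ndarray,
                              floor: float = PROB_FLOOR) -> np.ndarray:
    """Vectorized grade probabilities with the numerical floor applied.

    ``logits`` has shape (..., 3); the result has shape (..., 4).  Used by
    the likelihood kernel, where the floor keeps generator rates finite.
    """
    cum = expit(logits)
    p = np.empty(logits.shape[:-1] + (N_GRADES,))
    p[..., 0] = 1.0 - cum[..., 0]
    p[..., 1] = cum[..., 0] - cum[..., 1]
    p[..., 2] = cum[..., 1] - cum[..., 2]
    p[..., 3] = cum[..., 2]
    return np.maximum(p, floor)
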