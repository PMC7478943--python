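"""Four-state continuous-time Markov dynamics of toxicity-grade probabilities.

Between two observations the vector of grade probabilities evolves under a
tridiagonal generator: only transitions between adjacent grades carry rate.
In the minimal construction all adjacent rates share a single time scale,
the mean equilibration time (MET): each rate is proportional to the
destination grade's proportional-odds probability, normalized so that every
adjacent pair of states equilibrates with time constant MET,

    K(i -> j) = pi_j / (MET * (pi_i + pi_j)),   |i - j| = 1,

hence K(i -> j) + K(j -> i) = 1/MET for every adjacent pair — the property
that gives MET its name.  The construction satisfies detailed balance
pi_i K(i->j) = pi_j K(j->i) exactly, so the proportional-odds distribution
``pi`` is the stationary law of the chain.
Propagation over a dosing interval is the matrix exponential of the
generator; doses that change at cycle boundaries give a piecewise-constant
generator and a product of per-cycle transition matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .model_core import (
    N_GRADES,
    PROB_FLOOR,
    CovariateSpec,
    CovariateVector,
    EtaPair,
    GradeDistribution,
    PopulationParams,
    cumulative_logits,
    grade_distribution,
    individual_met,
)

__all__ = [
    "GeneratorMatrix",
    "TransitionMatrix",
    "build_generator",
    "propagate",
    "transition_matrix",
    "interval_transition_matrix",
    "transition_matrices_batch",
    "generators_batch",
]


@dataclass(frozen=True)
class GeneratorMatrix:
    """4x4 transition-rate matrix (per cycle); rows sum to zero."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (N_GRADES, N_GRADES):
            raise ValueError(f"generator must be 4x4, got {q.shape}")
        object.__setattr__(self, "q", q)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic matrix of grade-to-grade probabilities over ``elapsed``
    cycles."""

    t_mat: np.ndarray
    elapsed: float


def build_generator(target: GradeDistribution | np.ndarray,
                    met_i: float) -> GeneratorMatrix:
    """Generator whose stationary distribution is ``target``.

    The rate toward adjacent grade ``j`` is
    ``target[j] / (met_i * (target[i] + target[j]))``, so each adjacent
    pair's rates sum to ``1/met_i``; all other off-diagonal entries are
    zero and the diagonal balances each row.
    """
    if met_i <= 0:
        raise ValueError(f"met must be > 0, got {met_i}")
    if isinstance(target, GradeDistribution):
        p = target.floored()
    else:
        p = np.maximum(np.asarray(target, dtype=float), PROB_FLOOR)
    q = np.zeros((N_GRADES, N_GRADES))
    for i in range(N_GRADES - 1):
        pair = p[i] + p[i + 1]
        q[i, i + 1] = p[i + 1] / (met_i * pair)
        q[i + 1, i] = p[i] / (met_i * pair)
    np.fill_diagonal(q, -q.sum(axis=1))
    return GeneratorMatrix(q)


def propagate(gen: GeneratorMatrix, start_grade: int,
              elapsed: float) -> GradeDistribution:
    """Grade probabilities after ``elapsed`` cycles from a point mass.

    Solves dP/dt = P Q from the indicator initial condition at
    ``start_grade`` via the matrix exponential.
    """
    if elapsed < 0:
        raise ValueError(f"elapsed must be >= 0, got {elapsed}")
    if not 0 <= start_grade < N_GRADES:
        raise ValueError(f"start_grade must be 0..3, got {start_grade}")
    t = expm(gen.q * elapsed)
    row = np.clip(t[start_grade], 0.0, None)
    return GradeDistribution(row / row.sum())


def transition_matrix(params: PopulationParams,
                      eta: EtaPair | None = None,
                      daily_dose: float = 3000.0,
                      elapsed: float = 1.0,
                      spec: CovariateSpec | None = None,
                      cov: CovariateVector | None = None,
                      time: float = 0.0) -> TransitionMatrix:
    """Transition matrix over a constant-dose interval.

    Stacks :func:`propagate` over all four start grades (computed in one
    matrix exponential).  ``cov`` defaults to a covariate vector carrying
    only ``daily_dose``.
    """
    if cov is None:
        cov = CovariateVector(daily_dose=daily_dose)
    logits = cumulative_logits(params, eta, cov, spec, time)
    target = grade_distribution(logits)
    met_i = individual_met(params, eta, cov, spec, time)
    gen = build_generator(target, met_i)
    t = expm(gen.q * elapsed)
    t = np.clip(t, 0.0, None)
    t /= t.sum(axis=1, keepdims=True)
    return TransitionMatrix(t_mat=t, elapsed=elapsed)


def interval_transition_matrix(params: PopulationParams,
                               eta: EtaPair | None,
                               doses: Sequence[float],
                               durations: Sequence[float] | None = None,
                               spec: CovariateSpec | None = None,
                               cov: CovariateVector | None = None,
                               times: Sequence[float] | None = None,
                               ) -> TransitionMatrix:
    """Transition matrix over an interval with piecewise-constant dose.

    ``doses`` lists the per-cycle daily dose over the interval (one entry
    per cycle); multi-cycle gaps between questionnaires are propagated as
    the ordered product of per-cycle transition matrices.
    """
    doses = list(doses)
    if durations is None:
        durations = [1.0] * len(doses)
    if times is None:
        times = [0.0] * len(doses)
    t = np.eye(N_GRADES)
    elapsed = 0.0
    for dose, dur, tt in zip(doses, durations, times):
        seg_cov = (cov if cov is not None and cov.daily_dose == dose
                   else _with_dose(cov, dose))
        seg = transition_matrix(params, eta, dose, dur, spec, seg_cov, tt)
        t = t @ seg.t_mat
        elapsed += dur
    return TransitionMatrix(t_mat=t, elapsed=elapsed)


def _with_dose(cov: CovariateVector | None, dose: float) -> CovariateVector:
    if cov is None:
        return CovariateVector(daily_dose=dose)
    return CovariateVector(daily_dose=dose, age=cov.age, sex=cov.sex,
                           entity=cov.entity, monotherapy=cov.monotherapy,
                           adherence_group=cov.adherence_group)


# ---------------------------------------------------------------------------
# Batched kernel used by the likelihood engine and the simulators.

def generators_batch(p: np.ndarray, met: np.ndarray) -> np.ndarray:
    """Stacked tridiagonal generators from floored grade probabilities.

    ``p`` has shape (..., 4) (already floored), ``met`` shape (...,);
    returns (..., 4, 4).
    """
    shape = p.shape[:-1]
    q = np.zeros(shape + (N_GRADES, N_GRADES))
    for i in range(N_GRADES - 1):
        pair = met * (p[..., i] + p[..., i + 1])
        q[..., i, i + 1] = p[..., i + 1] / pair
        q[..., i + 1, i] = p[..., i] / pair
    d = np.arange(N_GRADES)
    q[..., d, d] = -q.sum(axis=-1)
    return q


def transition_matrices_batch(p: np.ndarray, met: np.ndarray,
                              elapsed: np.ndarray | float = 1.0) -> np.ndarray:
    """Stacked transition matrices exp(Q * elapsed); shapes as in
    :func:`generators_batch`.

    Exploits reversibility: D^{1/2} Q D^{-1/2} with D = diag(p) is
    symmetric, so the exponential reduces to one batched symmetric
    eigendecomposition (faster and vectorizable, unlike Pade scaling and
    squaring).
    """
    p = np.asarray(p, dtype=float)
    met = np.asarray(met, dtype=float)
    elapsed = np.asarray(elapsed, dtype=float)
    shape = p.shape[:-1]
    k_up = np.empty(shape + (N_GRADES - 1,))   # rate i -> i+1
    k_dn = np.empty(shape + (N_GRADES - 1,))   # rate i+1 -> i
    for i in range(N_GRADES - 1):
        pair = met * (p[..., i] + p[..., i + 1])
        k_up[..., i] = p[..., i + 1] / pair
        k_dn[..., i] = p[..., i] / pair
    s = np.zeros(shape + (N_GRADES, N_GRADES))
    off = np.sqrt(k_up * k_dn)
    for i in range(N_GRADES - 1):
        s[..., i, i + 1] = off[..., i]
        s[..., i + 1, i] = off[..., i]
    d = np.arange(N_GRADES)
    s[..., 0, 0] = -k_up[..., 0]
    s[..., 1, 1] = -(k_dn[..., 0] + k_up[..., 1])
    s[..., 2, 2] = -(k_dn[..., 1] + k_up[..., 2])
    s[..., 3, 3] = -k_dn[..., 2]
    w, v = np.linalg.eigh(s)
    ew = np.exp(w * elapsed[..., None])
    sp = np.sqrt(p)
    t = np.einsum("...ik,...k,...jk->...ij", v, ew, v)
    t *= sp[..., None, :] / sp[..., :, None]
    np.clip(t, 0.0, None, out=t)
    t /= t.sum(axis=-1, keepdims=True)
    return t
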