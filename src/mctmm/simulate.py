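"""Trajectory simulation and categorical visual predictive checks.

Simulation draws subject random effects from their population distribution
and walks the grade chain forward cycle by cycle: starting from the
asymptomatic baseline, each cycle's grade is sampled from the row of that
cycle's transition matrix indexed by the previous grade.  The visual
predictive check (VPC) simulates many replicates of the observed design and
overlays the observed per-cycle grade proportions on the 2.5-97.5 percentile
band of the simulated proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PatientRecord
from .model_core import (
    CovariateSpec,
    PopulationParams,
    _COVARIATE_VALUES,
    grade_probabilities_batch,
    linear_predictors,
)
from .markov import transition_matrices_batch

__all__ = ["VpcSummary", "simulate_subject", "simulate_dataset",
           "categorical_vpc"]


def _static_regressors(records) -> dict:
    out = {}
    for name, fn in _COVARIATE_VALUES.items():
        if name in ("daily_dose", "time"):
            continue
        out[name] = np.array([fn(r.covariates, 0.0) for r in records])
    return out


def _simulate_grades(records, params: PopulationParams, spec: CovariateSpec,
                     rng: np.random.Generator, n_replicates: int = 1,
                     eta: np.ndarray | None = None,
                     chunk: int = 50) -> np.ndarray:
    """Simulated grade paths on the records' design.

    Returns an integer array (n_replicates, n_subjects, max_cycle) of the
    grade at the end of each cycle (cycle 1 .. max over subjects); cycles
    beyond a subject's last observation are still walked but unused.
    """
    n = len(records)
    max_c = int(max((r.times.max() if r.n_observations else 0)
                    for r in records)) if n else 0
    doses = np.zeros((n, max_c))
    for i, r in enumerate(records):
        k = min(len(r.cycle_doses), max_c)
        doses[i, :k] = r.cycle_doses[:k]
    regs = _static_regressors(records)
    times = np.arange(1, max_c + 1, dtype=float)
    shift_fix, log_met_fix = linear_predictors(
        params, spec, doses, times[None, :],
        {k: v[:, None] for k, v in regs.items()})

    out = np.empty((n_replicates, n, max_c), dtype=np.int8)
    for lo in range(0, n_replicates, chunk):
        hi = min(lo + chunk, n_replicates)
        r = hi - lo
        if eta is None:
            ea = rng.normal(0.0, params.omega_alpha, size=(r, n))
            em = rng.normal(0.0, params.omega_met, size=(r, n))
        else:
            ea = np.broadcast_to(eta[:, 0], (r, n))
            em = np.broadcast_to(eta[:, 1], (r, n))
        logits = (params.intercepts
                  + (shift_fix[None] + ea[..., None])[..., None])
        p = grade_probabilities_batch(logits)
        t = transition_matrices_batch(
            p, np.exp(log_met_fix[None] + em[..., None]), 1.0)
        g = np.zeros((r, n), dtype=np.int8)
        ii = np.arange(r)[:, None], np.arange(n)[None, :]
        for c in range(max_c):
            probs = t[ii[0], ii[1], c, g]              # (r, n, 4)
            u = rng.random((r, n, 1))
            g = (probs.cumsum(axis=-1) < u).sum(axis=-1).astype(np.int8)
            np.clip(g, 0, 3, out=g)
            out[lo:hi, :, c] = g
    return out


def simulate_subject(template: PatientRecord, params: PopulationParams,
                     spec: CovariateSpec | None = None,
                     rng: np.random.Generator | None = None,
                     eta: np.ndarray | None = None) -> PatientRecord:
    """One simulated subject on a template's design (times, doses,
    covariates).  Random effects are drawn from N(0, diag(omega^2)) unless
    ``eta`` (length-2 array) is given."""
    return simulate_dataset([template], params, spec, rng,
                            eta=None if eta is None else np.atleast_2d(eta))[0]


def simulate_dataset(records, params: PopulationParams,
                     spec: CovariateSpec | None = None,
                     rng: np.random.Generator | None = None,
                     eta: np.ndarray | None = None) -> list[PatientRecord]:
    """Simulate grades for every record on its own design."""
    spec = spec or CovariateSpec.final()
    rng = rng if rng is not None else np.random.default_rng()
    records = list(records)
    if not records:
        return []
    grades = _simulate_grades(records, params, spec, rng, 1, eta=eta)[0]
    out = []
    for i, r in enumerate(records):
        if r.n_observations == 0:
            out.append(dc_replace_record(r, r.grades))
            continue
        g = grades[i, r.times.astype(int) - 1]
        out.append(dc_replace_record(r, g))
    return out


def dc_replace_record(r: PatientRecord, grades) -> PatientRecord:
    return PatientRecord(
        patient_id=r.patient_id, times=r.times.copy(),
        grades=np.asarray(grades, dtype=int), cycle_doses=r.cycle_doses.copy(),
        covariates=r.covariates,
        discontinuation_cycle=r.discontinuation_cycle)


@dataclass
class VpcSummary:
    """Tidy per-(cycle, grade) VPC table: observed proportion and the
    simulated 2.5-97.5 percentile band."""

    table: pd.DataFrame
    n_sim: int
    seed: int | None

    def coverage(self) -> float:
        """Fraction of cycle-by-grade bins whose observed proportion falls
        inside the simulated band."""
        t = self.table.dropna(subset=["observed_prop", "lo95", "hi95"])
        inside = (t.observed_prop >= t.lo95) & (t.observed_prop <= t.hi95)
        return float(inside.mean())


def categorical_vpc(records, params: PopulationParams,
                    spec: CovariateSpec | None = None,
                    n_sim: int = 1000, seed: int | None = None) -> VpcSummary:
    """Categorical VPC of the model against an observed dataset.

    Simulates ``n_sim`` replicates on the observed design (same subjects,
    times, doses, covariates; no simulated dose adaptation) and, per cycle
    and grade, reports the observed proportion of subjects at that grade
    and the empirical 2.5-97.5 percentile band of the simulated
    proportions.  Cycles with no observed subjects are emitted as missing.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    spec = spec or CovariateSpec.final()
    records = [r for r in records if r.n_observations > 0]
    rng = np.random.default_rng(seed)
    sims = _simulate_grades(records, params, spec, rng, n_sim)
    max_c = sims.shape[2]

    # observation mask per subject x cycle, and observed grades
    n = len(records)
    mask = np.zeros((n, max_c), dtype=bool)
    obs = np.zeros((n, max_c), dtype=int)
    for i, r in enumerate(records):
        idx = r.times.astype(int) - 1
        mask[i, idx] = True
        obs[i, idx] = r.grades

    rows = []
    for c in range(max_c):
        m = mask[:, c]
        n_obs = int(m.sum())
        for g in range(4):
            if n_obs == 0:
                rows.append({"cycle": c + 1, "grade": g, "n_subjects": 0,
                             "observed_prop": np.nan, "lo95": np.nan,
                             "hi95": np.nan})
                continue
            obs_prop = float(np.mean(obs[m, c] == g))
            sim_props = np.mean(sims[:, m, c] == g, axis=1)  # (n_sim,)
            rows.append({
                "cycle": c + 1, "grade": g, "n_subjects": n_obs,
                "observed_prop": obs_prop,
                "lo95": float(np.percentile(sim_props, 2.5)),
                "hi95": float(np.percentile(sim_props, 97.5)),
            })
    return VpcSummary(table=pd.DataFrame(rows), n_sim=n_sim, seed=seed)
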