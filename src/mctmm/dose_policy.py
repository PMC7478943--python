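"""Virtual-cohort simulation of BSA-based dosing with and without
severity-driven dose adjustments.

Virtual patients start at the standard capecitabine monotherapy regimen of
1250 mg/m^2 twice daily (daily dose = 2 x 1250 x BSA).  Each cycle the
grade-probability state is propagated one cycle at the current dose, the
modal grade (highest probability, ties broken toward the lower grade) is
taken as the cycle's toxicity assessment, and — in the adjustment scenario —
the next cycle's dose follows the label's severity-driven modification
rules, expressed as fractions of the starting dose per (grade, occurrence
count).  Patients for whom a discontinuation would be recommended are kept
in the analysis so both scenarios retain the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import binom, truncnorm

from .model_core import (
    CovariateSpec,
    PopulationParams,
    grade_probabilities_batch,
    linear_predictors,
)
from .markov import transition_matrices_batch

__all__ = ["DoseAdjustmentRule", "ScenarioSummary", "sample_bsa",
           "run_scenario", "default_smpc_rule", "DISCONTINUE"]

#: Sentinel action: a treatment discontinuation would be recommended.
DISCONTINUE = "discontinue"


@dataclass(frozen=True)
class DoseAdjustmentRule:
    """Severity-driven dose modifications applied at cycle boundaries.

    ``actions[grade]`` is the sequence of actions over occurrence counts
    (1-based) of that grade; each entry is a fraction of the *starting*
    dose or :data:`DISCONTINUE`.  Counts beyond the sequence keep the last
    entry.  Grades absent from the mapping (0 and 1) always maintain the
    current dose.  Doses are never re-escalated.
    """

    actions: Mapping[int, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for grade, seq in self.actions.items():
            if grade <= 1:
                raise ValueError("grades <= 1 always maintain the dose")
            prev = np.inf
            for a in seq:
                if a == DISCONTINUE:
                    prev = 0.0
                    continue
                if not 0 < a <= 1:
                    raise ValueError(f"dose fraction must be in (0, 1], got {a}")
                if a > prev:
                    raise ValueError(
                        "dose fraction must be non-increasing with occurrence count")
                prev = a

    def action_for(self, grade: int, count: int):
        """Action for the ``count``-th occurrence of ``grade``; None means
        maintain."""
        seq = self.actions.get(int(grade))
        if not seq or count < 1:
            return None
        return seq[min(count, len(seq)) - 1]


def default_smpc_rule() -> DoseAdjustmentRule:
    """Label-style modification table for capecitabine: grade 2 at the
    2nd/3rd/4th occurrence -> 75%/50% of the starting dose/discontinue;
    grade 3 at the 1st/2nd/3rd occurrence -> 75%/50%/discontinue.
    Within-cycle interruptions collapse to the next cycle's dose change
    because the model has no within-cycle time axis."""
    return DoseAdjustmentRule(actions={
        2: (1.0, 0.75, 0.50, DISCONTINUE),
        3: (0.75, 0.50, DISCONTINUE),
    })


def sample_bsa(n: int, mean_m2: float = 1.8, sd_m2: float = 0.2,
               rng: np.random.Generator | None = None,
               low: float = 1.2, high: float = 2.6) -> np.ndarray:
    """Body surface areas (m^2): normal draws truncated to [low, high].

    The default mean/SD are implementer assumptions typical of adult
    oncology populations, not values from the source cohort (whose BSA was
    not recorded).
    """
    if mean_m2 <= 0 or sd_m2 < 0:
        raise ValueError("mean must be > 0 and sd >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    if sd_m2 == 0:
        return np.full(n, float(np.clip(mean_m2, low, high)))
    a, b = (low - mean_m2) / sd_m2, (high - mean_m2) / sd_m2
    return truncnorm.rvs(a, b, loc=mean_m2, scale=sd_m2, size=n,
                         random_state=rng)


def _median_ci(x: np.ndarray) -> tuple[float, float, float]:
    """Median and order-statistic (binomial) 95% CI of the median."""
    x = np.sort(x)
    n = len(x)
    j = int(binom.ppf(0.025, n, 0.5))
    k = int(binom.ppf(0.975, n, 0.5))
    j = max(j, 0)
    k = min(k, n - 1)
    return float(np.median(x)), float(x[j]), float(x[k])


@dataclass
class ScenarioSummary:
    """Outputs of one simulated dosing scenario."""

    probabilities: pd.DataFrame     # cycle, grade, median, lo95, hi95
    transition_counts: pd.DataFrame  # 4x4 modal-grade transition counts
    modal_grades: np.ndarray        # (n_cycles, n_patients)
    grade_probs: np.ndarray         # (n_cycles, n_patients, 4)
    dose_trail: np.ndarray          # (n_cycles, n_patients) dose during cycle
    discontinue_recommended: np.ndarray  # (n_patients,) bool
    seed: int | None
    adjusted: bool


def run_scenario(n_patients: int = 1000, n_cycles: int = 6,
                 params: PopulationParams | None = None,
                 rule: DoseAdjustmentRule | None = None,
                 bsa_mean: float = 1.8, bsa_sd: float = 0.2,
                 seed: int | None = None,
                 spec: CovariateSpec | None = None,
                 dose_per_m2: float = 1250.0,
                 reset: str = "none",
                 round_to: float | None = None) -> ScenarioSummary:
    """Simulate one dosing scenario over ``n_cycles`` cycles.

    With the same ``seed``, the BSA values and random effects are identical
    across scenarios, so a rule-vs-no-rule pair compares the same virtual
    patients.

    ``reset="none"`` (default) propagates each patient's full grade
    probability vector across cycles from the asymptomatic start, reading
    off the modal grade each cycle for toxicity assessment — the pure
    probability-dynamics reading of the simulation study.  ``reset="modal"``
    additionally collapses the state to the modal grade before each cycle;
    with the destination-probability rate construction this variant is
    degenerate at high doses (the exit rate from grade 0, pi_1/MET, shrinks
    as dose concentrates mass on high grades, so virtual patients never
    leave grade 0), and it is retained only as a diagnostic.
    ``round_to`` optionally rounds doses down to a tablet-strength multiple.
    """
    if params is None:
        params = PopulationParams.reference()
    spec = spec or CovariateSpec.final()
    if reset not in ("modal", "none"):
        raise ValueError("reset must be 'modal' or 'none'")
    rng = np.random.default_rng(seed)
    bsa = sample_bsa(n_patients, bsa_mean, bsa_sd, rng)
    eta_alpha = rng.normal(0.0, params.omega_alpha, n_patients)
    eta_met = rng.normal(0.0, params.omega_met, n_patients)

    start_dose = 2.0 * dose_per_m2 * bsa
    if round_to:
        start_dose = np.floor(start_dose / round_to) * round_to
    dose = start_dose.copy()

    modal = np.zeros((n_cycles, n_patients), dtype=int)
    probs_out = np.zeros((n_cycles, n_patients, 4))
    dose_trail = np.zeros((n_cycles, n_patients))
    counters = np.zeros((n_patients, 4), dtype=int)
    stopped = np.zeros(n_patients, dtype=bool)

    state_grade = np.zeros(n_patients, dtype=int)
    state_probs = np.zeros((n_patients, 4))
    state_probs[:, 0] = 1.0

    for c in range(n_cycles):
        dose_trail[c] = dose
        shift, log_met = linear_predictors(params, spec, dose)
        logits = params.intercepts + (shift + eta_alpha)[:, None]
        p = grade_probabilities_batch(logits)
        t = transition_matrices_batch(p, np.exp(log_met + eta_met), 1.0)
        if reset == "modal":
            probs = t[np.arange(n_patients), state_grade]
        else:
            probs = np.einsum("ni,nij->nj", state_probs, t)
            state_probs = probs
        probs_out[c] = probs
        g = probs.argmax(axis=1)        # ties break toward the lower grade
        modal[c] = g
        state_grade = g
        counters[np.arange(n_patients), g] += 1

        if rule is not None and c < n_cycles - 1:
            new_dose = dose.copy()
            for grade in rule.actions:
                hit = g == grade
                if not hit.any():
                    continue
                for i in np.flatnonzero(hit):
                    action = rule.action_for(grade, counters[i, grade])
                    if action is None:
                        continue
                    if action == DISCONTINUE:
                        stopped[i] = True  # kept in analysis at last dose
                    else:
                        frac_dose = action * start_dose[i]
                        if round_to:
                            frac_dose = np.floor(frac_dose / round_to) * round_to
                        new_dose[i] = min(new_dose[i], frac_dose)
            dose = new_dose

    rows = []
    for c in range(n_cycles):
        for grade in range(4):
            med, lo, hi = _median_ci(probs_out[c, :, grade])
            rows.append({"cycle": c + 1, "grade": grade, "median": med,
                         "lo95": lo, "hi95": hi})
    trans = np.zeros((4, 4), dtype=int)
    for c in range(1, n_cycles):
        np.add.at(trans, (modal[c - 1], modal[c]), 1)
    return ScenarioSummary(
        probabilities=pd.DataFrame(rows),
        transition_counts=pd.DataFrame(
            trans, index=[f"from_{i}" for i in range(4)],
            columns=[f"to_{j}" for j in range(4)]),
        modal_grades=modal, grade_probs=probs_out, dose_trail=dose_trail,
        discontinue_recommended=stopped, seed=seed, adjusted=rule is not None)
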