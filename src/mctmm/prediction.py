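"""Individual predictive assessment: empirical-Bayes random effects and
next-cycle grade prediction with PPV/NPV summaries.

For each patient and each cycle k >= 2, the random effects are estimated
from the observations up to cycle k-1 as the mode of the per-subject
posterior (MAP / empirical Bayes, population parameters fixed), the grade
distribution at cycle k is propagated from the last observed grade at the
known dose schedule, and the modal grade is compared with the observed one.
Predictions are grouped into clinically relevant (grade >= 2) versus not
(grade <= 1); the positive and negative predictive values are the fractions
of correct predictions within each predicted group.  Baseline is excluded
(it is deterministic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import PatientRecord, pack
from .likelihood import inner_modes
from .markov import interval_transition_matrix
from .model_core import (
    CovariateSpec,
    EtaPair,
    GradeDistribution,
    PopulationParams,
)

__all__ = ["map_eta", "predict_next_cycle", "prediction_table",
           "ppv_npv", "ppv_npv_by_cycle"]


def map_eta(record: PatientRecord, params: PopulationParams,
            spec: CovariateSpec | None = None,
            upto_cycle: float | None = None) -> EtaPair:
    """MAP (empirical-Bayes) random effects from observations up to
    ``upto_cycle`` (all observations if None).  With no usable
    observations, or zero random-effect variances, returns the prior
    mode eta = 0."""
    spec = spec or CovariateSpec.final()
    rec = record if upto_cycle is None else record.truncated(upto_cycle)
    if rec.n_observations == 0:
        return EtaPair(0.0, 0.0)
    packed = pack([rec])
    eta_hat, _, _, active = inner_modes(packed, params, spec)
    full = np.zeros(2)
    for k, dim in enumerate(active):
        full[dim] = eta_hat[0, k]
    return EtaPair(float(full[0]), float(full[1]))


def predict_next_cycle(record: PatientRecord, params: PopulationParams,
                       spec: CovariateSpec | None = None,
                       eta: EtaPair | None = None,
                       at_cycle: float | None = None,
                       ) -> tuple[GradeDistribution, int]:
    """Grade distribution and modal grade at ``at_cycle``.

    Propagates from the last observation before ``at_cycle`` (or baseline)
    over the intervening cycles at the recorded per-cycle doses.  Ties in
    the modal grade break toward the lower grade.
    """
    spec = spec or CovariateSpec.final()
    eta = eta or EtaPair()
    if at_cycle is None:
        at_cycle = (record.times.max() if record.n_observations else 0) + 1
    at_cycle = int(at_cycle)
    prev = record.truncated(at_cycle - 1)
    if prev.n_observations:
        last_t = int(prev.times.max())
        last_g = int(prev.grades[np.argmax(prev.times)])
    else:
        last_t, last_g = 0, 0
    if at_cycle > len(record.cycle_doses):
        raise ValueError(
            f"no dose recorded for cycle {at_cycle} of {record.patient_id}")
    doses = record.cycle_doses[last_t:at_cycle]
    times = np.arange(last_t + 1, at_cycle + 1, dtype=float)
    tm = interval_transition_matrix(params, eta, doses,
                                    spec=spec, cov=record.covariates,
                                    times=times)
    dist = GradeDistribution(tm.t_mat[last_g])
    return dist, int(np.argmax(dist.p))


def prediction_table(records, params: PopulationParams,
                     spec: CovariateSpec | None = None,
                     cycles=range(2, 7)) -> pd.DataFrame:
    """Predicted versus observed modal grades for cycles 2..6.

    For each target cycle the MAP random effects are re-estimated from the
    observations before it (batched across subjects); subjects without an
    observation at the target cycle contribute no row.
    """
    spec = spec or CovariateSpec.final()
    records = list(records)
    rows = []
    for cyc in cycles:
        todo = [(r, int(np.flatnonzero(r.times == cyc)[0]))
                for r in records if np.any(r.times == cyc)
                and cyc <= len(r.cycle_doses)]
        if not todo:
            continue
        prefixes = [r.truncated(cyc - 1) for r, _ in todo]
        nonempty = [i for i, p in enumerate(prefixes) if p.n_observations > 0]
        etas = np.zeros((len(todo), 2))
        if nonempty:
            packed = pack([prefixes[i] for i in nonempty])
            eta_hat, _, _, active = inner_modes(packed, params, spec)
            for k, dim in enumerate(active):
                etas[nonempty, dim] = eta_hat[:, k]
        for (r, j), eta in zip(todo, etas):
            _, modal = predict_next_cycle(
                r, params, spec, EtaPair(*eta), at_cycle=cyc)
            rows.append({"patient_id": r.patient_id, "cycle": cyc,
                         "predicted": modal, "observed": int(r.grades[j])})
    df = pd.DataFrame(rows, columns=["patient_id", "cycle",
                                     "predicted", "observed"])
    if len(df):
        df["predicted_relevant"] = df.predicted >= 2
        df["observed_relevant"] = df.observed >= 2
    return df


def ppv_npv(table: pd.DataFrame) -> tuple[float, float]:
    """Positive and negative predictive values of the grade >= 2 grouping.

    PPV = correct grade >= 2 predictions / all grade >= 2 predictions;
    NPV likewise for grade <= 1.  An empty denominator yields NaN.
    """
    if table.empty:
        raise ValueError("prediction table is empty")
    pos = table[table.predicted >= 2]
    neg = table[table.predicted <= 1]
    ppv = float((pos.observed >= 2).mean()) if len(pos) else float("nan")
    npv = float((neg.observed <= 1).mean()) if len(neg) else float("nan")
    return ppv, npv


def ppv_npv_by_cycle(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cycle PPV/NPV plus a pooled all-cycles row."""
    rows = []
    for cyc, sub in table.groupby("cycle"):
        ppv, npv = ppv_npv(sub)
        rows.append({"cycle": cyc, "n": len(sub), "ppv": ppv, "npv": npv})
    ppv, npv = ppv_npv(table)
    rows.append({"cycle": "pooled", "n": len(table), "ppv": ppv, "npv": npv})
    return pd.DataFrame(rows)
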