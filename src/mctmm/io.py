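"""Dataset and configuration I/O, plus the end-to-end pipeline runner.

The dataset format is a long-format CSV in the conventional nonlinear
mixed-effects layout: one baseline row (CYCLE 0, TIME 0, DV 0) per subject,
then one row per treatment cycle carrying the daily dose during that cycle
(DOSE, mg/day over the cycle ending at TIME) and the questionnaire grade at
the cycle end (DV, blank when no questionnaire was returned).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import PatientRecord
from .dose_policy import (
    DISCONTINUE,
    DoseAdjustmentRule,
    default_smpc_rule,
    run_scenario,
)
from .estimation import bootstrap, fit
from .model_core import CovariateSpec, CovariateVector, PopulationParams
from .prediction import ppv_npv_by_cycle, prediction_table
from .simulate import categorical_vpc

__all__ = ["read_dataset", "write_dataset", "read_params", "write_params",
           "read_rule", "records_from_frame", "records_to_frame",
           "AnalysisConfig", "run_pipeline", "DatasetFormatError"]

logger = logging.getLogger(__name__)

COLUMNS = ["ID", "CYCLE", "TIME", "DOSE", "DV",
           "AGE", "SEX", "ENTITY", "MONO", "ADH"]


class DatasetFormatError(ValueError):
    """The dataset violates the long-format contract."""


#: Fixed cycle duration; time is expressed in cycle units throughout the
#: package, these converters exist for display only.
CYCLE_DAYS = 21.0


def days_to_cycles(days: float) -> float:
    return days / CYCLE_DAYS


def cycles_to_days(cycles: float) -> float:
    return cycles * CYCLE_DAYS


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        cov = r.covariates
        base = {"ID": r.patient_id, "AGE": cov.age, "SEX": cov.sex,
                "ENTITY": cov.entity, "MONO": int(cov.monotherapy),
                "ADH": cov.adherence_group}
        rows.append({**base, "CYCLE": 0, "TIME": 0.0, "DOSE": np.nan, "DV": 0})
        obs = {int(t): int(g) for t, g in zip(r.times, r.grades)}
        for c, dose in enumerate(r.cycle_doses, start=1):
            rows.append({**base, "CYCLE": c, "TIME": float(c), "DOSE": dose,
                         "DV": obs.get(c, np.nan)})
    return pd.DataFrame(rows, columns=COLUMNS)


def write_dataset(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    """Validated records from a long-format frame.

    Raises :class:`DatasetFormatError` naming the offending row (1-based,
    header excluded) for unknown grades, non-increasing times, or a missing
    baseline row.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing columns: {missing}")
    records = []
    for pid, sub in df.groupby("ID", sort=False):
        sub = sub.sort_values("TIME", kind="stable")
        base = sub[sub.CYCLE == 0]
        if len(base) != 1 or float(base.TIME.iloc[0]) != 0.0:
            raise DatasetFormatError(
                f"subject {pid!r}: exactly one baseline row "
                "(CYCLE 0, TIME 0) is required")
        if not pd.isna(base.DV.iloc[0]) and int(base.DV.iloc[0]) != 0:
            raise DatasetFormatError(
                f"subject {pid!r} row {base.index[0] + 1}: baseline grade "
                "must be 0 (patients start asymptomatic)")
        cyc = sub[sub.CYCLE > 0]
        times, grades, doses = [], [], []
        prev_t = 0.0
        for idx, row in cyc.iterrows():
            t = float(row.TIME)
            if t <= prev_t:
                raise DatasetFormatError(
                    f"subject {pid!r} row {idx + 1}: TIME {t} is not "
                    "strictly increasing")
            prev_t = t
            doses.append(float(row.DOSE))
            if not pd.isna(row.DV):
                g = float(row.DV)
                if g not in (0.0, 1.0, 2.0, 3.0):
                    raise DatasetFormatError(
                        f"subject {pid!r} row {idx + 1}: grade {row.DV!r} "
                        "is not in 0..3")
                times.append(t)
                grades.append(int(g))
        first = sub.iloc[0]
        cov = CovariateVector(
            daily_dose=float(np.nanmax(doses)) if doses else 3000.0,
            age=float(first.AGE), sex=str(first.SEX),
            entity=str(first.ENTITY), monotherapy=bool(int(first.MONO)),
            adherence_group=str(first.ADH))
        doses = np.asarray(doses)
        disc = _infer_discontinuation(doses)
        try:
            records.append(PatientRecord(
                patient_id=str(pid), times=np.asarray(times),
                grades=np.asarray(grades), cycle_doses=doses,
                covariates=cov, discontinuation_cycle=disc))
        except ValueError as exc:
            raise DatasetFormatError(f"subject {pid!r}: {exc}") from exc
    return records


def _infer_discontinuation(doses: np.ndarray) -> int | None:
    """Cycle after which all doses are zero (None if never dosed or dosed
    to the end)."""
    pos = np.flatnonzero(doses > 0)
    if len(pos) == 0 or pos[-1] == len(doses) - 1:
        return None
    return int(pos[-1]) + 1


def read_dataset(path) -> list[PatientRecord]:
    df = pd.read_csv(path)
    return records_from_frame(df)


# ---------------------------------------------------------------------------
# Parameter and rule files

PARAM_KEYS = ["alpha1", "b2", "b3", "met", "theta_dose",
              "omega_alpha", "omega_met", "dose_center"]


def write_params(params: PopulationParams, path,
                 dose_center: float = 3000.0) -> None:
    payload = {"alpha1": params.alpha1, "b2": params.b2, "b3": params.b3,
               "met": params.met, "theta_dose": params.theta_dose,
               "omega_alpha": params.omega_alpha,
               "omega_met": params.omega_met, "dose_center": dose_center}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_params(path) -> tuple[PopulationParams, float]:
    """Returns (params, dose_center)."""
    payload = yaml.safe_load(Path(path).read_text())
    unknown = set(payload) - set(PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    dose_center = float(payload.pop("dose_center", 3000.0))
    return PopulationParams(**{k: float(v) for k, v in payload.items()}), dose_center


def read_rule(path) -> DoseAdjustmentRule:
    """Dose-adjustment rule from a YAML mapping grade -> list of dose
    fractions (of the starting dose) or the string 'discontinue'."""
    payload = yaml.safe_load(Path(path).read_text())
    actions = {}
    for grade, seq in payload.items():
        actions[int(grade)] = tuple(
            DISCONTINUE if a == DISCONTINUE else float(a) for a in seq)
    return DoseAdjustmentRule(actions=actions)


# ---------------------------------------------------------------------------
# Pipeline

@dataclass
class AnalysisConfig:
    """Configuration of the end-to-end pipeline run."""

    dataset: str
    output_dir: str
    params_file: str | None = None
    method: str = "laplace"
    n_sim: int = 1000
    n_bootstrap: int = 0
    n_virtual_patients: int = 1000
    n_cycles: int = 6
    bsa_mean: float = 1.8
    bsa_sd: float = 0.2
    seed: int = 12345
    compute_se: bool = True

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute fit -> bootstrap -> VPC -> dose simulation -> prediction.

    Writes a parameter table, VPC table, scenario summaries, the PPV/NPV
    table, and a manifest recording seeds, versions, and a config hash.
    Stage failures raise with the stage name; artifacts written before the
    failure are left in place.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    timings: dict = {}

    def stage(name, fn):
        t0 = _time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(_time.perf_counter() - t0, 3)
        logger.info("stage %s finished in %.1fs", name, timings[name])
        return result

    records = stage("read", lambda: read_dataset(config.dataset))
    if config.params_file:
        start, dose_center = read_params(config.params_file)
    else:
        start, dose_center = PopulationParams.reference(), 3000.0
    spec = CovariateSpec.final(dose_center=dose_center)

    result = stage("fit", lambda: fit(
        records, start, spec, method=config.method,
        compute_se=config.compute_se))
    table = result.parameter_table()

    if config.n_bootstrap > 0:
        boot = stage("bootstrap", lambda: bootstrap(
            records, result.estimates, spec, n_replicates=config.n_bootstrap,
            seed=config.seed, method=config.method))
        table = table.merge(boot.table(), on="parameter", how="left")
    table.to_csv(out / "parameter_table.csv", index=False)
    artifacts["parameter_table"] = str(out / "parameter_table.csv")

    vpc = stage("vpc", lambda: categorical_vpc(
        records, result.estimates, spec, n_sim=config.n_sim,
        seed=config.seed + 1))
    vpc.table.to_csv(out / "vpc.csv", index=False)
    artifacts["vpc"] = str(out / "vpc.csv")

    def dose_sim():
        kwargs = dict(n_patients=config.n_virtual_patients,
                      n_cycles=config.n_cycles, params=result.estimates,
                      bsa_mean=config.bsa_mean, bsa_sd=config.bsa_sd,
                      seed=config.seed + 2, spec=spec)
        return (run_scenario(rule=None, **kwargs),
                run_scenario(rule=default_smpc_rule(), **kwargs))

    no_adj, adj = stage("dose_sim", dose_sim)
    for label, scen in (("no_adjustment", no_adj), ("smpc_adjustment", adj)):
        scen.probabilities.to_csv(out / f"dose_sim_{label}.csv", index=False)
        scen.transition_counts.to_csv(out / f"dose_sim_{label}_transitions.csv")
        artifacts[f"dose_sim_{label}"] = str(out / f"dose_sim_{label}.csv")

    ptab = stage("predict", lambda: prediction_table(
        records, result.estimates, spec))
    ptab.to_csv(out / "prediction_table.csv", index=False)
    ppv_npv_by_cycle(ptab).to_csv(out / "ppv_npv.csv", index=False)
    artifacts["prediction_table"] = str(out / "prediction_table.csv")
    artifacts["ppv_npv"] = str(out / "ppv_npv.csv")

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config),
                       sort_keys=True).encode()).hexdigest(),
        "seeds": {"bootstrap": config.seed, "vpc": config.seed + 1,
                  "dose_sim": config.seed + 2},
        "ofv": result.ofv,
        "convergence": result.convergence,
        "n_subjects": result.n_subjects,
        "n_observations": result.n_observations,
        "timings_seconds": timings,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = str(out / "manifest.json")
    return manifest
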