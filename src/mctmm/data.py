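"""Longitudinal patient records and their packed array form.

A :class:`PatientRecord` holds one subject's questionnaire series: grade
observations at integer cycle times (one questionnaire per 3-week cycle, up
to six), the per-cycle daily-dose schedule, and baseline covariates.  All
subjects start asymptomatic, so the baseline grade at time 0 is fixed at 0.

:class:`PackedData` flattens a cohort into index arrays for the vectorized
likelihood kernel: each observation interval is split into per-cycle
segments of constant dose, and intervals are grouped contiguously by
subject so per-subject log-likelihoods reduce to a single ``reduceat``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_core import CovariateVector, _COVARIATE_VALUES

__all__ = ["PatientRecord", "PackedData", "pack"]

MAX_OCCASIONS = 6


@dataclass
class PatientRecord:
    """One subject's dose history, grade observations, and covariates.

    ``times`` are strictly increasing integer cycle indices (>= 1); the
    implicit baseline observation is grade 0 at time 0.  ``cycle_doses[c-1]``
    is the daily dose (mg) during cycle ``c``, i.e. over ``(c-1, c]``.
    """

    patient_id: str
    times: np.ndarray
    grades: np.ndarray
    cycle_doses: np.ndarray
    covariates: CovariateVector = field(default_factory=CovariateVector)
    discontinuation_cycle: int | None = None
    baseline_grade: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.grades = np.asarray(self.grades, dtype=int)
        self.cycle_doses = np.asarray(self.cycle_doses, dtype=float)
        if self.baseline_grade != 0:
            raise ValueError("baseline grade is fixed at 0 (asymptomatic at start)")
        if self.times.shape != self.grades.shape:
            raise ValueError("times and grades must have equal length")
        if len(self.times) > MAX_OCCASIONS:
            raise ValueError(
                f"at most {MAX_OCCASIONS} observation occasions per patient, "
                f"got {len(self.times)}")
        if len(self.times):
            if np.any(np.diff(np.concatenate([[0.0], self.times])) <= 0):
                raise ValueError(
                    f"cycle times must be strictly increasing and > 0, got {self.times}")
            if np.any((self.grades < 0) | (self.grades > 3)):
                raise ValueError(f"grades must be in 0..3, got {self.grades}")
            if len(self.cycle_doses) < int(self.times.max()):
                raise ValueError(
                    "dose schedule must cover every observed cycle "
                    f"(need {int(self.times.max())}, got {len(self.cycle_doses)})")
        if np.any(self.cycle_doses < 0):
            raise ValueError("doses must be >= 0")
        if self.discontinuation_cycle is not None:
            after = self.cycle_doses[self.discontinuation_cycle:]
            if np.any(after != 0):
                raise ValueError(
                    "doses must be 0 for all cycles after discontinuation "
                    f"(cycle {self.discontinuation_cycle})")

    @property
    def n_observations(self) -> int:
        return len(self.times)

    def truncated(self, upto_cycle: float) -> "PatientRecord":
        """Copy keeping only observations at times <= ``upto_cycle``."""
        keep = self.times <= upto_cycle
        return PatientRecord(
            patient_id=self.patient_id,
            times=self.times[keep],
            grades=self.grades[keep],
            cycle_doses=self.cycle_doses,
            covariates=self.covariates,
            discontinuation_cycle=self.discontinuation_cycle,
        )


@dataclass
class PackedData:
    """Cohort flattened into kernel-ready arrays.

    Segments are (interval, cycle) pairs of constant dose; intervals are
    consecutive-observation pairs including baseline -> first observation.
    """

    n_subjects: int
    subject_ids: list
    # per segment
    seg_sub: np.ndarray        # subject index
    seg_dose: np.ndarray       # daily dose during the segment (mg)
    seg_time: np.ndarray       # cycle time at segment end
    seg_elapsed: np.ndarray    # segment length (cycles)
    # chain-product schedule
    first_seg: np.ndarray      # per interval: segment index at position 0
    chain_steps: list          # [(interval_idx, seg_idx), ...] per position >= 1
    # per interval
    int_sub: np.ndarray
    int_from: np.ndarray
    int_to: np.ndarray
    # per-subject reduction (intervals grouped by subject)
    red_starts: np.ndarray     # reduceat starts into interval axis
    red_sub: np.ndarray        # subject index per reduceat group
    n_observations: int
    # per-subject static covariate regressors, keyed by covariate name
    subject_regressors: dict = field(default_factory=dict)


def pack(records: Sequence[PatientRecord]) -> PackedData:
    """Flatten records for the vectorized likelihood kernel.

    Subjects observed only at baseline contribute no interval (baseline is
    deterministic) and drop out of the likelihood, but keep a subject index
    so random-effect arrays stay aligned with the input order.
    """
    seg_sub, seg_dose, seg_time, seg_elapsed = [], [], [], []
    int_sub, int_from, int_to, int_nseg = [], [], [], []
    first_seg, chain = [], []
    n_obs = 0
    for s, rec in enumerate(records):
        prev_t, prev_g = 0.0, 0
        n_obs += rec.n_observations
        for t, g in zip(rec.times, rec.grades):
            # cycles prev_t+1 .. t, each one segment of constant dose
            cycles = np.arange(int(np.floor(prev_t)) + 1, int(np.floor(t)) + 1)
            first_seg.append(len(seg_sub))
            for pos, c in enumerate(cycles):
                if pos >= 1:
                    chain.append((len(int_sub), len(seg_sub)))
                seg_sub.append(s)
                seg_dose.append(rec.cycle_doses[c - 1])
                seg_time.append(float(c))
                seg_elapsed.append(1.0)
            int_sub.append(s)
            int_from.append(prev_g)
            int_to.append(g)
            int_nseg.append(len(cycles))
            prev_t, prev_g = t, g

    int_sub = np.asarray(int_sub, dtype=int)
    # group intervals contiguously by subject (input order already is)
    if len(int_sub):
        starts = np.flatnonzero(np.diff(int_sub, prepend=int_sub[0] - 1))
        red_sub = int_sub[starts]
    else:
        starts = np.zeros(0, dtype=int)
        red_sub = np.zeros(0, dtype=int)

    # group chain steps by position for batched products
    chain_steps: list = []
    if chain:
        by_int: dict = {}
        for i, (iv, sg) in enumerate(chain):
            by_int.setdefault(iv, []).append(sg)
        max_pos = max(len(v) for v in by_int.values())
        for pos in range(max_pos):
            ivs = [iv for iv, v in by_int.items() if len(v) > pos]
            sgs = [by_int[iv][pos] for iv in ivs]
            chain_steps.append((np.asarray(ivs), np.asarray(sgs)))

    regressors = {}
    for name, fn in _COVARIATE_VALUES.items():
        if name in ("daily_dose", "time"):
            continue
        regressors[name] = np.array([fn(r.covariates, 0.0) for r in records])

    return PackedData(
        n_subjects=len(records),
        subject_ids=[r.patient_id for r in records],
        seg_sub=np.asarray(seg_sub, dtype=int),
        seg_dose=np.asarray(seg_dose, dtype=float),
        seg_time=np.asarray(seg_time, dtype=float),
        seg_elapsed=np.asarray(seg_elapsed, dtype=float),
        first_seg=np.asarray(first_seg, dtype=int),
        chain_steps=chain_steps,
        int_sub=int_sub,
        int_from=np.asarray(int_from, dtype=int),
        int_to=np.asarray(int_to, dtype=int),
        red_starts=starts,
        red_sub=red_sub,
        n_observations=n_obs,
        subject_regressors=regressors,
    )
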