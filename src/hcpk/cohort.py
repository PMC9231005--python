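"""Synthetic study cohorts and the event/observation dataset format.

The generator emulates a randomized double-blind crossover design in
secondary adrenal insufficiency: each subject receives a low hydrocortisone
dose (0.2-0.3 mg/kg/day) in one period and a high dose (0.4-0.6 mg/kg/day)
in the other, given as three divided daily doses (7:00, 13:00, 19:00,
default split 4:2:1, rounded to 0.5 mg).  On the visit day of each period a
blood sample is drawn ~1 h after the 7:00 dose and again ~5-6 h later; each
sample is assayed for both free and total hydrocortisone.  Individual
(V, CL, RC) are drawn from the population IIV model, covariates (weight,
albumin, total CBG) from fixed physiological distributions, and
observations carry combined additive + proportional residual noise.

The on-disk format is a single flat CSV mixing dose rows and observation
rows (NONMEM-style event list), one subject's covariates repeated on each
of its rows.  ``read_dataset(write_dataset(x)) == x`` field for field.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import BindingSystem, total_from_free
from .pkmodel import DoseEvent, PKParameters, simulate_free
from .population import PopulationModel

__all__ = [
    "StudyDesign",
    "Observation",
    "SubjectRecord",
    "CohortTruth",
    "generate",
    "write_dataset",
    "read_dataset",
    "noise_model",
    "rich_design",
]

logger = logging.getLogger(__name__)

PERIODS = ("low", "high")

#: Covariate distributions (implementer defaults; physiologically typical,
#: not taken from any study table): weight ~ Normal(80, 15) kg truncated to
#: [50, 120]; albumin ~ log-normal, median 600,000 nM, CV 10%; total CBG ~
#: log-normal, median 700 nM, CV 20%.
WEIGHT_MEAN, WEIGHT_SD, WEIGHT_RANGE = 80.0, 15.0, (50.0, 120.0)
ALBUMIN_MEDIAN, ALBUMIN_CV = 600_000.0, 0.10
CBG_MEDIAN, CBG_CV = 700.0, 0.20


@dataclass(frozen=True)
class StudyDesign:
    """Crossover study layout and sampling scheme.

    Dose levels are daily totals in mg/kg/day, drawn uniformly within each
    band.  ``sample_offsets`` (hours after the 7:00 dose on the visit day)
    overrides the default sparse scheme of one sample at
    ``first_sample_offset`` and a second one 5-6 h later.
    """

    n_subjects: int = 46
    low_dose: tuple[float, float] = (0.2, 0.3)
    high_dose: tuple[float, float] = (0.4, 0.6)
    split_ratio: tuple[float, float, float] = (4.0, 2.0, 1.0)
    dose_times: tuple[float, float, float] = (7.0, 13.0, 19.0)
    first_sample_offset: float = 1.0
    second_sample_gap: tuple[float, float] = (5.0, 6.0)
    sample_offsets: tuple[float, ...] | None = None
    run_in_days: int = 3
    period_gap_days: int = 7
    dose_granularity_mg: float = 0.5

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        for name, band in (("low_dose", self.low_dose),
                           ("high_dose", self.high_dose)):
            if not (0 < band[0] <= band[1]):
                raise ValueError(f"{name} band must satisfy 0 < lo <= hi")
        if not self.low_dose[1] <= self.high_dose[0]:
            raise ValueError("low dose band must lie below the high band")
        if min(self.split_ratio) < 0 or sum(self.split_ratio) <= 0:
            raise ValueError("split_ratio must be nonnegative, positive sum")
        if self.sample_offsets is not None:
            if any(not 0.0 < o < 12.0 for o in self.sample_offsets):
                raise ValueError("sample_offsets must lie within (0, 12) h")
        if not 0.0 < self.first_sample_offset < 12.0:
            raise ValueError("first_sample_offset must lie within (0, 12) h")
        if self.run_in_days < 1:
            raise ValueError("run_in_days must be >= 1")


def rich_design(n_subjects: int = 46) -> StudyDesign:
    """A rich-sampling variant: 12 draws per subject per period.

    Offsets span the dosing day from shortly after the morning dose to late
    evening; used for residual-error re-estimation, which is poorly
    identified under the sparse two-sample scheme.
    """
    return StudyDesign(
        n_subjects=n_subjects,
        sample_offsets=(0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0,
                        6.0, 8.0, 10.0, 11.5),
    )


@dataclass(frozen=True)
class Observation:
    time: float          # h from study start
    value: float         # nM, on the analyte's scale
    kind: str            # 'free' | 'total'
    period: str          # 'low' | 'high'

    def __post_init__(self) -> None:
        if self.kind not in ("free", "total"):
            raise ValueError(f"unknown observation kind {self.kind!r}")
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}")
        if self.value < 0:
            raise ValueError(f"observation value must be >= 0, got {self.value}")


@dataclass(frozen=True)
class SubjectRecord:
    """Covariates, dose history and observations for one subject."""

    id: str
    weight: float            # kg
    TotA: float              # albumin, nM
    TotC_total: float        # total CBG, nM
    doses: tuple[DoseEvent, ...] = ()
    observations: tuple[Observation, ...] = ()

    def binding_system(self, RC: float, constants=None) -> BindingSystem:
        kw = {} if constants is None else {"constants": constants}
        return BindingSystem(self.TotA, self.TotC_total, RC, **kw)


@dataclass(frozen=True)
class CohortTruth:
    """Ground-truth ledger kept alongside every generated dataset."""

    individual: pd.DataFrame          # subject_id, V, CL, RC, weight, ...
    generating: PopulationModel

    def to_frame(self) -> pd.DataFrame:
        return self.individual.copy()


def noise_model(f, sigma_add: float, sigma_prop: float,
                rng: np.random.Generator):
    """Observed value y = f*(1 + eps_prop) + eps_add, truncated at zero.

    ``eps_prop ~ N(0, sigma_prop^2)`` and ``eps_add ~ N(0, sigma_add^2)``;
    draws that land below zero are clipped to 0 and counted in the log.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("prediction f must be >= 0")
    y = (f * (1.0 + sigma_prop * rng.standard_normal(f.shape))
         + sigma_add * rng.standard_normal(f.shape))
    n_neg = int(np.sum(y < 0))
    if n_neg:
        logger.info("noise_model truncated %d negative draw(s) to 0", n_neg)
    y = np.clip(y, 0.0, None)
    return y if y.ndim else float(y)


def _round_to(x: float, granularity: float) -> float:
    return max(granularity, round(x / granularity) * granularity)


def _period_schedule(design: StudyDesign, order: tuple[str, str]
                     ) -> dict[str, float]:
    """Start hour (study time) of each period's dosing block."""
    block = (design.run_in_days + design.period_gap_days) * 24.0
    return {order[0]: 0.0, order[1]: block}


def _subject_doses(design: StudyDesign, daily_mg: dict[str, float],
                   start_h: dict[str, float]) -> list[DoseEvent]:
    ratio = np.asarray(design.split_ratio, float)
    ratio = ratio / ratio.sum()
    doses: list[DoseEvent] = []
    for period in PERIODS:
        amounts = [_round_to(daily_mg[period] * r, design.dose_granularity_mg)
                   for r in ratio]
        for day in range(design.run_in_days + 1):   # run-in + visit day
            for t_clock, amt in zip(design.dose_times, amounts):
                doses.append(DoseEvent(
                    time=start_h[period] + 24.0 * day + t_clock, amount=amt))
    return doses


def _sample_times(design: StudyDesign, visit_h: float,
                  rng: np.random.Generator) -> list[float]:
    """Blood-draw times (study h) on a visit day starting at ``visit_h``."""
    t0 = visit_h + design.dose_times[0]
    if design.sample_offsets is not None:
        return [t0 + o for o in design.sample_offsets]
    first = t0 + design.first_sample_offset
    second = first + rng.uniform(*design.second_sample_gap)
    return [first, second]


def generate(design: StudyDesign, pop: PopulationModel, seed: int,
             *, fixed: PKParameters | None = None,
             constants=None) -> tuple[list[SubjectRecord], CohortTruth]:
    """Simulate a full crossover cohort from the population model.

    ``fixed`` supplies the non-estimated structural constants (ka, tlag,
    F_bio); its V/CL/RC entries are ignored.  Identical seeds give
    byte-identical datasets.
    """
    rng = np.random.default_rng(seed)
    fixed = fixed or PKParameters(V=1.0, CL=1.0)

    records: list[SubjectRecord] = []
    truth_rows: list[dict] = []
    thetas = pop.sample_individuals(design.n_subjects, rng)
    for i in range(design.n_subjects):
        sid = f"S{i + 1:03d}"
        # covariates
        while True:
            w = rng.normal(WEIGHT_MEAN, WEIGHT_SD)
            if WEIGHT_RANGE[0] <= w <= WEIGHT_RANGE[1]:
                break
        TotA = ALBUMIN_MEDIAN * np.exp(
            np.sqrt(np.log1p(ALBUMIN_CV**2)) * rng.standard_normal())
        TotC = CBG_MEDIAN * np.exp(
            np.sqrt(np.log1p(CBG_CV**2)) * rng.standard_normal())
        V, CL, RC = thetas[i]

        order = ("low", "high") if rng.uniform() < 0.5 else ("high", "low")
        daily = {"low": rng.uniform(*design.low_dose) * w,
                 "high": rng.uniform(*design.high_dose) * w}
        start_h = _period_schedule(design, order)
        doses = _subject_doses(design, daily, start_h)

        params = PKParameters(V=V, CL=CL, ka=fixed.ka, tlag=fixed.tlag,
                              F_bio=fixed.F_bio, RC=RC)
        system = BindingSystem(TotA, TotC, RC,
                               **({} if constants is None
                                  else {"constants": constants}))
        obs: list[Observation] = []
        for period in PERIODS:
            visit_h = start_h[period] + design.run_in_days * 24.0
            times = _sample_times(design, visit_h, rng)
            free = simulate_free(doses, params, times)
            total = np.atleast_1d(total_from_free(free, system))
            for t, f_free, f_tot in zip(times, free, total):
                y_free = noise_model(f_free, pop.sigma_add, pop.sigma_prop, rng)
                y_tot = noise_model(f_tot, pop.sigma_add, pop.sigma_prop, rng)
                obs.append(Observation(t, float(y_free), "free", period))
                obs.append(Observation(t, float(y_tot), "total", period))

        records.append(SubjectRecord(
            id=sid, weight=float(w), TotA=float(TotA), TotC_total=float(TotC),
            doses=tuple(doses), observations=tuple(obs)))
        truth_rows.append({"subject_id": sid, "V": V, "CL": CL, "RC": RC,
                           "weight": float(w), "TotA": float(TotA),
                           "TotC_total": float(TotC),
                           "order": "-".join(order)})

    truth = CohortTruth(
        individual=pd.DataFrame(
            truth_rows, columns=["subject_id", "V", "CL", "RC", "weight",
                                 "TotA", "TotC_total", "order"]),
        generating=pop)
    return records, truth


_COLUMNS = ["subject_id", "weight_kg", "albumin_nM", "cbg_nM", "row_type",
            "time_h", "amount_mg", "release", "lag_h", "rate_mg_per_h",
            "value_nM", "kind", "period"]


def write_dataset(dataset: list[SubjectRecord], path) -> None:
    """Serialise a cohort to the flat event/observation CSV."""
    rows = []
    for s in dataset:
        # repr() keeps full double precision so the round trip is exact
        base = {"subject_id": s.id, "weight_kg": repr(s.weight),
                "albumin_nM": repr(s.TotA), "cbg_nM": repr(s.TotC_total)}
        for d in s.doses:
            rows.append({**base, "row_type": "dose", "time_h": repr(d.time),
                         "amount_mg": repr(d.amount), "release": d.release,
                         "lag_h": repr(d.lag),
                         "rate_mg_per_h": "" if d.rate is None else repr(d.rate),
                         "value_nM": "", "kind": "", "period": ""})
        for o in s.observations:
            rows.append({**base, "row_type": "obs", "time_h": repr(o.time),
                         "amount_mg": "", "release": "", "lag_h": "",
                         "rate_mg_per_h": "", "value_nM": repr(o.value),
                         "kind": o.kind, "period": o.period})
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


class DatasetFormatError(ValueError):
    """Raised when a dataset CSV violates the format contract."""


def read_dataset(path) -> list[SubjectRecord]:
    """Parse and validate the event/observation CSV back into records.

    Errors carry 1-based CSV line numbers (header = line 1).
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=False,
                     na_values=[""], float_precision="round_trip")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise DatasetFormatError(f"missing columns: {sorted(missing)}")

    records: list[SubjectRecord] = []
    for sid, grp in df.groupby("subject_id", sort=False):
        doses: list[DoseEvent] = []
        obs: list[Observation] = []
        for idx, row in grp.iterrows():
            line = idx + 2
            try:
                if row["row_type"] == "dose":
                    rate = row["rate_mg_per_h"]
                    doses.append(DoseEvent(
                        time=float(row["time_h"]),
                        amount=float(row["amount_mg"]),
                        release=str(row["release"]),
                        lag=float(row["lag_h"]),
                        rate=None if pd.isna(rate) else float(rate)))
                elif row["row_type"] == "obs":
                    obs.append(Observation(
                        time=float(row["time_h"]),
                        value=float(row["value_nM"]),
                        kind=str(row["kind"]),
                        period=str(row["period"])))
                else:
                    raise ValueError(f"unknown row_type {row['row_type']!r}")
            except (ValueError, TypeError) as exc:
                raise DatasetFormatError(f"line {line}: {exc}") from exc
        first = grp.iloc[0]
        records.append(SubjectRecord(
            id=str(sid), weight=float(first["weight_kg"]),
            TotA=float(first["albumin_nM"]), TotC_total=float(first["cbg_nM"]),
            doses=tuple(doses), observations=tuple(obs)))
    return records


def dataset_to_csv_bytes(dataset: list[SubjectRecord]) -> bytes:
    """In-memory CSV serialisation (used for determinism checks)."""
    buf = io.StringIO()
    write_dataset(dataset, buf)
    return buf.getvalue().encode()
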