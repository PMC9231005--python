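"""Study-level statistics: rank correlations, AUC24 association, GOF summaries.

The headline diagnostic of the binding-aware model is the per-subject
association between the 24-h steady-state exposure (AUC24) computed on the
free scale and on the total scale: because total concentration is a
saturable (hence subject-specific, nonlinear) transform of the free
concentration, the two exposures need not rank identically across
subjects; heterogeneity in albumin, CBG and the cleaved fraction RC
decouples the ranks.  Associations are quantified with Spearman's rank
correlation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binding import BindingConstants, BindingSystem
from .cohort import PERIODS, SubjectRecord
from .pkmodel import DoseEvent, PKParameters, auc, steady_state_profile

__all__ = [
    "spearman",
    "fisher_z_ci",
    "auc24_association",
    "Auc24Result",
    "gof_summary",
    "GofSummary",
    "unpaired_t_from_stats",
]


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (reported as missing) when either vector is constant.
    Symmetric in its arguments and invariant under strictly increasing
    transforms of either one.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def fisher_z_ci(r: float, n: int, level: float = 0.95
                ) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient."""
    if not np.isfinite(r) or n < 4:
        return (float("nan"), float("nan"))
    if abs(r) >= 1.0:           # degenerate: no sampling variability model
        return (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + level / 2)
    return float(np.tanh(z - q * se)), float(np.tanh(z + q * se))


def _daily_regimen(subject: SubjectRecord, period: str) -> list[DoseEvent]:
    """Within-day dose pattern of a subject's period, from its dose history.

    Periods are identified by the time window of that period's observations;
    the visit day's doses are folded to clock time.
    """
    obs_t = [o.time for o in subject.observations if o.period == period]
    if not obs_t:
        raise ValueError(f"subject {subject.id} has no {period!r}-period "
                         "observations to anchor the regimen")
    visit_day = int(min(obs_t) // 24)
    day0 = visit_day * 24.0
    out = [DoseEvent(time=d.time - day0, amount=d.amount, release=d.release,
                     lag=d.lag, rate=d.rate)
           for d in subject.doses if day0 <= d.time < day0 + 24.0]
    if not out:
        raise ValueError(f"subject {subject.id}: no doses on the {period!r} "
                         "visit day")
    return out


@dataclass(frozen=True)
class Auc24Result:
    r: float
    n: int
    ci: tuple[float, float]            # bootstrap percentile CI
    table: pd.DataFrame                # per subject-period AUC24 free/total


def auc24_association(dataset: list[SubjectRecord],
                      individual: pd.DataFrame,
                      *, ka: float = 0.7, tlag: float = 0.0,
                      F_bio: float = 0.96,
                      constants: BindingConstants | None = None,
                      n_boot: int = 2000, seed: int = 0,
                      grid_step: float = 0.05) -> Auc24Result:
    """Spearman r between free and total steady-state AUC24 across units.

    One unit = one subject-period; the 24-h steady-state profile is
    simulated from the subject's individual (V, CL, RC) estimate under that
    period's daily regimen, and both exposures are integrated over the full
    day.  A seeded bootstrap over units gives the percentile CI.
    """
    constants = constants or BindingConstants()
    ind = individual.set_index("subject_id")
    rows = []
    for s in dataset:
        if s.id not in ind.index:
            continue
        r = ind.loc[s.id]
        params = PKParameters(V=float(r["V"]), CL=float(r["CL"]), ka=ka,
                              tlag=tlag, F_bio=F_bio, RC=float(r["RC"]))
        system = BindingSystem(s.TotA, s.TotC_total, float(r["RC"]),
                               constants=constants)
        for period in PERIODS:
            try:
                regimen = _daily_regimen(s, period)
            except ValueError:
                continue
            prof = steady_state_profile(regimen, params, system,
                                        grid_step=grid_step)
            rows.append({
                "subject_id": s.id, "period": period,
                "auc24_free": auc(prof.times, prof.free, 0.0, 24.0),
                "auc24_total": auc(prof.times, prof.total, 0.0, 24.0),
            })
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("need >= 3 subject-periods for the AUC24 association")
    r_hat = spearman(table["auc24_free"], table["auc24_total"])

    rng = np.random.default_rng(seed)
    n = len(table)
    free_v = table["auc24_free"].to_numpy()
    tot_v = table["auc24_total"].to_numpy()
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.ptp(free_v[idx]) == 0 or np.ptp(tot_v[idx]) == 0:
            continue
        boots.append(spearman(free_v[idx], tot_v[idx]))
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return Auc24Result(r=r_hat, n=n, ci=ci, table=table)


@dataclass(frozen=True)
class GofSummary:
    r_population: float
    r_individual: float
    ci_population: tuple[float, float]
    ci_individual: tuple[float, float]
    n: int


def gof_summary(records: pd.DataFrame) -> GofSummary:
    """Observed-vs-predicted rank agreement, pooled over both analytes.

    ``records`` needs columns observed / pred_population / pred_individual
    (the weighted-residual table provides them).  Confidence intervals are
    Fisher-z.
    """
    req = {"observed", "pred_population", "pred_individual"}
    if not req <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    if len(records) < 3:
        raise ValueError("need >= 3 records")
    obs = records["observed"].to_numpy(float)
    n = len(records)
    r_pop = spearman(obs, records["pred_population"].to_numpy(float))
    r_ind = spearman(obs, records["pred_individual"].to_numpy(float))
    return GofSummary(
        r_population=r_pop, r_individual=r_ind,
        ci_population=fisher_z_ci(r_pop, n),
        ci_individual=fisher_z_ci(r_ind, n),
        n=n,
    )


def unpaired_t_from_stats(mean1: float, sd1: float, n1: int,
                          mean2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Two-sample t test from summary statistics; returns (t, p).

    Provided for comparing fitted typical values against published
    parameter sets available only as summary numbers.
    """
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=False)
    return float(res.statistic), float(res.pvalue)
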