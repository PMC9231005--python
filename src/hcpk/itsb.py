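"""Iterative two-stage Bayesian (ITSB) population estimation.

The algorithm alternates two stages until the population parameters
stabilise:

1. *Individual stage* — for every subject the Bayesian objective

       sum_obs 1/2 [ (y - f)^2 / v + ln v ]
           + sum_k 1/2 (t_k - t_k(mu))^2 / omega_k^2

   is minimised over the transformed individual parameters
   ``t = (log V, log CL, logit RC)``, with residual variance
   ``v = sigma_add^2 + (sigma_prop * f)^2``.  Free-analyte observations are
   predicted directly by the kinetic model; total-analyte observations are
   mapped through the binding isotherm (forward direction only — no
   numerical inversion enters the likelihood).  The MAP point is then
   refined to the posterior mean and variance by adaptive Gauss-Hermite
   quadrature centred on the Laplace approximation: with sparse data the
   posterior for RC is visibly skewed (the likelihood is close to Gaussian
   in RC itself, not in logit RC), and the raw MAP point is biased for
   low-RC subjects while the posterior mean is not.

2. *Population stage* — the typical values are the back-transformed means
   of the transformed individual estimates; the IIV SDs add each subject's
   posterior variance to its squared deviation (EM-type moment update),
   which prevents the omega collapse that a plain SD of shrunken estimates
   produces.

The residual parameters stay at their configured values by default; an
optional step re-estimates (sigma_add, sigma_prop) each iteration by
pooled maximum likelihood over all residuals.  The loop contains no
randomness: identical dataset and settings give an identical trace.

The plain two-stage building blocks remain available: ``map_estimate``
returns the unrefined MAP point, ``update_population`` the plain moment
update, and ``FitSettings(individual_estimator="map", omega_method="sd")``
reproduces the classic (uncorrected) two-stage algorithm.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit

from .binding import BindingConstants
from .cohort import SubjectRecord
from .pkmodel import MOLAR_MASS_HC, PKParameters, simulate_free
from .population import (PARAM_NAMES, PopulationModel, from_transformed,
                         to_transformed)

__all__ = [
    "FitSettings",
    "FitResult",
    "neg_log_posterior",
    "map_estimate",
    "update_population",
    "fit",
    "shrinkage",
    "weighted_residuals",
]

logger = logging.getLogger(__name__)

# relative |ka - k| below which the Bateman form degenerates
_KA_EQ_K_RTOL = 1e-9


@dataclass(frozen=True)
class FitSettings:
    """Structural constants and solver controls for an ITSB run.

    ka / tlag / F_bio are fixed (not estimated); only V, CL and RC carry
    inter-individual variability.  ``individual_estimator`` selects the
    summary used in the population stage: the adaptive-quadrature posterior
    mean (default) or the raw MAP point.  ``omega_method`` selects the IIV
    update: EM-type with posterior variances (default) or the plain sample
    SD.  ``reestimate_residual`` switches on the pooled-ML update of
    (sigma_add, sigma_prop) between iterations.
    """

    ka: float = 0.7
    tlag: float = 0.0
    F_bio: float = 0.96
    constants: BindingConstants = field(default_factory=BindingConstants)
    reestimate_residual: bool = False
    max_iter: int = 50
    rtol: float = 1e-4
    individual_estimator: str = "posterior_mean"   # | 'map'
    omega_method: str = "em"                       # | 'sd'
    agh_nodes: int = 5

    def __post_init__(self) -> None:
        if self.omega_method not in ("em", "sd"):
            raise ValueError("omega_method must be 'em' or 'sd'")
        if self.individual_estimator not in ("posterior_mean", "map"):
            raise ValueError(
                "individual_estimator must be 'posterior_mean' or 'map'")
        if self.agh_nodes < 2:
            raise ValueError("agh_nodes must be >= 2")


class _Workspace:
    """Per-subject arrays precomputed for fast objective evaluation.

    The observation grid, dose schedule and absorption constants are fixed
    during a fit, so the Bateman time differences and the absorption
    exponential are evaluated once; each objective evaluation then needs a
    single fresh elimination exponential.  Only first-order doses are
    supported on this fast path (study dosing is immediate-release); any
    zero-order dose falls back to the general simulator.
    """

    def __init__(self, subject: SubjectRecord, settings: FitSettings):
        self.subject = subject
        self.settings = settings
        self.times = np.array([o.time for o in subject.observations])
        self.values = np.array([o.value for o in subject.observations])
        self.is_total = np.array([o.kind == "total"
                                  for o in subject.observations])
        self.n_obs = self.times.size
        k = settings.constants
        self._prot_kd = np.array([k.K_A, k.K_Ci, k.K_Ce])
        self._fast = all(d.release == "first_order" for d in subject.doses)
        if self._fast and subject.doses and self.n_obs:
            onset = np.array([d.time + d.lag for d in subject.doses])
            onset += settings.tlag
            amt = np.array([d.amount for d in subject.doses])
            amt = amt * 1e6 / MOLAR_MASS_HC * settings.F_bio  # nmol absorbed
            tau = self.times[:, None] - onset[None, :]
            self._active = tau > 0
            self._tau = np.where(self._active, tau, 0.0)
            self._exp_ka = np.exp(-settings.ka * self._tau)
            self._amt = amt

    def _free(self, V: float, CL: float) -> np.ndarray:
        st = self.settings
        if not self._fast:
            params = PKParameters(V=V, CL=CL, ka=st.ka, tlag=st.tlag,
                                  F_bio=st.F_bio)
            return simulate_free(self.subject.doses, params, self.times)
        if not self.subject.doses:
            return np.zeros(self.n_obs)
        k = CL / V
        ka = st.ka
        if abs(ka - k) <= _KA_EQ_K_RTOL * k:
            contrib = self._amt * k * self._tau * np.exp(-k * self._tau) / V
        else:
            contrib = (self._amt * ka / (V * (ka - k))
                       * (np.exp(-k * self._tau) - self._exp_ka))
        return np.sum(np.where(self._active, contrib, 0.0), axis=1)

    def predict(self, theta_t: np.ndarray) -> np.ndarray:
        """Model prediction on each observation's own scale (free or total)."""
        V = float(np.exp(theta_t[0]))
        CL = float(np.exp(theta_t[1]))
        RC = float(expit(theta_t[2]))
        pred = self._free(V, CL)
        if self.is_total.any():
            F = pred[self.is_total]
            s = self.subject
            prot = np.array([s.TotA, (1.0 - RC) * s.TotC_total,
                             RC * s.TotC_total])
            tot = F * (1.0 + np.sum(prot / (self._prot_kd + F[:, None]),
                                    axis=1))
            pred = pred.copy()
            pred[self.is_total] = tot
        return pred

    def nlp(self, theta_t: np.ndarray, pop: PopulationModel) -> float:
        """Negative log posterior on the transformed scale."""
        f = self.predict(theta_t)
        v = pop.sigma_add**2 + (pop.sigma_prop * f) ** 2
        if np.any(v <= 0):
            return np.inf
        like = 0.5 * np.sum((self.values - f) ** 2 / v + np.log(v))
        omega = np.asarray(pop.omega)
        dev = theta_t - pop.mu_transformed
        prior = 0.0
        for d, w in zip(dev, omega):
            if w > 0:
                prior += 0.5 * (d / w) ** 2
            elif abs(d) > 1e-12:
                return np.inf
        return float(like + prior)


def neg_log_posterior(theta: tuple[float, float, float],
                      subject: SubjectRecord, pop: PopulationModel,
                      settings: FitSettings | None = None) -> float:
    """MAP objective at natural-scale ``theta = (V, CL, RC)``.

    Finite for any valid theta with non-degenerate priors; with omega = 0
    the prior contribution is 0 at theta = mu and +inf elsewhere.
    """
    settings = settings or FitSettings()
    ws = _Workspace(subject, settings)
    return ws.nlp(to_transformed(*theta), pop)


def _map_transformed(ws: _Workspace, pop: PopulationModel,
                     start_t: np.ndarray) -> tuple[np.ndarray, bool]:
    omega = np.asarray(pop.omega)
    free_idx = omega > 0
    if not ws.n_obs or not free_idx.any():
        return pop.mu_transformed.copy(), True  # prior mode

    def obj(x: np.ndarray) -> float:
        t = pop.mu_transformed.copy()
        t[free_idx] = x
        return ws.nlp(t, pop)

    x0 = start_t[free_idx]
    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000})
    theta = pop.mu_transformed.copy()
    theta[free_idx] = res.x
    if res.fun > obj(x0):    # never return a point worse than the start
        theta[free_idx] = x0
        return theta, False
    return theta, bool(res.success)


def map_estimate(subject: SubjectRecord, pop: PopulationModel,
                 start: tuple[float, float, float] | None = None,
                 settings: FitSettings | None = None
                 ) -> tuple[float, float, float]:
    """MAP individual estimate of (V, CL, RC) for one subject.

    With no observations (or a fully degenerate prior) the prior mode
    ``pop.mu`` is returned.  The objective at the solution never exceeds
    the objective at ``start``.
    """
    settings = settings or FitSettings()
    ws = _Workspace(subject, settings)
    start_t = (to_transformed(*start) if start is not None
               else pop.mu_transformed.copy())
    theta_t, ok = _map_transformed(ws, pop, start_t)
    if not ok:
        logger.warning("MAP optimiser did not fully converge for subject %s",
                       subject.id)
    return from_transformed(theta_t)


def _hessian(ws: _Workspace, theta_t: np.ndarray, pop: PopulationModel,
             idx: np.ndarray, h: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of the objective in the free dimensions."""
    m = idx.size
    H = np.empty((m, m))
    f0 = ws.nlp(theta_t, pop)

    def f_at(delta: np.ndarray) -> float:
        return ws.nlp(theta_t + delta, pop)

    for a in range(m):
        e_a = np.zeros(3); e_a[idx[a]] = h
        H[a, a] = (f_at(e_a) - 2 * f0 + f_at(-e_a)) / h**2
        for b in range(a + 1, m):
            e_b = np.zeros(3); e_b[idx[b]] = h
            H[a, b] = H[b, a] = (f_at(e_a + e_b) - f_at(e_a - e_b)
                                 - f_at(-e_a + e_b) + f_at(-e_a - e_b)
                                 ) / (4 * h**2)
    return H


def _posterior_moments(ws: _Workspace, mode_t: np.ndarray,
                       pop: PopulationModel, settings: FitSettings
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and marginal variances by adaptive Gauss-Hermite.

    The quadrature grid is centred on the MAP point and scaled by the
    Cholesky factor of the Laplace covariance; node weights are corrected
    by the ratio of the true posterior to the Gaussian approximation, so a
    skewed posterior shifts the mean off the mode.  Falls back to the
    Laplace approximation (mode, clipped inverse-Hessian variances) when
    the Hessian is not positive definite.
    """
    omega2 = np.asarray(pop.omega, float) ** 2
    idx = np.flatnonzero(omega2 > 0)
    mean = mode_t.copy()
    var = np.zeros(3)
    if idx.size == 0 or not ws.n_obs:
        return mean, var
    H = _hessian(ws, mode_t, pop, idx)
    try:
        cov = np.linalg.inv(H)
        L = np.linalg.cholesky((cov + cov.T) / 2)
    except np.linalg.LinAlgError:
        logger.debug("subject %s: non-PD Hessian, Laplace fallback",
                     ws.subject.id)
        var[idx] = omega2[idx]
        return mean, var
    z1, w1 = hermegauss(settings.agh_nodes)
    Z = np.array(list(itertools.product(z1, repeat=idx.size)))
    W = np.prod(np.array(list(itertools.product(w1, repeat=idx.size))),
                axis=1)
    pts = np.tile(mode_t, (len(Z), 1))
    pts[:, idx] += Z @ L.T
    f0 = ws.nlp(mode_t, pop)
    nlp = np.array([ws.nlp(p, pop) for p in pts])
    log_ratio = -(nlp - f0) + 0.5 * np.sum(Z**2, axis=1)
    wgt = W * np.exp(log_ratio - log_ratio.max())
    total = wgt.sum()
    if not np.isfinite(total) or total <= 0:
        var[idx] = np.minimum(np.diag(cov), omega2[idx])
        return mean, var
    wgt /= total
    m_free = wgt @ pts[:, idx]
    v_free = wgt @ (pts[:, idx] - m_free) ** 2
    mean[idx] = m_free
    var[idx] = np.minimum(v_free, omega2[idx])
    return mean, var


def update_population(thetas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plain two-stage moment update from transformed individual estimates.

    ``thetas``: (n, 3) array on the transformed scale.  Returns
    (mu_transformed, omega) with omega the sample SD (ddof=1).  Order of
    subjects is irrelevant.
    """
    thetas = np.asarray(thetas, float)
    if thetas.ndim != 2 or thetas.shape[0] < 2:
        raise ValueError("population update needs >= 2 fitted subjects")
    return thetas.mean(axis=0), thetas.std(axis=0, ddof=1)


def _reestimate_sigma(y: np.ndarray, f: np.ndarray,
                      sigma_add: float, sigma_prop: float
                      ) -> tuple[float, float]:
    """Pooled-ML update of the combined residual model given predictions."""

    def nll(x):
        sa, sp = np.exp(x)
        v = sa**2 + (sp * f) ** 2
        return 0.5 * np.sum((y - f) ** 2 / v + np.log(v))

    x0 = np.log([max(sigma_add, 1e-3), max(sigma_prop, 1e-3)])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    sa, sp = np.exp(res.x)
    return float(sa), float(sp)


@dataclass
class FitResult:
    """Converged population model plus per-subject estimates and the trace."""

    population: PopulationModel
    individual: pd.DataFrame            # subject_id, V, CL, RC
    trace: pd.DataFrame                 # iteration-by-iteration state
    n_iter: int
    converged: bool

    def cv_percent(self) -> dict[str, float]:
        return self.population.cv_percent()


def fit(dataset: list[SubjectRecord], initial: PopulationModel,
        settings: FitSettings | None = None) -> FitResult:
    """Run the full ITSB loop on a dataset.

    Iterates the individual stage over subjects and the population update
    until the largest relative change of any (mu, omega) component falls
    below ``settings.rtol`` (default 1e-4) or ``settings.max_iter`` is
    reached.  Subjects whose MAP step fails to improve on its start are
    excluded from that iteration's population update with a logged
    warning.
    """
    settings = settings or FitSettings()
    if not dataset:
        raise ValueError("dataset must contain at least one subject")
    workspaces = [_Workspace(s, settings) for s in dataset]
    fittable = [ws for ws in workspaces if ws.n_obs]
    if len(fittable) < 2:
        raise ValueError("need >= 2 subjects with observations for a "
                         "population fit")

    pop = initial
    n = len(fittable)
    theta_t = np.tile(pop.mu_transformed, (n, 1))
    post_var = np.zeros((n, 3))
    trace_rows = []
    converged = False
    n_done = 0
    for it in range(1, settings.max_iter + 1):
        ok_mask = np.ones(n, bool)
        for j, ws in enumerate(fittable):
            mode, ok = _map_transformed(ws, pop, theta_t[j])
            ok_mask[j] = ok
            if not ok:
                logger.warning("iteration %d: subject %s MAP step stalled; "
                               "excluded from this population update",
                               it, ws.subject.id)
            if settings.individual_estimator == "posterior_mean":
                theta_t[j], post_var[j] = _posterior_moments(
                    ws, mode, pop, settings)
            else:
                theta_t[j] = mode
                if settings.omega_method == "em":
                    _, post_var[j] = _posterior_moments(ws, mode, pop,
                                                        settings)
        if ok_mask.sum() < 2:
            raise RuntimeError(
                f"ITSB iteration {it}: fewer than two subjects converged")

        mu_t, omega = update_population(theta_t[ok_mask])
        if settings.omega_method == "em":
            dev2 = (theta_t[ok_mask] - mu_t) ** 2
            omega = np.sqrt(np.mean(dev2 + post_var[ok_mask], axis=0))
        new_pop = pop.with_updates(mu=from_transformed(mu_t),
                                   omega=tuple(omega))
        if settings.reestimate_residual:
            y = np.concatenate([ws.values for ws in fittable])
            f = np.concatenate([ws.predict(theta_t[j])
                                for j, ws in enumerate(fittable)])
            sa, sp = _reestimate_sigma(y, f, new_pop.sigma_add,
                                       new_pop.sigma_prop)
            new_pop = new_pop.with_updates(sigma_add=sa, sigma_prop=sp)

        old_vec = np.concatenate([pop.mu_transformed, pop.omega])
        new_vec = np.concatenate([new_pop.mu_transformed, new_pop.omega])
        rel = np.max(np.abs(new_vec - old_vec) / (np.abs(old_vec) + 1e-12))
        trace_rows.append({
            "iteration": it, "V": new_pop.mu[0], "CL": new_pop.mu[1],
            "RC": new_pop.mu[2], "omega_V": new_pop.omega[0],
            "omega_CL": new_pop.omega[1], "omega_RC": new_pop.omega[2],
            "sigma_add": new_pop.sigma_add, "sigma_prop": new_pop.sigma_prop,
            "max_rel_change": rel,
        })
        pop = new_pop
        n_done = it
        if rel < settings.rtol:
            converged = True
            break

    shr = shrinkage(theta_t, pop)
    pop = pop.with_updates(shrinkage=shr)
    individual = pd.DataFrame({
        "subject_id": [ws.subject.id for ws in fittable],
        "V": np.exp(theta_t[:, 0]),
        "CL": np.exp(theta_t[:, 1]),
        "RC": expit(theta_t[:, 2]),
    })
    return FitResult(population=pop, individual=individual,
                     trace=pd.DataFrame(trace_rows), n_iter=n_done,
                     converged=converged)


def shrinkage(theta_t: np.ndarray, pop: PopulationModel
              ) -> dict[str, float | None]:
    """Per-parameter shrinkage, 100*(1 - SD(eta)/omega), clipped to [0, 100].

    ``eta`` are the transformed-scale deviations of the individual
    estimates from the typical value.  Undefined (None) where omega = 0.
    """
    theta_t = np.asarray(theta_t, float)
    eta = theta_t - pop.mu_transformed
    sd = eta.std(axis=0, ddof=1)
    out: dict[str, float | None] = {}
    for k, name in enumerate(PARAM_NAMES):
        w = pop.omega[k]
        if w <= 0:
            out[name] = None
        else:
            out[name] = float(np.clip(100.0 * (1.0 - sd[k] / w), 0.0, 100.0))
    return out


def weighted_residuals(dataset: list[SubjectRecord], pop: PopulationModel,
                       individual: pd.DataFrame | None = None,
                       settings: FitSettings | None = None) -> pd.DataFrame:
    """WRES table: (y - f) / sqrt(sigma_add^2 + (sigma_prop*f)^2).

    Population residuals use predictions at the typical values; individual
    residuals (column ``wres_individual``) are added when per-subject
    estimates are supplied.
    """
    settings = settings or FitSettings()
    ind = (individual.set_index("subject_id")
           if individual is not None else None)
    rows = []
    for s in dataset:
        ws = _Workspace(s, settings)
        if not ws.n_obs:
            continue
        f_pop = ws.predict(pop.mu_transformed)
        v_pop = np.sqrt(pop.sigma_add**2 + (pop.sigma_prop * f_pop) ** 2)
        wres_pop = (ws.values - f_pop) / v_pop
        if ind is not None and s.id in ind.index:
            r = ind.loc[s.id]
            f_ind = ws.predict(to_transformed(r["V"], r["CL"], r["RC"]))
            v_ind = np.sqrt(pop.sigma_add**2 + (pop.sigma_prop * f_ind) ** 2)
            wres_ind = (ws.values - f_ind) / v_ind
        else:
            f_ind = np.full_like(f_pop, np.nan)
            wres_ind = np.full_like(f_pop, np.nan)
        for j, o in enumerate(s.observations):
            rows.append({"subject_id": s.id, "time_h": o.time,
                         "kind": o.kind, "observed": o.value,
                         "pred_population": f_pop[j],
                         "pred_individual": f_ind[j],
                         "wres_population": wres_pop[j],
                         "wres_individual": wres_ind[j]})
    return pd.DataFrame(rows)
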