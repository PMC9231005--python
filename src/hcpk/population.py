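"""Population-level parameter distributions and scale transforms.

Inter-individual variability (IIV) is modelled on transformed scales:
log-normal for the volume of distribution V and clearance CL (both strictly
positive, variability conventionally reported as CV%), and logit-normal for
the cleaved-CBG fraction RC so that individual values respect [0, 1].  The
"typical" value of a parameter is its median (the back-transformed mean of
the transformed scale).

CV% conversions: for a log-normal component with transformed-scale SD w,
CV = sqrt(exp(w^2) - 1) * 100.  The logit-normal has no closed-form CV; it
is computed by Gauss-Hermite quadrature, and the inverse problem (which
logit-scale SD yields a requested CV at a given median) is solved
numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "PopulationModel",
    "to_transformed",
    "from_transformed",
    "omega_from_cv_lognormal",
    "cv_from_omega_lognormal",
    "cv_logitnormal",
    "logit_sd_for_cv",
    "PARAM_NAMES",
]

PARAM_NAMES = ("V", "CL", "RC")


def to_transformed(V: float, CL: float, RC: float) -> np.ndarray:
    """Map (V, CL, RC) to the estimation scale (log V, log CL, logit RC)."""
    return np.array([np.log(V), np.log(CL), logit(RC)])


def from_transformed(t) -> tuple[float, float, float]:
    """Inverse of :func:`to_transformed`."""
    t = np.asarray(t, float)
    return float(np.exp(t[0])), float(np.exp(t[1])), float(expit(t[2]))


def omega_from_cv_lognormal(cv: float) -> float:
    """Log-scale SD reproducing a coefficient of variation ``cv`` (fraction)."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    return float(np.sqrt(np.log1p(cv**2)))


def cv_from_omega_lognormal(omega: float) -> float:
    """Coefficient of variation (fraction) of a log-normal with log-SD omega."""
    return float(np.sqrt(np.expm1(omega**2)))


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(201)


def cv_logitnormal(median: float, sd_logit: float) -> float:
    """CV (fraction) of a logit-normal with given median and logit-scale SD."""
    if not 0.0 < median < 1.0:
        raise ValueError("median must lie in (0, 1)")
    x = expit(logit(median) + sd_logit * _GH_NODES)
    w = _GH_WEIGHTS / _GH_WEIGHTS.sum()
    m = np.sum(w * x)
    var = np.sum(w * x**2) - m**2
    return float(np.sqrt(max(var, 0.0)) / m)


def logit_sd_for_cv(median: float, cv: float) -> float:
    """Logit-scale SD reproducing a requested CV (fraction) at ``median``.

    Solved by bracketing on the monotone map sd -> CV.  The achievable CV of
    a logit-normal is bounded (mass piles up at 0 and 1 as the SD grows), so
    an unattainable request raises instead of silently saturating.
    """
    if cv == 0.0:
        return 0.0
    hi = 40.0
    if cv >= cv_logitnormal(median, hi):
        raise ValueError(f"CV {cv:.3f} not attainable for a logit-normal "
                         f"with median {median}")
    return float(brentq(lambda s: cv_logitnormal(median, s) - cv, 1e-9, hi))


@dataclass(frozen=True)
class PopulationModel:
    """Population means, inter-individual SDs and the residual-error model.

    mu : typical (median) values of V (L), CL (L/h) and RC (dimensionless)
    omega : IIV SDs on the transformed scale — (SD log V, SD log CL,
        SD logit RC); zero means a homogeneous population
    sigma_add : additive residual SD (nM, on the observation scale)
    sigma_prop : proportional residual SD (fraction)
    shrinkage : per-parameter shrinkage in percent, populated after a fit
    """

    mu: tuple[float, float, float]
    omega: tuple[float, float, float]
    sigma_add: float = 1.1
    sigma_prop: float = 0.095
    shrinkage: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        V, CL, RC = self.mu
        if not (V > 0 and CL > 0):
            raise ValueError("typical V and CL must be positive")
        if not 0.0 < RC < 1.0:
            raise ValueError("typical RC must lie in (0, 1)")
        if any(w < 0 for w in self.omega):
            raise ValueError("omega components must be >= 0")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("residual SDs must be >= 0")

    @classmethod
    def from_cv(cls, V: float, CL: float, RC: float,
                cv_V: float, cv_CL: float, cv_RC: float,
                sigma_add: float = 1.1,
                sigma_prop: float = 0.095) -> "PopulationModel":
        """Build from typical values and CVs given as fractions (0.55 = 55%)."""
        return cls(
            mu=(V, CL, RC),
            omega=(omega_from_cv_lognormal(cv_V),
                   omega_from_cv_lognormal(cv_CL),
                   logit_sd_for_cv(RC, cv_RC)),
            sigma_add=sigma_add, sigma_prop=sigma_prop,
        )

    @property
    def mu_transformed(self) -> np.ndarray:
        return to_transformed(*self.mu)

    def cv_percent(self) -> dict[str, float]:
        """IIV expressed as CV% per parameter (logit-normal RC by quadrature)."""
        return {
            "V": 100.0 * cv_from_omega_lognormal(self.omega[0]),
            "CL": 100.0 * cv_from_omega_lognormal(self.omega[1]),
            "RC": 100.0 * cv_logitnormal(self.mu[2], self.omega[2]),
        }

    def sample_individuals(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n individual (V, CL, RC) rows from the IIV distribution."""
        eta = rng.standard_normal((n, 3)) * np.asarray(self.omega)
        t = self.mu_transformed + eta
        return np.column_stack([np.exp(t[:, 0]), np.exp(t[:, 1]),
                                expit(t[:, 2])])

    def with_updates(self, **kw) -> "PopulationModel":
        return replace(self, **kw)
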