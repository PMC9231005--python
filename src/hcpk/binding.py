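"""Plasma protein binding of hydrocortisone (cortisol).

Hydrocortisone in plasma distributes between the free (unbound) state and
three binding partners: albumin (high capacity, low affinity),
intact corticosteroid-binding globulin (CBGi; low capacity, high affinity)
and elastase-cleaved CBG (CBGe; ~10-fold lower affinity than CBGi).
Each protein P is treated as an independent single-site binder with
dissociation constant ``K_P`` (nM), so the bound concentration at free
ligand ``F`` is ``TotP * F / (K_P + F)`` and the total drug concentration is

    TotF = F * (1 + TotA/(K_A + F) + TotCi/(K_Ci + F) + TotCe/(K_Ce + F))

All concentrations are nmol/L (nM) throughout; there are no mass-unit
variants inside this module.

The split of total CBG into intact and cleaved pools is governed by the
cleaved fraction ``RC``: ``CBGe = RC * CBG`` and ``CBGi = (1 - RC) * CBG``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BindingConstants",
    "BindingSystem",
    "split_cbg",
    "total_from_free",
    "free_from_total",
    "fraction_unbound",
    "bound_breakdown",
    "DEFAULT_CONSTANTS",
]


@dataclass(frozen=True)
class BindingConstants:
    """Dissociation constants (nM) of the three hydrocortisone binders.

    A larger ``Kd`` means weaker affinity.  The default assignment gives
    intact CBG the smallest constant (highest affinity) and cleaved CBG a
    10-fold larger one, consistent with cleaved CBG binding cortisol ~10x
    more weakly; albumin is a weak, high-capacity binder.
    """

    K_A: float = 330_000.0   # albumin
    K_Ci: float = 33.0       # intact CBG
    K_Ce: float = 330.0      # cleaved CBG

    def __post_init__(self) -> None:
        for name in ("K_A", "K_Ci", "K_Ce"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if not self.K_Ce > self.K_Ci:
            raise ValueError(
                "K_Ce must exceed K_Ci: cleaved CBG has lower affinity "
                f"(got K_Ci={self.K_Ci}, K_Ce={self.K_Ce})"
            )

    @classmethod
    def printed_assignment(cls) -> "BindingConstants":
        """The alternative literal reading K_C=330 (intact), K_C*=33 (cleaved).

        This ordering contradicts cleaved CBG having lower affinity, so the
        class invariant would reject it; the instance is constructed with the
        invariant bypassed and is provided only for sensitivity analyses.
        """
        obj = object.__new__(cls)
        object.__setattr__(obj, "K_A", 330_000.0)
        object.__setattr__(obj, "K_Ci", 330.0)
        object.__setattr__(obj, "K_Ce", 33.0)
        return obj


DEFAULT_CONSTANTS = BindingConstants()


def split_cbg(TotC_total: float, RC: float) -> tuple[float, float]:
    """Split total CBG into (intact, cleaved) pools: CBGe = RC*CBG.

    Returns ``(TotCi, TotCe)`` with ``TotCi + TotCe == TotC_total`` exactly.
    """
    if TotC_total < 0:
        raise ValueError(f"TotC_total must be >= 0, got {TotC_total}")
    if not 0.0 <= RC <= 1.0:
        raise ValueError(f"RC must lie in [0, 1], got {RC}")
    TotCe = RC * TotC_total
    return TotC_total - TotCe, TotCe


@dataclass(frozen=True)
class BindingSystem:
    """Per-subject binding milieu: protein pools plus dissociation constants.

    Parameters
    ----------
    TotA : total albumin concentration (nM)
    TotC_total : total CBG concentration, intact + cleaved (nM)
    RC : cleaved fraction of CBG, in [0, 1]
    constants : the three dissociation constants
    """

    TotA: float
    TotC_total: float
    RC: float
    constants: BindingConstants = field(default_factory=BindingConstants)

    def __post_init__(self) -> None:
        if self.TotA < 0:
            raise ValueError(f"TotA must be >= 0, got {self.TotA}")
        if self.TotC_total < 0:
            raise ValueError(f"TotC_total must be >= 0, got {self.TotC_total}")
        if not 0.0 <= self.RC <= 1.0:
            raise ValueError(f"RC must lie in [0, 1], got {self.RC}")

    @property
    def TotCi(self) -> float:
        return split_cbg(self.TotC_total, self.RC)[0]

    @property
    def TotCe(self) -> float:
        return split_cbg(self.TotC_total, self.RC)[1]

    def _pools(self) -> tuple[np.ndarray, np.ndarray]:
        k = self.constants
        tot = np.array([self.TotA, self.TotCi, self.TotCe])
        kd = np.array([k.K_A, k.K_Ci, k.K_Ce])
        return tot, kd


def total_from_free(F, system: BindingSystem):
    """Total hydrocortisone (nM) at free concentration ``F`` (nM).

    Accepts a scalar or array; vectorises over ``F``.  Strictly increasing
    in ``F`` and reduces to the identity when all protein pools are zero.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("free concentration F must be >= 0")
    tot, kd = system._pools()
    Fe = F[..., None]
    out = F * (1.0 + np.sum(tot / (kd + Fe), axis=-1))
    return out if out.ndim else float(out)


def bound_breakdown(F: float, system: BindingSystem) -> tuple[float, float, float]:
    """Bound hydrocortisone per protein at free concentration ``F``.

    Returns ``(albumin_bound, CBGi_bound, CBGe_bound)`` in nM.  By
    construction ``F + sum(bound) == total_from_free(F)`` to machine
    precision.
    """
    if F < 0:
        raise ValueError("free concentration F must be >= 0")
    tot, kd = system._pools()
    b = tot * F / (kd + F)
    return float(b[0]), float(b[1]), float(b[2])


def fraction_unbound(F, system: BindingSystem):
    """Fraction unbound fu = F / TotF at free concentration ``F``.

    At ``F == 0`` the analytic dilute limit
    ``1 / (1 + sum(TotP / K_P))`` is returned instead of 0/0.
    fu is nondecreasing in F (binding saturates) and tends to 1 as F grows.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("free concentration F must be >= 0")
    tot, kd = system._pools()
    Fe = F[..., None]
    fu = 1.0 / (1.0 + np.sum(tot / (kd + Fe), axis=-1))
    return fu if fu.ndim else float(fu)


def free_from_total(TotF, system: BindingSystem, *, rtol: float = 1e-12):
    """Invert the binding isotherm: the unique F with total_from_free(F)=TotF.

    The forward map is strictly increasing with ``F <= TotF``, so the root is
    bracketed on ``[0, TotF]`` and found by Brent's method to ``rtol``
    relative tolerance.  Vectorises over ``TotF``.
    """
    TotF_arr = np.asarray(TotF, dtype=float)
    if np.any(TotF_arr < 0):
        raise ValueError("total concentration TotF must be >= 0")

    def _solve(t: float) -> float:
        if t == 0.0:
            return 0.0
        try:
            return brentq(
                lambda f: total_from_free(f, system) - t,
                0.0, t, xtol=1e-12, rtol=max(rtol, 4e-16), maxiter=200,
            )
        except RuntimeError as exc:  # pragma: no cover - brentq is robust here
            raise ArithmeticError(
                f"binding inversion failed on bracket [0, {t}]: {exc}"
            ) from exc

    if TotF_arr.ndim == 0:
        return _solve(float(TotF_arr))
    return np.array([_solve(t) for t in TotF_arr.ravel()]).reshape(TotF_arr.shape)
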