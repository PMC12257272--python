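"""Domain types for the three-compartment doxycycline disposition model.

All parameters are per-kg (clearances in L/kg/h, volumes in L/kg) and all
doses are doxycycline *base* in mg/kg; :func:`salt_to_base_factor` converts
labelled salt doses.  The disposition model is mammillary: a central
(plasma) compartment exchanging with two peripheral compartments, with
elimination from the central compartment only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Route",
    "DispositionParams",
    "AbsorptionParams",
    "CovariateEffect",
    "DoseEvent",
    "SecondaryParams",
    "scale_by_bw",
    "salt_to_base_factor",
]

#: Reference body weight (kg) for the covariate power model.
REFERENCE_BW = 50.0

# Molecular weights (g/mol): doxycycline base and its marketed salts.
# Hyclate combines two doxycycline molecules with HCl and ethanol.
_MW_BASE = 444.4
_MW_HYCLATE = 1025.9  # contains two base molecules
_MW_MONOHYDRATE = 462.0
_MW_HYDROCHLORIDE = 480.9


class Route(str, enum.Enum):
    """Administration route / oral submodel label."""

    IV = "IV"
    FEED_TLS = "FEED_TLS"            # in-feed, field conditions
    FEED_OTHERS = "FEED_OTHERS"      # in-feed, laboratory conditions
    SOL_DW = "SOL_DW"                # solution in drinking water
    SOL_TUBING = "SOL_TUBING"        # solution by stomach tube

    @property
    def is_oral(self) -> bool:
        return self is not Route.IV


ORAL_ROUTES = (Route.FEED_TLS, Route.FEED_OTHERS, Route.SOL_DW, Route.SOL_TUBING)


def salt_to_base_factor(salt: str) -> float:
    """Multiplicative factor converting a salt dose to doxycycline base.

    Parameters
    ----------
    salt
        One of ``"base"``, ``"hyclate"``, ``"monohydrate"``,
        ``"hydrochloride"``.
    """
    factors = {
        "base": 1.0,
        "hyclate": 2.0 * _MW_BASE / _MW_HYCLATE,
        "monohydrate": _MW_BASE / _MW_MONOHYDRATE,
        "hydrochloride": _MW_BASE / _MW_HYDROCHLORIDE,
    }
    try:
        return factors[salt.lower()]
    except KeyError:
        raise ValueError(f"unknown doxycycline salt {salt!r}; expected one of {sorted(factors)}")


@dataclass(frozen=True)
class DispositionParams:
    """Structural disposition parameters of the mammillary 3-compartment model.

    Attributes
    ----------
    cl : float
        Plasma (elimination) clearance, L/kg/h.
    cl2, cl3 : float
        Distributional clearances to peripheral compartments 2 and 3, L/kg/h.
    vc, v2, v3 : float
        Central and peripheral distribution volumes, L/kg.
    """

    cl: float
    cl2: float
    cl3: float
    vc: float
    v2: float
    v3: float

    def __post_init__(self) -> None:
        for name in ("cl", "cl2", "cl3", "vc", "v2", "v3"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"disposition parameter {name} must be strictly positive, got {value}")

    @property
    def micro_constants(self) -> dict[str, float]:
        """First-order micro-constants k10, k12, k21, k13, k31 (1/h)."""
        return {
            "k10": self.cl / self.vc,
            "k12": self.cl2 / self.vc,
            "k21": self.cl2 / self.v2,
            "k13": self.cl3 / self.vc,
            "k31": self.cl3 / self.v3,
        }

    def rate_matrix(self) -> np.ndarray:
        """3x3 first-order rate matrix acting on compartment amounts
        (central, peripheral-2, peripheral-3)."""
        k = self.micro_constants
        return np.array(
            [
                [-(k["k10"] + k["k12"] + k["k13"]), k["k21"], k["k31"]],
                [k["k12"], -k["k21"], 0.0],
                [k["k13"], 0.0, -k["k31"]],
            ]
        )

    def replace(self, **kwargs: float) -> "DispositionParams":
        values = {n: getattr(self, n) for n in ("cl", "cl2", "cl3", "vc", "v2", "v3")}
        values.update(kwargs)
        return DispositionParams(**values)


@dataclass(frozen=True)
class AbsorptionParams:
    """Route-specific absorption: first-order rate Ka (1/h) and absolute
    bioavailability F.

    For IV, ``ka`` is None and ``f`` is fixed at 1.  F is *not* constrained
    to be <= 1: individual lognormal realizations of F may exceed unity and
    are deliberately left untruncated by this type.
    """

    route: Route
    ka: float | None = None
    f: float = 1.0

    def __post_init__(self) -> None:
        route = Route(self.route)
        object.__setattr__(self, "route", route)
        if route.is_oral:
            if self.ka is None or self.ka <= 0.0:
                raise ValueError(f"oral route {route.value} requires ka > 0, got {self.ka}")
        elif self.ka is not None:
            raise ValueError("IV route takes no absorption rate constant")
        if self.f <= 0.0:
            raise ValueError(f"bioavailability must be positive, got {self.f}")


@dataclass(frozen=True)
class CovariateEffect:
    """Body-weight power-model scaling of one disposition parameter.

    ``scaled = theta_pop * (bw / ref_bw) ** theta_bw`` with the reference
    weight fixed at 50 kg, near the population median.
    """

    parameter_name: str
    theta_pop: float
    theta_bw: float
    ref_bw: float = REFERENCE_BW

    def __post_init__(self) -> None:
        if self.ref_bw <= 0.0:
            raise ValueError("reference body weight must be positive")

    def scale(self, bw: float) -> float:
        return scale_by_bw(self, bw)


def scale_by_bw(effect: CovariateEffect, bw: float) -> float:
    """Evaluate the body-weight power model for one parameter.

    Returns ``theta_pop * (bw / ref_bw) ** theta_bw``; exact identity at the
    reference weight.
    """
    if bw <= 0.0:
        raise ValueError(f"body weight must be positive, got {bw}")
    return effect.theta_pop * (bw / effect.ref_bw) ** effect.theta_bw


@dataclass(frozen=True)
class DoseEvent:
    """A single dose: time (h since the subject's first dose) and amount
    (mg/kg doxycycline base)."""

    time: float
    amount: float
    route: Route = Route.IV

    def __post_init__(self) -> None:
        object.__setattr__(self, "route", Route(self.route))
        if self.time < 0.0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount <= 0.0:
            raise ValueError(f"dose amount must be positive, got {self.amount}")


@dataclass(frozen=True)
class SecondaryParams:
    """Derived (secondary) parameters of one parameter set.

    terminal_half_life (h), vss = Vc+V2+V3 (L/kg), mrt_iv = Vss/Cl (h),
    mat = 1/Ka (h, oral only), auc_ss_24h = F*daily_dose/Cl (ug*h/mL).
    """

    terminal_half_life: float
    vss: float
    mrt_iv: float
    mat: float | None = None
    auc_ss_24h: float | None = None
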