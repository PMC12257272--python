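"""Generative population layer: typical values, body-weight covariates,
between-subject variability (BSV) and residual error.

Between-subject variability is exponential (lognormal): an individual's
parameter is the covariate-scaled typical value times ``exp(eta)`` with
``eta ~ N(0, omega^2)``.  Published BSV figures are coefficients of
variation in percent; the default conversion is the lognormal-CV identity
``omega = sqrt(ln(1 + (CV/100)^2))``, with the cruder ``omega = CV/100``
reading available as an alternative convention.  Residual error is
additive plus proportional on the concentration scale, with route-specific
magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from doxypk.params import (
    REFERENCE_BW,
    AbsorptionParams,
    CovariateEffect,
    DispositionParams,
    Route,
    scale_by_bw,
)

__all__ = [
    "ResidualModel",
    "PopulationModel",
    "IndividualRealization",
    "bsv_percent_to_omega",
    "omega_to_bsv_percent",
    "draw_population",
    "apply_residual_error",
    "published_model",
]

DISPOSITION_NAMES = ("cl", "cl2", "cl3", "vc", "v2", "v3")


def bsv_percent_to_omega(bsv_percent: float, convention: str = "lognormal-cv") -> float:
    """Convert a published BSV% to a log-scale standard deviation omega.

    ``"lognormal-cv"`` (default): omega = sqrt(ln(1 + (CV/100)^2)), the
    exact CV of a lognormal.  ``"sd"``: omega = CV/100, reading the
    percentage directly as 100*omega.
    """
    if bsv_percent < 0.0:
        raise ValueError("BSV percent must be non-negative")
    cv = bsv_percent / 100.0
    if convention == "lognormal-cv":
        return math.sqrt(math.log1p(cv * cv))
    if convention == "sd":
        return cv
    raise ValueError(f"unknown BSV convention {convention!r}")


def omega_to_bsv_percent(omega: float, convention: str = "lognormal-cv") -> float:
    """Inverse of :func:`bsv_percent_to_omega`."""
    if omega < 0.0:
        raise ValueError("omega must be non-negative")
    if convention == "lognormal-cv":
        return 100.0 * math.sqrt(math.expm1(omega * omega))
    if convention == "sd":
        return 100.0 * omega
    raise ValueError(f"unknown BSV convention {convention!r}")


@dataclass(frozen=True)
class ResidualModel:
    """Additive plus proportional residual error.

    The observation SD at a model prediction ``f`` is
    ``sqrt(stdev0^2 + (cmult * f)^2)`` with stdev0 in ug/mL and cmult a
    dimensionless fraction (read as a CV at high concentrations).
    """

    stdev0: float
    cmult: float

    def __post_init__(self) -> None:
        if self.stdev0 < 0.0 or self.cmult < 0.0:
            raise ValueError("residual SD components must be non-negative")
        if self.stdev0 == 0.0 and self.cmult == 0.0:
            raise ValueError("residual model must have a nonzero component")

    def sd(self, pred) -> np.ndarray:
        pred = np.asarray(pred, dtype=float)
        return np.sqrt(self.stdev0**2 + (self.cmult * pred) ** 2)


@dataclass(frozen=True)
class IndividualRealization:
    """One simulated animal: body weight, random effects, and the realized
    parameter set (covariate-scaled typical times exp(eta))."""

    subject_id: int
    bw: float
    route: Route
    eta: dict[str, float]
    disposition: DispositionParams
    absorption: AbsorptionParams


@dataclass
class PopulationModel:
    """Full population model: typical disposition at the 50-kg reference,
    body-weight power-model covariates, four oral absorption submodels,
    diagonal BSV (omega, log-scale SD per parameter) and per-route residual
    error.

    Omega keys are the lowercase disposition names plus ``ka_<ROUTE>`` and
    ``f_<ROUTE>`` for the oral submodels; absent keys mean no BSV.
    """

    disposition: DispositionParams
    covariates: tuple[CovariateEffect, ...] = ()
    absorption: dict[Route, AbsorptionParams] = field(default_factory=dict)
    omega: dict[str, float] = field(default_factory=dict)
    residual: dict[Route, ResidualModel] = field(default_factory=dict)
    ref_bw: float = REFERENCE_BW
    #: optional exponential health-status effect on F per oral route:
    #: F_sick = F * exp(beta); absent key means no effect.
    health_effect: dict[Route, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.omega.items():
            if value < 0.0:
                raise ValueError(f"omega[{name!r}] must be non-negative")
        seen = set()
        for eff in self.covariates:
            if eff.parameter_name not in DISPOSITION_NAMES:
                raise ValueError(f"covariate on unknown parameter {eff.parameter_name!r}")
            if eff.parameter_name in seen:
                raise ValueError(f"duplicate covariate on {eff.parameter_name!r}")
            seen.add(eff.parameter_name)

    # -- typical values ----------------------------------------------------
    def disposition_at(self, bw: float) -> DispositionParams:
        """Covariate-scaled typical disposition parameters at body weight bw."""
        values = {n: getattr(self.disposition, n) for n in DISPOSITION_NAMES}
        for eff in self.covariates:
            values[eff.parameter_name] = scale_by_bw(eff, bw)
        return DispositionParams(**values)

    def covariate_effect(self, parameter: str) -> CovariateEffect | None:
        for eff in self.covariates:
            if eff.parameter_name == parameter:
                return eff
        return None

    def residual_for(self, route: Route) -> ResidualModel:
        route = Route(route)
        if route in self.residual:
            return self.residual[route]
        raise KeyError(f"no residual model for route {route.value}")

    # -- individuals -------------------------------------------------------
    def individual(
        self,
        bw: float,
        route: Route,
        eta: dict[str, float] | None = None,
        subject_id: int = 0,
        cap_f_at_1: bool = False,
        health: str | None = None,
    ) -> IndividualRealization:
        """Realize one animal from body weight and log-scale random effects."""
        route = Route(route)
        eta = dict(eta or {})
        typ = self.disposition_at(bw)
        disp = DispositionParams(
            **{n: getattr(typ, n) * math.exp(eta.get(n, 0.0)) for n in DISPOSITION_NAMES}
        )
        if route.is_oral:
            if route not in self.absorption:
                raise KeyError(f"population model has no absorption submodel for {route.value}")
            base = self.absorption[route]
            f = base.f * math.exp(eta.get(f"f_{route.value}", 0.0))
            if health == "sick" and route in self.health_effect:
                f *= math.exp(self.health_effect[route])
            if cap_f_at_1:
                f = min(f, 1.0)
            absorption = AbsorptionParams(
                route=route,
                ka=base.ka * math.exp(eta.get(f"ka_{route.value}", 0.0)),
                f=f,
            )
        else:
            absorption = AbsorptionParams(route=Route.IV)
        return IndividualRealization(
            subject_id=subject_id, bw=bw, route=route, eta=eta, disposition=disp, absorption=absorption
        )

    def eta_names(self, route: Route) -> list[str]:
        """Omega keys relevant to a subject on the given route."""
        route = Route(route)
        names = [n for n in DISPOSITION_NAMES if self.omega.get(n, 0.0) > 0.0]
        if route.is_oral:
            for key in (f"ka_{route.value}", f"f_{route.value}"):
                if self.omega.get(key, 0.0) > 0.0:
                    names.append(key)
        return names

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "reference_bw": self.ref_bw,
            "disposition": {n: float(getattr(self.disposition, n)) for n in DISPOSITION_NAMES},
            "covariates": [
                {"parameter": e.parameter_name, "exponent": float(e.theta_bw)} for e in self.covariates
            ],
            "absorption": {
                r.value: {"ka": float(a.ka), "f": float(a.f)} for r, a in self.absorption.items()
            },
            "omega": {k: float(v) for k, v in self.omega.items()},
            "residual": {
                r.value: {"stdev0": float(m.stdev0), "cmult": float(m.cmult)}
                for r, m in self.residual.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PopulationModel":
        ref_bw = float(data.get("reference_bw", REFERENCE_BW))
        disp = DispositionParams(**{k: float(v) for k, v in data["disposition"].items()})
        covariates = tuple(
            CovariateEffect(
                parameter_name=c["parameter"],
                theta_pop=float(getattr(disp, c["parameter"])),
                theta_bw=float(c["exponent"]),
                ref_bw=ref_bw,
            )
            for c in data.get("covariates", [])
        )
        absorption = {
            Route(r): AbsorptionParams(route=Route(r), ka=float(v["ka"]), f=float(v["f"]))
            for r, v in data.get("absorption", {}).items()
        }
        residual = {
            Route(r): ResidualModel(stdev0=float(v["stdev0"]), cmult=float(v["cmult"]))
            for r, v in data.get("residual", {}).items()
        }
        omega = {k: float(v) for k, v in data.get("omega", {}).items()}
        return cls(
            disposition=disp,
            covariates=covariates,
            absorption=absorption,
            omega=omega,
            residual=residual,
            ref_bw=ref_bw,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def draw_population(
    model: PopulationModel,
    n: int,
    bw,
    route: Route,
    seed: int | np.random.Generator,
    cap_f_at_1: bool = False,
) -> list[IndividualRealization]:
    """Draw n individual realizations.

    ``bw`` is either a fixed body weight (kg) or a callable
    ``bw(rng, n) -> array``.  Etas are independent normals with the
    model's diagonal omega; the draw is deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    route = Route(route)
    if route.is_oral and route not in model.absorption:
        raise KeyError(f"population model has no absorption submodel for {route.value}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bws = bw(rng, n) if callable(bw) else np.full(n, float(bw))
    names = model.eta_names(route)
    etas = rng.standard_normal((n, len(names))) * np.array(
        [model.omega[k] for k in names], dtype=float
    )
    return [
        model.individual(
            bw=float(bws[i]),
            route=route,
            eta={k: float(etas[i, j]) for j, k in enumerate(names)},
            subject_id=i,
            cap_f_at_1=cap_f_at_1,
        )
        for i in range(n)
    ]


def apply_residual_error(
    true_conc, residual: ResidualModel, seed: int | np.random.Generator
) -> np.ndarray:
    """Add additive-plus-proportional Gaussian noise to noise-free
    concentrations.  Observations may come out negative; LLOQ censoring is
    applied downstream."""
    conc = np.asarray(true_conc, dtype=float)
    if np.any(conc < 0.0):
        raise ValueError("true concentrations must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return conc + rng.standard_normal(conc.shape) * residual.sd(conc)


def published_model(convention: str = "lognormal-cv") -> PopulationModel:
    """The final published population model (typical values, BW covariates,
    BSV and residual errors) shipped with the package."""
    ref = resources.files("doxypk").joinpath("data/published_model.yaml")
    data = yaml.safe_load(ref.read_text())
    bsv = data.pop("bsv_percent", {})
    model = PopulationModel.from_dict(data)
    model.omega = {k: bsv_percent_to_omega(float(v), convention) for k, v in bsv.items()}
    return model
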