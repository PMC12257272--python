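"""Hierarchical estimation of the population model.

The marginal likelihood of the nonlinear mixed-effects model is
approximated per subject by the Laplace method: the joint log-density of
the observations and the subject's random effects is maximized over the
etas (inner optimization), and the Gaussian curvature correction
(log-determinant of the Hessian at the conditional mode) is added.  The
approximation is exact when the prediction is linear in eta.  The
objective function value (OFV) is -2 times the summed approximate
marginal log-likelihood, and AIC = OFV + 2 * (number of estimated
parameters).

Fitting is staged as in the meta-analytic workflow: the disposition
parameters and their body-weight exponents are estimated from the rich IV
data alone; the oral absorption submodels (Ka, F per route) are then
estimated with the IV fixed effects frozen and all random effects
re-estimated.  Free parameters are optimized on the log scale
(bound-constrained) with a derivative-free simplex/Powell search;
covariate exponents and the health-status effect stay on the linear
scale.  Bootstrap resampling of subjects (stratified by route) provides
percentile confidence intervals; shrinkage and visual-predictive-check
diagnostics round out the surface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from doxypk.io import Dataset, SubjectData
from doxypk.params import (
    AbsorptionParams,
    CovariateEffect,
    DispositionParams,
    Route,
)
from doxypk.pk import conc_profile
from doxypk.population import (
    DISPOSITION_NAMES,
    PopulationModel,
    ResidualModel,
    omega_to_bsv_percent,
)

__all__ = [
    "EstimationError",
    "PopPKModel",
    "PopPKResults",
    "BootstrapResult",
    "VPCResult",
    "build_model",
    "laplace_nll",
    "marginal_ofv",
    "fit",
    "covariate_search",
    "bootstrap_ci",
    "shrinkage",
    "vpc_check",
]

#: AIC improvement declaring a covariate scenario significant
#: (the chi-square 1-df p<0.01 equivalent on -2LL).
AIC_SIGNIFICANCE = 6.635

_PENALTY = 1e12


class EstimationError(RuntimeError):
    """Raised when the likelihood is non-computable (e.g. a non-positive
    predicted residual SD) for an identifiable subject."""

    def __init__(self, message: str, subject_id=None):
        super().__init__(message)
        self.subject_id = subject_id


# ---------------------------------------------------------------------------
# model (re)construction from a named parameter dictionary
# ---------------------------------------------------------------------------

def build_model(
    base: PopulationModel,
    thetas: dict[str, float] | None = None,
    omegas: dict[str, float] | None = None,
) -> PopulationModel:
    """Return a copy of ``base`` with named parameters replaced.

    Theta names: the six disposition parameters (``cl`` ... ``v3``),
    body-weight exponents ``bw_<param>``, absorption ``ka_<ROUTE>`` /
    ``f_<ROUTE>``, residual ``stdev0_<ROUTE>`` / ``cmult_<ROUTE>`` and the
    health effect ``health_f_<ROUTE>``.  Omega keys match the population
    model's omega dictionary.
    """
    thetas = thetas or {}
    omegas = omegas or {}
    disp_vals = {n: float(thetas.get(n, getattr(base.disposition, n))) for n in DISPOSITION_NAMES}
    disp = DispositionParams(**disp_vals)
    exponents = {e.parameter_name: e.theta_bw for e in base.covariates}
    absorption = dict(base.absorption)
    residual = dict(base.residual)
    health = dict(base.health_effect)
    for name, value in thetas.items():
        if name in DISPOSITION_NAMES:
            continue
        if name.startswith("bw_"):
            exponents[name[3:]] = float(value)
        elif name.startswith("ka_"):
            route = Route(name[3:])
            absorption[route] = AbsorptionParams(route, float(value), absorption[route].f)
        elif name.startswith("f_"):
            route = Route(name[2:])
            absorption[route] = AbsorptionParams(route, absorption[route].ka, float(value))
        elif name.startswith("stdev0_"):
            route = Route(name[7:])
            residual[route] = ResidualModel(float(value), residual[route].cmult)
        elif name.startswith("cmult_"):
            route = Route(name[6:])
            residual[route] = ResidualModel(residual[route].stdev0, float(value))
        elif name.startswith("health_f_"):
            health[Route(name[9:])] = float(value)
        else:
            raise KeyError(f"unknown theta name {name!r}")
    covariates = tuple(
        CovariateEffect(p, disp_vals[p], ex, base.ref_bw) for p, ex in exponents.items()
    )
    omega = dict(base.omega)
    omega.update({k: float(v) for k, v in omegas.items()})
    return PopulationModel(
        disposition=disp,
        covariates=covariates,
        absorption=absorption,
        omega=omega,
        residual=residual,
        ref_bw=base.ref_bw,
        health_effect=health,
    )


def _theta_value(model: PopulationModel, name: str) -> float:
    if name in DISPOSITION_NAMES:
        return float(getattr(model.disposition, name))
    if name.startswith("bw_"):
        eff = model.covariate_effect(name[3:])
        return float(eff.theta_bw) if eff is not None else 0.0
    if name.startswith("ka_"):
        return float(model.absorption[Route(name[3:])].ka)
    if name.startswith("f_"):
        return float(model.absorption[Route(name[2:])].f)
    if name.startswith("stdev0_"):
        return float(model.residual[Route(name[7:])].stdev0)
    if name.startswith("cmult_"):
        return float(model.residual[Route(name[6:])].cmult)
    if name.startswith("health_f_"):
        return float(model.health_effect.get(Route(name[9:]), 0.0))
    raise KeyError(f"unknown theta name {name!r}")


def _is_linear_scale(name: str) -> bool:
    return name.startswith("bw_") or name.startswith("health_f_")


# ---------------------------------------------------------------------------
# Laplace marginal likelihood
# ---------------------------------------------------------------------------

def _num_hessian(fun, x: np.ndarray, f0: float, step: float = 1e-4) -> np.ndarray:
    d = len(x)
    h = step * (1.0 + np.abs(x))
    hess = np.empty((d, d))
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = h[i]
        fp[i] = fun(x + e)
        fm[i] = fun(x - e)
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fmm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm) / (
                2.0 * h[i] * h[j]
            )
    return hess


def laplace_nll(joint_nll, d: int, eta0: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Laplace approximation of ``-log ∫ exp(-joint_nll(eta)) d eta``.

    ``joint_nll`` is the joint negative log density as a function of the
    d-dimensional eta vector.  Returns the approximate negative log
    marginal likelihood and the conditional mode.  Exact when the joint is
    quadratic in eta (e.g. a linear-Gaussian model).
    """
    if d == 0:
        return float(joint_nll(np.empty(0))), np.empty(0)
    x0 = np.zeros(d) if eta0 is None else np.asarray(eta0, dtype=float)
    res = minimize(joint_nll, x0, method="BFGS", options={"gtol": 1e-8, "maxiter": 500})
    hess = _num_hessian(joint_nll, res.x, res.fun)
    sign, logdet = np.linalg.slogdet(hess)
    if sign <= 0:
        raise EstimationError("joint density is not locally concave at the mode")
    nll = float(res.fun) + 0.5 * logdet - 0.5 * d * math.log(2.0 * math.pi)
    return nll, res.x


def _subject_joint_nll(subj: SubjectData, model: PopulationModel, names: list[str]):
    """Closure evaluating the per-subject joint negative log density of the
    observations and the eta vector."""
    residual = model.residual_for(subj.route)
    omega = np.array([model.omega[k] for k in names], dtype=float)
    y = subj.obs_conc
    doses = subj.doses
    obs_times = subj.obs_times
    eta_const = 0.5 * np.sum(np.log(2.0 * np.pi * omega**2)) if len(names) else 0.0

    def joint(eta_vec: np.ndarray) -> float:
        eta = {k: float(v) for k, v in zip(names, eta_vec)}
        try:
            ind = model.individual(subj.bw, subj.route, eta, health=subj.health)
            pred = conc_profile(ind.disposition, ind.absorption, doses, obs_times)
        except (ValueError, OverflowError, FloatingPointError):
            return np.inf
        sd = residual.sd(pred)
        if not np.all(np.isfinite(sd)) or np.any(sd <= 0.0):
            raise EstimationError(
                f"non-positive residual SD for subject {subj.subject_id!r}", subj.subject_id
            )
        nll = 0.5 * float(np.sum(((y - pred) / sd) ** 2 + np.log(2.0 * np.pi * sd**2)))
        if len(names):
            nll += 0.5 * float(np.sum((eta_vec / omega) ** 2)) + eta_const
        return nll if np.isfinite(nll) else np.inf

    return joint


def _laplace_subject(
    subj: SubjectData, model: PopulationModel, eta0: np.ndarray | None = None
) -> tuple[float, dict[str, float]]:
    """Laplace -log marginal likelihood of one subject and its EBE."""
    names = model.eta_names(subj.route)
    joint = _subject_joint_nll(subj, model, names)
    d = len(names)
    if d == 0:
        return joint(np.empty(0)), {}
    x0 = np.zeros(d) if eta0 is None or len(eta0) != d else np.asarray(eta0, dtype=float)
    res = minimize(joint, x0, method="BFGS", options={"gtol": 1e-5, "maxiter": 100})
    if not np.isfinite(res.fun):
        return np.inf, {k: 0.0 for k in names}
    hess = _num_hessian(joint, res.x, res.fun)
    sign, logdet = np.linalg.slogdet(hess)
    if sign <= 0:  # fall back to a ridge-stabilized curvature
        hess = hess + np.eye(d) * (1e-8 + np.abs(np.diag(hess)).max() * 1e-8)
        sign, logdet = np.linalg.slogdet(hess)
        if sign <= 0:
            return np.inf, dict(zip(names, res.x))
    nll = float(res.fun) + 0.5 * logdet - 0.5 * d * math.log(2.0 * math.pi)
    return nll, {k: float(v) for k, v in zip(names, res.x)}


def _as_subjects(data) -> list[SubjectData]:
    if isinstance(data, Dataset):
        return data.subjects()
    return list(data)


def marginal_ofv(
    dataset,
    model: PopulationModel,
    thetas: dict[str, float] | None = None,
    omegas: dict[str, float] | None = None,
    return_ebes: bool = False,
    warm_etas: dict | None = None,
):
    """Laplace-approximate OFV (-2 marginal log-likelihood) of a dataset.

    ``thetas`` / ``omegas`` optionally override named parameters of the
    model (see :func:`build_model`).  With all omegas zero the OFV reduces
    to the pooled extended-least-squares -2LL of the fixed-effect model.
    When ``return_ebes`` is set, also returns the per-subject empirical
    Bayes eta estimates.
    """
    subjects = _as_subjects(dataset)
    if not subjects:
        raise ValueError("dataset contains no subjects")
    if thetas or omegas:
        model = build_model(model, thetas, omegas)
    total = 0.0
    ebes: dict[str, dict[str, float]] = {}
    for subj in subjects:
        eta0 = None
        if warm_etas is not None and subj.subject_id in warm_etas:
            eta0 = np.array(list(warm_etas[subj.subject_id].values()))
        nll, eta_hat = _laplace_subject(subj, model, eta0)
        if warm_etas is not None:
            warm_etas[subj.subject_id] = eta_hat
        ebes[subj.subject_id] = eta_hat
        total += 2.0 * nll
    if return_ebes:
        return total, ebes
    return total


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class PopPKResults:
    """Estimation results: estimates, OFV/AIC, empirical Bayes etas and
    diagnostics."""

    model: PopulationModel
    thetas: dict[str, float]
    omegas: dict[str, float]
    ofv: float
    n_params: int
    aic: float
    ebes: dict[str, dict[str, float]]
    converged: bool
    message: str
    stage: str
    n_subjects: int
    n_observations: int
    ofv_history: list[float] = field(default_factory=list)
    _subjects: list[SubjectData] | None = field(default=None, repr=False)

    def eta_shrinkage(self) -> dict[str, float | None]:
        """Per-parameter eta shrinkage, 100*(1 - SD(EBE)/omega)."""
        return shrinkage(self.ebes, self.model.omega)

    def epsilon_shrinkage(self) -> float | None:
        """Epsilon shrinkage, 100*(1 - SD(IWRES))."""
        if not self._subjects:
            return None
        iwres = []
        for subj in self._subjects:
            eta = self.ebes.get(subj.subject_id, {})
            ind = self.model.individual(subj.bw, subj.route, eta, health=subj.health)
            pred = conc_profile(ind.disposition, ind.absorption, subj.doses, subj.obs_times)
            sd = self.model.residual_for(subj.route).sd(pred)
            iwres.extend(((subj.obs_conc - pred) / sd).tolist())
        if len(iwres) < 2:
            return None
        return 100.0 * (1.0 - float(np.std(iwres, ddof=1)))

    def summary(self) -> pd.DataFrame:
        """Parameter table: estimates and BSV% (lognormal CV) per omega."""
        rows = [
            {"parameter": k, "kind": "theta", "estimate": v, "bsv_percent": np.nan}
            for k, v in self.thetas.items()
        ]
        rows += [
            {
                "parameter": f"omega_{k}",
                "kind": "omega",
                "estimate": v,
                "bsv_percent": omega_to_bsv_percent(v),
            }
            for k, v in self.omegas.items()
        ]
        rows.append(
            {"parameter": "OFV", "kind": "fit", "estimate": self.ofv, "bsv_percent": np.nan}
        )
        rows.append(
            {"parameter": "AIC", "kind": "fit", "estimate": self.aic, "bsv_percent": np.nan}
        )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)


def _default_free(dataset: Dataset, base_model: PopulationModel, stage: str):
    routes = dataset.routes()
    if stage == "iv_only":
        thetas = list(DISPOSITION_NAMES)
        thetas += [f"bw_{e.parameter_name}" for e in base_model.covariates]
        thetas += ["stdev0_IV", "cmult_IV"]
        omegas = [k for k in DISPOSITION_NAMES if k in base_model.omega]
        return thetas, omegas
    if stage == "oral_given_iv":
        thetas = []
        for r in routes:
            if r.is_oral:
                thetas += [f"ka_{r.value}", f"f_{r.value}", f"stdev0_{r.value}", f"cmult_{r.value}"]
        omegas = list(base_model.omega)
        return thetas, omegas
    # joint
    thetas = list(DISPOSITION_NAMES)
    thetas += [f"bw_{e.parameter_name}" for e in base_model.covariates]
    for r in routes:
        thetas += [f"stdev0_{r.value}", f"cmult_{r.value}"]
        if r.is_oral:
            thetas += [f"ka_{r.value}", f"f_{r.value}"]
    return thetas, list(base_model.omega)


def fit(
    dataset: Dataset,
    base_model: PopulationModel,
    stage: str = "joint",
    free_thetas: list[str] | None = None,
    free_omegas: list[str] | None = None,
    inits: dict[str, float] | None = None,
    prior: PopPKResults | None = None,
    maxiter: int = 500,
    method: str = "Nelder-Mead",
    tol: float = 1e-3,
) -> PopPKResults:
    """Estimate free parameters by minimizing the Laplace OFV.

    Parameters
    ----------
    stage
        ``"iv_only"`` restricts the dataset to IV subjects and estimates
        the disposition block; ``"oral_given_iv"`` freezes the IV fixed
        effects at a prior fit's optimum (``prior``) and estimates only
        the oral Ka/F, oral residuals and — jointly — all omegas;
        ``"joint"`` frees everything.
    free_thetas, free_omegas
        Explicit parameter lists overriding the stage defaults.
    inits
        Initial values by parameter name (default: the base model's).
    """
    if stage not in ("iv_only", "oral_given_iv", "joint"):
        raise ValueError(f"unknown stage {stage!r}")
    if stage == "iv_only":
        dataset = dataset.filter_routes([Route.IV])
    if stage == "oral_given_iv":
        if prior is None:
            raise ValueError("stage 'oral_given_iv' requires the prior IV fit result")
        base_model = prior.model

    defaults = _default_free(dataset, base_model, stage)
    free_thetas = list(free_thetas) if free_thetas is not None else defaults[0]
    free_omegas = list(free_omegas) if free_omegas is not None else defaults[1]
    for name in free_omegas:
        if name not in base_model.omega:
            raise KeyError(f"free omega {name!r} not present in the base model's omega")

    inits = dict(inits or {})
    subjects = _as_subjects(dataset)
    if not subjects:
        raise ValueError("no subjects to fit")

    # encode: positive parameters on the log scale, exponents linear
    names = [("theta", n) for n in free_thetas] + [("omega", n) for n in free_omegas]
    x0, bounds, scales = [], [], []
    for kind, name in names:
        if kind == "theta":
            value = inits.get(name, _theta_value(base_model, name))
        else:
            value = inits.get(f"omega_{name}", base_model.omega[name])
        if kind == "theta" and _is_linear_scale(name):
            x0.append(value)
            bounds.append((-5.0, 5.0))
            scales.append("linear")
        else:
            if value <= 0.0:
                value = 1e-3
            x0.append(math.log(value))
            bounds.append((math.log(value) + math.log(1e-4), math.log(value) + math.log(1e3)))
            scales.append("log")
    x0 = np.asarray(x0, dtype=float)

    warm: dict = {}
    history: list[float] = []

    def decode(x: np.ndarray):
        thetas, omegas = {}, {}
        for (kind, name), value, scale in zip(names, x, scales):
            value = float(value) if scale == "linear" else math.exp(float(value))
            if kind == "theta":
                thetas[name] = value
            else:
                omegas[name] = value
        return thetas, omegas

    def objective(x: np.ndarray) -> float:
        thetas, omegas = decode(x)
        try:
            model = build_model(base_model, thetas, omegas)
            ofv = marginal_ofv(subjects, model, warm_etas=warm)
        except (EstimationError, ValueError, KeyError, FloatingPointError):
            return _PENALTY
        if not np.isfinite(ofv):
            return _PENALTY
        history.append(min(ofv, history[-1]) if history else ofv)
        return ofv

    if len(x0):
        if method.lower() == "nelder-mead":
            options = {"maxiter": maxiter, "xatol": tol, "fatol": tol}
        elif method.lower() == "powell":
            options = {"maxiter": maxiter, "xtol": tol, "ftol": tol}
        else:
            options = {"maxiter": maxiter}
        res = minimize(objective, x0, method=method, bounds=bounds, options=options)
        x_best, converged, message = res.x, bool(res.success), str(res.message)
    else:
        x_best, converged, message = x0, True, "nothing to estimate"

    thetas, omegas = decode(x_best)
    final_model = build_model(base_model, thetas, omegas)
    ofv, ebes = marginal_ofv(subjects, final_model, return_ebes=True)
    if not np.isfinite(ofv):
        converged, message = False, "non-finite OFV at reported optimum"
    n_params = len(free_thetas) + len(free_omegas)
    return PopPKResults(
        model=final_model,
        thetas=thetas,
        omegas=omegas,
        ofv=float(ofv),
        n_params=n_params,
        aic=float(ofv) + 2.0 * n_params,
        ebes=ebes,
        converged=converged,
        message=message,
        stage=stage,
        n_subjects=len(subjects),
        n_observations=int(sum(len(s.obs_times) for s in subjects)),
        ofv_history=history,
        _subjects=subjects,
    )


# ---------------------------------------------------------------------------
# covariate search
# ---------------------------------------------------------------------------

def covariate_search(
    dataset: Dataset,
    base_model: PopulationModel,
    parameters: tuple[str, ...] = DISPOSITION_NAMES,
    free_thetas: list[str] | None = None,
    free_omegas: list[str] | None = None,
    delta_aic: float = AIC_SIGNIFICANCE,
    **fit_kwargs,
) -> pd.DataFrame:
    """Shotgun body-weight covariate search.

    Fits every subset of ``parameters`` with a power-model BW exponent
    (2^k subsets including the empty base model) and ranks by AIC; subsets
    improving the base AIC by at least ``delta_aic`` (the p<0.01 LRT
    equivalent) are flagged.  Ties in AIC are broken toward the smaller
    subset (parsimony).  ``base_model`` should carry no BW covariates;
    exponent thetas are added per subset.
    """
    bws = {s.subject_id: s.bw for s in dataset.subjects()}
    if len(set(round(b, 9) for b in bws.values())) < 2:
        raise ValueError("body weight is constant across subjects; exponents are unidentifiable")
    if base_model.covariates:
        raise ValueError("pass a base model without BW covariates to covariate_search")

    if free_thetas is None:
        free_thetas = list(DISPOSITION_NAMES)
        for r in dataset.routes():
            free_thetas += [f"stdev0_{r.value}", f"cmult_{r.value}"]
            if r.is_oral:
                free_thetas += [f"ka_{r.value}", f"f_{r.value}"]
    if free_omegas is None:
        free_omegas = list(base_model.omega)

    subsets: list[tuple[str, ...]] = [()]
    for p in parameters:
        subsets += [s + (p,) for s in subsets]

    rows = []
    base_result = None
    for subset in sorted(subsets, key=len):
        extra = [f"bw_{p}" for p in subset]
        result = fit(
            dataset,
            base_model,
            stage="joint",
            free_thetas=free_thetas + extra,
            free_omegas=free_omegas,
            **fit_kwargs,
        )
        if subset == ():
            base_result = result
        rows.append(
            {
                "subset": subset,
                "n_cov": len(subset),
                "ofv": result.ofv,
                "aic": result.aic,
                "converged": result.converged,
                **{f"bw_{p}": result.thetas.get(f"bw_{p}", np.nan) for p in parameters},
            }
        )
    table = pd.DataFrame(rows)
    base_aic = base_result.aic
    table["delta_aic"] = table["aic"] - base_aic
    table["flagged"] = table["delta_aic"] <= -delta_aic
    table = table.sort_values(["aic", "n_cov"], kind="stable").reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Percentile bootstrap summary over subject resamples."""

    table: pd.DataFrame  # index: parameter; columns: mean, cv_percent, median, p2_5, p97_5
    n_success: int
    n_failed: int
    estimates: pd.DataFrame  # one row per successful resample

    def significant(self, parameter: str) -> bool:
        """True when the 95% CI of the parameter excludes 0."""
        row = self.table.loc[parameter]
        return bool(row["p2_5"] > 0.0 or row["p97_5"] < 0.0)


def _resample_dataset(dataset: Dataset, rng: np.random.Generator, stratify: bool) -> Dataset:
    df = dataset.df
    groups = dict(tuple(df.groupby("subject", sort=False)))
    route_of = {sid: g["route"].iloc[0] for sid, g in groups.items()}
    chosen: list[str] = []
    if stratify:
        by_route: dict[str, list[str]] = {}
        for sid, r in route_of.items():
            by_route.setdefault(r, []).append(sid)
        for r, sids in by_route.items():
            chosen.extend(rng.choice(sids, size=len(sids), replace=True).tolist())
    else:
        sids = list(groups)
        chosen = rng.choice(sids, size=len(sids), replace=True).tolist()
    parts = []
    for k, sid in enumerate(chosen):
        part = groups[sid].copy()
        part["subject"] = f"{sid}#bs{k}"
        parts.append(part)
    return Dataset(pd.concat(parts, ignore_index=True))


def bootstrap_ci(
    dataset: Dataset,
    base_model: PopulationModel,
    free_thetas: list[str],
    free_omegas: list[str] | None = None,
    n_resamples: int = 100,
    seed: int = 0,
    stratify_by_route: bool = True,
    max_failure_fraction: float = 0.2,
    **fit_kwargs,
) -> BootstrapResult:
    """Percentile bootstrap CIs by resampling subjects with replacement
    (stratified by route), refitting each resample.

    Each resample has exactly as many subjects as the original dataset.
    Aborts when more than ``max_failure_fraction`` of the refits fail.
    """
    if dataset.n_subjects < 10:
        raise ValueError("bootstrap requires at least 10 subjects")
    free_omegas = list(free_omegas or [])
    rng = np.random.default_rng(seed)
    records = []
    n_failed = 0
    for _ in range(n_resamples):
        resampled = _resample_dataset(dataset, rng, stratify_by_route)
        try:
            result = fit(
                resampled,
                base_model,
                free_thetas=free_thetas,
                free_omegas=free_omegas,
                **fit_kwargs,
            )
        except (EstimationError, ValueError):
            n_failed += 1
            continue
        if not np.isfinite(result.ofv):
            n_failed += 1
            continue
        records.append({**result.thetas, **{f"omega_{k}": v for k, v in result.omegas.items()}})
        if n_failed > max_failure_fraction * n_resamples:
            raise RuntimeError(
                f"bootstrap aborted: {n_failed} of {n_resamples} resample fits failed"
            )
    if n_failed > max_failure_fraction * n_resamples:
        raise RuntimeError(f"bootstrap aborted: {n_failed} of {n_resamples} resample fits failed")
    estimates = pd.DataFrame.from_records(records)
    table = pd.DataFrame(
        {
            "mean": estimates.mean(),
            "cv_percent": 100.0 * estimates.std(ddof=1) / estimates.mean().abs(),
            "median": estimates.median(),
            "p2_5": estimates.quantile(0.025),
            "p97_5": estimates.quantile(0.975),
        }
    )
    return BootstrapResult(table=table, n_success=len(records), n_failed=n_failed, estimates=estimates)


# ---------------------------------------------------------------------------
# shrinkage and VPC
# ---------------------------------------------------------------------------

def shrinkage(ebes, omega: dict[str, float]) -> dict[str, float | None]:
    """Eta shrinkage per parameter: ``100 * (1 - SD(eta_EBE) / omega)``.

    ``ebes`` is a mapping subject -> {eta name: value} (or an iterable of
    such dictionaries).  Parameters with omega = 0 or fewer than two
    subjects are reported as None (undefined).
    """
    if isinstance(ebes, dict):
        ebe_list = list(ebes.values())
    else:
        ebe_list = list(ebes)
    if len(ebe_list) < 2:
        raise ValueError("shrinkage requires at least 2 subjects")
    out: dict[str, float | None] = {}
    for name, om in omega.items():
        values = [e[name] for e in ebe_list if name in e]
        if om <= 0.0 or len(values) < 2:
            out[name] = None
        else:
            out[name] = 100.0 * (1.0 - float(np.std(values, ddof=1)) / om)
    return out


@dataclass
class VPCResult:
    """Observed vs simulated quantile bands per time bin."""

    table: pd.DataFrame
    quantiles: tuple[float, ...]
    n_replicates: int

    def fraction_within_bands(self) -> float:
        """Fraction of (bin, quantile) cells whose observed quantile lies
        inside the simulated 95% band."""
        ok = 0
        total = 0
        for q in self.quantiles:
            obs = self.table[f"obs_q{q:g}"]
            lo = self.table[f"sim_q{q:g}_lo"]
            hi = self.table[f"sim_q{q:g}_hi"]
            total += len(obs)
            ok += int(((obs >= lo) & (obs <= hi)).sum())
        return ok / total if total else float("nan")


def vpc_check(
    dataset: Dataset,
    model: PopulationModel,
    n_replicates: int = 500,
    quantiles: tuple[float, ...] = (10.0, 50.0, 90.0),
    seed: int = 0,
    max_bins: int = 12,
) -> VPCResult:
    """Visual predictive check: simulate every subject's design
    ``n_replicates`` times from the model (BSV + residual error) and
    compare observed quantiles per time bin with the simulated quantile
    distribution (median and 95% band).

    Time bins are the unique sampling times when few, otherwise
    equal-count bins; empty bins are merged with their neighbor.
    """
    subjects = _as_subjects(dataset)
    obs_times = np.concatenate([s.obs_times for s in subjects])
    obs_conc = np.concatenate([s.obs_conc for s in subjects])
    uniq = np.unique(obs_times)
    if len(uniq) <= max_bins:
        edges = np.concatenate([[uniq[0] - 1e-9], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1e-9]])
    else:
        qs = np.linspace(0.0, 1.0, max_bins + 1)
        edges = np.unique(np.quantile(obs_times, qs))
        edges[0] -= 1e-9
        edges[-1] += 1e-9
    idx = np.clip(np.searchsorted(edges, obs_times, side="right") - 1, 0, len(edges) - 2)
    # merge empty bins with their left neighbor
    counts = np.bincount(idx, minlength=len(edges) - 1)
    if np.any(counts == 0):
        warnings.warn("empty VPC time bins merged with neighbors", stacklevel=2)
        keep = counts > 0
        edges = np.concatenate([[edges[0]], edges[1:][keep]])
        idx = np.clip(np.searchsorted(edges, obs_times, side="right") - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1

    rng = np.random.default_rng(seed)
    qfracs = [q / 100.0 for q in quantiles]
    obs_q = np.array(
        [
            [np.quantile(obs_conc[idx == b], f) for f in qfracs]
            for b in range(n_bins)
        ]
    )
    sim_q = np.empty((n_replicates, n_bins, len(qfracs)))
    names_cache = {s.subject_id: model.eta_names(s.route) for s in subjects}
    for r in range(n_replicates):
        sims = []
        for s in subjects:
            names = names_cache[s.subject_id]
            eta = {
                k: float(rng.standard_normal() * model.omega[k]) for k in names
            }
            ind = model.individual(s.bw, s.route, eta, health=s.health)
            pred = conc_profile(ind.disposition, ind.absorption, s.doses, s.obs_times)
            noisy = pred + rng.standard_normal(pred.shape) * model.residual_for(s.route).sd(pred)
            sims.append(noisy)
        sim_conc = np.concatenate(sims)
        for b in range(n_bins):
            sel = sim_conc[idx == b]
            for j, f in enumerate(qfracs):
                sim_q[r, b, j] = np.quantile(sel, f)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        row = {
            "t_mid": float(np.median(obs_times[sel])),
            "n_obs": int(sel.sum()),
        }
        for j, q in enumerate(quantiles):
            row[f"obs_q{q:g}"] = float(obs_q[b, j])
            row[f"sim_q{q:g}_lo"] = float(np.quantile(sim_q[:, b, j], 0.025))
            row[f"sim_q{q:g}_med"] = float(np.quantile(sim_q[:, b, j], 0.5))
            row[f"sim_q{q:g}_hi"] = float(np.quantile(sim_q[:, b, j], 0.975))
        rows.append(row)
    return VPCResult(table=pd.DataFrame(rows), quantiles=tuple(quantiles), n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# statsmodels-style front door
# ---------------------------------------------------------------------------

class PopPKModel:
    """Population PK model bound to a dataset, statsmodels-style.

    Construct from a :class:`~doxypk.io.Dataset` (or a long-format
    DataFrame via :meth:`from_dataframe`) plus a base
    :class:`~doxypk.population.PopulationModel` giving the structure and
    starting values; :meth:`fit` returns :class:`PopPKResults`.
    """

    def __init__(
        self,
        dataset: Dataset,
        base_model: PopulationModel,
        free_thetas: list[str] | None = None,
        free_omegas: list[str] | None = None,
    ):
        self.dataset = dataset
        self.base_model = base_model
        self.free_thetas = free_thetas
        self.free_omegas = free_omegas

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, base_model: PopulationModel, **kwargs) -> "PopPKModel":
        return cls(Dataset(df), base_model, **kwargs)

    def ofv(self, thetas=None, omegas=None) -> float:
        return marginal_ofv(self.dataset, self.base_model, thetas, omegas)

    def fit(self, stage: str = "joint", **kwargs) -> PopPKResults:
        kwargs.setdefault("free_thetas", self.free_thetas)
        kwargs.setdefault("free_omegas", self.free_omegas)
        return fit(self.dataset, self.base_model, stage=stage, **kwargs)

    def covariate_search(self, **kwargs) -> pd.DataFrame:
        return covariate_search(self.dataset, self.base_model, **kwargs)

    def bootstrap(self, **kwargs) -> BootstrapResult:
        kwargs.setdefault("free_thetas", self.free_thetas or [])
        kwargs.setdefault("free_omegas", self.free_omegas)
        return bootstrap_ci(self.dataset, self.base_model, **kwargs)

    def vpc(self, fitted: PopulationModel | None = None, **kwargs) -> VPCResult:
        return vpc_check(self.dataset, fitted or self.base_model, **kwargs)
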