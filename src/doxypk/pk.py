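"""Closed-form concentration-time solutions for the 3-compartment model.

The disposition matrix of a mammillary model with positive parameters has
three real, negative, distinct eigenvalues, so the IV-bolus solution is a
tri-exponential and the first-order-input (oral) solution a
quadri-exponential in the central compartment.  Profiles are assembled by
modal (eigen) decomposition and multi-dose superposition; a matrix
exponential fallback covers near-degenerate eigenvalue spacing, and an
absorption rate colliding with a disposition eigenvalue (a removable
singularity) is resolved by a relative 1e-7 perturbation of Ka.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
from scipy.linalg import expm

from doxypk.params import (
    AbsorptionParams,
    DispositionParams,
    DoseEvent,
    Route,
    SecondaryParams,
)

__all__ = ["disposition_eigenvalues", "conc_profile", "derived_params"]

# Relative eigenvalue spacing below which the modal expansion is abandoned
# for the (slower, unconditionally stable) matrix-exponential path.
_EIG_SPACING_TOL = 1e-9
# Relative |Ka - lambda| below which Ka is perturbed off the singularity.
_KA_COLLISION_TOL = 1e-8


def disposition_eigenvalues(disp: DispositionParams) -> np.ndarray:
    """Eigenvalues of the 3x3 disposition rate matrix, ascending (most
    negative first); all three are real, negative and distinct for any
    positive parameter set."""
    lam = np.linalg.eigvals(disp.rate_matrix())
    lam = np.real_if_close(lam, tol=1e6)
    if np.iscomplexobj(lam):  # pragma: no cover - excluded by model structure
        lam = lam.real
    return np.sort(lam)


def _system(
    disp: DispositionParams, absorption: AbsorptionParams, ka_scale: float = 1.0
) -> tuple[np.ndarray, int, np.ndarray]:
    """Build the full first-order system for one dose.

    Returns (matrix, central_index, initial_amount_vector_per_unit_dose).
    """
    k3 = disp.rate_matrix()
    if not absorption.route.is_oral:
        a0 = np.array([1.0, 0.0, 0.0])
        return k3, 0, a0
    m = np.zeros((4, 4))
    ka = float(absorption.ka) * ka_scale
    m[0, 0] = -ka
    m[1, 0] = ka
    m[1:, 1:] = k3
    a0 = np.zeros(4)
    a0[0] = absorption.f  # only the bioavailable fraction enters the depot
    return m, 1, a0


def _decompose(matrix: np.ndarray, central: int, a0: np.ndarray):
    """Eigendecompose the system once; returns (coeff, lam) for the modal
    expansion ``amount(t) = sum_m coeff[m] * exp(lam[m] * t)`` of the
    central compartment per unit dose, or None when the eigenvalue spacing
    is too tight for a stable expansion."""
    lam, vec = np.linalg.eig(matrix)
    lam = np.real_if_close(lam, tol=1e6)
    if np.iscomplexobj(lam):
        return None
    if lam.size > 1:
        sorted_lam = np.sort(lam)
        gaps = np.diff(sorted_lam)
        if np.min(np.abs(gaps) / np.max(np.abs(sorted_lam))) < _EIG_SPACING_TOL:
            return None
    coeff = vec[central, :] * np.linalg.solve(vec, a0)
    return np.real_if_close(coeff).astype(float), lam.astype(float)


def _expm_profile(
    matrix: np.ndarray, central: int, a0: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Matrix-exponential fallback for near-degenerate eigenvalue spacing."""
    out = np.empty_like(times, dtype=float)
    state = a0.copy()
    prev = 0.0
    order = np.argsort(times, kind="stable")
    for idx in order:
        t = times[idx]
        if t != prev:
            state = expm(matrix * (t - prev)) @ state
            prev = t
        out[idx] = state[central]
    return out


def conc_profile(
    disp: DispositionParams,
    absorption: AbsorptionParams,
    doses: Sequence[DoseEvent],
    times: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Central-compartment concentration (ug/mL) at the requested times.

    Multi-dose profiles are the superposition of per-dose closed-form
    solutions (the model is linear).  For IV bolus the value at a dose time
    is the post-dose concentration C(0+) = dose/Vc; first-order input is
    continuous with C(0) = 0.

    Parameters
    ----------
    disp, absorption
        Typical or individual parameter set; every dose's route must match
        ``absorption.route``.
    doses
        Dose events, mg/kg doxycycline base.
    times
        Non-negative, sorted sampling times in hours since the first dose.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if times.size and times[0] < 0.0:
        raise ValueError("times must be non-negative")
    if np.any(np.diff(times) < 0.0):
        raise ValueError("times must be sorted ascending")
    if not doses:
        raise ValueError("at least one dose event is required")
    for d in doses:
        if d.route is not absorption.route:
            raise ValueError(
                f"dose route {d.route.value} does not match absorption route {absorption.route.value}"
            )

    matrix, central, a0 = _system(disp, absorption)
    modes = _decompose(matrix, central, a0)
    if modes is None and absorption.route.is_oral:
        # near-degenerate spacing with first-order input almost always
        # means Ka collided with a disposition eigenvalue — a removable
        # singularity; perturb Ka and retry before the slow expm fallback
        lam = disposition_eigenvalues(disp)
        if np.min(np.abs(absorption.ka + lam) / np.abs(lam)) < _KA_COLLISION_TOL * 10:
            warnings.warn(
                "absorption rate constant coincides with a disposition eigenvalue; "
                "perturbing Ka by 1e-7 relative to lift the removable singularity",
                stacklevel=2,
            )
            matrix, central, a0 = _system(disp, absorption, ka_scale=1.0 + 1e-7)
            modes = _decompose(matrix, central, a0)
    conc = np.zeros_like(times, dtype=float)
    for dose in doses:
        rel = times - dose.time
        active = rel >= 0.0
        if not np.any(active):
            continue
        if modes is not None:
            coeff, lam = modes
            amount = np.exp(np.outer(rel[active], lam)) @ coeff
        else:
            amount = _expm_profile(matrix, central, a0, rel[active])
        conc[active] += dose.amount * np.maximum(amount, 0.0)
    return conc / disp.vc


def terminal_half_life(disp: DispositionParams) -> float:
    """ln 2 over the smallest-magnitude disposition eigenvalue (h)."""
    lam = disposition_eigenvalues(disp)
    return float(np.log(2.0) / np.abs(lam).min())


def derived_params(
    disp: DispositionParams,
    absorption: AbsorptionParams | None = None,
    daily_dose: float | None = None,
) -> SecondaryParams:
    """Secondary parameters of one parameter set.

    The terminal half-life comes from the smallest-magnitude root of the
    characteristic polynomial of the disposition matrix; Vss = Vc+V2+V3;
    MRT_iv = Vss/Cl.  With an oral absorption submodel, MAT = 1/Ka and,
    given a daily dose (mg/kg), the steady-state daily exposure
    AUC_ss_24h = F*daily_dose/Cl.
    """
    vss = disp.vc + disp.v2 + disp.v3
    mat = None
    f = 1.0
    if absorption is not None and absorption.route.is_oral:
        mat = 1.0 / absorption.ka
        f = absorption.f
    auc = None
    if daily_dose is not None:
        if daily_dose <= 0.0:
            raise ValueError("daily dose must be positive")
        auc = f * daily_dose / disp.cl
    return SecondaryParams(
        terminal_half_life=terminal_half_life(disp),
        vss=vss,
        mrt_iv=vss / disp.cl,
        mat=mat,
        auc_ss_24h=auc,
    )
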