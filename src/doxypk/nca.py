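"""Non-compartmental analysis of concentration-time profiles.

Exposure metrics follow the standard IV-bolus NCA conventions: AUC by the
linear trapezoidal rule, terminal slope (lambda_z) by log-linear least
squares on the best contiguous terminal window, extrapolation to infinity
from the last measured concentration, and the clearance/volume quantities
derived from them.  Clearance and volumes are reported in mL-based units
(mL/h/kg, mL/kg) as customary in NCA summary tables; concentrations are
ug/mL and doses mg/kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from doxypk.params import Route

__all__ = ["NCAResult", "BioavailabilityResult", "run_nca", "bioavailability"]


@dataclass(frozen=True)
class NCAResult:
    """Per-profile NCA metrics.

    lambda_z-dependent fields are None when no acceptable terminal fit
    exists (fewer than 3 usable points or a non-negative terminal slope),
    mirroring the "not computable" convention of NCA reports.  Clearance
    and volume fields are populated for IV profiles only (oral profiles
    confound them with F).
    """

    auc_last: float
    auc_last_per_dose: float
    auc_inf: float | None
    lambda_z: float | None
    terminal_half_life: float | None
    n_lambda_z: int | None
    cl: float | None          # mL/h/kg (Cl/F would apply for oral)
    mrt: float | None         # h
    vss: float | None         # mL/kg
    vz: float | None          # mL/kg


@dataclass(frozen=True)
class BioavailabilityResult:
    """Absolute oral bioavailability from dose-normalized AUC ratio."""

    f_percent: float
    auc_oral_per_dose: float
    auc_iv_per_dose: float


def _trapz(t: np.ndarray, y: np.ndarray) -> float:
    return float(np.trapezoid(y, t))


def _best_terminal_window(t: np.ndarray, c: np.ndarray) -> tuple[float, float, int] | None:
    """Log-linear terminal fit by best adjusted R^2 over all contiguous
    windows of >= 3 points that end at the last observation and exclude
    Cmax.  Returns (lambda_z, intercept_log, n_points) or None."""
    i_cmax = int(np.argmax(c))
    n = len(t)
    best = None
    best_score = -np.inf
    logc = np.log(c)
    for start in range(i_cmax + 1, n - 2):
        tt, yy = t[start:], logc[start:]
        m = len(tt)
        slope, intercept = np.polyfit(tt, yy, 1)
        if slope >= 0.0:
            continue
        resid = yy - (slope * tt + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        if ss_tot <= 0.0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
        if adj > best_score + 1e-12:
            best_score = adj
            best = (-slope, intercept, m)
    return best


def run_nca(
    times,
    concentrations,
    dose: float,
    route: Route | str = Route.IV,
    lloq: float | None = None,
) -> NCAResult:
    """Run NCA on one profile.

    Parameters
    ----------
    times, concentrations
        Sorted sampling times (h) and plasma concentrations (ug/mL); at
        least 3 positive concentrations are required.  Values below
        ``lloq`` (if given) are excluded up front.
    dose
        Administered dose, mg/kg doxycycline base.
    route
        IV enables the clearance/volume block; any oral label restricts
        output to the exposure metrics.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("times and concentrations must be 1-d arrays of equal length")
    if np.any(np.diff(t) < 0.0):
        raise ValueError("times must be sorted ascending")
    if dose <= 0.0:
        raise ValueError("dose must be positive")
    keep = c > 0.0
    if lloq is not None:
        keep &= c >= lloq
    t, c = t[keep], c[keep]
    if len(t) < 3:
        raise ValueError("NCA requires at least 3 positive concentrations")

    route = Route(route)
    if route is Route.IV and t[0] > 0.0:
        # IV bolus: back-extrapolate C0 log-linearly from the first two
        # positive concentrations (the standard bolus convention) so the
        # area before the first sample is not dropped
        if c[1] > 0.0 and c[0] > c[1]:
            slope0 = (math.log(c[1]) - math.log(c[0])) / (t[1] - t[0])
            c0 = math.exp(math.log(c[0]) - slope0 * t[0])
        else:
            c0 = c[0]
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[c0], c])
    auc_last = _trapz(t, c)
    aumc_last = _trapz(t, t * c)
    fit = _best_terminal_window(t, c)

    if fit is None:
        return NCAResult(
            auc_last=auc_last,
            auc_last_per_dose=auc_last / dose,
            auc_inf=None,
            lambda_z=None,
            terminal_half_life=None,
            n_lambda_z=None,
            cl=None,
            mrt=None,
            vss=None,
            vz=None,
        )

    lz, _, n_lz = fit
    clast, tlast = c[-1], t[-1]
    auc_inf = auc_last + clast / lz
    aumc_inf = aumc_last + clast * tlast / lz + clast / lz**2
    mrt = aumc_inf / auc_inf
    cl = vss = vz = None
    if route is Route.IV:
        cl = dose / auc_inf * 1000.0            # mL/h/kg
        vss = cl * mrt                          # mL/kg
        vz = cl / lz                            # mL/kg
    return NCAResult(
        auc_last=auc_last,
        auc_last_per_dose=auc_last / dose,
        auc_inf=auc_inf,
        lambda_z=lz,
        terminal_half_life=math.log(2.0) / lz,
        n_lambda_z=n_lz,
        cl=cl,
        mrt=mrt if route is Route.IV else None,
        vss=vss,
        vz=vz,
    )


def bioavailability(
    oral: NCAResult,
    iv: NCAResult | None = None,
    reference_iv_auc_per_dose: float | None = None,
) -> BioavailabilityResult:
    """Absolute bioavailability F% from dose-normalized AUCs.

    Uses the within-trial IV result when available, otherwise a
    caller-supplied reference dose-normalized IV AUC (e.g. an all-trial
    mean) for trials with no IV arm.
    """
    if iv is not None:
        ref = iv.auc_last_per_dose
    elif reference_iv_auc_per_dose is not None:
        ref = reference_iv_auc_per_dose
    else:
        raise ValueError("either an IV NCA result or a reference IV AUC per dose is required")
    if ref is None or ref <= 0.0:
        raise ValueError("IV reference AUC must be positive")
    return BioavailabilityResult(
        f_percent=100.0 * oral.auc_last_per_dose / ref,
        auc_oral_per_dose=oral.auc_last_per_dose,
        auc_iv_per_dose=ref,
    )
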