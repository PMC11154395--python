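"""Threshold-hazard toxicodynamic (TD) survival model.

Mortality is modelled in the stochastic-death hazard form: toxic hazard
accrues only while the internal concentration exceeds a threshold C_IT
(µg g⁻¹), at a rate proportional to the excess, with killing rate kk
((µg g⁻¹)⁻¹ h⁻¹) plus a background hazard h0 (h⁻¹):

    dH/dt = kk * max(C_int(t) - C_IT, 0) + h0
    S(t)  = exp(-H(t)),   H(0) = 0

so H(t) = h0*t + kk * ∫₀ᵗ max(C_int(s) - C_IT, 0) ds.  Control animals see
no internal excess and survive with S0(t) = exp(-h0*t); h0 defaults to 0,
appropriate when controls show no mortality.

The excess integral is evaluated exactly on the TK trajectory's closed-form
segments: within a segment C_int is unimodal (its derivative satisfies a
first-order linear ODE and changes sign at most once), so threshold
crossings are isolated by monotone-piece root finding — in closed form for
constant-forcing segments, by Brent's method to near machine precision
otherwise — and the polynomial-exponential antiderivative is applied between
crossings.  An adaptive-quadrature route is kept as an independent check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .toxicokinetics import TissueTrajectory, _Segment

__all__ = [
    "TDParams",
    "HazardTrajectory",
    "hazard",
    "survival",
    "control_survival",
    "survival_curve",
]


@dataclass(frozen=True)
class TDParams:
    """Internal threshold c_it (µg g⁻¹), killing rate kk ((µg g⁻¹)⁻¹ h⁻¹),
    background hazard h0 (h⁻¹, default 0)."""

    c_it: float
    kk: float
    h0: float = 0.0

    def __post_init__(self) -> None:
        if self.c_it < 0 or self.kk < 0 or self.h0 < 0:
            raise ValueError("TD parameters must be nonnegative")


@dataclass(frozen=True)
class HazardTrajectory:
    """Cumulative hazard H(t) and survival S(t) = e^{-H(t)} over time."""

    times: np.ndarray
    hazard: np.ndarray
    survival: np.ndarray


def _excess_integral_segment(seg: _Segment, c_it: float, ta: float, tb: float) -> float:
    """∫ max(C_int(s) - c_it, 0) ds over [ta, tb] within one segment."""
    if tb <= ta:
        return 0.0

    def f(t):
        return seg.conc(t) - c_it

    # split [ta, tb] into monotone pieces at the (at most one) extremum
    knots = [ta]
    ext = seg.extremum()
    if ext is not None and ta < ext < tb:
        knots.append(ext)
    knots.append(tb)

    # collect threshold crossings on each monotone piece
    cuts = [ta]
    for lo, hi in zip(knots, knots[1:]):
        flo, fhi = f(lo), f(hi)
        if flo == 0.0 or fhi == 0.0:
            pass  # endpoint exactly on the threshold: no interior crossing needed
        elif flo * fhi < 0:
            if seg.B == 0 and seg.Q == 0 and seg.ke > 0 and seg.D != 0:
                # constant forcing: A + D e^{-ke τ} = c_it has a log solution
                tau = -math.log((c_it - seg.A) / seg.D) / seg.ke
                cuts.append(seg.t0 + tau)
            else:
                cuts.append(brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16))
    cuts.append(tb)
    cuts = sorted(cuts)

    total = 0.0
    for lo, hi in zip(cuts, cuts[1:]):
        if hi - lo <= 0:
            continue
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            total += seg.conc_integral(lo, hi) - c_it * (hi - lo)
    return total


def hazard(
    td: TDParams,
    trajectory: TissueTrajectory,
    t: float,
    method: str = "analytic",
) -> float:
    """Cumulative hazard H(t) for a tissue trajectory.

    ``method="analytic"`` (default) integrates the excess exactly on the
    trajectory's closed-form segments; ``method="quad"`` uses adaptive
    quadrature (absolute tolerance 1e-8) as an independent route.
    """
    t = float(t)
    if t < 0 or t > trajectory.t_end * (1 + 1e-12) + 1e-12:
        raise ValueError(f"time {t} outside trajectory support [0, {trajectory.t_end}]")
    if method == "quad":
        points = sorted(
            {s.t0 for s in trajectory.segments if 0 < s.t0 < t} | {t / 2}
        )
        excess, _ = quad(
            lambda s: max(trajectory.concentration(s) - td.c_it, 0.0),
            0.0,
            t,
            points=points or None,
            epsabs=1e-8,
            limit=200,
        )
    else:
        excess = 0.0
        for seg in trajectory.segments:
            ta = max(seg.t0, 0.0)
            tb = min(seg.t1, t)
            if tb > ta:
                excess += _excess_integral_segment(seg, td.c_it, ta, tb)
    return td.h0 * t + td.kk * excess


def survival(
    td: TDParams,
    trajectory: TissueTrajectory,
    t: float,
    method: str = "analytic",
) -> float:
    """Survival probability S(t) = exp(-H(t)), in (0, 1]."""
    return math.exp(-hazard(td, trajectory, t, method=method))


def control_survival(h0: float, t) -> float:
    """Background-only survival S0(t) = exp(-h0·t)."""
    if h0 < 0:
        raise ValueError("background hazard must be nonnegative")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    out = np.exp(-h0 * t)
    return float(out) if out.ndim == 0 else out


def survival_curve(
    td: TDParams, trajectory: TissueTrajectory, times
) -> HazardTrajectory:
    """Evaluate H and S at a grid of times (ascending, within support)."""
    times = np.asarray(times, dtype=float)
    haz = np.array([hazard(td, trajectory, t) for t in times])
    return HazardTrajectory(times=times, hazard=haz, survival=np.exp(-haz))
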