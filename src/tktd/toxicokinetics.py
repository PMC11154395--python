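"""One-compartment toxicokinetic (TK) model of copper accumulation.

The tissue concentration C_int(t) (µg g⁻¹ dry weight) of an animal exposed to
a waterborne concentration C_w(t) (µg L⁻¹) follows the linear one-compartment
balance

    dC_int/dt = ku * C_w(t) - ke * C_int(t)

with uptake rate constant ku (L g⁻¹ h⁻¹) and elimination rate constant ke
(h⁻¹).  The instantaneous uptake flux is J_int(t) = ku * C_w(t)
(µg g⁻¹ h⁻¹).  Growth dilution is not modelled.

Exposure profiles are constant, piecewise-constant or piecewise-linear in
time, and the trajectory is composed from exact closed-form solutions on each
segment (integrating-factor solution for linear forcing), so no numerical
integration error enters the forward model.  On a segment starting at t0 with
C_w(t) = a + b*(t - t0), the solution is

    C_int(t0 + τ) = A + B τ + Q τ² + D e^{-ke τ}

with (for ke > 0)  A = ku a / ke - ku b / ke²,  B = ku b / ke,  Q = 0,
D = C_int(t0) - A, and (for ke = 0)  A = C_int(t0),  B = ku a,  Q = ku b / 2,
D = 0.  The ke = 0 case is the analytic limit, not a small-ke substitution.

All times are hours; all rates h⁻¹.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TKParams",
    "ExposureMode",
    "ExposureProfile",
    "TissueTrajectory",
    "cint_constant_cw",
    "uptake_rate",
    "depuration",
    "simulate_trajectory",
]


@dataclass(frozen=True)
class TKParams:
    """Uptake (ku, L g⁻¹ h⁻¹) and elimination (ke, h⁻¹) rate constants."""

    ku: float
    ke: float

    def __post_init__(self) -> None:
        if not self.ku > 0:
            raise ValueError(f"ku must be positive (got {self.ku})")
        if self.ke < 0:
            raise ValueError(f"ke must be nonnegative (got {self.ke})")


class ExposureMode(str, enum.Enum):
    CONSTANT = "constant"
    PIECEWISE_CONSTANT = "piecewise_constant"
    PIECEWISE_LINEAR = "piecewise_linear"


@dataclass(frozen=True)
class ExposureProfile:
    """Waterborne Cu concentration C_w(t), µg L⁻¹, as a function of time.

    ``breakpoints`` are strictly ascending times in hours with the first at
    0; ``values`` are the concentrations at those times.  Piecewise-constant
    profiles hold each value up to the next breakpoint; piecewise-linear
    profiles interpolate.  Beyond the last breakpoint the final value holds.
    """

    breakpoints: tuple = (0.0,)
    values: tuple = (0.0,)
    mode: ExposureMode = ExposureMode.CONSTANT

    def __post_init__(self) -> None:
        bp = tuple(float(t) for t in self.breakpoints)
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mode", ExposureMode(self.mode))
        if len(bp) != len(vals):
            raise ValueError("breakpoints and values must have equal length")
        if len(bp) == 0 or bp[0] != 0.0:
            raise ValueError("first breakpoint must be t = 0")
        if any(b1 <= b0 for b0, b1 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly ascending")
        if any(v < 0 for v in vals):
            raise ValueError("exposure concentrations must be nonnegative")

    @classmethod
    def constant(cls, cw: float) -> "ExposureProfile":
        return cls((0.0,), (cw,), ExposureMode.CONSTANT)

    @classmethod
    def pulse(cls, cw: float, duration: float) -> "ExposureProfile":
        """Constant exposure at ``cw`` for ``duration`` hours, then clean water."""
        return cls((0.0, duration), (cw, 0.0), ExposureMode.PIECEWISE_CONSTANT)

    def value(self, t):
        """Evaluate C_w at scalar or array time(s); final value held beyond."""
        t = np.asarray(t, dtype=float)
        bp = np.array(self.breakpoints)
        vals = np.array(self.values)
        if self.mode is ExposureMode.PIECEWISE_LINEAR:
            out = np.interp(t, bp, vals)
        else:
            idx = np.clip(np.searchsorted(bp, t, side="right") - 1, 0, len(bp) - 1)
            out = vals[idx]
        return float(out) if out.ndim == 0 else out

    def linear_pieces(self, t_end: float):
        """Decompose C_w on [0, t_end] into pieces (t0, t1, a, b) with
        C_w(t) = a + b*(t - t0) on [t0, t1]."""
        pieces = []
        bp = list(self.breakpoints)
        vals = list(self.values)
        for i in range(len(bp)):
            t0 = bp[i]
            t1 = bp[i + 1] if i + 1 < len(bp) else t_end
            if t0 >= t_end:
                break
            t1 = min(t1, t_end)
            if self.mode is ExposureMode.PIECEWISE_LINEAR and i + 1 < len(bp):
                slope = (vals[i + 1] - vals[i]) / (bp[i + 1] - bp[i])
            else:
                slope = 0.0
            if t1 > t0:
                pieces.append((t0, t1, vals[i], slope))
        if not pieces or pieces[-1][1] < t_end:
            # exposure held at final value beyond the last breakpoint
            t0 = pieces[-1][1] if pieces else 0.0
            pieces.append((t0, t_end, vals[-1], 0.0))
        return pieces


@dataclass(frozen=True)
class _Segment:
    """Closed-form C_int on [t0, t1]: A + B τ + Q τ² + D e^{-ke τ}, τ = t - t0."""

    t0: float
    t1: float
    A: float
    B: float
    Q: float
    D: float
    ke: float

    def conc(self, t):
        tau = np.asarray(t, dtype=float) - self.t0
        out = self.A + self.B * tau + self.Q * tau**2 + self.D * np.exp(-self.ke * tau)
        return float(out) if out.ndim == 0 else out

    def conc_prime(self, t: float) -> float:
        tau = t - self.t0
        return self.B + 2 * self.Q * tau - self.ke * self.D * math.exp(-self.ke * tau)

    def antiderivative(self, t: float) -> float:
        """∫ conc dt evaluated at absolute time t (constant of integration free)."""
        tau = t - self.t0
        out = self.A * tau + self.B * tau**2 / 2 + self.Q * tau**3 / 3
        if self.ke > 0:
            out -= (self.D / self.ke) * math.exp(-self.ke * tau)
        else:
            out += self.D * tau
        return out

    def conc_integral(self, ta: float, tb: float) -> float:
        return self.antiderivative(tb) - self.antiderivative(ta)

    def extremum(self):
        """Interior time where conc' = 0, or None (conc is unimodal here)."""
        if self.ke > 0 and self.D != 0:
            # B = ke * D * exp(-ke*tau)  =>  tau = -ln(B/(ke*D))/ke
            ratio = self.B / (self.ke * self.D)
            if ratio > 0:
                tau = -math.log(ratio) / self.ke
                if 0 < tau < self.t1 - self.t0:
                    return self.t0 + tau
        elif self.Q != 0:
            tau = -self.B / (2 * self.Q)
            if 0 < tau < self.t1 - self.t0:
                return self.t0 + tau
        return None


@dataclass(frozen=True)
class TissueTrajectory:
    """Tissue Cu concentration over time with its closed-form segment data.

    ``times``/``cint`` hold the values at the requested observation times;
    ``concentration(t)`` evaluates the exact solution anywhere on the
    trajectory's support [0, t_end].
    """

    times: np.ndarray
    cint: np.ndarray
    params: TKParams
    segments: tuple = field(default=(), repr=False)
    t_end: float = 0.0

    def concentration(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0) or np.any(t_arr > self.t_end * (1 + 1e-12) + 1e-12):
            raise ValueError(f"time outside trajectory support [0, {self.t_end}]")
        starts = np.array([s.t0 for s in self.segments])
        idx = np.clip(np.searchsorted(starts, t_arr, side="right") - 1, 0, None)
        out = np.array([self.segments[i].conc(tv) for i, tv in zip(idx, t_arr)])
        return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def cint_constant_cw(
    params: TKParams, cw: float, cint0: float, t
) -> float:
    """Tissue concentration under constant exposure, exact solution.

    ``(ku·cw/ke)(1 − e^{−ke·t}) + cint0·e^{−ke·t}`` for ke > 0, and the
    analytic limit ``cint0 + ku·cw·t`` for ke = 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    if params.ke > 0:
        css = params.ku * cw / params.ke
        out = css + (cint0 - css) * np.exp(-params.ke * t)
    else:
        out = cint0 + params.ku * cw * t
    return float(out) if out.ndim == 0 else out


def uptake_rate(params: TKParams, cw: float) -> float:
    """Uptake flux J_int = ku · C_w (µg g⁻¹ h⁻¹)."""
    if cw < 0:
        raise ValueError("water concentration must be nonnegative")
    return params.ku * cw


def depuration(params: TKParams, cint0: float, t) -> float:
    """First-order loss in clean water: cint0 · e^{−ke·t}."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    out = cint0 * np.exp(-params.ke * t)
    return float(out) if out.ndim == 0 else out


def simulate_trajectory(
    params: TKParams,
    exposure: ExposureProfile,
    cint0: float,
    times: Sequence[float],
) -> TissueTrajectory:
    """Compose the exact piecewise solution of the TK balance.

    Parameters
    ----------
    params
        Rate constants.
    exposure
        Waterborne concentration profile.
    cint0
        Initial tissue concentration (0 for a tracer study: the isotope
        correction removes the natural background).
    times
        Ascending observation times in hours.

    Returns
    -------
    TissueTrajectory
        Concentrations at ``times`` plus the exact segment representation,
        continuous across segment boundaries.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a nonempty 1-D sequence")
    if np.any(np.diff(times) < 0) or times[0] < 0:
        raise ValueError("times must be ascending and nonnegative")
    t_end = float(times[-1]) if times[-1] > 0 else 1.0
    ku, ke = params.ku, params.ke

    segments = []
    c = float(cint0)
    for (t0, t1, a, b) in exposure.linear_pieces(t_end):
        if ke > 0:
            A = ku * a / ke - ku * b / ke**2
            B = ku * b / ke
            Q = 0.0
            D = c - A
        else:
            A, B, Q, D = c, ku * a, ku * b / 2, 0.0
        seg = _Segment(t0, t1, A, B, Q, D, ke)
        segments.append(seg)
        c = seg.conc(t1)

    traj = TissueTrajectory(
        times=times,
        cint=np.empty_like(times),
        params=params,
        segments=tuple(segments),
        t_end=t_end,
    )
    cint = traj.concentration(times)
    object.__setattr__(traj, "cint", np.atleast_1d(cint))
    return traj
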