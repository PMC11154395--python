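"""Dose–response summaries: Michaelis–Menten uptake saturation and LC50.

Uptake flux saturates with waterborne concentration as
J = Jmax·[Cu]/(Km + [Cu]) with maximal rate Jmax (µg g⁻¹ h⁻¹) and
half-saturation constant Km (µg L⁻¹).

Two LC50 routes are provided:

* :func:`lc50_model` — the concentration at which the fitted TK–TD model
  predicts 50% survival after a stated constant exposure duration (solved by
  root bracketing on the survival function);
* :func:`lc50_probit` — the classical probit regression of mortality on
  log₁₀ dose, maximum likelihood, delta-method CI (the convention of
  standard ecotoxicological dose–response software).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy.optimize import brentq

from .fitting import FitResult, UnderdeterminedError, lm_fit
from .toxicodynamics import TDParams, survival
from .toxicokinetics import ExposureProfile, TKParams, simulate_trajectory

__all__ = [
    "MMParams",
    "DoseResponseData",
    "BracketingError",
    "SeparationError",
    "mm_evaluate",
    "fit_mm",
    "lc50_model",
    "lc50_probit",
]


@dataclass(frozen=True)
class MMParams:
    """Michaelis–Menten parameters: jmax (µg g⁻¹ h⁻¹) and km (µg L⁻¹)."""

    jmax: float
    km: float

    def __post_init__(self) -> None:
        if not (self.jmax > 0 and self.km > 0):
            raise ValueError("jmax and km must be positive")


@dataclass(frozen=True)
class DoseResponseData:
    """Mortality counts at a set of waterborne doses after ``duration`` h."""

    doses: np.ndarray
    n_dead: np.ndarray
    n_total: np.ndarray
    duration: float = 96.0

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        dead = np.asarray(self.n_dead, dtype=int)
        total = np.asarray(self.n_total, dtype=int)
        for name, arr in (("doses", doses), ("n_dead", dead), ("n_total", total)):
            object.__setattr__(self, name, arr)
        if not (len(doses) == len(dead) == len(total)):
            raise ValueError("doses, n_dead, n_total must have equal length")
        if np.any(doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(dead < 0) or np.any(dead > total):
            raise ValueError("need 0 <= n_dead <= n_total")


class BracketingError(RuntimeError):
    """The search bracket does not straddle 50% survival."""


class SeparationError(RuntimeError):
    """Mortality is completely separated in dose: probit MLE does not exist."""


def mm_evaluate(mm: MMParams, cw) -> float:
    """Saturating uptake flux jmax·cw/(km + cw)."""
    cw = np.asarray(cw, dtype=float)
    if np.any(cw < 0):
        raise ValueError("water concentration must be nonnegative")
    out = mm.jmax * cw / (mm.km + cw)
    return float(out) if out.ndim == 0 else out


def fit_mm(points: Sequence[Tuple[float, float]]) -> FitResult:
    """Fit (jmax, km) to (water concentration, uptake flux) points.

    Requires at least 3 distinct concentrations.  Data that are effectively
    linear in concentration (no saturation within the observed range) leave
    km unbounded; the returned fit then carries an inflated km SD rather
    than an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (cw, jint) pairs")
    cw, jint = pts[:, 0], pts[:, 1]
    if len(np.unique(cw)) < 3:
        raise UnderdeterminedError("need >= 3 distinct concentrations to fit (jmax, km)")

    init = {"jmax": 1.2 * float(np.max(jint)), "km": float(np.median(cw))}
    bounds = {"jmax": (1e-12, None), "km": (1e-12, None)}

    def residual(p):
        return jint - p["jmax"] * cw / (p["km"] + cw)

    return lm_fit(residual, init, bounds)


def _survival_at(tk: TKParams, td: TDParams, cw: float, duration: float) -> float:
    traj = simulate_trajectory(tk, ExposureProfile.constant(cw), 0.0, [0.0, duration])
    return survival(td, traj, duration)


def lc50_model(
    tk: TKParams,
    td: TDParams,
    duration: float,
    bracket: Tuple[float, float],
) -> float:
    """Model-implied LC50: the constant waterborne concentration at which
    the TK–TD model predicts S(duration) = 0.5.

    Solved by root bracketing on ``cw ↦ S(duration | cw) − 0.5`` to a
    relative tolerance well below 1e−3 µg L⁻¹.
    """
    lo, hi = bracket
    if not 0 <= lo < hi:
        raise ValueError("bracket must satisfy 0 <= lo < hi")
    s_lo = _survival_at(tk, td, lo, duration)
    s_hi = _survival_at(tk, td, hi, duration)
    if not (s_lo >= 0.5 >= s_hi):
        raise BracketingError(
            f"bracket does not straddle 50% survival: S({lo}) = {s_lo:.4g}, "
            f"S({hi}) = {s_hi:.4g}"
        )
    return brentq(
        lambda cw: _survival_at(tk, td, cw, duration) - 0.5,
        lo,
        hi,
        xtol=1e-9,
        rtol=1e-12,
    )


def lc50_probit(data: DoseResponseData) -> Tuple[float, Tuple[float, float]]:
    """Probit regression of mortality on log₁₀ dose; returns (LC50, 95% CI).

    LC50 = 10^(−intercept/slope) from the maximum-likelihood probit fit;
    the CI comes from the delta method on the log₁₀ scale.
    """
    frac = data.n_dead / data.n_total
    if np.all((frac == 0) | (frac == 1)):
        # every dose all-dead or all-alive: likelihood maximised at infinity
        raise SeparationError(
            "mortality completely separated in dose; probit MLE does not "
            "exist — use an exact or adjusted method"
        )
    x = sm.add_constant(np.log10(data.doses))
    endog = np.column_stack([data.n_dead, data.n_total - data.n_dead])
    model = sm.GLM(endog, x, family=sm.families.Binomial(sm.families.links.Probit()))
    try:
        res = model.fit()
    except Exception as exc:  # statsmodels raises on perfect separation too
        raise SeparationError(f"probit fit failed: {exc}") from exc
    b0, b1 = res.params
    if b1 <= 0 or not np.all(np.isfinite(res.bse)):
        raise SeparationError("probit slope non-positive or unstable; check data")
    log_lc50 = -b0 / b1
    grad = np.array([-1.0 / b1, b0 / b1**2])
    var = float(grad @ res.cov_params() @ grad)
    se = math.sqrt(max(var, 0.0))
    lo, hi = 10 ** (log_lc50 - 1.959964 * se), 10 ** (log_lc50 + 1.959964 * se)
    return 10**log_lc50, (lo, hi)
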