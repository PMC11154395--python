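"""Nonlinear least-squares parameter estimation (Marquardt-style).

The fitting strategy is two-stage, matching how one-compartment biokinetic
studies are normally analysed:

1. a single elimination rate ke is fitted jointly to all depuration series
   (elimination is treated as a physiological constant, independent of the
   exposure treatment), each series keeping its own initial concentration at
   the start of depuration;
2. with ke fixed, one uptake rate ku is fitted per treatment from the
   12-h uptake series;
3. with the TK parameters fixed, the toxicodynamic pair (C_IT, kk) is
   fitted per humic-acid level from the pooled survival fractions of the
   toxicity test (least squares by default; an interval-censored multinomial
   likelihood is available, statistically preferable for count data).

All fits run through :func:`lm_fit`, a thin named-parameter wrapper around
Levenberg–Marquardt minimisation (lmfit/MINPACK).  Standard deviations are
the classical ones: sqrt of the diagonal of rss/(n−p) · (JᵀJ)⁻¹ at the
solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datasets import TreatmentDataset
from .toxicodynamics import TDParams, hazard, survival
from .toxicokinetics import TKParams, simulate_trajectory

__all__ = [
    "FitResult",
    "FitError",
    "UnderdeterminedError",
    "DegenerateDataError",
    "UnidentifiableError",
    "lm_fit",
    "fit_ke_shared",
    "fit_ku",
    "fit_tk_joint",
    "fit_td",
]


class FitError(RuntimeError):
    """A fit failed for a data- or model-related reason."""


class UnderdeterminedError(FitError):
    """Fewer observations than free parameters."""


class DegenerateDataError(FitError):
    """Observations carry no signal for the requested parameters."""


class UnidentifiableError(FitError):
    """No deaths observed: only a lower bound on the threshold exists."""

    def __init__(self, message: str, c_it_lower_bound: float):
        super().__init__(message)
        self.c_it_lower_bound = c_it_lower_bound


@dataclass
class FitResult:
    """Point estimates and uncertainty from a nonlinear least-squares fit."""

    estimates: Dict[str, float]
    sds: Dict[str, float]
    rss: float
    n_obs: int
    n_iter: int
    converged: bool
    covariance: Optional[np.ndarray] = None
    param_names: List[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]

    def summary(self) -> str:
        lines = [
            f"{name} = {self.estimates[name]:.6g} ± {self.sds.get(name, float('nan')):.3g}"
            for name in self.param_names
        ]
        lines.append(f"rss = {self.rss:.6g}, n = {self.n_obs}, converged = {self.converged}")
        return "\n".join(lines)


_FIT_KWARGS = dict(xtol=1e-12, ftol=1e-12, gtol=1e-10, max_nfev=50000)


def lm_fit(
    residual_fn: Callable[[Dict[str, float]], np.ndarray],
    init: Dict[str, float],
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
) -> FitResult:
    """Levenberg–Marquardt least squares over named parameters.

    Parameters
    ----------
    residual_fn
        Maps a dict of parameter values to a 1-D residual vector.
    init
        Initial values, one entry per free parameter; must satisfy bounds.
    bounds
        Optional per-parameter (lo, hi); ``None`` entries mean unbounded.

    Raises
    ------
    UnderdeterminedError
        If the residual vector is not longer than the parameter vector.
    FitError
        If residuals are non-finite at the initial point.
    """
    bounds = bounds or {}
    names = list(init)
    params = lmfit.Parameters()
    for name in names:
        lo, hi = bounds.get(name, (-np.inf, np.inf))
        lo = -np.inf if lo is None else lo
        hi = np.inf if hi is None else hi
        params.add(name, value=init[name], min=lo, max=hi)

    def _residual(p: lmfit.Parameters) -> np.ndarray:
        return np.asarray(residual_fn({n: p[n].value for n in names}), dtype=float)

    r0 = _residual(params)
    if not np.all(np.isfinite(r0)):
        raise FitError(f"non-finite residuals at initial point {dict(init)}")
    if len(r0) <= len(names):
        raise UnderdeterminedError(
            f"{len(r0)} observations cannot determine {len(names)} parameters"
        )

    out = lmfit.minimize(_residual, params, method="leastsq", **_FIT_KWARGS)
    estimates = {n: float(out.params[n].value) for n in names}
    sds = {
        n: float(out.params[n].stderr) if out.params[n].stderr is not None else float("nan")
        for n in names
    }
    return FitResult(
        estimates=estimates,
        sds=sds,
        rss=float(out.chisqr),
        n_obs=int(out.ndata),
        n_iter=int(out.nfev),
        converged=bool(out.success),
        covariance=None if out.covar is None else np.asarray(out.covar),
        param_names=names,
    )


# ---------------------------------------------------------------------------
# TK fits


def fit_ke_shared(datasets: Sequence[TreatmentDataset]) -> FitResult:
    """Fit one elimination rate ke (h⁻¹) jointly to all depuration series.

    Each dataset with depuration observations contributes residuals
    ``cint − c0_i · exp(−ke·(t − t0_i))`` with its own free initial
    concentration ``c0_i`` at its depuration start ``t0_i``.
    """
    with_dep = [d for d in datasets if len(d.depuration)]
    if not with_dep:
        raise DegenerateDataError("no depuration observations in any dataset")

    init: Dict[str, float] = {}
    bounds: Dict[str, Tuple[float, float]] = {}
    slopes = []
    for i, d in enumerate(with_dep):
        df = d.depuration
        t0 = d.depuration_start
        means = df.groupby("time_h")["cint"].mean()
        first = float(means.iloc[0])
        init[f"c0_{i}"] = max(first, 1e-9)
        bounds[f"c0_{i}"] = (1e-12, None)
        pos = means[means > 0]
        if len(pos) >= 2:
            slope, _ = np.polyfit(pos.index.values, np.log(pos.values), 1)
            slopes.append(max(-slope, 1e-6))
    init["ke"] = float(np.mean(slopes)) if slopes else 1e-3
    bounds["ke"] = (0.0, None)

    def residual(p: Dict[str, float]) -> np.ndarray:
        res = []
        for i, d in enumerate(with_dep):
            df = d.depuration
            t = df["time_h"].values - d.depuration_start
            model = p[f"c0_{i}"] * np.exp(-p["ke"] * t)
            res.append(df["cint"].values - model)
        return np.concatenate(res)

    result = lm_fit(residual, init, bounds)
    result.param_names = ["ke"] + [n for n in result.param_names if n != "ke"]
    return result


def fit_ku(dataset: TreatmentDataset, ke_fixed: float) -> FitResult:
    """Fit the uptake rate ku (L g⁻¹ h⁻¹) for one treatment, ke held fixed.

    The model trajectory starts at C_int(0) = 0 (tracer study) and follows
    the dataset's exposure profile.
    """
    if ke_fixed < 0:
        raise ValueError("ke_fixed must be nonnegative")
    df = dataset.uptake
    if not len(df):
        raise DegenerateDataError("uptake table is empty")
    if np.allclose(df["cint"].values, 0.0):
        raise DegenerateDataError("all uptake observations are zero: ku has no signal")

    obs_t = df["time_h"].values
    obs_c = df["cint"].values
    unique_t = np.unique(obs_t)
    cw0 = dataset.exposure.value(0.0)
    t_last = float(unique_t[-1]) if unique_t[-1] > 0 else 1.0
    last_mean = float(df[df["time_h"] == unique_t[-1]]["cint"].mean())
    ku0 = max(last_mean / max(cw0 * t_last, 1e-12), 1e-6)

    def residual(p: Dict[str, float]) -> np.ndarray:
        traj = simulate_trajectory(
            TKParams(p["ku"], ke_fixed), dataset.exposure, 0.0, unique_t
        )
        model = np.interp(obs_t, unique_t, traj.cint)
        return obs_c - model

    return lm_fit(residual, {"ku": ku0}, {"ku": (1e-12, None)})


def fit_tk_joint(datasets: Sequence[TreatmentDataset]) -> FitResult:
    """Joint fit of shared ke plus one ku per dataset on uptake + depuration.

    Weakly identified when few datasets carry depuration data; the staged
    :func:`fit_ke_shared` + :func:`fit_ku` route is the default elsewhere.
    """
    if not datasets:
        raise DegenerateDataError("no datasets supplied")
    init: Dict[str, float] = {"ke": 1e-3}
    bounds: Dict[str, Tuple[float, float]] = {"ke": (0.0, None)}
    for i, d in enumerate(datasets):
        unique_t = np.unique(d.uptake["time_h"].values)
        cw0 = d.exposure.value(0.0)
        t_last = float(unique_t[-1]) if len(unique_t) and unique_t[-1] > 0 else 1.0
        last_mean = float(d.uptake[d.uptake["time_h"] == unique_t[-1]]["cint"].mean())
        init[f"ku_{i}"] = max(last_mean / max(cw0 * t_last, 1e-12), 1e-6)
        bounds[f"ku_{i}"] = (1e-12, None)

    def residual(p: Dict[str, float]) -> np.ndarray:
        res = []
        for i, d in enumerate(datasets):
            obs = (
                d.uptake
                if not len(d.depuration)
                else pd.concat([d.uptake, d.depuration])
            )
            t_unique = np.unique(obs["time_h"].values)
            traj = simulate_trajectory(
                TKParams(p[f"ku_{i}"], p["ke"]), d.exposure, 0.0, t_unique
            )
            model = np.interp(obs["time_h"].values, t_unique, traj.cint)
            res.append(obs["cint"].values - model)
        return np.concatenate(res)

    return lm_fit(residual, init, bounds)


# ---------------------------------------------------------------------------
# TD fit


def _td_initial_values(
    times: np.ndarray, frac: np.ndarray, traj, h0_fixed: float
) -> Tuple[float, float]:
    """Data-driven starting point for (c_it, kk).

    c_it starts just below the tissue concentration at the first observed
    death; kk starts at the value that would reproduce the hazard implied by
    the observation closest to 50% survival, given that threshold.
    """
    dead_idx = np.where(frac < 1.0)[0]
    first_death_t = times[dead_idx[0]] if len(dead_idx) else times[-1]
    c_at_death = traj.concentration(float(first_death_t))
    c_it0 = max(0.5 * c_at_death, 1e-9)

    target_idx = int(np.argmin(np.abs(frac - 0.5)))
    t_mid = float(times[target_idx]) if times[target_idx] > 0 else float(times[-1])
    h_target = -math.log(max(float(frac[target_idx]), 1e-3))
    h_unit = hazard(TDParams(c_it0, 1.0, 0.0), traj, t_mid)
    kk0 = h_target / h_unit if h_unit > 0 else 0.01
    return c_it0, max(kk0, 1e-12)


def fit_td(
    dataset: TreatmentDataset,
    tk: TKParams,
    h0_fixed: float = 0.0,
    objective: str = "least_squares",
) -> FitResult:
    """Fit the threshold-hazard pair (c_it, kk) to survival observations.

    The internal-concentration trajectory is computed from ``tk`` and the
    dataset's exposure profile; survival fractions are pooled over
    replicates (total alive / total initial).  ``objective`` selects plain
    least squares on the fractions (default) or the interval-censored
    multinomial death-count likelihood.

    Raises
    ------
    UnidentifiableError
        If no deaths were observed; carries ``c_it_lower_bound`` (the
        maximum tissue concentration reached).
    """
    times, alive, n0 = dataset.pooled_survival()
    frac = alive / n0
    traj = simulate_trajectory(tk, dataset.exposure, 0.0, times)
    max_cint = float(np.max(traj.cint))
    if np.all(alive == alive[0]):
        raise UnidentifiableError(
            "no deaths observed: c_it is only bounded below by the peak "
            f"tissue concentration {max_cint:.4g} µg/g",
            c_it_lower_bound=max_cint,
        )

    c_it0, kk0 = _td_initial_values(times, frac, traj, h0_fixed)
    t_obs = times[times > 0]
    f_obs = frac[times > 0]

    if objective == "least_squares":

        def residual(p: Dict[str, float]) -> np.ndarray:
            td = TDParams(p["c_it"], p["kk"], h0_fixed)
            model = np.array([survival(td, traj, t) for t in t_obs])
            return f_obs - model

        # multistart over the threshold guards against the flat c_it
        # direction collapsing onto a boundary local minimum
        best = None
        for c_start in (c_it0, 0.25 * c_it0, 2.0 * c_it0):
            fit = lm_fit(
                residual,
                {"c_it": c_start, "kk": kk0},
                {"c_it": (0.0, max_cint * 2), "kk": (1e-15, None)},
            )
            if best is None or fit.rss < best.rss:
                best = fit
        return best

    if objective != "multinomial_likelihood":
        raise ValueError(f"unknown objective {objective!r}")

    deaths = -np.diff(alive)

    def nll(theta: np.ndarray) -> float:
        td = TDParams(max(theta[0], 0.0), max(theta[1], 1e-15), h0_fixed)
        s = np.array([1.0] + [survival(td, traj, t) for t in times[1:]])
        p_int = np.clip(s[:-1] - s[1:], 1e-300, None)
        ll = float(np.sum(deaths * np.log(p_int)))
        ll += float(alive[-1]) * math.log(max(s[-1], 1e-300))
        return -ll

    res = minimize(
        nll,
        x0=np.array([c_it0, kk0]),
        method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-10, maxiter=5000),
    )
    cov = _numeric_hessian_inverse(nll, res.x)
    sds = (
        np.sqrt(np.clip(np.diag(cov), 0, None))
        if cov is not None
        else np.full(2, np.nan)
    )
    return FitResult(
        estimates={"c_it": float(res.x[0]), "kk": float(res.x[1])},
        sds={"c_it": float(sds[0]), "kk": float(sds[1])},
        rss=float(res.fun),  # negative log-likelihood, not an RSS
        n_obs=len(times),
        n_iter=int(res.nfev),
        converged=bool(res.success),
        covariance=cov,
        param_names=["c_it", "kk"],
    )


def _numeric_hessian_inverse(fn, x: np.ndarray) -> Optional[np.ndarray]:
    """Central-difference Hessian of fn at x, inverted; None if singular."""
    n = len(x)
    h = np.maximum(np.abs(x) * 1e-4, 1e-10)
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fn(x + ei + ej)
            fpm = fn(x + ei - ej)
            fmp = fn(x - ei + ej)
            fmm = fn(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        return np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
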