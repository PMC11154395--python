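"""End-to-end analysis: raw tables → TK fits → TD fits → dose metrics.

``run_analysis`` reproduces the full study workflow on either real CSV
inputs or a simulated experiment: shared elimination rate from the
depuration series, per-treatment uptake rates with ke fixed, per-HA-level
threshold-hazard fits from the toxicity test, Michaelis–Menten saturation
of the uptake flux across Cu levels, and a model-implied 96-h LC50 per HA
level.  Outputs are plain CSV tables plus a run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import SurvivalSeries, TreatmentDataset
from .dose_response import BracketingError, fit_mm, lc50_model
from .fitting import (FitError, FitResult, UnidentifiableError, fit_ke_shared,
                      fit_ku, fit_td)
from .simulate import (ExperimentDesign, GroundTruth, generate_toxicity,
                       generate_uptake_depuration, write_datasets)
from .toxicodynamics import TDParams, survival_curve
from .toxicokinetics import ExposureProfile, TKParams, simulate_trajectory
from .tracer import ke_per_hour_to_per_day

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis", "load_datasets",
           "recover_report"]


@dataclass
class AnalysisConfig:
    """Configuration of one analysis run.

    Exactly one of (``tissue_csv``) or ``simulate`` must be set.  When
    simulating, ``truth`` selects the generating parameter set
    (``"reported"`` or ``"calibrated"``).
    """

    tissue_csv: Optional[str] = None
    water_csv: Optional[str] = None
    survival_csv: Optional[str] = None
    simulate: bool = False
    truth: str = "calibrated"
    noise_cv: Optional[float] = None
    tracer_mode: str = "as_printed"
    objective: str = "least_squares"
    outdir: str = "tktd_out"
    seed: int = 0
    lc50_duration: float = 96.0
    lc50_bracket: tuple = (1e-2, 1e6)

    def __post_init__(self) -> None:
        if self.simulate == (self.tissue_csv is not None):
            raise ValueError(
                "exactly one of tissue_csv or simulate=True must be given"
            )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class AnalysisResult:
    ke_fit: FitResult
    ku_fits: Dict[tuple, FitResult]
    td_fits: Dict[float, FitResult]
    mm_fits: Dict[float, FitResult]
    lc50: Dict[float, float]
    errors: Dict[str, str] = field(default_factory=dict)
    tables: Dict[str, Path] = field(default_factory=dict)


def load_datasets(
    tissue_csv, water_csv=None, survival_csv=None
) -> List[TreatmentDataset]:
    """Rebuild per-treatment datasets from the pipeline's CSV schemas.

    ``tissue.csv``: ha_mg_per_l, cu_ug_per_l, phase, time_h, replicate, cint.
    ``water.csv``:  ha_mg_per_l, cu_ug_per_l, time_h, cw (optional; nominal
    concentrations are used when absent).
    ``survival.csv``: ha_mg_per_l, cu_ug_per_l, replicate, time_h, n_alive.
    """
    tissue = pd.read_csv(tissue_csv)
    water = pd.read_csv(water_csv) if water_csv else None
    surv = pd.read_csv(survival_csv) if survival_csv else None

    datasets = []
    keys = tissue[["ha_mg_per_l", "cu_ug_per_l"]].drop_duplicates().values
    if surv is not None:
        extra = surv[["ha_mg_per_l", "cu_ug_per_l"]].drop_duplicates().values
        seen = {tuple(k) for k in keys}
        keys = list(keys) + [k for k in extra if tuple(k) not in seen]
    for ha, cu in keys:
        sub = tissue[(tissue.ha_mg_per_l == ha) & (tissue.cu_ug_per_l == cu)]
        up = sub[sub.phase == "uptake"][["time_h", "cint", "replicate"]].reset_index(drop=True)
        dep = sub[sub.phase == "depuration"][["time_h", "cint", "replicate"]].reset_index(drop=True)
        uptake_end = float(up["time_h"].max()) if len(up) else 12.0
        cw = float(cu)
        if water is not None:
            wsub = water[(water.ha_mg_per_l == ha) & (water.cu_ug_per_l == cu)]
            if len(wsub):
                cw = float(wsub["cw"].mean())
        series = []
        if surv is not None:
            ssub = surv[(surv.ha_mg_per_l == ha) & (surv.cu_ug_per_l == cu)]
            for rep, grp in ssub.groupby("replicate"):
                grp = grp.sort_values("time_h")
                series.append(
                    SurvivalSeries(grp["time_h"].values, grp["n_alive"].values, int(rep))
                )
        if series and not len(up):
            exposure = ExposureProfile.constant(cw)  # toxicity test: not renewed
        else:
            exposure = ExposureProfile.pulse(cw, uptake_end)
        datasets.append(
            TreatmentDataset(
                treatment_id=(float(ha), float(cu)),
                uptake=up,
                depuration=dep,
                exposure=exposure,
                survival=series,
            )
        )
    return datasets


def _fmt(est: float, sd: float) -> str:
    return f"{est:.4g} ± {sd:.3g}"


def run_analysis(config: AnalysisConfig) -> AnalysisResult:
    """Run the full workflow and write the report bundle to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    errors: Dict[str, str] = {}

    if config.simulate:
        design = ExperimentDesign(seed=config.seed)
        if config.noise_cv is not None:
            design = dataclasses.replace(design, noise_cv=config.noise_cv)
        truth = (
            GroundTruth.calibrated() if config.truth == "calibrated"
            else GroundTruth.reported()
        )
        kinetic = generate_uptake_depuration(design, truth)
        tox = generate_toxicity(design, truth)
        write_datasets(kinetic + tox, outdir / "simulated_inputs")
    else:
        all_ds = load_datasets(config.tissue_csv, config.water_csv, config.survival_csv)
        kinetic = [d for d in all_ds if len(d.uptake)]
        tox = [d for d in all_ds if d.survival]

    # --- TK: shared ke, then per-treatment ku -------------------------------
    ke_fit = fit_ke_shared(kinetic)
    ke = ke_fit["ke"]
    ku_fits: Dict[tuple, FitResult] = {}
    for ds in kinetic:
        try:
            ku_fits[ds.treatment_id] = fit_ku(ds, ke)
        except FitError as exc:
            errors[f"ku {ds.treatment_id}"] = str(exc)

    # --- TD per HA level, using that level's toxicity-test ku ---------------
    td_fits: Dict[float, FitResult] = {}
    for ds in tox:
        ha, cu = ds.treatment_id
        if cu == 0.0:
            continue  # control group
        key = (ha, cu)
        if key not in ku_fits:
            errors[f"td HA={ha}"] = f"no uptake fit for treatment {key}"
            continue
        tk = TKParams(ku_fits[key]["ku"], ke)
        try:
            td_fits[ha] = fit_td(ds, tk, objective=config.objective)
        except UnidentifiableError as exc:
            errors[f"td HA={ha}"] = (
                f"{exc} (c_it lower bound {exc.c_it_lower_bound:.4g})"
            )
        except FitError as exc:
            errors[f"td HA={ha}"] = str(exc)

    # --- Michaelis-Menten uptake saturation per HA level --------------------
    mm_fits: Dict[float, FitResult] = {}
    ha_levels = sorted({ds.treatment_id[0] for ds in kinetic})
    for ha in ha_levels:
        pts = [
            (cu, ku_fits[(h, cu)]["ku"] * cu)
            for (h, cu) in ku_fits
            if h == ha
        ]
        try:
            mm_fits[ha] = fit_mm(pts)
        except FitError as exc:
            errors[f"mm HA={ha}"] = str(exc)

    # --- model-implied LC50 per HA level ------------------------------------
    lc50: Dict[float, float] = {}
    for ha, td_fit in td_fits.items():
        tk = TKParams(ku_fits[(ha, 300.0)]["ku"], ke) if (ha, 300.0) in ku_fits else None
        if tk is None:
            continue
        td = TDParams(td_fit["c_it"], td_fit["kk"])
        try:
            lc50[ha] = lc50_model(tk, td, config.lc50_duration, config.lc50_bracket)
        except BracketingError as exc:
            errors[f"lc50 HA={ha}"] = str(exc)

    result = AnalysisResult(ke_fit, ku_fits, td_fits, mm_fits, lc50, errors)
    _write_tables(result, ke, kinetic, tox, config, outdir)
    return result


def _write_tables(result, ke, kinetic, tox, config, outdir: Path) -> None:
    cu_levels = sorted({cu for (_, cu) in result.ku_fits})
    rows = []
    for ha in sorted({h for (h, _) in result.ku_fits}):
        row = {"ha_mg_per_l": ha}
        for cu in cu_levels:
            fit = result.ku_fits.get((ha, cu))
            row[f"ku_{cu:g}"] = _fmt(fit["ku"], fit.sds["ku"]) if fit else ""
        td = result.td_fits.get(ha)
        row["c_it"] = _fmt(td["c_it"], td.sds["c_it"]) if td else ""
        row["kk"] = _fmt(td["kk"], td.sds["kk"]) if td else ""
        rows.append(row)
    params = pd.DataFrame(rows)
    ke_d = ke_per_hour_to_per_day(ke)
    sd_d = ke_per_hour_to_per_day(result.ke_fit.sds["ke"])
    footnote = {col: "" for col in params.columns}
    footnote["ha_mg_per_l"] = f"shared ke = {ke:.4g} /h ({_fmt(ke_d, sd_d)} /d)"
    params = pd.concat([params, pd.DataFrame([footnote])], ignore_index=True)
    params.to_csv(outdir / "params_table.csv", index=False)

    rows = []
    for ha in sorted(result.mm_fits):
        mm = result.mm_fits[ha]
        rows.append(
            {
                "ha_mg_per_l": ha,
                "lc50_96h_model": f"{result.lc50[ha]:.4g}" if ha in result.lc50 else "",
                "jmax": _fmt(mm["jmax"], mm.sds["jmax"]),
                "km": _fmt(mm["km"], mm.sds["km"]),
                "formula": f"{mm['jmax']:.3g} × [Cu]/({mm['km']:.3g} + [Cu])",
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "kinetics_table.csv", index=False)

    rows = []
    for ds in tox:
        ha, cu = ds.treatment_id
        if ha not in result.td_fits or (ha, cu) not in result.ku_fits:
            continue
        tk = TKParams(result.ku_fits[(ha, cu)]["ku"], ke)
        td = TDParams(result.td_fits[ha]["c_it"], result.td_fits[ha]["kk"])
        times, alive, n0 = ds.pooled_survival()
        traj = simulate_trajectory(tk, ds.exposure, 0.0, times)
        curve = survival_curve(td, traj, times)
        for t, s_mod, n in zip(times, curve.survival, alive):
            rows.append(
                {"ha_mg_per_l": ha, "time_h": t, "survival_prob": s_mod,
                 "observed_frac": n / n0}
            )
    pd.DataFrame(rows).to_csv(
        outdir / "survival_curves.csv", index=False, float_format="%.10g"
    )

    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in dataclasses.asdict(config).items()}
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]
    log = [
        f"tktd version {__version__}",
        f"seed {config.seed}",
        f"config sha256 {cfg_hash}",
        f"datasets: {len(kinetic)} kinetic, {len(tox)} toxicity",
        f"shared ke = {ke:.6g} /h",
    ] + [f"ERROR {k}: {v}" for k, v in result.errors.items()]
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    result.tables = {
        name: outdir / f"{name}.csv"
        for name in ("params_table", "kinetics_table", "survival_curves")
    }


def recover_report(
    seed: int = 0,
    noise_cv: float = 0.15,
    truth: Optional[GroundTruth] = None,
    n_sd: float = 3.0,
) -> pd.DataFrame:
    """Simulate with known truth, refit, and tabulate truth vs estimate.

    A parameter passes when |estimate − truth| ≤ ``n_sd`` fitted SDs (or,
    for noise-free runs where SDs vanish, when it agrees to 0.1%).
    """
    design = ExperimentDesign(seed=seed, noise_cv=noise_cv)
    truth = truth or GroundTruth.calibrated()
    kinetic = generate_uptake_depuration(design, truth)
    tox = generate_toxicity(design, truth, include_control=False)

    rows = []

    def _row(name, true, fit: FitResult, pname: str):
        est, sd = fit[pname], fit.sds[pname]
        tol = max(n_sd * (0.0 if np.isnan(sd) else sd), 1e-3 * abs(true))
        rows.append(
            {"parameter": name, "truth": true, "estimate": est, "sd": sd,
             "passed": abs(est - true) <= tol}
        )

    ke_fit = fit_ke_shared(kinetic)
    _row("ke", truth.ke, ke_fit, "ke")
    ke = ke_fit["ke"]
    for ds in kinetic:
        fit = fit_ku(ds, ke)
        _row(f"ku{ds.treatment_id}", truth.ku[ds.treatment_id], fit, "ku")
    for ds in tox:
        ha, cu = ds.treatment_id
        tk = TKParams(truth.ku[(ha, cu)], truth.ke)
        try:
            fit = fit_td(ds, tk)
        except FitError as exc:
            rows.append({"parameter": f"td HA={ha}", "truth": np.nan,
                         "estimate": np.nan, "sd": np.nan, "passed": False})
            continue
        _row(f"c_it HA={ha}", truth.td[ha].c_it, fit, "c_it")
        _row(f"kk HA={ha}", truth.td[ha].kk, fit, "kk")
    return pd.DataFrame(rows)
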