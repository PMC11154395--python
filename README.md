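# tktd

Toxicokinetic–toxicodynamic (TK–TD) modelling of copper accumulation and
mortality in the razor clam *Sinonovacula constricta*, an estuarine bivalve
farmed along the Chinese coast where dissolved organic carbon (DOC, largely
humic acid) modulates how much waterborne Cu the animals take up and how
toxic it is to them.

The package is for ecotoxicologists and biokinetic modellers who want a
tested, scriptable implementation of this analysis chain: stable-isotope
tracer correction, one-compartment uptake/elimination kinetics, a
threshold-hazard survival model, Levenberg–Marquardt parameter estimation
with standard deviations, Michaelis–Menten uptake saturation, LC50
estimation, and a seeded virtual-experiment generator for parameter-recovery
studies.

## The model

Tissue copper (µg g⁻¹ dry weight) under waterborne exposure C_w(t) (µg L⁻¹):

    dC_int/dt = k_u · C_w(t) − k_e · C_int(t),        J_int = k_u · C_w

with uptake rate constant k_u (L g⁻¹ h⁻¹) and elimination rate constant k_e
(h⁻¹). Mortality follows the stochastic-death threshold-hazard form: hazard
accrues only above an internal threshold C_IT,

    dH/dt = k_k · max(C_int(t) − C_IT, 0) + h_0,      S(t) = e^{−H(t)},

with killing rate k_k ((µg g⁻¹)⁻¹ h⁻¹) and background hazard h_0 (zero when
controls show no mortality). Trajectories are exact piecewise closed forms
(no ODE discretisation error); the hazard integral is evaluated
analytically, with threshold crossings solved in closed form or by Brent's
method. Uptake flux versus concentration saturates as
J = J_max[Cu]/(K_m + [Cu]). Details, estimation strategy and known
limitations: [docs/methods.md](docs/methods.md).

## Worked example

Generate a noisy virtual experiment at the published best-fit parameters and
refit the kinetics (see `examples/fit_kinetics.py`; the other scripts in
`examples/` each demonstrate one capability):

```python
from tktd import (ExperimentDesign, GroundTruth, fit_ke_shared, fit_ku,
                  generate_uptake_depuration)

truth = GroundTruth.calibrated()
design = ExperimentDesign(seed=1)          # 15% measurement noise
datasets = generate_uptake_depuration(design, truth)

ke = fit_ke_shared(datasets)["ke"]         # shared elimination rate
for ds in datasets[:3]:
    fit = fit_ku(ds, ke)
    print(ds.treatment_id, f"{fit['ku']:.4f} ± {fit.sds['ku']:.4f}")
```

prints

```
(0.0, 15.0) 0.2897 ± 0.0077
(0.0, 150.0) 0.5999 ± 0.0144
(0.0, 300.0) 0.4696 ± 0.0133
```

i.e. for the zero-humic-acid treatments the uptake rate constants recovered
from one noisy replicate of the design sit within a few standard deviations
of the generating values (0.307, 0.625, 0.481 L g⁻¹ h⁻¹), and the shared
k_e comes back as 0.00240 h⁻¹ ≈ 0.058 d⁻¹. Each tuple is a treatment
(humic acid mg L⁻¹, nominal Cu µg L⁻¹).

There is also a thin CLI over the same pipeline:

```bash
tktd simulate --seed 7 --out sim/          # virtual experiment → CSVs
tktd fit --tissue sim/tissue.csv --water sim/water.csv \
         --survival sim/survival.csv --out out/
tktd recover --seed 1 --noise-cv 0         # generate → fit → truth-vs-estimate
```

`tktd fit` writes `params_table.csv` (k_u per treatment, C_IT and k_k per
humic-acid level, shared k_e footnote), `kinetics_table.csv` (J_max, K_m and
model-implied 96-h LC50 per humic-acid level), `survival_curves.csv` and a
run log.

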