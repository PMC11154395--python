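import numpy as np
import pandas as pd
import pytest

from tktd import (ExperimentDesign, ExposureProfile, GroundTruth,
                  SurvivalSeries, TKParams, TreatmentDataset,
                  simulate_trajectory)
from tktd.toxicodynamics import survival_curve


def rk4_trajectory(ku, ke, cw_fn, c0, t_end, step=1e-3):
    """Independent fixed-step RK4 integration of dC/dt = ku*cw(t) - ke*C.

    Returns (times, concentrations) on the step grid.  Deliberately naive:
    this is the numerical oracle the closed-form solver is checked against.
    """
    n = int(round(t_end / step))
    t = np.arange(n + 1) * step
    cw = np.asarray(cw_fn(t), dtype=float)
    cw_mid = np.asarray(cw_fn(t[:-1] + step / 2), dtype=float)

    def f(c, cw_val):
        return ku * cw_val - ke * c

    c = np.empty(n + 1)
    c[0] = c0
    for i in range(n):
        k1 = f(c[i], cw[i])
        k2 = f(c[i] + step / 2 * k1, cw_mid[i])
        k3 = f(c[i] + step / 2 * k2, cw_mid[i])
        k4 = f(c[i] + step * k3, cw[i + 1])
        c[i + 1] = c[i] + step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return t, c


def exact_fraction_dataset(tk, td, cw, times, n0=10**7):
    """Survival dataset whose observed fractions equal the model's S(t) to
    ~1/n0: the noise-free limit of the toxicity experiment."""
    exposure = ExposureProfile.constant(cw)
    traj = simulate_trajectory(tk, exposure, 0.0, times)
    s = survival_curve(td, traj, times).survival
    alive = np.minimum.accumulate(np.round(s * n0).astype(int))
    return TreatmentDataset(
        (0.0, cw),
        pd.DataFrame(columns=["time_h", "cint", "replicate"]),
        exposure=exposure,
        survival=[SurvivalSeries(times, alive)],
    )


@pytest.fixture(scope="session")
def truth_reported():
    return GroundTruth.reported()


@pytest.fixture(scope="session")
def truth_calibrated():
    return GroundTruth.calibrated()


@pytest.fixture
def design_noise_free():
    return ExperimentDesign(seed=1, noise_cv=0.0)


@pytest.fixture
def design_default():
    return ExperimentDesign(seed=1)


def random_piecewise_linear_profile(rng, t_end=24.0, n_breaks=4, cw_max=300.0):
    bp = np.sort(rng.uniform(0.1, t_end, n_breaks - 1))
    bp = tuple([0.0] + list(bp))
    vals = tuple(rng.uniform(0.0, cw_max, n_breaks))
    return ExposureProfile(bp, vals, "piecewise_linear")
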