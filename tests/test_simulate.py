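import math

import numpy as np
import pandas as pd
import pytest

from tktd import (ExperimentDesign, GroundTruth, TKParams,
                  generate_toxicity, generate_uptake_depuration,
                  simulate_trajectory, write_datasets)
from tktd.simulate import DOC_BY_HA, KU_REPORTED, _lognormal_noise
from tktd.toxicodynamics import TDParams, survival_curve
from tktd.toxicokinetics import ExposureProfile


class TestDesignAndTruth:
    def test_default_design_matches_study_layout(self):
        d = ExperimentDesign()
        assert d.doc_map == {0.0: 0.58, 5.0: 3.05, 10.0: 5.61, 20.0: 8.98}
        assert d.uptake_times == (0.0, 3.0, 6.0, 9.0, 12.0)
        assert d.depuration_times == (12.0, 24.0, 48.0, 72.0, 120.0, 168.0)
        assert d.tissue_n == 6
        assert d.tox_replicates * d.tox_n_per_replicate == 60
        np.testing.assert_allclose(d.tox_check_times[-1], 96.0)

    def test_reported_truth_matches_published_grid(self, truth_reported):
        assert truth_reported.ku[(0.0, 15.0)] == 0.307
        assert truth_reported.ku[(20.0, 150.0)] == 0.578
        assert truth_reported.ke == pytest.approx(0.0582 / 24)
        assert truth_reported.td[0.0].c_it == 104.0
        assert truth_reported.td[20.0].kk == 5.68

    def test_calibrated_truth_rescales_only_kk(self, truth_reported, truth_calibrated):
        assert truth_calibrated.ku == truth_reported.ku
        assert truth_calibrated.ke == truth_reported.ke
        ratios = [
            truth_calibrated.td[ha].kk / truth_reported.td[ha].kk
            for ha in truth_reported.td
        ]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)
        assert all(
            truth_calibrated.td[ha].c_it == truth_reported.td[ha].c_it
            for ha in truth_reported.td
        )

    def test_calibrated_truth_hits_survival_floor(self, truth_calibrated):
        """The common kk rescaling pins the most sensitive treatment's 96-h
        survival at the 1% floor."""
        s_min = 1.0
        for ha, td in truth_calibrated.td.items():
            tk = truth_calibrated.tk_for(ha, 300.0)
            traj = simulate_trajectory(
                tk, ExposureProfile.constant(300.0), 0.0, [0.0, 96.0]
            )
            s_min = min(s_min, survival_curve(td, traj, [96.0]).survival[0])
        assert s_min == pytest.approx(0.01, rel=1e-6)


class TestNoiseModel:
    def test_unit_mean_at_large_sample(self):
        rng = np.random.default_rng(8)
        draws = _lognormal_noise(rng, 0.15, 10_000)
        assert np.mean(draws) == pytest.approx(1.0, rel=0.01)
        assert np.std(draws) == pytest.approx(0.15, rel=0.05)

    def test_zero_cv_is_exact(self):
        rng = np.random.default_rng(8)
        assert np.all(_lognormal_noise(rng, 0.0, 100) == 1.0)


class TestGenerateUptakeDepuration:
    def test_noise_free_observations_equal_closed_form(self, truth_calibrated):
        design = ExperimentDesign(seed=1, noise_cv=0.0)
        datasets = generate_uptake_depuration(design, truth_calibrated)
        assert len(datasets) == 12
        for ds in datasets:
            ha, cu = ds.treatment_id
            tk = truth_calibrated.tk_for(ha, cu)
            times = np.unique(ds.uptake["time_h"].values)
            traj = simulate_trajectory(tk, ds.exposure, 0.0, times)
            expected = dict(zip(traj.times, traj.cint))
            for t, grp in ds.uptake.groupby("time_h"):
                np.testing.assert_allclose(grp["cint"], expected[t], rtol=1e-12)

    def test_depuration_only_for_low_cu_group(self, truth_calibrated):
        design = ExperimentDesign(seed=1)
        for ds in generate_uptake_depuration(design, truth_calibrated):
            if ds.treatment_id[1] == 15.0:
                assert len(ds.depuration) == 6 * design.tissue_n
            else:
                assert len(ds.depuration) == 0

    def test_same_seed_reproduces_datasets(self, truth_calibrated):
        design = ExperimentDesign(seed=7)
        a = generate_uptake_depuration(design, truth_calibrated)
        b = generate_uptake_depuration(design, truth_calibrated)
        for da, db in zip(a, b):
            pd.testing.assert_frame_equal(da.uptake, db.uptake)
            pd.testing.assert_frame_equal(da.depuration, db.depuration)
            pd.testing.assert_frame_equal(da.water, db.water)

    def test_write_is_byte_identical_for_same_seed(self, truth_calibrated, tmp_path):
        design = ExperimentDesign(seed=7)
        p1 = write_datasets(
            generate_uptake_depuration(design, truth_calibrated), tmp_path / "a"
        )
        p2 = write_datasets(
            generate_uptake_depuration(design, truth_calibrated), tmp_path / "b"
        )
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()


class TestGenerateToxicity:
    def test_counts_start_full_and_never_increase(self, truth_calibrated):
        design = ExperimentDesign(seed=2)
        for ds in generate_toxicity(design, truth_calibrated):
            for s in ds.survival:
                assert s.n0 == design.tox_n_per_replicate
                assert np.all(np.diff(s.n_alive) <= 0)

    def test_no_deaths_when_threshold_unreachable(self, truth_calibrated):
        truth = GroundTruth(
            ku=dict(truth_calibrated.ku),
            ke=truth_calibrated.ke,
            td={ha: TDParams(1e9, 1.0) for ha in (0.0, 5.0, 10.0, 20.0)},
        )
        for ds in generate_toxicity(ExperimentDesign(seed=3), truth):
            for s in ds.survival:
                assert np.all(s.n_alive == s.n0)

    def test_mean_survival_matches_model_within_mc_error(self, truth_calibrated):
        """Averaged over 1000 seeded replicate containers, observed survival
        fractions match S(t) within binomial Monte-Carlo error."""
        design = ExperimentDesign(
            seed=0, ha_levels=(0.0,), tox_replicates=1, tox_n_per_replicate=20
        )
        td = truth_calibrated.td[0.0]
        tk = truth_calibrated.tk_for(0.0, 300.0)
        times = design.tox_check_times
        traj = simulate_trajectory(tk, ExposureProfile.constant(300.0), 0.0, times)
        s_true = survival_curve(td, traj, times).survival
        total = np.zeros(len(times))
        n_rep = 1000
        for seed in range(n_rep):
            ds = generate_toxicity(design, truth_calibrated, seed=seed,
                                   include_control=False)[0]
            total += ds.survival[0].n_alive
        frac = total / (n_rep * 20)
        mc_se = np.sqrt(s_true * (1 - s_true) / (n_rep * 20))
        assert np.all(np.abs(frac - s_true) <= 4 * mc_se + 1e-12)

    def test_control_group_survives_fully(self, truth_calibrated):
        control = generate_toxicity(ExperimentDesign(seed=4), truth_calibrated)[-1]
        assert control.treatment_id == (0.0, 0.0)
        for s in control.survival:
            assert np.all(s.n_alive == s.n0)
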