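"""Calibration procedures: growth, parasite uptake, joint host kinetics."""

import numpy as np
import pytest

import biodyn as b
from biodyn.errors import BiodynError, InsufficientDataError
from biodyn.kinetics import _interval_host_stats


class TestProjectWeight:
    def test_hand_value(self):
        assert b.project_weight(10.0, 0.015, 36) == pytest.approx(17.09, rel=1e-3)

    def test_identity_at_t0_and_zero_growth(self):
        assert b.project_weight(10.0, 0.015, 0) == 10.0
        assert b.project_weight(10.0, 0.0, 25) == 10.0

    def test_invalid_growth_raises(self):
        with pytest.raises(BiodynError):
            b.project_weight(10.0, -1.5, 5)


class TestGrowthModel:
    times = np.arange(0.0, 37.0, 3.0)

    @pytest.mark.parametrize("g_true", [0.015, 0.021])
    def test_noise_free_recovery(self, g_true):
        w = b.project_weight(10.0, g_true, self.times)
        res = b.fit_growth_rate(b.WeightSeries(self.times, w))
        assert res.g == pytest.approx(g_true, rel=1e-6)

    def test_constant_weights_give_zero_growth(self):
        res = b.fit_growth_rate(b.WeightSeries(self.times,
                                               np.full_like(self.times, 8.0)))
        assert res.g == pytest.approx(0.0, abs=1e-7)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        w = b.project_weight(10.0, 0.02, self.times) * rng.lognormal(0, 0.05,
                                                                     self.times.size)
        a = b.fit_growth_rate(b.WeightSeries(self.times, w)).g
        c = b.fit_growth_rate(b.WeightSeries(self.times, 7.3 * w)).g
        assert a == pytest.approx(c, abs=1e-9)

    def test_joint_w0_and_log_scale_agree_noise_free(self):
        w = b.project_weight(10.0, 0.015, self.times)
        series = b.WeightSeries(self.times, w)
        for kw in ({"fit_w0": True}, {"scale": "log"},
                   {"scale": "log", "fit_w0": True}):
            assert b.fit_growth_rate(series, **kw).g == pytest.approx(0.015,
                                                                      rel=1e-6)

    def test_single_point_raises(self):
        with pytest.raises(InsufficientDataError):
            b.GrowthModel(b.WeightSeries([0.0], [10.0]))

    def test_summary_mentions_estimate(self):
        w = b.project_weight(10.0, 0.015, self.times)
        res = b.fit_growth_rate(b.WeightSeries(self.times, w))
        assert "growth rate" in res.summary()


def _calibration_from_simulation(kp_true, seed=3, noise=0.0):
    """Generate a parasite series with the forward model, return the
    calibration inputs and the truth."""
    cfg = b.SyntheticConfig(seed=seed)
    sched = b.generate_exposure(cfg)
    params = b.derive_params(10.0, 6.0, g=0.015, kp=kp_true)
    load = b.ParasiteLoad(n_parasites=5, Wp0=0.008, gp=0.021, Cp0=0.0)
    sys_ = b.HostParasiteSystem(b.FishState(0.0, 10.0), load)
    times = np.arange(3.0, 36.1, 3.0)
    series = b.simulate_infected(sched, params, sys_, times)
    cp = series.parasite_conc
    if noise:
        rng = np.random.default_rng(seed + 1)
        cp = cp * rng.lognormal(0, noise, cp.size)
    host_rep = _interval_host_stats(sched, params.total_loss, params.ku, 0.0,
                                    "start")
    cal = b.CalibrationSeries(times=times, parasite_conc=cp,
                              interval_starts=sched.renewal_times,
                              cf=host_rep * 10.0 / 0.008,
                              horizon=sched.horizon, n_parasites=5, gp=0.021)
    return cal


class TestParasiteUptakeModel:
    def test_noise_free_recovery_of_standard_kp(self):
        cal = _calibration_from_simulation(1.36e-3)
        res = b.fit_parasite_uptake_rate(cal)
        assert res.kp == pytest.approx(1.36e-3, rel=1e-2)

    def test_endpoint_mode_single_ratio(self):
        cal = _calibration_from_simulation(1.36e-3)
        res = b.fit_parasite_uptake_rate(cal, mode="endpoint")
        assert res.kp == pytest.approx(1.36e-3, rel=1e-6)

    def test_zero_kp_data_gives_zero(self):
        cal = _calibration_from_simulation(0.0)
        res = b.fit_parasite_uptake_rate(cal)
        assert res.kp == pytest.approx(0.0, abs=1e-12)

    def test_steady_state_ratio_inversion(self):
        # Cp held at steady state: kp recoverable from a single ratio
        kp_true, np_, gp, cf = 2e-3, 5, 0.021, 1000.0
        cp_ss = kp_true * cf / (np_ * gp)
        cal = b.CalibrationSeries(times=np.array([3000.0]),
                                  parasite_conc=np.array([cp_ss]),
                                  interval_starts=np.array([0.0]),
                                  cf=np.array([cf]), horizon=3000.0,
                                  n_parasites=np_, gp=gp)
        res = b.fit_parasite_uptake_rate(cal)
        assert res.kp == pytest.approx(kp_true, rel=1e-6)

    def test_negative_estimate_clipped_with_warning(self):
        cal = _calibration_from_simulation(1e-3)
        shrunk = b.CalibrationSeries(times=cal.times,
                                     parasite_conc=-cal.parasite_conc,
                                     interval_starts=cal.interval_starts,
                                     cf=cal.cf, horizon=cal.horizon,
                                     n_parasites=cal.n_parasites, gp=cal.gp)
        with pytest.warns(UserWarning, match="clipped"):
            res = b.fit_parasite_uptake_rate(shrunk)
        assert res.kp == 0.0
        assert res.clipped

    def test_zero_forcing_unidentifiable_warns(self):
        cal = b.CalibrationSeries(times=np.array([3.0, 6.0]),
                                  parasite_conc=np.array([1.0, 2.0]),
                                  interval_starts=np.array([0.0]),
                                  cf=np.array([0.0]), horizon=6.0,
                                  n_parasites=5, gp=0.021)
        with pytest.warns(UserWarning, match="unidentifiable"):
            res = b.fit_parasite_uptake_rate(cal)
        assert res.kp == 0.0

    def test_estimate_linear_in_observations(self):
        cal = _calibration_from_simulation(1.5e-3)
        doubled = b.CalibrationSeries(times=cal.times,
                                      parasite_conc=2 * cal.parasite_conc,
                                      interval_starts=cal.interval_starts,
                                      cf=cal.cf, horizon=cal.horizon,
                                      n_parasites=cal.n_parasites, gp=cal.gp)
        a = b.fit_parasite_uptake_rate(cal).kp
        c = b.fit_parasite_uptake_rate(doubled).kp
        assert c == pytest.approx(2 * a, rel=1e-10)


class TestWholeFishFromMuscle:
    def test_identity_and_offset(self):
        assert b.whole_fish_from_muscle(3.4, 1.0, 0.0) == 3.4
        assert b.whole_fish_from_muscle(0.0, 2.0, 0.7) == 0.7

    def test_linearity(self):
        lo = b.whole_fish_from_muscle(2.0, 1.8, 0.3)
        hi = b.whole_fish_from_muscle(4.0, 1.8, 0.3)
        assert hi - lo == pytest.approx(1.8 * 2.0, rel=1e-12)


class TestUptakeKineticsModel:
    def _observations(self, noise_cv, rng, n_subjects=7):
        # ke chosen so the curve approaches its plateau within 36 d:
        # the plateau pins ku/ke and the approach rate pins ke, keeping
        # the two constants separately identifiable
        cfg = b.SyntheticConfig(seed=17)
        sched = b.generate_exposure(cfg)
        true = b.KineticParams(ku=5e-3, ke=0.1, g=0.015)
        times = np.array([3.0, 9.0, 18.0, 27.0, 36.0])  # 5 sampling times
        series = b.simulate_uninfected(sched, true.replace(kp=0.0),
                                       b.FishState(0.0, 10.0), times)
        t_all = np.tile(times, n_subjects)
        truth = np.tile(series.host_conc, n_subjects)
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        obs = truth * rng.lognormal(0, sigma, truth.size) if noise_cv else truth
        return sched, t_all, obs, true

    def test_noise_free_joint_recovery(self):
        rng = np.random.default_rng(0)
        sched, t, obs, true = self._observations(0.0, rng, n_subjects=1)
        res = b.UptakeKineticsModel(sched, t, obs, g=0.015).fit()
        assert res.ku == pytest.approx(true.ku, rel=1e-3)
        assert res.ke == pytest.approx(true.ke, rel=1e-3)

    def test_noisy_recovery_median_error(self):
        # CV 20%, 7 subjects x 5 times, 200 replicates: median relative
        # error of both constants stays within 15%
        rng = np.random.default_rng(99)
        errs_ku, errs_ke = [], []
        for _ in range(200):
            sched, t, obs, true = self._observations(0.2, rng)
            res = b.UptakeKineticsModel(sched, t, obs, g=0.015).fit()
            errs_ku.append(abs(res.ku - true.ku) / true.ku)
            errs_ke.append(abs(res.ke - true.ke) / true.ke)
        assert np.median(errs_ku) <= 0.15
        assert np.median(errs_ke) <= 0.15
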