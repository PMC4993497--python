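"""Core mass-balance engines: closed-form examples, oracle agreement and
structural invariants."""

import numpy as np
import pytest

import biodyn as b
from biodyn.errors import BiodynError, DegenerateLossError
from biodyn.kinetics import ode_oracle_batch, simulate_uninfected

from conftest import random_uninfected_configs


def _series(schedule, ku, lam, c0, times, **kw):
    params = b.KineticParams(ku=ku, ke=lam, g=0.0)
    return b.simulate_uninfected(schedule, params, b.FishState(C0=c0, W0=10.0),
                                 times, **kw)


class TestUninfectedClosedForm:
    def test_single_interval_buildup(self):
        # C0=0, Cw=100, ku=0.01, lam=0.1, t=10 -> 10*(1-exp(-1))
        s = b.ExposureSchedule.constant(100.0, 10.0)
        out = _series(s, 0.01, 0.1, 0.0, [10.0]).host_conc[0]
        assert out == pytest.approx(10.0 * (1 - np.exp(-1.0)), rel=1e-12)

    def test_pure_decay_with_zero_forcing(self):
        s = b.ExposureSchedule.regular(10.0, 2.0, np.zeros(5))
        out = _series(s, 0.01, 0.1, 5.0, [10.0]).host_conc[0]
        assert out == pytest.approx(5.0 * np.exp(-1.0), rel=1e-12)

    def test_long_horizon_reaches_steady_state(self):
        s = b.ExposureSchedule.regular(2000.0, 3.0, np.full(667, 80.0))
        params = b.KineticParams(ku=0.005, ke=0.04, g=0.01)
        out = b.simulate_uninfected(s, params, b.FishState(0.0, 10.0),
                                    [2000.0]).host_conc[0]
        assert out == pytest.approx(b.steady_state(params, 80.0), rel=1e-3)

    def test_degenerate_loss_raises(self):
        s = b.ExposureSchedule.constant(100.0, 10.0)
        with pytest.raises(DegenerateLossError):
            _series(s, 0.01, 0.0, 0.0, [5.0])

    def test_eval_time_outside_horizon_raises(self):
        s = b.ExposureSchedule.constant(100.0, 10.0)
        with pytest.raises(BiodynError):
            _series(s, 0.01, 0.1, 0.0, [11.0])


class TestSteadyState:
    def test_closed_form(self):
        assert b.steady_state(b.KineticParams(ku=0.005, ke=0.05), 100.0) == \
            pytest.approx(10.0)

    def test_linearity_in_ku(self):
        one = b.steady_state(b.KineticParams(ku=0.005, ke=0.05), 100.0)
        two = b.steady_state(b.KineticParams(ku=0.010, ke=0.05), 100.0)
        assert two == pytest.approx(2 * one)

    def test_zero_exposure(self):
        assert b.steady_state(b.KineticParams(ku=0.005, ke=0.05), 0.0) == 0.0


class TestRecurrenceExpansionIdentity:
    def test_agrees_on_random_schedules(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(2, 8)
            starts = np.sort(rng.uniform(0, 30, size=n))
            starts[0] = 0.0
            s = b.ExposureSchedule(starts, rng.uniform(0, 150, size=n), 36.0)
            ku, lam, c0 = rng.uniform(1e-4, 1e-2), rng.uniform(0.01, 0.5), rng.uniform(0, 5)
            t = rng.uniform(0, 36, size=5)
            a = _series(s, ku, lam, c0, t).host_conc
            e = _series(s, ku, lam, c0, t, _method="expanded").host_conc
            np.testing.assert_allclose(a, e, rtol=1e-10, atol=1e-12)


class TestOracleEquivalence:
    def test_uninfected_matches_oracle(self, schedule_36d):
        rng = np.random.default_rng(5)
        concs, ku, lam, c0 = random_uninfected_configs(20, rng)
        t = np.array([36.0])
        for i in range(20):
            s = b.ExposureSchedule.regular(36.0, 3.0, concs[i])
            ana = _series(s, ku[i], lam[i], c0[i], t).host_conc[0]
            orc = b.ode_oracle(s, b.KineticParams(ku=ku[i], ke=lam[i]),
                               b.HostParasiteSystem(b.FishState(c0[i], 10.0)),
                               t, step=1e-2).host_conc[0]
            assert ana == pytest.approx(orc, rel=1e-6)

    def test_batch_oracle_matches_scalar_oracle(self, schedule_36d):
        rng = np.random.default_rng(6)
        concs, ku, lam, c0 = random_uninfected_configs(3, rng)
        batch = ode_oracle_batch(schedule_36d, concs, ku, lam, c0, 36.0, step=1e-2)
        for i in range(3):
            s = b.ExposureSchedule.regular(36.0, 3.0, concs[i])
            orc = b.ode_oracle(s, b.KineticParams(ku=ku[i], ke=lam[i]),
                               b.HostParasiteSystem(b.FishState(c0[i], 10.0)),
                               [36.0], step=1e-2).host_conc[0]
            assert batch[i] == pytest.approx(orc, rel=1e-10)

    def test_oracle_step_validation(self, schedule_36d, pb_like_params,
                                    infected_system):
        with pytest.raises(BiodynError):
            b.ode_oracle(schedule_36d, pb_like_params, infected_system,
                         [36.0], step=-1.0)
        with pytest.raises(BiodynError):
            b.ode_oracle(schedule_36d, pb_like_params, infected_system,
                         [36.0], step=5.0)  # exceeds shortest interval


class TestInfected:
    def test_kp_zero_reduces_to_uninfected(self, schedule_36d, infected_system):
        params = b.KineticParams(ku=5e-3, ke=0.05, g=0.015, kp=0.0)
        t = np.arange(0.0, 36.1, 3.0)
        inf = b.simulate_infected(schedule_36d, params, infected_system, t)
        unf = b.simulate_uninfected(schedule_36d, params,
                                    infected_system.fish, t)
        np.testing.assert_allclose(inf.host_conc, unf.host_conc, rtol=1e-12)
        np.testing.assert_array_equal(inf.parasite_conc, 0.0)

    def test_parasite_steady_state_under_constant_forcing(self):
        # constant Cf -> Cp -> kp*Cf/(np*gp)
        s = b.ExposureSchedule.regular(3000.0, 3.0, np.full(1000, 100.0))
        params = b.KineticParams(ku=1e-3, ke=1.0, g=0.0, kp=1.36e-3)
        load = b.ParasiteLoad(n_parasites=5, Wp0=0.008, gp=0.021)
        sys_ = b.HostParasiteSystem(b.FishState(0.0, 10.0), load)
        out = b.simulate_infected(s, params, sys_, [3000.0])
        ct_ss = b.steady_state(params, 100.0)
        cf = ct_ss * 10.0 / 0.008
        cp_ss = params.kp * cf / (5 * 0.021)
        assert out.parasite_conc[0] == pytest.approx(cp_ss, rel=1e-3)

    def test_standard_rate_constants_match_oracle_on_refined_grid(
            self, pb_like_params, infected_system):
        # standard kp and gp values; analytical parasite series checked
        # against the coupled oracle in the fine-forcing limit
        rng = np.random.default_rng(3)
        fine = b.ExposureSchedule.regular(36.0, 0.25, np.repeat(
            rng.uniform(40, 120, 12), 12))
        out = b.simulate_infected(fine, pb_like_params, infected_system, [36.0])
        orc = b.ode_oracle(fine, pb_like_params, infected_system, [36.0],
                           step=0.01)
        assert out.parasite_conc[0] == pytest.approx(orc.parasite_conc[0],
                                                     rel=2e-3)

    def test_convergence_first_order_in_interval_length(
            self, pb_like_params, infected_system):
        # halving the renewal grid at fixed forcing halves-or-better the
        # discrepancy with the coupled oracle
        base = b.ExposureSchedule.regular(36.0, 3.0,
                                          np.full(12, 80.0))
        orc = b.ode_oracle(base, pb_like_params, infected_system, [36.0],
                           step=0.005).parasite_conc[0]
        errs = []
        for factor in (1, 2, 4):
            fine = base.refined(factor)
            ana = b.simulate_infected(fine, pb_like_params, infected_system,
                                      [36.0]).parasite_conc[0]
            errs.append(abs(ana - orc))
        assert errs[1] <= 0.55 * errs[0]
        assert errs[2] <= 0.55 * errs[1]

    def test_mass_budget_identity(self, infected_system):
        # host efflux kp*Ct*W equals total parasite influx kp*Ct*(W/Wp)*Wp
        load = infected_system.load
        fish = infected_system.fish
        ct = 3.7
        kp = 1.36e-3
        efflux = kp * ct * fish.W0
        influx = kp * b.host_source_concentration(ct, fish.W0, load.Wp0) * load.Wp0
        assert influx == pytest.approx(efflux, rel=1e-12)

    def test_cf_sampling_options_bracket_start(self, schedule_36d,
                                               pb_like_params, infected_system):
        outs = {mode: b.simulate_infected(schedule_36d, pb_like_params,
                                          infected_system, [36.0],
                                          cf_sampling=mode).parasite_conc[0]
                for mode in ("start", "midpoint", "mean")}
        # with rising host concentration the start-sample underestimates
        assert outs["start"] < outs["mean"]
        assert outs["start"] < outs["midpoint"]

    def test_gp_only_loss_option(self, schedule_36d, pb_like_params,
                                 infected_system):
        printed = b.simulate_infected(schedule_36d, pb_like_params,
                                      infected_system, [36.0],
                                      parasite_loss="np_gp").parasite_conc[0]
        alt = b.simulate_infected(schedule_36d, pb_like_params,
                                  infected_system, [36.0],
                                  parasite_loss="gp").parasite_conc[0]
        assert alt > printed  # smaller loss rate accumulates more


class TestHostSource:
    def test_direct_arithmetic(self):
        assert b.host_source_concentration(2.0, 10.0, 0.01) == pytest.approx(2000.0)

    def test_zero_host_concentration(self):
        assert b.host_source_concentration(0.0, 10.0, 0.01) == 0.0

    def test_identity_when_weights_equal(self):
        assert b.host_source_concentration(3.3, 5.0, 5.0) == pytest.approx(3.3)

    def test_nonpositive_weight_raises(self):
        with pytest.raises(BiodynError):
            b.host_source_concentration(1.0, 0.0, 0.01)


class TestMonotonicityAndPositivity:
    def test_monotone_in_ku_cw_ke(self, schedule_36d):
        rng = np.random.default_rng(9)
        for _ in range(10):
            ku, lam, c0 = rng.uniform(1e-4, 1e-2), rng.uniform(0.02, 0.4), 0.0
            base = _series(schedule_36d, ku, lam, c0, [36.0]).host_conc[0]
            assert _series(schedule_36d, ku * 1.5, lam, c0, [36.0]).host_conc[0] > base
            assert _series(schedule_36d, ku, lam * 1.5, c0, [36.0]).host_conc[0] < base
            boosted = b.ExposureSchedule.regular(
                36.0, 3.0, schedule_36d.interval_concentrations * 1.5)
            assert _series(boosted, ku, lam, c0, [36.0]).host_conc[0] > base

    def test_nonnegative_outputs(self, schedule_36d, pb_like_params,
                                 infected_system):
        t = np.linspace(0, 36, 37)
        out = b.simulate_infected(schedule_36d, pb_like_params,
                                  infected_system, t)
        assert np.all(out.host_conc >= 0)
        assert np.all(out.parasite_conc >= 0)
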