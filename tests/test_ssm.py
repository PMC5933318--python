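"""Grid construction, model primitives, diagnostics and the MCMC fit."""

import math
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
import scipy.stats

from dcrws import (MCMCConfig, ProcessParams, TDistParams, Track, build_grid,
                   gelman_rubin, observation_loglik, process_model_step,
                   switch_states)
from dcrws.argos_io import ArgosFix
from dcrws.ssm import GridError, PriorSpec

UTC = timezone.utc
T0 = datetime(2016, 4, 5, 10, 0, tzinfo=UTC)


def track_spanning(hours, tag="w"):
    return Track(track_id=tag, fixes=[
        ArgosFix(tag_id=tag, time=T0 + timedelta(hours=h),
                 lon=-74.0, lat=-43.0, loc_class="1") for h in hours])


def default_params(**kw):
    base = dict(gamma=(0.8, 0.2), theta=(0.0, 1.5), alpha=(0.9, 0.1),
                Sigma=np.diag([0.01, 0.01]))
    base.update(kw)
    return ProcessParams(**base)


class TestBuildGrid:
    def test_96h_span_at_48h_step_gives_three_times(self):
        g = build_grid(track_spanning([0, 50, 96]), 48.0)
        assert g.n_times == 3
        assert g.times[-1] - g.times[0] == timedelta(hours=96)

    def test_fix_on_grid_boundary_starts_its_interval(self):
        g = build_grid(track_spanning([0, 48, 96]), 48.0)
        assert g.fix_interval[1] == 1
        assert g.fix_j[1] == pytest.approx(0.0, abs=1e-9)

    def test_fractional_position_within_interval(self):
        g = build_grid(track_spanning([0, 60, 96]), 48.0)
        assert g.fix_interval[1] == 1
        assert g.fix_j[1] == pytest.approx(0.25)

    def test_200_day_span_at_6h_step(self):
        # whale #10's window (2016-04-05 to 2016-10-22) spans 200 days:
        # ceil(200*24/6) + 1 = 801 grid times
        g = build_grid(track_spanning([0, 1000, 200 * 24]), 6.0)
        assert g.n_times == 801

    def test_short_track_rejected(self):
        with pytest.raises(GridError):
            build_grid(track_spanning([0, 40]), 48.0)


class TestProcessModel:
    def test_full_persistence_zero_turn_continues_straight(self):
        p = default_params(gamma=(1.0, 0.2), theta=(0.0, 1.5))
        x = process_model_step((0.0, 0.0), (1.0, 0.5), 1, p)
        np.testing.assert_allclose(x - np.array([1.0, 0.5]),
                                   np.array([1.0, 0.5]), atol=1e-12)

    def test_zero_persistence_stays_put(self):
        p = default_params(gamma=(0.8, 0.0))
        x = process_model_step((0.0, 0.0), (1.0, 0.5), 2, p)
        np.testing.assert_allclose(x, (1.0, 0.5), atol=1e-12)

    def test_quarter_turn_rotates_difference(self):
        p = default_params(gamma=(1.0, 0.2), theta=(math.pi / 2, 0.0))
        x = process_model_step((0.0, 0.0), (1.0, 0.0), 1, p)
        np.testing.assert_allclose(x - np.array([1.0, 0.0]), (0.0, 1.0),
                                   atol=1e-12)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            process_model_step((0, 0), (1, 0), 3, default_params())


class TestObservationLoglik:
    def fix_at(self, lon, lat, lc="B"):
        return ArgosFix(tag_id="w", time=T0, lon=lon, lat=lat, loc_class=lc)

    def test_zero_residual_attains_t_mode(self):
        td = TDistParams()
        f = self.fix_at(-74.0, -43.0, "2")
        ll = observation_loglik(f, (-74.0, -43.0), (-70.0, -40.0), 0.0, td)
        nu, tau = td.nu("2"), td.tau("2")
        expected = (scipy.stats.t.logpdf(0, nu[0], scale=tau[0])
                    + scipy.stats.t.logpdf(0, nu[1], scale=tau[1]))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_doubling_scale_at_mode_costs_2_log_2(self):
        td = TDistParams()
        doubled = TDistParams(table={
            c: (v[0], 2 * v[1], v[2], 2 * v[3])
            for c, v in td.table.items()})
        f = self.fix_at(-74.0, -43.0, "1")
        x = ((-74.0, -43.0), (-74.0, -43.0))
        drop = (observation_loglik(f, *x, 0.0, td)
                - observation_loglik(f, *x, 0.0, doubled))
        assert drop == pytest.approx(2 * math.log(2), abs=1e-10)

    def test_class_b_tail_beats_matched_normal(self):
        td = TDistParams()
        nu, tau = td.nu("B"), td.tau("B")
        f = self.fix_at(-74.0 + 5 * tau[0], -43.0 + 5 * tau[1], "B")
        ll_t = observation_loglik(f, (-74.0, -43.0), (-74.0, -43.0), 0.0, td)
        ll_n = (scipy.stats.norm.logpdf(5 * tau[0], scale=tau[0])
                + scipy.stats.norm.logpdf(5 * tau[1], scale=tau[1]))
        assert ll_t > ll_n

    def test_interpolation_uses_fraction_j(self):
        td = TDistParams()
        f = self.fix_at(-72.0, -43.0, "3")
        # at j=0.5 the prediction is the midpoint -72, zero residual in lon
        ll_mid = observation_loglik(f, (-74.0, -43.0), (-70.0, -43.0), 0.5, td)
        ll_edge = observation_loglik(f, (-74.0, -43.0), (-70.0, -43.0), 0.0, td)
        assert ll_mid > ll_edge

    def test_unknown_class_is_config_error(self):
        td = TDistParams(table={c: (2.0, 0.01, 2.0, 0.01) for c in "3210AB"})
        f = self.fix_at(-74.0, -43.0, "3")
        bad = {k: v for k, v in td.table.items()}
        del bad["3"]
        with pytest.raises(ValueError):
            TDistParams(table=bad)
        with pytest.raises(KeyError):
            td.tau("Z")

    def test_matches_scipy_on_random_draws(self, rng):
        """Oracle: direct t-density evaluation, 100 random configurations."""
        td = TDistParams()
        classes = list("3210AB")
        for _ in range(100):
            lc = classes[rng.integers(6)]
            xs = rng.uniform(-80, -70, 2), rng.uniform(-50, -40, 2)
            j = float(rng.uniform(0, 1))
            f = self.fix_at(float(rng.uniform(-80, -70)),
                            float(rng.uniform(-50, -40)), lc)
            pred = (1 - j) * np.array([xs[0][0], xs[1][0]]) \
                + j * np.array([xs[0][1], xs[1][1]])
            nu, tau = td.nu(lc), td.tau(lc)
            want = (scipy.stats.t.logpdf(f.lon - pred[0], nu[0], scale=tau[0])
                    + scipy.stats.t.logpdf(f.lat - pred[1], nu[1],
                                           scale=tau[1]))
            got = observation_loglik(f, (xs[0][0], xs[1][0]),
                                     (xs[0][1], xs[1][1]), j, td)
            assert got == pytest.approx(want, abs=1e-10)


class TestSwitchStates:
    def test_absorbing_chain(self):
        p = default_params(alpha=(1.0, 0.0))
        assert all(switch_states(1, p, u) == 1 for u in (0.01, 0.5, 0.99))
        assert all(switch_states(2, p, u) == 2 for u in (0.01, 0.5, 0.99))

    def test_stationary_distribution_two_thirds(self, rng):
        # alpha = (0.9, 0.2): stationary P(state 1) = 0.2/(1-0.9+0.2) = 2/3
        p = default_params(alpha=(0.9, 0.2))
        b, hits = 1, 0
        n = 30_000
        for _ in range(n):
            b = switch_states(b, p, rng.random())
            hits += b == 1
        assert hits / n == pytest.approx(2 / 3, abs=0.02)


class TestGelmanRubin:
    def test_identical_chains_give_unity(self, rng):
        c = rng.normal(size=1000)
        assert gelman_rubin(np.stack([c, c])) == pytest.approx(1.0, abs=0.01)

    def test_well_mixed_chains_below_1_01(self, rng):
        chains = rng.normal(size=(2, 10_000))
        assert gelman_rubin(chains) < 1.01

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(chains) > 3.0

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.normal(size=(1, 100)))

    def test_agrees_with_arviz_verdicts(self, rng):
        az = pytest.importorskip("arviz")
        good = rng.normal(size=(2, 5_000))
        bad = np.stack([rng.normal(0, 1, 200), rng.normal(5, 1, 200)])
        assert gelman_rubin(good) < 1.01
        assert float(az.rhat(az.convert_to_dataset(good[..., None]))["x"].values[0]) < 1.01
        assert gelman_rubin(bad) > 1.5
        assert float(az.rhat(az.convert_to_dataset(bad[..., None]))["x"].values[0]) > 1.5


class TestConfigs:
    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=1000, n_burnin=1000, thin=1)

    def test_retained_sample_bookkeeping(self):
        cfg = MCMCConfig(n_chains=2, n_iter=12_000, n_burnin=2_000, thin=10)
        assert cfg.retained_samples == 2 * (12_000 - 2_000) // 10

    def test_prior_spec_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(gamma1=(0.0, 2.0))

    def test_process_params_ordering_enforced(self):
        with pytest.raises(ValueError, match="gamma_1 > gamma_2"):
            default_params(gamma=(0.2, 0.8))


class TestFit:
    def test_bookkeeping_and_mode_bounds(self, sim_fit, short_mcmc):
        _, _, res = sim_fit
        assert res.retained_samples == short_mcmc.retained_samples
        for tp in res.tracks:
            assert tp.mode.min() >= 1.0 and tp.mode.max() <= 2.0
            assert np.all(tp.ci_lon[:, 0] <= tp.mean_lon + 1e-12)
            assert np.all(tp.mean_lon <= tp.ci_lon[:, 1] + 1e-12)
            assert len(tp.mean_lon) == tp.grid.n_times

    def test_ordering_constraint_holds_in_every_draw(self, sim_fit):
        _, _, res = sim_fit
        g1 = res.param_samples["gamma1"].ravel()
        g2 = res.param_samples["gamma2"].ravel()
        assert np.all(g1 > g2)

    def test_posterior_tracks_the_observed_region(self, sim_fit):
        _, track, res = sim_fit
        xy = track.lonlat()
        tp = res.tracks[0]
        assert abs(np.median(tp.mean_lon) - np.median(xy[:, 0])) < 2.0
        assert abs(np.median(tp.mean_lat) - np.median(xy[:, 1])) < 2.0
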