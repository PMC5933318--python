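"""Dive extraction, diel tagging and grid binning."""

from dataclasses import replace
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from dcrws import (SimScenario, bin_dive_stats, detect_dives, diel_tag,
                   simulate_dives)
from dcrws.dive import (DiveBout, bout_from_samples, BoutSpacingError,
                        read_depth_csv, whale_diel_summary, write_depth_csv)
from dcrws.simulate import simulate_latent
from dcrws.ssm import RegularGrid

UTC = timezone.utc
T0 = datetime(2015, 5, 1, 12, 0, tzinfo=UTC)


def bout(depths, start=T0):
    return DiveBout(tag_id="mk", start=start, depths=np.asarray(depths, float))


class TestDetectDives:
    def test_shallow_series_has_no_dives(self):
        assert detect_dives(bout([2, 5, 8, 3])) == []

    def test_two_dive_series_statistics(self):
        dives = detect_dives(bout([3, 15, 40, 15, 3, 2, 20, 3]))
        assert len(dives) == 2
        d1, d2 = dives
        assert d1.max_depth == 40.0 and d2.max_depth == 20.0
        assert d1.duration_s == 225.0 and d2.duration_s == 75.0
        assert d1.post_dive_interval_s == 150.0
        assert d2.post_dive_interval_s is None
        assert (d1.end - d1.start).total_seconds() == 225.0

    def test_minimum_dive_duration_is_one_sample(self):
        (d,) = detect_dives(bout([3, 15, 3]))
        assert d.duration_s == 75.0

    def test_threshold_extremes(self):
        b = bout([3, 15, 40, 15, 3, 2, 20, 3])
        assert detect_dives(b, threshold=1e9) == []
        assert len(detect_dives(b, threshold=1e-6)) == 1  # all > 0 joins up

    def test_raising_threshold_shrinks_and_nests_dives(self, rng):
        # a higher threshold can split one dive into several, but total
        # submerged time never grows and every dive stays nested inside
        # a dive found at the lower threshold
        depths = np.abs(rng.normal(0, 30, 200))
        b = bout(depths)
        prev = detect_dives(b, threshold=5.0)
        for thr in (10.0, 20.0, 40.0):
            cur = detect_dives(b, threshold=thr)
            assert sum(d.duration_s for d in cur) <= \
                sum(d.duration_s for d in prev)
            for d in cur:
                assert any(p.start <= d.start and d.end <= p.end
                           for p in prev)
                assert d.max_depth > thr
            prev = cur

    def test_time_conservation_within_bout(self, rng):
        depths = np.abs(rng.normal(0, 25, 300))
        b = bout(depths)
        dives = detect_dives(b)
        if not dives:
            pytest.skip("degenerate draw")
        total = sum(d.duration_s for d in dives)
        total += sum(d.post_dive_interval_s for d in dives
                     if d.post_dive_interval_s is not None)
        lead = (dives[0].start - b.start).total_seconds()
        trail = b.duration_s - (dives[-1].end - b.start).total_seconds()
        assert total + lead + trail == pytest.approx(b.duration_s)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, st.integers(min_value=2, max_value=120),
                      elements=st.floats(0.0, 250.0, allow_nan=False)))
    def test_time_conservation_holds_for_any_depth_series(self, depths):
        b = bout(depths)
        dives = detect_dives(b)
        interior = sum(d.duration_s for d in dives)
        interior += sum(d.post_dive_interval_s for d in dives
                        if d.post_dive_interval_s is not None)
        if dives:
            lead = (dives[0].start - b.start).total_seconds()
            trail = b.duration_s - (dives[-1].end - b.start).total_seconds()
        else:
            lead, trail = b.duration_s, 0.0
        assert interior + lead + trail == pytest.approx(b.duration_s)
        assert all(d.max_depth > 10.0 for d in dives)

    def test_irregular_spacing_rejected(self):
        times = [T0, T0 + timedelta(seconds=75), T0 + timedelta(seconds=200)]
        with pytest.raises(BoutSpacingError):
            bout_from_samples("mk", times, [1.0, 2.0, 3.0])


class TestDielTag:
    def test_equatorial_noon_is_day(self):
        assert diel_tag(datetime(2015, 3, 20, 12, 0, tzinfo=UTC), 0.0, 0.0) \
            == "day"

    def test_equatorial_midnight_is_night(self):
        assert diel_tag(datetime(2015, 3, 20, 0, 0, tzinfo=UTC), 0.0, 0.0) \
            == "night"

    def test_austral_winter_evening_is_night(self):
        # 42S off Chile, mid-June, 17:30 local clock (UTC-4)
        t = datetime(2015, 6, 15, 21, 30, tzinfo=UTC)
        assert diel_tag(t, -73.0, -42.0) == "night"


class TestBinning:
    def grid(self, hours=6.0, n=20, t0=T0):
        return RegularGrid(t0=t0, step_hours=hours, n_steps=n,
                           fix_interval=np.empty(0, int), fix_j=np.empty(0))

    def test_single_dive_bin_has_zero_sd(self):
        dives = detect_dives(bout([3, 15, 40, 3]))
        tagged = [replace(d, diel="day") for d in dives]
        table = bin_dive_stats(tagged, self.grid())
        assert len(table) == 1
        assert table.loc[0, "max_depth_sd"] == 0.0
        assert table.loc[0, "max_depth_mean"] == 40.0

    def test_empty_bins_absent(self):
        dives = detect_dives(bout([3, 15, 3]))
        tagged = [replace(d, diel="night") for d in dives]
        table = bin_dive_stats(tagged, self.grid(n=40))
        assert set(table["bin"]) == {0}

    def test_diel_structure_recovered_from_generator(self):
        sc = SimScenario(seed=5, n_steps=40)
        latent = simulate_latent(sc)
        bouts, truth = simulate_dives(sc, latent)
        found = [d for b in bouts for d in detect_dives(b)]
        assert len(found) == len(truth)
        # extraction reproduces the generator's own dive records exactly
        for got, want in zip(found, truth):
            assert got.start == want.start
            assert got.max_depth == pytest.approx(want.max_depth)
            assert got.duration_s == want.duration_s
            assert got.post_dive_interval_s == want.post_dive_interval_s
        grid = RegularGrid(t0=sc.t0, step_hours=sc.step_hours,
                           n_steps=sc.n_steps,
                           fix_interval=np.empty(0, int), fix_j=np.empty(0))
        table = bin_dive_stats(truth, grid)
        day = table[table["diel"] == "day"]
        night = table[table["diel"] == "night"]
        both = set(day["bin"]) & set(night["bin"])
        # day dives are generated deeper than night dives
        if both:
            d_means = day.set_index("bin").loc[sorted(both), "max_depth_mean"]
            n_means = night.set_index("bin").loc[sorted(both),
                                                 "max_depth_mean"]
            assert (d_means.to_numpy() > n_means.to_numpy()).mean() > 0.7
        assert day["max_depth_mean"].mean() > night["max_depth_mean"].mean()

    def test_whale_summary_pools_by_tag_and_diel(self):
        sc = SimScenario(seed=5, n_steps=40)
        latent = simulate_latent(sc)
        _, truth = simulate_dives(sc, latent)
        summary = whale_diel_summary(truth)
        assert set(summary["diel"]) <= {"day", "night"}
        assert summary["n_dives"].sum() == len(truth)


class TestDepthIO:
    def test_round_trip_and_gap_split(self, tmp_path):
        sc = SimScenario(seed=9, n_steps=20)
        latent = simulate_latent(sc)
        bouts, _ = simulate_dives(sc, latent)
        p = tmp_path / "depth.csv"
        write_depth_csv(bouts, p)
        back = read_depth_csv(p)
        assert sum(b.depths.size for b in back) == \
            sum(b.depths.size for b in bouts)
        # separate bouts are far apart in time, so they stay separate
        assert len(back) == len(bouts)
        np.testing.assert_allclose(back[0].depths, bouts[0].depths)
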