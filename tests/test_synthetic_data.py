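import dataclasses
import datetime as dt
import math

import numpy as np
import pytest
from scipy import stats

from pamsurvey.synthetic_data import (
    ActivityShape,
    SiteConfig,
    default_activity_shape,
    default_sites,
    simulate_bellow_events,
    simulate_outages,
    simulate_playback_levels,
)
from pamsurvey.vocal_activity import hours_from_sunset, sunset_time

START = dt.date(2016, 8, 1)


def males(events):
    return [e for e in events if e.sex == "male"]


class TestSimulateBellowEvents:
    def test_zero_rate_gives_no_events(self, flat_shape):
        site = SiteConfig("A", 0.5, 0.0, -38.0, 145.0)
        events = simulate_bellow_events(
            [site], flat_shape, START, START + dt.timedelta(days=10), seed=1,
            include_females=False,
        )
        assert events == []

    def test_flat_rate_count_near_poisson_mean(self, flat_shape, one_site):
        # base 2/h over 30 days: mean 1440, check within 3 sigma
        events = simulate_bellow_events(
            [one_site], flat_shape, START, START + dt.timedelta(days=29), seed=42,
            include_females=False,
        )
        n = len(males(events))
        assert abs(n - 1440) < 3 * math.sqrt(1440)

    def test_seed_determinism(self, default_shape):
        sites = default_sites()[:3]
        a = simulate_bellow_events(sites, default_shape, START, dt.date(2016, 9, 1), seed=7)
        b = simulate_bellow_events(sites, default_shape, START, dt.date(2016, 9, 1), seed=7)
        assert a == b
        c = simulate_bellow_events(sites, default_shape, START, dt.date(2016, 9, 1), seed=8)
        assert a != c

    def test_events_sorted_and_in_range(self, default_shape):
        sites = default_sites()[:2]
        end = dt.date(2016, 8, 20)
        events = simulate_bellow_events(sites, default_shape, START, end, seed=3)
        keys = [(e.site_id, e.timestamp) for e in events]
        assert keys == sorted(keys)
        hi = dt.datetime.combine(end + dt.timedelta(days=1), dt.time(0, 0))
        lo = dt.datetime.combine(START, dt.time(0, 0))
        assert all(lo <= e.timestamp < hi for e in events)

    def test_high_density_night_rate_in_published_range(self, default_shape):
        # the densest default site should average 2.55-8.89 bellows/h over
        # the six-hour night block across the season
        site = [s for s in default_sites() if s.site_id == "Cape Otway"][0]
        end = dt.date(2017, 1, 31)
        events = simulate_bellow_events([site], default_shape, START, end, seed=11,
                                        include_females=False)
        hist_nights = (end - START).days + 1
        from pamsurvey.scheduling import night_block_minutes, events_to_frame

        _, offs = night_block_minutes(events_to_frame(events)["timestamp"])
        n_block = int((offs >= 0).sum())
        rate = n_block / (hist_nights * 6.0)
        assert 2.55 <= rate <= 8.89

    def test_diel_shape_reproduced(self, one_site):
        # flat seasonal, default diel: binned proportions match the curve
        shape = default_activity_shape()
        flat_seasonal = ActivityShape(
            diel_curve=shape.diel_curve,
            seasonal_curve={w: 1.0 for w in range(0, 30)},
            week_origin=START,
        )
        site = dataclasses.replace(one_site, base_rate=40.0)
        end = dt.date(2016, 10, 31)
        events = simulate_bellow_events([site], flat_seasonal, START, end, seed=5,
                                        include_females=False)
        assert len(events) >= 10_000
        bins = []
        sunsets = {
            d: sunset_time(site.latitude, site.longitude, d)
            for d in (START + dt.timedelta(days=i) for i in range((end - START).days + 2))
        }
        for e in events:
            # nearest sunset: the one whose bin window contains the event
            d0 = e.timestamp.date()
            best = min(
                (s for s in (sunsets.get(d0 - dt.timedelta(days=1)), sunsets.get(d0),
                             sunsets.get(d0 + dt.timedelta(days=1))) if s),
                key=lambda s: abs((e.timestamp - s).total_seconds()),
            )
            bins.append(hours_from_sunset(e.timestamp, best))
        observed = np.bincount(np.array(bins) + 12, minlength=24)
        expected_w = np.array([flat_seasonal.diel_curve[b] for b in range(-12, 12)])
        expected = expected_w / expected_w.sum() * observed.sum()
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        assert stats.chi2.sf(chi2, 23) > 0.01

    def test_errors(self, flat_shape):
        with pytest.raises(ValueError):
            simulate_bellow_events([], flat_shape, START, START, seed=1)
        with pytest.raises(ValueError):
            SiteConfig("A", density=-1, base_rate=1, latitude=0, longitude=0)
        with pytest.raises(ValueError):
            SiteConfig("A", density=1, base_rate=-1, latitude=0, longitude=0)
        site = SiteConfig("A", 1, 1, -38, 145)
        with pytest.raises(ValueError):
            simulate_bellow_events([site], flat_shape, START, START - dt.timedelta(days=1), seed=1)

    def test_activity_shape_validation(self):
        with pytest.raises(ValueError):  # missing bins
            ActivityShape({0: 1.0}, {0: 1.0}, START)
        with pytest.raises(ValueError):  # max != 1
            ActivityShape({b: 0.5 for b in range(-12, 12)}, {0: 1.0}, START)


class TestSimulateOutages:
    SITES = [SiteConfig(f"s{i}", 0.5, 1.0, -38, 145) for i in range(3)]

    def test_zero_cap_empty(self):
        cals = simulate_outages(self.SITES, START, dt.date(2016, 10, 1), 0, 3, seed=1)
        assert all(not c.dates for c in cals.values())

    def test_cap_one(self):
        cals = simulate_outages(self.SITES, START, dt.date(2016, 10, 1), 1, 3, seed=2)
        assert all(len(c.dates) <= 1 for c in cals.values())

    @pytest.mark.parametrize("seed", range(100))
    def test_default_caps_always_respected(self, seed):
        cals = simulate_outages(
            self.SITES[:1], START, dt.date(2017, 1, 31), 9, 3, seed=seed
        )
        for cal in cals.values():
            days = sorted(cal.dates)
            assert len(days) <= 9
            run = best = 1 if days else 0
            for a, b in zip(days, days[1:]):
                run = run + 1 if (b - a).days == 1 else 1
                best = max(best, run)
            assert best <= 3

    def test_negative_caps_rejected(self):
        with pytest.raises(ValueError):
            simulate_outages(self.SITES, START, START, -1, 3, seed=1)


class TestSimulatePlaybackLevels:
    def test_reference_distance(self):
        prof = simulate_playback_levels(75, [1], 20, 0, 0)
        assert prof.levels[0] == pytest.approx(75)

    def test_spherical_spreading_100m(self):
        prof = simulate_playback_levels(75, [100], 20, 0, 0)
        assert prof.levels[0] == pytest.approx(35)

    def test_excess_attenuation(self):
        prof = simulate_playback_levels(75, [10], 20, 0.1, 0)
        assert prof.levels[0] == pytest.approx(54)

    def test_monotone_attenuation_noiseless(self):
        d = np.arange(1, 141, 5, dtype=float)
        prof = simulate_playback_levels(75, d, 20, 0.05, 0)
        assert np.all(np.diff(prof.levels) < 0)

    def test_noise_seeded(self):
        d = [1, 20, 40]
        a = simulate_playback_levels(75, d, 20, 0, noise_sd=2, seed=5)
        b = simulate_playback_levels(75, d, 20, 0, noise_sd=2, seed=5)
        assert np.array_equal(a.levels, b.levels)

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            simulate_playback_levels(75, [0], 20, 0, 0)
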