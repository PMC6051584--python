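import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pamsurvey.occupancy import (
    Stratum,
    cumulative_detection,
    design_table,
    density_class,
    fit_occupancy,
    nights_required,
    one_way_anova,
    pearson_correlation,
    season_stage_of_month,
    simulate_detection_history,
)
from pamsurvey.reference import (
    design_table_reference,
    low_density_p_by_season,
    site_summary_reference,
)
from pamsurvey.scheduling import DetectionHistory


def make_history(detected, valid=None):
    detected = np.asarray(detected, dtype=int)
    n_sites, n_nights = detected.shape
    return DetectionHistory(
        site_ids=tuple(f"s{i}" for i in range(n_sites)),
        nights=tuple(dt.date(2016, 8, 1) + dt.timedelta(days=j) for j in range(n_nights)),
        detected=detected,
        valid=np.ones_like(detected, dtype=bool) if valid is None else np.asarray(valid, bool),
    )


def grid_loglik_max(history, n_grid=1001):
    """Independent brute-force oracle: max log-likelihood on an (psi, p) grid."""
    K = history.valid.sum(axis=1).astype(float)
    d = np.where(history.valid, history.detected, 0).sum(axis=1).astype(float)
    keep = K > 0
    K, d = K[keep], d[keep]
    psi = np.linspace(0, 1, n_grid)[:, None]
    p = np.linspace(0, 1, n_grid)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.zeros((n_grid, n_grid))
        for Ki, di in zip(K, d):
            if di > 0:
                term = np.log(psi) + di * np.log(p) + (Ki - di) * np.log1p(-p)
            else:
                term = np.log(psi * (1 - p) ** Ki + 1 - psi)
            ll = ll + term
    return float(np.nanmax(np.where(np.isfinite(ll), ll, -np.inf)))


class TestFitOccupancy:
    def test_all_detected_closed_form_vs_grid(self):
        h = make_history([[1, 1, 0], [1, 1, 1]])  # d = (2, 3), K = 3 each
        fit = fit_occupancy(h)
        assert fit.psi_hat == 1.0 and fit.boundary
        assert fit.p_hat == pytest.approx(5 / 6, abs=1e-12)
        assert fit.loglik >= grid_loglik_max(h, 1001) - 1e-6

    def test_single_site_single_detection(self):
        fit = fit_occupancy(make_history([[1]]))
        assert fit.psi_hat == 1.0 and fit.p_hat == 1.0 and fit.boundary

    def test_all_zero_degenerate(self):
        fit = fit_occupancy(make_history([[0, 0], [0, 0]]))
        assert fit.degenerate and np.isnan(fit.p_hat)

    def test_no_valid_nights_error(self):
        h = make_history([[0, 0]], valid=[[False, False]])
        with pytest.raises(ValueError):
            fit_occupancy(h)

    def test_mixed_history_beats_grid(self):
        h = make_history([[1, 0, 1, 0], [0, 0, 0, 0], [1, 1, 0, 0]])
        fit = fit_occupancy(h)
        assert fit.loglik >= grid_loglik_max(h) - 1e-6
        assert 0 < fit.p_hat < 1 and 0 < fit.psi_hat <= 1

    def test_invalid_nights_reduce_exposure(self):
        # one invalid night: K = (2, 3), d = (1, 1)
        h = make_history([[1, 0, 0], [0, 1, 0]], valid=[[True, True, False], [True] * 3])
        fit = fit_occupancy(h)
        assert fit.n_nights_total == 5
        assert fit.p_hat == pytest.approx(2 / 5, abs=1e-12)  # all sites detected

    def test_parameter_recovery_within_3se(self):
        h = simulate_detection_history(0.8, 0.4, n_sites=200, n_nights=10, seed=123)
        fit = fit_occupancy(h)
        assert abs(fit.psi_hat - 0.8) < 3 * fit.se_psi
        assert abs(fit.p_hat - 0.4) < 3 * fit.se_p
        assert fit.se_p > 0 and fit.se_psi > 0


class TestCumulativeDetection:
    def test_examples(self):
        assert cumulative_detection([0.5, 0.5]) == pytest.approx(0.75)
        assert cumulative_detection([]) == 0.0
        assert cumulative_detection([0.385] * 7) == pytest.approx(0.9667, abs=5e-4)
        assert cumulative_detection([0.385] * 7) >= 0.95

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cumulative_detection([0.5, 1.2])


class TestNightsRequired:
    def test_published_examples(self):
        assert nights_required(0.385, 0.95) == 7
        assert nights_required(0.280, 0.95) == 10
        assert nights_required(1.0, 0.95) == 1
        assert nights_required(0.274, 0.80) == 6  # n=5 falls just short of 0.80
        assert nights_required(0.778, 0.95) == 2  # n=2 gives 0.9507, just over

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            nights_required(0.0, 0.95)

    def test_full_published_table_consistent(self):
        """All 30 published (p, nights) triples are reproduced exactly."""
        for r in design_table_reference().itertuples():
            assert nights_required(r.p_hat, 0.80) == r.nights_80, r
            assert nights_required(r.p_hat, 0.95) == r.nights_95, r

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        p=st.floats(0.01, 0.999),
        confidence=st.floats(0.05, 0.99, exclude_max=True),
    )
    def test_threshold_consistency(self, p, confidence):
        n = nights_required(p, confidence)
        assert cumulative_detection([p] * n) >= confidence
        if n >= 2:
            assert cumulative_detection([p] * (n - 1)) < confidence

    def test_monotone_in_p_and_confidence(self):
        ps = np.linspace(0.05, 0.95, 19)
        n_by_p = [nights_required(p, 0.95) for p in ps]
        assert all(a >= b for a, b in zip(n_by_p, n_by_p[1:]))
        cs = [0.5, 0.8, 0.9, 0.95, 0.99]
        n_by_c = [nights_required(0.3, c) for c in cs]
        assert all(a <= b for a, b in zip(n_by_c, n_by_c[1:]))


class TestDesignTable:
    def test_reproduces_published_night_counts(self):
        # histories engineered so p-hat equals published values exactly
        h1 = make_history([[1] * 558 + [0] * 442])  # p = 0.558
        h2 = make_history([[1] * 494 + [0] * 6])  # p = 0.988
        rows = design_table(
            {
                (Stratum("mid", "low"), "six_hours"): h1,
                (Stratum("late", "high"), "six_hours"): h2,
            }
        )
        by_key = {(r.season_stage, r.density_class): r for r in rows}
        assert by_key[("mid", "low")].nights_95 == 4
        assert by_key[("late", "high")].nights_80 == 1
        assert by_key[("late", "high")].nights_95 == 1
        assert all(r.nights_80 <= r.nights_95 for r in rows)

    def test_failed_fit_does_not_abort_others(self):
        rows = design_table(
            {
                (Stratum("early", "low"), "six_hours"): make_history([[0, 0]]),
                (Stratum("early", "high"), "six_hours"): make_history([[1, 0]]),
            }
        )
        notes = {r.density_class: r.note for r in rows}
        assert "fit failed" in notes["low"]
        assert notes["high"] != "fit failed"


class TestStratification:
    def test_season_stages(self):
        assert season_stage_of_month(8) == "early"
        assert season_stage_of_month(11) == "mid"
        assert season_stage_of_month(1) == "late"
        with pytest.raises(ValueError):
            season_stage_of_month(5)

    def test_density_classes(self):
        assert density_class(0.0) == "low"  # a zero-density occupied site stays low
        assert density_class(0.99) == "low"
        assert density_class(1.0) == "high"


class TestOneWayAnova:
    def test_published_season_effect(self):
        groups = low_density_p_by_season()
        values = sum(groups.values(), [])
        labels = sum([[k] * len(v) for k, v in groups.items()], [])
        F, dfb, dfw, p = one_way_anova(values, labels)
        assert (dfb, dfw) == (2, 12)
        assert F == pytest.approx(16.02, abs=0.005)
        assert p == pytest.approx(0.0004, abs=0.0001)

    def test_equal_group_means_give_zero(self):
        F, _, _, p = one_way_anova([1.0, 2.0, 1.0, 2.0], ["a", "a", "b", "b"])
        assert F == 0.0 and p == 1.0

    def test_identical_values(self):
        F, _, _, p = one_way_anova([3.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert F == 0.0 and p == 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0, 2.0], ["a", "a"])


class TestPearsonCorrelation:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = pearson_correlation(x, [2 * v for v in x])
        assert r == pytest.approx(1.0)
        r, _ = pearson_correlation(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_published_density_vs_bellow_rate(self):
        # computed directly from the published ten-site columns
        tab = site_summary_reference()
        r, p = pearson_correlation(tab.density_koalas_ha, tab.bellows_per_hour)
        assert r == pytest.approx(0.87, abs=0.005)
        assert p < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
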