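import numpy as np
import pandas as pd
import pytest

from crossingmon.regression import (
    AlignmentError,
    DegenerateDesignError,
    LivestockDamage,
    MortalityRecord,
    RegressionBattery,
    build_covariate_table,
    events_minpack_correlation,
    fit_ols,
    livestock_damage_percent,
    partition_mortality,
    pool_summaries,
)
from crossingmon.trends import AnnualPackSummary

from helpers import closed_form_ols

YEARS = ["2009/2010", "2010/2011", "2011/2012", "2012/2013", "2013/2014"]


def make_summaries(wolf, minpack, prey=None, pack_id="OSM"):
    prey = prey or [10, 13, 9, 15, 11][: len(wolf)]
    return [
        AnnualPackSummary(
            pack_id=pack_id,
            monitoring_year=YEARS[i],
            n_events_total=wolf[i] + prey[i],
            n_events_wolf=wolf[i],
            n_events_prey=prey[i],
            n_events_roe_deer=0,
            n_events_red_deer=0,
            n_events_wild_boar=prey[i],
            minimal_pack_size=minpack[i],
            trap_days=1460,
        )
        for i in range(len(wolf))
    ]


class TestFitOls:
    def test_perfect_fit(self):
        x = np.arange(5.0)
        res = fit_ols(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.adjusted_r2 == pytest.approx(1.0)
        assert res.p_two_sided < 1e-8
        assert res.significant

    def test_constant_regressor_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_ols([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_ols([1.0, 2.0], [1.0, 2.0])

    def test_constant_response_is_no_signal(self):
        res = fit_ols([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
        assert res.slope == 0.0
        assert res.p_two_sided == 1.0
        assert not res.significant

    def test_no_signal_adjusted_r2_can_be_negative(self):
        rng = np.random.default_rng(42)
        x = np.arange(5.0)
        negatives = 0
        for _ in range(50):
            res = fit_ols(x, rng.normal(size=5))
            assert res.adjusted_r2 <= res.r2 + 1e-12
            if res.adjusted_r2 < 0:
                negatives += 1
        assert negatives > 0

    def test_matches_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            res = fit_ols(x, y)
            slope, intercept, r2, adj, t, p = closed_form_ols(x, y)
            assert res.slope == pytest.approx(slope, abs=1e-10)
            assert res.intercept == pytest.approx(intercept, abs=1e-10)
            assert res.adjusted_r2 == pytest.approx(adj, abs=1e-10)
            assert res.t_slope == pytest.approx(t, abs=1e-10, rel=1e-10)
            assert res.p_two_sided == pytest.approx(p, abs=1e-10)


class TestPooling:
    def test_pooled_subset_sums_events_and_takes_max_minpack(self):
        s = make_summaries([10, 8, 6, 4, 2], [5, 4, 3, 2, 1], pack_id="OSM")
        s += make_summaries([1, 2, 3, 4, 5], [1, 2, 6, 2, 1], pack_id="Mosor")
        pooled = pool_summaries(s, ["OSM", "Mosor"])
        assert list(pooled["n_events_wolf"]) == [11, 10, 9, 8, 7]
        assert list(pooled["minimal_pack_size"]) == [5, 4, 6, 2, 1]

    def test_missing_pack_rejected(self):
        s = make_summaries([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        with pytest.raises(AlignmentError, match="Mosor"):
            pool_summaries(s, ["OSM", "Mosor"])


def covariates_frame(**cols):
    base = {
        "monitoring_year": YEARS,
        "legal_cull": [10, 4, 12, 2, 5],
        "accidental": [3, 5, 4, 6, 5],
        "domestic_killed": [30, 40, 25, 50, 35],
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestBattery:
    def test_battery_has_one_row_per_pair(self):
        s = make_summaries([20, 35, 10, 42, 30], [3, 4, 2, 5, 4])
        results = RegressionBattery(s, covariates_frame(), ["OSM"]).fit()
        assert len(results.table) == 2 * 5
        assert set(results.table["dependent"]) == {
            "n_events_wolf",
            "minimal_pack_size",
        }

    def test_total_mortality_derived_from_parts(self):
        s = make_summaries([20, 35, 10, 42, 30], [3, 4, 2, 5, 4])
        battery = RegressionBattery(s, covariates_frame(), ["OSM"])
        assert list(battery.data["total_mortality"]) == [13, 9, 16, 8, 10]

    def test_self_regression_recovers_r2_of_one(self):
        wolf = [20, 35, 10, 42, 30]
        s = make_summaries(wolf, [3, 4, 2, 5, 4])
        cov = covariates_frame(wolf_copy=wolf)
        results = RegressionBattery(
            s, cov, ["OSM"], independents=("wolf_copy",)
        ).fit()
        assert results[("n_events_wolf", "wolf_copy")].r2 == pytest.approx(1.0)

    def test_missing_years_listed_in_alignment_error(self):
        s = make_summaries([20, 35, 10, 42, 30], [3, 4, 2, 5, 4])
        cov = covariates_frame().iloc[:3]
        with pytest.raises(AlignmentError, match="2012/2013"):
            RegressionBattery(s, cov, ["OSM"])

    def test_lag_aligns_earlier_covariate_to_later_response(self):
        # responses in years 1..3, covariates observed one year earlier
        s = [
            AnnualPackSummary("OSM", YEARS[i], 30, 20, 10, 0, 0, 10, 3, 1460)
            for i in (1, 2, 3)
        ]
        cov = covariates_frame().iloc[:4]
        battery = RegressionBattery(s, cov, ["OSM"], lag=1)
        assert list(battery.data["legal_cull"]) == [10, 4, 12]

    def test_holm_adjustment_never_reduces_p(self):
        s = make_summaries([20, 35, 10, 42, 30], [3, 4, 2, 5, 4])
        battery = RegressionBattery(s, covariates_frame(), ["OSM"])
        plain = battery.fit().table
        holm = battery.fit(holm=True).table
        assert (holm["p"].to_numpy() >= plain["p"].to_numpy() - 1e-12).all()


class TestEventsMinpackCorrelation:
    def test_proportional_series_gives_r2_one(self):
        s = make_summaries([10, 20, 30, 40, 50], [1, 2, 3, 4, 5])
        res = events_minpack_correlation(s, ["OSM"])
        assert res.r2 == pytest.approx(1.0)
        assert res.slope > 0

    def test_constant_minimal_pack_size_is_no_signal(self):
        s = make_summaries([10, 20, 30, 40, 50], [2, 2, 2, 2, 2])
        res = events_minpack_correlation(s, ["OSM"])
        assert res.slope == 0.0
        assert res.p_two_sided == 1.0


class TestPartitionMortality:
    def test_even_split(self):
        shares = partition_mortality({"legal_cull": 1, "vehicle_collision": 1})
        assert shares.legal_pct == 50.0
        assert shares.accidental_pct == 50.0

    def test_within_accidental_breakdown(self):
        shares = partition_mortality({"vehicle_collision": 3, "poaching": 1})
        assert shares.within_accidental["vehicle_collision"] == 75.0
        assert shares.within_accidental["poaching"] == 25.0

    def test_accepts_record_lists(self):
        records = [
            MortalityRecord("Split-Dalmatia", "2009/2010", "legal_cull", 2),
            MortalityRecord("Split-Dalmatia", "2010/2011", "legal_cull", 1),
            MortalityRecord("Split-Dalmatia", "2009/2010", "poisoning", 1),
        ]
        shares = partition_mortality(records)
        assert shares.legal_pct == 75.0
        assert shares.n_total == 4

    def test_shares_sum_to_100_within_rounding(self):
        rng = np.random.default_rng(0)
        causes = ("legal_cull", "vehicle_collision", "poaching", "poisoning", "unknown")
        for _ in range(200):
            counts = dict(zip(causes, rng.integers(0, 20, 5)))
            if sum(counts.values()) == 0:
                continue
            shares = partition_mortality(counts)
            assert shares.legal_pct + shares.accidental_pct == pytest.approx(
                100.0, abs=0.2
            )
            if shares.accidental_pct > 0:
                assert sum(shares.within_accidental.values()) == pytest.approx(
                    100.0, abs=0.2
                )

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            partition_mortality({"legal_cull": 0})

    def test_unknown_cause_rejected(self):
        with pytest.raises(ValueError):
            partition_mortality({"lightning": 3})


class TestLivestock:
    @pytest.mark.parametrize(
        "killed, registered, expected",
        [(0, 10_000, 0.0), (100, 10_000, 1.0), (25, 10_000, 0.25)],
    )
    def test_damage_percent(self, killed, registered, expected):
        d = LivestockDamage("Split-Dalmatia", "2009/2010", killed, registered)
        assert livestock_damage_percent(d) == pytest.approx(expected)

    def test_killed_cannot_exceed_registered(self):
        with pytest.raises(ValueError):
            LivestockDamage("X", "2009/2010", 11, 10)


def test_covariate_table_sums_over_county_subset():
    mortality = [
        MortalityRecord("Split-Dalmatia", YEARS[0], "legal_cull", 5),
        MortalityRecord("Split-Dalmatia", YEARS[0], "poaching", 2),
        MortalityRecord("Karlovac", YEARS[0], "legal_cull", 7),
    ]
    livestock = [
        LivestockDamage("Split-Dalmatia", YEARS[0], 100, 10_000),
        LivestockDamage("Karlovac", YEARS[0], 10, 10_000),
    ]
    table = build_covariate_table(
        mortality, livestock, ["Split-Dalmatia"], YEARS[:1]
    )
    row = table.iloc[0]
    assert row["legal_cull"] == 5
    assert row["accidental"] == 2
    assert row["total_mortality"] == 7
    assert row["domestic_killed"] == 100
    assert row["livestock_pct"] == pytest.approx(1.0)
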