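"""Person-years, event rates per 1000 and stratified annual rate tables."""

import numpy as np
import pandas as pd
import pytest

import panelmsm as pm
from panelmsm.rates import (
    DAYS_PER_YEAR,
    episodes_from_histories,
    events_from_histories,
    event_rate,
    person_years,
    rate_series,
)


def ep(start, end, ind="a", gender="Female", slum="Korogocho", birth_day=-7305.0):
    return {"individual_id": ind, "start": float(start), "end": float(end),
            "gender": gender, "slum_area": slum, "birth_day": birth_day}


class TestPersonYears:
    def test_full_calendar_year_is_one_person_year(self):
        # 2003 spans days 365..730 from the 2002-01-01 epoch
        episodes = pd.DataFrame([ep(365.0, 730.0)])
        assert person_years(episodes, 2003) == pytest.approx(1.0, abs=1 / DAYS_PER_YEAR)

    def test_no_overlap_gives_zero(self):
        episodes = pd.DataFrame([ep(0.0, 100.0)])
        assert person_years(episodes, 2010) == 0.0

    def test_uniform_coverage_matches_analytic_expectation(self):
        """1000 episodes of 90 days with starts uniform over 2002-2003:
        expected person-time inside 2003 has a closed form."""
        rng = np.random.default_rng(7)
        starts = rng.uniform(0.0, 730.0 - 90.0, size=1000)
        episodes = pd.DataFrame([ep(s, s + 90.0, ind=i)
                                 for i, s in enumerate(starts)])
        got = person_years(episodes, 2003)
        # E[overlap with [365,730)] for uniform start on [0,640):
        # integral of min(s+90,730)-max(s,365) clipped at 0, over s
        s = np.linspace(0.0, 640.0, 200001)
        overlap = np.clip(np.minimum(s + 90, 730) - np.maximum(s, 365), 0, None)
        expected = 1000 * overlap.mean() / DAYS_PER_YEAR
        assert got == pytest.approx(expected, rel=0.05)

    def test_stratum_filter_and_midyear_age_group(self):
        young = ep(0.0, 365.0, ind="y", birth_day=-10 * DAYS_PER_YEAR)
        old = ep(0.0, 365.0, ind="o", birth_day=-60 * DAYS_PER_YEAR)
        episodes = pd.DataFrame([young, old])
        assert person_years(episodes, 2002, age_group="0-14") == pytest.approx(
            1.0, abs=0.01)
        assert person_years(episodes, 2002, age_group="51+") == pytest.approx(
            1.0, abs=0.01)


class TestEventRate:
    def test_zero_events(self):
        assert event_rate(0, 123.4) == 0.0

    def test_net_migration_arithmetic(self):
        assert event_rate(10 - 30, 1000.0) == pytest.approx(-20.0)

    def test_nonpositive_person_years_rejected(self):
        with pytest.raises(ValueError):
            event_rate(1, 0.0)

    def test_poisson_recovery_within_three_standard_errors(self):
        """Counts drawn at 25 per 1000 PY over 10,000 PY recover the rate."""
        rng = np.random.default_rng(11)
        true = 25.0
        count = rng.poisson(true * 10_000 / 1000)
        est = event_rate(int(count), 10_000.0)
        se = 1000 * np.sqrt(count) / 10_000
        assert abs(est - true) <= 3 * se


class TestAgeGroup:
    @pytest.mark.parametrize("age,label", [
        (14.9, "0-14"), (15.0, "15-19"), (19.99, "15-19"),
        (20.0, "20-35"), (36.0, "36-50"), (51.0, "51+"), (0.0, "0-14"),
    ])
    def test_bins(self, age, label):
        assert pm.age_group(age) == label

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            pm.age_group(-0.1)


class TestRateSeries:
    def toy_tables(self):
        episodes = pd.DataFrame(
            [ep(0.0, 100 * DAYS_PER_YEAR / 100, ind=i) for i in range(100)])
        episodes["end"] = DAYS_PER_YEAR  # 100 individuals x 1 full year
        events = pd.DataFrame([
            {"individual_id": "0", "day": 30.0, "event_type": "birth",
             "gender": "Female", "slum_area": "Korogocho", "birth_day": -7305.0},
            {"individual_id": "1", "day": 60.0, "event_type": "birth",
             "gender": "Female", "slum_area": "Korogocho", "birth_day": -7305.0},
        ])
        return events, episodes

    def test_toy_birth_rate_twenty_per_thousand(self):
        events, episodes = self.toy_tables()
        tab = rate_series(events, episodes)
        birth = tab[(tab.year == 2002) & (tab.event_type == "birth")].iloc[0]
        assert birth["count"] == 2
        # 100 episodes each spanning the 365 days of 2002
        assert birth.person_years == pytest.approx(100 * 365 / DAYS_PER_YEAR)
        assert birth.rate_per_1000 == pytest.approx(20.0, abs=0.02)
        assert birth.rate_per_1000 == pytest.approx(
            1000 * 2 / birth.person_years)

    def test_balanced_migration_nets_to_zero(self):
        events, episodes = self.toy_tables()
        extra = pd.DataFrame([
            dict(events.iloc[0]) | {"event_type": "in_migration"},
            dict(events.iloc[1]) | {"event_type": "out_migration"},
        ])
        tab = rate_series(pd.concat([events, extra], ignore_index=True), episodes)
        net = tab[tab.event_type == "net_migration"].iloc[0]
        assert net["count"] == 0 and net.rate_per_1000 == 0.0

    def test_rate_identity_holds_on_every_row(self, small_dataset):
        cfg, _, _, histories = small_dataset
        roster = pm.simulate_covariates(cfg)
        episodes = episodes_from_histories(histories, roster, cfg.horizon)
        events = events_from_histories(histories, roster)
        tab = rate_series(events, episodes, ("gender", "slum_area"))
        np.testing.assert_allclose(
            tab.rate_per_1000, 1000 * tab["count"] / tab.person_years)
        # net migration = in - out on every stratum-year
        piv = tab.pivot_table(index=["year", "gender", "slum_area"],
                              columns="event_type", values="rate_per_1000")
        np.testing.assert_allclose(
            piv["net_migration"], piv["in_migration"] - piv["out_migration"],
            atol=1e-12)

    def test_stratified_counts_decompose_total(self, small_dataset):
        cfg, _, _, histories = small_dataset
        roster = pm.simulate_covariates(cfg)
        episodes = episodes_from_histories(histories, roster, cfg.horizon)
        events = events_from_histories(histories, roster)
        total = rate_series(events, episodes)
        strat = rate_series(events, episodes, ("gender",))
        for etype in ("birth", "death", "out_migration"):
            a = total[total.event_type == etype].set_index("year")["count"]
            b = strat[strat.event_type == etype].groupby("year")["count"].sum()
            pd.testing.assert_series_equal(a, b, check_names=False)
        a = total[total.event_type == "birth"].set_index("year").person_years
        b = strat[strat.event_type == "birth"].groupby("year").person_years.sum()
        np.testing.assert_allclose(a, b)

    def test_rates_invariant_to_episode_splitting(self):
        events, episodes = self.toy_tables()
        half = DAYS_PER_YEAR / 2
        split = []
        for _, e in episodes.iterrows():
            split.append(dict(e) | {"end": half})
            split.append(dict(e) | {"start": half})
        tab1 = rate_series(events, episodes)
        tab2 = rate_series(events, pd.DataFrame(split))
        pd.testing.assert_frame_equal(tab1, tab2)

    def test_closed_cohort_net_migration_runs_negative(self, small_dataset):
        """Everyone starts resident and in-migration requires a prior
        out-migration, so the cumulative net count can never be positive and
        the study total is negative (a persistent-outflow cohort)."""
        cfg, _, _, histories = small_dataset
        roster = pm.simulate_covariates(cfg)
        episodes = episodes_from_histories(histories, roster, cfg.horizon)
        events = events_from_histories(histories, roster)
        tab = rate_series(events, episodes)
        net = tab[tab.event_type == "net_migration"].sort_values("year")
        assert (net["count"].cumsum() <= 0).all()
        assert net["count"].sum() < 0


class TestEpisodesFromHistories:
    def test_residency_toggles_on_migration_and_ends_at_death(self):
        h = pm.EventHistory("x", ((0.0, 1), (100.0, 5), (300.0, 6), (400.0, 7)))
        roster = pd.DataFrame([{"individual_id": "x", "gender": "Female",
                                "slum_area": "Korogocho", "age": 20.0}])
        eps = episodes_from_histories([h], roster, horizon=1000.0)
        assert [(e.start, e.end) for e in eps.itertuples()] == [
            (0.0, 100.0), (300.0, 400.0)]

    def test_open_episode_censored_at_horizon(self):
        h = pm.EventHistory("x", ((0.0, 1),))
        roster = pd.DataFrame([{"individual_id": "x", "gender": "Female",
                                "slum_area": "Korogocho", "age": 20.0}])
        eps = episodes_from_histories([h], roster, horizon=500.0)
        assert [(e.start, e.end) for e in eps.itertuples()] == [(0.0, 500.0)]
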