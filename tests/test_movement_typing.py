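"""NSD model family, movement-type classification, dispersal events."""

import numpy as np
import pandas as pd
import pytest

from dispersal_ssf import classify, extract_dispersal_event, fit_movement_models
from dispersal_ssf.movement_typing import (
    LN39,
    DispersalNotCompletedError,
    InsufficientSpanError,
    classification_report,
    classify_trajectory,
    make_period_windows,
    match_residents,
    nsd_dispersal,
    nsd_migration,
    DispersalEvent,
)


def profile(t, y):
    return pd.DataFrame({"elapsed_days": t, "nsd_km2": y})


@pytest.fixture()
def days():
    return np.arange(0, 214, 1 / 12.0)  # Apr-Oct at 2-h fixes


class TestModelFamily:
    def test_constant_profile_selects_resident(self, days, rng):
        y = np.abs(4.0 + rng.normal(0, 1.0, len(days)))
        fits = fit_movement_models(profile(days, y), require_span=None)
        assert fits[0].model_name == "resident"

    def test_single_sigmoid_selects_dispersal_with_98km_asymptote(self, days, rng):
        y = nsd_dispersal(days, 9604.0, 110.0, 5.0) + rng.normal(0, 150.0, len(days))
        fits = fit_movement_models(profile(days, y), require_span=None)
        assert fits[0].model_name == "dispersal"
        assert np.sqrt(fits[0].params["delta"]) == pytest.approx(98.0, rel=0.02)

    def test_double_sigmoid_selects_migration(self, days, rng):
        y = nsd_migration(days, 900.0, 60.0, 4.0, 160.0, 4.0) + rng.normal(0, 40.0, len(days))
        fits = fit_movement_models(profile(days, y), require_span=None)
        assert fits[0].model_name == "migration"
        assert fits[0].params["theta_return"] > fits[0].params["theta_depart"]

    def test_short_series_refused(self):
        times = pd.date_range("2009-06-01", periods=200, freq="2h", tz="UTC")
        prof = pd.DataFrame(
            {
                "timestamp": times,
                "elapsed_days": np.arange(200) / 12.0,
                "nsd_km2": np.ones(200),
            }
        )
        with pytest.raises(InsufficientSpanError):
            fit_movement_models(prof)
        cls = classify_trajectory(prof, "short")
        assert cls.assigned_type == "other"
        assert any("insufficient_span" in r for r in cls.rationale)


class TestClassification:
    def test_truncated_mid_rise_is_other(self, days, rng):
        # series ends while NSD is still climbing (hunter-kill truncation)
        t = days[days < 120]
        y = nsd_dispersal(t, 5000.0, 115.0, 6.0) + rng.normal(0, 80.0, len(t))
        fits = fit_movement_models(profile(t, y), require_span=None)
        cls = classify(fits, profile(t, y), "trunc")
        assert cls.assigned_type == "other"
        assert "truncated_mid_rise" in cls.rationale

    def test_out_and_back_weeks_is_exploratory(self, days, rng):
        # ~3 weeks away and a return to near the origin
        y = nsd_migration(days, 3000.0, 100.0, 2.5, 121.0, 2.5) + rng.normal(0, 60, len(days))
        fits = fit_movement_models(profile(days, y), require_span=None)
        cls = classify(fits, profile(days, y), "exp")
        assert cls.assigned_type == "exploratory"

    def test_months_away_is_migrant(self, days, rng):
        y = nsd_migration(days, 900.0, 55.0, 4.0, 175.0, 4.0) + rng.normal(0, 40, len(days))
        fits = fit_movement_models(profile(days, y), require_span=None)
        assert classify(fits, profile(days, y), "mig").assigned_type == "migrant"

    def test_classification_invariant_to_rigid_motion(self, landscape):
        import dispersal_ssf as ds

        rng = np.random.default_rng(9)
        traj, _ = ds.simulate_trajectory(landscape, "disperser", rng=rng, clean=True)
        base = classify_trajectory(ds.compute_nsd(traj), require_span=None).assigned_type
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy = traj[["x", "y"]].to_numpy() @ rot.T + [1e5, -2e5]
        moved = traj.assign(x=xy[:, 0], y=xy[:, 1])
        assert classify_trajectory(ds.compute_nsd(moved), require_span=None).assigned_type == base


class TestDispersalEvent:
    def test_sigmoid_inversion_closed_form(self, days):
        # delta=2500, theta=170, phi=4: crossings at theta +/- phi*ln(39)
        t = np.arange(0, 214, 1 / 12.0)
        y = nsd_dispersal(t, 2500.0, 170.0, 4.0)
        fits = fit_movement_models(profile(t, y), require_span=None)
        ev = extract_dispersal_event(profile(t, y), fits[0])
        assert ev.start_day == round(170 - 4 * LN39)  # 155.3 -> 155
        assert ev.end_day == round(170 + 4 * LN39)  # 184.7 -> 185
        assert 170 - 4 * LN39 == pytest.approx(155.3, abs=0.05)

    def test_duration_recovery_on_simulated_dispersal(self, landscape):
        import dispersal_ssf as ds

        rng = np.random.default_rng(21)
        cfg = ds.SimulationConfig(dispersal_duration_days=(12.0, 12.0))
        traj, truth = ds.simulate_trajectory(landscape, "disperser", cfg, rng=rng, clean=True)
        nsd = ds.compute_nsd(traj)
        fits = fit_movement_models(nsd, require_span=None)
        ev = extract_dispersal_event(nsd, fits[0], traj)
        assert abs(ev.duration_days - truth["dispersal_duration_days"]) <= 2.0

    def test_stationary_prelude_excluded(self, days):
        # short 2-km displacement, 35 stationary days, then the main rise:
        # the fitted main sigmoid's crossing days exclude the prelude
        t = days
        y = 4.0 * (t > 60) + nsd_dispersal(t, 3000.0, 130.0, 3.0)
        fits = fit_movement_models(profile(t, y), require_span=None)
        win = next(f for f in fits if f.model_name == "dispersal")
        ev = extract_dispersal_event(profile(t, y), win)
        assert ev.start_day > 95  # well after the day-60 prelude

    def test_incomplete_dispersal_raises(self, days):
        t = days[days < 150]
        y = nsd_dispersal(t, 4000.0, 148.0, 6.0)
        fits = fit_movement_models(profile(t, y), require_span=None)
        win = next(f for f in fits if f.model_name == "dispersal")
        with pytest.raises(DispersalNotCompletedError):
            extract_dispersal_event(profile(t, y), win)


class TestPeriodWindows:
    def test_26_day_window_arithmetic(self):
        ev = DispersalEvent(
            start_day=0,
            end_day=0,
            duration_days=26,
            straight_line_km=40.0,
            completed=True,
            start_time=pd.Timestamp("2009-06-10", tz="UTC"),
            end_time=pd.Timestamp("2009-07-05", tz="UTC"),
        )
        win = make_period_windows(ev)
        assert win.before == (pd.Timestamp("2009-05-15", tz="UTC"), pd.Timestamp("2009-06-10", tz="UTC"))
        assert (win.before[1] - win.before[0]).days == 26
        assert win.after[0] == pd.Timestamp("2009-07-06", tz="UTC")

    def test_windows_disjoint_and_assignment(self):
        ev = DispersalEvent(0, 0, 20, 30.0, True,
                            pd.Timestamp("2009-06-10", tz="UTC"), pd.Timestamp("2009-06-30", tz="UTC"))
        win = make_period_windows(ev)
        ts = pd.date_range("2009-05-01", "2009-09-01", freq="12h", tz="UTC")
        labels = win.assign(ts)
        for name, (lo, hi) in (("before", win.before), ("during", win.during), ("after", win.after)):
            inside = (ts >= lo) & (ts < hi)
            assert set(labels[inside]) == {name}

    def test_perfect_matching_of_ten(self):
        year = (pd.Timestamp("2009-01-01", tz="UTC"), pd.Timestamp("2010-01-01", tz="UTC"))
        wins = {}
        for i in range(10):
            s = pd.Timestamp("2009-06-01", tz="UTC") + pd.Timedelta(days=i)
            ev = DispersalEvent(0, 0, 20, 30.0, True, s, s + pd.Timedelta(days=20))
            wins[f"d{i}"] = make_period_windows(ev)
        residents = {f"r{i}": year for i in range(10)}
        pairing, unmatched = match_residents(wins, residents)
        assert len(pairing) == 10 and not unmatched
        assert len(set(pairing.values())) == 10

    def test_unmatched_disperser_reported(self):
        s = pd.Timestamp("2009-06-01", tz="UTC")
        ev = DispersalEvent(0, 0, 20, 30.0, True, s, s + pd.Timedelta(days=20))
        wins = {"d0": make_period_windows(ev)}
        short = {"r0": (pd.Timestamp("2009-07-01", tz="UTC"), pd.Timestamp("2009-08-01", tz="UTC"))}
        pairing, unmatched = match_residents(wins, short)
        assert pairing == {} and unmatched == ["d0"]


class TestReportArithmetic:
    def test_percentages_recompute_from_counts(self):
        counts = pd.DataFrame(
            {
                "male": {"migrant": 26, "resident": 2, "other": 10, "dispersal_event": 15},
                "female": {"migrant": 71, "resident": 15, "other": 8, "dispersal_event": 1},
            }
        )
        counts["total"] = counts["male"] + counts["female"]
        rep = classification_report(counts, n_males=38, n_females=94, n_exploratory_male=6)
        # row-sum identity: shares recompute from the table's own counts
        assert rep["pct_migrant"] == round(100 * 97 / 132)
        assert rep["pct_resident"] + rep["pct_migrant"] + rep["pct_other"] == 100
        assert rep["pct_males_dispersing"] == round(100 * 15 / 38)
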