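"""Intake analytics: displacement correction, events, meals, accuracy, microstructure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import chronofeed as cf
from chronofeed.intake import IntakeError
from chronofeed.series import ScanSeries


def make_series(weights, flags=None, species=cf.Species.RAT):
    n = len(weights)
    return ScanSeries(times=np.arange(n) * 1.5,
                      weights=np.asarray(weights, dtype=float),
                      lid=np.full(n, "OPEN", dtype=object),
                      flags=np.asarray(flags if flags is not None
                                       else [""] * n, dtype=object),
                      species=species)


def weights_from_deltas(start, deltas):
    return start - np.cumsum(np.concatenate([[0.0], np.asarray(deltas)]))


class TestCorrectDeltas:
    def test_step_on_off_worked_example(self):
        """The mouse Ω19 sequence: carry the zeroed displacements forward."""
        out, open_ = cf.correct_deltas([-30.62, -0.38, +31.13, 0.0], 1.0)
        assert not open_
        assert np.allclose(out, [0.0, 0.0, 0.0, 0.13], atol=1e-9)

    def test_below_threshold_identity(self):
        d = [0.1, -0.02, 0.0, 0.4]
        out, open_ = cf.correct_deltas(d, 1.0)
        assert not open_
        assert np.array_equal(out, d)

    def test_total_mass_preserved(self):
        d = [-30.62, -0.38, +31.13, 0.0, 0.05]
        out, _ = cf.correct_deltas(d, 1.0)
        assert out.sum() == pytest.approx(sum(d), abs=1e-12)

    def test_open_episode_warns_and_deposits_at_end(self):
        with pytest.warns(UserWarning):
            out, open_ = cf.correct_deltas([0.1, -30.0, -0.2], 1.0)
        assert open_
        assert out.sum() == pytest.approx(0.1 - 30.0 - 0.2)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(IntakeError):
            cf.correct_deltas([0.0], 0.0)

    @given(st.lists(st.one_of(
        st.floats(-0.05, 0.3),  # plausible per-scan intake + noise
        st.floats(25.0, 40.0).map(lambda m: -m),  # step-on
        st.floats(25.0, 40.0),  # step-off
    ), min_size=1, max_size=40))
    def test_idempotent(self, deltas):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            once, _ = cf.correct_deltas(deltas, 1.0)
            twice, _ = cf.correct_deltas(once, 1.0)
        assert np.allclose(once, twice, atol=1e-12)


class TestCorrectDisplacements:
    def _mouse_run_with_artifacts(self, seed=3, noise_sd=0.0):
        mouse = cf.mouse_model()
        policy = cf.AllowancePolicy(mode=cf.AllowanceMode.FIXED_MASS,
                                    fixed_mass=0.5)
        sched = cf.build_grazing_schedule(policy=policy)
        res = cf.simulate_session(sched, mouse, days=2, seed=seed,
                                  noise_sd=noise_sd)
        art = cf.inject_mouse_artifacts(res.series, mouse, 2.0, seed=seed + 1)
        return res, art

    def test_series_level_idempotence(self):
        _, art = self._mouse_run_with_artifacts()
        once = cf.correct_displacements(art.series)
        twice = cf.correct_displacements(once)
        assert np.allclose(once.weights, twice.weights, atol=1e-12)

    def test_recovers_ground_truth_daily_totals(self):
        res, art = self._mouse_run_with_artifacts(noise_sd=0.01)
        corrected = cf.correct_displacements(art.series)
        events = cf.extract_events(corrected)
        system = cf.daily_totals(events)
        tol = 2 * 0.01 * np.sqrt(960)
        for day, truth in res.daily_totals.items():
            assert system.get(day, 0.0) == pytest.approx(truth, abs=tol)

    def test_noise_free_recovery_is_exact(self):
        res, art = self._mouse_run_with_artifacts(noise_sd=0.0)
        corrected = cf.correct_displacements(art.series)
        assert cf.extract_events(corrected)["grams"].sum() == pytest.approx(
            res.events["grams"].sum(), abs=1e-6)


class TestExtractEvents:
    def test_monotone_drop(self):
        w = weights_from_deltas(50.0, [0.1] * 10)
        ev = cf.extract_events(make_series(w))
        assert np.allclose(ev["grams"][1:], 0.1)
        assert ev["grams"].sum() == pytest.approx(1.0)

    def test_flat_series_no_events(self):
        ev = cf.extract_events(make_series(np.full(20, 50.0)))
        assert ev["grams"].sum() == 0.0

    def test_unflagged_refill_raises(self):
        w = np.array([50.0, 49.9, 60.0, 59.9])
        with pytest.raises(IntakeError, match="REFILL|refill"):
            cf.extract_events(make_series(w))

    def test_flagged_refill_excluded(self):
        w = np.array([50.0, 49.9, 60.0, 59.9])
        ev = cf.extract_events(make_series(w, flags=["", "", "REFILL", ""]))
        assert ev["grams"].sum() == pytest.approx(0.2)

    def test_matches_simulator_ground_truth(self, grazing_schedule, rat):
        res = cf.simulate_session(grazing_schedule, rat, days=1, seed=17,
                                  noise_sd=0.0)
        ev = cf.extract_events(res.series)
        nz = ev[ev["grams"] > 0]
        truth = res.events
        assert np.allclose(nz["time_min"].to_numpy(), truth["time_min"].to_numpy())
        assert np.allclose(nz["grams"].to_numpy(), truth["grams"].to_numpy())


class TestCumulativeProfile:
    def test_final_value_equals_daily_total(self, grazing_schedule, rat):
        res = cf.simulate_session(grazing_schedule, rat, days=2, seed=19,
                                  noise_sd=0.0)
        cp = cf.cumulative_profile(cf.extract_events(res.series))
        for day, total in res.daily_totals.items():
            assert cp.loc[cp.day == day, "cumulative_g"].iloc[-1] == \
                pytest.approx(total, abs=1e-9)

    def test_grazing_rise_is_approximately_linear(self, grazing_schedule, rat):
        """Max deviation from the straight dark-phase ramp < one window allowance."""
        res = cf.simulate_session(grazing_schedule, rat, days=1, seed=23,
                                  noise_sd=0.0)
        cp = cf.cumulative_profile(cf.extract_events(res.series))
        dark = cp[(cp.time_min > 720.0) & (cp.time_min <= 1440.0)]
        total = dark["cumulative_g"].iloc[-1]
        line = (dark["time_min"] - 720.0) / 720.0 * total
        assert np.abs(dark["cumulative_g"] - line).max() < 1.0

    def test_meal_fed_ramp_is_flat_between_meals(self, meal_schedule, rat):
        res = cf.simulate_session(meal_schedule, rat, days=1, seed=29,
                                  noise_sd=0.0)
        cp = cf.cumulative_profile(cf.extract_events(res.series))
        # between meal 1 (ends 1900 -> t=780) and meal 2 (opens 2330 -> t=1050)
        gap = cp[(cp.time_min > 781.5) & (cp.time_min <= 1050.0)]
        assert gap["grams"].sum() == 0.0


class TestMealMetrics:
    def test_hand_computed_window(self, meal_schedule):
        t0 = (1080 - 360) % 1440  # meal 1 opens at session minute 720
        times = np.arange(960) * 1.5
        grams = np.zeros(960)
        first = int(t0 / 1.5) + 1  # first scan ending inside the window
        grams[first:first + 20] = 0.1
        events = pd.DataFrame({"time_min": times, "grams": grams})
        mm = cf.meal_metrics(events, meal_schedule)
        row = mm[(mm.day == 0) & (mm.meal_index == 1)].iloc[0]
        assert row["size"] == pytest.approx(2.0)
        assert row.duration == pytest.approx(30.0)  # 20 x 1.5 min
        assert row.first30 == pytest.approx(2.0)

    def test_subthreshold_event_gives_zero_duration(self, meal_schedule):
        times = np.arange(960) * 1.5
        grams = np.zeros(960)
        grams[481] = 0.019  # first scan of meal 1, below the 0.02-g rule
        events = pd.DataFrame({"time_min": times, "grams": grams})
        row = cf.meal_metrics(events, meal_schedule).iloc[0]
        assert row["size"] == pytest.approx(0.019)
        assert row.duration == 0.0

    def test_empty_window_flagged(self, meal_schedule):
        events = pd.DataFrame({"time_min": np.arange(960) * 1.5,
                               "grams": np.zeros(960)})
        mm = cf.meal_metrics(events, meal_schedule)
        assert len(mm) == 3
        assert (mm["size"] == 0).all() and (mm.duration == 0).all()
        assert mm["empty"].all()

    def test_requires_meal_fed_schedule(self, grazing_schedule):
        events = pd.DataFrame({"time_min": [1.5], "grams": [0.1]})
        with pytest.raises(IntakeError):
            cf.meal_metrics(events, grazing_schedule)

    def test_wrapped_meal_duration_crosses_midnight(self, meal_schedule):
        # meal 2 opens at 2330 (session minute 1050) and wraps midnight
        times = np.arange(960) * 1.5
        grams = np.zeros(960)
        open_scan = int(1050 / 1.5) + 1
        grams[open_scan:open_scan + 30] = 0.05  # eats 45 min into the meal
        events = pd.DataFrame({"time_min": times, "grams": grams})
        row = cf.meal_metrics(events, meal_schedule)
        row = row[(row.day == 0) & (row.meal_index == 2)].iloc[0]
        assert row.duration == pytest.approx(45.0)
        assert row["size"] == pytest.approx(1.5)


class TestAccuracy:
    @staticmethod
    def _frame(animal, days, grams):
        return pd.DataFrame({"animal_id": animal, "day": days, "grams": grams})

    def test_identity_gives_r2_one_and_100pct(self):
        sys = self._frame("a", [0, 1, 2], [20.0, 21.0, 22.5])
        rep = cf.accuracy_vs_manual(sys, sys)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.accuracy_mean == pytest.approx(100.0)
        assert rep.accuracy_sem == 0.0

    def test_constant_bias_scales_accuracy(self):
        manual = self._frame("a", [0, 1, 2, 3], [20.0, 22.0, 24.0, 26.0])
        system = manual.assign(grams=manual.grams * 0.974)
        rep = cf.accuracy_vs_manual(system, manual)
        assert rep.accuracy_mean == pytest.approx(97.4)
        assert rep.r_squared == pytest.approx(1.0)

    def test_matches_spreadsheet_style_recomputation(self):
        rng = np.random.default_rng(12345)
        animals = ["a", "b", "c"]
        rows_s, rows_m = [], []
        for a in animals:
            g = rng.uniform(18, 28, size=6)
            rows_s.append(self._frame(a, np.arange(6), g))
            rows_m.append(self._frame(a, np.arange(6),
                                      g + rng.normal(0, 0.5, size=6)))
        system = pd.concat(rows_s, ignore_index=True)
        manual = pd.concat(rows_m, ignore_index=True)
        rep = cf.accuracy_vs_manual(system, manual)
        # brute-force oracle: plain python loops over the merged pairs
        pairs = system.merge(manual, on=["animal_id", "day"],
                             suffixes=("_s", "_m"))
        x = pairs["grams_m"].to_list()
        y = pairs["grams_s"].to_list()
        mx, my = sum(x) / len(x), sum(y) / len(y)
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        vx = sum((a - mx) ** 2 for a in x)
        vy = sum((b - my) ** 2 for b in y)
        assert rep.r_squared == pytest.approx(cov * cov / (vx * vy), abs=1e-9)
        accs = []
        for a in animals:
            sub = pairs[pairs.animal_id == a]
            accs.append(sum(s / m * 100 for s, m in
                            zip(sub["grams_s"], sub["grams_m"])) / len(sub))
        assert rep.accuracy_mean == pytest.approx(sum(accs) / 3, abs=1e-9)

    def test_zero_variance_rejected(self):
        flat = self._frame("a", [0, 1, 2], [20.0, 20.0, 20.0])
        with pytest.raises(IntakeError):
            cf.accuracy_vs_manual(flat, flat)


class TestMicrostructure:
    def test_identical_grids_nothing_significant(self):
        g = np.random.default_rng(0).gamma(2.0, 0.05, size=(4, 480))
        out = cf.microstructure_compare(g, g.copy())
        assert out.n_timepoints == 480
        assert out.n_significant == 0

    def test_dark_phase_grid_has_480_points(self, grazing_schedule, rat):
        res = cf.simulate_session(grazing_schedule, rat, days=1, seed=31,
                                  noise_sd=0.0)
        grid = cf.dark_phase_grid(cf.extract_events(res.series), 0,
                                  grazing_schedule)
        assert grid.shape == (480,)
        assert grid.sum() == pytest.approx(res.daily_totals[0], abs=1e-9)

    def test_fewer_than_two_animals_rejected(self):
        with pytest.raises(IntakeError):
            cf.microstructure_compare(np.zeros((1, 480)), np.ones((1, 480)))

    def test_fdr_correction_is_more_conservative(self):
        rng = np.random.default_rng(7)
        a = rng.gamma(2.0, 0.05, size=(6, 480))
        b = rng.gamma(2.0, 0.05, size=(6, 480))
        raw = cf.microstructure_compare(a, b)
        adj = cf.microstructure_compare(a, b, correct=True)
        assert adj.n_significant <= raw.n_significant
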