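"""Psychometric curves, boundary discrimination, adaptive-whisking counts,
touch-count-conditioned lick probability, and resolution comparison."""

import numpy as np
import pandas as pd
import pytest

from whiskloc.behavior import (boundary_discrimination,
                               lick_probability_by_touch_count,
                               protraction_targeting, psychometric_curve,
                               resolution_comparison, session_psychometric,
                               whisk_count_distributions)
from whiskloc.config import SessionConfig
from whiskloc.kinematics import Whisk
from whiskloc.session import GO, LICK, NO_LICK, NOGO
from whiskloc.synth import generate_session

from conftest import make_toy_session, make_toy_trial, make_touch


def ideal_observer(n_per_bin=10):
    positions, licks = [], []
    for c in np.arange(0.5, 10.0, 1.0):
        positions += [c] * n_per_bin
        licks += [1 if c < 5.0 else 0] * n_per_bin
    return np.array(positions), np.array(licks)


class TestPsychometric:
    def test_ideal_observer_is_exact_step(self):
        pos, licks = ideal_observer()
        curve = psychometric_curve(pos, licks, bin_width=1.0,
                                   position_range=(0.0, 10.0))
        np.testing.assert_array_equal(curve.lick_probability,
                                      [1, 1, 1, 1, 1, 0, 0, 0, 0, 0])

    def test_constant_lick_model_is_flat_one(self):
        pos, _ = ideal_observer()
        curve = psychometric_curve(pos, np.ones_like(pos), bin_width=1.0,
                                   position_range=(0.0, 10.0))
        np.testing.assert_array_equal(curve.lick_probability, np.ones(10))

    def test_probabilities_bounded_and_cis_contain_estimate(self, default_session):
        curve = session_psychometric(default_session)
        occ = curve.trial_counts > 0
        assert np.all(curve.lick_probability[occ] >= 0)
        assert np.all(curve.lick_probability[occ] <= 1)
        assert np.all(curve.ci_low[occ] <= curve.lick_probability[occ] + 1e-12)
        assert np.all(curve.ci_high[occ] >= curve.lick_probability[occ] - 1e-12)
        assert curve.trial_counts.sum() == len(default_session)

    def test_empty_session_raises(self):
        with pytest.raises(ValueError, match="no trials"):
            psychometric_curve([], [], 1.0)

    def test_simulator_curve_near_monotone(self, recovery_sessions):
        """Averaged across seeds, lick probability decreases posterior ->
        anterior with at most one adjacent-bin violation."""
        curves = np.vstack([session_psychometric(s).lick_probability
                            for s in recovery_sessions])
        mean_curve = np.nanmean(curves, axis=0)
        diffs = np.diff(mean_curve[np.isfinite(mean_curve)])
        assert np.sum(diffs > 0.02) <= 1

    def test_curve_invariant_to_trial_order(self, default_session):
        import copy
        shuffled = copy.copy(default_session)
        shuffled.trials = list(reversed(default_session.trials))
        c1 = session_psychometric(default_session)
        c2 = session_psychometric(shuffled)
        np.testing.assert_array_equal(c1.lick_probability, c2.lick_probability)


class TestBoundaryDiscrimination:
    def _session_from(self, positions, licks, config=None):
        cfg = config or SessionConfig(n_trials=len(positions))
        trials = []
        for i, (p, lk) in enumerate(zip(positions, licks)):
            tt = GO if p < cfg.boundary_position else NOGO
            trials.append(make_toy_trial(i, pole_position=float(p), trial_type=tt,
                                         choice=LICK if lk else NO_LICK,
                                         n_samples=10))
        return make_toy_session(cfg, trials)

    def test_ideal_observer_difference_is_one(self):
        pos, licks = ideal_observer()
        s = self._session_from(pos, licks)
        out = boundary_discrimination(s)
        np.testing.assert_array_equal(out["lick_diff"], np.ones(6))

    def test_position_independent_choice_near_zero(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 10, 600)
        licks = (rng.random(600) < 0.5).astype(int)
        out = boundary_discrimination(self._session_from(pos, licks))
        for _, row in out.iterrows():
            se = np.sqrt(0.25 / row.n_go + 0.25 / row.n_nogo)
            assert abs(row.lick_diff) < 3 * se

    def test_monotone_observer_gives_nondecreasing_difference(self):
        """Exact construction: lick probability linear in position."""
        positions, licks = [], []
        for c in np.arange(0.5, 10.0, 1.0):
            k = int(round(10 * (1.0 - c / 10.0)))
            positions += [c] * 10
            licks += [1] * k + [0] * (10 - k)
        out = boundary_discrimination(self._session_from(positions, licks))
        assert np.all(np.diff(out["lick_diff"]) >= -1e-12)

    def test_unoccupied_side_marked_missing(self):
        pos = np.full(20, 7.0)  # no-go side only
        out = boundary_discrimination(self._session_from(pos, np.zeros(20)))
        assert out["lick_diff"].isna().all()

    def test_windows_use_exactly_the_trials_within_distance(self):
        # one go trial at 4.6 (0.4 from boundary), one at 2.0
        s = self._session_from([4.6, 2.0, 5.4, 8.0], [1, 1, 0, 0])
        out = boundary_discrimination(s, max_distances=[0.5, 5.0])
        assert out.loc[0, "n_go"] == 1 and out.loc[0, "n_nogo"] == 1
        assert out.loc[1, "n_go"] == 2 and out.loc[1, "n_nogo"] == 2


class TestWhiskCounts:
    def _counting_session(self, counts_touch, counts_notouch):
        """Trials whose whisk lists realize given pre-window counts."""
        cfg = SessionConfig(n_trials=len(counts_touch) + len(counts_notouch))
        trials, whisks = [], []
        t0 = cfg.pole_trigger_time
        for i, c in enumerate(counts_touch):
            trials.append(make_toy_trial(i, touch_events=[make_touch(1000.0)],
                                         choice=LICK, lick_times=[1800.0]))
            whisks.append([Whisk(t0 + 30 * k, t0 + 30 * k + 10, t0 + 30 * k + 25,
                                 20.0, 10.0) for k in range(c)])
        for j, c in enumerate(counts_notouch):
            i = len(counts_touch) + j
            trials.append(make_toy_trial(i, choice=NO_LICK))
            whisks.append([Whisk(t0 + 30 * k, t0 + 30 * k + 10, t0 + 30 * k + 25,
                                 20.0, 10.0) for k in range(c)])
        return make_toy_session(cfg, trials), whisks

    def test_identical_prewindow_distributions_give_zero_kl(self):
        s, whisks = self._counting_session([2, 3, 2, 3], [2, 3, 2, 3])
        dts = np.full(len(s.trials), 1800.0)
        res = whisk_count_distributions(s, whisks, dts)
        assert res.kl_pre == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_distributions_zero_kl(self):
        s, whisks = self._counting_session([3, 3, 3], [3, 3])
        res = whisk_count_distributions(s, whisks, np.full(5, 1800.0))
        assert res.kl_pre == 0.0

    def test_no_touch_session_raises(self):
        s, whisks = self._counting_session([], [2, 3])
        with pytest.raises(ValueError, match="no touch trials"):
            whisk_count_distributions(s, whisks, np.full(2, 1800.0))

    def test_touch_adaptive_simulator_inflates_post_window(self, default_session):
        res = whisk_count_distributions(default_session)
        assert res.kl_post > res.kl_pre
        # whisk-count calibration: ~2.5 whisks before vs ~6.5 after first touch
        assert 1.5 < res.pre_counts_touch.mean() < 3.5
        assert 4.5 < res.post_counts_touch.mean() < 8.5


class TestLickByTouchCount:
    def test_count_only_rule_makes_curves_coincide(self):
        cfg = SessionConfig(n_trials=80)
        trials = []
        rng = np.random.default_rng(0)
        for i in range(80):
            tt = GO if i % 2 == 0 else NOGO
            c = int(rng.integers(0, 6))
            lick = c >= 3  # choice depends on count only
            touches = [make_touch(800.0 + 10 * k) for k in range(c)]
            trials.append(make_toy_trial(
                i, trial_type=tt, choice=LICK if lick else NO_LICK,
                touch_events=touches, lick_times=[1800.0] if lick else []))
        out = lick_probability_by_touch_count(make_toy_session(cfg, trials),
                                              min_trials=1)
        merged = out.pivot(index="count", columns="trial_type",
                           values="lick_probability").dropna()
        np.testing.assert_array_equal(merged[GO], merged[NOGO])

    def test_simulator_go_exceeds_nogo_at_matched_counts(self, recovery_sessions):
        diffs = []
        for session in recovery_sessions[:5]:
            out = lick_probability_by_touch_count(session, min_trials=3)
            merged = out.pivot(index="count", columns="trial_type",
                               values="lick_probability").dropna()
            merged = merged[merged.index > 0]
            if len(merged):
                diffs.append(float((merged[GO] - merged[NOGO]).mean()))
        assert len(diffs) >= 3
        assert np.mean(diffs) > 0

    def test_position_independent_counts_normalize_to_identity_shift(self):
        cfg = SessionConfig(n_trials=40)
        trials = [make_toy_trial(i, pole_position=float(i % 10) + 0.5,
                                 trial_type=GO if (i % 10) < 5 else NOGO,
                                 touch_events=[make_touch(800), make_touch(900)],
                                 choice=LICK, lick_times=[1800.0])
                  for i in range(40)]
        out = lick_probability_by_touch_count(make_toy_session(cfg, trials),
                                              normalize_by_position=True,
                                              min_trials=1)
        assert set(out["count"]) == {0}


class TestProtractionTargeting:
    def test_first_whisks_target_boundary(self, default_session):
        out = protraction_targeting(default_session)
        first = out[out.whisk_index == 0]
        assert np.all(np.abs(first["mean_peak_rel_boundary"]) < 6.0)

    def test_pole_blocks_go_protraction_from_third_whisk(self, default_session):
        out = protraction_targeting(default_session)
        late = out[(out.whisk_index >= 2) & (out.whisk_index <= 5)]
        go = late[late.trial_type == GO].set_index("whisk_index")
        nogo = late[late.trial_type == NOGO].set_index("whisk_index")
        shared = go.index.intersection(nogo.index)
        assert len(shared) >= 3
        assert np.all(go.loc[shared, "mean_peak_rel_boundary"].to_numpy()
                      < nogo.loc[shared, "mean_peak_rel_boundary"].to_numpy())

    def test_single_trial_sd_missing(self):
        cfg = SessionConfig(n_trials=1)
        trial = make_toy_trial(0, trial_type=GO, choice=LICK, lick_times=[1800.0],
                               touch_events=[make_touch(900.0)])
        whisks = [[Whisk(700.0, 730.0, 760.0, 25.0, 12.0)]]
        out = protraction_targeting(make_toy_session(cfg, [trial]), whisks,
                                    np.array([1800.0]))
        assert out["sd"].isna().all()


class TestResolutionComparison:
    def _curve(self, probs, target="c"):
        n = len(probs)
        from whiskloc.behavior import PsychometricCurve
        return PsychometricCurve(
            bin_edges=np.arange(n + 1, dtype=float),
            lick_probability=np.asarray(probs, dtype=float),
            trial_counts=np.full(n, 10.0), ci_low=np.zeros(n),
            ci_high=np.ones(n), target=target)

    def test_identical_curves_zero_deviation(self):
        subj = self._curve([1, 1, 0.5, 0, 0], "subject")
        out = resolution_comparison(subj, [self._curve([1, 1, 0.5, 0, 0])])
        np.testing.assert_allclose(out["deviation"], 0.0)

    def test_constant_lick_versus_step_subject(self):
        subj = self._curve([1, 1, 0, 0], "subject")
        out = resolution_comparison(subj, [self._curve([1, 1, 1, 1], "const")])
        per_bin = out[out["bin_center"].notna()]
        np.testing.assert_array_equal(per_bin["deviation"], [0, 0, 1, 1])
        total = out[out["bin_center"].isna()]["deviation"].iloc[0]
        assert total == 2.0

    def test_mismatched_bins_raise(self):
        subj = self._curve([1, 0], "subject")
        with pytest.raises(ValueError, match="bins"):
            resolution_comparison(subj, [self._curve([1, 0, 0])])
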