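"""Window metrics, trigger decisions, episode identification and the
no-cue protocol."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fogmerge.core import FOGEpisode
from fogmerge.evaluate import (
    aggregate_report,
    apply_no_cue,
    classify_mtds,
    episode_identification,
    generate_mtds,
    precision,
    target_zones,
    window_metrics,
)

P, N = True, False


def ends_for(preds, shift=0.2, length=1.0):
    return np.arange(len(preds)) * shift + length


class TestWindowMetrics:
    def test_perfect(self):
        assert window_metrics([P, N, P], [P, N, P]) == (100.0, 100.0)

    def test_all_negative_predictions(self):
        assert window_metrics([N, N, N], [P, N, P]) == (0.0, 100.0)

    def test_confusion_arithmetic(self):
        assert window_metrics([P, N, N, P], [P, P, N, N]) == (50.0, 50.0)

    def test_undefined_sensitivity_flagged_nan(self):
        sens, spec = window_metrics([N, P], [N, N])
        assert math.isnan(sens) and spec == 50.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            window_metrics([P], [P, N])


class TestGenerateMTDs:
    def test_no_run_of_three(self):
        assert generate_mtds([P, P, N, P, P], ends_for([0] * 5)).size == 0

    def test_single_run_triggers_at_third_window_end(self):
        mtds = generate_mtds([P, P, P], ends_for([0] * 3))
        np.testing.assert_allclose(mtds, [1.4])  # end of third window

    def test_long_run_yields_one_trigger_per_extra_window(self):
        preds = [P, P, N, P, P, P, P]
        mtds = generate_mtds(preds, ends_for(preds))
        np.testing.assert_allclose(mtds, [2.0, 2.2])  # ends of windows 6, 7

    def test_per_run_mode_keeps_first_only(self):
        preds = [P] * 6
        assert generate_mtds(preds, ends_for(preds), per_run=True).size == 1

    @given(st.lists(st.booleans(), max_size=40), st.integers(2, 4))
    def test_matches_run_enumeration_oracle(self, preds, k):
        """Independent oracle: enumerate maximal positive runs; a run of
        length L >= k yields MTDs at window indices s+k-1 .. s+L-1."""
        ends = ends_for(preds)
        expected = []
        i = 0
        while i < len(preds):
            if preds[i]:
                j = i
                while j < len(preds) and preds[j]:
                    j += 1
                if j - i >= k:
                    expected.extend(ends[i + k - 1:j])
                i = j
            else:
                i += 1
        np.testing.assert_allclose(generate_mtds(preds, ends, k=k), expected)


class TestClassifyMTDs:
    ZONES = target_zones([FOGEpisode(10.0, 14.0)])  # [(8, 14)]

    def test_pre_onset_trigger_is_tp(self):
        (e,) = classify_mtds([9.0], self.ZONES)
        assert e.status == "TP" and e.matched_episode == 0

    def test_post_episode_trigger_is_fp(self):
        (e,) = classify_mtds([14.1], self.ZONES)
        assert e.status == "FP" and e.matched_episode is None

    def test_closed_zone_boundaries(self):
        assert classify_mtds([8.0], self.ZONES)[0].status == "TP"
        assert classify_mtds([14.0], self.ZONES)[0].status == "TP"

    def test_overlapping_zones_match_earliest(self):
        zones = target_zones([FOGEpisode(10.0, 14.0), FOGEpisode(15.0, 16.0)])
        (e,) = classify_mtds([13.5], zones)  # inside both (8,14) and (13,16)
        assert e.matched_episode == 0

    def test_each_trigger_classified_exactly_once(self):
        mtds = np.linspace(0, 20, 41)
        events = classify_mtds(mtds, self.ZONES)
        assert len(events) == len(mtds)
        tp = sum(e.status == "TP" for e in events)
        fp = sum(e.status == "FP" for e in events)
        assert tp + fp == len(mtds)


class TestEpisodeIdentification:
    EPS = [FOGEpisode(10.0, 14.0)]

    def test_early_trigger_negative_delay(self):
        results, pct = episode_identification(self.EPS, [9.5])
        assert pct == 100.0
        assert results[0].identified
        assert results[0].identification_delay_s == pytest.approx(-0.5)

    def test_earliest_in_zone_trigger_sets_delay(self):
        results, _ = episode_identification(self.EPS, [9.0, 12.0])
        assert results[0].identification_delay_s == pytest.approx(-1.0)

    def test_no_in_zone_trigger_not_identified(self):
        results, pct = episode_identification(self.EPS, [20.0])
        assert not results[0].identified and pct == 0.0
        assert math.isnan(results[0].identification_delay_s)

    def test_zero_episodes_flagged(self):
        _, pct = episode_identification([], [1.0])
        assert math.isnan(pct)

    def test_invariant_to_out_of_zone_triggers(self):
        _, pct1 = episode_identification(self.EPS, [9.0])
        _, pct2 = episode_identification(self.EPS, [1.0, 9.0, 20.0, 25.0])
        assert pct1 == pct2

    def test_delay_bounded_by_zone(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            m = float(rng.uniform(7.9, 14.1))
            results, _ = episode_identification(self.EPS, [m])
            if results[0].identified:
                d = results[0].identification_delay_s
                assert -2.0 - 1e-9 <= d <= self.EPS[0].duration_s + 1e-9


class TestPrecision:
    def test_published_worked_example(self):
        assert round(precision(324, 231), 1) == 58.4

    def test_degenerate_cases(self):
        assert precision(5, 0) == 100.0
        assert precision(0, 7) == 0.0
        assert math.isnan(precision(0, 0))
        with pytest.raises(ValueError):
            precision(-1, 2)


class TestNoCue:
    EPS = [FOGEpisode(10.0, 14.0)]

    def test_greedy_refractory_scan(self):
        nc = apply_no_cue([10.0, 10.2, 10.4, 13.0], self.EPS)
        np.testing.assert_allclose(nc.surviving_mtds, [10.0, 13.0])

    def test_single_trigger_unchanged(self):
        nc = apply_no_cue([9.0], self.EPS)
        np.testing.assert_allclose(nc.surviving_mtds, [9.0])

    def test_boundary_trigger_survives(self):
        # the no-cue interval is half-open: (t, t + 2.5]
        nc = apply_no_cue([0.0, 2.5, 5.0], [FOGEpisode(20.0, 21.0)])
        np.testing.assert_allclose(nc.surviving_mtds, [0.0, 5.0])

    def test_episode_starting_inside_interval_credited(self):
        # the only trigger precedes the zone (FP) but its interval covers the onset
        eps = [FOGEpisode(5.0, 6.0)]
        nc = apply_no_cue([2.6], eps)  # zone is (3,6); 2.6 is FP
        assert nc.fp == 1 and nc.tp == 0
        assert nc.episode_results[0].identified  # onset 5.0 in (2.6, 5.1]
        assert math.isnan(nc.episode_results[0].identification_delay_s)
        assert nc.episodes_identified_pct == 100.0

    def test_survivors_thinner_and_spaced(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            mtds = np.sort(rng.uniform(0, 60, size=rng.integers(0, 40)))
            nc = apply_no_cue(mtds, self.EPS)
            assert len(nc.surviving_mtds) <= len(mtds)
            diffs = np.diff(nc.surviving_mtds)
            assert np.all(diffs > 2.5)
            assert nc.tp + nc.fp == len(nc.surviving_mtds)


class TestAggregateReport:
    def test_mean_population_sd_and_totals(self):
        df = pd.DataFrame(
            {"sensitivity": [80.0, 90.0, 100.0], "tp": [10, 20, 30], "fp": [1, 2, 3]}
        )
        agg = aggregate_report(df, count_cols=("tp", "fp"))
        assert agg["mean"]["sensitivity"] == pytest.approx(90.0)
        assert agg["sd"]["sensitivity"] == pytest.approx(np.std([80, 90, 100.0]))
        assert agg["total"]["tp"] == 60 and agg["total"]["fp"] == 6

    def test_nan_metrics_excluded_from_means(self):
        df = pd.DataFrame({"specificity": [90.0, float("nan"), 80.0]})
        assert aggregate_report(df)["mean"]["specificity"] == pytest.approx(85.0)

    def test_single_row_mean_is_row_sd_zero(self):
        df = pd.DataFrame({"sensitivity": [77.0]})
        agg = aggregate_report(df)
        assert agg["mean"]["sensitivity"] == 77.0
        assert agg["sd"]["sensitivity"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_report(pd.DataFrame({"a": []}))
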