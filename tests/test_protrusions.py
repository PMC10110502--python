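import numpy as np
import pytest
from scipy.stats import hypergeom

from pgcprot import InputError
from pgcprot import protrusions as pro
from pgcprot import segmentation as seg
from pgcprot import synthetic as sy


def make_event(start=0, mx=2, end=4, bleb=30.0, cell=300.0):
    return pro.BlebEvent(start, mx, end, bleb, cell)


class TestEligibility:
    def test_four_minute_run_eligible(self):
        # 49 frames at 5 s: run spans 240 s > 180 s
        flags = [True] * 49
        ok, span = pro.eligibility_filter(flags, 5.0)
        assert ok and span == (0, 48)

    def test_split_runs_ineligible(self):
        # two 2-min runs separated by tumbling
        flags = [True] * 25 + [False] * 5 + [True] * 25
        ok, span = pro.eligibility_filter(flags, 5.0)
        assert not ok
        assert span in ((0, 24), (30, 54))

    def test_exactly_three_minutes_strict(self):
        # 37 frames at 5 s span exactly 180 s: strict ">" excludes
        ok, _ = pro.eligibility_filter([True] * 37, 5.0)
        assert not ok
        ok, _ = pro.eligibility_filter([True] * 38, 5.0)
        assert ok

    def test_missing_annotations_error(self):
        with pytest.raises(InputError):
            pro.eligibility_filter([], 5.0)


class TestBlebMetrics:
    def test_frequency(self):
        events = [make_event(start=i * 10, mx=i * 10 + 2, end=i * 10 + 4) for i in range(5)]
        m = pro.bleb_metrics(events, analyzed_time_min=10.0)
        assert m.blebbing_frequency_per_min == 0.5

    def test_relative_size(self):
        m = pro.bleb_metrics([make_event(bleb=30.0, cell=300.0)], 1.0)
        assert m.mean_relative_bleb_size == pytest.approx(0.1)

    def test_truth_bookkeeping_exact(self):
        params = sy.CellMovieParams(n_frames=120, bleb_rate_per_min=2.0, render=False)
        scene = sy.generate_cell_movie(params, seed=13)
        truth = scene.truth
        m = pro.bleb_metrics(truth.bleb_events, truth.duration_min)
        assert m.blebbing_frequency_per_min == len(truth.bleb_events) / truth.duration_min
        if truth.bleb_events:
            expected = np.mean([e.max_area_px2 / e.cell_area_px2 for e in truth.bleb_events])
            assert m.mean_relative_bleb_size == pytest.approx(expected, rel=1e-12)

    def test_no_events_size_absent(self):
        m = pro.bleb_metrics([], 5.0)
        assert m.mean_relative_bleb_size is None
        assert m.blebbing_frequency_per_min == 0.0

    def test_nonpositive_time_error(self):
        with pytest.raises(InputError):
            pro.bleb_metrics([], 0.0)

    def test_frequency_additive_over_halves(self):
        params = sy.CellMovieParams(n_frames=120, bleb_rate_per_min=2.0, render=False)
        truth = sy.generate_cell_movie(params, seed=23).truth
        half = 60
        first = [e for e in truth.bleb_events if e.start_frame < half]
        second = [e for e in truth.bleb_events if e.start_frame >= half]
        t_half = truth.duration_min / 2
        f1 = pro.bleb_metrics(first, t_half).blebbing_frequency_per_min
        f2 = pro.bleb_metrics(second, t_half).blebbing_frequency_per_min
        whole = pro.bleb_metrics(truth.bleb_events, truth.duration_min).blebbing_frequency_per_min
        assert (f1 * t_half + f2 * t_half) / truth.duration_min == pytest.approx(whole)


class TestNormalizeToReference:
    def test_reference_mean_one(self):
        vals, ref = pro.normalize_to_reference([3.0], [2.0, 4.0])
        np.testing.assert_allclose(ref, [2 / 3, 4 / 3])
        np.testing.assert_allclose(vals, [1.0])
        assert ref.mean() == pytest.approx(1.0, abs=1e-12)

    def test_identity(self):
        vals, ref = pro.normalize_to_reference([2.0, 4.0], [2.0, 4.0])
        assert vals.mean() == pytest.approx(1.0, abs=1e-12)

    def test_zero_reference_error(self):
        with pytest.raises(InputError):
            pro.normalize_to_reference([1.0], [0.0, 0.0])


class TestDetectBlebs:
    FAVORABLE = dict(min_area_fraction=0.02, max_rise_time_s=30.0, actin_deficit_ratio=0.75)

    @staticmethod
    def movie(seed, rate=2.0):
        params = sy.CellMovieParams(
            n_frames=60,
            bleb_rate_per_min=rate,
            min_event_gap_s=40.0,
            noise_sd=0.0,
            speed_px_per_frame=0.0,
        )
        return sy.generate_cell_movie(params, seed=seed)

    @staticmethod
    def agreement(truth_events, detected):
        used = set()
        tp = 0
        for te in truth_events:
            for i, de in enumerate(detected):
                if i in used:
                    continue
                if de.start_frame <= te.end_frame and de.end_frame >= te.start_frame:
                    tp += 1
                    used.add(i)
                    break
        return tp

    def test_static_cell_no_events(self):
        scene = self.movie(3, rate=0.0)
        masks = seg.CellMaskSeries.from_masks(scene.truth.masks)
        assert pro.detect_blebs(scene.stack(), masks, **self.FAVORABLE) == []

    def test_perfect_precision_recall_on_truth(self):
        for s in range(8):
            scene = self.movie(s)
            masks = seg.CellMaskSeries.from_masks(scene.truth.masks)
            det = pro.detect_blebs(scene.stack(), masks, **self.FAVORABLE)
            tp = self.agreement(scene.truth.bleb_events, det)
            assert tp == len(scene.truth.bleb_events) == len(det)

    def test_small_blebs_filtered(self):
        scene = self.movie(4)
        masks = seg.CellMaskSeries.from_masks(scene.truth.masks)
        strict = dict(self.FAVORABLE, min_area_fraction=0.5)  # nothing is half the cell
        assert pro.detect_blebs(scene.stack(), masks, **strict) == []

    def test_misaligned_error(self):
        scene = self.movie(5)
        masks = seg.CellMaskSeries.from_masks(scene.truth.masks[:-1])
        with pytest.raises(InputError):
            pro.detect_blebs(scene.stack(), masks, **self.FAVORABLE)


class TestActinRichFraction:
    def test_half(self):
        assert pro.actin_rich_fraction(["actin_rich"] * 30 + ["bleb"] * 30) == 0.5

    def test_all_actin(self):
        assert pro.actin_rich_fraction(["actin_rich"] * 10) == 1.0

    def test_known_mix_exact(self):
        labels = ["actin_rich"] * 70 + ["bleb"] * 30 + ["unpolarized"] * 50
        assert pro.actin_rich_fraction(labels) == pytest.approx(0.7)

    def test_no_polarized_error(self):
        with pytest.raises(InputError):
            pro.actin_rich_fraction(["unpolarized"] * 5)


class TestScoreGelResponse:
    def test_no_change(self):
        n = 120
        r = pro.score_gel_response(np.zeros(n), ["actin_rich"] * n, 20, 5.0)
        assert r.category == "no_change" and r.response_time_s is None

    @pytest.mark.parametrize("behavior", ["turn", "loss_of_polarity", "no_change"])
    def test_generator_truth_agreement(self, behavior):
        scene = sy.generate_gel_encounter_movie(behavior=behavior, turn_angle_deg=90.0, seed=2)
        t = scene.truth
        r = pro.score_gel_response(
            t["polarity_angle_per_frame"],
            t["front_type_per_frame"],
            t["encounter_frame"],
            t["frame_interval_s"],
            turn_threshold_deg=45.0,
        )
        assert r.category == behavior
        if behavior != "no_change":
            assert r.response_time_s == pytest.approx(t["response_lag_s"])

    def test_window_constants(self):
        assert pro.GEL_WINDOW_BEFORE_S == 60.0
        assert pro.GEL_WINDOW_AFTER_S == 300.0
        r = pro.score_gel_response(np.zeros(120), ["actin_rich"] * 120, 20, 5.0)
        assert r.window_s == (-60.0, 300.0)

    def test_window_fit_error(self):
        with pytest.raises(InputError):
            pro.score_gel_response(np.zeros(30), ["actin_rich"] * 30, 5, 5.0)


class TestContingency:
    def test_identical_conditions_p_one(self):
        counts = {
            "soft": {"turn": 5, "loss_of_polarity": 5, "no_change": 10},
            "stiff": {"turn": 5, "loss_of_polarity": 5, "no_change": 10},
        }
        res = pro.response_contingency_test(counts)
        assert res[0]["p"] == pytest.approx(1.0)

    def test_p_matches_hypergeometric_enumeration(self):
        counts = {
            "soft": {"turn": 6, "loss_of_polarity": 4, "no_change": 0},
            "stiff": {"turn": 0, "loss_of_polarity": 0, "no_change": 10},
        }
        res = pro.response_contingency_test(counts)
        # table [[10, 0], [0, 10]]: enumerate hypergeometric probabilities
        n_total, row1, col1 = 20, 10, 10
        probs = [hypergeom.pmf(k, n_total, row1, col1) for k in range(11)]
        obs_p = probs[10]
        expected = sum(p for p in probs if p <= obs_p * (1 + 1e-9))
        assert res[0]["p"] == pytest.approx(expected, rel=1e-9)

    def test_bonferroni_cap(self):
        counts = {
            "a": {"turn": 2, "no_change": 3},
            "b": {"turn": 2, "no_change": 3},
        }
        res = pro.response_contingency_test(counts, n_comparisons=3)
        assert res[0]["p_adjusted"] == 1.0  # p = 1, capped

    def test_empty_condition_error(self):
        with pytest.raises(InputError):
            pro.response_contingency_test({"a": {"turn": 1, "no_change": 1}, "b": {}})


class TestBlebEventValidation:
    def test_frame_order(self):
        with pytest.raises(InputError):
            pro.BlebEvent(5, 3, 8, 10.0, 100.0)

    def test_area_order(self):
        with pytest.raises(InputError):
            pro.BlebEvent(0, 1, 2, 200.0, 100.0)
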