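"""Extrema detection, state windows, lumen proxy, ED/ES selection, stack QC."""

import numpy as np
import pytest

import respsort as rs
from respsort.sort import StateWindow
from conftest import RESP_ROI, LV_ROI


def _cosine_curve(period, n_cycles, orientation="expiration-up"):
    n = period * n_cycles
    y = np.cos(2 * np.pi * np.arange(n) / period)
    return rs.RespCurve(y, orientation=orientation)


class TestDetectExtrema:
    def test_pure_cosine_extrema_positions(self):
        P = 50
        ex = rs.detect_extrema(_cosine_curve(P, 4))
        # interior maxima at multiples of P (boundary peak at 0 has no left side)
        for m in ex.expiration_frames:
            assert min(abs(m - np.array([0, P, 2 * P, 3 * P]))) <= 1
        for m in ex.inspiration_frames:
            assert min(abs(m - np.array([P // 2 + P * c for c in range(4)]))) <= 1
        assert ex.estimated_period_frames == pytest.approx(P, rel=0.05)

    def test_constant_curve_raises(self):
        with pytest.raises(ValueError, match="no respiratory signal"):
            rs.detect_extrema(rs.RespCurve(np.ones(100), orientation="expiration-up"))

    def test_undetermined_orientation_requires_override(self):
        curve = _cosine_curve(50, 4, orientation="undetermined")
        with pytest.raises(ValueError, match="orientation"):
            rs.detect_extrema(curve)
        ex = rs.detect_extrema(curve, orientation="expiration-up")
        assert len(ex.expiration_frames) >= 2

    def test_extrema_interleave(self, phantom_slice):
        series, _ = phantom_slice
        curve = rs.respiratory_curve(series, RESP_ROI)
        ex = rs.detect_extrema(curve)
        events = ex.events()
        for (f1, s1), (f2, s2) in zip(events[:-1], events[1:]):
            assert s1 != s2, "consecutive same-type extrema"

    def test_phantom_extrema_match_truth(self, phantom_slice):
        series, truth = phantom_slice
        curve = rs.respiratory_curve(series, RESP_ROI)
        ex = rs.detect_extrema(curve)
        assert len(ex.expiration_frames) == len(truth.expiration_extrema)
        assert len(ex.inspiration_frames) == len(truth.inspiration_extrema)
        for det, tru in ((ex.expiration_frames, truth.expiration_extrema),
                         (ex.inspiration_frames, truth.inspiration_extrema)):
            err = np.abs(np.subtract.outer(det, tru)).min(axis=1)
            assert err.max() <= 2


class TestStateWindows:
    def _extrema(self, exp, insp, n):
        return rs.RespExtrema(np.array(exp), np.array(insp),
                              estimated_period_frames=90.0, confidence=1.0,
                              n_frames=n)

    def test_rest_expiration_halfwidth_15(self):
        ws = rs.state_windows(self._extrema([100], [300], 500), mode="rest")
        w = next(w for w in ws if w.state == rs.EXPIRATION)
        assert (w.lo, w.hi) == (85, 115)

    def test_exercise_inspiration_clipped_at_start(self):
        ws = rs.state_windows(self._extrema([200], [4], 500), mode="exercise")
        w = next(w for w in ws if w.state == rs.INSPIRATION)
        assert (w.lo, w.hi) == (0, 9)

    def test_adjacent_opposite_windows_truncated_at_midpoint(self):
        ws = rs.state_windows(self._extrema([100], [110], 500), mode="rest")
        we = next(w for w in ws if w.state == rs.EXPIRATION)
        wi = next(w for w in ws if w.state == rs.INSPIRATION)
        assert we.hi == 105
        assert wi.lo == 106
        assert we.hi < wi.lo

    def test_windows_never_overlap(self, phantom_slice):
        series, _ = phantom_slice
        curve = rs.respiratory_curve(series, RESP_ROI)
        ws = rs.state_windows(rs.detect_extrema(curve), mode="rest")
        for a, b in zip(ws[:-1], ws[1:]):
            assert a.hi < b.lo


class TestLumenSignal:
    def test_proxy_tracks_true_endo_area(self, phantom_slice):
        series, truth = phantom_slice
        proxy = rs.lumen_signal(series, LV_ROI)
        ed = int(np.argmin(np.minimum(truth.cardiac_phase, 1 - truth.cardiac_phase)))
        assert proxy[ed] == pytest.approx(truth.endo_area_cm2[ed], rel=0.10)

    def test_proxy_extrema_at_true_ed_es(self, phantom_slice):
        series, truth = phantom_slice
        proxy = rs.lumen_signal(series, LV_ROI)
        # within one full cardiac cycle, max at true ED +-1, min at true ES +-1
        period = 27
        lo = 100
        win = slice(lo, lo + period)
        ph = truth.cardiac_phase[win]
        true_ed = lo + int(np.argmin(np.minimum(ph, 1 - ph)))
        true_es = lo + int(np.argmin(np.abs(ph - 1.0 / 3.0)))
        assert abs(lo + int(np.argmax(proxy[win])) - true_ed) <= 1
        assert abs(lo + int(np.argmin(proxy[win])) - true_es) <= 1

    def test_uniform_roi_raises(self):
        series = rs.CineSeries(np.full((5, 32, 32), 0.5), (1.0, 1.0), 35.0, 10.0)
        with pytest.raises(ValueError, match="lumen proxy unavailable"):
            rs.lumen_signal(series, rs.RespROI(0, 16, 0, 16))


class TestSuggestEdEs:
    def test_argmax_argmin(self):
        proxy = np.zeros(20)
        proxy[10:15] = [5, 9, 3, 7, 4]
        ed, es = rs.suggest_ed_es(proxy, StateWindow(12, rs.EXPIRATION, 10, 14))
        assert (ed, es) == (11, 12)

    def test_tie_broken_toward_centre_then_later(self):
        proxy = np.zeros(20)
        proxy[10:15] = [5, 9, 3, 9, 3]
        ed, es = rs.suggest_ed_es(proxy, StateWindow(12, rs.EXPIRATION, 10, 14))
        assert (ed, es) == (13, 12)

    def test_narrow_window_raises(self):
        with pytest.raises(ValueError, match="window too narrow"):
            rs.suggest_ed_es(np.arange(10.0), (3, 4))

    def test_flat_proxy_raises(self):
        with pytest.raises(ValueError, match="no cardiac variation"):
            rs.suggest_ed_es(np.ones(10), (2, 8))

    def test_phantom_suggestions_match_truth(self, phantom_slice):
        series, truth = phantom_slice
        curve = rs.respiratory_curve(series, RESP_ROI)
        windows = rs.state_windows(rs.detect_extrema(curve), mode="rest")
        proxy = rs.lumen_signal(series, LV_ROI)
        checked = 0
        for w in windows:
            if w.state != rs.EXPIRATION or len(w) < 2 * 27:
                continue  # only windows guaranteed to contain a full cycle
            ed, es = rs.suggest_ed_es(proxy, w)
            true_ed, true_es = truth.true_ed_es_in_window(w.lo, w.hi)
            assert abs(ed - true_ed) <= 1
            assert abs(es - true_es) <= 1
            checked += 1

    def test_selection_inside_window(self, sorted_run):
        for sel in sorted_run["selections"]:
            if sel.ed_frame is not None:
                assert sel.ed_window[0] <= sel.ed_frame <= sel.ed_window[1]
            if sel.es_frame is not None:
                assert sel.es_window[0] <= sel.es_frame <= sel.es_window[1]


class TestAssembleAndQC:
    def test_full_selection_no_flags(self, sorted_run):
        ss = sorted_run["sorted_stack"]
        assert ss.incomplete == []
        assert ss.duplicate_pairs == []
        assert len(ss.slice_indices(rs.EXPIRATION)) == 8

    def test_missing_phase_flagged_incomplete(self, phantom_stack):
        stack, _ = phantom_stack
        sels = [rs.SliceStateSelection(i, rs.EXPIRATION, ed_frame=10, es_frame=20)
                for i in range(len(stack))]
        sels[0].es_frame = None  # basal slice without an in-window ES
        ss = rs.assemble_stack(stack, sels, states=(rs.EXPIRATION,))
        assert (0, rs.EXPIRATION) in ss.incomplete
        assert ss.complete_slices(rs.EXPIRATION) == list(range(1, 8))

    def test_no_selection_raises_empty_stack(self, phantom_stack):
        stack, _ = phantom_stack
        sels = [rs.SliceStateSelection(i, rs.EXPIRATION, None, None)
                for i in range(len(stack))]
        with pytest.raises(ValueError, match="empty stack"):
            rs.assemble_stack(stack, sels, states=(rs.EXPIRATION,))

    def test_duplicate_slice_flagged(self, phantom_stack):
        stack, _ = phantom_stack
        sels = [rs.SliceStateSelection(i, rs.EXPIRATION, ed_frame=10, es_frame=20)
                for i in range(len(stack))]
        ss = rs.assemble_stack(stack, sels, states=(rs.EXPIRATION,))
        # copy slice 4's ED image into slice 3: NCC = 1
        ss.get(3, rs.EXPIRATION).ed_image = ss.get(4, rs.EXPIRATION).ed_image.copy()
        rs.flag_duplicate_slices(ss)
        assert any(p[:2] == (3, 4) for p in ss.duplicate_pairs)

    def test_uncorrelated_noise_not_flagged(self):
        rng = np.random.default_rng(0)
        slices = [rs.CineSeries(rng.random((3, 16, 16)), (1.0, 1.0), 35.0, 10.0,
                                slice_location=10.0 * i) for i in range(2)]
        stack = rs.CineStack(slices)
        sels = [rs.SliceStateSelection(i, rs.EXPIRATION, 0, 1) for i in range(2)]
        ss = rs.assemble_stack(stack, sels, states=(rs.EXPIRATION,))
        rs.flag_duplicate_slices(ss)
        assert ss.duplicate_pairs == []

    def test_sorted_stack_round_trip(self, sorted_run, tmp_path):
        ss = sorted_run["sorted_stack"]
        ss.save(tmp_path / "sorted")
        back = rs.SortedStack.load(tmp_path / "sorted")
        assert set(back.entries) == set(ss.entries)
        e0 = ss.get(0, rs.EXPIRATION)
        b0 = back.get(0, rs.EXPIRATION)
        assert np.array_equal(e0.ed_image, b0.ed_image)
        assert b0.provenance["ed_frame"] == e0.provenance["ed_frame"]


class TestLvLength:
    @pytest.mark.parametrize("measured,expect_flag", [
        (140.0, False),   # exact agreement
        (155.0, True),    # off by 15 mm > one 10 mm slice
        (148.0, False),   # off by 8 mm <= one slice
    ])
    def test_one_slice_rule(self, measured, expect_flag):
        flag, computed = rs.check_lv_length(measured, 14, 10.0, 0.0)
        assert computed == 140.0
        assert flag is expect_flag

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError, match="invalid length"):
            rs.check_lv_length(0.0, 14, 10.0)
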