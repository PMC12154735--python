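"""Scoring rules: gating, division calling, swelling, classification,
population curves — strict thresholds and stated boundary behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from germquant.config import PipelineConfig
from germquant.phenotyping import (
    GerminationCall,
    call_first_division,
    detect_swelling_window,
    gate_spores,
    germination_efficiency,
    population_curves,
)

from conftest import make_track, match_calls_to_truth


class TestGating:
    def test_strict_boundary(self, config):
        just_below = make_track([1.39] * 5, track_id=0)
        at_threshold = make_track([1.40] * 5, track_id=1)
        gated, rejected = gate_spores([just_below, at_threshold], config)
        assert [t.track_id for t in gated] == [0]
        assert [t.track_id for t in rejected] == [1]

    def test_late_appearing_track_rejected(self, config):
        t = make_track([1.0] * 5)
        t.measures["frame"] += 3  # appears only at frame 3
        gated, rejected = gate_spores([t], config)
        assert gated == [] and len(rejected) == 1

    def test_scene_spores_gated_debris_rejected(self, config):
        from germquant.morphometrics import measure_all
        from germquant.synthetic import ScenarioConfig, simulate_truth_masks
        from germquant.tracking import link_tracks

        sc = ScenarioConfig(
            n_spores=25,
            n_debris=12,
            debris_area_range_um2=(4.0, 7.0),  # above the min-area filter
            debris_ar_range=(1.6, 3.0),
            duration_min=300,
            seed=19,
        )
        labels, truth = simulate_truth_masks(sc)
        tracks = link_tracks(measure_all(labels), n_frames=labels.n_frames)
        frame0 = [t for t in tracks if t.start_frame == 0]
        gated, rejected = gate_spores(frame0, config)
        assert len(gated) == 25
        assert len(rejected) == 12


class TestFirstDivision:
    def test_first_crossing_example(self, config):
        t = make_track([1.1, 1.3, 2.0, 3.05, 3.4])
        assert call_first_division(t, config) == (3, 30.0)

    def test_never_crossing(self, config):
        assert call_first_division(make_track([1.0, 2.0, 2.9, 2.9]), config) is None

    def test_interpolated_crossing_shifts_to_next_measured(self, config):
        t = make_track(
            [1.0, 2.0, 3.2, 3.4, 3.5],
            interpolated=[False, False, True, True, False],
        )
        assert call_first_division(t, config)[0] == 4

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1.0, 6.0), min_size=1, max_size=40))
    def test_no_earlier_frame_exceeds_threshold(self, ars):
        config = PipelineConfig()
        t = make_track(ars)
        result = call_first_division(t, config)
        if result is not None:
            frame, _ = result
            assert all(a <= config.division_ar for a in ars[:frame])
            assert ars[frame] > config.division_ar

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(1.0, 6.0), min_size=1, max_size=30),
        st.floats(2.0, 4.0),
        st.floats(0.0, 1.5),
    )
    def test_raising_threshold_never_advances_division(self, ars, thr, delta):
        lo = call_first_division(make_track(ars), PipelineConfig(division_ar=thr))
        hi = call_first_division(make_track(ars), PipelineConfig(division_ar=thr + delta))
        if hi is not None:
            assert lo is not None
            assert hi[0] >= lo[0]


class TestEfficiency:
    def _call(self, tid, divided, frame=50):
        return GerminationCall(
            track_id=tid,
            is_spore=True,
            germinated=divided,
            division_frame=frame if divided else None,
            division_time_min=frame * 10.0 if divided else None,
            starting_area_um2=8.0,
            phenotype="normal" if divided else "none",
            outgrowth_length_um=None,
        )

    def test_fraction_with_counts(self):
        calls = [self._call(i, i < 62) for i in range(100)]
        eff, n_germ, n_total = germination_efficiency(calls, end_frame=100)
        assert (eff, n_germ, n_total) == (0.62, 62, 100)

    def test_zero_divided(self):
        calls = [self._call(i, False) for i in range(60)]
        assert germination_efficiency(calls, 100)[0] == 0.0

    def test_no_gated_spores_is_error(self):
        with pytest.raises(ValueError):
            germination_efficiency([], 100)

    def test_small_n_warns(self):
        calls = [self._call(i, True) for i in range(10)]
        with pytest.warns(UserWarning, match="N>50"):
            germination_efficiency(calls, 100)

    def test_monotone_in_end_frame(self):
        calls = [self._call(i, True, frame=10 * i) for i in range(1, 9)]
        effs = [germination_efficiency(calls, e)[0] for e in (80, 50, 20)]
        assert effs[0] >= effs[1] >= effs[2]


class TestSwelling:
    @staticmethod
    def brute_force_window(area, ar, w, eps_a, eps_r):
        """Independent oracle: smooth, scan all runs, keep the longest."""
        kern = np.ones(w) / w
        sa = np.convolve(area, kern, mode="valid")
        sr = np.convolve(ar, kern, mode="valid")
        frames = np.arange(len(area))[w // 2 : len(area) - (w // 2)]
        best = None
        for s in range(len(sa) - 1):
            for e in range(s, len(sa) - 1):
                steps = range(s, e + 1)
                if all(
                    (sa[i + 1] - sa[i]) / sa[i] > eps_a and abs(sr[i + 1] - sr[i]) <= eps_r
                    for i in steps
                ):
                    if best is None or (e - s) > (best[1] - best[0]):
                        best = (s, e)
        if best is None:
            return None
        return int(frames[best[0]]), int(frames[best[1] + 1])

    def test_swelling_phase_detected_and_matches_oracle(self, config):
        n = 25
        area = np.full(n, 7.0)
        area[5:13] = np.linspace(7.0, 12.0, 8)
        area[13:] = 12.0
        ar = 1.0 + 0.005 * np.sin(np.arange(n))
        t = make_track(ar, area_series=area)
        win = detect_swelling_window(t, config)
        oracle = self.brute_force_window(
            area, ar, config.smoothing_window_frames,
            config.swelling_area_eps, config.swelling_ar_eps,
        )
        assert win is not None and oracle is not None
        assert (win.start_frame, win.end_frame) == oracle
        assert 4 <= win.start_frame <= 6
        assert 11 <= win.end_frame <= 13
        assert win.area_gain_fraction > 0.3

    def test_constant_area_no_window(self, config):
        t = make_track(np.ones(20), area_series=np.full(20, 8.0))
        assert detect_swelling_window(t, config) is None

    def test_area_and_ar_rising_together_is_not_swelling(self, config):
        n = 20
        area = np.linspace(8.0, 20.0, n)
        ar = np.linspace(1.0, 2.5, n)  # outgrowth: AR rises with area
        t = make_track(ar, area_series=area)
        assert detect_swelling_window(t, config) is None


class TestClassification:
    def test_scene_phenotypes_match_truth(self, small_scene):
        truth = small_scene["truth"]
        pairs = match_calls_to_truth(
            small_scene["seg"]["tracks"], small_scene["seg"]["calls"], truth
        )
        agree = sum(
            1
            for cell, call in pairs
            if call.phenotype == ("none" if cell.phenotype == "dead" else cell.phenotype)
        )
        assert agree / len(pairs) >= 0.9

    def test_bipolar_priority_over_elongated(self, config):
        """A constructed cell protruding >6 μm from both poles satisfies the
        elongated rule but must be scored bipolar."""
        from germquant.io import LabelStack
        from germquant.phenotyping import classify_outgrowth

        psz = config.pixel_size_um
        h = w = 220
        frames = np.zeros((3, h, w), dtype=np.int32)
        yy, xx = np.mgrid[:h, :w]
        r0_px = 1.55 / psz
        disc = np.hypot(xx - w / 2, yy - h / 2) <= r0_px
        frames[0][disc] = 1
        # both-pole tube: total half-length 8 μm on each side, 1.8 μm wide
        half_len = 8.0 / psz
        half_w = 0.9 / psz
        rod = (np.abs(xx - w / 2) <= half_len) & (np.abs(yy - h / 2) <= half_w)
        frames[1] = frames[2] = np.where(rod | disc, 1, 0)
        labels = LabelStack(frames, psz, 10.0)
        from germquant.morphometrics import measure_all
        from germquant.tracking import link_tracks

        tracks = link_tracks(measure_all(labels), n_frames=3)
        track = [t for t in tracks if t.start_frame == 0][0]
        phenotype, length, _ = classify_outgrowth(track, labels, config)
        assert phenotype == "bipolar"
        assert length > config.elongated_cutoff_um  # would qualify as elongated


class TestPopulationCurves:
    def test_single_track_se_zero(self):
        t = make_track([1.0, 1.1, 1.2], area_series=[7.0, 8.0, 9.0])
        curves = population_curves([t])
        assert (curves["se_area_um2"] == 0).all()
        assert list(curves["mean_area_um2"]) == [7.0, 8.0, 9.0]
        assert (curves["n"] == 1).all()

    def test_identical_tracks_se_zero(self):
        a = make_track([1.0, 1.5], area_series=[7.0, 9.0], track_id=0)
        b = make_track([1.0, 1.5], area_series=[7.0, 9.0], track_id=1)
        curves = population_curves([a, b])
        assert (curves["se_ar"] == 0).all()
        assert (curves["n"] == 2).all()

    def test_mean_area_tracks_generator_expectation(self, small_scene):
        """Population mean area stays within 5% of the closed-form mean of
        the generator's analytic shapes, frame by frame."""
        from germquant.geometry import shape_moments

        truth = small_scene["truth"]
        tracks = small_scene["seg"]["tracks"]
        calls = small_scene["seg"]["calls"]
        pairs = match_calls_to_truth(tracks, calls, truth)
        live = [
            (cell, call)
            for cell, call in pairs
            if cell.phenotype == "normal" and cell.split_frame is not None
        ]
        by_id = {t.track_id: t for t in tracks}
        dt = truth.frame_interval_min
        for frame in (0, 30, 45):
            measured, analytic = [], []
            for cell, call in live:
                t = by_id[call.track_id]
                v = t.value_at(frame, "area_um2")
                if v is None or frame > t.end_frame:
                    continue
                measured.append(v)
                analytic.append(shape_moments(cell.shape_at(frame * dt))[0])
            assert len(measured) >= 3
            assert np.mean(measured) == pytest.approx(np.mean(analytic), rel=0.05)

    def test_excluded_frames_removed(self):
        t = make_track([1.0, 1.1, 1.2, 1.3])
        curves = population_curves([t], exclude_frames=(1,))
        assert 1 not in set(curves["frame"])
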