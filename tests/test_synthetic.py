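"""Generator contracts: determinism, closed-form kinematics, rendering
fidelity, vacuole-channel partition, and CFU decay simulation."""

import numpy as np
import pytest

from germquant.geometry import shape_aspect_ratio
from germquant.morphometrics import measure_all
from germquant.stats import normalize_cfu
from germquant.synthetic import (
    DecayModel,
    ScenarioConfig,
    simulate_cfu_experiment,
    simulate_scene,
    simulate_truth_masks,
    simulate_vacuole_channel,
)


class TestSceneBasics:
    def test_empty_scene(self):
        sc = ScenarioConfig(n_spores=0, n_debris=0, duration_min=100, seed=1)
        stack, truth, labels = simulate_scene(sc, return_labels=True)
        assert labels.labels.max() == 0
        assert truth.cells == [] and truth.debris == []
        # background-only frames: uniform background plus noise
        assert abs(float(stack.frames.mean()) - 1000.0) < 20.0

    def test_single_dead_spore_constant_area(self):
        sc = ScenarioConfig(
            n_spores=1,
            phenotype_mix={"dead": 1.0},
            duration_min=300,
            noise_sd=0.0,
            seed=3,
        )
        labels, truth = simulate_truth_masks(sc)
        counts = [(labels.labels[k] > 0).sum() for k in range(labels.n_frames)]
        assert len(set(counts)) == 1  # static object: identical rasterization

    def test_same_seed_bit_identical(self):
        sc = ScenarioConfig(n_spores=6, duration_min=300, seed=17)
        s1, t1, l1 = simulate_scene(sc, return_labels=True)
        s2, t2, l2 = simulate_scene(sc, return_labels=True)
        assert np.array_equal(s1.frames, s2.frames)
        assert np.array_equal(l1.labels, l2.labels)
        assert [c.division_frame for c in t1.cells] == [c.division_frame for c in t2.cells]

    def test_different_seed_differs(self):
        a, _ = simulate_truth_masks(ScenarioConfig(n_spores=6, duration_min=300, seed=1))
        b, _ = simulate_truth_masks(ScenarioConfig(n_spores=6, duration_min=300, seed=2))
        assert not np.array_equal(a.labels, b.labels)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(phenotype_mix={"normal": 0.5})
        with pytest.raises(ValueError):
            ScenarioConfig(phenotype_mix={"normal": 0.5, "ghost": 0.5})

    def test_overdense_scene_errors(self):
        with pytest.raises(RuntimeError):
            simulate_truth_masks(
                ScenarioConfig(n_spores=40, duration_min=200, packing_fraction=3.0, seed=0)
            )


class TestKinematics:
    def test_division_frame_from_outgrowth_speed(self):
        """A mean-radius spore whose tube reaches 4.5 μm at frame 60 divides
        (analytic AR crosses 3.0) at exactly frame 60."""
        sc = ScenarioConfig(
            n_spores=1,
            phenotype_mix={"normal": 1.0},
            spore_radius_sd_um=0.0,
            lag_shape=1e9,  # lag pinned at its 240-min mean
            lag_mean_min=240.0,
            swell_duration_min=60.0,
            tube_speed_um_per_frame=0.15,  # 4.5 μm over frames 30..60
            seed=5,
        )
        _, truth = simulate_truth_masks(sc)
        cell = truth.cells[0]
        assert cell.outgrowth_at(600.0) == pytest.approx(4.5, abs=1e-3)
        assert cell.division_frame == 60

    def test_truth_division_is_first_analytic_ar_crossing(self, small_scene):
        """For tube-growing phenotypes the recorded division frame is the
        first frame whose closed-form shape has AR above the threshold."""
        truth = small_scene["truth"]
        dt = truth.frame_interval_min
        checked = 0
        for cell in truth.cells:
            if cell.phenotype not in ("normal", "elongated", "bipolar"):
                continue
            if cell.division_frame is None:
                continue
            k = cell.division_frame
            assert shape_aspect_ratio(cell.shape_at(k * dt)) > 3.0
            assert shape_aspect_ratio(cell.shape_at((k - 1) * dt)) <= 3.0
            checked += 1
        assert checked >= 5

    def test_rendered_disc_area_close_to_pi_r_squared(self):
        sc = ScenarioConfig(
            n_spores=4,
            phenotype_mix={"dead": 1.0},
            spore_radius_um=1.55,
            spore_radius_sd_um=0.05,
            duration_min=50,
            seed=8,
        )
        labels, truth = simulate_truth_masks(sc)
        table = measure_all(labels)
        t0 = table[table["frame"] == 0].sort_values("label")
        for cell in truth.cells:  # r ≈ 8.6 px at the default calibration
            row = t0[t0["label"] == cell.label].iloc[0]
            assert row["area_um2"] == pytest.approx(np.pi * cell.radius_um**2, rel=0.05)

    def test_debris_rendered_with_drawn_aspect_ratio(self):
        sc = ScenarioConfig(
            n_spores=0,
            n_debris=6,
            debris_area_range_um2=(4.0, 8.0),
            debris_ar_range=(1.8, 2.8),
            duration_min=50,
            seed=12,
        )
        labels, truth = simulate_truth_masks(sc)
        table = measure_all(labels)
        t0 = table[table["frame"] == 0]
        for deb in truth.debris:
            row = t0[t0["label"] == deb.label].iloc[0]
            assert row["aspect_ratio"] == pytest.approx(deb.aspect_ratio, rel=0.08)
            assert row["area_um2"] == pytest.approx(deb.area_um2, rel=0.12)


class TestVacuoleChannel:
    def _vacuole_scene(self, fraction, noise_sd=0.0, seed=21):
        sc = ScenarioConfig(
            n_spores=3,
            phenotype_mix={"normal": 1.0},
            vacuole_mode="two_channel",
            vacuole_body_fraction=fraction,
            vacuole_noise_sd=noise_sd,
            blur_sigma_px=0.0,
            noise_sd=0.0,
            seed=seed,
        )
        return simulate_scene(sc, return_labels=True)

    def test_fraction_one_means_dark_outgrowth(self):
        stack, truth, labels = self._vacuole_scene(1.0)
        cell = next(c for c in truth.cells if c.division_frame is not None)
        k = cell.division_frame - 1
        ch2 = stack.channel(1)[k].astype(float) - 100.0  # background level
        mask = labels.labels[k] == cell.label
        rb = cell.body_radius_at(k * truth.frame_interval_min)
        rows, cols = np.nonzero(mask)
        bx = cell.center_x_um - (rb - cell.radius_um) * cell.axis_x
        by = cell.center_y_um - (rb - cell.radius_um) * cell.axis_y
        psz = truth.pixel_size_um
        in_body = ((cols + 0.5) * psz - bx) ** 2 + ((rows + 0.5) * psz - by) ** 2 <= cell.radius_um**2
        assert ch2[rows[~in_body], cols[~in_body]].max() == 0.0
        assert ch2[rows[in_body], cols[in_body]].sum() > 0

    @pytest.mark.parametrize("fraction", [0.5, 0.64])
    def test_pixel_sum_recovers_fraction(self, fraction):
        stack, truth, labels = self._vacuole_scene(fraction)
        cell = next(c for c in truth.cells if c.division_frame is not None)
        k = cell.division_frame - 1
        ch2 = stack.channel(1)[k].astype(float) - 100.0
        mask = labels.labels[k] == cell.label
        rb = cell.body_radius_at(k * truth.frame_interval_min)
        rows, cols = np.nonzero(mask)
        psz = truth.pixel_size_um
        bx = cell.center_x_um - (rb - cell.radius_um) * cell.axis_x
        by = cell.center_y_um - (rb - cell.radius_um) * cell.axis_y
        in_body = ((cols + 0.5) * psz - bx) ** 2 + ((rows + 0.5) * psz - by) ** 2 <= cell.radius_um**2
        total = ch2[rows, cols].sum()
        body = ch2[rows[in_body], cols[in_body]].sum()
        assert body / total == pytest.approx(fraction, abs=0.01)

    def test_fraction_out_of_range_rejected(self):
        sc = ScenarioConfig(
            n_spores=1, phenotype_mix={"normal": 1.0}, duration_min=200, seed=2
        )
        labels, truth = simulate_truth_masks(sc)
        with pytest.raises(ValueError):
            simulate_vacuole_channel(truth, labels, body_fractions={0: 1.4})


class TestCFU:
    def test_exponential_half_life_closed_form(self):
        model = DecayModel(half_life_days=10.0, replicate_noise_sd=0.0)
        series = simulate_cfu_experiment(model, [0, 10], n_reps=1, seed=0)
        norm = normalize_cfu(series[0])
        assert norm.normalized[1] == pytest.approx(0.5, abs=1e-12)

    def test_slow_decay_half_life_80(self):
        model = DecayModel(half_life_days=80.0, replicate_noise_sd=0.0)
        series = simulate_cfu_experiment(model, [0, 80], n_reps=1, seed=0)
        assert normalize_cfu(series[0]).normalized[1] == pytest.approx(0.5, abs=1e-12)

    def test_noisy_mean_near_half_monte_carlo(self):
        model = DecayModel(half_life_days=10.0, replicate_noise_sd=0.1)
        series = simulate_cfu_experiment(model, [0, 10], n_reps=1000, seed=7)
        vals = [normalize_cfu(s).normalized[1] for s in series]
        assert np.mean(vals) == pytest.approx(0.5, rel=0.02)

    def test_times_without_day_zero_rejected(self):
        with pytest.raises(ValueError):
            simulate_cfu_experiment(DecayModel(), [5, 10], n_reps=3, seed=0)

    def test_biphasic_survival_between_components(self):
        model = DecayModel(
            form="biphasic",
            half_life_days=5.0,
            half_life_days_2=80.0,
            mixture_weight=0.5,
            replicate_noise_sd=0.0,
        )
        s = model.survival([20.0])[0]
        assert 0.5 * 2 ** (-4.0) < s < 0.5 + 0.5 * 2 ** (-0.25)

    def test_determinism(self):
        model = DecayModel(half_life_days=10.0, replicate_noise_sd=0.2)
        a = simulate_cfu_experiment(model, [0, 10, 20], 3, seed=9)
        b = simulate_cfu_experiment(model, [0, 10, 20], 3, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.cfu, y.cfu)
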