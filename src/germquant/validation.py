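"""End-to-end validation experiments on synthetic scenes.

Each function builds a seeded synthetic dataset at its stated study size,
runs the full analysis through the package's public surface, and returns
the measured recovery/agreement statistics.  These are the package's own
ground-truth benchmarks: the test suite asserts on their outputs, and the
reproduction script reports them.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .config import PipelineConfig
from .morphometrics import fit_region_ellipse, measure_all
from .phenotyping import build_calls, germination_efficiency
from .segmentation import SegParams, detect_focus_loss, segment_stack
from .stats import compare_survival_auc, fisher_exact, normalize_cfu
from .synthetic import (
    DecayModel,
    ScenarioConfig,
    simulate_cfu_experiment,
    simulate_scene,
    simulate_truth_masks,
)
from .tracking import link_tracks
from .vacuole import measure_vacuole_partitions

__all__ = [
    "division_call_recovery",
    "gating_fidelity",
    "efficiency_recovery",
    "phenotype_accuracy",
    "bipolar_priority_ok",
    "morphometrics_oracles",
    "vacuole_recovery",
    "fisher_enumeration_sweep",
    "stats_oracles",
    "longevity_power",
    "focus_loss_check",
    "cli_determinism",
]


def _match_calls(tracks, calls, truth):
    by_id = {t.track_id: t for t in tracks}
    pairs = []
    for call in calls:
        first = by_id[call.track_id].measures.iloc[0]
        best = min(
            truth.cells,
            key=lambda c: (c.center_x_um - first.centroid_x_um) ** 2
            + (c.center_y_um - first.centroid_y_um) ** 2,
        )
        pairs.append((best, call))
    return pairs


def _analyze_labels(labels, cfg):
    table = measure_all(labels)
    tracks = link_tracks(table, n_frames=labels.n_frames)
    calls = build_calls(tracks, labels, cfg)
    return tracks, calls


def division_call_recovery(seed: int, n_cells: int = 200) -> dict:
    """Full pipeline (rendered images -> classical segmentation -> tracking
    -> division calls) on a default mixed-phenotype scene; fraction of
    truth-dividing cells whose detected division frame is within +-1."""
    cfg = PipelineConfig()
    scenario = ScenarioConfig(n_spores=n_cells, seed=seed)
    stack, truth = simulate_scene(scenario)
    labels = segment_stack(stack, SegParams())
    tracks, calls = _analyze_labels(labels, cfg)
    pairs = _match_calls(tracks, calls, truth)
    dividing = [(c, call) for c, call in pairs if c.division_frame is not None]
    hits = sum(
        1
        for c, call in dividing
        if call.division_frame is not None and abs(call.division_frame - c.division_frame) <= 1
    )
    return {
        "n_cells": len(pairs),
        "n_dividing": len(dividing),
        "hits_within_1": hits,
        "pct_within_1": 100.0 * hits / len(dividing) if dividing else float("nan"),
    }


def gating_fidelity(seed: int, n_spores: int = 60, n_debris: int = 40) -> dict:
    """Spore gate at t0 on rendered images at default noise: all circular
    spores pass (AR < 1.4), all elongated debris (drawn AR >= 1.5) fail."""
    cfg = PipelineConfig()
    scenario = ScenarioConfig(
        n_spores=n_spores,
        n_debris=n_debris,
        debris_area_range_um2=(4.0, 7.0),
        debris_ar_range=(1.5, 3.0),
        duration_min=300,
        seed=seed,
    )
    stack, truth = simulate_scene(scenario)
    labels = segment_stack(stack, SegParams())
    table = measure_all(labels)
    tracks = link_tracks(table, n_frames=labels.n_frames)
    from .phenotyping import gate_spores

    frame0 = [t for t in tracks if t.start_frame == 0]
    gated, rejected = gate_spores(frame0, cfg)

    def nearest_kind(track):
        first = track.measures.iloc[0]
        objs = [(c.center_x_um, c.center_y_um, "spore") for c in truth.cells]
        objs += [(d.center_x_um, d.center_y_um, "debris") for d in truth.debris]
        return min(
            objs,
            key=lambda o: (o[0] - first.centroid_x_um) ** 2 + (o[1] - first.centroid_y_um) ** 2,
        )[2]

    spores_gated = sum(1 for t in gated if nearest_kind(t) == "spore")
    debris_gated = len(gated) - spores_gated
    debris_rejected = sum(1 for t in rejected if nearest_kind(t) == "debris")
    return {
        "n_spores": n_spores,
        "n_debris": n_debris,
        "spores_gated_pct": 100.0 * spores_gated / n_spores,
        "debris_rejected_pct": 100.0 * debris_rejected / n_debris,
        "debris_gated": debris_gated,
    }


def efficiency_recovery(
    seed: int, n_runs: int = 20, n_spores: int = 300, viability: float = 0.7
) -> dict:
    """Germination efficiency of scenes with a known viable fraction; counts
    runs whose estimate falls inside the exact 95% binomial interval."""
    cfg = PipelineConfig()
    lo = sps.binom.ppf(0.025, n_spores, viability) / n_spores
    hi = sps.binom.ppf(0.975, n_spores, viability) / n_spores
    estimates = []
    hits = 0
    for i in range(n_runs):
        scenario = ScenarioConfig(
            n_spores=n_spores,
            phenotype_mix={"normal": viability, "dead": 1.0 - viability},
            duration_min=800,
            seed=seed + 1000 * (i + 1),
        )
        labels, truth = simulate_truth_masks(scenario)
        tracks, calls = _analyze_labels(labels, cfg)
        eff, _, _ = germination_efficiency(calls, labels.n_frames - 1)
        estimates.append(eff)
        if lo <= eff <= hi:
            hits += 1
    return {
        "n_runs": n_runs,
        "hits_in_ci": hits,
        "ci": (float(lo), float(hi)),
        "estimates": estimates,
        "mean_estimate": float(np.mean(estimates)),
    }


def phenotype_accuracy(seed: int, per_class: int = 50) -> dict:
    """Balanced five-class scene; per-class agreement with generator truth."""
    cfg = PipelineConfig()
    classes = ("normal", "elongated", "bubble", "bipolar", "exploded")
    scenario = ScenarioConfig(
        n_spores=per_class * len(classes),
        phenotype_mix={c: 1.0 / len(classes) for c in classes},
        seed=seed,
    )
    labels, truth = simulate_truth_masks(scenario)
    tracks, calls = _analyze_labels(labels, cfg)
    pairs = _match_calls(tracks, calls, truth)
    per = {c: [0, 0] for c in classes}
    for cell, call in pairs:
        per[cell.phenotype][1] += 1
        if call.phenotype == cell.phenotype:
            per[cell.phenotype][0] += 1
    acc = {c: 100.0 * ok / n if n else float("nan") for c, (ok, n) in per.items()}
    return {
        "per_class_pct": acc,
        "min_class_pct": min(acc.values()),
        "overall_pct": 100.0
        * sum(ok for ok, _ in per.values())
        / max(sum(n for _, n in per.values()), 1),
    }


def bipolar_priority_ok(config: PipelineConfig | None = None) -> bool:
    """Constructed cells protruding >6 um from BOTH poles (satisfying the
    elongated rule) must always be scored bipolar."""
    from .io import LabelStack
    from .phenotyping import classify_outgrowth

    cfg = config or PipelineConfig()
    psz = cfg.pixel_size_um
    for angle in (0.0, 0.5, 1.1, 2.4):
        h = w = 240
        yy, xx = np.mgrid[:h, :w]
        c, s = np.cos(angle), np.sin(angle)
        xr = c * (xx - w / 2) + s * (yy - h / 2)
        yr = -s * (xx - w / 2) + c * (yy - h / 2)
        disc = np.hypot(xr, yr) <= 1.55 / psz
        frames = np.zeros((4, h, w), dtype=np.int32)
        frames[0][disc] = 1
        for k, half in enumerate((4.0, 6.5, 9.0), start=1):
            rod = (np.abs(xr) <= half / psz) & (np.abs(yr) <= 0.9 / psz)
            frames[k][disc | rod] = 1
        labels = LabelStack(frames, psz, 10.0)
        tracks = link_tracks(measure_all(labels), n_frames=4)
        track = [t for t in tracks if t.start_frame == 0][0]
        phenotype, length, _ = classify_outgrowth(track, labels, cfg)
        if phenotype != "bipolar" or length <= cfg.elongated_cutoff_um:
            return False
    return True


def morphometrics_oracles() -> dict:
    """Rasterized-shape oracles for the moment-ellipse fit."""

    def ellipse_mask(a, b, angle=0.0, pad=8):
        size = int(2 * max(a, b)) + 2 * pad
        yy, xx = np.mgrid[:size, :size]
        x, y = xx - size / 2, yy - size / 2
        c, s = np.cos(angle), np.sin(angle)
        return ((c * x + s * y) / a) ** 2 + ((-s * x + c * y) / b) ** 2 <= 1.0

    disc = fit_region_ellipse(ellipse_mask(20, 20), pixel_size_um=0.2)
    ell = fit_region_ellipse(ellipse_mask(30, 10), pixel_size_um=0.2)
    rot = fit_region_ellipse(ellipse_mask(30, 10, np.pi / 3), pixel_size_um=0.2)
    return {
        "disc_area_um2": disc.area_um2,
        "disc_area_expected_um2": float(np.pi * (20 * 0.2) ** 2),
        "disc_ar": disc.aspect_ratio,
        "ellipse_30x10_ar": ell.aspect_ratio,
        "rotation_ar_change_pct": 100.0 * abs(rot.aspect_ratio - ell.aspect_ratio) / ell.aspect_ratio,
    }


def vacuole_recovery(seed: int, n_cells: int = 100) -> dict:
    """Recovery of drawn body fractions (uniform 0.3-0.9) from the rendered
    two-channel scene at default noise."""
    cfg = PipelineConfig()
    scenario = ScenarioConfig(
        n_spores=n_cells,
        phenotype_mix={"normal": 1.0},
        vacuole_mode="two_channel",
        vacuole_body_fraction=(0.3, 0.9),
        seed=seed,
    )
    stack, truth, labels = simulate_scene(scenario, return_labels=True)
    tracks, calls = _analyze_labels(labels, cfg)
    parts = measure_vacuole_partitions(stack, labels, tracks, calls, cfg, channel=1)
    by_id = {t.track_id: t for t in tracks}
    errors = []
    conservation_exact = True
    for _, row in parts.iterrows():
        first = by_id[int(row.track_id)].measures.iloc[0]
        cell = min(
            truth.cells,
            key=lambda c: (c.center_x_um - first.centroid_x_um) ** 2
            + (c.center_y_um - first.centroid_y_um) ** 2,
        )
        errors.append(abs(row.fraction_in_body - cell.vacuole_body_fraction))
        if row.fraction_in_body + row.fraction_in_outgrowth != 1.0:
            conservation_exact = False
    return {
        "n_measured": len(parts),
        "mae": float(np.mean(errors)) if errors else float("nan"),
        "max_error": float(np.max(errors)) if errors else float("nan"),
        "conservation_exact": conservation_exact,
    }


def fisher_enumeration_sweep(max_margin: int = 30) -> float:
    """Max |p - oracle| over every 2x2 table with all margins <= max_margin,
    with the oracle an independent math.comb hypergeometric enumeration."""
    worst = 0.0
    for r1 in range(1, max_margin + 1):
        for r2 in range(1, max_margin + 1):
            n = r1 + r2
            for c1 in range(1, min(n, max_margin + 1)):
                if not 1 <= n - c1 <= max_margin:
                    continue
                lo, hi = max(0, c1 - r2), min(r1, c1)
                denom = math.comb(n, c1)
                pmf = [
                    math.comb(r1, a) * math.comb(r2, c1 - a) / denom
                    for a in range(lo, hi + 1)
                ]
                for a in range(lo, hi + 1):
                    oracle = min(
                        sum(q for q in pmf if q <= pmf[a - lo] * (1 + 1e-12)), 1.0
                    )
                    p = fisher_exact(
                        [[a, r1 - a], [c1 - a, r2 - (c1 - a)]]
                    ).p_value
                    worst = max(worst, abs(p - oracle))
    return worst


def stats_oracles() -> dict:
    """Exact oracles for the statistical layer."""
    from .stats import CFUSeries, anova_oneway, auc

    fisher_dev = fisher_enumeration_sweep(30)
    rng = np.random.default_rng(123)
    a = rng.normal(400, 40, 30)
    b = rng.normal(430, 40, 25)
    f_stat = anova_oneway([a, b]).statistic
    t_stat = sps.ttest_ind(a, b).statistic
    series = CFUSeries("c", 0, np.array([0.0, 10.0, 20.0]), np.array([200.0, 100.0, 50.0]))
    return {
        "fisher_sweep_max_abs_dp": fisher_dev,
        "f_vs_t2_rel_err": abs(f_stat - t_stat**2) / t_stat**2,
        "auc_example": auc(normalize_cfu(series)),
    }


def longevity_power(seed: int, n_power: int = 200, n_null: int = 1000) -> dict:
    """Power of the AUC t test for 10- vs 80-day half-lives, and its size
    under identical decay models, at alpha = 0.01."""
    days = list(range(0, 81, 10))

    def one(seed_a, seed_b, h2):
        ga = [
            normalize_cfu(s)
            for s in simulate_cfu_experiment(
                DecayModel(half_life_days=10.0, replicate_noise_sd=0.05), days, 3, seed_a
            )
        ]
        gb = [
            normalize_cfu(s)
            for s in simulate_cfu_experiment(
                DecayModel(half_life_days=h2, replicate_noise_sd=0.05), days, 3, seed_b
            )
        ]
        return compare_survival_auc(ga, gb).p_value < 0.01

    power = sum(one(seed + 2 * i, seed + 2 * i + 1, 80.0) for i in range(n_power))
    null = sum(
        one(seed + 100_000 + 2 * i, seed + 100_000 + 2 * i + 1, 10.0)
        for i in range(n_null)
    )
    return {
        "power_pct": 100.0 * power / n_power,
        "null_rejection_pct": 100.0 * null / n_null,
        "n_power": n_power,
        "n_null": n_null,
    }


def focus_loss_check(seed: int) -> dict:
    """Inject 6 (then 5) defocused frames; the exclusion rule is strict
    'more than 5 timepoints'."""
    cfg = PipelineConfig()
    six = (5, 6, 7, 20, 21, 22)
    stack6, _ = simulate_scene(
        ScenarioConfig(n_spores=10, duration_min=500, focus_loss_frames=six, seed=seed)
    )
    rep6 = detect_focus_loss(stack6, cfg)
    stack5, _ = simulate_scene(
        ScenarioConfig(n_spores=10, duration_min=500, focus_loss_frames=six[:5], seed=seed)
    )
    rep5 = detect_focus_loss(stack5, cfg)
    return {
        "flagged_with_six": len(rep6.flagged_frames),
        "all_six_found": set(six).issubset(rep6.flagged_frames),
        "excluded_with_six": bool(rep6.excluded),
        "flagged_with_five": len(rep5.flagged_frames),
        "excluded_with_five": bool(rep5.excluded),
    }


def cli_determinism(workdir: str | Path, seed: int) -> dict:
    """Run every CLI subcommand twice with identical arguments and compare
    the bytes of all CSV/JSON outputs."""
    import json
    import shutil

    from click.testing import CliRunner

    from .cli import main as cli_main

    workdir = Path(workdir)
    runner = CliRunner()

    def run_all(root: Path) -> dict:
        root.mkdir(parents=True, exist_ok=True)
        scen = root / "scenario.yaml"
        scen.write_text(
            "n_spores: 8\nduration_min: 400\nvacuole_mode: two_channel\n"
            "cfu:\n  model: {half_life_days: 10.0, replicate_noise_sd: 0.05}\n"
            "  times_days: [0, 10, 20, 40]\n  n_reps: 3\n"
        )
        steps = [
            ["simulate", "--scenario", str(scen), "--seed", str(seed), "--out", str(root / "sim")],
            ["segment", "--in", str(root / "sim/stack.tif"), "--out", str(root / "masks.tif")],
            ["track", "--masks", str(root / "masks.tif"), "--out", str(root / "tracks.csv")],
            [
                "phenotype",
                "--tracks", str(root / "tracks.csv"),
                "--masks", str(root / "masks.tif"),
                "--out", str(root / "calls.csv"),
            ],
            [
                "vacuole",
                "--stack", str(root / "sim/stack.tif"),
                "--masks", str(root / "masks.tif"),
                "--tracks", str(root / "tracks.csv"),
                "--out", str(root / "vacuole.csv"),
            ],
            ["stats", "--test", "cfu", "--in", str(root / "sim/cfu.csv"), "--out", str(root / "cfu_stats.json")],
        ]
        fisher_in = root / "fisher.json"
        fisher_in.write_text(json.dumps({"table": [[40, 12], [25, 30]]}))
        steps.append(
            ["stats", "--test", "fisher", "--in", str(fisher_in), "--out", str(root / "fisher_out.json")]
        )
        for args in steps:
            result = runner.invoke(cli_main, args, catch_exceptions=False)
            assert result.exit_code == 0, f"{args}: {result.output}"
        return {
            str(p.relative_to(root)): p.read_bytes()
            for p in sorted(root.rglob("*"))
            if p.suffix in (".csv", ".json")
        }

    root = workdir / "determinism"
    first = run_all(root)
    shutil.rmtree(root)
    second = run_all(root)
    identical = set(first) == set(second) and all(first[k] == second[k] for k in first)
    return {"n_outputs": len(first), "byte_identical": identical}
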