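"""Synthetic germination timelapses with complete ground truth.

The generator emulates the cytology the analysis assumes: circular dormant
spores (~7-9 μm² true area) sit motionless under agar, break dormancy after
a gamma-distributed lag, swell isotropically, then extend a polarized germ
tube until the moments-ellipse aspect ratio crosses the division threshold,
at which point the object splits into two touching-then-separating
components.  Five aberrant outcomes are modelled alongside normal
germination: elongated (cell-cycle defect; the split only happens at a
drawn outgrowth length >6 μm), bubble (divides while still circular),
bipolar (tubes from both poles), exploded (fragments and vanishes during
germination) and dead (never changes).  Scenes may also contain debris
blobs, injected focus-loss frames, and a second fluorescence channel whose
signal is partitioned between spore body and outgrowth with a configurable
body fraction (vacuole-dye emulation).

All kinematic ground truth (division frames, outgrowth lengths) is computed
from the closed-form shape model in :mod:`germquant.geometry`, never from
the pixel renderer.

Default geometry: spore radius 1.55 ± 0.1 μm (area ≈ 7.6 μm²), swelling
gain +25% over 60 min, tube width 1.766 μm.  The last two are calibrated
jointly so that the analytic aspect ratio of the mean cell crosses 3.0 at
an outgrowth of ≈4.45 μm, reproducing the observed coincidence of ~4.5 μm
outgrowths and AR ≈ 3 at the first division.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import SporeShape, shape_moments, solve_outgrowth_for_ar
from .io import ImageStack, LabelStack
from .stats import CFUSeries

__all__ = [
    "PHENOTYPES",
    "ScenarioConfig",
    "CellTruth",
    "DebrisTruth",
    "SceneGroundTruth",
    "DecayModel",
    "simulate_scene",
    "simulate_truth_masks",
    "simulate_vacuole_channel",
    "simulate_cfu_experiment",
]

PHENOTYPES = ("normal", "elongated", "bubble", "bipolar", "exploded", "dead")

# Intensity rendering constants (uint16 scale).
_BG = 1000.0
_AMP = 3000.0
_CH2_BG = 100.0
_CH2_TOTAL = 60000.0  # integrated channel-2 signal per cell


@dataclass
class ScenarioConfig:
    """Scene description; defaults are the standard study conditions."""

    n_spores: int = 50
    phenotype_mix: dict = field(
        default_factory=lambda: {
            "normal": 0.55,
            "elongated": 0.12,
            "bubble": 0.08,
            "bipolar": 0.10,
            "exploded": 0.05,
            "dead": 0.10,
        }
    )
    spore_radius_um: float = 1.55
    spore_radius_sd_um: float = 0.1
    lag_mean_min: float = 240.0
    lag_shape: float = 16.0  # gamma shape; sd = mean / sqrt(shape)
    swell_duration_min: float = 60.0
    swell_area_gain: float = 0.25
    tube_width_um: float = 1.766
    tube_speed_um_per_frame: float = 0.2
    normal_outgrowth_at_division_um: float = 4.5  # expected value, see module docstring
    elongated_outgrowth_range_um: tuple = (6.5, 20.0)
    division_ar: float = 3.0
    split_delay_frames: int = 2
    septum_gap_px: float = 2.0
    bubble_area_growth_per_frame: float = 0.02
    bubble_split_area_factor: float = 1.6
    explode_outgrowth_range_um: tuple = (0.5, 2.5)
    explode_fragment_frames: int = 2
    n_debris: int = 0
    debris_area_range_um2: tuple = (0.8, 2.0)
    debris_ar_range: tuple = (1.5, 3.0)
    noise_sd: float = 100.0
    blur_sigma_px: float = 0.7
    focus_loss_frames: tuple = ()
    focus_blur_sigma_px: float = 8.0
    vacuole_mode: str = "off"  # "off" | "two_channel"
    vacuole_body_fraction: object = 0.64  # float or (lo, hi) for a per-cell draw
    vacuole_noise_sd: float = 30.0
    duration_min: float = 1000.0
    frame_interval_min: float = 10.0
    pixel_size_um: float = 0.18
    packing_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.phenotype_mix.get(p, 0.0) for p in PHENOTYPES)
        unknown = set(self.phenotype_mix) - set(PHENOTYPES)
        if unknown:
            raise ValueError(f"unknown phenotype(s) in mix: {sorted(unknown)}")
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"phenotype_mix must sum to 1, got {total}")
        for name in (
            "spore_radius_um",
            "lag_mean_min",
            "swell_duration_min",
            "tube_width_um",
            "tube_speed_um_per_frame",
            "duration_min",
            "frame_interval_min",
            "pixel_size_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.elongated_outgrowth_range_um[0] <= 6.0:
            raise ValueError("elongated outgrowth range must start above the 6 um cutoff")
        if self.vacuole_mode not in ("off", "two_channel"):
            raise ValueError("vacuole_mode must be 'off' or 'two_channel'")

    @property
    def n_frames(self) -> int:
        return int(self.duration_min // self.frame_interval_min) + 1


@dataclass
class CellTruth:
    """Per-cell ground truth plus the closed-form kinematic parameters."""

    cell_id: int
    label: int
    phenotype: str
    center_x_um: float
    center_y_um: float
    axis_x: float
    axis_y: float
    radius_um: float  # dormant (t0) radius
    swollen_radius_um: float
    tube_radius_um: float
    lag_min: float
    outgrowth_start_min: float
    tube_speed_um_per_min: float
    division_frame: int | None = None  # first frame with analytic AR > threshold
    split_frame: int | None = None  # frame from which the rendered object is split
    explode_frame: int | None = None
    outgrowth_at_division_um: float | None = None
    outgrowth_at_split_um: float | None = None
    vacuole_body_fraction: float | None = None
    child_labels: tuple | None = None
    fragment_labels: tuple = ()
    # internal rendering state
    _frag_geom: tuple = ()
    _split_cut_x: float = 0.0
    _elong_target_um: float | None = None
    _bubble_split_factor: float | None = None

    # ---- closed-form kinematics -------------------------------------------------
    def body_radius_at(self, t_min: float) -> float:
        if self.phenotype == "dead":
            return self.radius_um
        if t_min <= self.lag_min:
            return self.radius_um
        r0, rs = self.radius_um, self.swollen_radius_um
        dur = self.outgrowth_start_min - self.lag_min
        if t_min < self.outgrowth_start_min:
            frac = (t_min - self.lag_min) / dur
            return r0 * math.sqrt(1.0 + frac * ((rs / r0) ** 2 - 1.0))
        if self.phenotype == "bubble":
            per_min = (self._bubble_split_factor_rate or 0.0)
            grown = 1.0 + per_min * (t_min - self.outgrowth_start_min)
            cap = self._bubble_split_factor or 1.0
            return rs * math.sqrt(min(grown, cap))
        return rs

    @property
    def _bubble_split_factor_rate(self) -> float | None:
        return getattr(self, "_bubble_rate_per_min", None)

    def outgrowth_at(self, t_min: float) -> float:
        """Analytic germ-tube protrusion length at time t (per pole)."""
        if self.phenotype in ("dead", "bubble"):
            return 0.0
        length = max(0.0, (t_min - self.outgrowth_start_min) * self.tube_speed_um_per_min)
        if self._elong_target_um is not None:
            length = min(length, self._elong_target_um)
        elif self.outgrowth_at_split_um is not None:
            length = min(length, self.outgrowth_at_split_um)
        return length

    def shape_at(self, t_min: float) -> SporeShape | None:
        """Closed-form unsplit shape at time t (None once exploded away)."""
        if self.phenotype == "dead":
            return SporeShape(self.radius_um)
        rb = self.body_radius_at(t_min)
        length = self.outgrowth_at(t_min)
        if length <= 0:
            return SporeShape(rb)
        rt = min(self.tube_radius_um, rb * 0.999)
        if self.phenotype == "bipolar":
            return SporeShape(rb, rt, tube_plus=length, tube_minus=length)
        return SporeShape(rb, rt, tube_plus=length)


@dataclass
class DebrisTruth:
    debris_id: int
    label: int
    center_x_um: float
    center_y_um: float
    axis_x: float
    axis_y: float
    area_um2: float
    aspect_ratio: float
    body_radius_um: float
    rod_length_um: float


@dataclass
class SceneGroundTruth:
    """Everything the generator knows about a scene."""

    cells: list
    debris: list
    focus_loss_frames: tuple
    n_frames: int
    field_shape: tuple
    pixel_size_um: float
    frame_interval_min: float
    seed: int

    def cell_by_label(self, label: int) -> CellTruth | None:
        for c in self.cells:
            if c.label == label:
                return c
        return None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_frames": self.n_frames,
            "field_shape": list(self.field_shape),
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_min": self.frame_interval_min,
            "seed": self.seed,
            "focus_loss_frames": list(self.focus_loss_frames),
            "cells": [
                {k: v for k, v in asdict(c).items() if not k.startswith("_")}
                for c in self.cells
            ],
            "debris": [asdict(d) for d in self.debris],
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------


def _draw_cells(scenario: ScenarioConfig, rng: np.random.Generator) -> list[CellTruth]:
    """Draw all per-cell parameters from one stream, in cell-ID order."""
    mix_names = [p for p in PHENOTYPES if scenario.phenotype_mix.get(p, 0.0) > 0]
    mix_probs = np.array([scenario.phenotype_mix[p] for p in mix_names], dtype=float)
    mix_probs /= mix_probs.sum()
    dt = scenario.frame_interval_min
    v = scenario.tube_speed_um_per_frame / dt  # μm per minute
    n_frames = scenario.n_frames
    gain = scenario.swell_area_gain
    rt_nom = scenario.tube_width_um / 2.0
    cells: list[CellTruth] = []
    for cid in range(scenario.n_spores):
        phenotype = mix_names[int(rng.choice(len(mix_names), p=mix_probs))]
        r0 = float(
            np.clip(
                rng.normal(scenario.spore_radius_um, scenario.spore_radius_sd_um),
                scenario.spore_radius_um - 3 * scenario.spore_radius_sd_um,
                scenario.spore_radius_um + 3 * scenario.spore_radius_sd_um,
            )
        )
        r0 = max(r0, 0.8)
        lag = float(
            rng.gamma(scenario.lag_shape, scenario.lag_mean_min / scenario.lag_shape)
        )
        theta = float(rng.uniform(0, 2 * np.pi))
        rs = r0 * math.sqrt(1.0 + gain)
        rt = min(rt_nom, rs * 0.999)
        t_out = lag + scenario.swell_duration_min
        cell = CellTruth(
            cell_id=cid,
            label=cid + 1,
            phenotype=phenotype,
            center_x_um=0.0,
            center_y_um=0.0,
            axis_x=math.cos(theta),
            axis_y=math.sin(theta),
            radius_um=r0,
            swollen_radius_um=rs,
            tube_radius_um=rt,
            lag_min=lag,
            outgrowth_start_min=t_out,
            tube_speed_um_per_min=v,
        )
        if phenotype == "elongated":
            cell._elong_target_um = float(rng.uniform(*scenario.elongated_outgrowth_range_um))
        elif phenotype == "exploded":
            target = float(rng.uniform(*scenario.explode_outgrowth_range_um))
            cell._elong_target_um = None
            cell.outgrowth_at_split_um = None
            cell.explode_frame = None
            cell._explode_target_um = target  # type: ignore[attr-defined]
            n_frag = int(rng.integers(3, 6))
            frags = []
            for _ in range(n_frag):
                fr = float(rng.uniform(0.35, 0.6))
                ang = float(rng.uniform(0, 2 * np.pi))
                dist = float(rng.uniform(0.5, 1.8))
                frags.append((dist * math.cos(ang), dist * math.sin(ang), fr))
            cell._frag_geom = tuple(frags)
        elif phenotype == "bubble":
            cell._bubble_split_factor = scenario.bubble_split_area_factor
            cell._bubble_rate_per_min = scenario.bubble_area_growth_per_frame / dt  # type: ignore[attr-defined]
        if scenario.vacuole_mode == "two_channel":
            vbf = scenario.vacuole_body_fraction
            if isinstance(vbf, (tuple, list)):
                cell.vacuole_body_fraction = float(rng.uniform(vbf[0], vbf[1]))
            else:
                cell.vacuole_body_fraction = float(vbf)
        _schedule_events(cell, scenario)
        cells.append(cell)
    return cells


def _schedule_events(cell: CellTruth, scenario: ScenarioConfig) -> None:
    """Fill division/split/explosion frames from the closed-form kinematics."""
    dt = scenario.frame_interval_min
    n_frames = scenario.n_frames
    v = cell.tube_speed_um_per_min
    t_out = cell.outgrowth_start_min

    def frame_when_length(length: float, strict: bool) -> int | None:
        t = t_out + length / v
        k = int(math.floor(t / dt)) + 1 if strict else int(math.ceil(t / dt))
        return k if k < n_frames else None

    if cell.phenotype == "dead":
        return
    if cell.phenotype == "bubble":
        rate = cell._bubble_rate_per_min  # type: ignore[attr-defined]
        t_split = t_out + (cell._bubble_split_factor - 1.0) / rate
        k = int(math.ceil(t_split / dt))
        if k < n_frames - 1:
            cell.division_frame = k
            cell.split_frame = k
            cell.outgrowth_at_split_um = 0.0
        return
    if cell.phenotype == "exploded":
        target = cell._explode_target_um  # type: ignore[attr-defined]
        k = frame_when_length(target, strict=False)
        if k is not None:
            cell.explode_frame = k
        return
    # normal / elongated / bipolar: division when analytic AR crosses threshold
    bipolar = cell.phenotype == "bipolar"
    try:
        l_star = solve_outgrowth_for_ar(
            cell.swollen_radius_um,
            min(cell.tube_radius_um, cell.swollen_radius_um * 0.999),
            scenario.division_ar,
            bipolar=bipolar,
        )
    except ValueError:  # pragma: no cover - defensive; defaults always cross
        return
    k_div = frame_when_length(l_star, strict=True)
    if k_div is None:
        return
    cell.division_frame = k_div
    cell.outgrowth_at_division_um = v * (k_div * dt - t_out)
    if cell.phenotype == "elongated":
        k_split = frame_when_length(cell._elong_target_um, strict=False)
    else:
        k_split = k_div + scenario.split_delay_frames
        k_split = k_split if k_split < n_frames - 1 else None
    if k_split is not None:
        cell.split_frame = k_split
        cell.outgrowth_at_split_um = min(
            v * (k_split * dt - t_out),
            cell._elong_target_um or np.inf,
        )
        shape = cell.shape_at(k_split * dt)
        _, cx, _, _ = shape_moments(shape)
        cell._split_cut_x = cx


def _draw_debris(
    scenario: ScenarioConfig, rng: np.random.Generator, next_label: int
) -> list[DebrisTruth]:
    """Static elongated debris blobs (capsules); AR drawn, then scaled to the
    drawn area (aspect ratio is scale invariant)."""
    debris = []
    for i in range(scenario.n_debris):
        target_ar = float(rng.uniform(*scenario.debris_ar_range))
        target_area = float(rng.uniform(*scenario.debris_area_range_um2))
        theta = float(rng.uniform(0, 2 * np.pi))
        # unit capsule: body radius 1, rod length solved for the AR
        rod = solve_outgrowth_for_ar(1.0, 1.0, target_ar, l_max=200.0)
        unit = SporeShape(1.0, 1.0, tube_plus=rod)
        area_unit, _, _, _ = shape_moments(unit)
        s = math.sqrt(target_area / area_unit)
        debris.append(
            DebrisTruth(
                debris_id=i,
                label=next_label + i,
                center_x_um=0.0,
                center_y_um=0.0,
                axis_x=math.cos(theta),
                axis_y=math.sin(theta),
                area_um2=target_area,
                aspect_ratio=target_ar,
                body_radius_um=s,
                rod_length_um=rod * s,
            )
        )
    return debris


def _object_extent_um(cell: CellTruth, scenario: ScenarioConfig) -> float:
    """Maximal radial extent from the object centre over the whole movie."""
    dt = scenario.frame_interval_min
    t_end = (scenario.n_frames - 1) * dt
    if cell.phenotype == "dead":
        return cell.radius_um
    if cell.phenotype == "bubble":
        return cell.swollen_radius_um * math.sqrt(cell._bubble_split_factor or 1.0)
    if cell.phenotype == "exploded":
        reach = max((math.hypot(ox, oy) + r for ox, oy, r in cell._frag_geom), default=0.0)
        return max(
            cell.swollen_radius_um + (cell._explode_target_um or 0.0),  # type: ignore[attr-defined]
            reach,
        )
    length = cell.outgrowth_at(t_end)
    if cell.split_frame is not None:
        length = max(length, cell.outgrowth_at_split_um or 0.0)
    return cell.swollen_radius_um + length + 0.5


def _place_objects(
    scenario: ScenarioConfig,
    cells: list[CellTruth],
    debris: list[DebrisTruth],
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Rejection-sample non-overlapping positions; returns field (H, W) px."""
    extents = [_object_extent_um(c, scenario) for c in cells]
    extents += [d.body_radius_um + d.rod_length_um for d in debris]
    margin = 0.8
    area = sum(math.pi * (r + 0.5) ** 2 for r in extents)
    side = max(math.sqrt(area / scenario.packing_fraction), 40.0)
    side = max(side, 2 * (max(extents, default=5.0) + 2.0) + 4.0)
    placed_x: list[float] = []
    placed_y: list[float] = []
    placed_r: list[float] = []
    objs = list(cells) + list(debris)
    # place the largest objects first: rejection sampling then jams far later
    order = sorted(range(len(objs)), key=lambda i: -extents[i])
    for i in order:
        obj, r = objs[i], extents[i]
        px = np.asarray(placed_x)
        py = np.asarray(placed_y)
        pr = np.asarray(placed_r)
        ok = False
        for _ in range(20000):
            x = float(rng.uniform(r + 1.0, side - r - 1.0))
            y = float(rng.uniform(r + 1.0, side - r - 1.0))
            if px.size == 0 or np.all(
                np.hypot(x - px, y - py) > r + pr + margin
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not place objects without overlap; scene too dense"
            )
        obj.center_x_um = x
        obj.center_y_um = y
        placed_x.append(x)
        placed_y.append(y)
        placed_r.append(r)
    n_px = int(math.ceil(side / scenario.pixel_size_um))
    return n_px, n_px


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _cell_render_state(cell: CellTruth, frame: int, scenario: ScenarioConfig):
    """Return a hashable state key and geometry for one frame."""
    dt = scenario.frame_interval_min
    t = frame * dt
    if cell.phenotype == "exploded" and cell.explode_frame is not None:
        if frame >= cell.explode_frame + scenario.explode_fragment_frames:
            return ("gone",), None
        if frame >= cell.explode_frame:
            return ("frags",), ("frags", cell._frag_geom)
    if cell.split_frame is not None and frame >= cell.split_frame:
        since = frame - cell.split_frame
        gap_half = 0.5 * scenario.septum_gap_px * scenario.pixel_size_um + min(
            0.05 * since, 0.4
        )
        shape = cell.shape_at(cell.split_frame * dt)
        key = ("split", round(gap_half, 4))
        return key, ("split", shape, cell._split_cut_x, gap_half)
    shape = cell.shape_at(t)
    key = (
        "shape",
        round(shape.body_radius, 4),
        round(shape.tube_plus, 4),
        round(shape.tube_minus, 4),
    )
    return key, ("shape", shape)


def _patch_for(
    geom,
    center: tuple[float, float],
    axis: tuple[float, float],
    psz: float,
    shape_px: tuple[int, int],
):
    """Rasterize one object near its centre.

    Returns (row_slice, col_slice, signed_distance, axial_coord,
    perp_coord) arrays, or None when the object is empty/outside.
    """
    kind = geom[0]
    if kind == "frags":
        frags = geom[1]
        ext = max(math.hypot(ox, oy) + r for ox, oy, r in frags)
        x_lo = y_lo = -ext
        x_hi = y_hi = ext
    else:
        shape = geom[1]
        x_lo, x_hi = shape.x_min, shape.x_max
        y_hi = shape.body_radius
        y_lo = -y_hi
    ux, uy = axis
    cx, cy = center
    corners_x, corners_y = [], []
    for ax in (x_lo, x_hi):
        for ay in (y_lo, y_hi):
            corners_x.append(cx + ax * ux - ay * uy)
            corners_y.append(cy + ax * uy + ay * ux)
    m = 3 * psz
    c0 = max(int((min(corners_x) - m) / psz), 0)
    c1 = min(int((max(corners_x) + m) / psz) + 1, shape_px[1])
    r0 = max(int((min(corners_y) - m) / psz), 0)
    r1 = min(int((max(corners_y) + m) / psz) + 1, shape_px[0])
    if c1 <= c0 or r1 <= r0:
        return None
    xs = (np.arange(c0, c1, dtype=np.float32) + 0.5) * psz - cx
    ys = (np.arange(r0, r1, dtype=np.float32) + 0.5) * psz - cy
    dx, dy = np.meshgrid(xs, ys)
    a = dx * ux + dy * uy  # axial coordinate
    b = -dx * uy + dy * ux
    if kind == "frags":
        d = np.full(a.shape, np.inf, dtype=np.float32)
        for ox, oy, r in geom[1]:
            d = np.minimum(d, np.hypot(a - ox, b - oy) - r)
    else:
        d = geom[1].signed_distance(a, b).astype(np.float32)
        if kind == "split":
            _, _, cut_x, gap_half = geom
            d = np.maximum(d, gap_half - np.abs(a - cut_x))
    return slice(r0, r1), slice(c0, c1), d, a, b


def _simulate(scenario: ScenarioConfig, render_intensity: bool):
    ss = np.random.SeedSequence([int(scenario.seed) & 0x7FFFFFFF, 917])
    rng_cells, rng_place, rng_noise, rng_ch2 = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    cells = _draw_cells(scenario, rng_cells)
    debris = _draw_debris(scenario, rng_cells, next_label=scenario.n_spores + 1)
    H, W = _place_objects(scenario, cells, debris, rng_place)
    n_frames = scenario.n_frames
    psz = scenario.pixel_size_um

    # allocate split/fragment labels deterministically
    next_label = scenario.n_spores + scenario.n_debris + 1
    for cell in cells:
        if cell.split_frame is not None:
            cell.child_labels = (next_label, next_label + 1)
            next_label += 2
        if cell.phenotype == "exploded" and cell.explode_frame is not None:
            cell.fragment_labels = tuple(
                range(next_label, next_label + len(cell._frag_geom))
            )
            next_label += len(cell._frag_geom)

    labels = np.zeros((n_frames, H, W), dtype=np.uint16)
    images = (
        np.zeros((n_frames, H, W), dtype=np.uint16) if render_intensity else None
    )
    cache: dict[int, tuple] = {}
    for frame in range(n_frames):
        lab = labels[frame]
        cov = np.zeros((H, W), dtype=np.float32) if render_intensity else None
        for cell in cells:
            key, geom = _cell_render_state(cell, frame, scenario)
            if key[0] == "gone":
                continue
            cached = cache.get(cell.cell_id)
            if cached is None or cached[0] != key:
                patch = _patch_for(
                    geom,
                    (cell.center_x_um, cell.center_y_um),
                    (cell.axis_x, cell.axis_y),
                    psz,
                    (H, W),
                )
                cached = (key, geom, patch)
                cache[cell.cell_id] = cached
            _, geom, patch = cached
            if patch is None:
                continue
            rsl, csl, d, a, b = patch
            inside = d < 0
            if geom[0] == "split":
                cut_x = geom[2]
                la, lb = cell.child_labels
                lab[rsl, csl][inside & (a <= cut_x)] = la
                lab[rsl, csl][inside & (a > cut_x)] = lb
            elif geom[0] == "frags":
                for j, (ox, oy, r) in enumerate(cell._frag_geom):
                    lab[rsl, csl][np.hypot(a - ox, b - oy) - r < 0] = (
                        cell.fragment_labels[j]
                    )
            else:
                lab[rsl, csl][inside] = cell.label
            if cov is not None:
                np.maximum(
                    cov[rsl, csl],
                    np.clip(0.5 - d / psz, 0.0, 1.0),
                    out=cov[rsl, csl],
                )
        for deb in debris:
            cached = cache.get(-1 - deb.debris_id)
            if cached is None:
                shape = SporeShape(
                    deb.body_radius_um, deb.body_radius_um, tube_plus=deb.rod_length_um
                )
                patch = _patch_for(
                    ("shape", shape),
                    (deb.center_x_um, deb.center_y_um),
                    (deb.axis_x, deb.axis_y),
                    psz,
                    (H, W),
                )
                cached = (("static",), ("shape", shape), patch)
                cache[-1 - deb.debris_id] = cached
            _, _, patch = cached
            if patch is None:
                continue
            rsl, csl, d, a, b = patch
            lab[rsl, csl][d < 0] = deb.label
            if cov is not None:
                np.maximum(
                    cov[rsl, csl],
                    np.clip(0.5 - d / psz, 0.0, 1.0),
                    out=cov[rsl, csl],
                )
        if render_intensity:
            img = _AMP * cov
            sigma = (
                scenario.focus_blur_sigma_px
                if frame in set(scenario.focus_loss_frames)
                else scenario.blur_sigma_px
            )
            if sigma > 0:
                img = gaussian_filter(img, sigma)
            img += _BG
            if scenario.noise_sd > 0:
                img += rng_noise.normal(0.0, scenario.noise_sd, size=img.shape)
            images[frame] = np.clip(img, 0, 65535).astype(np.uint16)

    truth = SceneGroundTruth(
        cells=cells,
        debris=debris,
        focus_loss_frames=tuple(scenario.focus_loss_frames),
        n_frames=n_frames,
        field_shape=(H, W),
        pixel_size_um=psz,
        frame_interval_min=scenario.frame_interval_min,
        seed=scenario.seed,
    )
    label_stack = LabelStack(labels, psz, scenario.frame_interval_min)

    if scenario.vacuole_mode == "two_channel":
        ch2 = simulate_vacuole_channel(
            truth, label_stack, noise_sd=scenario.vacuole_noise_sd, rng=rng_ch2,
            blur_sigma_px=scenario.blur_sigma_px if render_intensity else 0.0,
        )
        if render_intensity:
            frames = np.stack([images, ch2], axis=1)
            stack = ImageStack(
                frames, psz, scenario.frame_interval_min, ["transmitted", "vacuole"]
            )
        else:
            stack = ImageStack(
                np.stack([np.zeros_like(ch2), ch2], axis=1),
                psz,
                scenario.frame_interval_min,
                ["transmitted", "vacuole"],
            )
    else:
        if render_intensity:
            stack = ImageStack(images, psz, scenario.frame_interval_min)
        else:
            stack = ImageStack(
                np.zeros((1, 1, 1), dtype=np.uint16), psz, scenario.frame_interval_min
            )
    return stack, truth, label_stack


def simulate_scene(
    scenario: ScenarioConfig, *, return_labels: bool = False
):
    """Render a full synthetic timelapse.

    Returns ``(ImageStack, SceneGroundTruth)``, or with ``return_labels=True``
    additionally the generator's own per-frame label masks
    ``(ImageStack, SceneGroundTruth, LabelStack)``.  Deterministic given
    ``scenario.seed``.
    """
    stack, truth, labels = _simulate(scenario, render_intensity=True)
    if return_labels:
        return stack, truth, labels
    return stack, truth


def simulate_truth_masks(scenario: ScenarioConfig):
    """Like :func:`simulate_scene` but skips intensity rendering; returns
    ``(LabelStack, SceneGroundTruth)``.  Useful when the analysis is driven
    from externally supplied masks."""
    _, truth, labels = _simulate(scenario, render_intensity=False)
    return labels, truth


# ---------------------------------------------------------------------------
# vacuole channel
# ---------------------------------------------------------------------------


def simulate_vacuole_channel(
    truth: SceneGroundTruth,
    labels: LabelStack,
    body_fractions: dict | None = None,
    noise_sd: float = 30.0,
    rng: np.random.Generator | None = None,
    blur_sigma_px: float = 0.7,
) -> np.ndarray:
    """Render the second (vacuole dye) channel for a simulated scene.

    For each cell the integrated signal inside its spore-body region equals
    ``body_fraction`` x the cell's total signal before noise; the body region
    is the disc of the dormant (t0) radius internally tangent at the pole
    opposite the outgrowth.  Gaussian noise preserves the expectation.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    psz = truth.pixel_size_um
    dt = truth.frame_interval_min
    T, H, W = labels.labels.shape
    out = np.zeros((T, H, W), dtype=np.uint16)
    for frame in range(T):
        lab = labels.labels[frame]
        canvas = np.zeros((H, W), dtype=np.float32)
        # index all foreground pixels once, grouped by label
        rows_all, cols_all = np.nonzero(lab)
        vals_all = lab[rows_all, cols_all]
        order = np.argsort(vals_all, kind="stable")
        rows_all, cols_all, vals_all = rows_all[order], cols_all[order], vals_all[order]
        uniq, starts = np.unique(vals_all, return_index=True)
        bounds = dict(
            zip(uniq.tolist(), zip(starts.tolist(), np.append(starts[1:], vals_all.size).tolist()))
        )

        def pixels_of(label_id):
            span = bounds.get(label_id)
            if span is None:
                return None
            lo, hi = span
            return rows_all[lo:hi], cols_all[lo:hi]

        for cell in truth.cells:
            f = (
                body_fractions.get(cell.cell_id)
                if body_fractions is not None
                else cell.vacuole_body_fraction
            )
            if f is None:
                continue
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"body fraction must be within [0, 1], got {f}")
            active = [cell.label]
            if cell.child_labels and cell.split_frame is not None and frame >= cell.split_frame:
                active = list(cell.child_labels)
            parts = [p for p in (pixels_of(l) for l in active) if p is not None]
            if not parts:
                continue
            rows = np.concatenate([p[0] for p in parts])
            cols = np.concatenate([p[1] for p in parts])
            n_cell = rows.size
            rb = cell.body_radius_at(frame * dt)
            bx = cell.center_x_um - (rb - cell.radius_um) * cell.axis_x
            by = cell.center_y_um - (rb - cell.radius_um) * cell.axis_y
            px = (cols + 0.5) * psz
            py = (rows + 0.5) * psz
            in_body = (px - bx) ** 2 + (py - by) ** 2 <= cell.radius_um**2
            n_body = int(in_body.sum())
            n_out = n_cell - n_body
            vals = np.empty(n_cell, dtype=np.float32)
            if n_out == 0 or n_body == 0:
                vals[:] = _CH2_TOTAL / n_cell
            else:
                vals[in_body] = f * _CH2_TOTAL / n_body
                vals[~in_body] = (1.0 - f) * _CH2_TOTAL / n_out
            canvas[rows, cols] = vals
        if blur_sigma_px > 0:
            canvas = gaussian_filter(canvas, blur_sigma_px)
        canvas += _CH2_BG
        if noise_sd > 0:
            canvas += rng.normal(0.0, noise_sd, size=canvas.shape)
        out[frame] = np.clip(canvas, 0, 65535).astype(np.uint16)
    return out


# ---------------------------------------------------------------------------
# CFU longevity experiments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecayModel:
    """Spore-viability decay over storage time.

    ``exponential``: survival = 2^(-t / half_life_days).
    ``biphasic``: mixture of two exponentials with ``mixture_weight`` on the
    first.  Replicate counts get multiplicative log-normal noise with the
    given log-sd.
    """

    form: str = "exponential"
    half_life_days: float = 10.0
    half_life_days_2: float | None = None
    mixture_weight: float = 1.0
    replicate_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.form not in ("exponential", "biphasic"):
            raise ValueError("form must be 'exponential' or 'biphasic'")
        if self.half_life_days <= 0:
            raise ValueError("half-lives must be positive")
        if self.form == "biphasic":
            if self.half_life_days_2 is None or self.half_life_days_2 <= 0:
                raise ValueError("biphasic form needs a positive second half-life")
            if not 0.0 <= self.mixture_weight <= 1.0:
                raise ValueError("mixture_weight must be in [0, 1]")

    def survival(self, t_days) -> np.ndarray:
        t = np.asarray(t_days, dtype=float)
        s1 = np.exp2(-t / self.half_life_days)
        if self.form == "exponential":
            return s1
        s2 = np.exp2(-t / self.half_life_days_2)
        return self.mixture_weight * s1 + (1.0 - self.mixture_weight) * s2


def simulate_cfu_experiment(
    model: DecayModel,
    times_days,
    n_reps: int,
    seed: int,
    condition: str = "simulated",
    starting_cfu: float = 500.0,
) -> list[CFUSeries]:
    """Simulate replicate colony-count series over storage time.

    Each replicate count is survival(t) x starting CFU x log-normal noise.
    ``times_days`` must include day 0 (the normalization reference).
    """
    times = np.asarray(list(times_days), dtype=float)
    if times.size < 1 or not np.isclose(times.min(), 0.0):
        raise ValueError("times must include day 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    order = np.argsort(times)
    times = times[order]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 404]))
    out = []
    base = model.survival(times) * starting_cfu
    for rep in range(n_reps):
        if model.replicate_noise_sd > 0:
            noise = rng.lognormal(0.0, model.replicate_noise_sd, size=times.size)
        else:
            noise = np.ones(times.size)
        out.append(
            CFUSeries(
                condition=condition,
                replicate=rep,
                times_days=times.copy(),
                cfu=base * noise,
            )
        )
    return out
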