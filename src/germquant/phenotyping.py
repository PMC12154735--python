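"""Germination scoring on tracked cells.

Implements the published scoring rules: particles are gated as spores when
their aspect ratio at time point zero is below 1.4 (circular objects);
first division is the first frame whose aspect ratio exceeds 3.0; swelling
is an increase in area without an increase in aspect ratio; germination
efficiency is the fraction of gated spores that divide before the end of
the timelapse; and each outgrowth is classified as normal, elongated
(> 6 μm), bubbled, exploded, or bipolar — a spore that is both bipolar and
elongated counts as bipolar.  All thresholds are strict as printed ("less
than 1.4", "greater than 3.0", "more than 6 μm").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import LabelStack
from .tracking import Track

__all__ = [
    "GerminationCall",
    "SwellingWindow",
    "gate_spores",
    "call_first_division",
    "germination_efficiency",
    "detect_swelling_window",
    "classify_outgrowth",
    "build_calls",
    "population_curves",
    "write_calls",
]

PHENOTYPE_CLASSES = ("normal", "elongated", "bubble", "bipolar", "exploded", "none")


@dataclass
class GerminationCall:
    """Scoring summary for one gated particle."""

    track_id: int
    is_spore: bool
    germinated: bool
    division_frame: int | None
    division_time_min: float | None
    starting_area_um2: float
    phenotype: str
    outgrowth_length_um: float | None
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class SwellingWindow:
    """Longest early-germination phase with rising area but flat AR."""

    track_id: int
    start_frame: int
    end_frame: int
    area_gain_fraction: float


def gate_spores(
    tracks: list[Track], config: PipelineConfig | None = None
) -> tuple[list[Track], list[Track]]:
    """Split tracks into gated spores (AR < spore_ar_max at frame 0) and
    rejected particles (non-circular at t0, or absent at t0 — late-appearing
    objects such as debris or division products)."""
    if config is None:
        config = PipelineConfig()
    gated, rejected = [], []
    for t in tracks:
        ar0 = t.value_at(0, "aspect_ratio")
        if ar0 is not None and ar0 < config.spore_ar_max:
            gated.append(t)
        else:
            rejected.append(t)
    return gated, rejected


def call_first_division(
    track: Track, config: PipelineConfig | None = None
) -> tuple[int, float] | None:
    """First frame at which the aspect ratio exceeds the division threshold.

    A crossing supported only by an interpolated (gap/focus) frame is
    shifted to the next measured frame.  Returns (frame, time in minutes),
    or None if the threshold is never exceeded.
    """
    if config is None:
        config = PipelineConfig()
    m = track.measures
    above = m["aspect_ratio"].to_numpy() > config.division_ar
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    i = int(idx[0])
    interp = m["interpolated"].to_numpy()
    while i < len(m) and interp[i]:
        i += 1
    if i >= len(m):
        return None
    frame = int(m["frame"].iloc[i])
    return frame, frame * config.frame_interval_min


def germination_efficiency(
    calls: list[GerminationCall], end_frame: int
) -> tuple[float, int, int]:
    """Fraction of gated spores that complete first division by ``end_frame``.

    Returns (fraction, n_germinated, n_gated).  Scoring fewer than 50 spores
    triggers a warning (the reference convention requires N > 50 per
    sample); zero gated spores is an error.
    """
    gated = [c for c in calls if c.is_spore]
    if not gated:
        raise ValueError("germination efficiency undefined: no gated spores")
    if len(gated) < 50:
        warnings.warn(
            f"only {len(gated)} gated spores; the reporting convention "
            "requires N>50 spores per sample",
            stacklevel=2,
        )
    n_germ = sum(
        1
        for c in gated
        if c.germinated and (c.division_frame is None or c.division_frame <= end_frame)
    )
    return n_germ / len(gated), n_germ, len(gated)


def detect_swelling_window(
    track: Track, config: PipelineConfig | None = None
) -> SwellingWindow | None:
    """Longest run of frames with rising area and flat aspect ratio.

    Series are smoothed with a centred moving average; a frame-to-frame
    step qualifies when the relative area slope exceeds
    ``swelling_area_eps`` while the absolute AR slope stays within
    ``swelling_ar_eps``.  Runs shorter than one step (two frames) give
    None.  When a division was called, the scan stops at the division
    frame (swelling precedes division).
    """
    if config is None:
        config = PipelineConfig()
    w = config.smoothing_window_frames
    m = track.measures
    if len(m) < max(w, 2):
        return None
    division = call_first_division(track, config)
    frames = m["frame"].to_numpy()
    area = m["area_um2"].to_numpy(dtype=float)
    ar = m["aspect_ratio"].to_numpy(dtype=float)
    if division is not None:
        keep = frames < division[0]
        frames, area, ar = frames[keep], area[keep], ar[keep]
    if frames.size < max(w, 2):
        return None
    kernel = np.ones(w) / w
    sm_area = np.convolve(area, kernel, mode="valid")
    sm_ar = np.convolve(ar, kernel, mode="valid")
    sm_frames = frames[w // 2 : frames.size - (w // 2)]
    if sm_area.size < 2:
        return None
    rel_slope = np.diff(sm_area) / sm_area[:-1]
    ar_slope = np.diff(sm_ar)
    ok = (rel_slope > config.swelling_area_eps) & (
        np.abs(ar_slope) <= config.swelling_ar_eps
    )
    best = _longest_run(ok)
    if best is None:
        return None
    s, e = best  # indices into the slope array; window spans frames [s, e+1]
    return SwellingWindow(
        track_id=track.track_id,
        start_frame=int(sm_frames[s]),
        end_frame=int(sm_frames[e + 1]),
        area_gain_fraction=float(sm_area[e + 1] / sm_area[s] - 1.0),
    )


def _longest_run(ok: np.ndarray) -> tuple[int, int] | None:
    best = None
    start = None
    for i, flag in enumerate(list(ok) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            length = i - start
            if best is None or length > best[1] - best[0] + 1:
                best = (start, i - 1)
            start = None
    return best


def _principal_axis(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Unit vector (x, y) of the principal axis of a pixel set."""
    x = cols - cols.mean()
    y = rows - rows.mean()
    cov = np.array([[np.mean(x * x), np.mean(x * y)], [np.mean(x * y), np.mean(y * y)]])
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, int(np.argmax(vals))]
    return v / np.linalg.norm(v)


def protrusion_lengths(
    track: Track, labels: LabelStack, frame: int
) -> tuple[float, float] | None:
    """Per-pole protrusion beyond the t0 spore-body disc, along the major axis.

    Returns (longer, shorter) protrusion in μm, or None when the track has
    no measured mask at ``frame``.
    """
    row = track.measures[
        (track.measures["frame"] == frame) & (~track.measures["interpolated"])
    ]
    if row.empty:
        return None
    label = int(row.iloc[0]["label"])
    mask = labels.labels[frame] == label
    if not mask.any():
        return None
    psz = labels.pixel_size_um
    first = track.measures.iloc[0]
    r0 = float(np.sqrt(first["area_um2"] / np.pi))
    c0 = np.array([first["centroid_x_um"], first["centroid_y_um"]])
    rows, cols = np.nonzero(mask)
    u = _principal_axis(rows.astype(float), cols.astype(float))
    px = (cols + 0.5) * psz - c0[0]
    py = (rows + 0.5) * psz - c0[1]
    proj = px * u[0] + py * u[1]
    prot_a = max(float(proj.max()) - r0, 0.0)
    prot_b = max(-float(proj.min()) - r0, 0.0)
    return (max(prot_a, prot_b), min(prot_a, prot_b))


def classify_outgrowth(
    track: Track,
    labels: LabelStack,
    config: PipelineConfig | None = None,
    last_analyzed_frame: int | None = None,
) -> tuple[str, float | None, bool]:
    """Classify a gated track's outgrowth phenotype.

    Evaluated at the frame before the division split (or the last tracked
    frame when no split happened).  Priority order: exploded, bubble,
    bipolar, elongated, normal — a spore that is both bipolar and elongated
    counts as bipolar.  Returns (phenotype, outgrowth_length_um, flagged).
    """
    if config is None:
        config = PipelineConfig()
    if last_analyzed_frame is None:
        last_analyzed_frame = labels.n_frames - 1
    m = track.measures
    real = m[~m["interpolated"]]
    # (1) exploded: the track ends early (no split) — by fragmentation with a
    # large area drop, or by outright disappearance
    if track.terminal_event == "lost" and track.end_frame < last_analyzed_frame:
        return "exploded", None, False
    split = track.split_children is not None
    eval_frame = int(real["frame"].iloc[-1])
    # (2) bubble: split while still circular
    if split:
        ar_pre = float(real["aspect_ratio"].iloc[-1])
        if ar_pre < config.bubble_ar_max:
            return "bubble", 0.0, False
    prot = protrusion_lengths(track, labels, eval_frame)
    if prot is None:
        return "none", None, True
    longer, shorter = prot
    # (3) bipolar: both poles protrude beyond a tube radius + 0.5 um
    bipolar_min = config.tube_width_um / 2.0 + 0.5
    if longer > bipolar_min and shorter > bipolar_min:
        return "bipolar", longer, False
    # (4) elongated: outgrowth beyond the 6 um cutoff
    if longer > config.elongated_cutoff_um:
        return "elongated", longer, False
    # (5) normal, provided the cell actually germinated; otherwise "none"
    division = call_first_division(track, config)
    if division is not None or split:
        return "normal", longer, False
    return "none", longer if longer > 0 else None, False


def build_calls(
    tracks: list[Track],
    labels: LabelStack,
    config: PipelineConfig | None = None,
    end_frame: int | None = None,
) -> list[GerminationCall]:
    """Run gating, division calling and phenotype classification on tracks."""
    if config is None:
        config = PipelineConfig()
    if end_frame is None:
        end_frame = labels.n_frames - 1
    gated, _ = gate_spores(tracks, config)
    gated_ids = {t.track_id for t in gated}
    calls = []
    for t in tracks:
        if t.track_id not in gated_ids:
            continue
        division = call_first_division(t, config)
        phenotype, outgrowth, flagged = classify_outgrowth(
            t, labels, config, last_analyzed_frame=end_frame
        )
        div_frame = division[0] if division else None
        if phenotype == "bubble" and div_frame is None and t.split_children is not None:
            div_frame = t.end_frame + 1  # the split itself is the division
        germinated = div_frame is not None and div_frame <= end_frame
        first = t.measures.iloc[0]
        calls.append(
            GerminationCall(
                track_id=t.track_id,
                is_spore=True,
                germinated=germinated,
                division_frame=div_frame,
                division_time_min=(
                    div_frame * config.frame_interval_min if div_frame is not None else None
                ),
                starting_area_um2=float(first["area_um2"]),
                phenotype=phenotype if (germinated or phenotype == "exploded") else "none",
                outgrowth_length_um=outgrowth,
                flagged=flagged,
            )
        )
    return calls


def population_curves(
    tracks: list[Track], exclude_frames=(), frame_interval_min: float | None = None
) -> pd.DataFrame:
    """Per-frame mean ± standard error of area and AR over live tracks.

    Interpolated rows and excluded (focus-loss) frames do not contribute.
    SE = sd/sqrt(n) with ddof=1; a single contributing track reports SE 0.
    When ``frame_interval_min`` is given a ``time_min`` column is included.
    """
    if not tracks:
        raise ValueError("population curves need at least one track")
    skip = set(int(f) for f in exclude_frames)
    rows = []
    for t in tracks:
        m = t.measures
        m = m[~m["interpolated"]]
        rows.append(m[["frame", "area_um2", "aspect_ratio"]])
    allm = pd.concat(rows, ignore_index=True)
    allm = allm[~allm["frame"].isin(skip)]
    out = []
    for f, g in allm.groupby("frame"):
        n = len(g)
        se_area = float(g["area_um2"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        se_ar = float(g["aspect_ratio"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(
            {
                "frame": int(f),
                "mean_area_um2": float(g["area_um2"].mean()),
                "se_area_um2": se_area,
                "mean_ar": float(g["aspect_ratio"].mean()),
                "se_ar": se_ar,
                "n": n,
            }
        )
    curves = pd.DataFrame(out).sort_values("frame").reset_index(drop=True)
    if frame_interval_min is not None:
        curves.insert(1, "time_min", curves["frame"] * frame_interval_min)
    return curves


_CALL_COLS = [
    "track_id",
    "is_spore",
    "germinated",
    "division_frame",
    "division_time_min",
    "starting_area_um2",
    "phenotype",
    "outgrowth_length_um",
    "flagged",
]


def write_calls(calls: list[GerminationCall], path: str | Path) -> None:
    df = pd.DataFrame([c.__dict__ for c in calls])
    if df.empty:
        df = pd.DataFrame(columns=_CALL_COLS)
    df[_CALL_COLS].to_csv(path, index=False, float_format="%.9g")
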