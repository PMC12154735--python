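"""Vacuole-dye partitioning between spore body and germ-tube outgrowth.

At the first division, vacuoles are preferentially retained in the round
(spore-body) end of the germinating cell.  This module quantifies that
asymmetry from a second fluorescence channel: the spore body is defined as
the disc of the particle's t0 radius internally tangent at the pole
opposite the outgrowth, and the retained fraction is the
background-subtracted channel-2 signal inside the body over the signal in
the whole cell.  The partition is evaluated at the frame immediately before
the division (the last single-object frame); computation always uses raw
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import ImageStack, LabelStack
from .phenotyping import GerminationCall, _principal_axis
from .tracking import Track

__all__ = [
    "VacuolePartition",
    "define_spore_body",
    "partition_fraction",
    "measure_vacuole_partitions",
]

_MIN_PROTRUSION_UM = 0.5


@dataclass
class VacuolePartition:
    """Body/outgrowth split of the channel-2 signal for one cell."""

    track_id: int
    frame: int
    fraction_in_body: float
    fraction_in_outgrowth: float
    body_px: int
    outgrowth_px: int
    background: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_in_body <= 1.0):
            raise ValueError("fraction_in_body must be within [0, 1]")


def define_spore_body(
    track: Track, labels: LabelStack, frame: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split a germinated cell's mask into (cell_mask, body_mask).

    The body is the disc of the t0 radius placed internally tangent at the
    round-end pole (the pole farthest from the outgrowth tip), intersected
    with the current cell mask.  Raises when the cell has not outgrown
    enough to partition (protrusion < 0.5 μm).
    """
    row = track.measures[
        (track.measures["frame"] == frame) & (~track.measures["interpolated"])
    ]
    if row.empty:
        raise ValueError(f"track {track.track_id} has no measured mask at frame {frame}")
    label = int(row.iloc[0]["label"])
    mask = labels.labels[frame] == label
    if not mask.any():
        raise ValueError(f"label {label} absent from frame {frame}")
    psz = labels.pixel_size_um
    first = track.measures.iloc[0]
    r0 = float(np.sqrt(first["area_um2"] / np.pi))
    c0 = np.array([first["centroid_x_um"], first["centroid_y_um"]])
    rows, cols = np.nonzero(mask)
    u = _principal_axis(rows.astype(float), cols.astype(float))
    px = (cols + 0.5) * psz - c0[0]
    py = (rows + 0.5) * psz - c0[1]
    proj = px * u[0] + py * u[1]
    prot_pos = float(proj.max()) - r0
    prot_neg = -float(proj.min()) - r0
    if max(prot_pos, prot_neg) < _MIN_PROTRUSION_UM:
        raise ValueError("cell not germinated enough to partition")
    # tip lies on the side with the larger protrusion; the round end opposite
    if prot_pos >= prot_neg:
        pole_proj, toward_tip = float(proj.min()), u
    else:
        pole_proj, toward_tip = float(proj.max()), -u
    pole = c0 + abs(pole_proj) * (-toward_tip)
    body_center = pole + r0 * toward_tip
    bx = (cols + 0.5) * psz - body_center[0]
    by = (rows + 0.5) * psz - body_center[1]
    in_body = bx * bx + by * by <= r0 * r0
    body_mask = np.zeros_like(mask)
    body_mask[rows[in_body], cols[in_body]] = True
    return mask, body_mask


def partition_fraction(
    cell_mask: np.ndarray,
    body_mask: np.ndarray,
    channel2: np.ndarray,
    background: float,
    track_id: int = -1,
    frame: int = -1,
) -> VacuolePartition:
    """Fraction of background-subtracted channel-2 signal inside the body.

    Negative background-subtracted pixels are clamped to zero; the body and
    outgrowth fractions sum to exactly 1.  Zero total signal is an error.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    body_mask = np.asarray(body_mask, dtype=bool)
    if np.any(body_mask & ~cell_mask):
        raise ValueError("body mask must be contained in the cell mask")
    img = np.asarray(channel2, dtype=float)
    signal = np.clip(img - background, 0.0, None)
    total = float(signal[cell_mask].sum())
    if total <= 0:
        raise ValueError("zero total channel-2 signal in the cell; fraction undefined")
    body = float(signal[body_mask].sum())
    frac = body / total
    return VacuolePartition(
        track_id=track_id,
        frame=frame,
        fraction_in_body=frac,
        fraction_in_outgrowth=1.0 - frac,
        body_px=int(body_mask.sum()),
        outgrowth_px=int(cell_mask.sum() - body_mask.sum()),
        background=float(background),
    )


def frame_background(channel2: np.ndarray, label_frame: np.ndarray) -> float:
    """Per-frame background: median channel-2 intensity outside all masks."""
    outside = label_frame == 0
    if not outside.any():
        raise ValueError("no background pixels in frame")
    return float(np.median(np.asarray(channel2, dtype=float)[outside]))


def measure_vacuole_partitions(
    stack: ImageStack,
    labels: LabelStack,
    tracks: list[Track],
    calls: list[GerminationCall],
    config: PipelineConfig | None = None,
    channel: int = 1,
) -> pd.DataFrame:
    """Vacuole partition for every germinated, outgrown cell at the frame
    immediately before its division.  Cells that cannot be partitioned
    (no outgrowth, missing mask, no signal) are skipped."""
    if config is None:
        config = PipelineConfig()
    ch2 = stack.channel(channel)
    by_id = {t.track_id: t for t in tracks}
    out = []
    for call in calls:
        if not call.germinated or call.division_frame is None:
            continue
        if call.phenotype in ("bubble", "exploded", "none"):
            continue
        track = by_id.get(call.track_id)
        if track is None:
            continue
        frame = min(call.division_frame - 1, track.end_frame)
        if frame < track.start_frame:
            continue
        try:
            cell_mask, body_mask = define_spore_body(track, labels, frame)
            bg = frame_background(ch2[frame], labels.labels[frame])
            part = partition_fraction(
                cell_mask, body_mask, ch2[frame], bg, call.track_id, frame
            )
        except ValueError:
            continue
        out.append(part.__dict__)
    cols = [
        "track_id",
        "frame",
        "fraction_in_body",
        "fraction_in_outgrowth",
        "body_px",
        "outgrowth_px",
        "background",
    ]
    return pd.DataFrame(out, columns=cols)
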