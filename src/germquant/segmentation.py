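"""Classical per-frame segmentation, external-mask adapter, focus-loss QC.

The reference analysis used a learned segmenter for inference; here the same
output contract (per-frame integer label masks) is produced by a classical
threshold-plus-morphology segmenter, and externally produced masks (e.g.
from a Cellpose model) can be dropped in through :func:`load_external_masks`
with identical downstream behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation as skseg

from .config import PipelineConfig
from .io import ImageStack, LabelStack

__all__ = [
    "SegParams",
    "FocusReport",
    "segment_frame",
    "segment_stack",
    "load_external_masks",
    "detect_focus_loss",
]


@dataclass(frozen=True)
class SegParams:
    """Classical segmenter parameters.

    ``threshold_method`` is ``"otsu"`` or ``"fixed"`` (with
    ``threshold_value``); components smaller than ``min_area_um2`` are
    removed; ``morphology_radius_px`` sets the opening radius used to clean
    speckle; ``invert_contrast`` handles dark-on-bright data;
    ``erode_px`` optionally shrinks masks to counter systematic mask
    inflation (off by default — areas are reported as measured);
    ``split_touching`` enables a watershed split of touching objects
    (off by default: a rendered/real septum gap already separates
    daughters into distinct connected components).
    """

    threshold_method: str = "otsu"
    threshold_value: float | None = None
    min_area_um2: float = 3.0
    morphology_radius_px: int = 1
    invert_contrast: bool = False
    erode_px: int = 0
    split_touching: bool = False

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ValueError("fixed threshold requires threshold_value")
        if self.min_area_um2 <= 0:
            raise ValueError("min_area_um2 must be positive")


def segment_frame(
    frame: np.ndarray, params: SegParams, pixel_size_um: float
) -> np.ndarray:
    """Label one transmitted-light frame (bright objects on dark background).

    Background is 0; labels are consecutive positive integers, one connected
    component each; holes are filled; components below the minimum area are
    removed.  A constant frame with Otsu thresholding yields an empty
    labelling rather than an error.
    """
    img = np.asarray(frame, dtype=np.float32)
    if not np.all(np.isfinite(img)):
        raise ValueError("frame contains non-finite intensities")
    if params.invert_contrast:
        img = -img
    if params.threshold_method == "otsu":
        if img.max() == img.min():
            return np.zeros(img.shape, dtype=np.int32)
        thr = filters.threshold_otsu(img)
    else:
        thr = params.threshold_value
    binary = img > thr
    if params.morphology_radius_px > 0:
        binary = morphology.opening(
            binary, morphology.disk(params.morphology_radius_px)
        )
    binary = ndi.binary_fill_holes(binary)
    if params.erode_px > 0:
        binary = morphology.binary_erosion(binary, morphology.disk(params.erode_px))
    # 4-connectivity keeps objects separated by a 1-px diagonal septum apart
    labels = measure.label(binary, connectivity=1)
    min_px = params.min_area_um2 / pixel_size_um**2
    if labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        too_small = np.flatnonzero(sizes < min_px)
        mask = np.isin(labels, too_small[too_small > 0])
        labels[mask] = 0
    if params.split_touching and labels.max() > 0:
        labels = _watershed_split(labels, img)
    labels, _, _ = skseg.relabel_sequential(labels)
    return labels.astype(np.int32)


def _watershed_split(labels: np.ndarray, img: np.ndarray) -> np.ndarray:
    """Split labels that contain two intensity minima separated by >= 2 px;
    objects with a single interior minimum are kept whole."""
    from skimage.feature import peak_local_max

    out = labels.copy()
    next_id = labels.max() + 1
    for region in measure.regionprops(labels):
        sub = region.image
        inv = -img[region.slice] * sub
        peaks = peak_local_max(inv, min_distance=2, labels=sub, num_peaks=2)
        if len(peaks) < 2:
            continue
        markers = np.zeros(sub.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks):
            markers[r, c] = i + 1
        ws = skseg.watershed(-inv, markers=markers, mask=sub)
        out[region.slice][ws == 2] = next_id
        next_id += 1
    return out


def segment_stack(
    stack: ImageStack, params: SegParams, channel: int = 0
) -> LabelStack:
    """Apply :func:`segment_frame` to every frame of a stack."""
    frames = stack.channel(channel)
    labels = np.zeros(frames.shape, dtype=np.int32)
    for k in range(frames.shape[0]):
        labels[k] = segment_frame(frames[k], params, stack.pixel_size_um)
    return LabelStack(labels, stack.pixel_size_um, stack.frame_interval_min)


def load_external_masks(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_min: float,
    expected_frames: int | None = None,
) -> LabelStack:
    """Adapter for externally produced label masks (one 16-bit TIFF stack, or
    a directory of per-frame TIFFs ordered by filename sort).

    Labels pass through unchanged except for per-frame relabelling to
    consecutive integers; downstream analysis is independent of the mask
    source.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if not files:
            raise OSError(f"no TIFF mask files found in {path}")
        pages = [tifffile.imread(str(f)) for f in files]
        shapes = {p.shape for p in pages}
        if len(shapes) != 1:
            raise OSError("mask frames have inconsistent shapes")
        arr = np.stack(pages)
    else:
        arr = tifffile.imread(str(path))
        if arr.ndim == 2:
            arr = arr[None]
    if arr.ndim != 3:
        raise OSError(f"label masks must be 2-D pages, got array shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.any(np.mod(arr, 1) != 0):
            raise ValueError("mask pixel values must be integers")
        arr = arr.astype(np.int32)
    if expected_frames is not None and arr.shape[0] != expected_frames:
        raise ValueError(
            f"mask frame count {arr.shape[0]} does not match image stack "
            f"frame count {expected_frames}"
        )
    out = np.zeros(arr.shape, dtype=np.int32)
    for k in range(arr.shape[0]):
        out[k], _, _ = skseg.relabel_sequential(arr[k].astype(np.int64))
    return LabelStack(out, pixel_size_um, frame_interval_min)


@dataclass
class FocusReport:
    """Focus QC for one timelapse."""

    flagged_frames: tuple
    excluded: bool
    sharpness: np.ndarray


def detect_focus_loss(
    stack: ImageStack, config: PipelineConfig | None = None, channel: int = 0
) -> FocusReport:
    """Flag defocused frames and decide whole-timelapse exclusion.

    Per-frame sharpness is the variance of the gradient magnitude; a frame
    is flagged when its sharpness falls below median - 3*MAD across frames.
    The timelapse is excluded when the number of flagged frames exceeds
    ``focus_loss_max_frames`` (strictly more than; a dip of exactly that
    many frames is kept).
    """
    if config is None:
        config = PipelineConfig()
    frames = stack.channel(channel)
    if frames.shape[0] < 7:
        raise ValueError("focus QC needs at least 7 frames for a robust baseline")
    sharp = np.empty(frames.shape[0])
    for k in range(frames.shape[0]):
        img = frames[k].astype(np.float32)
        gy, gx = np.gradient(img)
        sharp[k] = np.var(np.hypot(gx, gy))
    med = float(np.median(sharp))
    mad = float(np.median(np.abs(sharp - med)))
    cutoff = med - 3.0 * max(mad, 1e-12 * max(med, 1.0))
    flagged = tuple(int(i) for i in np.flatnonzero(sharp < cutoff))
    excluded = len(flagged) > config.focus_loss_max_frames
    return FocusReport(flagged_frames=flagged, excluded=excluded, sharpness=sharp)
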