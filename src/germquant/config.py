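"""Pipeline configuration with the published scoring thresholds as defaults.

The defaults encode the scoring rules used throughout the package: a particle
is gated as a spore when its aspect ratio at time point zero is below 1.4,
first division is called when the aspect ratio exceeds 3.0, an outgrowth
longer than 6 μm is scored elongated, and a timelapse that loses focus for
more than 5 timepoints is excluded from analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised for malformed configuration files or invalid threshold values."""


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and calibration for the germination-phenotyping pipeline.

    Attributes
    ----------
    pixel_size_um:
        Physical side of one pixel in μm. Not printed in typical acquisition
        metadata for transmitted light, so it is a required calibration input;
        the default 0.18 μm matches a 60x objective with an 11 μm camera pixel.
    frame_interval_min, duration_min_default:
        Acquisition cadence: one frame every 10 min for at least 1,000 min.
    spore_ar_max:
        Gate: particles with aspect ratio below this at frame 0 are counted
        as spores (circular objects).
    division_ar:
        First division is called at the first frame whose aspect ratio
        exceeds this value.
    elongated_cutoff_um:
        Outgrowths longer than this are scored "elongated".
    tube_width_um:
        Nominal germ-tube width; half of it plus 0.5 μm is the minimum
        per-pole protrusion for a "bipolar" call.
    focus_loss_max_frames:
        A timelapse with more than this many focus-loss frames is excluded.
    smoothing_window_frames:
        Centred moving-average window (odd) used by swelling detection.
    swelling_area_eps / swelling_ar_eps:
        Per-frame relative area slope / absolute AR slope bounds defining the
        swelling window (area rising while AR flat).
    bubble_ar_max:
        A split occurring while the parent is still rounder than this is a
        "bubble" division.
    explode_area_drop_frac:
        Fractional area loss within two frames that, together with track
        disappearance/fragmentation, marks an "exploded" spore.
    """

    pixel_size_um: float = 0.18
    frame_interval_min: float = 10.0
    duration_min_default: float = 1000.0
    spore_ar_max: float = 1.4
    division_ar: float = 3.0
    elongated_cutoff_um: float = 6.0
    tube_width_um: float = 1.766
    focus_loss_max_frames: int = 5
    smoothing_window_frames: int = 3
    swelling_area_eps: float = 0.01
    swelling_ar_eps: float = 0.02
    bubble_ar_max: float = 1.6
    explode_area_drop_frac: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "pixel_size_um",
            "frame_interval_min",
            "duration_min_default",
            "spore_ar_max",
            "division_ar",
            "elongated_cutoff_um",
            "tube_width_um",
            "swelling_area_eps",
            "swelling_ar_eps",
            "bubble_ar_max",
            "explode_area_drop_frac",
        )
        for name in positive:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and value > 0):
                raise ConfigError(f"{name} must be strictly positive, got {value!r}")
        if self.spore_ar_max >= self.division_ar:
            raise ConfigError(
                "spore_ar_max must be below division_ar "
                f"({self.spore_ar_max} >= {self.division_ar})"
            )
        if self.focus_loss_max_frames < 0:
            raise ConfigError("focus_loss_max_frames must be >= 0")
        w = self.smoothing_window_frames
        if w < 1 or w % 2 == 0:
            raise ConfigError(f"smoothing_window_frames must be odd and >= 1, got {w}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML key-value config; missing keys take the defaults above."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain key: value pairs")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
    for key, value in raw.items():
        if not isinstance(value, (int, float)):
            raise ConfigError(f"configuration key {key!r} must be numeric, got {value!r}")
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
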