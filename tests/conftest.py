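import warnings

import numpy as np
import pandas as pd
import pytest

from germquant.config import PipelineConfig
from germquant.morphometrics import measure_all
from germquant.phenotyping import build_calls
from germquant.segmentation import SegParams, segment_stack
from germquant.synthetic import ScenarioConfig, simulate_scene
from germquant.tracking import Track, link_tracks

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_scene():
    """A 30-cell mixed-phenotype scene shared across test modules, analyzed
    both from classical segmentation and from the generator's own masks."""
    scenario = ScenarioConfig(n_spores=30, seed=11)
    stack, truth, truth_labels = simulate_scene(scenario, return_labels=True)
    cfg = PipelineConfig()
    seg_labels = segment_stack(stack, SegParams())
    out = {}
    for name, labels in (("seg", seg_labels), ("truth_masks", truth_labels)):
        table = measure_all(labels)
        tracks = link_tracks(table, n_frames=labels.n_frames)
        calls = build_calls(tracks, labels, cfg)
        out[name] = {"labels": labels, "table": table, "tracks": tracks, "calls": calls}
    return {
        "scenario": scenario,
        "stack": stack,
        "truth": truth,
        "truth_labels": truth_labels,
        **out,
    }


def match_calls_to_truth(tracks, calls, truth):
    """Pair each gated call with the nearest ground-truth cell at t0."""
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


def make_track(
    ar_series,
    area_series=None,
    track_id=0,
    frame_interval=10.0,
    interpolated=None,
    terminal_event=None,
):
    """Build a Track directly from an AR (and optional area) series."""
    ar = np.asarray(ar_series, dtype=float)
    n = ar.size
    area = np.asarray(area_series, dtype=float) if area_series is not None else np.full(n, 8.0)
    interp = np.asarray(interpolated, dtype=bool) if interpolated is not None else np.zeros(n, bool)
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "label": np.ones(n, dtype=int),
            "centroid_x_um": np.zeros(n),
            "centroid_y_um": np.zeros(n),
            "area_um2": area,
            "major_um": np.sqrt(area * ar / np.pi) * 2,
            "minor_um": np.sqrt(area / (ar * np.pi)) * 2,
            "aspect_ratio": ar,
            "orientation_rad": np.zeros(n),
            "interpolated": interp,
        }
    )
    return Track(
        track_id=track_id,
        measures=df,
        start_frame=0,
        end_frame=n - 1,
        terminal_event=terminal_event,
    )
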