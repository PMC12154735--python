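"""Frame-to-frame particle linking for (nearly) motionless spores.

Objects are linked by greedy nearest-centroid assignment per frame pair
under a maximum displacement, with ties broken by smallest relative area
change and then lowest label — spores are trapped under agar, so a global
assignment would add complexity without benefit and the documented
tie-breaks make the greedy pass deterministic.  Tracks tolerate short
detection gaps (linear interpolation, flagged), and a one-parent →
two-children event with conserved area is recorded as a division split:
the parent track ends and the daughters start new tracks, so division
metrics are read from the pre-split object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Track", "link_tracks", "write_tracks", "read_tracks"]

_NUMERIC_COLS = [
    "centroid_x_um",
    "centroid_y_um",
    "area_um2",
    "major_um",
    "minor_um",
    "aspect_ratio",
    "orientation_rad",
]


@dataclass
class Track:
    """One particle followed over frames.

    ``measures`` has one row per frame from ``start_frame`` to ``end_frame``
    inclusive, with gap/focus-loss frames filled by linear interpolation and
    flagged in the ``interpolated`` column.  ``terminal_event`` is ``None``
    (alive at the end of the analyzed range), ``"lost"``, or
    ``("split", (child_id_a, child_id_b))``.
    """

    track_id: int
    measures: pd.DataFrame
    start_frame: int
    end_frame: int
    terminal_event: object = None
    parent_id: int | None = None

    def value_at(self, frame: int, column: str):
        row = self.measures[self.measures["frame"] == frame]
        if row.empty:
            return None
        return row.iloc[0][column]

    @property
    def split_children(self):
        if isinstance(self.terminal_event, tuple) and self.terminal_event[0] == "split":
            return self.terminal_event[1]
        return None


class _Builder:
    __slots__ = (
        "id",
        "rows",
        "last_frame",
        "cx",
        "cy",
        "area",
        "major",
        "miss",
        "terminal",
        "parent",
    )

    def __init__(self, tid, frame, row):
        self.id = tid
        self.rows = [(frame, row)]
        self.last_frame = frame
        self.cx = row["centroid_x_um"]
        self.cy = row["centroid_y_um"]
        self.area = row["area_um2"]
        self.major = row["major_um"]
        self.miss = 0
        self.terminal = None
        self.parent = None

    def add(self, frame, row):
        self.rows.append((frame, row))
        self.last_frame = frame
        self.cx = row["centroid_x_um"]
        self.cy = row["centroid_y_um"]
        self.area = row["area_um2"]
        self.major = row["major_um"]
        self.miss = 0


def link_tracks(
    table: pd.DataFrame,
    max_disp_um: float = 2.0,
    max_gap: int = 2,
    skip_frames=(),
    n_frames: int | None = None,
) -> list[Track]:
    """Link a measurement table into tracks.

    ``skip_frames`` (e.g. flagged focus-loss frames) are excluded from
    matching entirely and do not count toward the gap limit; their values
    are interpolated in the returned tracks.
    """
    if table.empty:
        return []
    if n_frames is None:
        n_frames = int(table["frame"].max()) + 1
    skip = set(int(s) for s in skip_frames)
    good_frames = [f for f in range(n_frames) if f not in skip]
    by_frame = {
        int(f): g.sort_values("label", kind="stable").to_dict("records")
        for f, g in table[~table["frame"].isin(skip)].groupby("frame")
    }
    active: list[_Builder] = []
    finished: list[_Builder] = []
    next_id = 0
    prev_good: int | None = None
    for f in good_frames:
        dets = by_frame.get(f, [])
        matched_det: dict[int, int] = {}  # det index -> builder position
        matched_trk: dict[int, int] = {}
        if active and dets:
            tc = np.array([[t.cx, t.cy] for t in active])
            dc = np.array([[d["centroid_x_um"], d["centroid_y_um"]] for d in dets])
            dist = np.hypot(
                tc[:, 0:1] - dc[None, :, 0], tc[:, 1:2] - dc[None, :, 1]
            )
            cand = np.argwhere(dist <= max_disp_um)
            order = sorted(
                (
                    (
                        dist[i, j],
                        abs(dets[j]["area_um2"] - active[i].area) / max(active[i].area, 1e-9),
                        dets[j]["label"],
                        active[i].id,
                        i,
                        j,
                    )
                    for i, j in cand
                ),
            )
            for _, _, _, _, i, j in order:
                if i in matched_trk or j in matched_det:
                    continue
                matched_trk[i] = j
                matched_det[j] = i
            for i, j in matched_trk.items():
                active[i].add(f, dets[j])
        newborn: list[_Builder] = []
        for j, d in enumerate(dets):
            if j not in matched_det:
                tr = _Builder(next_id, f, d)
                next_id += 1
                newborn.append(tr)
        # division-split detection against the previous good frame
        consumed: set[int] = set()
        split_children: list[_Builder] = []
        if prev_good is not None:
            for pos in sorted(range(len(active)), key=lambda p: active[p].id):
                t = active[pos]
                if t.rows[-1][0] not in (prev_good, f):
                    continue
                if t.rows[-1][0] == f and (
                    len(t.rows) < 2 or t.rows[-2][0] != prev_good
                ):
                    continue
                if t.rows[-1][0] == f:
                    p_frame, p_row = t.rows[-2]
                else:
                    p_frame, p_row = t.rows[-1]
                px, py = p_row["centroid_x_um"], p_row["centroid_y_um"]
                p_area, p_major = p_row["area_um2"], p_row["major_um"]
                radius = max(max_disp_um, p_major / 2.0 + max_disp_um)
                cands = []
                if t.rows[-1][0] == f:
                    cands.append(("own", t.rows[-1][1]))
                for nb in newborn:
                    if id(nb) in consumed:
                        continue
                    d0 = nb.rows[0][1]
                    if (
                        np.hypot(d0["centroid_x_um"] - px, d0["centroid_y_um"] - py)
                        <= radius
                    ):
                        cands.append(("new", nb))
                if len(cands) != 2:
                    continue
                area_sum = sum(
                    (c[1]["area_um2"] if c[0] == "own" else c[1].rows[0][1]["area_um2"])
                    for c in cands
                )
                if abs(area_sum - p_area) > 0.3 * p_area:
                    continue
                child_ids = []
                for kind, payload in cands:
                    if kind == "own":
                        child = _Builder(next_id, f, payload)
                        next_id += 1
                        t.rows.pop()
                        t.last_frame = p_frame
                        child.parent = t.id
                        split_children.append(child)
                        child_ids.append(child.id)
                    else:
                        payload.parent = t.id
                        consumed.add(id(payload))
                        child_ids.append(payload.id)
                t.terminal = ("split", tuple(sorted(child_ids)))
                finished.append(t)
                active[pos] = None  # type: ignore[call-overload]
        active = [t for t in active if t is not None]
        # bookkeeping for unmatched tracks
        still = []
        for i, t in enumerate(active):
            if t.terminal is not None:
                finished.append(t)
                continue
            if t.rows[-1][0] != f:
                t.miss += 1
                if t.miss > max_gap:
                    t.terminal = "lost"
                    finished.append(t)
                    continue
            still.append(t)
        active = still + newborn + split_children
        prev_good = f
    finished.extend(active)
    finished.sort(key=lambda t: t.id)
    last_good = good_frames[-1] if good_frames else 0
    return [_finalize(t, skip, last_good) for t in finished]


def _finalize(builder: _Builder, skip: set, last_good: int) -> Track:
    rows = sorted(builder.rows, key=lambda fr: fr[0])
    start, end = rows[0][0], rows[-1][0]
    frames = np.arange(start, end + 1)
    known = {f: r for f, r in rows}
    data = {c: np.empty(frames.size) for c in _NUMERIC_COLS}
    labels = np.zeros(frames.size, dtype=int)
    interp = np.zeros(frames.size, dtype=bool)
    known_frames = np.array([f for f, _ in rows])
    for c in _NUMERIC_COLS:
        vals = np.array([r[c] for _, r in rows], dtype=float)
        data[c] = np.interp(frames, known_frames, vals)
    for i, f in enumerate(frames):
        if f in known:
            labels[i] = known[f]["label"]
        else:
            interp[i] = True
    df = pd.DataFrame({"frame": frames, "label": labels, **data, "interpolated": interp})
    terminal = builder.terminal
    if terminal is None and end < last_good:
        terminal = "lost"
    return Track(
        track_id=builder.id,
        measures=df,
        start_frame=int(start),
        end_frame=int(end),
        terminal_event=terminal,
        parent_id=builder.parent,
    )


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_TRACK_COLS = (
    ["track_id", "frame", "label"]
    + _NUMERIC_COLS
    + ["interpolated", "terminal_event", "child_a", "child_b", "parent_id"]
)


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    """Write tracks as one long CSV (track-level fields repeated per row)."""
    chunks = []
    for t in tracks:
        df = t.measures.copy()
        df.insert(0, "track_id", t.track_id)
        children = t.split_children
        df["terminal_event"] = (
            "split" if children else (t.terminal_event if t.terminal_event else "none")
        )
        df["child_a"] = children[0] if children else -1
        df["child_b"] = children[1] if children else -1
        df["parent_id"] = t.parent_id if t.parent_id is not None else -1
        chunks.append(df)
    if chunks:
        out = pd.concat(chunks, ignore_index=True)[_TRACK_COLS]
    else:
        out = pd.DataFrame(columns=_TRACK_COLS)
    out.to_csv(path, index=False, float_format="%.9g")


def read_tracks(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        first = g.iloc[0]
        terminal: object = first["terminal_event"]
        if terminal == "none":
            terminal = None
        elif terminal == "split":
            terminal = ("split", (int(first["child_a"]), int(first["child_b"])))
        parent = int(first["parent_id"])
        tracks.append(
            Track(
                track_id=int(tid),
                measures=g[["frame", "label"] + _NUMERIC_COLS + ["interpolated"]].reset_index(
                    drop=True
                ),
                start_frame=int(g["frame"].min()),
                end_frame=int(g["frame"].max()),
                terminal_event=terminal,
                parent_id=parent if parent >= 0 else None,
            )
        )
    return tracks
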