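"""GEDI ratio calibration, cell tracking and live/dead fate classification.

The GEDI (genetically encoded death indicator) reporter pairs a green
calcium sensor with a constitutive red morphology marker; lethal calcium
influx raises the per-cell green/red ratio.  This module calibrates the
live/dead ratio threshold from baseline and post-lethal-dose populations,
links per-frame cell measurements into tracks, and converts each track
into a survival record: a cell dies at its first threshold crossing or at
its disappearance from the field of view (detachment), whichever comes
first; cells alive and visible through the horizon are censored.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imageops import CellMeasurement
from .survival import SurvivalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GEDICalibration",
    "CellTrack",
    "calibrate_threshold",
    "link_tracks",
    "classify_fate",
]

MIN_CALIBRATION_SAMPLES = 30


@dataclass
class GEDICalibration:
    """Live/dead ratio threshold with the distributions that produced it."""

    threshold: float
    live_ratios: np.ndarray
    dead_ratios: np.ndarray
    live_median: float
    dead_median: float

    def __post_init__(self) -> None:
        if not (self.live_median < self.threshold < self.dead_median):
            raise ValueError(
                "threshold must lie strictly between the group medians"
            )
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "threshold": self.threshold,
                    "live_median": self.live_median,
                    "dead_median": self.dead_median,
                    "n_live": int(len(self.live_ratios)),
                    "n_dead": int(len(self.dead_ratios)),
                },
                indent=1,
            )
        )


def calibrate_threshold(
    live_ratios: np.ndarray, dead_ratios: np.ndarray
) -> GEDICalibration:
    """Calibrate the death threshold from pre- and post-lethal-dose ratios.

    The threshold is the geometric mean of the two group medians —
    symmetric on the log-ratio scale, and equal to 1 when the medians are
    reciprocal (e.g. 0.5 and 2.0, the reporter's operating regime).
    Requires at least 30 samples per group and a dead median strictly
    above the live median.
    """
    live = np.asarray(live_ratios, dtype=float)
    dead = np.asarray(dead_ratios, dtype=float)
    if live.size < MIN_CALIBRATION_SAMPLES or dead.size < MIN_CALIBRATION_SAMPLES:
        raise ValueError(
            f"need >= {MIN_CALIBRATION_SAMPLES} samples per group "
            f"(got {live.size} live, {dead.size} dead)"
        )
    live_med = float(np.median(live))
    dead_med = float(np.median(dead))
    if dead_med <= live_med:
        raise ValueError(
            f"dead median ({dead_med:.3g}) must exceed live median "
            f"({live_med:.3g}); calibration invalid"
        )
    threshold = math.sqrt(live_med * dead_med)
    return GEDICalibration(
        threshold=threshold,
        live_ratios=live,
        dead_ratios=dead,
        live_median=live_med,
        dead_median=dead_med,
    )


@dataclass
class CellTrack:
    """One cell's linked measurements across frames.

    ``disappeared_at_h`` is the midpoint of the interval bracketing the
    cell's disappearance, or None if the cell is visible at the final
    frame.
    """

    cell_id: int
    measurements: list[CellMeasurement] = field(default_factory=list)
    disappeared_at_h: float | None = None

    @property
    def times_h(self) -> list[float]:
        return [m.timepoint_h for m in self.measurements]

    @property
    def ratios(self) -> list[float]:
        return [m.gedi_ratio for m in self.measurements]


def link_tracks(
    frames: list[list[CellMeasurement]],
    max_displacement_px: float = 30.0,
) -> list[CellTrack]:
    """Link per-frame measurements into tracks by greedy nearest-centroid
    matching.

    Candidate frame-to-frame pairs are taken in ascending centroid
    distance; pairs beyond ``max_displacement_px`` are rejected.  Tracks
    unmatched in the next frame terminate with a disappearance timed at
    the midpoint of the bracketing frame interval; unmatched new objects
    start new tracks.  Near-coincident centroids (<1 px apart) are logged
    and resolved deterministically in favour of the lower track id.
    """
    if len(frames) < 1:
        raise ValueError("at least one frame of measurements is required")
    if max_displacement_px <= 0:
        raise ValueError("max_displacement_px must be positive")

    tracks: list[CellTrack] = []
    next_id = 0
    active: list[CellTrack] = []
    for m in frames[0]:
        tr = CellTrack(cell_id=next_id, measurements=[m])
        next_id += 1
        tracks.append(tr)
        active.append(tr)

    for fi in range(1, len(frames)):
        current = frames[fi]
        prev_pts = np.array(
            [tr.measurements[-1].centroid for tr in active], dtype=float
        ).reshape(len(active), 2)
        cur_pts = np.array(
            [m.centroid for m in current], dtype=float
        ).reshape(len(current), 2)

        # warn about ambiguous near-duplicate positions
        for pts, what in ((prev_pts, "previous"), (cur_pts, "current")):
            if len(pts) > 1:
                d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
                np.fill_diagonal(d, np.inf)
                if d.min() < 1.0:
                    logger.warning(
                        "near-duplicate %s-frame positions (<1 px); "
                        "ties broken by lower track id", what,
                    )

        if len(active) and len(current):
            dist = np.linalg.norm(
                prev_pts[:, None, :] - cur_pts[None, :, :], axis=-1
            )
            # ascending distance, ties by lower previous id then current index
            order = sorted(
                ((dist[i, j], i, j) for i in range(len(active))
                 for j in range(len(current)) if dist[i, j] <= max_displacement_px),
                key=lambda t: (t[0], t[1], t[2]),
            )
        else:
            order = []

        matched_prev: set[int] = set()
        matched_cur: set[int] = set()
        for _, i, j in order:
            if i in matched_prev or j in matched_cur:
                continue
            matched_prev.add(i)
            matched_cur.add(j)
            active[i].measurements.append(current[j])

        t_prev = None
        t_cur = current[0].timepoint_h if current else None
        survivors: list[CellTrack] = []
        for i, tr in enumerate(active):
            if i in matched_prev:
                survivors.append(tr)
            else:
                t_last = tr.measurements[-1].timepoint_h
                t_next = t_cur if t_cur is not None else t_last
                tr.disappeared_at_h = 0.5 * (t_last + t_next)
        del t_prev
        for j, m in enumerate(current):
            if j not in matched_cur:
                tr = CellTrack(cell_id=next_id, measurements=[m])
                next_id += 1
                tracks.append(tr)
                survivors.append(tr)
        active = survivors

    return tracks


def classify_fate(
    track: CellTrack,
    calib: GEDICalibration,
    horizon_h: float,
    group: str = "",
) -> SurvivalRecord | None:
    """Convert one track into a survival record.

    The death time is the earliest of (a) the first frame whose ratio
    exceeds the calibrated threshold (right-endpoint convention) and
    (b) the track's disappearance midpoint.  With neither by ``horizon_h``
    the cell is censored at the horizon.  Tracks whose measurements are
    all flagged (zero red signal) are excluded and None is returned.
    """
    if not track.measurements:
        raise ValueError("track has no measurements")
    usable = [m for m in track.measurements if not m.flagged]
    if not usable:
        logger.warning(
            "track %d excluded: all measurements flagged", track.cell_id
        )
        return None

    crossing_t: float | None = None
    for m in usable:
        if np.isfinite(m.gedi_ratio) and m.gedi_ratio > calib.threshold:
            crossing_t = m.timepoint_h
            break

    events: list[tuple[float, str]] = []
    if crossing_t is not None:
        events.append((crossing_t, "ratio_crossing"))
    if track.disappeared_at_h is not None:
        events.append((track.disappeared_at_h, "disappearance"))

    if events:
        t, mode = min(events, key=lambda e: e[0])
        if t <= horizon_h:
            return SurvivalRecord(
                cell_id=track.cell_id, group=group, time_h=float(t),
                event=1, death_mode=mode,
            )
    return SurvivalRecord(
        cell_id=track.cell_id, group=group, time_h=float(horizon_h),
        event=0, death_mode="none",
    )
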