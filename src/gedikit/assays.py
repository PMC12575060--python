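"""Ancillary assays: clonogenic colony growth and flow-cytometry gating.

Colony images are background-flattened (rolling ball), thresholded and
labelled per frame; colonies are linked across imaging days by centroid
proximity and each colony's growth is summarized as the least-squares
slope of log-area against frame index.  Flow-cytometry positivity is
gated above the upper tail of the matched unstained control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imageops import segment_cells, subtract_background_rolling_ball
from .stack import ImageStack
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["ColonyResult", "GateResult", "quantify_colonies", "gate_flow_events"]


@dataclass
class ColonyResult:
    """Per-frame colony areas plus per-colony fitted growth rates.

    ``records``: colony_id, frame, day, row, col, area_px.
    ``growth``: colony_id, growth_rate_per_frame (log-area slope),
    n_frames, flagged (True when the colony was lost in some frame and
    the fit used a shorter span).
    """

    records: pd.DataFrame
    growth: pd.DataFrame


def quantify_colonies(
    image_series: ImageStack,
    threshold_method: str = "otsu",
    manual_threshold: float | None = None,
    min_area_px: int = 50,
    rolling_ball_radius_px: float = 50.0,
    link_max_px: float = 15.0,
    channel: str | None = None,
) -> ColonyResult:
    """Quantify colony areas over an imaging series and fit growth rates.

    Each frame is rolling-ball corrected, thresholded (Otsu or manual) and
    labelled; objects below ``min_area_px`` are discarded.  Colonies are
    linked frame-to-frame by nearest centroid within ``link_max_px``.
    Growth is the least-squares slope of ln(area) on frame index,
    requiring at least 2 observed frames; colonies observed in fewer
    frames than the series are flagged.
    """
    if image_series.n_timepoints < 2:
        raise ValueError("need >= 2 frames to fit colony growth")
    ch = channel or image_series.channel_names[0]

    rows: list[dict] = []
    # colony registry: id -> last centroid
    last_seen: dict[int, tuple[float, float]] = {}
    next_id = 0
    for f in range(image_series.n_timepoints):
        img = subtract_background_rolling_ball(
            image_series.frame(f, ch), rolling_ball_radius_px
        )
        mask = segment_cells(
            img,
            method=threshold_method,
            manual_threshold=manual_threshold,
            min_area_px=min_area_px,
        )
        labels = mask.labels
        ids = mask.object_ids
        if ids.size:
            areas = ndimage.sum_labels(np.ones_like(labels), labels, ids)
            coms = ndimage.center_of_mass(np.ones_like(labels), labels, ids)
        else:
            areas, coms = [], []

        # greedy nearest-centroid assignment to known colonies
        assigned: dict[int, int] = {}
        if last_seen and len(coms):
            known = list(last_seen.items())
            pairs = sorted(
                (
                    (np.hypot(c[0] - kc[0], c[1] - kc[1]), ki, j)
                    for ki, (_, kc) in enumerate(known)
                    for j, c in enumerate(coms)
                ),
            )
            used_known: set[int] = set()
            for d, ki, j in pairs:
                if d > link_max_px or ki in used_known or j in assigned:
                    continue
                assigned[j] = known[ki][0]
                used_known.add(ki)
        for j in range(len(coms)):
            if j not in assigned:
                assigned[j] = next_id
                next_id += 1
        for j, com in enumerate(coms):
            cid = assigned[j]
            last_seen[cid] = (float(com[0]), float(com[1]))
            rows.append(
                {
                    "colony_id": cid,
                    "frame": f,
                    "day": float(image_series.timepoints_h[f]),
                    "row": float(com[0]),
                    "col": float(com[1]),
                    "area_px": float(areas[j]),
                }
            )

    records = pd.DataFrame(
        rows, columns=["colony_id", "frame", "day", "row", "col", "area_px"]
    )
    growth_rows = []
    n_frames_total = image_series.n_timepoints
    for cid, sub in records.groupby("colony_id"):
        frames = sub["frame"].to_numpy(dtype=float)
        la = np.log(sub["area_px"].to_numpy(dtype=float))
        if len(frames) < 2:
            slope = np.nan
        else:
            slope = float(np.polyfit(frames, la, 1)[0])
        flagged = len(frames) < n_frames_total
        if flagged:
            logger.warning(
                "colony %d seen in %d/%d frames; growth fitted on the "
                "available span", cid, len(frames), n_frames_total,
            )
        growth_rows.append(
            {
                "colony_id": cid,
                "growth_rate_per_frame": slope,
                "n_frames": int(len(frames)),
                "flagged": flagged,
            }
        )
    growth = pd.DataFrame(
        growth_rows,
        columns=["colony_id", "growth_rate_per_frame", "n_frames", "flagged"],
    )
    return ColonyResult(records=records, growth=growth)


@dataclass
class GateResult:
    """Positivity gate derived from an unstained control.

    ``gate_threshold`` sits in the upper tail of the unstained
    distribution; ``percent_positive`` is the share of stained events
    above it; MFIs are arithmetic means unless gated geometrically.
    """

    gate_threshold: float
    percent_positive: float
    mfi_positive: float
    mfi_all: float
    n_events: int


def _fluorescence(events) -> np.ndarray:
    if isinstance(events, pd.DataFrame):
        df = events
        if "is_singlet" in df.columns:
            df = df[df["is_singlet"].astype(bool)]
        return df["fl_bb515"].to_numpy(dtype=float)
    return np.asarray(events, dtype=float)


def gate_flow_events(
    stained_events,
    unstained_events,
    percentile: float = 99.5,
    geometric_mfi: bool = False,
) -> GateResult:
    """Gate stained events above the unstained control distribution.

    The gate is the given percentile (default 99.5) of the unstained
    fluorescence; ``percent_positive`` is the percentage of stained
    events above the gate.  MFI is reported for the positive events and
    for all stained events (arithmetic mean by convention; geometric on
    request).  Requires >= 100 unstained events with nonzero spread.
    """
    stained = _fluorescence(stained_events)
    unstained = _fluorescence(unstained_events)
    if unstained.size < 100:
        raise ValueError("need >= 100 unstained events to place the gate")
    if np.ptp(unstained) == 0:
        raise ValueError("unstained distribution is degenerate (zero variance)")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    gate = float(np.percentile(unstained, percentile))
    positive = stained > gate
    pct = 100.0 * positive.mean() if stained.size else 0.0

    def _mfi(x: np.ndarray) -> float:
        if x.size == 0:
            return float("nan")
        if geometric_mfi:
            return float(np.exp(np.mean(np.log(x[x > 0]))))
        return float(x.mean())

    return GateResult(
        gate_threshold=gate,
        percent_positive=float(pct),
        mfi_positive=_mfi(stained[positive]),
        mfi_all=_mfi(stained),
        n_events=int(stained.size),
    )
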