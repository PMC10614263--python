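"""Process-extension detection and the stability index.

The core measurement: a *new process extension* is a connected set of pixels
occupied at frame t but not at frame t-1, adjacent to a cell's existing
footprint. An extension that stays in place for at least the persistence
threshold (3 min by default — 3 frames at 1 frame/min) is *stable*; the
stability index of a cell is stable extensions divided by all extensions.
Low values mean restless, destabilized processes.

"Stays in place" is operationalized as: in every frame of the window, at
least ``overlap_fraction`` (default 0.5) of the onset footprint is still
occupied, after dilating the frame mask by 1 px to tolerate single-pixel
breathing of the binarized outline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.measure import label, regionprops

from .errors import ParameterError
from .preprocess import ProjectedSeries
from .segmentation import CellSegmentation

__all__ = [
    "ExtensionEvent", "StabilityResult",
    "detect_extensions", "classify_stability", "stability_index",
    "stability_threshold_frames", "score_series",
]

log = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class ExtensionEvent:
    """One detected process extension."""

    cell_id: int
    onset_frame: int
    footprint: Tuple[np.ndarray, np.ndarray]  # (rows, cols) at onset
    n_pixels: int
    persistence_frames: Optional[int] = None
    stable: Optional[bool] = None


@dataclass
class StabilityResult:
    """Stable/total extension counts for one cell (or pooled)."""

    cell_id: Optional[int]
    n_events: int
    n_stable: int
    undefined: bool

    @property
    def stability_index(self) -> float:
        return float("nan") if self.undefined else self.n_stable / self.n_events


def stability_threshold_frames(frame_interval_s: float,
                               min_persistence_s: float = 180.0) -> int:
    """Frames an extension must persist to count as stable.

    ``ceil(min_persistence_s / frame_interval_s)``: at 60 s/frame the default
    180 s window is 3 frames — present at onset and the two following frames.
    """
    if frame_interval_s <= 0:
        raise ParameterError(
            f"frame_interval_s must be > 0, got {frame_interval_s}")
    if min_persistence_s <= 0:
        raise ParameterError(
            f"min_persistence_s must be > 0, got {min_persistence_s}")
    return int(math.ceil(min_persistence_s / frame_interval_s))


def detect_extensions(binary_series: ProjectedSeries,
                      seg: CellSegmentation,
                      min_event_px: int = 4) -> List[ExtensionEvent]:
    """Find new process extensions in a registered, binarized series.

    For each frame t >= 1, connected components of (present at t) AND
    (absent at t-1) that touch the previous frame's foreground and have at
    least ``min_event_px`` pixels become events, assigned to the nearest
    segmented cell. Components touching no existing foreground are discarded
    as noise, as are sub-threshold flickers.
    """
    if binary_series.n_frames < 2:
        raise ParameterError("detect_extensions needs >= 2 frames")
    if not binary_series.is_binary:
        raise ParameterError("detect_extensions requires a binarized series")
    if not (binary_series.has_correction("correct_drift")
            or binary_series.has_correction("synthetic")):
        log.warning("detect_extensions: series has no drift-correction "
                    "provenance; residual drift will inflate event counts")
    masks = np.asarray(binary_series.data, dtype=bool)
    # nearest-cell lookup from the segmentation label image
    bg = seg.label_image == 0
    if bg.all():
        nearest = np.zeros_like(seg.label_image)
    else:
        _, (iy, ix) = ndi.distance_transform_edt(bg, return_indices=True)
        nearest = seg.label_image[iy, ix]
    events: List[ExtensionEvent] = []
    for t in range(1, masks.shape[0]):
        new = masks[t] & ~masks[t - 1]
        if not new.any():
            continue
        lbl = label(new, connectivity=2)
        for region in regionprops(lbl):
            if region.area < min_event_px:
                continue
            comp = lbl == region.label
            touch = ndi.binary_dilation(comp, _STRUCT8) & masks[t - 1]
            if not touch.any():
                continue  # not adjacent to any existing process
            rows, cols = np.nonzero(comp)
            cids, counts = np.unique(nearest[rows, cols], return_counts=True)
            order = np.argsort(-counts)
            cid = 0
            for k in order:
                if cids[k] != 0:
                    cid = int(cids[k])
                    break
            if cid == 0:
                continue  # no segmented cell anywhere near
            events.append(ExtensionEvent(
                cell_id=cid, onset_frame=t, footprint=(rows, cols),
                n_pixels=int(rows.size)))
    return events


def classify_stability(events: List[ExtensionEvent],
                       binary_series: ProjectedSeries,
                       stability_threshold_frames: int = 3,
                       overlap_fraction: float = 0.5,
                       footprint_dilation_px: int = 1) -> List[ExtensionEvent]:
    """Fill persistence and the stable flag on detected events.

    ``persistence_frames`` is the largest k such that in every frame
    onset..onset+k-1 at least ``overlap_fraction`` of the onset footprint is
    occupied (frame masks dilated by ``footprint_dilation_px``). Counting is
    inclusive of the onset frame, so persistence >= 1 always, and an event
    is stable iff persistence >= ``stability_threshold_frames``.
    """
    n_frames = binary_series.n_frames
    if stability_threshold_frames > n_frames:
        raise ParameterError(
            f"stability_threshold_frames={stability_threshold_frames} exceeds "
            f"series length {n_frames}")
    if stability_threshold_frames < 1:
        raise ParameterError("stability_threshold_frames must be >= 1")
    masks = np.asarray(binary_series.data, dtype=bool)
    if footprint_dilation_px > 0:
        dilated = np.stack([
            ndi.binary_dilation(m, _STRUCT8, iterations=footprint_dilation_px)
            for m in masks])
    else:
        dilated = masks
    out = []
    for ev in events:
        rows, cols = ev.footprint
        persistence = 0
        for f in range(ev.onset_frame, n_frames):
            frac = dilated[f][rows, cols].mean()
            if frac >= overlap_fraction:
                persistence += 1
            else:
                break
        out.append(ExtensionEvent(
            cell_id=ev.cell_id, onset_frame=ev.onset_frame,
            footprint=ev.footprint, n_pixels=ev.n_pixels,
            persistence_frames=persistence,
            stable=persistence >= stability_threshold_frames))
    return out


def stability_index(events: List[ExtensionEvent],
                    per_cell: bool = True) -> List[StabilityResult]:
    """Stable/total ratio per cell (or pooled across cells).

    Cells with zero events yield an ``undefined`` result carrying no number;
    they are excluded (with a logged count) from group statistics upstream.
    """
    for ev in events:
        if ev.stable is None:
            raise ParameterError(
                "stability_index requires classified events "
                "(run classify_stability first)")
    if not per_cell:
        n = len(events)
        return [StabilityResult(None, n, sum(e.stable for e in events),
                                undefined=(n == 0))]
    results = []
    for cid in sorted({e.cell_id for e in events}):
        evs = [e for e in events if e.cell_id == cid]
        results.append(StabilityResult(
            cid, len(evs), sum(e.stable for e in evs), undefined=False))
    return results


def score_series(binary_series: ProjectedSeries, seg: CellSegmentation,
                 min_event_px: int = 4,
                 min_persistence_s: float = 180.0,
                 overlap_fraction: float = 0.5,
                 footprint_dilation_px: int = 1,
                 per_cell: bool = True) -> Tuple[List[ExtensionEvent], List[StabilityResult]]:
    """Detect, classify and score in one call; thresholds given in seconds."""
    thr = stability_threshold_frames(binary_series.frame_interval_s,
                                     min_persistence_s)
    events = detect_extensions(binary_series, seg, min_event_px)
    events = classify_stability(events, binary_series, thr, overlap_fraction,
                                footprint_dilation_px)
    return events, stability_index(events, per_cell=per_cell)


def events_to_dataframe(events: List[ExtensionEvent]) -> pd.DataFrame:
    rows = [
        {"cell_id": e.cell_id, "onset_frame": e.onset_frame,
         "n_pixels": e.n_pixels, "persistence_frames": e.persistence_frames,
         "stable": e.stable}
        for e in events
    ]
    return pd.DataFrame(rows, columns=["cell_id", "onset_frame", "n_pixels",
                                       "persistence_frames", "stable"])


def results_to_dataframe(results: List[StabilityResult]) -> pd.DataFrame:
    rows = [
        {"cell_id": r.cell_id, "n_events": r.n_events, "n_stable": r.n_stable,
         "stability_index": r.stability_index, "undefined": r.undefined}
        for r in results
    ]
    return pd.DataFrame(rows, columns=["cell_id", "n_events", "n_stable",
                                       "stability_index", "undefined"])
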