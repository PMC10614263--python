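"""From raw 4D stacks to the corrected 2D+time series that gets scored.

The scoring algorithm compares pixel occupancy between consecutive frames, so
every correction here is chosen to avoid creating spurious occupancy changes:
maximum-intensity z-projection, integer-pixel translation registration to
frame 0 (phase correlation; subpixel interpolation would smear binary masks),
frame-mean bleach normalization, and a single binarization threshold computed
on frame 0 and applied to all frames (per-frame thresholds would turn
threshold jitter into fake extension/retraction events).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .errors import ParameterError

__all__ = [
    "TimeLapseStack", "ProjectedSeries",
    "max_project", "correct_drift", "correct_bleach", "binarize",
    "preprocess_stack",
]

log = logging.getLogger(__name__)


@dataclass
class TimeLapseStack:
    """Raw 4D intensity data (frame, z, y, x) with physical calibration.

    Every µm / µm² number downstream derives from ``pixel_size_um``.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    z_step_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ParameterError(
                f"data must be 4D (frame, z, y, x), got shape {self.data.shape}")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        for name in ("pixel_size_um", "frame_interval_s", "z_step_um"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]


@dataclass
class ProjectedSeries:
    """2D+time series (frame, y, x) plus the provenance of its corrections.

    ``provenance`` is an ordered list of dicts, one per applied operation,
    holding the estimated parameters (per-frame shifts, bleach factors, the
    binarization threshold).
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    provenance: List[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError(
                f"data must be 3D (frame, y, x), got shape {self.data.shape}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def is_binary(self) -> bool:
        return self.data.dtype == bool

    def has_correction(self, op: str) -> bool:
        return any(p.get("op") == op for p in self.provenance)

    def with_data(self, data: np.ndarray, entry: Optional[dict] = None) -> "ProjectedSeries":
        prov = [dict(p) for p in self.provenance]
        if entry is not None:
            prov.append(entry)
        return ProjectedSeries(data, self.pixel_size_um, self.frame_interval_s, prov)


def max_project(stack: TimeLapseStack,
                z_range_um: Optional[Tuple[float, float]] = None) -> ProjectedSeries:
    """Maximum-intensity z-projection over an optional slab.

    ``z_range_um`` selects planes whose depth ``z * z_step_um`` lies in the
    closed interval; by default all planes are used.
    """
    if z_range_um is None:
        lo, hi = 0, stack.n_z
    else:
        z0, z1 = z_range_um
        depths = np.arange(stack.n_z) * stack.z_step_um
        sel = np.flatnonzero((depths >= z0) & (depths <= z1))
        if sel.size == 0:
            raise ParameterError(
                f"z_range_um {z_range_um} selects no planes "
                f"(stack depth {depths[-1]:g} µm)")
        lo, hi = int(sel[0]), int(sel[-1]) + 1
    proj = stack.data[:, lo:hi].max(axis=1)
    return ProjectedSeries(
        proj, stack.pixel_size_um, stack.frame_interval_s,
        [{"op": "max_project", "z_planes": [lo, hi]}])


def correct_drift(series: ProjectedSeries) -> ProjectedSeries:
    """Register every frame to frame 0 by integer-pixel translation.

    Shifts are estimated by phase correlation against frame 0 (not pairwise,
    so estimation error cannot accumulate) and recorded in provenance as the
    correction applied to each frame. Pixels shifted in from outside the
    field are filled with the frame's median (background) intensity.
    """
    if series.n_frames < 2:
        raise ParameterError("correct_drift needs >= 2 frames")
    ref = np.asarray(series.data[0], dtype=float)
    out = np.empty_like(series.data, dtype=float)
    out[0] = ref
    shifts: List[Tuple[int, int]] = [(0, 0)]
    for t in range(1, series.n_frames):
        frame = np.asarray(series.data[t], dtype=float)
        if frame.std() == 0 or ref.std() == 0:
            log.warning("correct_drift: degenerate (constant) frame %d; "
                        "assuming zero shift", t)
            sy = sx = 0
        else:
            shift, _, _ = phase_cross_correlation(ref, frame, normalization=None)
            sy, sx = int(round(shift[0])), int(round(shift[1]))
        if (sy, sx) != (0, 0):
            fill = float(np.median(frame))
            frame = ndi.shift(frame, (sy, sx), order=0, cval=fill)
        out[t] = frame
        shifts.append((sy, sx))
    return series.with_data(out, {"op": "correct_drift",
                                  "shifts_px": [list(s) for s in shifts]})


def correct_bleach(series: ProjectedSeries, method: str = "mean_ratio") -> ProjectedSeries:
    """Undo photobleaching by normalizing per-frame mean intensity.

    ``mean_ratio`` rescales frame t by mean(frame 0)/mean(frame t), which
    makes the frame-mean exactly constant. ``exp_fit`` instead fits a single
    exponential decay to the frame means and divides it out, which is more
    robust when the cells themselves change brightness.
    """
    means = np.asarray([float(np.mean(f)) for f in series.data])
    for t, m in enumerate(means):
        if m <= 0:
            raise ParameterError(
                f"correct_bleach: frame {t} has non-positive mean {m}")
    if method == "mean_ratio":
        factors = means[0] / means
    elif method == "exp_fit":
        t = np.arange(series.n_frames)
        slope, _ = np.polyfit(t, np.log(means), 1)
        factors = np.exp(-slope * t)  # divide out only the fitted decay
    else:
        raise ParameterError(f"unknown bleach correction method {method!r}")
    out = np.asarray(series.data, dtype=float) * factors[:, None, None]
    return series.with_data(out, {"op": "correct_bleach", "method": method,
                                  "factors": [float(f) for f in factors]})


def binarize(series: ProjectedSeries, method: str = "otsu_frame0",
             threshold: Optional[float] = None) -> ProjectedSeries:
    """Threshold the intensity series into a binary occupancy series.

    With ``otsu_frame0`` a single Otsu threshold computed on frame 0 is
    applied to every frame; with ``fixed`` the given threshold is used.
    """
    if method == "otsu_frame0":
        frame0 = np.asarray(series.data[0], dtype=float)
        if frame0.min() == frame0.max():
            log.warning("binarize: frame 0 is constant; output is all background")
            thr = np.inf
        else:
            thr = float(threshold_otsu(frame0))
    elif method == "fixed":
        if threshold is None:
            raise ParameterError("binarize: method 'fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ParameterError(f"unknown binarize method {method!r}")
    binary = np.asarray(series.data, dtype=float) > thr
    for t in range(series.n_frames):
        if not binary[t].any():
            log.warning("binarize: frame %d has no foreground pixels", t)
    return series.with_data(binary, {"op": "binarize", "method": method,
                                     "threshold": thr})


def preprocess_stack(stack: TimeLapseStack,
                     z_range_um: Optional[Tuple[float, float]] = None,
                     threshold_method: str = "otsu_frame0",
                     threshold: Optional[float] = None,
                     ) -> Tuple[ProjectedSeries, ProjectedSeries]:
    """Full correction chain: project, register, de-bleach, binarize.

    Returns ``(corrected_intensity, binary)`` — the intensity series after
    drift and bleach correction, and its binarization.
    """
    series = max_project(stack, z_range_um)
    series = correct_drift(series)
    series = correct_bleach(series)
    binary = binarize(series, method=threshold_method, threshold=threshold)
    return series, binary
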