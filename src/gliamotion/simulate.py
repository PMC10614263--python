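"""Ground-truthed synthetic microglia time-lapse generator.

Geometry model: each cell is a disk soma with a handful of piecewise-linear
primary processes grown from the soma rim. Process motility is simulated at
the tips: per frame, each free tip may sprout a new terminal extension
(probability ``extension_prob``); the extension is persistent with
probability ``stable_fraction`` (it remains through the final frame and the
tip advances to its end) or transient (it retracts after
``unstable_lifetime_frames``). Every realized extension is recorded as a
ground-truth event with its onset frame, pixel footprint and stability
label, so the detection/classification pipeline can be scored against truth.

Rendering order is fixed — geometry, PSF blur, then artifacts (drift, bleach,
shot noise), matching physical image formation — and a single explicitly
seeded RNG stream drives everything, so identical seed + config gives
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.ndimage as ndi
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk as disk_footprint

from .config import SimulationConfig
from .errors import ParameterError, SpecificationError
from .preprocess import ProjectedSeries, TimeLapseStack

__all__ = [
    "TrueExtensionEvent", "CellTruth", "GroundTruth",
    "simulate_timelapse", "make_toy_binary_series", "apply_artifacts",
]

# minimum novel pixels for a sprouted segment to count as an event;
# smaller candidates (mostly re-occupying retracted ground) are skipped
_MIN_EVENT_FOOTPRINT_PX = 6


@dataclass
class TrueExtensionEvent:
    """One ground-truth process extension."""

    cell_id: int
    onset_frame: int
    footprint: Tuple[np.ndarray, np.ndarray]  # (rows, cols) of novel pixels
    lifetime_frames: int                      # frames present from onset
    stable: bool

    @property
    def n_pixels(self) -> int:
        return int(self.footprint[0].size)


@dataclass
class CellTruth:
    cell_id: int
    center_yx: Tuple[float, float]
    soma_radius_um: float
    process_length_um: np.ndarray  # per-frame total process length

    @property
    def soma_perimeter_um(self) -> float:
        return 2.0 * math.pi * self.soma_radius_um


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    cells: List[CellTruth]
    events: List[TrueExtensionEvent]
    drift_px: np.ndarray        # (n_frames, 2) cumulative applied (dy, dx)
    bleach_factors: np.ndarray  # (n_frames,) multiplicative intensity decay
    frame_masks: Optional[List[np.ndarray]] = None  # clean 2D occupancy per frame

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_stable(self) -> int:
        return sum(e.stable for e in self.events)

    @property
    def stability_index(self) -> float:
        """True stable/total fraction; NaN (undefined) when no events."""
        if not self.events:
            return float("nan")
        return self.n_stable / self.n_events

    @property
    def undefined(self) -> bool:
        return not self.events

    def events_dataframe(self) -> pd.DataFrame:
        rows = [
            {"cell_id": e.cell_id, "onset_frame": e.onset_frame,
             "n_pixels": e.n_pixels, "lifetime_frames": e.lifetime_frames,
             "stable": e.stable}
            for e in self.events
        ]
        return pd.DataFrame(
            rows, columns=["cell_id", "onset_frame", "n_pixels",
                           "lifetime_frames", "stable"])

    def summary(self) -> dict:
        return {
            "n_cells": len(self.cells),
            "n_events": self.n_events,
            "n_stable": self.n_stable,
            "stability_index": None if self.undefined else self.stability_index,
            "undefined": self.undefined,
        }


@dataclass
class _Tip:
    cell_id: int
    pos: Tuple[float, float]   # (y, x)
    angle: float
    busy_until: int = -1       # last frame occupied by a transient extension


def _thick_segment_mask(shape: Tuple[int, int], p0, p1, width_radius: int = 1) -> np.ndarray:
    """Boolean mask of a line segment dilated to ~(2*width_radius+1) px wide."""
    mask = np.zeros(shape, dtype=bool)
    r0, c0 = int(round(p0[0])), int(round(p0[1]))
    r1, c1 = int(round(p1[0])), int(round(p1[1]))
    rr, cc = draw_line(r0, c0, r1, c1)
    ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    mask[rr[ok], cc[ok]] = True
    if width_radius > 0:
        mask = dilation(mask, disk_footprint(width_radius))
    return mask


def _build_cells(cfg: SimulationConfig, rng: np.random.Generator):
    """Lay out somata on a jittered grid and grow primary processes."""
    size = cfg.image_size
    px = cfg.pixel_size_um
    soma_r_px = cfg.soma_radius_um / px
    reach_px = (cfg.soma_radius_um + cfg.process_length_um
                + 4 * cfg.extension_length_um) / px

    k = max(1, math.ceil(math.sqrt(cfg.n_cells)))
    spacing = size / k
    cells, tips = [], []
    base_masks = []
    for i in range(cfg.n_cells):
        gy, gx = divmod(i, k)
        jit = min(4.0, max(0.0, spacing / 2 - reach_px))
        cy = spacing * (gy + 0.5) + rng.uniform(-jit, jit)
        cx = spacing * (gx + 0.5) + rng.uniform(-jit, jit)
        mask = np.zeros((size, size), dtype=bool)
        rr, cc = draw_disk((cy, cx), soma_r_px, shape=(size, size))
        mask[rr, cc] = True

        proc_len_um = 0.0
        base_angle = rng.uniform(0, 2 * math.pi)
        for j in range(cfg.n_primary_processes):
            ang = base_angle + 2 * math.pi * j / cfg.n_primary_processes \
                + rng.uniform(-0.2, 0.2)
            p = (cy + soma_r_px * math.sin(ang), cx + soma_r_px * math.cos(ang))
            # two sub-segments with slight bend
            for _ in range(2):
                seg_len_px = (cfg.process_length_um / 2) / px
                a = ang + rng.uniform(-0.25, 0.25)
                q = (p[0] + seg_len_px * math.sin(a),
                     p[1] + seg_len_px * math.cos(a))
                mask |= _thick_segment_mask((size, size), p, q)
                proc_len_um += seg_len_px * px
                p, ang = q, a
            tips.append(_Tip(cell_id=i + 1, pos=p, angle=ang))
        base_masks.append(mask)
        cells.append(CellTruth(
            cell_id=i + 1, center_yx=(cy, cx),
            soma_radius_um=cfg.soma_radius_um,
            process_length_um=np.full(cfg.n_frames, proc_len_um)))
    return cells, tips, base_masks


def _simulate_masks(cfg: SimulationConfig, rng: np.random.Generator):
    """Run tip kinetics; return per-frame global masks, cells, events."""
    size = cfg.image_size
    px = cfg.pixel_size_um
    ext_len_px = cfg.extension_length_um / px
    cells, tips, base_masks = _build_cells(cfg, rng)
    base_global = (np.logical_or.reduce(base_masks)
                   if base_masks else np.zeros((size, size), dtype=bool))

    events: List[TrueExtensionEvent] = []
    # per-event pixel masks kept for frame composition
    event_masks: List[np.ndarray] = []
    frame_masks: List[np.ndarray] = [base_global.copy()]
    last_onset = cfg.n_frames - cfg.stable_min_frames

    for t in range(1, cfg.n_frames):
        prev = frame_masks[t - 1]
        if t <= last_onset:
            for tip in tips:
                if t <= tip.busy_until + 1:  # occupied, or retracted last frame
                    continue
                if rng.random() >= cfg.extension_prob:
                    continue
                stable = rng.random() < cfg.stable_fraction
                ang = tip.angle + rng.uniform(-0.9, 0.9)
                q = (tip.pos[0] + ext_len_px * math.sin(ang),
                     tip.pos[1] + ext_len_px * math.cos(ang))
                if not (2 <= q[0] < size - 2 and 2 <= q[1] < size - 2):
                    continue
                seg = _thick_segment_mask((size, size), tip.pos, q)
                novel = seg & ~prev
                if novel.sum() < _MIN_EVENT_FOOTPRINT_PX:
                    continue
                lifetime = (cfg.n_frames - t) if stable \
                    else cfg.unstable_lifetime_frames
                events.append(TrueExtensionEvent(
                    cell_id=tip.cell_id, onset_frame=t,
                    footprint=np.nonzero(novel),
                    lifetime_frames=lifetime, stable=stable))
                event_masks.append(seg)
                for cell in cells:
                    if cell.cell_id == tip.cell_id:
                        end = min(cfg.n_frames, t + lifetime)
                        cell.process_length_um[t:end] += cfg.extension_length_um
                if stable:
                    tip.pos, tip.angle = q, ang
                else:
                    tip.busy_until = t + lifetime
        frame = base_global.copy()
        for ev, m in zip(events, event_masks):
            if ev.onset_frame <= t < ev.onset_frame + ev.lifetime_frames:
                frame |= m
        frame_masks.append(frame)
    return frame_masks, cells, events


def _render_clean_stack(cfg: SimulationConfig, frame_masks, cells,
                        rng: np.random.Generator) -> np.ndarray:
    """Embed per-frame 2D masks into z and apply the PSF blur."""
    size, n_z = cfg.image_size, cfg.n_z
    sigma_px = cfg.psf_sigma_um / cfg.pixel_size_um
    # cells occupy a Gaussian band of z-planes around the slab center; the
    # max projection downstream recovers the full-intensity 2D geometry
    z_center = n_z / 2 + rng.uniform(-1, 1)
    z_sigma = max(1.0, n_z / 6)
    weights = np.exp(-0.5 * ((np.arange(n_z) - z_center) / z_sigma) ** 2)
    stack = np.zeros((cfg.n_frames, n_z, size, size), dtype=np.float32)
    for t, mask in enumerate(frame_masks):
        plane2d = mask.astype(np.float32)
        if sigma_px > 0:
            plane2d = ndi.gaussian_filter(plane2d, sigma_px)
        for z in range(n_z):
            if weights[z] <= 1e-4:
                continue
            stack[t, z] = plane2d * weights[z]
    stack += cfg.background_level
    return stack


def simulate_timelapse(config: SimulationConfig) -> Tuple[TimeLapseStack, GroundTruth]:
    """Simulate a calibrated 4D time-lapse stack plus its ground truth.

    The clean geometry is rendered first; drift, bleach and shot noise are
    applied afterwards by :func:`apply_artifacts` in that order. Ground-truth
    footprints are expressed in undrifted (frame-0) coordinates, which is the
    frame of reference restored by drift correction.
    """
    rng = np.random.default_rng(config.seed)
    frame_masks, cells, events = _simulate_masks(config, rng)
    clean = _render_clean_stack(config, frame_masks, cells, rng)
    stack = TimeLapseStack(clean, config.pixel_size_um,
                           config.frame_interval_s, config.z_step_um)
    noise_seed = int(rng.integers(0, 2**31 - 1))
    stack = apply_artifacts(stack, drift=config.drift_px_per_frame,
                            bleach_rate=config.bleach_rate,
                            noise_scale=config.noise_scale, seed=noise_seed)
    t_idx = np.arange(config.n_frames)
    drift = np.outer(t_idx, np.asarray(config.drift_px_per_frame, dtype=float))
    gt = GroundTruth(cells=cells, events=events, drift_px=drift,
                     bleach_factors=np.exp(-config.bleach_rate * t_idx),
                     frame_masks=frame_masks)
    return stack, gt


def apply_artifacts(stack: TimeLapseStack,
                    drift: Tuple[float, float] = (0.0, 0.0),
                    bleach_rate: float = 0.0,
                    noise_scale: float = 0.0,
                    seed: int = 0) -> TimeLapseStack:
    """Add acquisition artifacts: stage drift, photobleaching, shot noise.

    Frame t is translated by the cumulative drift ``t * (dy, dx)`` (regions
    drifting into the field are filled with the frame's median, i.e. the
    background level), multiplied by ``exp(-bleach_rate * t)``, and finally
    Poisson shot noise is applied at a photon scale of ``noise_scale`` counts
    per intensity unit. With all three parameters zero the output equals the
    input exactly.
    """
    data = np.asarray(stack.data, dtype=np.float32).copy()
    dy, dx = float(drift[0]), float(drift[1])
    integer_drift = float(dy).is_integer() and float(dx).is_integer()
    for t in range(stack.n_frames):
        cy, cx = dy * t, dx * t
        if cy != 0 or cx != 0:
            fill = float(np.median(data[t]))
            order = 0 if integer_drift else 1
            data[t] = ndi.shift(data[t], (0, cy, cx), order=order, cval=fill)
        if bleach_rate != 0:
            data[t] *= np.float32(np.exp(-bleach_rate * t))
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        data = (rng.poisson(np.clip(data, 0, None) * noise_scale)
                / noise_scale).astype(np.float32)
    return TimeLapseStack(data, stack.pixel_size_um, stack.frame_interval_s,
                          stack.z_step_um)


def make_toy_binary_series(
        event_spec: Sequence[Tuple[int, np.ndarray, int]],
        n_frames: int,
        base_mask: np.ndarray,
        pixel_size_um: float = 1.0,
        frame_interval_s: float = 60.0) -> ProjectedSeries:
    """Build a minimal binary series from explicit (onset, block, lifetime) events.

    The base mask is present in every frame; each block is present exactly
    during ``[onset, onset + lifetime)`` (clipped at the movie end). This is
    the oracle substrate for the extension-detection algorithm: the true
    stability of each block follows directly from its lifetime.
    """
    base = np.asarray(base_mask, dtype=bool)
    if n_frames < 1:
        raise ParameterError(f"n_frames must be >= 1, got {n_frames}")
    data = np.zeros((n_frames,) + base.shape, dtype=bool)
    data |= base[None]
    for i, (onset, block, lifetime) in enumerate(event_spec):
        block = np.asarray(block, dtype=bool)
        if block.shape != base.shape:
            raise SpecificationError(
                f"event {i}: block shape {block.shape} != base {base.shape}")
        if onset < 1:
            raise ParameterError(
                f"event {i}: onset_frame must be >= 1 (an extension needs a "
                f"preceding frame to be new), got {onset}")
        if lifetime < 1:
            raise ParameterError(f"event {i}: lifetime must be >= 1")
        if (block & base).any():
            raise SpecificationError(f"event {i}: block overlaps base_mask")
        data[onset:onset + lifetime] |= block[None]
    return ProjectedSeries(
        data, pixel_size_um, frame_interval_s,
        [{"op": "synthetic", "registered": True}])
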