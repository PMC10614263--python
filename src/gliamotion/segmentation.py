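"""Instance segmentation of microglia and Fig-2-style morphometry.

Cells are connected components of the binarized reference frame; the soma is
the disk-openable core of each component (morphological opening at a
soma-scale radius), and the phagocytic cup is operationalized as an enclosed
background cavity at a process terminal, revealed by morphological closing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import closing, dilation, disk, opening, skeletonize

from .errors import ParameterError
from .preprocess import ProjectedSeries

__all__ = [
    "CellInfo", "CellSegmentation", "MorphometryRecord",
    "segment_cells", "measure_soma_perimeter", "measure_phagocytic_cup",
    "cup_area_from_roi",
]

log = logging.getLogger(__name__)


@dataclass
class CellInfo:
    cell_id: int
    full_mask: np.ndarray   # boolean, full image
    soma_mask: np.ndarray   # boolean, subset of full_mask (may be empty)
    touches_border: bool


@dataclass
class CellSegmentation:
    """Per-pixel cell labels on a reference frame plus per-cell masks."""

    label_image: np.ndarray
    cells: Dict[int, CellInfo]
    pixel_size_um: float
    reference_frame: int = 0

    @property
    def cell_ids(self):
        return sorted(self.cells)

    def __contains__(self, cell_id: int) -> bool:
        return cell_id in self.cells

    @classmethod
    def from_single_mask(cls, mask: np.ndarray,
                         soma_mask: Optional[np.ndarray] = None,
                         pixel_size_um: float = 1.0) -> "CellSegmentation":
        """Wrap one known cell mask (e.g. a toy fixture) as a segmentation."""
        mask = np.asarray(mask, dtype=bool)
        soma = (np.zeros_like(mask) if soma_mask is None
                else np.asarray(soma_mask, dtype=bool))
        border = bool(mask[0].any() or mask[-1].any()
                      or mask[:, 0].any() or mask[:, -1].any())
        info = CellInfo(1, mask, soma & mask, border)
        return cls(mask.astype(np.int32), {1: info}, pixel_size_um)


@dataclass
class MorphometryRecord:
    """Per-cell morphometric endpoints, all in physical units."""

    cell_id: int
    soma_perimeter_um: float
    cup_area_um2: Optional[float]
    total_process_length_um: float
    n_branch_points: int
    n_endpoints: int

    def as_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "soma_perimeter_um": self.soma_perimeter_um,
            "cup_area_um2": self.cup_area_um2,
            "total_process_length_um": self.total_process_length_um,
            "n_branch_points": self.n_branch_points,
            "n_endpoints": self.n_endpoints,
        }


def segment_cells(binary_series: ProjectedSeries, reference_frame: int = 0,
                  min_area_px: int = 50,
                  soma_open_radius_um: float = 2.0) -> CellSegmentation:
    """Label individual cells on one frame of a binary series.

    Connected components (8-connectivity) of the reference frame with at
    least ``min_area_px`` pixels become cells, relabeled contiguously from 1.
    The soma of each cell is the largest connected component surviving a
    morphological opening with a disk of radius ``soma_open_radius_um``;
    components too thin to contain such a disk get an empty soma. Cells
    touching the image border are flagged and excluded from morphometry.
    """
    if not (0 <= reference_frame < binary_series.n_frames):
        raise ParameterError(
            f"reference_frame {reference_frame} outside series of "
            f"{binary_series.n_frames} frames")
    frame = np.asarray(binary_series.data[reference_frame]).astype(bool)
    raw = label(frame, connectivity=2)
    cells: Dict[int, CellInfo] = {}
    out_labels = np.zeros_like(raw, dtype=np.int32)
    radius_px = max(1, int(round(soma_open_radius_um / binary_series.pixel_size_um)))
    selem = disk(radius_px)
    next_id = 1
    for region in regionprops(raw):
        if region.area < min_area_px:
            continue
        mask = raw == region.label
        border = bool(mask[0].any() or mask[-1].any()
                      or mask[:, 0].any() or mask[:, -1].any())
        opened = opening(mask, selem)
        if opened.any():
            parts = label(opened, connectivity=2)
            best = max(regionprops(parts), key=lambda r: r.area)
            soma = parts == best.label
        else:
            soma = np.zeros_like(mask)
        cells[next_id] = CellInfo(next_id, mask, soma, border)
        out_labels[mask] = next_id
        next_id += 1
    if not cells:
        log.warning("segment_cells: no components above min_area_px=%d",
                    min_area_px)
    return CellSegmentation(out_labels, cells, binary_series.pixel_size_um,
                            reference_frame)


def _contour_length(mask: np.ndarray, smooth_sigma: float = 1.0) -> float:
    """Marching-squares boundary length of a binary mask, in pixels.

    The mask is lightly smoothed (Gaussian, 1 px) before tracing the 0.5
    level: on raw binary masks the contour staircases, overestimating smooth
    boundaries by ~5% with a ~6% rotation anisotropy; on the smoothed mask a
    digital disk measures within ~0.5% of 2*pi*r at any orientation.
    """
    import scipy.ndimage as ndi
    padded = np.pad(mask.astype(float), 3)
    if smooth_sigma > 0:
        padded = ndi.gaussian_filter(padded, smooth_sigma)
    contours = find_contours(padded, 0.5)
    if not contours:
        return 0.0
    longest = max(contours, key=lambda c: c.shape[0])
    diffs = np.diff(longest, axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def measure_soma_perimeter(seg: CellSegmentation, cell_id: int,
                           pixel_size_um: Optional[float] = None) -> float:
    """Soma boundary length in µm (marching-squares contour).

    Marching squares traces a subpixel contour, avoiding the up-to-27%
    overestimate of naive pixel-edge counting on smooth boundaries.
    """
    if cell_id not in seg:
        raise ParameterError(f"no cell with id {cell_id}")
    info = seg.cells[cell_id]
    if info.touches_border:
        raise ParameterError(
            f"cell {cell_id} touches the image border; morphometry refused")
    px = seg.pixel_size_um if pixel_size_um is None else pixel_size_um
    return _contour_length(info.soma_mask) * px


def measure_phagocytic_cup(binary_frame: np.ndarray, seg: CellSegmentation,
                           cell_id: int,
                           pixel_size_um: Optional[float] = None,
                           closing_radius_um: float = 1.0,
                           min_cup_area_px: int = 5) -> Optional[float]:
    """Projected area (µm²) of the largest terminal cup cavity, or None.

    Candidates are background cavities enclosed once a morphological closing
    seals the cup mouth (hole-filled closing minus the mask) that lie near a
    process endpoint of the cell's skeleton; the largest candidate above
    ``min_cup_area_px`` wins.
    ``None`` (absent) is a valid result for cells without cup structures.
    For real data with manually drawn cups use :func:`cup_area_from_roi`.
    """
    if cell_id not in seg:
        raise ParameterError(f"no cell with id {cell_id}")
    px = seg.pixel_size_um if pixel_size_um is None else pixel_size_um
    mask = seg.cells[cell_id].full_mask & np.asarray(binary_frame, dtype=bool)
    if not mask.any():
        mask = seg.cells[cell_id].full_mask
    radius_px = max(1, int(round(closing_radius_um / px)))
    pad = radius_px + 1
    padded = np.pad(mask, pad)
    closed = closing(padded, disk(radius_px))
    # the closing seals the cup mouth; hole-filling then exposes the whole
    # enclosed cavity even where the closing's erosion re-opened its floor
    import scipy.ndimage as ndi
    cavities = ndi.binary_fill_holes(closed) & ~padded
    cav_labels = label(cavities, connectivity=1)
    if cav_labels.max() == 0:
        return None
    # process endpoints of the cell skeleton mark candidate cup mouths
    skel = skeletonize(padded)
    neighbor_count = _neighbor_counts(skel)
    endpoints = skel & (neighbor_count == 1)
    reach = dilation(endpoints, disk(2 * radius_px + 2))
    best_area = 0
    for region in regionprops(cav_labels):
        if region.area < min_cup_area_px:
            continue
        cav = cav_labels == region.label
        if not (cav & reach).any():
            continue
        best_area = max(best_area, int(region.area))
    if best_area == 0:
        return None
    return best_area * px * px


def cup_area_from_roi(roi_mask: np.ndarray, pixel_size_um: float) -> float:
    """Area of a manually drawn cup ROI, in µm²."""
    return float(np.count_nonzero(np.asarray(roi_mask, dtype=bool))
                 * pixel_size_um ** 2)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    """8-neighbor count of each skeleton pixel (0 off-skeleton)."""
    import scipy.ndimage as ndi
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    counts = ndi.convolve(skel.astype(int), kernel, mode="constant")
    return np.where(skel, counts, 0)


def measure_all(binary_series: ProjectedSeries, seg: CellSegmentation,
                skeletons: Optional[dict] = None,
                closing_radius_um: float = 1.0,
                min_cup_area_px: int = 5) -> pd.DataFrame:
    """Morphometry table for every non-border cell of a segmentation."""
    from .morphometry import skeletonize_cell

    frame = np.asarray(binary_series.data[seg.reference_frame]).astype(bool)
    rows = []
    for cid in seg.cell_ids:
        if seg.cells[cid].touches_border:
            continue
        skel = (skeletons or {}).get(cid) or skeletonize_cell(seg, cid)
        rec = MorphometryRecord(
            cell_id=cid,
            soma_perimeter_um=measure_soma_perimeter(seg, cid),
            cup_area_um2=measure_phagocytic_cup(
                frame, seg, cid, closing_radius_um=closing_radius_um,
                min_cup_area_px=min_cup_area_px),
            total_process_length_um=skel.total_length_um,
            n_branch_points=skel.n_branch_points,
            n_endpoints=skel.n_endpoints,
        )
        rows.append(rec.as_dict())
    return pd.DataFrame(rows, columns=[
        "cell_id", "soma_perimeter_um", "cup_area_um2",
        "total_process_length_um", "n_branch_points", "n_endpoints"])
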