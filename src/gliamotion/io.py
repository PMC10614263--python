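"""Reading and writing the pipeline's on-disk formats.

Stacks travel as ImageJ-convention multi-page TIFF hyperstacks (axes TZYX)
with pixel size and frame interval embedded in the metadata; series and
tables are TIFF/CSV plus a JSON sidecar holding provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .errors import ParameterError
from .preprocess import ProjectedSeries, TimeLapseStack
from .simulate import GroundTruth


def write_stack(path: str | Path, stack: TimeLapseStack) -> Path:
    """Write a 4D stack as an ImageJ TZYX hyperstack with calibration."""
    path = Path(path)
    res = 1.0 / stack.pixel_size_um  # pixels per micron
    tifffile.imwrite(
        path, np.asarray(stack.data, dtype=np.float32), imagej=True,
        resolution=(res, res),
        metadata={"axes": "TZYX", "unit": "um", "spacing": stack.z_step_um,
                  "finterval": stack.frame_interval_s})
    return path


def read_stack(path: str | Path,
               pixel_size_um: Optional[float] = None,
               frame_interval_s: Optional[float] = None,
               z_step_um: Optional[float] = None) -> TimeLapseStack:
    """Read a TZYX hyperstack; explicit calibration overrides metadata."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.imagej_metadata or {}
        tags = tf.pages[0].tags
        if pixel_size_um is None:
            if "XResolution" in tags:
                num, den = tags["XResolution"].value
                pixel_size_um = den / num if num else None
        if frame_interval_s is None:
            frame_interval_s = meta.get("finterval")
        if z_step_um is None:
            z_step_um = meta.get("spacing")
    if data.ndim == 3:  # single z-plane stack
        data = data[:, None]
    if data.ndim != 4:
        raise ParameterError(
            f"{path}: expected a TZYX or TYX stack, got shape {data.shape}")
    if not pixel_size_um or not frame_interval_s:
        raise ParameterError(
            f"{path}: pixel size / frame interval absent from metadata; "
            "pass them explicitly")
    return TimeLapseStack(data, float(pixel_size_um), float(frame_interval_s),
                          float(z_step_um or 1.0))


def write_series(path: str | Path, series: ProjectedSeries) -> Path:
    """Write a 2D+time series as TYX TIFF plus a provenance sidecar JSON."""
    path = Path(path)
    data = series.data
    dtype = np.uint8 if data.dtype == bool else np.float32
    res = 1.0 / series.pixel_size_um
    tifffile.imwrite(path, data.astype(dtype), imagej=True,
                     resolution=(res, res),
                     metadata={"axes": "TYX", "unit": "um",
                               "finterval": series.frame_interval_s})
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps({
        "pixel_size_um": series.pixel_size_um,
        "frame_interval_s": series.frame_interval_s,
        "binary": bool(series.is_binary),
        "provenance": series.provenance,
    }, indent=2, sort_keys=True) + "\n")
    return path


def read_series(path: str | Path) -> ProjectedSeries:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    if not sidecar.exists():
        raise ParameterError(f"{path}: provenance sidecar {sidecar.name} missing")
    meta = json.loads(sidecar.read_text())
    data = tifffile.imread(path)
    if meta.get("binary"):
        data = data.astype(bool)
    return ProjectedSeries(data, meta["pixel_size_um"],
                           meta["frame_interval_s"], meta["provenance"])


def write_ground_truth(outdir: str | Path, gt: GroundTruth) -> Path:
    """Ground truth as an events CSV plus a run-level JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gt.events_dataframe().to_csv(outdir / "truth_events.csv", index=False)
    (outdir / "truth_summary.json").write_text(
        json.dumps(gt.summary(), indent=2, sort_keys=True) + "\n")
    return outdir / "truth_events.csv"
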