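"""Configuration objects for simulation and the end-to-end pipeline.

All physical parameters are expressed in physical units (µm, seconds) and
converted to pixels/frames internally, so a config survives changes of
acquisition settings (pixel size, frame interval) unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .errors import ParameterError

__all__ = ["SimulationConfig", "RunConfig"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic microglia time-lapse generator.

    Defaults emulate the acquisition conditions of live confocal imaging of
    lectin-labeled microglia in acute brain slices: 512×512 px frames covering
    a ~140 µm field (0.273 µm/px), one frame per minute for 10 min, z-stacks
    of 15 planes at 2 µm spacing (30 µm slab).

    Kinetic parameters control ground-truthed extension events: each process
    tip may sprout a new terminal extension per frame with probability
    ``extension_prob``; with probability ``stable_fraction`` the extension is
    persistent (remains until the end of the movie), otherwise it retracts
    after ``unstable_lifetime_frames`` frames.
    """

    image_size: int = 512
    pixel_size_um: float = 0.273
    n_frames: int = 10
    frame_interval_s: float = 60.0
    n_z: int = 15
    z_step_um: float = 2.0

    n_cells: int = 4
    soma_radius_um: float = 5.0
    n_primary_processes: int = 5
    process_length_um: float = 8.0

    extension_prob: float = 0.30
    stable_fraction: float = 0.5
    unstable_lifetime_frames: int = 1
    extension_length_um: float = 1.5
    # persistence window (frames) used to restrict event onsets so every
    # sampled stable event can display >= this many frames before movie end
    stable_min_frames: int = 3

    psf_sigma_um: float = 0.3
    background_level: float = 0.05
    noise_scale: float = 50.0
    bleach_rate: float = 0.0
    drift_px_per_frame: Tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = ("extension_prob", "stable_fraction")
        for name in probs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        positive = (
            "pixel_size_um", "frame_interval_s", "z_step_um", "soma_radius_um",
            "process_length_um", "extension_length_um",
        )
        for name in positive:
            v = getattr(self, name)
            if not v > 0:
                raise ParameterError(f"{name} must be > 0, got {v}")
        nonneg = ("psf_sigma_um", "background_level", "noise_scale",
                  "bleach_rate")
        for name in nonneg:
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v}")
        ints = ("image_size", "n_z", "n_primary_processes")
        for name in ints:
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ParameterError(f"{name} must be a positive integer, got {v}")
        if self.n_cells < 0:
            raise ParameterError(f"n_cells must be >= 0, got {self.n_cells}")
        if self.n_frames < 3:
            raise ParameterError(
                "n_frames must be >= 3 (persistence is undefined below the "
                f"stability window), got {self.n_frames}")
        if self.unstable_lifetime_frames < 1:
            raise ParameterError(
                "unstable_lifetime_frames must be >= 1, got "
                f"{self.unstable_lifetime_frames}")
        if len(tuple(self.drift_px_per_frame)) != 2:
            raise ParameterError("drift_px_per_frame must be a (dy, dx) pair")
        self.drift_px_per_frame = tuple(float(d) for d in self.drift_px_per_frame)

    # -- round-trip helpers -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drift_px_per_frame"] = list(self.drift_px_per_frame)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown simulation field(s): {sorted(unknown)}")
        d = dict(d)
        if "drift_px_per_frame" in d:
            d["drift_px_per_frame"] = tuple(d["drift_px_per_frame"])
        return cls(**d)


@dataclass
class RunConfig:
    """Every tunable of the end-to-end pipeline, with file round-trip.

    Time-like thresholds are stored in seconds (``min_persistence_s``) and
    converted to frames against the series' frame interval at run time.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    simulate: bool = True
    input_path: Optional[str] = None
    outdir: str = "gliamotion_run"
    seed: int = 0

    # preprocess
    z_range_um: Optional[Tuple[float, float]] = None
    threshold_method: str = "otsu_frame0"
    threshold_value: Optional[float] = None

    # segmentation / morphometry
    min_cell_area_px: int = 50
    soma_open_radius_um: float = 2.0
    cup_closing_radius_um: float = 1.0
    min_cup_area_px: int = 5
    spur_prune_px: int = 2

    # motility
    min_event_px: int = 4
    min_persistence_s: float = 180.0
    overlap_fraction: float = 0.5
    footprint_dilation_px: int = 1

    # reporting
    per_animal: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        if self.threshold_method not in ("otsu_frame0", "fixed"):
            raise ParameterError(
                f"threshold_method must be 'otsu_frame0' or 'fixed', got "
                f"{self.threshold_method!r}")
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ParameterError(
                f"overlap_fraction must be in (0, 1], got {self.overlap_fraction}")
        if self.min_persistence_s <= 0:
            raise ParameterError(
                f"min_persistence_s must be > 0, got {self.min_persistence_s}")
        if self.min_event_px < 1:
            raise ParameterError(f"min_event_px must be >= 1, got {self.min_event_px}")
        if self.z_range_um is not None:
            self.z_range_um = tuple(float(z) for z in self.z_range_um)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        if self.z_range_um is not None:
            d["z_range_um"] = list(self.z_range_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
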