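"""Core data containers shared by all analysis stages.

Conventions used throughout the package
---------------------------------------
* Physical lengths are carried in Ångström internally; nanometres appear
  only in user-facing reports and in the simulator specs (which mirror how
  the quantities are usually quoted: diameters in nm, pitches in Å).
* Image coordinates are 0-based pixel indices with the origin at the
  top-left corner; ``x`` indexes columns, ``y`` indexes rows.
* ``psi_deg`` is the counter-clockwise in-plane angle from the image
  vertical (the row axis) to the filament axis.  A segment extracted with
  its recorded ``psi`` therefore has its filament axis vertical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np

__all__ = [
    "Image2D",
    "Volume",
    "ParticleRecord",
    "ParticleTable",
    "PipelineConfig",
]


@dataclass
class Image2D:
    """A 2D pixel grid with a physical pixel size in Å/px."""

    pixels: np.ndarray
    pixel_size_A: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"Image2D expects a 2D array, got {self.pixels.ndim}D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image2D pixels must be finite")
        self.pixel_size_A = float(self.pixel_size_A)
        if not self.pixel_size_A > 0:
            raise ValueError(f"pixel_size_A must be positive, got {self.pixel_size_A}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_A(self) -> tuple[float, float]:
        """Physical (height, width) of the image in Å."""
        ny, nx = self.pixels.shape
        return ny * self.pixel_size_A, nx * self.pixel_size_A

    def copy(self) -> "Image2D":
        return Image2D(self.pixels.copy(), self.pixel_size_A)


@dataclass
class Volume:
    """A 3D voxel grid (z, y, x) with an isotropic voxel size in Å."""

    voxels: np.ndarray
    voxel_size_A: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"Volume expects a 3D array, got {self.voxels.ndim}D")
        self.voxel_size_A = float(self.voxel_size_A)
        if not self.voxel_size_A > 0:
            raise ValueError(f"voxel_size_A must be positive, got {self.voxel_size_A}")


@dataclass
class ParticleRecord:
    """One boxed filament segment and its placement metadata.

    ``tube_id`` groups segments that were picked along the same filament;
    ``segment_index`` orders them along the contour starting from 0.
    """

    micrograph_id: str
    x_px: float
    y_px: float
    psi_deg: float
    tube_id: int
    segment_index: int
    class_id: Optional[int] = None


class ParticleTable:
    """Ordered collection of :class:`ParticleRecord` with a pixel size.

    The table enforces that ``(tube_id, segment_index)`` pairs are unique,
    mirroring the bookkeeping of helical picking where every filament's
    segments are numbered consecutively along the tube.
    """

    def __init__(self, records: Iterable[ParticleRecord], pixel_size_A: float):
        self.records: list[ParticleRecord] = list(records)
        self.pixel_size_A = float(pixel_size_A)
        if not self.pixel_size_A > 0:
            raise ValueError("pixel_size_A must be positive")
        seen = set()
        for r in self.records:
            key = (r.tube_id, r.segment_index)
            if key in seen:
                raise ValueError(
                    f"duplicate (tube_id, segment_index) = {key} in particle table"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticleRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ParticleRecord:
        return self.records[i]

    def tube_ids(self) -> list[int]:
        return sorted({r.tube_id for r in self.records})

    def by_tube(self, tube_id: int) -> list[ParticleRecord]:
        """Records of one tube, sorted by segment_index (picking order)."""
        recs = [r for r in self.records if r.tube_id == tube_id]
        return sorted(recs, key=lambda r: r.segment_index)

    def sorted(self) -> "ParticleTable":
        recs = sorted(self.records, key=lambda r: (r.tube_id, r.segment_index))
        return ParticleTable(recs, self.pixel_size_A)


_CONFIG_FIELDS_DOC = """Pipeline-wide constants.

Defaults follow the geometry of helical single-particle processing of
keratin filaments: 50 Å inter-box picking distance, a 132 Å lateral mask
retained when back-plotting class averages, and 4.2 nm slabs for
cross-section projection.
"""


@dataclass
class PipelineConfig:
    __doc__ = _CONFIG_FIELDS_DOC

    box_px: int = 250
    interbox_A: float = 50.0
    mask_width_A: float = 132.0
    slab_thickness_nm: float = 4.2
    acf_min_lag_A: float = 60.0
    acf_prominence: float = 0.5
    seed: int = 0
    pixel_size_A: float = 2.206
    out_dir: str = "kerafil_out"

    def __post_init__(self) -> None:
        for name in ("box_px", "interbox_A", "mask_width_A", "slab_thickness_nm",
                     "acf_min_lag_A", "pixel_size_A"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if int(self.box_px) != self.box_px:
            raise ValueError("box_px must be an integer")
        self.box_px = int(self.box_px)

    def config_hash(self) -> str:
        """Stable short hash of the numeric settings, recorded in every
        output; output paths do not alter the scientific configuration."""
        payload = json.dumps(
            {k: v for k, v in sorted(self.__dict__.items())
             if k != "out_dir"}, sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
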