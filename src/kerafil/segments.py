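"""Segment picking along filament contours and boxed extraction.

Picking emulates helical single-particle preprocessing: boxes are placed
every ``interbox_A`` along the traced contour starting from its first
point, each carrying the local tangent angle psi so the segment can be
extracted with its filament axis vertical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .contour import Contour, resample_spline, tangent_angles
from .core import Image2D, ParticleRecord, ParticleTable

__all__ = ["SegmentBox", "pick_segments", "extract_segment", "psi_from_tangent"]


@dataclass
class SegmentBox:
    """A particle record paired with its extraction box size (px, even)."""

    record: ParticleRecord
    box_px: int

    def __post_init__(self) -> None:
        if self.box_px <= 0 or self.box_px % 2 != 0:
            raise ValueError("box_px must be a positive even integer")


def psi_from_tangent(t_x: float, t_y: float) -> float:
    """In-plane angle (deg, CCW from the image vertical) of a tangent
    vector given in pixel coordinates (x = column, y = row)."""
    return float(np.degrees(np.arctan2(t_x, t_y)))


def pick_segments(
    contour: Contour,
    interbox_A: float,
    pixel_size_A: float,
    tube_id: int = 0,
    micrograph_id: str = "",
) -> ParticleTable:
    """Place segment boxes every ``interbox_A`` along a contour (pixel
    coordinates), starting at the contour's first point.

    Returns floor(L / interbox) + 1 records; each record's psi_deg is the
    local tangent angle from a central-difference on the spline-resampled
    contour, and segment_index counts consecutively from 0.
    """
    if interbox_A <= 0:
        raise ValueError("interbox_A must be positive")
    if pixel_size_A <= 0:
        raise ValueError("pixel_size_A must be positive")

    interbox_px = interbox_A / pixel_size_A
    if len(contour) >= 3:
        fine = resample_spline(contour.points, step=min(0.25, interbox_px / 8))
    else:
        fine = Contour.from_points(contour.points)
    length_px = fine.length
    n = int(np.floor(length_px / interbox_px + 1e-9)) + 1
    s_targets = np.arange(n) * interbox_px

    xs = np.interp(s_targets, fine.arc_s, fine.points[:, 0])
    ys = np.interp(s_targets, fine.arc_s, fine.points[:, 1])
    if len(fine) >= 3:
        ang = tangent_angles(fine)
        ang_t = np.interp(s_targets, fine.arc_s, ang)
    else:
        d = fine.points[-1] - fine.points[0]
        ang_t = np.full(n, np.arctan2(d[1], d[0]))

    records = [
        ParticleRecord(
            micrograph_id=micrograph_id,
            x_px=float(xs[i]),
            y_px=float(ys[i]),
            psi_deg=psi_from_tangent(np.cos(ang_t[i]), np.sin(ang_t[i])),
            tube_id=tube_id,
            segment_index=i,
        )
        for i in range(n)
    ]
    return ParticleTable(records, pixel_size_A)


def extract_segment(micrograph: Image2D, record: ParticleRecord,
                    box_px: int) -> Image2D:
    """Extract a box around a particle, rotated by −psi so the filament
    axis is vertical (bilinear interpolation; out-of-field pixels are
    filled with the micrograph mean)."""
    ny, nx = micrograph.shape
    if box_px > min(ny, nx):
        raise ValueError("box_px larger than the micrograph")
    psi = np.deg2rad(record.psi_deg)
    # filament tangent and normal in (x, y) pixel coordinates
    t = np.array([np.sin(psi), np.cos(psi)])
    nvec = np.array([np.cos(psi), -np.sin(psi)])

    c = (box_px - 1) / 2.0
    v, u = np.mgrid[0:box_px, 0:box_px]   # v = output row (axial), u = column
    du, dv = u - c, v - c
    src_x = record.x_px + du * nvec[0] + dv * t[0]
    src_y = record.y_px + du * nvec[1] + dv * t[1]
    out = ndimage.map_coordinates(
        micrograph.pixels, [src_y, src_x], order=1,
        mode="constant", cval=float(micrograph.pixels.mean()),
    )
    return Image2D(out, micrograph.pixel_size_A)
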