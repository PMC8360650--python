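"""Computational reconstitution of filaments from 2D class averages.

Each boxed segment is replaced by its class average, inversely transformed
to the segment's original in-plane orientation and plotted at the original
picking coordinate.  Classes are laterally masked (only a central band is
plotted, removing background noise) and axially cropped with soft cosine
edges so that no more than four classes overlap at any pixel; overlaps are
resolved by soft-mask-weighted averaging and each reconstituted filament
is normalized to unit mean intensity over its footprint.  A spline contour
fitted through the picking coordinates then drives straightening:
resampling the reconstituted image along contour normals yields a
vertical-axis image whose length equals the contour arc length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .contour import Contour, resample_spline, tangent_angles
from .core import Image2D, ParticleRecord, ParticleTable

__all__ = [
    "ReconstitutedImage",
    "StraightenedFilament",
    "inverse_transform_class",
    "compose_reconstitution",
    "fit_contour",
    "straighten",
]

MAX_OVERLAP = 4          # hard bound on classes contributing per pixel
SOFT_EDGE_PX = 10        # raised-cosine ramp width on mask/crop boundaries


@dataclass
class ReconstitutedImage:
    image: Image2D
    coverage: np.ndarray                       # classes contributing per pixel
    provenance: list[tuple[ParticleRecord, int]] = field(default_factory=list)


@dataclass
class StraightenedFilament:
    image: Image2D            # filament axis vertical
    contour: Contour          # source contour (px)
    width_A: float


def _soft_band(n: int, center: float, half_width_px: float,
               edge_px: float) -> np.ndarray:
    """1D window: 1 inside ±(half_width − edge), raised-cosine ramp to 0
    at ±half_width."""
    x = np.abs(np.arange(n) - center)
    w = np.zeros(n)
    flat = half_width_px - edge_px
    if flat < 0:
        flat = 0.0
        edge_px = half_width_px
    w[x <= flat] = 1.0
    ramp = (x > flat) & (x < half_width_px)
    if edge_px > 0:
        w[ramp] = 0.5 * (1 + np.cos(np.pi * (x[ramp] - flat) / edge_px))
    return w


def lateral_mask(box_px: int, mask_width_A: float, pixel_size_A: float,
                 edge_px: float = SOFT_EDGE_PX) -> np.ndarray:
    """Column weights retaining the central ``mask_width_A`` of the box."""
    half_px = mask_width_A / 2.0 / pixel_size_A
    if 2 * half_px > box_px:
        raise ValueError("mask wider than the class box")
    return _soft_band(box_px, (box_px - 1) / 2.0, half_px, edge_px)


def inverse_transform_class(class_image: Image2D, psi_deg: float,
                            mask_width_A: float,
                            edge_px: float = SOFT_EDGE_PX) -> Image2D:
    """Mask the central lateral band of an axially aligned class and
    rotate it by +psi back to the original segment orientation."""
    box = class_image.shape[0]
    masked = class_image.pixels * lateral_mask(
        class_image.shape[1], mask_width_A, class_image.pixel_size_A, edge_px
    )[None, :]
    if psi_deg == 0:
        return Image2D(masked, class_image.pixel_size_A)
    out = _rotate_patch(masked, psi_deg)
    return Image2D(out, class_image.pixel_size_A)


def _rotate_patch(patch: np.ndarray, psi_deg: float) -> np.ndarray:
    """Rotate a class-frame patch into micrograph orientation.

    Inverse of the extraction mapping: a class pixel at (lateral u,
    axial v) lands at offset u·n + v·t from the center, with t the
    filament tangent for this psi."""
    ny, nx = patch.shape
    psi = np.deg2rad(psi_deg)
    t = np.array([np.sin(psi), np.cos(psi)])
    nvec = np.array([np.cos(psi), -np.sin(psi)])
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    gy, gx = np.mgrid[0:ny, 0:nx]
    dx, dy = gx - cx, gy - cy
    # solve dx·ex + dy·ey = u·n + v·t for (u, v): orthonormal basis
    u = dx * nvec[0] + dy * nvec[1]
    v = dx * t[0] + dy * t[1]
    return ndimage.map_coordinates(patch, [v + cy, u + cx], order=1,
                                   mode="constant", cval=0.0)


def compose_reconstitution(
    particles: ParticleTable,
    class_library: dict[int, Image2D],
    canvas_size_px: int,
    mask_width_A: float = 132.0,
    interbox_A: float = 50.0,
    edge_px: float = SOFT_EDGE_PX,
) -> ReconstitutedImage:
    """Back-map class averages to their picking coordinates.

    Per particle the class is laterally masked, axially cropped to a soft
    window of half-length 2×interbox (bounding the overlap at 4 classes
    for consecutive picks), rotated by +psi and accumulated at (x, y) as a
    weighted mean with the soft-mask weights.  Filaments (tubes) are each
    normalized to unit mean intensity over their footprint.
    """
    import warnings

    px = particles.pixel_size_A
    interbox_px = interbox_A / px
    # half-window just under 2×interbox: four consecutive picks can touch
    # any pixel, never five, even after interpolation spreads the support
    axial_half_px = 2.0 * interbox_px - 2.0

    num_total = np.zeros((canvas_size_px, canvas_size_px))
    den_total = np.zeros_like(num_total)
    coverage = np.zeros_like(num_total, dtype=int)
    provenance: list[tuple[ParticleRecord, int]] = []

    for tube_id in particles.tube_ids():
        # streaming top-4 contributions per pixel, selected by soft-mask
        # weight: bent filaments can stack arbitrarily many windows on the
        # curve's inside, but only the four best-covering classes may blend
        top_w = np.zeros((MAX_OVERLAP,) + num_total.shape)
        top_wv = np.zeros_like(top_w)
        for rec in particles.by_tube(tube_id):
            if rec.class_id is None or rec.class_id not in class_library:
                raise ValueError(
                    f"segment {tube_id}/{rec.segment_index}: class "
                    f"{rec.class_id} not in the library"
                )
            cls = class_library[rec.class_id]
            ny, nx = cls.shape
            if not (0 <= rec.x_px < canvas_size_px
                    and 0 <= rec.y_px < canvas_size_px):
                warnings.warn(
                    f"particle {tube_id}/{rec.segment_index} outside canvas; "
                    "skipped", stacklevel=2)
                continue

            w_lat = lateral_mask(nx, mask_width_A, px, edge_px)
            w_ax = _soft_band(ny, (ny - 1) / 2.0,
                              min(axial_half_px, ny / 2.0), edge_px)
            weights = w_ax[:, None] * w_lat[None, :]
            patch = cls.pixels * weights
            rpatch = _rotate_patch(patch, rec.psi_deg)
            rweights = _rotate_patch(weights, rec.psi_deg)

            # splat with subpixel shift onto the canvas
            x0 = int(np.floor(rec.x_px)) - nx // 2
            y0 = int(np.floor(rec.y_px)) - ny // 2
            fx, fy = rec.x_px - np.floor(rec.x_px), rec.y_px - np.floor(rec.y_px)
            if fx or fy:
                rpatch = ndimage.shift(rpatch, (fy, fx), order=1, cval=0.0)
                rweights = ndimage.shift(rweights, (fy, fx), order=1, cval=0.0)
            rweights = np.clip(rweights, 0.0, None)

            ys = slice(max(y0, 0), min(y0 + ny, canvas_size_px))
            xs = slice(max(x0, 0), min(x0 + nx, canvas_size_px))
            pys = slice(ys.start - y0, ys.stop - y0)
            pxs = slice(xs.start - x0, xs.stop - x0)
            w_new = rweights[pys, pxs]
            wv_new = rpatch[pys, pxs]
            # replace the weakest stored contribution where the new one
            # covers better (exact top-4, independent of particle order)
            sub_w = top_w[:, ys, xs]
            sub_wv = top_wv[:, ys, xs]
            amin = np.argmin(sub_w, axis=0)
            take = np.take_along_axis(sub_w, amin[None], axis=0)[0] < w_new
            if np.any(take):
                idx = amin[take]
                yy, xx = np.nonzero(take)
                sub_w[idx, yy, xx] = w_new[take]
                sub_wv[idx, yy, xx] = wv_new[take]
                top_w[:, ys, xs] = sub_w
                top_wv[:, ys, xs] = sub_wv
            provenance.append((rec, rec.class_id))

        den = top_w.sum(axis=0)
        num = top_wv.sum(axis=0)
        footprint = den > 1e-6
        if np.any(footprint):
            tube_img = np.zeros_like(num)
            tube_img[footprint] = num[footprint] / den[footprint]
            mean_val = tube_img[footprint].mean()
            if abs(mean_val) > 1e-12:
                tube_img /= mean_val
            num_total += tube_img * den
            den_total += den
            coverage += (top_w > 1e-6).sum(axis=0)

    image = np.zeros_like(num_total)
    nz = den_total > 1e-6
    image[nz] = num_total[nz] / den_total[nz]
    # the overlap bound holds per filament by construction (4 storage
    # slots); crossing filaments superimpose, so the total map may exceed
    # it only where distinct tubes intersect
    n_tubes = len(particles.tube_ids())
    if coverage.max() > MAX_OVERLAP * max(n_tubes, 1):
        raise AssertionError("coverage accounting is inconsistent")
    return ReconstitutedImage(Image2D(image, px), coverage, provenance)


def fit_contour(records: Sequence[ParticleRecord],
                smoothing: float = 0.0) -> Contour:
    """Smoothing-spline contour through one tube's picking coordinates,
    resampled at 1-px arc steps."""
    if len(records) < 2:
        raise ValueError("need at least 2 segments to fit a contour")
    recs = sorted(records, key=lambda r: r.segment_index)
    pts = np.array([[r.x_px, r.y_px] for r in recs])
    return resample_spline(pts, step=1.0, smoothing=smoothing)


def straighten(image: Image2D, contour: Contour,
               width_A: float) -> StraightenedFilament:
    """Resample an image along contour normals at 1-px arc steps,
    producing a vertical-axis image of lateral width ``width_A``."""
    ny, nx = image.shape
    pts = contour.points
    if (pts[:, 0].min() < 0 or pts[:, 0].max() > nx - 1
            or pts[:, 1].min() < 0 or pts[:, 1].max() > ny - 1):
        raise ValueError("contour exits the image")
    fine = (resample_spline(pts, step=1.0) if len(pts) >= 3
            else Contour.from_points(pts))
    ang = (tangent_angles(fine) if len(fine) >= 3
           else np.full(len(fine), np.arctan2(*(fine.points[-1]
                                                - fine.points[0])[::-1])))
    half_px = int(np.ceil(width_A / 2.0 / image.pixel_size_A))
    offsets = np.arange(-half_px, half_px + 1, dtype=float)  # 1-px steps

    # normal = tangent rotated by -90° so +offset is consistently one side
    nx_vec = np.sin(ang)
    ny_vec = -np.cos(ang)
    sx = fine.points[:, 0][:, None] + offsets[None, :] * nx_vec[:, None]
    sy = fine.points[:, 1][:, None] + offsets[None, :] * ny_vec[:, None]
    out = ndimage.map_coordinates(image.pixels, [sy, sx], order=1,
                                  mode="nearest")
    return StraightenedFilament(Image2D(out, image.pixel_size_A), fine, width_A)
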