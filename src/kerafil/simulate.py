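"""Synthetic keratin-filament image generator.

The forward model emulates what cryo-EM 2D class averages of intermediate
filaments look like after projection: a hollow cylinder (protofilament
wall) with an optional central core rod, decorated with a single-start
helical surface wave whose axial period is the pitch.  Filaments can be
straight, bent along an arbitrary contour, or tilted out of plane (which
compresses the apparent axial period by cos θ).  Noise is additive white
Gaussian added after projection; there is no contrast-transfer-function
simulation — the analyses this generator feeds are geometric.

Every generator is a pure function of (spec, seed): the same inputs always
produce the same image.

Default parameters follow the measured geometry of K5/K14 filaments:
10.1 nm outer diameter, 163 Å helical pitch, a ring of 6 protofilaments of
~3.5 nm ring radius around a central core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

from .contour import Contour, resample_spline
from .core import Image2D, ParticleRecord, ParticleTable
from .helix import tilt_project
from .profiles import A_PER_NM, LineProfile

__all__ = [
    "FilamentSpec",
    "CrossSectionSpec",
    "project_hollow_cylinder",
    "generate_filament_image",
    "generate_wlc_contour",
    "generate_micrograph",
    "generate_cross_section",
    "generate_class_library",
    "line_contour",
]


@dataclass
class FilamentSpec:
    """Ground-truth parameters for one synthetic filament.

    ``noise_sigma`` is the Gaussian noise SD relative to the peak
    projected density (the noise-free render is normalized to peak 1), so
    SNR = 1/noise_sigma.
    """

    pitch_A: float = 163.0
    diameter_nm: float = 10.1
    wall_fraction: float = 0.4     # inner radius = (1 - wall_fraction) * outer
    has_core: bool = True
    core_radius_nm: float = 1.0
    core_offset_nm: tuple[float, float] = (0.0, 0.0)
    tilt_deg: float = 0.0
    contour: Union[str, Contour] = "straight"
    noise_sigma: float = 0.0
    seed: int = 0
    modulation: float = 0.5        # helical surface-wave amplitude (fraction)

    def __post_init__(self) -> None:
        if self.pitch_A <= 0 or self.diameter_nm <= 0:
            raise ValueError("pitch_A and diameter_nm must be positive")
        if not 0 < self.wall_fraction <= 1:
            raise ValueError("wall_fraction must lie in (0, 1]")
        if not 0 <= self.tilt_deg < 90:
            raise ValueError("tilt_deg must lie in [0, 90)")
        if self.noise_sigma < 0 or self.core_radius_nm < 0:
            raise ValueError("noise_sigma and core_radius_nm must be >= 0")
        inner = self.inner_radius_nm
        if self.has_core:
            if self.core_radius_nm >= inner:
                raise ValueError("core must fit inside the lumen")
            off = float(np.hypot(*self.core_offset_nm))
            if off + self.core_radius_nm > inner:
                raise ValueError("offset core extends beyond the lumen")

    @property
    def outer_radius_nm(self) -> float:
        return self.diameter_nm / 2.0

    @property
    def inner_radius_nm(self) -> float:
        return (1.0 - self.wall_fraction) * self.outer_radius_nm


@dataclass
class CrossSectionSpec:
    """Ground truth for a synthetic filament cross-section: ``n_proto``
    Gaussian blobs equally spaced on a ring, plus an optional central core
    blob displaced by ``core_offset_nm``."""

    n_proto: int = 6
    ring_radius_nm: float = 3.5
    proto_sigma_nm: float = 0.75
    has_core: bool = True
    core_offset_nm: tuple[float, float] = (0.0, 0.0)
    core_amplitude: float = 0.8
    noise_sigma: float = 0.0
    seed: int = 0
    angles_deg: Sequence[float] | None = None   # explicit blob angles override

    def __post_init__(self) -> None:
        if self.n_proto < 0:
            raise ValueError("n_proto must be >= 0")
        if self.ring_radius_nm <= 0 or self.proto_sigma_nm <= 0:
            raise ValueError("ring radius and blob sigma must be positive")

    def blob_angles_rad(self) -> np.ndarray:
        if self.angles_deg is not None:
            return np.deg2rad(np.asarray(self.angles_deg, dtype=np.float64))
        return 2.0 * np.pi * np.arange(self.n_proto) / max(self.n_proto, 1)


# ---------------------------------------------------------------------------
# analytic projections
# ---------------------------------------------------------------------------

def _chord(r_A: float, x_A: np.ndarray) -> np.ndarray:
    """Chord length of a disk of radius r at lateral offset x (projection
    of a uniform solid cylinder along the view direction)."""
    return 2.0 * np.sqrt(np.clip(r_A**2 - x_A**2, 0.0, None))


def project_hollow_cylinder(
    outer_r_nm: float,
    inner_r_nm: float,
    core_r_nm: float = 0.0,
    core_density: float = 1.0,
    pixel_size_A: float = 1.0,
    half_width_A: float | None = None,
) -> LineProfile:
    """Analytic lateral projection of an annulus plus optional centered rod.

    The projected density at lateral offset x is the path length through
    the annulus, ``2(sqrt(Ro² − x²) − sqrt(Ri² − x²))``, plus
    ``core_density · 2·sqrt(Rc² − x²)`` for the core rod.  The outer edges
    of a hollow cylinder therefore project to the highest values — the
    behaviour that makes filament boundaries the most pronounced feature
    of the class averages.
    """
    if not 0 <= inner_r_nm < outer_r_nm:
        raise ValueError("need 0 <= inner radius < outer radius")
    if core_r_nm < 0:
        raise ValueError("core radius must be >= 0")
    ro, ri, rc = (outer_r_nm * A_PER_NM, inner_r_nm * A_PER_NM,
                  core_r_nm * A_PER_NM)
    if half_width_A is None:
        half_width_A = 1.5 * ro
    n_half = int(np.ceil(half_width_A / pixel_size_A))
    x = np.arange(-n_half, n_half + 1) * pixel_size_A
    y = _chord(ro, x) - _chord(ri, x) + core_density * _chord(rc, x)
    return LineProfile(x, y)


def _annulus_core_profile_A(spec: FilamentSpec, x_A: np.ndarray) -> np.ndarray:
    """Base (unmodulated) lateral density of a filament at offsets x (Å)."""
    ro = spec.outer_radius_nm * A_PER_NM
    ri = spec.inner_radius_nm * A_PER_NM
    y = _chord(ro, x_A) - _chord(ri, x_A)
    if spec.has_core and spec.core_radius_nm > 0:
        # projected core at its lateral offset component
        rc = spec.core_radius_nm * A_PER_NM
        dx = spec.core_offset_nm[0] * A_PER_NM
        y = y + 0.8 * _chord(rc, x_A - dx)
    return y


# ---------------------------------------------------------------------------
# filament renders
# ---------------------------------------------------------------------------

def _render_straight(spec: FilamentSpec, shape: tuple[int, int],
                     pixel_size_A: float) -> np.ndarray:
    ny, nx = shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size_A
    z = np.arange(ny) * pixel_size_A
    base = _annulus_core_profile_A(spec, x)
    ro = spec.outer_radius_nm * A_PER_NM
    azimuth = np.arcsin(np.clip(x / ro, -1.0, 1.0))
    phase = 2.0 * np.pi * z[:, None] / spec.pitch_A + azimuth[None, :]
    return base[None, :] * (1.0 + spec.modulation * np.cos(phase))


def _render_bent(spec: FilamentSpec, shape: tuple[int, int],
                 pixel_size_A: float, contour_px: Contour) -> np.ndarray:
    """Sweep the lateral density profile along an arbitrary contour.

    Each pixel is assigned the (signed lateral distance, arc position) of
    its nearest point on a finely resampled contour; valid for bending
    radii large compared to the filament radius.
    """
    ny, nx = shape
    fine = resample_spline(contour_px.points, step=0.25)
    tree = cKDTree(fine.points)
    ro_px = spec.outer_radius_nm * A_PER_NM / pixel_size_A

    gy, gx = np.mgrid[0:ny, 0:nx]
    pts = np.column_stack([gx.ravel(), gy.ravel()]).astype(np.float64)
    dist, idx = tree.query(pts, workers=-1,
                           distance_upper_bound=1.5 * ro_px + 2.0)
    ok = np.isfinite(dist)
    out = np.zeros(ny * nx)
    if np.any(ok):
        i = idx[ok]
        # signed lateral offset via cross product with the local tangent
        tang = np.gradient(fine.points, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        rel = pts[ok] - fine.points[i]
        signed = rel[:, 0] * tang[i, 1] - rel[:, 1] * tang[i, 0]
        x_A = signed * pixel_size_A
        s_A = fine.arc_s[i] * pixel_size_A
        base = _annulus_core_profile_A(spec, x_A)
        azim = np.arcsin(np.clip(x_A / (spec.outer_radius_nm * A_PER_NM),
                                 -1.0, 1.0))
        out[ok] = base * (1.0 + spec.modulation
                          * np.cos(2.0 * np.pi * s_A / spec.pitch_A + azim))
    return out.reshape(ny, nx)


def generate_filament_image(spec: FilamentSpec, box_px: int,
                            pixel_size_A: float) -> Image2D:
    """Render one filament segment into a ``box_px`` × ``box_px`` image.

    Straight filaments run vertically through the box center; a contour
    (in pixel coordinates of the box) bends the filament; a non-zero
    ``tilt_deg`` compresses the axial pattern by cos θ, emulating a
    filament oriented out of the image plane.  The noise-free render is
    normalized to peak 1 before Gaussian noise of SD ``noise_sigma`` is
    added, so SNR = 1/noise_sigma.
    """
    if pixel_size_A <= 0 or box_px <= 0:
        raise ValueError("box_px and pixel_size_A must be positive")
    if spec.pitch_A < 2.0 * pixel_size_A:
        raise ValueError(
            f"pitch {spec.pitch_A} Å violates Nyquist at {pixel_size_A} Å/px"
        )

    cos_t = np.cos(np.deg2rad(spec.tilt_deg))
    render_ny = box_px if spec.tilt_deg == 0 else int(np.ceil(box_px / cos_t)) + 2

    if isinstance(spec.contour, Contour):
        img = _render_bent(spec, (render_ny, box_px), pixel_size_A, spec.contour)
    elif spec.contour == "straight":
        img = _render_straight(spec, (render_ny, box_px), pixel_size_A)
    else:
        raise ValueError("contour must be 'straight' or a Contour")

    if spec.tilt_deg != 0:
        tilted = tilt_project(Image2D(img, pixel_size_A), spec.tilt_deg).pixels
        # center-crop / pad back to the requested box
        ny = tilted.shape[0]
        if ny >= box_px:
            o = (ny - box_px) // 2
            img = tilted[o:o + box_px]
        else:
            img = np.zeros((box_px, box_px))
            img[(box_px - ny) // 2:(box_px - ny) // 2 + ny] = tilted

    peak = np.max(np.abs(img))
    if peak > 0:
        img = img / peak
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return Image2D(img, pixel_size_A)


# ---------------------------------------------------------------------------
# contours and micrographs
# ---------------------------------------------------------------------------

def generate_wlc_contour(persistence_nm: float, total_length_nm: float,
                         step_nm: float, seed: int = 0) -> Contour:
    """2D worm-like chain: tangent-angle increments are Gaussian with
    variance step/persistence, giving the in-plane tangent correlation
    ⟨cos Δθ(s)⟩ = exp(−s / (2·Lp)).

    Returns a contour in nm with floor(total/step)+1 points at uniform
    arc spacing, starting at the origin heading along +x.
    """
    if persistence_nm <= 0 or total_length_nm <= 0 or step_nm <= 0:
        raise ValueError("lengths must be positive")
    n_steps = int(np.floor(total_length_nm / step_nm + 1e-9))
    rng = np.random.default_rng(seed)
    dtheta = rng.normal(0.0, np.sqrt(step_nm / persistence_nm), max(n_steps - 1, 0))
    # tangent angle of step i accumulates the first i increments
    theta = np.concatenate([[0.0], np.cumsum(dtheta)])
    pts = np.zeros((n_steps + 1, 2))
    if n_steps:
        pts[1:, 0] = np.cumsum(step_nm * np.cos(theta))
        pts[1:, 1] = np.cumsum(step_nm * np.sin(theta))
    return Contour(pts, np.arange(n_steps + 1) * step_nm)


def line_contour(p0: tuple[float, float], p1: tuple[float, float],
                 step_px: float = 1.0) -> Contour:
    """Straight contour between two pixel coordinates."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.floor(length / step_px)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    return Contour.from_points(p0 + np.outer(t, p1 - p0))


def generate_micrograph(
    specs: Sequence[FilamentSpec],
    size_px: int,
    pixel_size_A: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
    interbox_A: float = 50.0,
    micrograph_id: str = "synthetic_000001",
) -> tuple[Image2D, ParticleTable]:
    """Render several filaments into one field and return the image plus a
    ground-truth particle table (segments picked every ``interbox_A`` along
    each contour, psi from the local tangent, tube_id = spec index).

    Specs must carry an explicit contour (pixel coordinates); contours
    reaching outside the field are clipped with a warning.
    """
    from .segments import pick_segments  # local import: segments is downstream

    canvas = np.zeros((size_px, size_px))
    records: list[ParticleRecord] = []
    for tube_id, spec in enumerate(specs):
        if not isinstance(spec.contour, Contour):
            raise ValueError("micrograph specs need explicit contours")
        pts = spec.contour.points
        if pts.min() < 0 or pts.max() >= size_px:
            warnings.warn(f"contour of tube {tube_id} extends outside the "
                          "field; rendering clipped", stacklevel=2)
        render = _render_bent(spec, (size_px, size_px), pixel_size_A,
                              spec.contour)
        peak = np.max(np.abs(render))
        if peak > 0:
            canvas += render / peak
        table = pick_segments(spec.contour, interbox_A, pixel_size_A,
                              tube_id=tube_id, micrograph_id=micrograph_id)
        records.extend(table.records)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        canvas = canvas + rng.normal(0.0, noise_sigma, canvas.shape)
    return Image2D(canvas, pixel_size_A), ParticleTable(records, pixel_size_A)


# ---------------------------------------------------------------------------
# cross-sections and class libraries
# ---------------------------------------------------------------------------

def generate_cross_section(spec: CrossSectionSpec, box_px: int,
                           pixel_size_A: float) -> Image2D:
    """Render a filament cross-section: Gaussian protofilament blobs on a
    ring, plus an optional displaced central core blob."""
    if box_px <= 0 or pixel_size_A <= 0:
        raise ValueError("box_px and pixel_size_A must be positive")
    half_A = box_px * pixel_size_A / 2.0
    reach_A = (spec.ring_radius_nm + 3 * spec.proto_sigma_nm) * A_PER_NM
    if spec.n_proto > 0 and reach_A > half_A:
        raise ValueError("ring plus blobs does not fit in the box")

    c = (box_px - 1) / 2.0
    gy, gx = np.mgrid[0:box_px, 0:box_px]
    x_A = (gx - c) * pixel_size_A
    y_A = (gy - c) * pixel_size_A
    sig_A = spec.proto_sigma_nm * A_PER_NM
    img = np.zeros((box_px, box_px))
    r_A = spec.ring_radius_nm * A_PER_NM
    for ang in spec.blob_angles_rad():
        bx, by = r_A * np.cos(ang), r_A * np.sin(ang)
        img += np.exp(-((x_A - bx) ** 2 + (y_A - by) ** 2) / (2 * sig_A**2))
    if spec.has_core:
        ox, oy = (np.asarray(spec.core_offset_nm) * A_PER_NM)
        img += spec.core_amplitude * np.exp(
            -((x_A - ox) ** 2 + (y_A - oy) ** 2) / (2 * sig_A**2)
        )
    peak = img.max()
    if peak > 0:
        img /= peak
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return Image2D(img, pixel_size_A)


def generate_segment_class_library(
    micrograph: Image2D, table: ParticleTable, box_px: int
) -> dict[int, Image2D]:
    """Noise-free per-segment class library for round-trip tests.

    Extracts every picked segment from a (noise-free) micrograph and
    registers it as its own class, assigning ``class_id`` on the records
    in place.  This mirrors how 2D classification separates segments that
    differ in helical phase: each segment's class average genuinely looks
    like that segment.
    """
    from .segments import extract_segment

    library: dict[int, Image2D] = {}
    for i, rec in enumerate(table, start=1):
        library[i] = extract_segment(micrograph, rec, box_px)
        rec.class_id = i
    return library


def generate_class_library(specs: Sequence[FilamentSpec], box_px: int,
                           pixel_size_A: float
                           ) -> tuple[list[Image2D], dict[int, int]]:
    """One noise-free straight render per spec, emulating a 2D class
    library.  Returns (class images, spec index → class_id map); class ids
    are 1-based.  Background (off-filament) intensity is exactly zero."""
    classes: list[Image2D] = []
    class_map: dict[int, int] = {}
    for i, spec in enumerate(specs):
        clean = FilamentSpec(
            pitch_A=spec.pitch_A, diameter_nm=spec.diameter_nm,
            wall_fraction=spec.wall_fraction, has_core=spec.has_core,
            core_radius_nm=spec.core_radius_nm,
            core_offset_nm=spec.core_offset_nm, tilt_deg=spec.tilt_deg,
            contour="straight", noise_sigma=0.0, seed=spec.seed,
            modulation=spec.modulation,
        )
        classes.append(generate_filament_image(clean, box_px, pixel_size_A))
        class_map[i] = i + 1
    return classes, class_map
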