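"""Helical pitch analysis by axial autocorrelation, and out-of-plane tilt
modelling.

The pitch of the helical surface pattern of a filament class average is
estimated as the lag of the first prominent peak of the normalized
autocorrelation of the class's axial intensity profile.  A filament tilted
out of the image plane projects with its axial pattern foreshortened by
cos θ, so apparent pitches shorter than the reference pitch are modelled as
tilt: θ = acos(apparent / reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy import ndimage

from .core import Image2D, ParticleTable, PipelineConfig

__all__ = [
    "AutocorrSpectrum",
    "PatternLabel",
    "FilamentPatternSequence",
    "axial_autocorrelation",
    "detect_pitch",
    "tilt_project",
    "apparent_pitch_curve",
    "estimate_tilt",
    "classify_pattern",
    "order_patterns",
]


@dataclass
class AutocorrSpectrum:
    """Normalized axial autocorrelation with its detected pitch peak."""

    lags_A: np.ndarray
    acf: np.ndarray
    peak_lag_A: Optional[float] = None
    peak_prominence: float = 0.0
    n_samples: int = 0      # length of the axial signal (for taper correction)


@dataclass
class PatternLabel:
    """Helical/straight classification of one 2D class."""

    class_id: int
    label: str                 # "helical" | "straight"
    prominence: float
    pitch_A: Optional[float] = None


@dataclass
class FilamentPatternSequence:
    """Ordered helical/straight labels along one filament (tube)."""

    tube_id: int
    entries: list[tuple[int, str]]   # (segment_index, label), index increasing


def axial_autocorrelation(
    image: Image2D,
    lateral_mask_A: float = 132.0,
    min_lag_A: float = 60.0,
    prominence_threshold: float = 0.5,
) -> AutocorrSpectrum:
    """Normalized (biased) autocorrelation of the mask-averaged axial
    intensity profile.

    The 1D axial signal is the mean intensity per row over the columns
    within ``lateral_mask_A`` of the box center, mean-subtracted.  The
    biased estimator (sum divided by n) guarantees |acf| <= 1 and stable
    peak prominences.  Lags run from 0 to half the box height.
    """
    ny, nx = image.shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * image.pixel_size_A
    cols = np.abs(x) <= lateral_mask_A / 2.0
    if not np.any(cols):
        raise ValueError("lateral mask selects no columns")
    s = image.pixels[:, cols].mean(axis=1)
    s = s - s.mean()

    n = len(s)
    var = np.dot(s, s) / n
    max_lag = n // 2
    lags = np.arange(max_lag + 1)
    if var == 0:
        acf = np.zeros(max_lag + 1)
        acf[0] = 1.0
    else:
        full = np.correlate(s, s, mode="full")[n - 1:]
        acf = full[: max_lag + 1] / (n * var)

    spec = AutocorrSpectrum(lags * image.pixel_size_A, acf, n_samples=n)
    pitch, prom = _find_pitch_peak(spec, min_lag_A, prominence_threshold)
    spec.peak_lag_A = pitch
    spec.peak_prominence = prom
    return spec


def _find_pitch_peak(spectrum: AutocorrSpectrum, min_lag_A: float,
                     prominence_threshold: float
                     ) -> tuple[Optional[float], float]:
    acf = spectrum.acf
    lags = spectrum.lags_A
    peaks, props = sp_signal.find_peaks(acf, prominence=prominence_threshold)
    peaks = [(p, pr) for p, pr in zip(peaks, props["prominences"])
             if lags[p] >= min_lag_A]
    if not peaks:
        return None, 0.0
    idx, prom = peaks[0]  # first qualifying peak = fundamental

    # The biased estimator multiplies the true autocorrelation by the
    # triangular taper (n - k)/n, which drags peaks toward smaller lags.
    # Peak *location* is therefore refined on the taper-corrected curve.
    if spectrum.n_samples > 0:
        n = spectrum.n_samples
        k = np.arange(len(acf))
        with np.errstate(divide="ignore", invalid="ignore"):
            acf_c = np.where(k < n, acf * n / np.maximum(n - k, 1), 0.0)
        lo, hi = max(idx - 2, 1), min(idx + 3, len(acf) - 1)
        idx = lo + int(np.argmax(acf_c[lo:hi]))
        acf = acf_c

    # sub-sample refinement by parabolic fit through the peak triplet
    if 0 < idx < len(acf) - 1:
        y0, y1, y2 = acf[idx - 1], acf[idx], acf[idx + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    step = lags[1] - lags[0]
    return float(lags[idx] + shift * step), float(prom)


def detect_pitch(spectrum: AutocorrSpectrum, min_lag_A: float = 60.0,
                 prominence_threshold: float = 0.5) -> Optional[float]:
    """Pitch estimate: lag of the first autocorrelation peak at
    lag >= ``min_lag_A`` with prominence >= threshold, parabolically
    refined; None when no peak qualifies (no detectable periodicity)."""
    pitch, _ = _find_pitch_peak(spectrum, min_lag_A, prominence_threshold)
    return pitch


def tilt_project(image: Image2D, theta_deg: float) -> Image2D:
    """Orthographic projection of an in-plane pattern tilted by θ about
    the lateral axis: the axial (row) dimension is compressed by cos θ,
    the lateral dimension is unchanged.

    This mirrors the in-silico tilting used to explain apparent pitches
    shorter than the reference: an axial period P projects to P·cos θ.
    """
    if not 0 <= theta_deg < 90:
        raise ValueError("theta must lie in [0, 90) degrees")
    if theta_deg == 0:
        return image.copy()
    cos_t = float(np.cos(np.deg2rad(theta_deg)))
    ny, nx = image.shape
    new_ny = max(int(round(ny * cos_t)), 2)
    # center-preserving axial rescale by exactly cos θ (bilinear)
    j = np.arange(new_ny)
    src_rows = (j - (new_ny - 1) / 2.0) / cos_t + (ny - 1) / 2.0
    rows = np.broadcast_to(src_rows[:, None], (new_ny, nx))
    cols = np.broadcast_to(np.arange(nx)[None, :], (new_ny, nx))
    out = ndimage.map_coordinates(image.pixels, [rows, cols], order=1,
                                  mode="nearest")
    return Image2D(out, image.pixel_size_A)


def apparent_pitch_curve(
    pitch_A: float,
    theta_grid_deg: Sequence[float],
    box_px: int = 250,
    pixel_size_A: float = 2.206,
    min_lag_A: float = 60.0,
    prominence_threshold: float = 0.5,
) -> list[tuple[float, Optional[float]]]:
    """Apparent pitch vs tilt angle: render a noise-free synthetic class
    of the given pitch, tilt it by each θ, and re-measure the
    autocorrelation peak.  Entries where no peak survives the compression
    carry None."""
    from .simulate import FilamentSpec, generate_filament_image

    spec = FilamentSpec(pitch_A=pitch_A, noise_sigma=0.0)
    base = generate_filament_image(spec, box_px, pixel_size_A)
    out: list[tuple[float, Optional[float]]] = []
    for theta in theta_grid_deg:
        tilted = tilt_project(base, float(theta))
        spectrum = axial_autocorrelation(
            tilted, min_lag_A=min_lag_A,
            prominence_threshold=prominence_threshold)
        out.append((float(theta), spectrum.peak_lag_A))
    return out


def estimate_tilt(apparent_pitch_A: float, reference_pitch_A: float) -> float:
    """Out-of-plane tilt angle (degrees) explaining an apparent pitch
    under the cos-foreshortening model: θ = acos(apparent / reference)."""
    if apparent_pitch_A <= 0 or reference_pitch_A <= 0:
        raise ValueError("pitches must be positive")
    if apparent_pitch_A > reference_pitch_A:
        raise ValueError(
            "apparent pitch exceeds the reference; not explainable by tilt"
        )
    return float(np.degrees(np.arccos(apparent_pitch_A / reference_pitch_A)))


def classify_pattern(image: Image2D, config: PipelineConfig,
                     class_id: int = 0,
                     max_lag_A: Optional[float] = None) -> PatternLabel:
    """Label a class helical or straight: helical iff the axial
    autocorrelation has a peak of prominence >= ``config.acf_prominence``
    within the configured lag band."""
    spectrum = axial_autocorrelation(
        image, lateral_mask_A=config.mask_width_A,
        min_lag_A=config.acf_min_lag_A,
        prominence_threshold=config.acf_prominence)
    pitch = spectrum.peak_lag_A
    if pitch is not None and max_lag_A is not None and pitch > max_lag_A:
        pitch = None
    label = "helical" if pitch is not None else "straight"
    return PatternLabel(class_id, label, spectrum.peak_prominence, pitch)


def order_patterns(particles: ParticleTable,
                   labels: dict[int, PatternLabel]
                   ) -> list[FilamentPatternSequence]:
    """One helical/straight sequence per tube, segments in picking order
    along the filament."""
    sequences = []
    for tube_id in particles.tube_ids():
        entries = []
        for rec in particles.by_tube(tube_id):
            if rec.class_id is None or rec.class_id not in labels:
                raise ValueError(
                    f"segment {tube_id}/{rec.segment_index} has no labeled class"
                )
            entries.append((rec.segment_index, labels[rec.class_id].label))
        sequences.append(FilamentPatternSequence(tube_id, entries))
    return sequences
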