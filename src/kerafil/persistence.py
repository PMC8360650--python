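"""Minimal apparent persistence length of traced filament contours.

Highly bent filaments are characterised by the shortest contour length
over which the tangent direction turns by 90° (L90).  This is not the
equilibrium persistence length: it is measured on a selected sub-
population of bent filaments adsorbed to a substrate, so it systematically
underestimates the equilibrium value — the package's worm-like-chain
simulator makes that selection bias explicit and testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .contour import Contour, resample_spline, tangent_angles

__all__ = [
    "PersistenceResult",
    "min_apparent_persistence_length",
    "population_stats",
    "fit_tangent_correlation",
    "Contour",
    "resample_spline",
    "tangent_angles",
]

QUARTER_TURN = np.pi / 2.0
_TURN_TOL = 1e-9   # radians; keeps an exact 90° arc from rounding below it


@dataclass
class PersistenceResult:
    """Population summary of per-contour L90 values (nm).

    ``n`` counts only contours that achieve a 90° turn; mean and SD use
    the sample (n−1) convention.
    """

    values_nm: list[Optional[float]]
    mean_nm: float
    sd_nm: float
    n: int


def min_apparent_persistence_length(contour: Contour,
                                    from_origin: bool = False
                                    ) -> Optional[float]:
    """Shortest arc length over which the tangent turns by 90°.

    The tangent angle is the cumulative unwrapped direction, so an S-curve
    that nets 0° but swings through ±90° is detected through windows, not
    endpoints.  By default the minimum is taken over all start positions
    along the contour (the tightest 90° window anywhere); with
    ``from_origin=True`` only windows starting at the first point count.
    Returns None when no window achieves a 90° turn.
    """
    theta = tangent_angles(contour)
    s = contour.arc_s
    n = len(theta)
    starts = (0,) if from_origin else range(n - 1)
    best: Optional[float] = None
    for i in starts:
        dtheta = np.abs(theta[i + 1:] - theta[i])
        hits = np.nonzero(dtheta >= QUARTER_TURN - _TURN_TOL)[0]
        if hits.size == 0:
            continue
        j = hits[0] + i + 1
        # sub-step interpolation of the crossing between j-1 and j
        a = abs(theta[j - 1] - theta[i])
        b = abs(theta[j] - theta[i])
        if j - 1 > i and b > a:
            frac = (QUARTER_TURN - a) / (b - a)
            s_cross = s[j - 1] + frac * (s[j] - s[j - 1])
        else:
            s_cross = s[j]
        length = s_cross - s[i]
        if best is None or length < best:
            best = length
    return None if best is None else float(best)


def population_stats(values_nm: Sequence[Optional[float]]) -> PersistenceResult:
    """Mean ± sample SD of per-contour L90 over contours with a defined
    value; contours that never turn 90° are excluded from n."""
    defined = [v for v in values_nm if v is not None]
    if not defined:
        raise ValueError("no contour achieved a 90° turn")
    arr = np.asarray(defined, dtype=np.float64)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return PersistenceResult(list(values_nm), float(arr.mean()), sd, len(arr))


def fit_tangent_correlation(contours: Sequence[Contour],
                            max_lag_fraction: float = 0.5,
                            min_correlation: float = 0.2) -> float:
    """Decay length of the ensemble tangent-tangent correlation
    ⟨cos Δθ(s)⟩ ≈ exp(−s/ℓ), fitted log-linearly.

    For a 2D worm-like chain ℓ = 2·Lp.  This is a simulator-validation
    utility, not a headline measurement: it needs an equilibrium ensemble,
    which traced micrograph contours are not.
    """
    if not contours:
        raise ValueError("no contours given")
    step = float(contours[0].arc_s[1] - contours[0].arc_s[0])
    max_lag = int(len(contours[0]) * max_lag_fraction)
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for c in contours:
        theta = tangent_angles(c)
        for k in range(1, max_lag + 1):
            if k >= len(theta):
                break
            sums[k - 1] += np.cos(theta[k:] - theta[:-k]).sum()
            counts[k - 1] += len(theta) - k
    corr = sums / np.maximum(counts, 1)
    lags = np.arange(1, max_lag + 1) * step
    ok = corr > min_correlation
    if ok.sum() < 3:
        raise ValueError("correlation decays too fast for a stable fit")
    slope = np.polyfit(lags[ok], np.log(corr[ok]), 1)[0]
    if slope >= 0:
        raise ValueError("tangent correlation does not decay")
    return float(-1.0 / slope)
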