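"""Shared independent oracles used by the test suite."""

import numpy as np

from kerafil.contour import tangent_angles


def exhaustive_l90(contour):
    """Exhaustive double-loop scan for the minimal 90° tangent-turn
    window, with the same sub-step crossing interpolation as the
    implementation under test."""
    theta = tangent_angles(contour)
    s = contour.arc_s
    best = None
    for i in range(len(theta) - 1):
        for j in range(i + 1, len(theta)):
            if abs(theta[j] - theta[i]) >= np.pi / 2 - 1e-9:
                a = abs(theta[j - 1] - theta[i])
                b = abs(theta[j] - theta[i])
                if j - 1 > i and b > a:
                    frac = (np.pi / 2 - a) / (b - a)
                    s_cross = s[j - 1] + frac * (s[j] - s[j - 1])
                else:
                    s_cross = s[j]
                length = s_cross - s[i]
                if best is None or length < best:
                    best = length
                break
    return best
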