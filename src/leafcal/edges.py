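"""Profile normalization and 50%-intensity field-edge detection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Profile
from .exceptions import EdgeNotFoundError, NormalizationError

__all__ = ["EdgePair", "normalize_profile", "find_half_intensity_edges"]

#: Dose level (percent of the open-field-center value) defining the field edge.
HALF_INTENSITY = 50.0


@dataclass(frozen=True)
class EdgePair:
    """Detected field edges, each reported in its bank's own convention
    (Y2 on ``+u``, Y1 on ``-u``)."""

    y2_edge: float
    y1_edge: float


def normalize_profile(profile: Profile, center_u: float) -> Profile:
    """Scale the profile to 100 at the open-field center.

    ``center_u`` is the midpoint between the two displayed field edges on
    the ``u`` axis.  Idempotent and scale-invariant: the output depends only
    on the shape of the input.
    """
    v = np.asarray(profile.values, dtype=float)
    vmax, vmin = float(np.max(v)), float(np.min(v))
    if not vmax > 5.0 * max(vmin, 0.0):
        raise NormalizationError("profile has no open region (max <= 5 x min)")
    if center_u < profile.u[0] or center_u > profile.u[-1]:
        raise NormalizationError("open-field center lies outside the profile")
    center_val = float(np.interp(center_u, profile.u, v))
    if center_val <= 0:
        raise NormalizationError("non-positive value at the open-field center")
    return Profile(u=profile.u, values=v * (100.0 / center_val), x_line=profile.x_line)


def _crossings(u: np.ndarray, v: np.ndarray, level: float) -> np.ndarray:
    """All crossings of ``level``, one per bracketing sample pair, by linear
    interpolation.  Samples exactly at the level count as crossings."""
    d = v - level
    out = []
    for i in range(len(u) - 1):
        a, b = d[i], d[i + 1]
        if a == 0.0:
            out.append(u[i])
        elif a * b < 0.0:
            out.append(u[i] + (u[i + 1] - u[i]) * a / (a - b))
    if len(d) and d[-1] == 0.0:
        out.append(u[-1])
    return np.asarray(out)


def find_half_intensity_edges(
    profile: Profile, y2_displayed: float, y1_displayed: float
) -> EdgePair:
    """Locate the 50% crossings on the Y2 and Y1 sides of a normalized profile.

    Every adjacent sample pair is scanned for a sign change of
    ``value - 50``; the crossing is interpolated linearly within the
    bracketing pair.  For each side the crossing nearest the corresponding
    displayed edge is taken (displayed edges sit at ``u = +y2`` and
    ``u = -y1``), and the result is converted into that bank's convention.
    """
    u = np.asarray(profile.u, dtype=float)
    v = np.asarray(profile.values, dtype=float)
    crossings = _crossings(u, v, HALF_INTENSITY)
    if crossings.size == 0:
        raise EdgeNotFoundError("Y2", "profile never crosses the 50% level")

    u_y2_displayed = +float(y2_displayed)
    u_y1_displayed = -float(y1_displayed)

    c2 = crossings[np.argmin(np.abs(crossings - u_y2_displayed))]
    c1 = crossings[np.argmin(np.abs(crossings - u_y1_displayed))]
    if abs(c2 - c1) < 1e-12 and abs(u_y2_displayed - u_y1_displayed) > 0.5:
        # A single crossing cannot serve both sides of an open aperture.
        side = "Y2" if abs(c2 - u_y2_displayed) > abs(c1 - u_y1_displayed) else "Y1"
        raise EdgeNotFoundError(side)
    return EdgePair(y2_edge=float(+c2), y1_edge=float(-c1))
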