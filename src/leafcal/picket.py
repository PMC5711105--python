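"""Picket Fence test simulation and post analysis.

Narrow abutting strips are delivered sequentially, each shifted by a fixed
amount slightly smaller than the strip width; the overlap bands receive
double dose and show up as dark "posts".  Post count, spacing regularity
and amplitude are sensitive to leaf-position (and hence RLO-table) errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .engine import (
    DEFAULT_MARGIN,
    GridSpec,
    PlanarDose,
    Profile,
    _bilinear,
    compute_planar_dose,
)
from .exceptions import InvalidBeamError, NormalizationError
from .machine import BeamDefinition, MachineModel, PhantomSetup, RLOTable

__all__ = [
    "StripSequence",
    "PostReport",
    "build_strips",
    "simulate_composite",
    "detect_posts",
]

#: Local maxima above this level (percent of the strip plateau) count as posts.
POST_THRESHOLD = 130.0
#: Minimum separation between distinct posts (cm).
POST_MIN_SEPARATION = 1.0


@dataclass(frozen=True)
class StripSequence:
    """Ordered strip beams plus the construction parameters."""

    strips: tuple[BeamDefinition, ...]
    shift: float
    overlap: float  # cm

    @property
    def strip_width(self) -> float:
        return self.shift + self.overlap

    @property
    def n_strips(self) -> int:
        return len(self.strips)


@dataclass(frozen=True)
class PostReport:
    """Detected post centers (axis cm) and their spacing statistics."""

    post_positions: tuple[float, ...]
    mean_spacing: float
    spacing_sd: float
    amplitudes: tuple[float, ...] = ()

    @property
    def count(self) -> int:
        return len(self.post_positions)


def build_strips(
    model: MachineModel,
    overlap_mm: float = 2.0,
    *,
    n_strips: int = 12,
    shift: float = 2.0,
    first_center: float = 11.0,
    x1: float = 20.0,
    x2: float = 2.0,
    backup_gap: float = 2.0,
) -> StripSequence:
    """Strip sequence for the Picket Fence test.

    Strip ``j`` opens a ``shift + overlap`` wide aperture centered at
    ``first_center - j*shift``; consecutive apertures overlap by exactly
    ``overlap``.  With the defaults (2 mm overlap) the 12 strips run from
    ``(Y2, Y1) = (12.1, -9.9)`` down to ``(-9.9, 12.1)``; a 3 mm overlap
    widens each strip symmetrically to 2.3 cm, keeping the centers.  All
    strips share the X jaws (default ``X1=20, X2=2``).
    """
    overlap = overlap_mm / 10.0
    if overlap >= shift:
        raise InvalidBeamError("overlap must be smaller than the shift; strips would merge")
    if overlap_mm not in (2.0, 3.0):
        warnings.warn(
            f"overlap of {overlap_mm} mm differs from the standard 2 or 3 mm tests",
            stacklevel=2,
        )
    if n_strips < 1:
        raise InvalidBeamError("need at least one strip")

    width = shift + overlap
    strips = []
    for j in range(n_strips):
        c = first_center - j * shift
        y2 = c + 0.5 * width
        y1 = 0.5 * width - c
        model.check_travel([y2, y1, y2 + backup_gap, y1 + backup_gap])
        strips.append(
            BeamDefinition.uniform(
                model.layout, y2=y2, y1=y1, x1=x1, x2=x2, backup_gap=backup_gap
            )
        )
    return StripSequence(strips=tuple(strips), shift=shift, overlap=overlap)


def simulate_composite(
    model: MachineModel,
    seq: StripSequence,
    table: RLOTable,
    setup: PhantomSetup | None = None,
    *,
    margin: float = DEFAULT_MARGIN,
) -> PlanarDose:
    """Sum of the per-strip planar doses on a common grid, renormalized so
    the single-strip plateau level is 100."""
    if setup is None:
        setup = PhantomSetup()
    h = setup.grid_spacing

    lows, highs, centers = [], [], []
    x1 = seq.strips[0].x1
    x2 = seq.strips[0].x2
    for beam in seq.strips:
        lo, hi = beam.pair_aperture(1)
        lows.append(lo)
        highs.append(hi)
        centers.append(0.5 * (lo + hi))
    grid = GridSpec.cover(
        (-x1 - margin, x2 + margin),
        (min(lows) - margin, max(highs) + margin),
        h,
    )

    total = np.zeros((grid.nu, grid.nx))
    for beam in seq.strips:
        dose = compute_planar_dose(model, beam, table, setup, grid=grid)
        total += dose.values

    # Plateau = median composite value at the strip aperture centers (on the
    # X-jaw center line); robust against the posts, which sit between them.
    x_center = 0.5 * (-x1 + x2)
    plateau = float(
        np.median([_bilinear(total, grid.x0, grid.u0, h, x_center, c) for c in centers])
    )
    if plateau <= 0:
        raise NormalizationError("composite has no open plateau")
    return PlanarDose(grid.x0, grid.u0, h, total * (100.0 / plateau))


def detect_posts(
    profile: Profile,
    *,
    threshold: float = POST_THRESHOLD,
    min_separation: float = POST_MIN_SEPARATION,
) -> PostReport:
    """Locate picket-fence posts in a normalized composite profile.

    Posts are local maxima above ``threshold`` (percent of plateau) at least
    ``min_separation`` cm apart; each center is refined by a parabola
    through the three samples around the maximum.  An empty report (not an
    error) is returned when nothing exceeds the threshold.
    """
    v = np.asarray(profile.values, dtype=float)
    h = profile.spacing
    idx, _ = find_peaks(v, height=threshold, distance=max(1, int(round(min_separation / h))))

    positions, amplitudes = [], []
    for m in idx:
        if 0 < m < len(v) - 1:
            alpha, beta, gamma = v[m - 1], v[m], v[m + 1]
            denom = alpha - 2.0 * beta + gamma
            delta = 0.5 * (alpha - gamma) / denom if denom != 0 else 0.0
        else:
            delta = 0.0
        positions.append(float(profile.u[m] + delta * h))
        amplitudes.append(float(v[m]))

    spacings = np.diff(positions)
    return PostReport(
        post_positions=tuple(positions),
        mean_spacing=float(np.mean(spacings)) if len(spacings) else float("nan"),
        spacing_sd=float(np.std(spacings)) if len(spacings) >= 2 else float("nan"),
        amplitudes=tuple(amplitudes),
    )
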