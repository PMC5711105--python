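"""Light-field edge modeling and dosimetric <-> light-field conversion.

A machine whose leaves are calibrated with the light field places its tips
where the *geometric shadow boundary* (the source ray tangent to the tip
circle) lands on the displayed value, instead of the radiation 50% edge.
The conversion curve - light-field edge minus radiation edge per displayed
position, bank-averaged - is fitted with a straight line and folded into
the dosimetric RLO table to produce the light-field-calibration table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .edges import find_half_intensity_edges, normalize_profile
from .engine import compute_planar_dose, extract_line_profile
from .exceptions import DegenerateFitError
from .machine import (
    BeamDefinition,
    MachineModel,
    PhantomSetup,
    RLOTable,
    effective_edge,
)

__all__ = [
    "LinearFit",
    "light_field_edge",
    "conversion_offsets",
    "fit_linear",
    "make_light_table",
    "derive_light_table",
]


@dataclass(frozen=True)
class LinearFit:
    """Ordinary-least-squares line ``y = slope * x + intercept``."""

    slope: float
    intercept: float
    residual_rms: float
    n_points: int

    def __call__(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def _shadow_boundary_canonical(model: MachineModel, e_axis: float) -> float:
    """Shadow boundary (axis cm) for a canonical leaf: material at low u,
    open field at high u, apex projecting to ``e_axis``.

    The boundary is the extreme isocenter projection over the tip-face arc
    within the leaf slab: either the point where the source ray is tangent
    to the tip circle (interior critical point of the projection) or a slab
    corner of the arc.
    """
    sad = model.source_to_iso_distance
    zl = model.source_to_leaf_plane
    R = model.tip_radius
    half_t = 0.5 * model.leaf_thickness
    u_c = e_axis * zl / sad - R

    # Arc: u = u_c + R cos(theta), z = zl + R sin(theta), |sin(theta)| <= t/2R.
    theta_m = math.asin(min(half_t / R, 1.0))

    def proj(theta: float) -> float:
        return (u_c + R * math.cos(theta)) * sad / (zl + R * math.sin(theta))

    candidates = [-theta_m, theta_m]
    # Tangency condition d(proj)/d(theta) = 0  <=>  zl sin + u_c cos = -R.
    amp = math.hypot(zl, u_c)
    if amp > 0 and abs(R / amp) <= 1.0:
        phi = math.atan2(u_c, zl)
        base = math.asin(-R / amp)
        for theta in (base - phi, math.pi - base - phi):
            theta = math.atan2(math.sin(theta), math.cos(theta))  # wrap
            if -theta_m <= theta <= theta_m:
                candidates.append(theta)
    return max(proj(t) for t in candidates)


def light_field_edge(model: MachineModel, e_axis: float, opening_side: int = 1) -> float:
    """Light-field (geometric shadow) boundary on the ``u`` axis (cm) for a
    leaf whose tip apex projects to ``e_axis``.

    ``opening_side = +1``: open field at larger ``u`` (Y1-type leaf);
    ``-1``: open field at smaller ``u`` (Y2-type).  No transmission is
    involved: this is where the visible light shadow ends.  For
    ``tip_radius -> 0`` it degenerates to the apex projection itself.
    """
    return opening_side * _shadow_boundary_canonical(model, opening_side * e_axis)


def fit_linear(points) -> LinearFit:
    """Ordinary least squares line through ``points = [(x, y), ...]``."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise DegenerateFitError("need at least two (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise DegenerateFitError("all x values identical; slope undetermined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=len(x),
    )


def conversion_offsets(
    model: MachineModel,
    table: RLOTable,
    setup: PhantomSetup | None = None,
    positions=None,
    *,
    leaf_index: int = 19,
    aperture: float = 8.0,
) -> list[tuple[float, float]]:
    """Light-field minus radiation (50%) edge per displayed position,
    averaged over the two banks (cm).

    This is the engine's analogue of the bank shift a physicist applies to
    realign the light field after a dosimetric leaf calibration: for each
    displayed position the leaf is placed at its effective position
    ``e = d - r(d)`` and the two edge definitions are compared in bank
    coordinates.  Each bank is measured in a constant-width beam with the
    opposing bank at ``aperture - d``.
    """
    if setup is None:
        setup = PhantomSetup()
    if positions is None:
        positions = np.arange(-10.0, 18.0 + 1e-9, 2.0)
    positions = [float(p) for p in positions]
    x_line = model.layout.leaf_center(leaf_index)

    edge_cache: dict[tuple[float, float], object] = {}

    def radiation_edges(y2_d: float, y1_d: float):
        key = (round(y2_d, 9), round(y1_d, 9))
        if key not in edge_cache:
            model.check_travel([y2_d, y1_d, y2_d + 2.0, y1_d + 2.0])
            beam = BeamDefinition.uniform(model.layout, y2=y2_d, y1=y1_d)
            dose = compute_planar_dose(model, beam, table, setup)
            profile = normalize_profile(
                extract_line_profile(dose, x_line), 0.5 * (y2_d - y1_d)
            )
            edge_cache[key] = find_half_intensity_edges(profile, y2_d, y1_d)
        return edge_cache[key]

    out = []
    for d in positions:
        opposing = aperture - d
        e = effective_edge(d, table)

        # Y2 leaf displayed at d: apex at axis +e, opens toward smaller u.
        rad_y2 = radiation_edges(d, opposing).y2_edge
        light_y2 = +light_field_edge(model, +e, opening_side=-1)

        # Y1 leaf displayed at d: apex at axis -e, opens toward larger u.
        rad_y1 = radiation_edges(opposing, d).y1_edge
        light_y1 = -light_field_edge(model, -e, opening_side=+1)

        offset = 0.5 * ((light_y2 - rad_y2) + (light_y1 - rad_y1))
        out.append((d, float(offset)))
    return out


def make_light_table(dosimetric: RLOTable, fit: LinearFit) -> RLOTable:
    """Light-field-calibration RLO table: the dosimetric table plus the
    fitted conversion line, at the same node positions.

    The sign convention: leaves set by light field sit displaced by the
    conversion offset relative to dosimetric calibration, so the table must
    absorb ``+ (slope * d + intercept)``.  Subtracting the same line
    recovers the dosimetric table exactly (affine round trip).
    """
    pos = np.asarray(dosimetric.positions)
    return RLOTable.from_arrays(pos, np.asarray(dosimetric.offsets) + fit(pos))


def derive_light_table(
    model: MachineModel,
    dosimetric: RLOTable,
    setup: PhantomSetup | None = None,
    positions=None,
    **kwargs,
):
    """Full pipeline: conversion points -> linear fit -> light-field table.

    Returns ``(points, fit, table)``.
    """
    points = conversion_offsets(model, dosimetric, setup, positions, **kwargs)
    fit = fit_linear(points)
    return points, fit, make_light_table(dosimetric, fit)
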