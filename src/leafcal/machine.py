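"""Machine geometry, MLC layout, RLO tables and beam definitions.

Coordinate conventions (normative for the whole package)
--------------------------------------------------------
The leaf-travel axis at the isocenter plane is ``u`` (cm).  Each leaf bank
has a *bank coordinate* whose positive direction is the bank retracting
(opening the field): the Y2 bank coordinate equals ``+u`` and the Y1 bank
coordinate equals ``-u``.  A *displayed position* ``d`` is the intended
field-edge location in bank coordinates, so a Y2 leaf displayed at ``d``
puts its edge at ``u = +d`` and a Y1 leaf displayed at ``d`` puts its edge
at ``u = -d``.  The aperture of a pair displayed ``(y2, y1)`` therefore
spans ``[-y1, +y2]`` on the axis and its width is ``y2 + y1``; e.g.
``(18, -10)`` opens ``[+10, +18]`` (8 cm) and ``(12.1, -9.9)`` opens
``[+9.9, +12.1]`` (2.2 cm).

Rounded-leaf-offset (RLO) application: the effective apex position in bank
coordinates is ``e = d - r(d)`` where ``r`` is the RLO lookup.  A positive
offset moves the leaf toward the opposing bank (shrinks the aperture); a
negative offset retracts it.  Typical tungsten-leaf tables are <= 0
everywhere: the planning system pulls each leaf back before computing dose
so that the broadened rounded-tip penumbra lands its 50% level on the
displayed value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, InvalidBeamError

__all__ = [
    "MLCLayout",
    "MachineModel",
    "RLOTable",
    "BeamDefinition",
    "PhantomSetup",
    "rlo_lookup",
    "effective_edge",
    "aperture_width",
    "load_preset",
    "PRESET_NAMES",
]

PRESET_NAMES = ("elekta80", "varian120")


@dataclass(frozen=True)
class MLCLayout:
    """Per-bank leaf arrangement projected to the isocenter plane.

    Leaves are numbered 1..n by increasing X; leaf ``i`` occupies
    ``[leaf_edges_x[i-1], leaf_edges_x[i])`` with its center at the midpoint.
    The stack of widths is centered on X = 0.
    """

    leaf_widths: tuple[float, ...]

    def __post_init__(self):
        if len(self.leaf_widths) == 0:
            raise ConfigurationError("MLC layout needs at least one leaf pair")
        if any(w <= 0 for w in self.leaf_widths):
            raise ConfigurationError("leaf widths must be positive")

    @property
    def leaf_count_per_bank(self) -> int:
        return len(self.leaf_widths)

    @property
    def leaf_edges_x(self) -> np.ndarray:
        """Cumulative X boundaries (length n+1), centered about X = 0."""
        w = np.asarray(self.leaf_widths, dtype=float)
        edges = np.concatenate([[0.0], np.cumsum(w)])
        return edges - edges[-1] / 2.0

    def leaf_span(self, index: int) -> tuple[float, float]:
        """X interval covered by 1-based leaf ``index``."""
        self._check_index(index)
        e = self.leaf_edges_x
        return float(e[index - 1]), float(e[index])

    def leaf_center(self, index: int) -> float:
        lo, hi = self.leaf_span(index)
        return 0.5 * (lo + hi)

    def leaf_index_at(self, x: float) -> int | None:
        """1-based leaf covering X position ``x``, or None outside the stack."""
        e = self.leaf_edges_x
        if x < e[0] or x >= e[-1]:
            return None
        return int(np.searchsorted(e, x, side="right"))

    def _check_index(self, index: int) -> None:
        if not 1 <= index <= self.leaf_count_per_bank:
            raise ConfigurationError(
                f"leaf index {index} outside 1..{self.leaf_count_per_bank}"
            )


@dataclass(frozen=True)
class MachineModel:
    """Everything the dose engine needs to know about the treatment head.

    Parameters
    ----------
    source_to_iso_distance : cm
        SAD; the isocenter plane where all positions are expressed.
    source_to_leaf_plane : cm
        Distance from the point source to the mid-plane of the leaf slab.
    tip_radius : cm
        Radius of the circular rounded leaf end (physical units at the leaf).
    leaf_thickness : cm
        Leaf slab thickness along the beam direction.
    mu : 1/cm
        Effective linear attenuation coefficient of the leaf material.
    transmission_floor : dimensionless
        Relative fluence under a fully blocking leaf body (inter/intra-leaf
        leakage folded into one number).
    blur_sigma : cm at isocenter
        Gaussian kernel width folding source size and shallow-depth scatter
        into a single penumbra blur.
    layout : MLCLayout
    travel_min, travel_max : cm
        Displayed-position travel limits in bank coordinates.
    """

    source_to_iso_distance: float = 100.0
    source_to_leaf_plane: float = 38.0
    tip_radius: float = 4.0
    leaf_thickness: float = 7.5
    mu: float = 0.9
    transmission_floor: float = 0.017
    blur_sigma: float = 0.10
    layout: MLCLayout = field(default_factory=lambda: MLCLayout((1.0,) * 40))
    travel_min: float = -12.5
    travel_max: float = 20.0

    def __post_init__(self):
        if not 0 < self.source_to_leaf_plane < self.source_to_iso_distance:
            raise ConfigurationError(
                "need 0 < source_to_leaf_plane < source_to_iso_distance"
            )
        if self.tip_radius <= 0:
            raise ConfigurationError("tip_radius must be > 0")
        if self.leaf_thickness <= 0:
            raise ConfigurationError("leaf_thickness must be > 0")
        if self.mu <= 0:
            raise ConfigurationError("mu must be > 0")
        if not 0 <= self.transmission_floor < 1:
            raise ConfigurationError("transmission_floor must be in [0, 1)")
        if self.blur_sigma < 0:
            raise ConfigurationError("blur_sigma must be >= 0")
        if self.travel_min >= self.travel_max:
            raise ConfigurationError("travel_min must be < travel_max")

    def check_travel(self, displayed) -> None:
        d = np.asarray(displayed, dtype=float)
        if np.any(d < self.travel_min - 1e-9) or np.any(d > self.travel_max + 1e-9):
            raise InvalidBeamError(
                f"displayed position outside travel range "
                f"[{self.travel_min}, {self.travel_max}] cm"
            )


@dataclass(frozen=True)
class RLOTable:
    """Per-displayed-position leaf-edge correction curve.

    ``positions`` are strictly increasing displayed positions (cm at
    isocenter); ``offsets`` the correction values (cm).  Lookup is
    piecewise-linear between nodes and clamps to the end values outside the
    tabulated range, so it is total on the whole real line.
    """

    positions: tuple[float, ...]
    offsets: tuple[float, ...]

    def __post_init__(self):
        if len(self.positions) == 0:
            raise ConfigurationError("RLO table must have at least one node")
        if len(self.positions) != len(self.offsets):
            raise ConfigurationError("positions and offsets differ in length")
        p = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(p) <= 0):
            raise ConfigurationError("RLO table positions must be strictly increasing")

    @classmethod
    def from_arrays(cls, positions, offsets) -> "RLOTable":
        return cls(tuple(float(p) for p in positions), tuple(float(o) for o in offsets))

    @classmethod
    def zero(cls, positions=(-10.0, 18.0)) -> "RLOTable":
        """All-zero table over the given node positions (identity correction)."""
        return cls.from_arrays(positions, [0.0] * len(positions))

    def __call__(self, d):
        return rlo_lookup(self, d)


def rlo_lookup(table: RLOTable, d):
    """Offset (cm) for displayed position(s) ``d``.

    Piecewise-linear between the tabulated nodes, clamped to the first/last
    offset outside the tabulated range.  Exact at the nodes.
    """
    if not isinstance(table, RLOTable):
        raise ConfigurationError("rlo_lookup needs a valid RLOTable")
    out = np.interp(np.asarray(d, dtype=float), table.positions, table.offsets)
    return float(out) if np.ndim(d) == 0 else out


def effective_edge(d, table: RLOTable):
    """Effective apex position ``e = d - r(d)`` in bank coordinates (cm)."""
    r = rlo_lookup(table, d)
    return d - r


def aperture_width(y2_displayed: float, y1_displayed: float) -> float:
    """Aperture width (cm) of a leaf pair displayed at ``(y2, y1)``.

    In bank conventions the axis edges sit at ``+y2`` and ``-y1``, so the
    width is ``y2 + y1``.  Zero is a legally closed pair; a negative width
    means the leaves would interdigitate and raises :class:`InvalidBeamError`.
    """
    w = float(y2_displayed) + float(y1_displayed)
    if w < 0:
        if math.isclose(w, 0.0, abs_tol=1e-12):
            return 0.0
        raise InvalidBeamError(
            f"negative aperture width {w:.4f} cm for (Y2={y2_displayed}, Y1={y1_displayed})"
        )
    return w


@dataclass(frozen=True)
class BeamDefinition:
    """Jaw and per-leaf displayed positions for a single static beam.

    ``x1``/``x2`` are X-jaw displayed positions; the X aperture spans
    ``[-x1, +x2]``.  ``y1_positions``/``y2_positions`` hold one displayed
    value per leaf in each bank's own convention.  ``backup_y1``/``backup_y2``
    are the backup diaphragm displayed values (same conventions; they must
    trail their bank's leaves, i.e. be >= every leaf value in the bank).
    """

    x1: float
    x2: float
    y1_positions: tuple[float, ...]
    y2_positions: tuple[float, ...]
    backup_y1: float
    backup_y2: float

    def __post_init__(self):
        if len(self.y1_positions) != len(self.y2_positions):
            raise InvalidBeamError("leaf banks differ in leaf count")
        if len(self.y1_positions) == 0:
            raise InvalidBeamError("beam needs at least one leaf pair")
        if self.x1 + self.x2 < 0:
            raise InvalidBeamError("X jaw aperture is negative")
        for y2, y1 in zip(self.y2_positions, self.y1_positions):
            aperture_width(y2, y1)  # raises on negative pair width
        if self.backup_y1 < max(self.y1_positions) - 1e-9:
            raise InvalidBeamError("Y1 backup jaw protrudes past its leaves")
        if self.backup_y2 < max(self.y2_positions) - 1e-9:
            raise InvalidBeamError("Y2 backup jaw protrudes past its leaves")

    @classmethod
    def uniform(
        cls,
        layout: MLCLayout,
        y2: float,
        y1: float,
        *,
        x1: float = 10.0,
        x2: float = 10.0,
        backup_gap: float = 2.0,
    ) -> "BeamDefinition":
        """Beam with every leaf pair at the same displayed positions and the
        backup jaws ``backup_gap`` cm behind each bank."""
        n = layout.leaf_count_per_bank
        return cls(
            x1=float(x1),
            x2=float(x2),
            y1_positions=(float(y1),) * n,
            y2_positions=(float(y2),) * n,
            backup_y1=float(y1) + backup_gap,
            backup_y2=float(y2) + backup_gap,
        )

    @property
    def n_leaf_pairs(self) -> int:
        return len(self.y1_positions)

    def pair_aperture(self, index: int) -> tuple[float, float]:
        """Axis interval ``[-y1, +y2]`` opened by 1-based pair ``index``."""
        y2 = self.y2_positions[index - 1]
        y1 = self.y1_positions[index - 1]
        return (-y1, y2)

    def mirrored(self) -> "BeamDefinition":
        """Beam with the two leaf banks (and X jaws) exchanged, i.e. the
        geometry reflected about the axes."""
        return BeamDefinition(
            x1=self.x2,
            x2=self.x1,
            y1_positions=self.y2_positions,
            y2_positions=self.y1_positions,
            backup_y1=self.backup_y2,
            backup_y2=self.backup_y1,
        )


@dataclass(frozen=True)
class PhantomSetup:
    """Water phantom and scoring-grid geometry.

    ``ssd`` + ``calc_depth`` place the scoring plane at the isocenter for the
    standard setup (98 + 2 = 100 cm).  Only ``grid_spacing`` enters the dose
    computation directly; SSD and depth are folded into the machine's blur
    kernel (see the methods note).
    """

    ssd: float = 98.0
    calc_depth: float = 2.0
    grid_spacing: float = 0.05

    def __post_init__(self):
        if self.ssd <= 0 or self.calc_depth < 0:
            raise ConfigurationError("ssd must be > 0 and calc_depth >= 0")
        if self.grid_spacing <= 0:
            raise ConfigurationError("grid_spacing must be > 0")


def load_preset(name: str) -> tuple[MachineModel, PhantomSetup]:
    """Load a packaged machine preset by name.

    ``elekta80``: 40 leaf pairs, 1.0 cm wide at isocenter.
    ``varian120``: 60 pairs; central 40 are 0.5 cm, outer 2 x 10 are 1.0 cm.

    Returns ``(MachineModel, PhantomSetup)``.
    """
    from . import io as _io  # local import; io depends on these types

    if name not in PRESET_NAMES:
        raise ConfigurationError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        )
    return _io.load_machine_config(_io.preset_path(name))
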