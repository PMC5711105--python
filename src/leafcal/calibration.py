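"""Rounded-leaf-offset table calibration.

The procedure: sweep a fixed-width aperture across the leaf travel range in
constant steps so that every displayed position is visited once by each
bank, locate the calculated 50% field edge for each bank at each position,
and correct the RLO table by the residual shift::

    modified_b(d) = rlo_used(d) + (edge_b(d) - d)        for bank b
    new_table(d)  = (modified_Y2(d) + modified_Y1(d)) / 2

A single correction pass suffices up to the (weak) dependence of the tip
penumbra offset on the effective leaf position; `verify_closed_loop` reruns
the sweep with the candidate table and reports the worst residual.

`RLOCalibration` / `RLOCalibrationResults` wrap the functional pieces in a
fit/results pair; the module-level functions remain the primitive API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __about__
from .edges import find_half_intensity_edges, normalize_profile
from .engine import compute_planar_dose, extract_line_profile
from .exceptions import InvalidBeamError
from .machine import (
    BeamDefinition,
    MachineModel,
    PhantomSetup,
    RLOTable,
    rlo_lookup,
)

__all__ = [
    "SweepRow",
    "SweepResult",
    "SWEEP_COLUMNS",
    "build_sweep_beams",
    "compute_shift",
    "run_sweep",
    "derive_modified_table",
    "verify_closed_loop",
    "compare_tables",
    "RLOCalibration",
    "RLOCalibrationResults",
]

#: Column headers of the seven-column sweep table (TSV export order).
SWEEP_COLUMNS = (
    "Displayed Leaf Position (cm)",
    "Y2 Leaf Edge (cm)",
    "Y1 Leaf Edge (cm)",
    "RLO Values (cm)",
    "Y2 Modified RLO (cm)",
    "Y1 Modified RLO (cm)",
    "Av. of Y1 and Y2 Modified RLO (cm)",
)


def compute_shift(edge: float, displayed: float) -> float:
    """Residual shift ``edge - displayed`` (cm), both in bank convention."""
    return float(edge) - float(displayed)


@dataclass(frozen=True)
class SweepRow:
    """One displayed position of the sweep: measured edges, the RLO value in
    force, and the per-bank and averaged corrected values."""

    displayed: float
    y2_edge: float
    y1_edge: float
    rlo_used: float

    @property
    def y2_modified(self) -> float:
        return self.rlo_used + compute_shift(self.y2_edge, self.displayed)

    @property
    def y1_modified(self) -> float:
        return self.rlo_used + compute_shift(self.y1_edge, self.displayed)

    @property
    def average_modified(self) -> float:
        return 0.5 * (self.y2_modified + self.y1_modified)


@dataclass(frozen=True)
class SweepResult:
    """Rows of the sweep in ascending displayed position, plus the table
    that was in force while the edges were computed."""

    rows: tuple[SweepRow, ...]
    table_used: RLOTable

    def __post_init__(self):
        d = [r.displayed for r in self.rows]
        if len(set(d)) != len(d) or sorted(d) != d:
            raise InvalidBeamError("sweep rows must be unique and ascending")

    @property
    def displayed(self) -> np.ndarray:
        return np.array([r.displayed for r in self.rows])

    def max_residual(self) -> float:
        """Worst |edge - displayed| (cm) over both banks and all rows."""
        return max(
            max(abs(compute_shift(r.y2_edge, r.displayed)),
                abs(compute_shift(r.y1_edge, r.displayed)))
            for r in self.rows
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                SWEEP_COLUMNS[0]: [r.displayed for r in self.rows],
                SWEEP_COLUMNS[1]: [r.y2_edge for r in self.rows],
                SWEEP_COLUMNS[2]: [r.y1_edge for r in self.rows],
                SWEEP_COLUMNS[3]: [r.rlo_used for r in self.rows],
                SWEEP_COLUMNS[4]: [r.y2_modified for r in self.rows],
                SWEEP_COLUMNS[5]: [r.y1_modified for r in self.rows],
                SWEEP_COLUMNS[6]: [r.average_modified for r in self.rows],
            }
        )


def build_sweep_beams(
    model: MachineModel,
    start_y2: float = 18.0,
    start_y1: float = -10.0,
    step: float = 2.0,
    count: int = 15,
    *,
    x1: float = 10.0,
    x2: float = 10.0,
    backup_gap: float = 2.0,
) -> list[BeamDefinition]:
    """Constant-width sweep: beam ``k`` has all Y2 leaves displayed at
    ``start_y2 - k*step`` and all Y1 leaves at ``start_y1 + k*step``, with
    backup jaws trailing each bank by ``backup_gap``.

    The aperture width ``start_y2 + start_y1`` is the same for every beam;
    over the full sweep each bank visits every displayed position of the
    other, which is what lets one sweep populate both edge columns at all
    ``count`` positions.
    """
    width = start_y2 + start_y1
    if width <= 0:
        raise InvalidBeamError("sweep aperture width must be positive")
    if count < 1:
        raise InvalidBeamError("count must be >= 1")
    beams = []
    for k in range(count):
        y2 = start_y2 - k * step
        y1 = start_y1 + k * step
        model.check_travel([y2, y1, y2 + backup_gap, y1 + backup_gap])
        beams.append(
            BeamDefinition.uniform(
                model.layout, y2=y2, y1=y1, x1=x1, x2=x2, backup_gap=backup_gap
            )
        )
    return beams


def run_sweep(
    model: MachineModel,
    table: RLOTable,
    setup: PhantomSetup | None = None,
    *,
    leaf_index: int = 19,
    start_y2: float = 18.0,
    start_y1: float = -10.0,
    step: float = 2.0,
    count: int = 15,
) -> SweepResult:
    """Run the full edge sweep with ``table`` in force.

    For each beam the planar dose is computed, the profile through the
    center of leaf pair ``leaf_index`` extracted and normalized, and the 50%
    edges recorded.  Each beam contributes its Y2 edge to the row at its Y2
    displayed value and its Y1 edge to the row at its Y1 displayed value;
    the default design visits each of the 15 positions exactly once per
    bank.
    """
    if setup is None:
        setup = PhantomSetup()
    beams = build_sweep_beams(model, start_y2, start_y1, step, count)
    x_line = model.layout.leaf_center(leaf_index)

    y2_edges: dict[float, float] = {}
    y1_edges: dict[float, float] = {}
    for beam in beams:
        y2_d = beam.y2_positions[0]
        y1_d = beam.y1_positions[0]
        dose = compute_planar_dose(model, beam, table, setup)
        profile = extract_line_profile(dose, x_line)
        center_u = 0.5 * (y2_d - y1_d)  # midpoint of the displayed axis edges
        profile = normalize_profile(profile, center_u)
        pair = find_half_intensity_edges(profile, y2_d, y1_d)
        y2_edges[round(y2_d, 9)] = pair.y2_edge
        y1_edges[round(y1_d, 9)] = pair.y1_edge

    if set(y2_edges) != set(y1_edges):
        raise InvalidBeamError(
            "sweep design must visit the same displayed positions with both banks"
        )
    rows = tuple(
        SweepRow(
            displayed=d,
            y2_edge=y2_edges[d],
            y1_edge=y1_edges[d],
            rlo_used=rlo_lookup(table, d),
        )
        for d in sorted(y2_edges)
    )
    return SweepResult(rows=rows, table_used=table)


def derive_modified_table(sweep: SweepResult) -> RLOTable:
    """Corrected RLO table from a completed sweep: per row the bank-averaged
    ``rlo_used + (edge - displayed)``, tabulated at the sweep positions."""
    return RLOTable.from_arrays(
        [r.displayed for r in sweep.rows],
        [r.average_modified for r in sweep.rows],
    )


def verify_closed_loop(
    model: MachineModel,
    table: RLOTable,
    setup: PhantomSetup | None = None,
    **sweep_kwargs,
) -> float:
    """Re-run the sweep with ``table`` in force; return the maximum
    |edge - displayed| (cm) over both banks and all positions."""
    return run_sweep(model, table, setup, **sweep_kwargs).max_residual()


def compare_tables(a: RLOTable, b: RLOTable, n: int = 2001) -> float:
    """Maximum |lookup_a - lookup_b| (cm) on a dense grid over the shared
    position range of the two tables."""
    lo = max(a.positions[0], b.positions[0])
    hi = min(a.positions[-1], b.positions[-1])
    if lo > hi:
        raise ValueError("tables cover disjoint position ranges")
    grid = np.linspace(lo, hi, n) if hi > lo else np.array([lo])
    return float(np.max(np.abs(rlo_lookup(a, grid) - rlo_lookup(b, grid))))


@dataclass
class RLOCalibration:
    """RLO-table calibration model for one machine.

    Bundles the machine model, phantom setup, starting RLO table and sweep
    design; :meth:`fit` runs the sweep and derives the corrected table.

    Examples
    --------
    >>> from leafcal import load_preset, RLOTable, RLOCalibration
    >>> model, setup = load_preset("elekta80")
    >>> res = RLOCalibration(model, setup, RLOTable.zero()).fit()
    >>> res.table.offsets[-1] < res.table.offsets[len(res.table.offsets) // 2]
    True
    """

    model: MachineModel
    setup: PhantomSetup = field(default_factory=PhantomSetup)
    start_table: RLOTable = field(default_factory=RLOTable.zero)
    leaf_index: int = 19
    start_y2: float = 18.0
    start_y1: float = -10.0
    step: float = 2.0
    count: int = 15

    def _sweep_kwargs(self):
        return dict(
            leaf_index=self.leaf_index,
            start_y2=self.start_y2,
            start_y1=self.start_y1,
            step=self.step,
            count=self.count,
        )

    def fit(self) -> "RLOCalibrationResults":
        sweep = run_sweep(self.model, self.start_table, self.setup,
                          **self._sweep_kwargs())
        return RLOCalibrationResults(
            calibration=self,
            sweep=sweep,
            table=derive_modified_table(sweep),
        )


@dataclass
class RLOCalibrationResults:
    """Fitted RLO table plus the sweep it was derived from."""

    calibration: RLOCalibration
    sweep: SweepResult
    table: RLOTable
    _verified_residual: float | None = None

    @property
    def params(self) -> np.ndarray:
        """The fitted offsets (cm), one per sweep position."""
        return np.asarray(self.table.offsets)

    def to_frame(self) -> pd.DataFrame:
        return self.sweep.to_frame()

    def verify(self) -> float:
        """Closed-loop check: re-run the sweep with the fitted table and
        return the maximum |edge - displayed| (cm).  Cached."""
        if self._verified_residual is None:
            cal = self.calibration
            self._verified_residual = verify_closed_loop(
                cal.model, self.table, cal.setup, **cal._sweep_kwargs()
            )
        return self._verified_residual

    def summary(self) -> str:
        cal = self.calibration
        lines = [
            f"RLO table calibration (leafcal {__about__.__version__})",
            "=" * 58,
            f"sweep design : Y2 {cal.start_y2:+.1f} -> "
            f"{cal.start_y2 - (cal.count - 1) * cal.step:+.1f} cm, "
            f"step {cal.step:.1f} cm, {cal.count} beams, "
            f"leaf pair {cal.leaf_index}",
            f"aperture     : {cal.start_y2 + cal.start_y1:.1f} cm wide",
            f"grid spacing : {cal.setup.grid_spacing * 10:.1f} mm",
            f"start table  : {len(cal.start_table.positions)} nodes, "
            f"range [{min(cal.start_table.offsets):+.4f}, "
            f"{max(cal.start_table.offsets):+.4f}] cm",
            "",
            self.to_frame().to_string(index=False, float_format=lambda v: f"{v:8.4f}"),
        ]
        if self._verified_residual is not None:
            lines += [
                "",
                f"closed-loop max |edge - displayed| : "
                f"{self._verified_residual * 10:.4f} mm",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the fitted offset curve (and the starting table)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        start = self.calibration.start_table
        ax.plot(start.positions, start.offsets, "o--", label="starting table")
        ax.plot(self.table.positions, self.table.offsets, "s-", label="fitted table")
        ax.set_xlabel("displayed leaf position (cm)")
        ax.set_ylabel("rounded leaf offset (cm)")
        ax.legend()
        return ax

    def save_table(self, path, comment: str | None = None) -> None:
        from .io import write_rlo_table

        write_rlo_table(self.table, path, comment=comment)
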