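"""File formats and configuration.

Formats
-------
RLO table
    Plain text, two whitespace-separated columns ``position_cm offset_cm``,
    one node per row; ``#`` starts a comment.  Written sorted by position
    with 4 decimal places.  The reader sorts rows, so row order in a file is
    immaterial; duplicate positions are a parse error.

Planar dose (ASCII dialect)
    Optional leading ``#`` comment lines, then three header lines
    ``nx nu`` / ``x0 u0`` / ``spacing``, then ``nu`` rows of ``nx``
    space-separated values (row-major over ``u``), 6 significant digits.
    Read/write round-trips bit-identically at that precision.

Sweep table
    Tab-separated with the seven standard column headers, 4 decimals,
    ``#`` comment lines before the header row.

Machine configuration
    YAML with ``machine:`` and ``phantom:`` sections; the MLC layout is
    given either as an explicit ``leaf_widths`` list or as ``groups`` of
    ``{count, width}``.  Presets are packaged files in this schema.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .__about__ import __version__
from .calibration import SWEEP_COLUMNS, SweepResult, SweepRow
from .engine import PlanarDose
from .exceptions import ConfigurationError, ParseError
from .machine import MachineModel, MLCLayout, PhantomSetup, RLOTable

__all__ = [
    "read_rlo_table",
    "write_rlo_table",
    "read_planar_dose",
    "write_planar_dose",
    "read_sweep_tsv",
    "write_sweep_tsv",
    "load_machine_config",
    "dump_machine_config",
    "preset_path",
]


def _version_header(kind: str, comment: str | None = None) -> list[str]:
    lines = [f"# leafcal {__version__} {kind}"]
    if comment:
        for c in str(comment).splitlines():
            lines.append(f"# {c}")
    return lines


# ---------------------------------------------------------------------------
# RLO tables

def read_rlo_table(path) -> RLOTable:
    path = Path(path)
    rows: list[tuple[float, float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(
                f"expected 2 columns, got {len(parts)}", path=path, line=lineno
            )
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise ParseError(f"non-numeric value in {parts}", path=path, line=lineno)
    if not rows:
        raise ParseError("no table rows found", path=path)
    rows.sort(key=lambda r: r[0])
    pos = [r[0] for r in rows]
    if len(set(pos)) != len(pos):
        raise ParseError("duplicate positions in table", path=path)
    return RLOTable.from_arrays(pos, [r[1] for r in rows])


def write_rlo_table(table: RLOTable, path, comment: str | None = None) -> None:
    lines = _version_header("RLO table (position_cm offset_cm)", comment)
    order = np.argsort(table.positions)
    for i in order:
        lines.append(f"{table.positions[i]:.4f} {table.offsets[i]:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Planar dose ASCII dialect

def write_planar_dose(dose: PlanarDose, path, comment: str | None = None) -> None:
    lines = _version_header("planar dose (nx nu / x0 u0 / spacing / nu rows of nx)",
                            comment)
    lines.append(f"{dose.nx} {dose.nu}")
    lines.append(f"{dose.x0:.6g} {dose.u0:.6g}")
    lines.append(f"{dose.spacing:.6g}")
    for j in range(dose.nu):
        lines.append(" ".join(f"{v:.6g}" for v in dose.values[j]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_planar_dose(path) -> PlanarDose:
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if len(lines) < 4:
        raise ParseError("truncated planar dose file", path=path)
    try:
        nx, nu = (int(t) for t in lines[0].split())
        x0, u0 = (float(t) for t in lines[1].split())
        spacing = float(lines[2])
    except ValueError as exc:
        raise ParseError(f"bad header: {exc}", path=path)
    if len(lines) != 3 + nu:
        raise ParseError(f"expected {nu} data rows, found {len(lines) - 3}", path=path)
    values = np.empty((nu, nx))
    for j, row in enumerate(lines[3:]):
        parts = row.split()
        if len(parts) != nx:
            raise ParseError(f"expected {nx} values, got {len(parts)}",
                             path=path, line=4 + j)
        values[j] = [float(p) for p in parts]
    return PlanarDose(x0=x0, u0=u0, spacing=spacing, values=values)


# ---------------------------------------------------------------------------
# Sweep tables

def write_sweep_tsv(sweep: SweepResult, path, comment: str | None = None) -> None:
    lines = _version_header("sweep table", comment)
    lines.append("\t".join(SWEEP_COLUMNS))
    for r in sweep.rows:
        lines.append(
            "\t".join(
                f"{v:.4f}"
                for v in (r.displayed, r.y2_edge, r.y1_edge, r.rlo_used,
                          r.y2_modified, r.y1_modified, r.average_modified)
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_sweep_tsv(path, table_used: RLOTable | None = None) -> SweepResult:
    """Read a seven-column sweep table.

    Only the four input columns (displayed, edges, RLO in force) are taken
    from the file; the modified columns are recomputed at full precision so
    the row arithmetic invariants hold exactly.
    """
    path = Path(path)
    rows = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            if line.split("\t")[0] != SWEEP_COLUMNS[0]:
                raise ParseError("missing sweep table header row", path=path, line=lineno)
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ParseError(f"expected 7 columns, got {len(parts)}",
                             path=path, line=lineno)
        d, y2e, y1e, rlo = (float(p) for p in parts[:4])
        rows.append(SweepRow(displayed=d, y2_edge=y2e, y1_edge=y1e, rlo_used=rlo))
    if not rows:
        raise ParseError("no sweep rows found", path=path)
    rows.sort(key=lambda r: r.displayed)
    if table_used is None:
        table_used = RLOTable.from_arrays(
            [r.displayed for r in rows], [r.rlo_used for r in rows]
        )
    return SweepResult(rows=tuple(rows), table_used=table_used)


# ---------------------------------------------------------------------------
# Machine configuration

def _layout_from_config(cfg) -> MLCLayout:
    if "leaf_widths" in cfg:
        return MLCLayout(tuple(float(w) for w in cfg["leaf_widths"]))
    if "groups" in cfg:
        widths: list[float] = []
        for group in cfg["groups"]:
            widths.extend([float(group["width"])] * int(group["count"]))
        return MLCLayout(tuple(widths))
    raise ConfigurationError("layout needs 'leaf_widths' or 'groups'")


_MACHINE_KEYS = (
    "source_to_iso_distance", "source_to_leaf_plane", "tip_radius",
    "leaf_thickness", "mu", "transmission_floor", "blur_sigma",
    "travel_min", "travel_max",
)
_PHANTOM_KEYS = ("ssd", "calc_depth", "grid_spacing")


def load_machine_config(path) -> tuple[MachineModel, PhantomSetup]:
    """Read a YAML machine/phantom configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "machine" not in cfg:
        raise ConfigurationError(f"{path}: missing 'machine' section")
    mc = dict(cfg["machine"])
    layout_cfg = mc.pop("layout", None)
    if layout_cfg is None:
        raise ConfigurationError(f"{path}: machine section needs a 'layout'")
    unknown = set(mc) - set(_MACHINE_KEYS)
    if unknown:
        raise ConfigurationError(f"{path}: unknown machine keys {sorted(unknown)}")
    model = MachineModel(layout=_layout_from_config(layout_cfg),
                         **{k: float(v) for k, v in mc.items()})
    pc = dict(cfg.get("phantom", {}))
    unknown = set(pc) - set(_PHANTOM_KEYS)
    if unknown:
        raise ConfigurationError(f"{path}: unknown phantom keys {sorted(unknown)}")
    setup = PhantomSetup(**{k: float(v) for k, v in pc.items()})
    return model, setup


def dump_machine_config(model: MachineModel, setup: PhantomSetup) -> str:
    """Serialize a model/setup pair in the configuration schema."""
    cfg = {
        "machine": {
            **{k: getattr(model, k) for k in _MACHINE_KEYS},
            "layout": {"leaf_widths": list(model.layout.leaf_widths)},
        },
        "phantom": {k: getattr(setup, k) for k in _PHANTOM_KEYS},
    }
    return yaml.safe_dump(cfg, sort_keys=False)


def preset_path(name: str):
    """Filesystem path of a packaged preset configuration."""
    return resources.files("leafcal").joinpath("presets", f"{name}.yaml")
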