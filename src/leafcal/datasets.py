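"""Bundled reference datasets.

Two 15-beam edge sweeps computed by a commercial TPS (Pinnacle 9.2) for an
Elekta 80-leaf MLC - one with the vendor default RLO table in force, one
with an all-zero table - plus the vendor default RLO table itself.  The TPS
edge values depend on that system's proprietary beam model and are *inputs*
here: the exactly-reproducible part is the update-rule arithmetic applied
to them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .calibration import SweepResult
from .io import read_rlo_table, read_sweep_tsv
from .machine import RLOTable

__all__ = [
    "reference_sweep",
    "reference_sweep_frame",
    "default_rlo_table",
]

_KINDS = {
    "default": "elekta80_sweep_default.tsv",
    "zero": "elekta80_sweep_zero.tsv",
}


def _data_path(name: str):
    return resources.files("leafcal").joinpath("data", name)


def reference_sweep(kind: str = "default") -> SweepResult:
    """TPS reference sweep as a :class:`SweepResult`.

    Only the input columns (displayed position, both edges, RLO in force)
    come from the file; the modified columns are recomputed by the update
    rule at full precision.
    """
    if kind not in _KINDS:
        raise KeyError(f"kind must be one of {sorted(_KINDS)}")
    return read_sweep_tsv(_data_path(_KINDS[kind]))


def reference_sweep_frame(kind: str = "default") -> pd.DataFrame:
    """The reference sweep exactly as printed (all seven columns)."""
    if kind not in _KINDS:
        raise KeyError(f"kind must be one of {sorted(_KINDS)}")
    return pd.read_csv(_data_path(_KINDS[kind]), sep="\t", comment="#")


def default_rlo_table() -> RLOTable:
    """The vendor default RLO table for the Elekta 80-leaf MLC."""
    return read_rlo_table(_data_path("elekta80_default_rlo.txt"))
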