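"""Readers/writers for the file formats the pipeline touches.

Energy traces arrive as XVG (grace dialect, whitespace-separated columns,
``#``/``@`` metadata lines) or CSV; thermodynamic tables as CSV.  Everything
downstream works in kcal/mol, so conversion happens at the boundary.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import yaml

logger = logging.getLogger("bindcalor")

#: thermochemical calorie: 1 kcal = 4.184 kJ, exactly
KJ_PER_KCAL = 4.184

LEGS = ("complex", "solvent", "receptor", "ligand")

#: Unicode minus as printed in typeset tables
_UNICODE_MINUS = "−"


class XvgError(ValueError):
    """Malformed XVG input."""


class SchemaError(ValueError):
    """CSV table does not have the required columns."""


def convert_energy_units(value, from_units: str):
    """Convert an energy (scalar or array) to kcal/mol.

    kJ/mol is divided by exactly 4.184; kcal/mol passes through unchanged.
    """
    if from_units == "kcal/mol":
        return value
    if from_units == "kJ/mol":
        return value / KJ_PER_KCAL
    raise ValueError(f"unknown energy unit {from_units!r}; expected 'kJ/mol' or 'kcal/mol'")


@dataclass(frozen=True)
class EnergySeries:
    """One leg's potential-energy trace, replica-tagged, stored in kcal/mol."""

    values: np.ndarray
    dt: float  # frame spacing, ps
    leg: str
    replica_id: int = 0
    system_id: str = ""
    units_original: str = "kcal/mol"
    source_column: str | None = None  # provenance: which column was read

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("EnergySeries requires a 1-D series of length >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError("EnergySeries values must be finite")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.leg not in LEGS:
            raise ValueError(f"leg must be one of {LEGS}, got {self.leg!r}")
        if self.replica_id < 0:
            raise ValueError("replica_id must be >= 0")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ThermoRecord:
    """One row of a thermodynamic table: dH, TdS, dG in kcal/mol."""

    system_id: str
    dH: float
    TdS: float
    dG: float
    source: str = "experiment_ITC"

    def __post_init__(self):
        for name in ("dH", "TdS", "dG"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def consistency_gap(self) -> float:
        """|dG - (dH - TdS)| — evaluated, never assumed."""
        return abs(self.dG - (self.dH - self.TdS))


def _parse_number(token: str) -> float:
    return float(token.replace(_UNICODE_MINUS, "-"))


def read_energy_xvg(
    stream: TextIO | str,
    column: int = 1,
    leg: str = "complex",
    replica_id: int = 0,
    units: str = "kJ/mol",
    system_id: str = "",
) -> EnergySeries:
    """Parse one column of a GROMACS-style XVG energy file.

    Lines starting with ``#`` or ``@`` are metadata and skipped wherever they
    appear.  Column 0 must hold time in ps with uniform spacing; ``dt`` is
    inferred from the first two time stamps.  Energies are converted from
    ``units`` (GROMACS default kJ/mol) to kcal/mol.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    times: list[float] = []
    values: list[float] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "@")):
            continue
        tokens = line.split()
        try:
            t = _parse_number(tokens[0])
            v = _parse_number(tokens[column])
        except (ValueError, IndexError) as exc:
            raise XvgError(f"line {lineno}: cannot parse data line {line!r}") from exc
        times.append(t)
        values.append(v)
    if not values:
        raise XvgError("no data lines found in XVG input")
    if len(times) >= 2:
        dt = times[1] - times[0]
        if dt <= 0:
            raise XvgError("non-increasing time stamps")
        diffs = np.diff(times)
        if np.any(np.abs(diffs - dt) > 1e-6 * max(abs(dt), 1.0)):
            raise XvgError("non-uniform time spacing in XVG input")
    else:
        dt = 1.0
    kcal = convert_energy_units(np.asarray(values, dtype=float), units)
    return EnergySeries(
        values=kcal,
        dt=dt,
        leg=leg,
        replica_id=replica_id,
        system_id=system_id,
        units_original=units,
        source_column=str(column),
    )


_REQUIRED_COLUMNS = ("system_id", "dH", "TdS", "dG")


def read_benchmark_table(stream: TextIO | str) -> list[ThermoRecord]:
    """Read a CSV thermodynamic table into ThermoRecords.

    Requires header columns system_id, dH, TdS, dG (order-insensitive);
    Unicode minus is accepted as a sign.  Energies are kcal/mol.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream)
    header = reader.fieldnames or []
    missing = [c for c in _REQUIRED_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"benchmark table missing required column(s): {missing}")
    records = []
    for i, row in enumerate(reader, start=2):
        try:
            records.append(
                ThermoRecord(
                    system_id=row["system_id"].strip(),
                    dH=_parse_number(row["dH"]),
                    TdS=_parse_number(row["TdS"]),
                    dG=_parse_number(row["dG"]),
                    source=row.get("source", "experiment_ITC") or "experiment_ITC",
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"benchmark table row {i}: cannot parse cells") from exc
    return records


def write_benchmark_table(records: Iterable[ThermoRecord], stream: TextIO) -> None:
    writer = csv.writer(stream)
    writer.writerow(["system_id", "dH", "TdS", "dG", "source"])
    for r in records:
        writer.writerow([r.system_id, repr(r.dH), repr(r.TdS), repr(r.dG), r.source])


DEFAULT_CONFIG = {
    "units": {"xvg": "kJ/mol", "csv": "kcal/mol"},
    "blocking": {"min_blocks": 8, "mode": "per_replica", "discard_frames": 0},
    "states": {"psi_cut": 5.0, "phi_cut": -105.0, "min_dwell": 5},
}


def load_config(path: str | None = None) -> dict:
    """Load a YAML config, overlaying user sections onto the defaults."""
    config = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, entries in user.items():
            config.setdefault(section, {}).update(entries or {})
    return config


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=None,  # stderr by default
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
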