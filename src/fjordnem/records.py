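"""Domain types and tabular I/O for hydrographic bottle data.

A *bottle record* is one discrete water sample: station, region, time,
depth, temperature, salinity and a map of tracer concentrations in
µmol kg⁻¹.  Missing measurements are represented as *absent* map entries,
never as sentinel numbers; downstream statistics operate on present values
only (monitoring profiles routinely have gaps, e.g. no samples below 100 m
at shallow stations).

Concentrations are stored in µmol kg⁻¹.  Volumetric input (µmol L⁻¹, i.e.
µM) is converted with a single configurable reference density rather than
per-sample in-situ density; with the default 1000 kg m⁻³ the two units
coincide numerically.
"""

from __future__ import annotations

import io
import logging
import math
import sys
from dataclasses import dataclass, field
from datetime import date as _date
from enum import Enum
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

#: Canonical tracer names.  Free-form extension names are allowed anywhere a
#: tracer name is accepted; matching on read is case-insensitive.
CORE_TRACERS = (
    "nitrate_nitrite",
    "ammonium",
    "phosphate",
    "silicic_acid",
    "dic",
)

#: Molar mass of the budget-relevant element per tracer (g mol⁻¹).
MOLAR_MASS_G_PER_MOL = {
    "nitrate_nitrite": 14.007,  # N
    "ammonium": 14.007,         # N
    "dic": 12.011,              # C
    "phosphate": 30.974,        # P
    "silicic_acid": 28.086,     # Si
}


class Region(str, Enum):
    FJORD = "fjord"
    SHELF = "shelf"
    FRAM_STRAIT = "fram_strait"


class Unit(str, Enum):
    UMOL_PER_KG = "umol_per_kg"
    UMOL_PER_L = "umol_per_L"


@dataclass(frozen=True)
class UnitSpec:
    """Concentration unit of an input table plus the density used to convert.

    ``reference_density`` is in kg m⁻³ and must lie in [990, 1035] (fresh to
    dense seawater).  µmol L⁻¹ values are divided by ρ/1000 to obtain
    µmol kg⁻¹.
    """

    unit: Unit = Unit.UMOL_PER_KG
    reference_density: float = 1000.0

    def __post_init__(self) -> None:
        if not 990.0 <= self.reference_density <= 1035.0:
            raise ValidationError(
                f"reference_density {self.reference_density} outside [990, 1035] kg m^-3"
            )

    def to_umol_per_kg(self, value: float) -> float:
        if self.unit is Unit.UMOL_PER_KG:
            return value
        return value / (self.reference_density / 1000.0)

    def to_umol_per_L(self, value_umol_kg: float) -> float:
        """Inverse of :meth:`to_umol_per_kg` for the volumetric unit."""
        return value_umol_kg * (self.reference_density / 1000.0)


@dataclass
class BottleRecord:
    """One water sample with hydrography and tracer concentrations."""

    station_id: str
    region: Region
    year: int
    depth: float
    salinity: float
    temperature: float = math.nan
    date: _date | None = None
    tracers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.region, str):
            self.region = Region(self.region)
        if self.depth < 0:
            raise ValidationError(f"depth must be >= 0 m, got {self.depth}")
        if not 0.0 <= self.salinity <= 42.0:
            raise ValidationError(f"salinity {self.salinity} outside [0, 42]")
        for name, conc in self.tracers.items():
            if conc < 0:
                raise ValidationError(f"{name} concentration {conc} < 0")
            if name == "dic" and conc <= 0:
                raise ValidationError(f"dic must be > 0, got {conc}")


_REQUIRED = ("station", "region", "year", "depth", "salinity")


def read_bottle_table(
    source: str | IO[str],
    column_map: Mapping[str, str] | None = None,
    units: UnitSpec | None = None,
    sep: str | None = None,
) -> list[BottleRecord]:
    """Read a delimited bottle table into :class:`BottleRecord` objects.

    ``column_map`` maps canonical field names (``station``, ``region``,
    ``year``, ``depth``, ``salinity``, optionally ``temperature``, ``date``
    and tracer names) to the file's column headers.  Unmapped tracer columns
    are picked up by case-insensitive name match against the canonical
    tracer set.  Unparseable or empty tracer cells become absent entries,
    never zero.
    """
    units = units or UnitSpec()
    column_map = dict(column_map or {})
    df = pd.read_csv(source, sep=sep, engine="python" if sep is None else "c")

    lower_cols = {c.lower(): c for c in df.columns}

    def resolve(name: str) -> str | None:
        if name in column_map:
            col = column_map[name]
            if col not in df.columns:
                raise FormatError(f"mapped column '{col}' for '{name}' not in header")
            return col
        return lower_cols.get(name.lower())

    for req in _REQUIRED:
        if resolve(req) is None:
            raise FormatError(f"required column '{req}' missing from header")

    tracer_names = list(CORE_TRACERS) + [
        k for k in column_map if k not in _REQUIRED + ("temperature", "date")
        and k not in CORE_TRACERS
    ]
    tracer_cols = {t: resolve(t) for t in tracer_names}
    temp_col = resolve("temperature")
    date_col = resolve("date")

    records: list[BottleRecord] = []
    for i, row in df.iterrows():
        depth = float(row[resolve("depth")])
        salinity = float(row[resolve("salinity")])
        if depth < 0:
            raise ValidationError(f"row {i}: negative depth {depth}")
        if salinity < 0:
            raise ValidationError(f"row {i}: negative salinity {salinity}")
        tracers: dict[str, float] = {}
        for t, col in tracer_cols.items():
            if col is None:
                continue
            try:
                val = float(row[col])
            except (TypeError, ValueError):
                continue
            if math.isnan(val):
                continue
            tracers[t] = units.to_umol_per_kg(val)
        records.append(
            BottleRecord(
                station_id=str(row[resolve("station")]),
                region=Region(str(row[resolve("region")]).strip().lower()),
                year=int(row[resolve("year")]),
                depth=depth,
                salinity=salinity,
                temperature=float(row[temp_col]) if temp_col is not None else math.nan,
                date=pd.to_datetime(row[date_col]).date() if date_col is not None
                and not pd.isna(row[date_col]) else None,
                tracers=tracers,
            )
        )
    log.info("read %d bottle records", len(records))
    return records


def write_bottle_table(records: Iterable[BottleRecord], sep: str = ",") -> str:
    """Serialise bottle records back to delimited text (µmol kg⁻¹)."""
    records = list(records)
    tracer_names = sorted({t for r in records for t in r.tracers})
    rows = []
    for r in records:
        row: dict[str, object] = {
            "station": r.station_id,
            "region": r.region.value,
            "year": r.year,
            "date": r.date.isoformat() if r.date else "",
            "depth": r.depth,
            "temperature": r.temperature,
            "salinity": r.salinity,
        }
        for t in tracer_names:
            row[t] = r.tracers.get(t, "")
        rows.append(row)
    buf = io.StringIO()
    pd.DataFrame(rows).to_csv(buf, sep=sep, index=False, float_format="%.10g")
    return buf.getvalue()


def write_result_table(rows: Sequence[object], style: str = "tsv") -> str:
    """Render homogeneous result rows (source/sink or NEM estimates) as text.

    Missing values are rendered as ``-`` and significant source/sink terms
    get a ``*`` marker column; ΔC is rounded to one decimal.
    """
    if style not in ("tsv", "csv"):
        raise ValueError(f"unknown style '{style}'")
    sep = "\t" if style == "tsv" else ","
    types = {type(r).__name__ for r in rows}
    if len(types) > 1:
        raise ValidationError(f"mixed row types in result table: {sorted(types)}")

    def fmt(v: object, ndigits: int | None = None) -> str:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "-"
        if isinstance(v, float) and ndigits is not None:
            return f"{round(v, ndigits):.{ndigits}f}"
        return str(v)

    if not rows:
        return sep.join(["year", "tracer", "pair", "value", "significant"]) + "\n"

    kind = types.pop()
    lines = []
    if kind == "SourceSinkEstimate":
        header = ["year", "tracer", "pair", "S_obs", "C_obs", "C_cons",
                  "delta_C", "n_fjord", "n_shelf", "p_value", "significant"]
        lines.append(sep.join(header))
        for r in rows:  # type: ignore[assignment]
            lines.append(sep.join([
                fmt(r.year), r.tracer, r.pair,
                fmt(r.S_obs, 3), fmt(r.C_obs, 3), fmt(r.C_cons, 3),
                fmt(r.delta_C, 1),
                fmt(r.n_fjord), fmt(r.n_shelf),
                fmt(r.p_value, 4),
                "*" if r.significant else "",
            ]))
    elif kind == "NemEstimate":
        header = ["year", "tracer", "pair", "rate", "integrated_mol",
                  "integrated_g", "areal_tonnes", "depth", "density", "area"]
        lines.append(sep.join(header))
        for r in rows:  # type: ignore[assignment]
            lines.append(sep.join([
                fmt(r.year), r.tracer, r.pair,
                fmt(r.rate, 1), fmt(r.integrated_mol, 2), fmt(r.integrated_g, 1),
                fmt(None if r.areal_tonnes is None else float(round(r.areal_tonnes))),
                fmt(r.depth), fmt(r.density), fmt(r.area),
            ]))
    else:
        raise ValidationError(f"unsupported result row type {kind}")
    return "\n".join(lines) + "\n"


def configure_logging(quiet: bool = False) -> None:
    """Route package logs to stderr with level prefixes."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("fjordnem")
    root.handlers[:] = [handler]
    root.setLevel(logging.WARNING if quiet else logging.INFO)
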