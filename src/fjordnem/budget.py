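"""Nitrogen flux ledger for a fjord water column.

Every flux is a signed entry in tonnes N d⁻¹; positive means nitrogen added
to the fjord's water column, negative removed (sediment burial,
denitrification to the atmosphere, bird-food consumption).  Computed fluxes
are atmospheric deposition (precipitation × concentration over ~weekly
periods), riverine input (runoff volume × concentration), and fjord–ocean
exchange (volume transport × DIN concentration).  Literature-constant
fluxes enter as pass-through entries with provenance strings.

The *internal balance* sums all entries except a set of excluded categories
(by default the fjord–ocean exchange, which is orders of magnitude larger
than everything else and poorly constrained in net terms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Iterable, Sequence

from .errors import ValidationError

log = logging.getLogger(__name__)

N_MOLAR_MASS = 14.007  # g mol^-1
SECONDS_PER_DAY = 86400.0


class FluxCategory(str, Enum):
    ATMOSPHERIC = "atmospheric"
    RIVERINE = "riverine"
    OCEAN_EXCHANGE = "ocean_exchange"
    BIOLOGICAL = "biological"
    SEDIMENT = "sediment"
    INTERNAL_TRANSFORMATION = "internal_transformation"


class Season(str, Enum):
    SUMMER = "summer"
    ANNUAL = "annual"


@dataclass
class FluxEntry:
    """One signed nitrogen flux (tonnes N d⁻¹); positive = into the fjord."""

    name: str
    category: FluxCategory
    value: float
    range_lo: float | None = None
    range_hi: float | None = None
    season: Season = Season.SUMMER
    provenance: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.category, str):
            self.category = FluxCategory(self.category)
        if isinstance(self.season, str):
            self.season = Season(self.season)
        if self.range_lo is not None and self.range_hi is not None:
            if not self.range_lo <= self.value <= self.range_hi:
                raise ValidationError(
                    f"flux '{self.name}': value {self.value} outside "
                    f"[{self.range_lo}, {self.range_hi}]"
                )


@dataclass(frozen=True)
class DepositionPeriod:
    """One ~7-day precipitation-sampling period."""

    start: date
    end: date
    precip_total_mm: float
    conc_mg_per_L: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"period end {self.end} not after start {self.start}")
        if self.precip_total_mm < 0 or self.conc_mg_per_L < 0:
            raise ValidationError("precipitation and concentration must be >= 0")

    @property
    def days(self) -> float:
        return (self.end - self.start).days


def _union_days(periods: Sequence[DepositionPeriod]) -> float:
    """Total days covered by the union of the period intervals."""
    ivals = sorted((p.start, p.end) for p in periods)
    total = 0.0
    cur_start, cur_end = ivals[0]
    overlap = False
    for s, e in ivals[1:]:
        if s < cur_end:
            overlap = True
            cur_end = max(cur_end, e)
        else:
            total += (cur_end - cur_start).days
            cur_start, cur_end = s, e
    total += (cur_end - cur_start).days
    if overlap:
        log.warning("overlapping deposition periods; using union span")
    return total


def atmospheric_deposition(
    periods: Sequence[DepositionPeriod],
    area_km2: float,
    name: str = "atmospheric N deposition",
    season: Season = Season.SUMMER,
) -> FluxEntry:
    """Daily-mean wet deposition flux over the covered span, upscaled to area.

    Per period, deposition (mg N m⁻²) = precipitation (mm) × concentration
    (mg N L⁻¹), since 1 mm of rain over 1 m² is 1 L.
    """
    if not periods:
        raise ValidationError("at least one deposition period required")
    if area_km2 <= 0:
        raise ValidationError("area must be > 0 km^2")
    total_mg_per_m2 = sum(p.precip_total_mm * p.conc_mg_per_L for p in periods)
    days = _union_days(periods)
    # mg m^-2 d^-1 -> tonnes d^-1: x * area_km2 * 1e6 m^2 / 1e9 mg per tonne
    tonnes_per_day = total_mg_per_m2 / days * area_km2 * 1e6 * 1e-9
    return FluxEntry(name, FluxCategory.ATMOSPHERIC, tonnes_per_day,
                     season=season, provenance="computed: precip x conc")


def riverine_flux(
    runoff_volume_m3: float,
    span_days: float,
    conc_umol_per_L: float,
    name: str = "riverine DIN",
    season: Season = Season.SUMMER,
) -> FluxEntry:
    """Riverine nitrogen input from total runoff volume and concentration."""
    if span_days <= 0:
        raise ValidationError("span must be > 0 days")
    if runoff_volume_m3 < 0:
        raise ValidationError(f"negative runoff volume {runoff_volume_m3}")
    # µmol/L == mmol/m^3; m^3/d * mmol/m^3 = mmol/d -> g/d (*14.007e-3) -> t/d
    tonnes_per_day = (runoff_volume_m3 / span_days) * conc_umol_per_L * N_MOLAR_MASS * 1e-9
    return FluxEntry(name, FluxCategory.RIVERINE, tonnes_per_day,
                     season=season, provenance="computed: runoff x conc")


def ocean_exchange_flux(
    transport_m3_per_s: float,
    din_conc_umol_per_L: float,
    name: str = "fjord-ocean DIN exchange",
    season: Season = Season.SUMMER,
) -> FluxEntry:
    """Fjord–ocean DIN flux; sign follows the transport (positive inward)."""
    if din_conc_umol_per_L < 0:
        raise ValidationError("DIN concentration must be >= 0")
    tonnes_per_day = (
        transport_m3_per_s * SECONDS_PER_DAY * din_conc_umol_per_L * N_MOLAR_MASS * 1e-9
    )
    return FluxEntry(name, FluxCategory.OCEAN_EXCHANGE, tonnes_per_day,
                     season=season, provenance="computed: transport x conc")


def internal_balance(
    entries: Sequence[FluxEntry],
    exclude: Iterable[FluxCategory | str] = (FluxCategory.OCEAN_EXCHANGE,),
) -> float:
    """Signed sum of fluxes outside the excluded categories (negative = loss)."""
    if not entries:
        raise ValidationError("empty flux ledger")
    excluded = {FluxCategory(e) for e in exclude}
    kept = [e for e in entries if e.category not in excluded]
    if not kept:
        log.warning("all ledger entries excluded; balance is 0")
        return 0.0
    return sum(e.value for e in kept)


def budget_report(entries: Sequence[FluxEntry], sep: str = "\t") -> str:
    """Format the ledger: per-category subtotals, |value|-descending order."""
    header = sep.join(["category", "name", "tonnes_N_per_day", "range", "season"])
    lines = [header]
    by_cat: dict[FluxCategory, list[FluxEntry]] = {}
    for e in entries:
        by_cat.setdefault(e.category, []).append(e)
    for cat in FluxCategory:
        if cat not in by_cat:
            continue
        group = sorted(by_cat[cat], key=lambda e: abs(e.value), reverse=True)
        for e in group:
            rng = (f"{e.range_lo:g}–{e.range_hi:g}"
                   if e.range_lo is not None and e.range_hi is not None else "-")
            lines.append(sep.join([
                cat.value, e.name, f"{e.value:.2f}", rng, e.season.value]))
        subtotal = sum(e.value for e in group)
        lines.append(sep.join([cat.value, "(subtotal)", f"{subtotal:.2f}", "-", ""]))
    return "\n".join(lines) + "\n"
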