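"""Config-driven orchestration of the full analysis.

A single YAML config drives three stages, each available as a plain
function (the CLI is a thin wrapper):

* ``run_sources_sinks`` — classify bottles, pool water masses, build the
  annual ΔC tables per tracer;
* ``run_nem`` — convert ΔC to drawdown rates, depth-integrated and areal
  NEM, and summarise ranges and the C:N uptake ratio;
* ``run_budget`` — assemble the nitrogen flux ledger from input series and
  constants and report the internal (ocean-exchange-excluded) balance.

Outputs are deterministic for fixed inputs; every output file begins with a
header comment carrying the package version and a hash of the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .budget import (
    DepositionPeriod,
    FluxEntry,
    atmospheric_deposition,
    budget_report,
    internal_balance,
    ocean_exchange_flux,
    riverine_flux,
)
from .errors import ConfigError, DataError
from .mixing import DEFAULT_PAIRS, EndmemberConfig, SourceSinkEstimate, annual_source_sink_table
from .nem import NEM_PAIRS, CnRatioResult, FlushingSpec, NemEstimate, cn_uptake_ratio, nem_estimate
from .records import BottleRecord, write_result_table
from .watermass import WaterMassEnvelope, WaterMassScheme, assign_labels, default_scheme

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved settings for one analysis run."""

    scheme: WaterMassScheme = field(default_factory=default_scheme)
    endmembers: EndmemberConfig = field(default_factory=EndmemberConfig)
    flushing: FlushingSpec = field(default_factory=FlushingSpec)
    depth_max: float = 100.0
    density: float = 1000.0
    area_km2: float = 231.5
    alpha: float = 0.05
    tracers: tuple[str, ...] = ("nitrate_nitrite", "dic")
    pairs: tuple[str, ...] = DEFAULT_PAIRS
    exclusions: tuple[tuple[int, str], ...] = ()
    seed: int = 0
    out_dir: Path = Path("results")
    paths: dict[str, Path] = field(default_factory=dict)
    raw: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def header(self) -> str:
        return f"# fjordnem v{__version__} config={self.config_hash()}\n"


def load_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    scheme = default_scheme()
    if "watermasses" in raw:
        scheme = WaterMassScheme(
            envelopes=[
                WaterMassEnvelope(
                    name=e["name"], temp_min=e.get("tmin"), temp_max=e.get("tmax"),
                    sal_min=e.get("smin"), sal_max=e.get("smax"),
                    priority=e["priority"],
                )
                for e in raw["watermasses"]
            ],
            fallback_label=raw.get("fallback_label", "other"),
        )
    em = raw.get("endmembers", {})
    endmembers = EndmemberConfig(
        fresh=em.get("fresh") or None,
        fresh_salinity=em.get("fresh_salinity", 0.0),
        marine_source=em.get("marine_source", "pooled_AW_shelf"),
        marine_explicit={
            k: tuple(v) for k, v in em.get("marine_explicit", {}).items()
        } or None,
    )
    fl = raw.get("flushing", {})
    flushing = FlushingSpec(
        ft_days=fl.get("ft_days", 13.0), method=fl.get("method", "fixed"),
        volume=fl.get("volume"), q_freshwater=fl.get("q_freshwater"),
        s_ocean=fl.get("s_ocean"), s_fjord=fl.get("s_fjord"),
    )
    an = raw.get("analysis", {})
    return RunConfig(
        scheme=scheme, endmembers=endmembers, flushing=flushing,
        depth_max=an.get("depth_max", 100.0),
        density=an.get("density", 1000.0),
        area_km2=an.get("area_km2", 231.5),
        alpha=an.get("alpha", 0.05),
        tracers=tuple(an.get("tracers", ("nitrate_nitrite", "dic"))),
        pairs=tuple(an.get("pairs", DEFAULT_PAIRS)),
        exclusions=tuple(
            (int(y), p) for y, p in (tuple(x) for x in an.get("exclusions", ()))),
        seed=raw.get("seed", 0),
        out_dir=Path(raw.get("out_dir", "results")),
        paths={k: Path(v) for k, v in raw.get("paths", {}).items()},
        raw=raw,
    )


def run_sources_sinks(
    records: Sequence[BottleRecord], config: RunConfig,
) -> dict[str, list[SourceSinkEstimate]]:
    """Annual ΔC tables per tracer from raw bottle records."""
    labeled = assign_labels(records, config.scheme)
    estimates = annual_source_sink_table(
        labeled, config.scheme, config.endmembers,
        tracers=config.tracers, pairs=config.pairs,
        depth_max=config.depth_max, alpha=config.alpha,
    )
    out: dict[str, list[SourceSinkEstimate]] = {t: [] for t in config.tracers}
    for est in estimates:
        out[est.tracer].append(est)
    return out


@dataclass
class NemSummary:
    """Headline range statistics of a NEM run (module rounding rules)."""

    rate_min: dict[str, float]
    rate_max: dict[str, float]
    integrated_mol_min: dict[str, float]
    integrated_mol_max: dict[str, float]
    integrated_g_min: dict[str, float]
    integrated_g_max: dict[str, float]
    areal_tonnes_min: dict[str, float]
    areal_tonnes_max: dict[str, float]
    cn_ratio: CnRatioResult | None = None


def run_nem(
    tables: Mapping[str, Sequence[SourceSinkEstimate]],
    config: RunConfig,
) -> tuple[list[NemEstimate], NemSummary]:
    """ΔC tables → NEM estimates plus min/max summary.

    Summary ranges use the AWs-vs-IW and AWs-vs-SW contrasts only and apply
    the reporting rounding rules (rates to 1 decimal, mol to 2, g to 1,
    tonnes to integer).
    """
    from .nem import round_g, round_mol, round_rate, round_tonnes

    estimates: list[NemEstimate] = []
    excl = set(config.exclusions)
    for tracer, table in tables.items():
        for est in table:
            if est.delta_C is None or (est.year, est.pair) in excl:
                continue
            estimates.append(nem_estimate(
                est.delta_C, est.year, tracer, est.pair,
                ft=config.flushing, depth=config.depth_max,
                density=config.density, area_km2=config.area_km2,
            ))
    if not estimates:
        log.warning("empty source/sink table; no NEM estimates")
        empty: dict[str, float] = {}
        return [], NemSummary(empty, empty, empty, empty, empty, empty, empty, empty)

    def ranges(select, rounder):
        lo: dict[str, float] = {}
        hi: dict[str, float] = {}
        for e in estimates:
            if e.pair not in NEM_PAIRS:
                continue
            v = select(e)
            lo[e.tracer] = min(lo.get(e.tracer, v), v)
            hi[e.tracer] = max(hi.get(e.tracer, v), v)
        return ({t: rounder(v) for t, v in lo.items()},
                {t: rounder(v) for t, v in hi.items()})

    rate_min, rate_max = ranges(lambda e: e.rate, round_rate)
    mol_min, mol_max = ranges(lambda e: e.integrated_mol, round_mol)
    g_min, g_max = ranges(lambda e: e.integrated_g, round_g)
    t_min, t_max = ranges(lambda e: e.areal_tonnes, round_tonnes)

    cn = None
    n_est = [e for e in estimates if e.tracer == "nitrate_nitrite" and e.pair in NEM_PAIRS]
    c_est = [e for e in estimates if e.tracer == "dic" and e.pair in NEM_PAIRS]
    if n_est and c_est:
        try:
            cn = cn_uptake_ratio(n_est, c_est, exclusions=config.exclusions)
        except DataError:
            cn = None
    return estimates, NemSummary(rate_min, rate_max, mol_min, mol_max,
                                 g_min, g_max, t_min, t_max, cn)


def run_budget(
    config: RunConfig,
    periods: Sequence[DepositionPeriod] | None = None,
    runoff: pd.DataFrame | None = None,
    transport: pd.DataFrame | None = None,
) -> tuple[list[FluxEntry], float]:
    """Assemble the flux ledger and its ocean-exchange-excluded balance.

    Series not passed in are read from ``config.paths`` (``deposition``,
    ``runoff``, ``transport`` CSVs); constant fluxes come from the config's
    ``budget.constants`` section as {name: {category, value, ...}}.
    """
    entries: list[FluxEntry] = []
    if periods is None and "deposition" in config.paths:
        df = pd.read_csv(config.paths["deposition"], parse_dates=["start", "end"])
        periods = [
            DepositionPeriod(r.start.date(), r.end.date(), r.precip_mm, r.conc_mg_L)
            for r in df.itertuples()
        ]
    if periods:
        entries.append(atmospheric_deposition(periods, config.area_km2))

    budget_cfg = config.raw.get("budget", {})
    if runoff is None and "runoff" in config.paths:
        runoff = pd.read_csv(config.paths["runoff"])
    if runoff is not None and len(runoff):
        entries.append(riverine_flux(
            runoff_volume_m3=float(runoff["m3_per_day"].sum()),
            span_days=float(len(runoff)),
            conc_umol_per_L=budget_cfg.get("river_conc_umol_L", 2.0),
        ))
    if transport is None and "transport" in config.paths:
        transport = pd.read_csv(config.paths["transport"])
    if transport is not None and len(transport):
        entries.append(ocean_exchange_flux(
            transport_m3_per_s=float(transport["m3_per_s"].mean()),
            din_conc_umol_per_L=budget_cfg.get("din_conc_umol_L", 2.5),
        ))
    for name, spec in budget_cfg.get("constants", {}).items():
        entries.append(FluxEntry(
            name=name, category=spec["category"], value=float(spec["value"]),
            range_lo=spec.get("range_lo"), range_hi=spec.get("range_hi"),
            season=spec.get("season", "summer"),
            provenance=spec.get("provenance", "config constant"),
        ))
    if not entries:
        raise DataError("no budget inputs found (series or constants)")
    balance = internal_balance(entries)
    return entries, balance


def write_outputs(
    config: RunConfig,
    tables: Mapping[str, Sequence[SourceSinkEstimate]] | None = None,
    nem_rows: Sequence[NemEstimate] | None = None,
    entries: Sequence[FluxEntry] | None = None,
) -> list[Path]:
    """Write TSV outputs (with version/config-hash header) to the out dir."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    header = config.header()
    if tables:
        for tracer, rows in tables.items():
            p = config.out_dir / f"sources_sinks_{tracer}.tsv"
            p.write_text(header + write_result_table(list(rows)))
            written.append(p)
    if nem_rows is not None:
        p = config.out_dir / "nem.tsv"
        p.write_text(header + write_result_table(list(nem_rows)))
        written.append(p)
    if entries is not None:
        p = config.out_dir / "nitrogen_budget.tsv"
        p.write_text(header + budget_report(list(entries)))
        written.append(p)
    return written
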