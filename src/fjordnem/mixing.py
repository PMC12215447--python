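"""Two-endmember conservative mixing and biogeochemical source/sink terms.

A fjord water mass formed purely by diluting a marine endmember (salinity
S_AW, concentration C_AW) with freshwater (S_0, C_0) falls on the straight
mixing line in (S, C) space.  The conservatively expected concentration at
an observed salinity is

    C_cons = C_0 + (S_obs - S_0) * (C_AW - C_0) / (S_AW - S_0)

and the biogeochemical *Sources−Sinks* term is the departure from that line:

    ΔC = C_obs - C_cons

Negative ΔC means the water mass is a net sink relative to conservative
mixing (e.g. nutrient uptake by primary producers), positive a net source.

The freshwater DIC endmember cannot be measured directly in glacier melt;
it is estimated per year as the Y-intercept of an ordinary least-squares
regression of DIC on salinity within Surface Water.  Water-mass contrasts
are screened with two-tailed Welch t-tests (p < 0.05 by default);
non-significant estimates are reported, flagged, not suppressed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, EmptyPoolError, InsufficientDataError, ValidationError
from .records import BottleRecord, Region
from .watermass import PooledMean, WaterMassScheme, pool_water_mass

log = logging.getLogger(__name__)

#: default fjord-vs-shelf water-mass contrasts, shelf AW always the marine side
DEFAULT_PAIRS = ("AWs_vs_IW", "AWs_vs_SW", "AWs_vs_AWf")

#: default freshwater (glacial river) endmember concentrations, µmol kg⁻¹
DEFAULT_FRESH_CONCENTRATIONS = {
    "ammonium": 1.44,
    "nitrate_nitrite": 2.00,
    "phosphate": 0.064,
    "silicic_acid": 9.77,
    "dic": "regression",
}


@dataclass(frozen=True)
class Endmember:
    """A (salinity, concentration) anchor of the mixing line for one tracer."""

    salinity: float
    concentration: float
    tracer: str
    provenance: str = "config"

    def __post_init__(self) -> None:
        if self.salinity < 0:
            raise ValidationError(f"endmember salinity {self.salinity} < 0")
        if self.concentration < 0:
            log.warning(
                "endmember %s concentration %.3f < 0 (%s)",
                self.tracer, self.concentration, self.provenance,
            )


@dataclass
class RegressionFit:
    """OLS fit of concentration on salinity."""

    slope: float
    intercept: float
    intercept_se: float
    r_squared: float
    n: int


@dataclass
class SourceSinkEstimate:
    """ΔC for one year × water-mass pair × tracer, with test metadata.

    ``delta_C`` is None when the fjord pool (or the estimate) is absent for
    that year; result tables render such cells as "-".
    """

    year: int
    tracer: str
    pair: str
    S_obs: float | None = None
    C_obs: float | None = None
    C_cons: float | None = None
    delta_C: float | None = None
    n_fjord: int | None = None
    n_shelf: int | None = None
    p_value: float | None = None
    significant: bool = False

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")


def conservative_concentration(
    S_obs: float, marine: Endmember, fresh: Endmember
) -> float:
    """Concentration expected at S_obs from pure two-endmember dilution."""
    if marine.tracer != fresh.tracer:
        raise ConfigError(
            f"endmember tracer mismatch: {marine.tracer} vs {fresh.tracer}"
        )
    if marine.salinity == fresh.salinity:
        raise ValidationError(
            f"degenerate mixing line: both endmembers at S={marine.salinity}"
        )
    lo, hi = sorted((marine.salinity, fresh.salinity))
    if not lo <= S_obs <= hi:
        log.info("S_obs=%.3f outside endmember range [%.3f, %.3f]; extrapolating",
                 S_obs, lo, hi)
    return fresh.concentration + (S_obs - fresh.salinity) * (
        (marine.concentration - fresh.concentration)
        / (marine.salinity - fresh.salinity)
    )


def sources_sinks(
    C_obs: float, S_obs: float, marine: Endmember, fresh: Endmember
) -> float:
    """ΔC = C_obs − C_cons; negative = net biogeochemical sink."""
    return C_obs - conservative_concentration(S_obs, marine, fresh)


def freshwater_endmember_by_regression(
    sw_samples: Sequence[tuple[float, float]], tracer: str = "dic"
) -> tuple[Endmember, RegressionFit]:
    """Freshwater endmember as the Y-intercept of OLS concentration~salinity.

    Requires >= 3 samples with non-zero salinity variance.  A negative
    intercept is returned with a warning, not clamped.
    """
    if len(sw_samples) < 3:
        raise InsufficientDataError(
            f"regression endmember needs >= 3 samples, got {len(sw_samples)}"
        )
    sal = np.array([s for s, _ in sw_samples], dtype=float)
    conc = np.array([c for _, c in sw_samples], dtype=float)
    if np.ptp(sal) == 0:
        raise InsufficientDataError("zero salinity variance in SW samples")
    res = stats.linregress(sal, conc)
    fit = RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        intercept_se=float(res.intercept_stderr),
        r_squared=float(res.rvalue**2),
        n=len(sw_samples),
    )
    if fit.intercept < 0:
        log.warning("negative regression intercept %.2f for %s", fit.intercept, tracer)
    em = Endmember(
        salinity=0.0,
        concentration=fit.intercept,
        tracer=tracer,
        provenance="regression-intercept",
    )
    return em, fit


def contrast_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> tuple[float, bool]:
    """Two-tailed t-test of two concentration groups (Welch by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 values for a t-test")
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return p, p < alpha


@dataclass
class EndmemberConfig:
    """Per-tracer endmember settings for the annual source/sink table.

    ``fresh``: tracer -> concentration (µmol kg⁻¹) or the string
    ``"regression"`` (intercept of concentration~salinity in fjord SW, fit
    per year on raw bottle values pooled across stations).  Freshwater
    salinity is fixed at 0 (glacier melt).  The marine endmember is the
    pooled shelf AW unless explicit values are given.
    """

    fresh: Mapping[str, float | str] = None  # type: ignore[assignment]
    fresh_salinity: float = 0.0
    marine_source: str = "pooled_AW_shelf"
    marine_explicit: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.fresh is None:
            self.fresh = dict(DEFAULT_FRESH_CONCENTRATIONS)

    def fresh_endmember(self, tracer: str, sw_samples=None) -> tuple[Endmember, RegressionFit | None]:
        if tracer not in self.fresh:
            raise ConfigError(f"no freshwater endmember configured for '{tracer}'")
        spec = self.fresh[tracer]
        if spec == "regression":
            if not sw_samples:
                raise InsufficientDataError(
                    f"regression endmember for '{tracer}' requested but no SW samples"
                )
            return freshwater_endmember_by_regression(sw_samples, tracer)
        return Endmember(self.fresh_salinity, float(spec), tracer, "config"), None


def annual_source_sink_table(
    labeled: Sequence[tuple[BottleRecord, str]],
    scheme: WaterMassScheme,
    endmember_config: EndmemberConfig,
    tracers: Sequence[str],
    pairs: Sequence[str] = DEFAULT_PAIRS,
    depth_max: float = 100.0,
    alpha: float = 0.05,
    station_first: bool = True,
) -> list[SourceSinkEstimate]:
    """Build the per-year ΔC table for the requested tracers and contrasts.

    For each year × tracer × pair, the marine endmember is the pooled shelf
    AW, the fjord observation the pooled fjord water mass, and the
    freshwater endmember comes from config (fixed value or per-year SW
    regression intercept).  Missing pools yield absent estimates, not zeros.
    The p-value screens shelf vs fjord raw bottle concentrations.
    """
    years = sorted({r.year for r, _ in labeled})
    out: list[SourceSinkEstimate] = []
    for year, tracer in itertools.product(years, tracers):
        year_recs = [(r, lab) for r, lab in labeled if r.year == year]
        try:
            marine_pool = pool_water_mass(
                year_recs, Region.SHELF, "AW", tracer, depth_max, station_first)
        except EmptyPoolError:
            log.warning("%d %s: no shelf AW pool; estimates absent", year, tracer)
            out.extend(SourceSinkEstimate(year, tracer, p) for p in pairs)
            continue
        if endmember_config.marine_explicit and tracer in (endmember_config.marine_explicit or {}):
            s_m, c_m = endmember_config.marine_explicit[tracer]
            marine = Endmember(s_m, c_m, tracer, "config")
        else:
            marine = Endmember(
                marine_pool.mean_sal, marine_pool.mean_conc, tracer, "pooled-AWs")

        sw_samples = [
            (r.salinity, r.tracers[tracer])
            for r, lab in year_recs
            if r.region is Region.FJORD and lab == "SW" and tracer in r.tracers
            and r.depth <= depth_max
        ]
        try:
            fresh, _fit = endmember_config.fresh_endmember(tracer, sw_samples)
        except InsufficientDataError as exc:
            log.warning("%d %s: %s; estimates absent", year, tracer, exc)
            out.extend(SourceSinkEstimate(year, tracer, p) for p in pairs)
            continue

        for pair in pairs:
            fjord_label = pair.split("_vs_")[1].replace("AWf", "AW")
            try:
                fjord_pool = pool_water_mass(
                    year_recs, Region.FJORD, fjord_label, tracer, depth_max,
                    station_first)
            except EmptyPoolError:
                out.append(SourceSinkEstimate(year, tracer, pair,
                                              n_shelf=marine_pool.n))
                continue
            c_cons = conservative_concentration(fjord_pool.mean_sal, marine, fresh)
            delta = fjord_pool.mean_conc - c_cons
            p_value: float | None
            try:
                p_value, signif = contrast_test(
                    marine_pool.sample_concs, fjord_pool.sample_concs, alpha)
            except InsufficientDataError:
                p_value, signif = None, False
            out.append(SourceSinkEstimate(
                year=year, tracer=tracer, pair=pair,
                S_obs=fjord_pool.mean_sal, C_obs=fjord_pool.mean_conc,
                C_cons=c_cons, delta_C=delta,
                n_fjord=fjord_pool.n, n_shelf=marine_pool.n,
                p_value=p_value, significant=signif,
            ))
    return out
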