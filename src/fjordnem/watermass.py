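"""Water-mass classification and depth-weighted pooling.

Samples are classified from rectangular temperature/salinity envelopes
(e.g. Atlantic Water, Transformed Atlantic Water, Surface Water,
Intermediate Water on the West Spitsbergen shelf).  Envelope bounds live in
configuration, not code: the shipped defaults follow the Cottier et al.
(2005) Kongsfjorden envelopes but are placeholders the user can edit.

Pooled water-mass means are computed station-first: a depth-weighted
(trapezoidal) vertical mean per station over a depth window (default top
100 m), then an unweighted average across stations, so that heavily sampled
stations do not dominate.  Sample-level sd and n are kept for the t-test
screen.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, EmptyPoolError, ValidationError
from .records import BottleRecord, Region

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WaterMassEnvelope:
    """Rectangular T/S box; minima inclusive, maxima exclusive.

    Any bound may be omitted (open side).  ``priority`` ranks overlapping
    envelopes: lower numbers win.
    """

    name: str
    temp_min: float | None = None
    temp_max: float | None = None
    sal_min: float | None = None
    sal_max: float | None = None
    priority: int = 0

    def __post_init__(self) -> None:
        if all(b is None for b in (self.temp_min, self.temp_max, self.sal_min, self.sal_max)):
            raise ConfigError(f"envelope '{self.name}' has no bounds")
        if self.temp_min is not None and self.temp_max is not None and self.temp_min > self.temp_max:
            raise ConfigError(f"envelope '{self.name}': temp_min > temp_max")
        if self.sal_min is not None and self.sal_max is not None and self.sal_min > self.sal_max:
            raise ConfigError(f"envelope '{self.name}': sal_min > sal_max")

    def contains(self, temperature: float, salinity: float) -> bool:
        return (
            (self.temp_min is None or temperature >= self.temp_min)
            and (self.temp_max is None or temperature < self.temp_max)
            and (self.sal_min is None or salinity >= self.sal_min)
            and (self.sal_max is None or salinity < self.sal_max)
        )


@dataclass
class WaterMassScheme:
    """Ordered set of envelopes plus a fallback label for unmatched samples."""

    envelopes: list[WaterMassEnvelope]
    fallback_label: str = "other"

    def __post_init__(self) -> None:
        prios = [e.priority for e in self.envelopes]
        if len(set(prios)) != len(prios):
            raise ConfigError("envelope priorities must be unique within a scheme")
        self.envelopes = sorted(self.envelopes, key=lambda e: e.priority)

    @property
    def labels(self) -> list[str]:
        return [e.name for e in self.envelopes]


def default_scheme() -> WaterMassScheme:
    """Cottier et al. (2005) style envelopes for the West Spitsbergen shelf.

    Placeholder defaults — edit via config for other systems.
    """
    return WaterMassScheme(
        envelopes=[
            WaterMassEnvelope("AW", temp_min=3.0, sal_min=34.9, priority=1),
            WaterMassEnvelope("TAW", temp_min=1.0, temp_max=3.0, sal_min=34.7, priority=2),
            WaterMassEnvelope("IW", temp_min=1.0, sal_min=34.0, sal_max=34.65, priority=3),
            WaterMassEnvelope("SW", temp_min=1.0, sal_max=34.0, priority=4),
        ]
    )


def classify_sample(temperature: float, salinity: float, scheme: WaterMassScheme) -> str:
    """Label a (T, S) point with the highest-priority matching envelope."""
    if not scheme.envelopes:
        raise ConfigError("water-mass scheme is empty")
    if not (math.isfinite(temperature) and math.isfinite(salinity)):
        raise ValidationError(f"non-finite T/S: T={temperature}, S={salinity}")
    for env in scheme.envelopes:
        if env.contains(temperature, salinity):
            return env.name
    return scheme.fallback_label


def assign_labels(
    records: Iterable[BottleRecord], scheme: WaterMassScheme
) -> list[tuple[BottleRecord, str]]:
    """Attach a water-mass label to every record; counts per label are logged."""
    labeled = [(r, classify_sample(r.temperature, r.salinity, scheme)) for r in records]
    counts = Counter(label for _, label in labeled)
    log.info("water-mass labels: %s", dict(counts))
    return labeled


def depth_weighted_mean(
    samples: Sequence[tuple[float, float]], depth_max: float
) -> float:
    """Trapezoidal vertical mean of (depth, value) pairs over [0, depth_max].

    Duplicate depths are averaged first.  The integral runs from the
    shallowest sample to min(deepest sample, depth_max) and is divided by
    that span; a single sample returns its own value.
    """
    by_depth: dict[float, list[float]] = defaultdict(list)
    for d, v in samples:
        if d <= depth_max:
            by_depth[d].append(v)
    if not by_depth:
        raise EmptyPoolError(f"no samples within [0, {depth_max}] m")
    depths = np.array(sorted(by_depth))
    values = np.array([float(np.mean(by_depth[d])) for d in depths])
    if len(depths) == 1:
        return float(values[0])
    span = depths[-1] - depths[0]
    return float(np.trapezoid(values, depths) / span)


@dataclass
class PooledMean:
    """Pooled water-mass mean of one tracer over one region and depth window."""

    water_mass: str
    region: Region
    tracer: str
    mean_conc: float
    mean_sal: float
    n: int
    sd_conc: float | None = None
    #: raw per-bottle concentrations, retained for the t-test screen
    sample_concs: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("pooled mean requires n >= 1")
        if self.sd_conc is not None and self.sd_conc < 0:
            raise ValidationError("sd_conc must be >= 0")


def pool_water_mass(
    labeled: Sequence[tuple[BottleRecord, str]],
    region: Region | str,
    label: str,
    tracer: str,
    depth_max: float = 100.0,
    station_first: bool = True,
) -> PooledMean:
    """Pool a tracer over all samples of one water mass in one region.

    Per-station depth-weighted means are averaged with equal station weight
    (``station_first=True``, the default); sample-level pooling is available
    behind the switch.  Salinity is pooled the same way.
    """
    region = Region(region)
    matching = [
        r for r, lab in labeled
        if r.region is region and lab == label and tracer in r.tracers
        and r.depth <= depth_max
    ]
    if not matching:
        raise EmptyPoolError(f"no samples for ({region.value}, {label}, {tracer})")

    concs = np.array([r.tracers[tracer] for r in matching])
    if station_first:
        stations = sorted({r.station_id for r in matching})
        stn_conc = []
        stn_sal = []
        for s in stations:
            sub = [r for r in matching if r.station_id == s]
            stn_conc.append(depth_weighted_mean(
                [(r.depth, r.tracers[tracer]) for r in sub], depth_max))
            stn_sal.append(depth_weighted_mean(
                [(r.depth, r.salinity) for r in sub], depth_max))
        mean_conc = float(np.mean(stn_conc))
        mean_sal = float(np.mean(stn_sal))
    else:
        mean_conc = float(np.mean(concs))
        mean_sal = float(np.mean([r.salinity for r in matching]))

    n = len(matching)
    return PooledMean(
        water_mass=label,
        region=region,
        tracer=tracer,
        mean_conc=mean_conc,
        mean_sal=mean_sal,
        n=n,
        sd_conc=float(np.std(concs, ddof=1)) if n > 1 else None,
        sample_concs=[float(c) for c in concs],
    )
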