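"""Published Kongsfjorden summer source/sink estimates (input data).

Vertically averaged (top 100 m) biogeochemical *Sources−Sinks* terms
(µmol kg⁻¹) for Kongsfjorden, derived from the MOSJ summer monitoring
transect: fjord Surface Water (SW), Intermediate Water (IW) and fjord
Atlantic Water (AWf) contrasted against Atlantic Water on the shelf (AWs,
stations V10/V12/V14), with a freshwater nitrate+nitrite endmember of
2.0 µmol kg⁻¹ and per-year regression-derived freshwater DIC endmembers.

These numbers are *inputs* to the NEM stage (they carry no timescale of
their own); `None` marks year × contrast cells without data.  Entries whose
underlying water-mass means differed significantly (two-tailed t-test,
p < 0.05) are listed in ``SIGNIFICANT``.
"""

from __future__ import annotations

#: nitrate+nitrite ΔC (µmol kg⁻¹) per year, summer, top 100 m
NITRATE_SOURCES_SINKS: dict[int, dict[str, float | None]] = {
    2011: {"AWs_vs_IW": -2.0, "AWs_vs_SW": -1.2, "AWs_vs_AWf": None},
    2012: {"AWs_vs_IW": -4.9, "AWs_vs_SW": -5.0, "AWs_vs_AWf": -5.2},
    2013: {"AWs_vs_IW": -3.7, "AWs_vs_SW": -4.2, "AWs_vs_AWf": -2.6},
    2014: {"AWs_vs_IW": -4.7, "AWs_vs_SW": -4.0, "AWs_vs_AWf": -2.6},
    2015: {"AWs_vs_IW": -7.5, "AWs_vs_SW": -7.7, "AWs_vs_AWf": -4.4},
    2016: {"AWs_vs_IW": -5.3, "AWs_vs_SW": -5.0, "AWs_vs_AWf": -2.5},
    2017: {"AWs_vs_IW": -3.3, "AWs_vs_SW": -3.2, "AWs_vs_AWf": 0.5},
    2018: {"AWs_vs_IW": -1.7, "AWs_vs_SW": -1.8, "AWs_vs_AWf": 1.9},
    2019: {"AWs_vs_IW": -4.0, "AWs_vs_SW": -3.7, "AWs_vs_AWf": -2.9},
    2020: {"AWs_vs_IW": -4.7, "AWs_vs_SW": -5.2, "AWs_vs_AWf": -1.8},
}

#: DIC ΔC (µmol kg⁻¹) per year, summer, top 100 m
DIC_SOURCES_SINKS: dict[int, dict[str, float | None]] = {
    2012: {"AWs_vs_IW": -23.9, "AWs_vs_SW": -23.6, "AWs_vs_AWf": -17.4},
    2013: {"AWs_vs_IW": -13.1, "AWs_vs_SW": -4.6, "AWs_vs_AWf": 26.0},
    2014: {"AWs_vs_IW": -34.5, "AWs_vs_SW": -28.3, "AWs_vs_AWf": -10.9},
    2015: {"AWs_vs_IW": -68.6, "AWs_vs_SW": -72.8, "AWs_vs_AWf": -5.1},
    2017: {"AWs_vs_IW": -37.4, "AWs_vs_SW": -41.9, "AWs_vs_AWf": 4.7},
    2018: {"AWs_vs_IW": -14.4, "AWs_vs_SW": -23.9, "AWs_vs_AWf": 28.9},
    2019: {"AWs_vs_IW": -27.9, "AWs_vs_SW": -38.9, "AWs_vs_AWf": -9.3},
    2020: {"AWs_vs_IW": -10.4, "AWs_vs_SW": -12.8, "AWs_vs_AWf": 14.6},
}

#: regression-derived freshwater DIC endmember (µmol kg⁻¹) per year
DIC_FRESHWATER_ENDMEMBER: dict[int, float] = {
    2012: 668.0,
    2013: 769.0,
    2014: 615.0,
    2015: 1105.0,
    2017: 1180.0,
    2018: 949.0,
    2019: 834.0,
    2020: 555.0,
}

#: (tracer, year, pair) combinations with significant water-mass contrasts
SIGNIFICANT: set[tuple[str, int, str]] = {
    ("nitrate_nitrite", 2011, "AWs_vs_IW"),
    ("nitrate_nitrite", 2012, "AWs_vs_SW"),
    ("nitrate_nitrite", 2013, "AWs_vs_SW"),
    ("nitrate_nitrite", 2014, "AWs_vs_IW"),
    ("nitrate_nitrite", 2014, "AWs_vs_SW"),
    ("nitrate_nitrite", 2015, "AWs_vs_IW"),
    ("nitrate_nitrite", 2015, "AWs_vs_SW"),
    ("nitrate_nitrite", 2016, "AWs_vs_IW"),
    ("nitrate_nitrite", 2016, "AWs_vs_SW"),
    ("nitrate_nitrite", 2017, "AWs_vs_SW"),
    ("nitrate_nitrite", 2019, "AWs_vs_SW"),
    ("nitrate_nitrite", 2020, "AWs_vs_IW"),
    ("nitrate_nitrite", 2020, "AWs_vs_SW"),
    ("dic", 2012, "AWs_vs_IW"),
    ("dic", 2013, "AWs_vs_IW"),
    ("dic", 2014, "AWs_vs_IW"),
    ("dic", 2014, "AWs_vs_SW"),
    ("dic", 2015, "AWs_vs_IW"),
    ("dic", 2015, "AWs_vs_SW"),
    ("dic", 2017, "AWs_vs_IW"),
    ("dic", 2017, "AWs_vs_SW"),
    ("dic", 2018, "AWs_vs_IW"),
    ("dic", 2018, "AWs_vs_SW"),
    ("dic", 2019, "AWs_vs_IW"),
    ("dic", 2019, "AWs_vs_SW"),
    ("dic", 2020, "AWs_vs_IW"),
    ("dic", 2020, "AWs_vs_SW"),
}

#: fjord surface area (km²) enclosed by the mouth transect
FJORD_AREA_KM2 = 231.5

#: mean modeled fjord flushing time (days)
DEFAULT_FT_DAYS = 13.0


def published_delta_c(tracer: str) -> dict[int, dict[str, float | None]]:
    """ΔC table for ``tracer`` ('nitrate_nitrite' or 'dic')."""
    tables = {"nitrate_nitrite": NITRATE_SOURCES_SINKS, "dic": DIC_SOURCES_SINKS}
    if tracer not in tables:
        raise KeyError(f"no published source/sink table for '{tracer}'")
    return tables[tracer]
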