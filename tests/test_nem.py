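"""Drawdown rates, flushing time, depth integration and areal upscaling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fjordnem import (
    ConfigError,
    FlushingSpec,
    InsufficientDataError,
    NemEstimate,
    ValidationError,
    cn_uptake_ratio,
    drawdown_rate,
    integrate_drawdown,
    loicz_flushing_time,
    nem_estimate,
    upscale_areal,
)


class TestDrawdownRate:
    def test_strongest_dic_sink_at_13_days(self):
        # published 2015 shelf-AW-vs-SW DIC source/sink term
        assert drawdown_rate(-72.8, FlushingSpec(ft_days=13)) == pytest.approx(5.6)

    def test_nitrate_upper_rate(self):
        assert drawdown_rate(-7.7, 13.0) == pytest.approx(0.592, abs=5e-4)

    def test_zero_delta_gives_zero(self):
        assert drawdown_rate(0.0, 13.0) == 0.0

    def test_non_finite_delta_rejected(self):
        with pytest.raises(ValidationError):
            drawdown_rate(float("nan"), 13.0)

    @given(delta=st.floats(-100, 100), ft=st.floats(0.5, 100))
    def test_homogeneous_in_flushing_time(self, delta, ft):
        assert drawdown_rate(delta, ft / 2) == pytest.approx(
            2 * drawdown_rate(delta, ft), rel=1e-12, abs=1e-12)


class TestLoiczFlushingTime:
    def test_pure_freshwater_limit(self):
        v, q = 2.0e10, 100.0
        assert loicz_flushing_time(v, q, 35.0, 0.0) == pytest.approx(v / q / 86400)

    def test_salt_balance_example(self):
        # Q_out = 100 * 35 / 0.35 = 1e4 m3/s; FT = 2e10/1e4 s = 23.15 d
        assert loicz_flushing_time(2.0e10, 100.0, 35.0, 34.65) == pytest.approx(
            23.148, abs=1e-3)

    def test_vanishes_as_fjord_salinity_approaches_ocean(self):
        ft = [loicz_flushing_time(2e10, 100, 35.0, s) for s in (34.0, 34.9, 34.999)]
        assert ft[0] > ft[1] > ft[2]
        assert ft[2] < 0.1

    def test_degenerate_salt_balance_rejected(self):
        with pytest.raises(ValidationError):
            loicz_flushing_time(2e10, 100, 34.0, 35.0)

    @given(
        v=st.floats(1e9, 1e11), q=st.floats(10, 1000),
        ds=st.floats(0.01, 5.0),
    )
    def test_monotonicity(self, v, q, ds):
        s_ocean = 35.0
        base = loicz_flushing_time(v, q, s_ocean, s_ocean - ds)
        assert loicz_flushing_time(2 * v, q, s_ocean, s_ocean - ds) > base
        assert loicz_flushing_time(v, 2 * q, s_ocean, s_ocean - ds) < base
        if ds < 2.5:
            assert loicz_flushing_time(v, q, s_ocean, s_ocean - 2 * ds) > base


class TestIntegrationAndUpscaling:
    def test_carbon_chain(self):
        mol, g = integrate_drawdown(5.6, 100, 1000, tracer="dic")
        assert mol == pytest.approx(0.56)
        assert g == pytest.approx(6.726, abs=1e-3)
        assert round(g, 1) == 6.7

    def test_nitrogen_chain(self):
        mol, g = integrate_drawdown(0.592, 100, 1000, tracer="nitrate_nitrite")
        assert mol == pytest.approx(0.0592)
        assert round(mol, 2) == 0.06

    def test_zero_rate_maps_to_zero(self):
        assert integrate_drawdown(0.0, 100, 1000, molar_mass=14.007) == (0.0, 0.0)
        assert upscale_areal(0.0, 231.5) == 0.0

    def test_unknown_tracer_molar_mass(self):
        with pytest.raises(ConfigError):
            integrate_drawdown(1.0, 100, 1000, tracer="mystery")

    def test_areal_upscaling_range_endpoints(self):
        assert upscale_areal(0.8295, 231.5) == pytest.approx(192.0, abs=0.1)
        assert upscale_areal(0.1293, 231.5) == pytest.approx(29.9, abs=0.1)

    @given(delta=st.floats(-50, 0), scale=st.floats(0.1, 4))
    def test_full_chain_linear_in_delta(self, delta, scale):
        e1 = nem_estimate(delta, 2019, "dic", "AWs_vs_SW", area_km2=231.5)
        e2 = nem_estimate(scale * delta, 2019, "dic", "AWs_vs_SW", area_km2=231.5)
        assert e2.areal_tonnes == pytest.approx(scale * e1.areal_tonnes, rel=1e-9, abs=1e-12)


def _nem(year, pair, rate, tracer):
    return NemEstimate(year, tracer, pair, rate, 0, 0, 100, 1000)


class TestCnRatio:
    def test_redfield_construction(self):
        n = [_nem(2019, "AWs_vs_SW", 1.0, "nitrate_nitrite")]
        c = [_nem(2019, "AWs_vs_SW", 6.6, "dic")]
        assert cn_uptake_ratio(n, c).mean == pytest.approx(6.6)

    def test_arithmetic_mean_of_pair_ratios(self):
        n = [_nem(2019, "AWs_vs_SW", 1.0, "nitrate_nitrite"),
             _nem(2019, "AWs_vs_IW", 1.0, "nitrate_nitrite")]
        c = [_nem(2019, "AWs_vs_SW", 6.0, "dic"),
             _nem(2019, "AWs_vs_IW", 8.0, "dic")]
        res = cn_uptake_ratio(n, c)
        assert res.mean == pytest.approx(7.0) and res.n == 2

    def test_exclusions_drop_outliers(self):
        n = [_nem(2019, "AWs_vs_SW", 1.0, "nitrate_nitrite"),
             _nem(2020, "AWs_vs_SW", 0.1, "nitrate_nitrite")]
        c = [_nem(2019, "AWs_vs_SW", 6.6, "dic"),
             _nem(2020, "AWs_vs_SW", 5.0, "dic")]
        res = cn_uptake_ratio(n, c, exclusions=[(2020, "AWs_vs_SW")])
        assert res.mean == pytest.approx(6.6) and res.n == 1

    def test_negative_rates_skipped(self):
        n = [_nem(2019, "AWs_vs_SW", -1.0, "nitrate_nitrite")]
        c = [_nem(2019, "AWs_vs_SW", 6.6, "dic")]
        with pytest.raises(InsufficientDataError):
            cn_uptake_ratio(n, c)

    def test_noisy_ratio_recovery(self):
        rng = np.random.default_rng(11)
        n, c = [], []
        for i, year in enumerate(range(2011, 2021)):
            for pair in ("AWs_vs_SW", "AWs_vs_IW"):
                r = rng.uniform(0.1, 0.6)
                n.append(_nem(year, pair, r, "nitrate_nitrite"))
                c.append(_nem(year, pair, 7.0 * r * rng.normal(1, 0.05), "dic"))
        assert cn_uptake_ratio(n, c).mean == pytest.approx(7.0, abs=0.2)


def test_loicz_flushing_spec_computes_ft():
    spec = FlushingSpec(method="loicz", volume=2.0e10, q_freshwater=100.0,
                        s_ocean=35.0, s_fjord=34.65)
    assert spec.ft_days == pytest.approx(23.148, abs=1e-3)
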