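"""Two-endmember mixing, regression endmembers and the t-test screen."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fjordnem import (
    ConfigError,
    Endmember,
    EndmemberConfig,
    InsufficientDataError,
    ValidationError,
    annual_source_sink_table,
    assign_labels,
    conservative_concentration,
    contrast_test,
    freshwater_endmember_by_regression,
    sources_sinks,
)

MARINE = Endmember(35.0, 12.0, "nitrate_nitrite")
FRESH = Endmember(0.0, 2.0, "nitrate_nitrite")


class TestConservativeConcentration:
    def test_endpoint_identities(self):
        assert conservative_concentration(35.0, MARINE, FRESH) == pytest.approx(12.0)
        assert conservative_concentration(0.0, MARINE, FRESH) == pytest.approx(2.0)

    def test_interior_value(self):
        # 2 + 33 * 10 / 35
        assert conservative_concentration(33.0, MARINE, FRESH) == pytest.approx(
            11.428571428571429)

    def test_degenerate_mixing_line(self):
        with pytest.raises(ValidationError, match="degenerate"):
            conservative_concentration(33.0, MARINE, Endmember(35.0, 2.0, "nitrate_nitrite"))

    def test_tracer_mismatch(self):
        with pytest.raises(ConfigError):
            conservative_concentration(33.0, MARINE, Endmember(0.0, 900.0, "dic"))


class TestSourcesSinks:
    def test_interior_value(self):
        assert sources_sinks(4.0, 33.0, MARINE, FRESH) == pytest.approx(-7.428571428571429)

    @given(f=st.floats(0, 1))
    def test_conservative_mixing_null(self, f):
        s = f * MARINE.salinity + (1 - f) * FRESH.salinity
        c = f * MARINE.concentration + (1 - f) * FRESH.concentration
        assert abs(sources_sinks(c, s, MARINE, FRESH)) < 1e-9

    @given(f=st.floats(0, 1), u=st.floats(0, 10))
    def test_uptake_shifts_delta_linearly(self, f, u):
        s = f * MARINE.salinity
        c_cons = conservative_concentration(s, MARINE, FRESH)
        assert sources_sinks(c_cons - u, s, MARINE, FRESH) == pytest.approx(-u, abs=1e-9)

    @given(f=st.floats(0, 1), c_obs=st.floats(0, 20))
    def test_invariant_to_endmember_role_swap(self, f, c_obs):
        s = f * MARINE.salinity
        a = sources_sinks(c_obs, s, MARINE, FRESH)
        b = sources_sinks(c_obs, s, FRESH, MARINE)  # same line, roles swapped
        assert a == pytest.approx(b, abs=1e-9)


class TestRegressionEndmember:
    def test_exact_line_recovers_intercept_and_slope(self):
        pts = [(30.0, 1800.0), (32.0, 1900.0), (34.0, 2000.0)]
        em, fit = freshwater_endmember_by_regression(pts)
        assert em.salinity == 0.0
        assert em.concentration == pytest.approx(300.0)
        assert fit.slope == pytest.approx(50.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_line_intercept_within_3se(self):
        rng = np.random.default_rng(42)
        sal = rng.uniform(28, 35, 200)
        conc = 900.0 + 40.0 * sal + rng.normal(0, 20, 200)
        em, fit = freshwater_endmember_by_regression(list(zip(sal, conc)))
        assert abs(em.concentration - 900.0) <= 3 * fit.intercept_se
        assert em.provenance == "regression-intercept"

    def test_degenerate_designs_rejected(self):
        with pytest.raises(InsufficientDataError):
            freshwater_endmember_by_regression([(30.0, 1800.0), (34.0, 2000.0)])
        with pytest.raises(InsufficientDataError):
            freshwater_endmember_by_regression([(30.0, 1.0)] * 5)

    def test_negative_intercept_returned_not_clamped(self):
        pts = [(30.0, 10.0), (32.0, 30.0), (34.0, 50.0)]  # intercept -290
        em, _ = freshwater_endmember_by_regression(pts)
        assert em.concentration == pytest.approx(-290.0)


class TestContrastTest:
    def test_identical_groups_not_significant(self):
        p, sig = contrast_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0) and not sig

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20)
        p, sig = contrast_test(a, b)
        assert sig and p < 1e-6

    def test_alpha_zero_never_significant(self):
        rng = np.random.default_rng(7)
        p, sig = contrast_test(rng.normal(0, 1, 20), rng.normal(5, 1, 20), alpha=0.0)
        assert not sig

    def test_zero_variance_equal_means(self):
        p, _ = contrast_test([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_too_small_group_raises(self):
        with pytest.raises(InsufficientDataError):
            contrast_test([1.0], [1.0, 2.0])


class TestAnnualTable:
    def test_conservative_dataset_gives_zero_everywhere(self):
        from fjordnem.synthetic import SyntheticConfig, generate_transect
        cfg = SyntheticConfig(seed=1, years=(2018, 2019))
        records, _ = generate_transect(cfg)
        labeled = assign_labels(records, cfg.scheme)
        rows = annual_source_sink_table(
            labeled, cfg.scheme, cfg.endmember_config(),
            tracers=("nitrate_nitrite", "dic"))
        assert len(rows) == 2 * 2 * 3
        assert all(abs(r.delta_C) < 1e-9 for r in rows)

    def test_imposed_drawdown_recovered_each_year(self, kongsfjorden_run):
        cfg, _, truth, _, tables = kongsfjorden_run
        for row in tables["nitrate_nitrite"]:
            wm = row.pair.split("_vs_")[1].replace("AWf", "AW")
            expected = truth.expected_delta_c(wm, "nitrate_nitrite")
            assert row.delta_C == pytest.approx(expected, abs=0.5)
            assert row.significant  # drawdowns are far larger than noise

    def test_year_with_missing_water_mass_gets_absent_estimate(self):
        from fjordnem.synthetic import SyntheticConfig, generate_transect
        from fjordnem.records import Region
        cfg = SyntheticConfig(seed=2, years=(2019,))
        records, _ = generate_transect(cfg)
        records = [r for r in records if not (r.region is Region.FJORD and r.depth < 25)]
        labeled = assign_labels(records, cfg.scheme)
        rows = annual_source_sink_table(
            labeled, cfg.scheme,
            EndmemberConfig(fresh={"nitrate_nitrite": 2.0}),
            tracers=("nitrate_nitrite",))
        by_pair = {r.pair: r for r in rows}
        assert by_pair["AWs_vs_SW"].delta_C is None
        assert by_pair["AWs_vs_IW"].delta_C is not None

    def test_missing_endmember_config_raises(self):
        with pytest.raises(ConfigError):
            EndmemberConfig(fresh={"dic": 900.0}).fresh_endmember("phosphate")
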