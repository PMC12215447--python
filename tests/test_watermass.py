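"""Water-mass classification and depth-weighted pooling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fjordnem import (
    BottleRecord,
    EmptyPoolError,
    Region,
    ValidationError,
    WaterMassEnvelope,
    WaterMassScheme,
    assign_labels,
    classify_sample,
    default_scheme,
    depth_weighted_mean,
    pool_water_mass,
)
from fjordnem.errors import ConfigError


@pytest.fixture
def aw_scheme():
    return WaterMassScheme([WaterMassEnvelope("AW", temp_min=3.0, sal_min=34.9, priority=1)])


class TestClassify:
    def test_envelope_match(self, aw_scheme):
        assert classify_sample(4.0, 35.0, aw_scheme) == "AW"

    def test_fallback_when_nothing_matches(self, aw_scheme):
        assert classify_sample(0.0, 30.0, aw_scheme) == "other"

    def test_priority_breaks_overlap(self):
        scheme = WaterMassScheme([
            WaterMassEnvelope("B", temp_min=0.0, priority=2),
            WaterMassEnvelope("A", temp_min=0.0, priority=1),
        ])
        assert classify_sample(5.0, 34.0, scheme) == "A"

    def test_minima_inclusive_maxima_exclusive(self):
        scheme = default_scheme()
        assert classify_sample(3.0, 34.9, scheme) == "AW"     # at minima
        assert classify_sample(2.999, 34.9, scheme) == "TAW"  # below AW temp_min
        assert classify_sample(2.0, 34.65, scheme) == "other"  # at IW sal_max

    def test_non_finite_rejected(self, aw_scheme):
        with pytest.raises(ValidationError):
            classify_sample(math.nan, 35.0, aw_scheme)

    def test_duplicate_priorities_rejected(self):
        with pytest.raises(ConfigError):
            WaterMassScheme([
                WaterMassEnvelope("A", temp_min=0, priority=1),
                WaterMassEnvelope("B", temp_min=0, priority=1),
            ])


def test_assign_labels_matches_generator_truth():
    from fjordnem.synthetic import scenario_kongsfjorden_summer, generate_transect
    cfg = scenario_kongsfjorden_summer()
    records, truth = generate_transect(cfg)
    labeled = assign_labels(records, cfg.scheme)
    assert [lab for _, lab in labeled] == truth.labels


def test_assign_labels_empty():
    assert assign_labels([], default_scheme()) == []


class TestDepthWeightedMean:
    def test_linear_profile_symmetry(self):
        assert depth_weighted_mean([(0, 1), (50, 2), (100, 3)], 100) == pytest.approx(2.0)

    def test_uneven_spacing_trapezoid(self):
        # (4+2)/2*20 + (2+1)/2*80 = 180 over 100 m span
        assert depth_weighted_mean([(0, 4), (20, 2), (100, 1)], 100) == pytest.approx(1.8)

    def test_single_sample_returns_its_value(self):
        assert depth_weighted_mean([(10, 5.5)], 100) == 5.5

    def test_samples_below_window_excluded(self):
        assert depth_weighted_mean([(10, 5.5), (200, 99.0)], 100) == 5.5

    def test_duplicate_depths_averaged_first(self):
        assert depth_weighted_mean([(0, 1), (0, 3), (10, 2)], 100) == pytest.approx(2.0)

    def test_empty_window_raises(self):
        with pytest.raises(EmptyPoolError):
            depth_weighted_mean([(150, 1.0)], 100)

    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.floats(-10, 10)),
            min_size=1, max_size=20,
        ),
        st.floats(50, 150),
    )
    def test_bounded_by_min_and_max(self, samples, depth_max):
        try:
            m = depth_weighted_mean(samples, depth_max)
        except EmptyPoolError:
            return
        vals = [v for d, v in samples if d <= depth_max]
        assert min(vals) - 1e-9 <= m <= max(vals) + 1e-9

    @given(st.floats(-5, 5), st.floats(10, 150))
    def test_constant_profile_returns_constant(self, c, depth_max):
        samples = [(d, c) for d in (0, 10, 30, 60, 90)]
        assert depth_weighted_mean(samples, depth_max) == pytest.approx(c)


def _rec(station, depth, conc, sal=34.0):
    return BottleRecord(station_id=station, region=Region.FJORD, year=2019,
                        depth=depth, salinity=sal, temperature=2.0,
                        tracers={"nitrate_nitrite": conc})


class TestPooling:
    def test_uniform_concentration_any_depth_window(self):
        labeled = [(_rec("a", d, 7.0), "IW") for d in (0, 20, 80)]
        pm = pool_water_mass(labeled, "fjord", "IW", "nitrate_nitrite", 100)
        assert pm.mean_conc == pytest.approx(7.0)
        assert pm.n == 3 and pm.sd_conc == pytest.approx(0.0)

    def test_stations_weighted_equally(self):
        labeled = (
            [(_rec("a", d, 2.0), "IW") for d in (0, 50)]
            + [(_rec("b", d, 4.0), "IW") for d in (0, 10, 20, 30)]
        )
        pm = pool_water_mass(labeled, "fjord", "IW", "nitrate_nitrite", 100)
        assert pm.mean_conc == pytest.approx(3.0)

    def test_sample_level_pooling_behind_switch(self):
        labeled = (
            [(_rec("a", d, 2.0), "IW") for d in (0, 50)]
            + [(_rec("b", d, 4.0), "IW") for d in (0, 10, 20, 30)]
        )
        pm = pool_water_mass(labeled, "fjord", "IW", "nitrate_nitrite", 100,
                             station_first=False)
        assert pm.mean_conc == pytest.approx((2 * 2 + 4 * 4) / 6)

    def test_empty_pool_names_request(self):
        with pytest.raises(EmptyPoolError, match="shelf.*AW.*dic"):
            pool_water_mass([(_rec("a", 0, 1.0), "IW")], "shelf", "AW", "dic", 100)

    def test_recovers_generator_water_mass_mean(self):
        from fjordnem.synthetic import SyntheticConfig, generate_transect
        cfg = SyntheticConfig(seed=3, n_stations_fjord=10,
                              noise_sd={"nitrate_nitrite": 0.3})
        records, truth = generate_transect(cfg)
        labeled = assign_labels(records, cfg.scheme)
        pm = pool_water_mass(labeled, "fjord", "SW", "nitrate_nitrite", 100)
        true_mean = np.mean([
            truth.conservative[i]["nitrate_nitrite"]
            for i, lab in enumerate(truth.labels)
            if lab == "SW" and records[i].region is Region.FJORD
        ])
        assert pm.mean_conc == pytest.approx(true_mean, abs=2 * 0.3 / np.sqrt(pm.n) * 3)
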