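"""National products, population interpolation, smoothing, shares."""

import numpy as np
import pandas as pd
import pytest

import revoquant as rq
from revoquant.aggregate import AggregationConfig, loess_smooth, prepare_birth_years
from revoquant.exceptions import InvalidConfigError


class TestNationalProduct:
    def test_hand_example(self, tiny_bios):
        # peaks at 1635, 1645, 1685; window [1625, 1675] catches the
        # first two scores only
        assert rq.national_product(tiny_bios, "france", 1650) == 3.0

    def test_window_endpoints_inclusive(self, tiny_bios):
        # birth 1600 -> peak 1635 sits exactly on y - 25 for y = 1660
        assert rq.national_product(tiny_bios, "france", 1660) >= 1.0
        solo = tiny_bios.iloc[[0]]
        assert rq.national_product(solo, "france", 1660) == 1.0
        assert rq.national_product(solo, "france", 1610) == 1.0  # peak == y + 25

    def test_no_qualifying_individuals(self, tiny_bios):
        assert rq.national_product(tiny_bios, "france", 1900) == 0.0

    def test_unknown_country_warns_and_returns_zero(self, tiny_bios):
        with pytest.warns(UserWarning):
            assert rq.national_product(tiny_bios, "atlantis", 1650) == 0.0

    def test_pooling_additivity(self, tiny_bios):
        other = tiny_bios.assign(country="italy")
        both = pd.concat([tiny_bios, other], ignore_index=True)
        pooled = rq.subset_and_pool(both, {"france": "west", "italy": "west"})
        assert rq.national_product(pooled, "west", 1650) == (
            rq.national_product(both, "france", 1650)
            + rq.national_product(both, "italy", 1650)
        )

    def test_birth_year_imputed_from_death(self, caplog):
        bios = pd.DataFrame({"country": ["x"], "birth_year": [np.nan],
                             "death_year": [1700.0], "score": [2.0]})
        with caplog.at_level("WARNING"):
            out = prepare_birth_years(bios)
        assert out["birth_year"].iloc[0] == 1640.0


class TestPopulationInterpolation:
    anchors = [(1600, 10e6), (1700, 20e6)]

    def test_midpoint(self):
        assert rq.interpolate_population(self.anchors, [1650])[0] == pytest.approx(15e6)

    def test_linear_extrapolation(self):
        assert rq.interpolate_population(self.anchors, [1710])[0] == pytest.approx(21e6)

    def test_duplicate_anchor_years_rejected(self):
        with pytest.raises(InvalidConfigError):
            rq.interpolate_population([(1600, 1e6), (1600, 2e6)], [1650])

    def test_single_anchor_constant_with_warning(self):
        with pytest.warns(UserWarning):
            out = rq.interpolate_population([(1600, 1e6)], [1500, 1700])
        assert np.allclose(out, 1e6)


class TestPerCapitaAndGrowth:
    years = np.arange(1300, 1600, 10)

    def test_constant_series_smooths_to_itself(self):
        n = len(self.years)
        out = rq.per_capita_series(np.full(n, 6.0), np.full(n, 2.0), self.years)
        np.testing.assert_allclose(out["production_pc_smooth"], 3.0)

    def test_doubling_population_halves_per_capita(self, rng):
        n = len(self.years)
        prod = rng.uniform(1, 5, n)
        pop = rng.uniform(1e6, 2e6, n)
        a = rq.per_capita_series(prod, pop, self.years)
        b = rq.per_capita_series(prod, 2 * pop, self.years)
        np.testing.assert_allclose(b["production_pc"], a["production_pc"] / 2)

    def test_loess_reproduces_linear_trend(self):
        vals = 0.01 * (self.years - 1300) + 2.0
        sm = loess_smooth(self.years, vals, window=50)
        np.testing.assert_allclose(sm, vals, rtol=1e-8)

    def test_zero_population_rejected(self):
        with pytest.raises(InvalidConfigError):
            rq.per_capita_series([1.0], [0.0], [1300])

    def test_score_scaling_equivariance(self, rng):
        n = len(self.years)
        prod = rng.uniform(1, 5, n)
        pop = rng.uniform(1e6, 2e6, n)
        a = rq.per_capita_series(prod, pop, self.years)
        b = rq.per_capita_series(3.0 * prod, pop, self.years)
        np.testing.assert_allclose(b["production_pc"], 3.0 * a["production_pc"])
        np.testing.assert_allclose(b["production_pc_smooth"],
                                   3.0 * a["production_pc_smooth"], rtol=1e-8)

    def test_growth_rate_exact_log_slope(self):
        t = np.arange(0, 100, 10)
        assert np.allclose(rq.growth_rate(np.exp(0.02 * t), step=10), 0.02)
        assert np.allclose(rq.growth_rate(np.full(5, 3.3), step=10), 0.0)
        assert rq.growth_rate([2.0], step=10).size == 0

    def test_growth_rate_requires_positive_values(self):
        with pytest.raises(InvalidConfigError):
            rq.growth_rate([1.0, 0.0], step=10)


class TestShares:
    def test_single_country(self):
        assert rq.country_shares({"a": 5.0}).iloc[0] == 1.0

    def test_direct_ratio(self):
        s = rq.country_shares({"a": 3.0, "b": 1.0})
        assert s["a"] == 0.75 and s["b"] == 0.25

    def test_random_shares_sum_to_one(self, rng):
        for _ in range(5):
            v = rng.uniform(0.1, 9.0, size=6)
            s = rq.country_shares(dict(enumerate(v)))
            assert s.sum() == pytest.approx(1.0)
            assert ((s >= 0) & (s <= 1)).all()

    def test_zero_total_rejected(self):
        with pytest.raises(InvalidConfigError):
            rq.country_shares({"a": 0.0, "b": 0.0})


class TestSubsetAndPool:
    def test_top_decile_of_100(self, rng):
        bios = pd.DataFrame({"country": "x", "birth_year": 1500,
                             "score": rng.permutation(100).astype(float)})
        assert len(rq.subset_and_pool(bios, "top10")) == 10
        assert len(rq.subset_and_pool(bios, "bottom90")) == 90

    def test_identity_map_unchanged(self, tiny_bios):
        out = rq.subset_and_pool(tiny_bios, {})
        pd.testing.assert_frame_equal(out, tiny_bios)

    def test_empty_result_warns(self, tiny_bios):
        high = tiny_bios.assign(score=[1.0, 1.0, 1.0])
        # all scores equal: the 90th percentile equals every score, so
        # bottom90 is empty
        with pytest.warns(UserWarning):
            out = rq.subset_and_pool(high, "bottom90")
        assert out.empty


def test_aggregation_config_validation():
    with pytest.raises(InvalidConfigError):
        AggregationConfig(loess_window=5, grid_step=10)
    with pytest.raises(InvalidConfigError):
        AggregationConfig(peak_age=0)
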