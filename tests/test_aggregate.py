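import numpy as np
import pandas as pd
import pytest

from greenhia import (
    aggregate,
    build_hierarchy,
    compute_exposures,
    per_capita_rate,
    rank_units,
    region_province_map,
    round_half_away,
    run_hia,
    run_sensitivity,
)
from greenhia.aggregate import national_totals


def _results(rows):
    return pd.DataFrame(rows, columns=["city_id", "scenario", "deaths",
                                       "adult_pop"])


def _hier(rows):
    return pd.DataFrame(rows, columns=["city_id", "province", "region"])


REGIONAL_2000_2010 = {
    "North China": 1800.0,
    "Northeast China": -979.0,
    "East China": 8767.0,
    "Central China": 2562.0,
    "South China": -1381.0,
    "Southwest China": -609.0,
    "Northwest China": -209.0,
}


class TestAggregate:
    def test_regional_values_sum_to_published_national(self):
        res = _results(
            [(r, "change_2000_2010", d, 0.0)
             for r, d in REGIONAL_2000_2010.items()]
        )
        hier = _hier([(r, r, r) for r in REGIONAL_2000_2010])
        agg = aggregate(res, hier, clip_scenarios=())
        assert national_totals(agg)["change_2000_2010"] == 9951.0

    def test_single_city_national_equals_city(self):
        res = _results([("A", "change_2000_2010", -42.5, 1000.0)])
        agg = aggregate(res, _hier([("A", "P", "North China")]))
        assert national_totals(agg)["change_2000_2010"] == -42.5

    def test_orphan_city_rejected_by_name(self):
        res = _results([("A", "s", 1.0, 1.0), ("GHOST", "s", 1.0, 1.0)])
        with pytest.raises(ValueError, match="GHOST"):
            aggregate(res, _hier([("A", "P", "R")]))

    def test_conservation_exact_across_levels(self, small_bundle):
        expo = compute_exposures(small_bundle)
        results = run_hia(expo, small_bundle.demographics)
        hierarchy = build_hierarchy(small_bundle.cities)
        agg = aggregate(results, hierarchy, clip_scenarios=())
        for scenario, grp in agg.groupby("scenario"):
            nat = grp[grp.level == "national"]["deaths"].iloc[0]
            regions = grp[grp.level == "region"]
            assert regions["deaths"].sum() == nat
            for _, reg in regions.iterrows():
                provinces = grp[(grp.level == "province")
                                & (grp.region == reg["region"])]
                assert provinces.sort_values("unit_id")["deaths"].sum() == (
                    reg["deaths"])

    def test_counterfactual_totals_clip_above_target_cities(self):
        res = _results(
            [("A", "counterfactual_2000", 50.0, 1.0),
             ("B", "counterfactual_2000", -20.0, 1.0)]
        )
        hier = _hier([("A", "P", "R"), ("B", "P", "R")])
        agg = aggregate(res, hier)
        # city rows stay signed; totals count only below-target cities
        cities = agg[agg.level == "city"].set_index("unit_id")["deaths"]
        assert cities["B"] == -20.0
        assert national_totals(agg)["counterfactual_2000"] == 50.0

    def test_municipality_counted_once(self):
        # a province-level municipality is its own single leaf city
        res = _results([("Beijing", "s", 10.0, 5.0), ("A", "s", 1.0, 1.0)])
        hier = _hier([("Beijing", "Beijing", "North China"),
                      ("A", "Hebei", "North China")])
        agg = aggregate(res, hier, clip_scenarios=())
        assert national_totals(agg)["s"] == 11.0
        prov = agg[(agg.level == "province") & (agg.unit_id == "Beijing")]
        assert prov["deaths"].iloc[0] == 10.0


class TestRates:
    def test_per_100k_hand_value(self):
        assert per_capita_rate(-279.0, 1_000_000.0) == pytest.approx(-27.9)
        assert per_capita_rate(0.0, 123.0) == 0.0

    def test_linear_in_deaths(self):
        assert per_capita_rate(30.0, 1e6) == pytest.approx(
            3 * per_capita_rate(10.0, 1e6))

    def test_split_city_invariance(self):
        whole = per_capita_rate(100.0, 2e6)
        half = per_capita_rate(50.0, 1e6)
        assert whole == pytest.approx(half, rel=1e-14)

    def test_rounding_half_away_from_zero(self):
        np.testing.assert_array_equal(
            round_half_away([2.5, -2.5, 1.4, -1.4]), [3.0, -3.0, 1.0, -1.0])


class TestRanks:
    def _expo(self, values, ids=None):
        ids = ids or [f"C{i}" for i in range(len(values))]
        return pd.DataFrame({"city_id": ids, "weighted_ndvi": values})

    def test_rank_one_is_greenest(self):
        out = rank_units(self._expo([0.5, 0.3, 0.4]))
        assert list(out["rank"]) == [1, 3, 2]

    def test_ties_break_by_city_id(self):
        out = rank_units(self._expo([0.4, 0.4, 0.4], ids=["B", "A", "C"]))
        assert dict(zip(out["city_id"], out["rank"])) == {"A": 1, "B": 2, "C": 3}

    def test_matches_sort_oracle(self, rng):
        values = rng.uniform(0, 1, 40)
        out = rank_units(self._expo(list(values)))
        order = sorted(range(40), key=lambda i: (-values[i], f"C{i}"))
        expected = {f"C{i}": r + 1 for r, i in enumerate(order)}
        assert dict(zip(out["city_id"], out["rank"])) == expected
        assert sorted(out["rank"]) == list(range(1, 41))


class TestSensitivity:
    def test_identity_erf_variant_changes_nothing(self, noiseless_bundle):
        expo = compute_exposures(noiseless_bundle)
        hierarchy = build_hierarchy(noiseless_bundle.cities)
        out = run_sensitivity(expo, noiseless_bundle.demographics, hierarchy,
                              variant="alternative_erf", rr=0.96)
        assert np.allclose(out["percent_change"], 0.0, atol=1e-9)

    def test_weaker_erf_shrinks_every_scenario(self, noiseless_bundle):
        expo = compute_exposures(noiseless_bundle)
        hierarchy = build_hierarchy(noiseless_bundle.cities)
        out = run_sensitivity(expo, noiseless_bundle.demographics, hierarchy,
                              variant="alternative_erf", rr=0.98)
        assert (np.abs(out["variant_deaths"])
                < np.abs(out["base_deaths"])).all()

    def test_unweighted_variant_identical_when_means_agree(self, noiseless_bundle):
        # uniform within-city NDVI: weighted and unweighted exposure coincide
        expo = compute_exposures(noiseless_bundle)
        hierarchy = build_hierarchy(noiseless_bundle.cities)
        out = run_sensitivity(expo, noiseless_bundle.demographics, hierarchy,
                              variant="unweighted_ndvi")
        assert np.allclose(out["percent_change"], 0.0, atol=1e-6)


def test_region_province_fixture_covers_seven_regions():
    table = region_province_map()
    assert table["region"].nunique() == 7
    assert table["province"].is_unique
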