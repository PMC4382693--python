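"""Global proportions, region weighting, zones and zone comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import admixkit as ak
from admixkit.datatypes import InvalidParameterError
from conftest import make_markers


def _callset(markers, calls, names=("NAT", "EUR", "AFR")):
    n = calls.shape[0]
    return ak.AncestryCallSet(
        markers=markers, calls=calls, samples=[f"i{j}" for j in range(n)],
        ancestry_names=names, method="test",
    )


class TestGlobalProportions:
    def test_uniform_calls_give_unit_proportion(self):
        markers = make_markers([100, 200, 300])
        calls = np.full((2, 2, 3), 1, dtype=np.int8)  # all EUR
        props = ak.global_proportions(_callset(markers, calls))
        assert np.allclose(props.proportions, [[0, 1, 0], [0, 1, 0]])

    def test_half_interval_weighting_hand_example(self):
        # 3 equally spaced markers -> per-haplotype weights 1/4, 1/2, 1/4;
        # haplotypes (NAT,NAT,EUR) + (EUR,EUR,EUR) -> NAT share 3/8
        markers = make_markers([100, 200, 300])
        calls = np.array([[[0, 0, 1], [1, 1, 1]]], dtype=np.int8)
        props = ak.global_proportions(_callset(markers, calls))
        assert props.proportions[0, 0] == pytest.approx(3 / 8)
        assert props.proportions[0, 1] == pytest.approx(5 / 8)

    def test_rows_sum_to_one(self, small_cohort):
        props = ak.global_proportions(small_cohort["truth"])
        assert np.allclose(props.proportions.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_callset_rejected(self):
        markers = make_markers([])
        calls = np.zeros((1, 2, 0), dtype=np.int8)
        with pytest.raises(InvalidParameterError):
            ak.global_proportions(_callset(markers, calls))


class TestRegionWeights:
    def test_published_worked_examples(self, region_table):
        w = ak.region_weights(region_table).set_index("region")
        assert w.loc["Arica y Parinacota", "weight_2dp"] == pytest.approx(1.83)
        assert w.loc["Metropolitana", "weight_2dp"] == pytest.approx(1.02)

    def test_equal_fractions_give_unit_weight(self):
        tab = ak.RegionTable(pd.DataFrame(
            {"region": ["a", "b"], "n_sample": [5, 5],
             "sample_fraction": [50.0, 50.0], "census_fraction": [50.0, 50.0]}
        ))
        w = ak.region_weights(tab)
        assert np.allclose(w["weight"], 1.0)

    def test_zero_sample_fraction_with_samples_rejected(self):
        tab = ak.RegionTable(pd.DataFrame(
            {"region": ["a", "b"], "n_sample": [5, 5],
             "sample_fraction": [0.0, 100.0], "census_fraction": [50.0, 50.0]}
        ))
        with pytest.raises(InvalidParameterError):
            ak.region_weights(tab)


class TestWeightedProportions:
    def _props(self, rows):
        rows = np.asarray(rows, dtype=float)
        return ak.GlobalProportions(
            proportions=rows, samples=[f"i{j}" for j in range(len(rows))]
        )

    def test_equal_weights_equal_the_mean(self):
        p = self._props([[0.4, 0.5, 0.1], [0.6, 0.3, 0.1]])
        est = ak.weighted_proportions(p, np.ones(2))
        assert est[0] == pytest.approx(0.5)
        assert np.allclose(est, p.proportions.mean(axis=0))

    def test_weighted_hand_example(self):
        p = self._props([[0.2, 0.7, 0.1], [0.8, 0.1, 0.1]])
        est = ak.weighted_proportions(p, np.array([1.0, 3.0]))
        assert est[0] == pytest.approx(0.65)

    def test_invariant_to_weight_rescaling(self):
        rng = np.random.default_rng(0)
        raw = rng.dirichlet((2, 3, 1), size=9)
        p = self._props(raw)
        w = rng.uniform(0.5, 2.0, size=9)
        assert np.allclose(
            ak.weighted_proportions(p, w), ak.weighted_proportions(p, 17.3 * w)
        )

    def test_all_zero_weights_rejected(self):
        p = self._props([[0.5, 0.4, 0.1]])
        with pytest.raises(InvalidParameterError):
            ak.weighted_proportions(p, np.zeros(1))


class TestZones:
    def test_published_zone_counts(self, region_table, zone_map):
        counts = ak.assign_zones(region_table, zone_map).set_index("zone")["n"]
        assert counts.to_dict() == {"N": 16, "C1": 159, "C2": 41, "S1": 73, "S2": 12}

    def test_unknown_region_excluded_from_zones(self, region_table, zone_map):
        out = ak.assign_zones(region_table, zone_map)
        assert out.attrs["n_unzoned"] == 12
        assert out["n"].sum() + out.attrs["n_unzoned"] == region_table.total_samples

    def test_unmapped_sampled_region_raises_with_name(self, region_table):
        partial = ak.ZoneMap(mapping={"Metropolitana": "C1"})
        with pytest.raises(InvalidParameterError, match="Arica y Parinacota"):
            ak.assign_zones(region_table, partial)


class TestZoneComparison:
    def test_identical_constant_zones(self):
        vals = {z: np.full(5, 0.3) for z in ("N", "C1", "C2")}
        cmp = ak.zone_comparison(vals)
        assert np.allclose(cmp.tukey["q"], 0.0)
        assert np.allclose(cmp.tukey["p_adj"], 1.0)

    def test_five_zones_give_ten_pairwise_rows(self):
        rng = np.random.default_rng(1)
        vals = {z: rng.normal(size=6) for z in ("N", "C1", "C2", "S1", "S2")}
        cmp = ak.zone_comparison(vals)
        assert len(cmp.tukey) == 10

    def test_q_statistics_match_independent_tukey(self):
        # balanced 3-group configuration cross-checked against scipy's
        # independent Tukey HSD implementation
        g = {
            "a": np.array([24.5, 23.5, 26.4, 27.1, 29.9]),
            "b": np.array([28.4, 34.2, 29.5, 32.2, 30.1]),
            "c": np.array([26.1, 28.3, 24.3, 26.2, 27.8]),
        }
        cmp = ak.zone_comparison(g)
        ref = stats.tukey_hsd(g["a"], g["b"], g["c"])
        pairs = {("a", "b"): (0, 1), ("a", "c"): (0, 2), ("b", "c"): (1, 2)}
        for _, row in cmp.tukey.iterrows():
            i, j = pairs[(row["zone_a"], row["zone_b"])]
            assert row["p_adj"] == pytest.approx(ref.pvalue[i, j], abs=1e-6)
            assert abs(row["mean_diff"]) == pytest.approx(
                abs(ref.statistic[i, j]), abs=1e-9
            )

    def test_box_stats_quartiles(self):
        vals = {"N": np.arange(1, 12, dtype=float), "S": np.arange(1, 12, dtype=float)}
        box = ak.zone_comparison(vals).box_stats.set_index("zone")
        assert box.loc["N", "median"] == 6.0
        assert box.loc["N", "q1"] == 3.5
        assert box.loc["N", "q3"] == 8.5

    def test_small_zone_excluded_but_reported(self):
        vals = {"N": np.array([1.0]), "C1": np.array([0.1, 0.2, 0.3]),
                "C2": np.array([0.2, 0.4, 0.3])}
        cmp = ak.zone_comparison(vals)
        assert cmp.excluded_zones == ["N"]
        assert set(cmp.tukey["zone_a"]) | set(cmp.tukey["zone_b"]) == {"C1", "C2"}


class TestGradientRecovery:
    def test_configured_north_south_afr_gradient_recovered(self):
        # per-zone AFR means decreasing N->S; estimated zone means (from
        # truth tracts at n=50 per region) must recover the configured order
        gm = ak.gen_genetic_map((50_000_000,) * 2, (1.0,) * 2, (150,) * 2, seed=31)
        panel = ak.gen_frequency_panel(markers=gm.markers, F_per_ancestry=(0.25,) * 3, seed=31)
        regions = ["R1", "R2", "R3"]
        afr = {"R1": 0.10, "R2": 0.05, "R3": 0.02}
        tab = ak.RegionTable(pd.DataFrame(
            {"region": regions, "n_sample": [50] * 3,
             "sample_fraction": [100 / 3] * 3, "census_fraction": [100 / 3] * 3}
        ))
        cfg = ak.SimCohortConfig(
            n_individuals=150, seed=31, region_table=tab,
            region_proportions={
                r: (0.5 - a / 2, 0.5 - a / 2, a) for r, a in afr.items()
            },
        )
        _, _, tracts, labels = ak.simulate_cohort(cfg, panel, gm)
        truth = ak.truth_calls(tracts, panel.markers)
        props = ak.global_proportions(truth)
        means = {
            r: props.proportions[[i for i, l in enumerate(labels) if l == r], 2].mean()
            for r in regions
        }
        assert means["R1"] > means["R2"] > means["R3"]
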