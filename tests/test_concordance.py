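"""Two-method agreement statistics and the Pearson correlation test."""

import numpy as np
import pytest

import admixkit as ak
from admixkit.datatypes import InvalidParameterError
from conftest import make_markers


def _cs(calls, method="A"):
    calls = np.asarray(calls, dtype=np.int8)
    markers = make_markers((np.arange(calls.shape[2]) + 1) * 100)
    return ak.AncestryCallSet(
        markers=markers, calls=calls,
        samples=[f"i{j}" for j in range(calls.shape[0])], method=method,
    )


class TestLocalConcordance:
    def test_identical_callsets_are_fully_concordant(self):
        a = _cs([[[0, 1, 2], [2, 1, 0]]])
        rep = ak.local_concordance(a, _cs(a.calls, "B"))
        assert rep.coincidence_pct == 100.0
        off = rep.cross_tab.to_numpy() - np.diag(np.diag(rep.cross_tab))
        assert (off == 0).all()

    def test_single_disagreement_in_four(self):
        a = _cs([[[0, 1], [2, 0]]])
        b = _cs([[[0, 1], [2, 1]]], "B")
        rep = ak.local_concordance(a, b)
        assert rep.coincidence_pct == pytest.approx(75.0)
        assert rep.n_total == 4

    def test_symmetric_and_crosstab_transposes(self):
        rng = np.random.default_rng(3)
        a = _cs(rng.integers(0, 3, (4, 2, 20)))
        b = _cs(rng.integers(0, 3, (4, 2, 20)), "B")
        ab = ak.local_concordance(a, b)
        ba = ak.local_concordance(b, a)
        assert ab.coincidence_pct == pytest.approx(ba.coincidence_pct)
        assert np.array_equal(ab.cross_tab.to_numpy(), ba.cross_tab.to_numpy().T)

    def test_crosstab_marginals_equal_label_frequencies(self):
        rng = np.random.default_rng(4)
        a = _cs(rng.integers(0, 3, (5, 2, 30)))
        b = _cs(rng.integers(0, 3, (5, 2, 30)), "B")
        rep = ak.local_concordance(a, b, match_phase=False)
        tab = rep.cross_tab.to_numpy()
        for k in range(3):
            assert tab[k].sum() == (a.calls == k).sum()
            assert tab[:, k].sum() == (b.calls == k).sum()

    def test_phase_matching_is_order_invariant(self):
        # swapping b's haplotypes must not change the coincidence
        rng = np.random.default_rng(5)
        a = _cs(rng.integers(0, 3, (3, 2, 40)))
        b_calls = rng.integers(0, 3, (3, 2, 40))
        rep1 = ak.local_concordance(a, _cs(b_calls, "B"))
        rep2 = ak.local_concordance(a, _cs(b_calls[:, ::-1, :], "B"))
        assert rep1.coincidence_pct == pytest.approx(rep2.coincidence_pct)

    def test_dimension_mismatch_rejected(self):
        a = _cs([[[0, 1], [1, 0]]])
        b = _cs([[[0, 1, 2], [1, 0, 2]]], "B")
        with pytest.raises(ak.InconsistentInputError):
            ak.local_concordance(a, b)


class TestGlobalBands:
    def _props(self, rows):
        rows = np.asarray(rows, float)
        return ak.GlobalProportions(
            proportions=rows, samples=[f"i{j}" for j in range(len(rows))]
        )

    def test_identical_sets_fall_in_tightest_band(self):
        p = self._props([[0.4, 0.5, 0.1], [0.2, 0.7, 0.1]])
        bands = ak.global_concordance_bands(p, p)
        assert (bands["within_0.1pct"] == 2).all()

    def test_hand_counted_bands(self):
        a = self._props([[0.400, 0.500, 0.100], [0.400, 0.500, 0.100]])
        b = self._props([[0.404, 0.496, 0.100], [0.420, 0.480, 0.100]])
        bands = ak.global_concordance_bands(a, b).set_index("ancestry")
        # |dNAT| = 0.4% and 2.0% -> within 0.5%: 1, within 3%: 2
        assert bands.loc["NAT", "within_0.5pct"] == 1
        assert bands.loc["NAT", "within_3.0pct"] == 2

    def test_counts_monotone_over_nested_thresholds(self):
        rng = np.random.default_rng(6)
        a = self._props(rng.dirichlet((5, 5, 1), 20))
        b = self._props(rng.dirichlet((5, 5, 1), 20))
        bands = ak.global_concordance_bands(a, b)
        cols = [c for c in bands.columns if c.startswith("within_")]
        vals = bands[cols].to_numpy()
        assert (np.diff(vals, axis=1) >= 0).all()

    def test_correlation_column_is_pearson_r(self):
        rng = np.random.default_rng(7)
        a = self._props(rng.dirichlet((5, 5, 1), 30))
        b = self._props(a.proportions + 0.0)
        bands = ak.global_concordance_bands(a, b)
        assert np.allclose(bands["correlation"], 1.0)


class TestCorrelationTest:
    def test_perfect_linear_relation(self):
        x = np.arange(10, dtype=float)
        res = ak.correlation_test(x, 2 * x)
        assert res["r"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(0.0, abs=1e-12)

    def test_df_is_n_minus_two(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 57))
        assert ak.correlation_test(x, y)["df"] == 55

    def test_five_point_hand_oracle(self):
        # r and t computed by hand from the Pearson formula:
        # x=(1..5), y=(2,1,4,3,5): sxy=8, sxx=10, syy=10 -> r=0.8,
        # t = 0.8*sqrt(3/0.36) = 2.3094
        x = np.array([1, 2, 3, 4, 5], float)
        y = np.array([2, 1, 4, 3, 5], float)
        res = ak.correlation_test(x, y)
        assert res["r"] == pytest.approx(0.8)
        assert res["t"] == pytest.approx(0.8 * np.sqrt(3 / 0.36))
        assert res["df"] == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidParameterError):
            ak.correlation_test(np.ones(5), np.arange(5.0))

    def test_sign_of_r_preserved_in_t(self):
        x = np.arange(20, dtype=float)
        res = ak.correlation_test(x, -x + np.sin(x))
        assert res["r"] < 0 and res["t"] < 0


class TestRecombinationRates:
    def test_uniform_map_gives_constant_rate(self):
        gm = ak.gen_genetic_map((10**6,), (1.0,), (50,), "uniform", seed=2)
        rates = ak.marker_recombination_rates(gm)
        assert np.allclose(rates, rates[0])

    def test_gamma_map_gives_variable_rates(self):
        gm = ak.gen_genetic_map((10**6,), (1.0,), (50,), "gamma", seed=2)
        rates = ak.marker_recombination_rates(gm)
        assert rates.std() > 0


class TestDirectionalSigns:
    def test_inter_decoder_inconsistency_correlates_with_rate_and_differentiation(self):
        # viterbi vs max-posterior disagreement: positively correlated with
        # local recombination rate, negatively with (f_NAT - f_EUR)^2
        gm = ak.gen_genetic_map((100_000_000,) * 2, (1.5,) * 2, (800,) * 2,
                                "gamma", seed=17, rate_shape=1.0)
        panel = ak.gen_frequency_panel(markers=gm.markers,
                                       F_per_ancestry=(0.2,) * 3, seed=17)
        cfg = ak.SimCohortConfig(n_individuals=100, seed=17)
        _, haps, _, _ = ak.simulate_cohort(cfg, panel, gm)
        cv = ak.call_haplotypes(haps, panel, gm, ak.HmmConfig(decode_mode="viterbi"))
        cm = ak.call_haplotypes(haps, panel, gm, ak.HmmConfig(decode_mode="max-posterior"))
        rep = ak.local_concordance(cv, cm)
        inc = rep.per_marker_inconsistency.astype(float)
        rates = ak.marker_recombination_rates(gm)
        diff = ak.marker_differentiation(panel, "NAT", "EUR")
        sq = diff.sort_values("marker_index")["sq_diff"].to_numpy()
        r_rate = ak.correlation_test(inc, rates)
        r_diff = ak.correlation_test(inc, sq)
        assert r_rate["r"] > 0 and r_rate["p"] < 0.05
        assert r_diff["r"] < 0 and r_diff["p"] < 0.05
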