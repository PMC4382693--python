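"""Synthetic-data generator: frequency panels, maps, HI tracts, cohorts."""

import numpy as np
import pandas as pd
import pytest

import admixkit as ak
from admixkit.datatypes import InvalidParameterError


class TestFrequencyPanel:
    def test_zero_F_degenerates_to_base_frequency(self):
        base = lambda rng, n: np.full(n, 0.37)
        panel = ak.gen_frequency_panel(50, base, F_per_ancestry=(0.0, 0.0), seed=3)
        assert np.allclose(panel.freqs, 0.37)

    def test_deterministic_given_seed(self):
        a = ak.gen_frequency_panel(200, F_per_ancestry=(0.2, 0.1), seed=5)
        b = ak.gen_frequency_panel(200, F_per_ancestry=(0.2, 0.1), seed=5)
        assert np.array_equal(a.freqs, b.freqs)
        assert a.markers.equals(b.markers)

    def test_realized_fst_matches_generating_F(self):
        # Hudson FST between the two frequency tracks themselves: the
        # ratio-of-averages of (f1-f2)^2 over f1(1-f2)+f2(1-f1) estimates F
        panel = ak.gen_frequency_panel(10_000, F_per_ancestry=(0.2, 0.2), seed=7)
        f1, f2 = panel.freqs
        fst = ((f1 - f2) ** 2).sum() / (f1 * (1 - f2) + f2 * (1 - f1)).sum()
        assert fst == pytest.approx(0.2, abs=0.02)

    @pytest.mark.parametrize("F", [1.0, 1.5, -0.1])
    def test_invalid_F_rejected(self, F):
        with pytest.raises(InvalidParameterError):
            ak.gen_frequency_panel(10, F_per_ancestry=(F,), seed=0)

    def test_base_frequency_outside_open_interval_rejected(self):
        bad = lambda rng, n: np.zeros(n)
        with pytest.raises(InvalidParameterError):
            ak.gen_frequency_panel(10, bad, F_per_ancestry=(0.1,), seed=0)


class TestGeneticMap:
    def test_uniform_profile_cm_proportional_to_bp(self):
        gm = ak.gen_genetic_map((1_000_000,), (1.0,), (100,), "uniform", seed=2)
        bp = gm.markers["bp"].to_numpy()
        assert np.allclose(gm.cm, 100.0 * bp / 1_000_000)

    def test_total_length_is_additive(self):
        gm = ak.gen_genetic_map((10**6, 10**6), (1.0, 2.0), (50, 50), seed=2)
        assert gm.total_morgans == pytest.approx(3.0)

    @pytest.mark.parametrize("profile", ["uniform", "gamma"])
    def test_adjacent_distances_nonnegative_and_bounded_by_G(self, profile):
        gm = ak.gen_genetic_map((10**6, 10**6), (1.0, 0.5), (80, 40), profile, seed=9)
        d = gm.adjacent_morgans()
        assert (d >= 0).all()
        # marker-to-marker distances telescope to at most the chromosome spans
        assert d.sum() <= gm.total_morgans + 1e-12
        assert gm.total_morgans == pytest.approx(1.5)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            ak.gen_genetic_map((0,), (1.0,), (10,), seed=0)


class TestTracts:
    def test_no_admixture_age_means_single_tract_per_haplotype(self, small_map):
        cfg = ak.SimCohortConfig(n_individuals=5, t_generations=0.0, seed=1)
        tracts = ak.simulate_tracts(cfg, small_map)
        per_hap = tracts.tracts.groupby(["sample", "haplotype", "chrom"]).size()
        assert (per_hap == 1).all()

    def test_single_ancestry_proportions(self, small_map):
        cfg = ak.SimCohortConfig(
            n_individuals=4, proportions=(1.0, 0.0, 0.0), seed=1
        )
        tracts = ak.simulate_tracts(cfg, small_map)
        assert (tracts.tracts["ancestry"] == 0).all()

    def test_visible_switch_count_matches_poisson_thinning(self):
        # single 1-Morgan chromosome, 500 diploids = 1000 haplotypes
        gm = ak.gen_genetic_map((10**8,), (1.0,), (100,), seed=4)
        p = (0.45, 0.52, 0.03)
        cfg = ak.SimCohortConfig(
            n_individuals=500, t_generations=10.0, proportions=p, seed=4
        )
        tracts = ak.simulate_tracts(cfg, gm)
        k = ak.count_switches(tracts)["K_switches"].to_numpy()
        het = 1 - sum(x * x for x in p)
        expect = 2 * 10.0 * 1.0 * het  # per diploid
        se = k.std(ddof=1) / np.sqrt(len(k))
        assert abs(k.mean() - expect) < 3 * se + 1e-9

    def test_tract_length_mean_matches_hi_limit(self):
        # long chromosome: ancestry-k tract length ~ Exp(T(1-p_k)) Morgans
        gm = ak.gen_genetic_map((10**9,), (10.0,), (100,), "uniform", seed=5)
        p = (0.3, 0.7)
        cfg = ak.SimCohortConfig(
            n_individuals=200, t_generations=10.0, proportions=p,
            ancestry_names=("NAT", "EUR"), seed=5,
        )
        tracts = ak.simulate_tracts(cfg, gm)
        df = tracts.tracts
        # interior tracts only (chromosome ends censor the length)
        interior = df[(df["start"] > 0) & (df["end"] < 10**9)]
        morgans_per_bp = 10.0 / 10**9
        for k, pk in enumerate(p):
            lens = (
                (interior.loc[interior["ancestry"] == k, "end"]
                 - interior.loc[interior["ancestry"] == k, "start"])
                * morgans_per_bp
            ).to_numpy()
            expect = 1.0 / (10.0 * (1 - pk))
            se = lens.std(ddof=1) / np.sqrt(len(lens))
            assert abs(lens.mean() - expect) < 4 * se

    def test_bit_identical_across_runs(self, small_map):
        cfg = ak.SimCohortConfig(n_individuals=6, seed=42)
        a = ak.simulate_tracts(cfg, small_map)
        b = ak.simulate_tracts(cfg, small_map)
        pd.testing.assert_frame_equal(a.tracts, b.tracts)


class TestCohort:
    def test_truth_tracts_tile_every_chromosome(self, small_cohort):
        small_cohort["tracts"].validate_tiling()

    def test_deterministic_emission_at_fixed_frequency(self, small_map):
        # f = 1 for every ancestry and no noise forces allele 1 everywhere
        panel = ak.AlleleFrequencyPanel(
            markers=small_map.markers,
            freqs=np.ones((3, len(small_map.markers))),
        )
        cfg = ak.SimCohortConfig(n_individuals=3, seed=2)
        _, haps, _, _ = ak.simulate_cohort(cfg, panel, small_map)
        assert (haps == 1).all()

    def test_conditional_allele_frequency_recovers_panel(self, small_map, small_panel):
        cfg = ak.SimCohortConfig(n_individuals=250, seed=8)
        _, haps, tracts, _ = ak.simulate_cohort(cfg, small_panel, small_map)
        truth = ak.truth_calls(tracts, small_panel.markers)
        j = 37
        for k in range(3):
            mask = truth.calls[:, :, j] == k
            n = mask.sum()
            if n < 50:
                continue
            emp = haps[:, :, j][mask].mean()
            f = small_panel.freqs[k, j]
            # binomial error band
            assert abs(emp - f) < 4 * np.sqrt(f * (1 - f) / n) + 1e-9

    def test_marker_mismatch_rejected(self, small_map, small_panel):
        other = ak.gen_genetic_map((10**6,), (1.0,), (30,), seed=1)
        cfg = ak.SimCohortConfig(n_individuals=2, seed=0)
        with pytest.raises(ak.InconsistentInputError):
            ak.simulate_cohort(cfg, small_panel, other)

    def test_missing_rate_injects_missing_calls(self, small_map, small_panel):
        cfg = ak.SimCohortConfig(n_individuals=10, missing_rate=0.2, seed=3)
        genotypes, _, _, _ = ak.simulate_cohort(cfg, small_panel, small_map)
        frac = (genotypes.calls == ak.MISSING).mean()
        assert 0.15 < frac < 0.25

    def test_region_labels_follow_sampling_scheme(self, small_map, small_panel, region_table):
        cfg = ak.SimCohortConfig(
            n_individuals=region_table.total_samples, seed=3, region_table=region_table
        )
        _, _, _, labels = ak.simulate_cohort(cfg, small_panel, small_map)
        counts = pd.Series(labels).value_counts()
        assert counts["Metropolitana"] == 124
        assert counts["Unknown"] == 12
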