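import numpy as np
import pandas as pd
import pytest

import admixkit as ak


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes, 1.5 Morgans each, hotspot-like rate variation."""
    return ak.gen_genetic_map(
        chrom_lengths_bp=(100_000_000, 100_000_000),
        morgans_per_chrom=(1.5, 1.5),
        markers_per_chrom=(400, 400),
        rate_profile="gamma",
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_map):
    return ak.gen_frequency_panel(
        markers=small_map.markers, F_per_ancestry=(0.3, 0.3, 0.3), seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_panel, small_map):
    """30 individuals, T=10, noiseless emissions, with ground truth."""
    cfg = ak.SimCohortConfig(n_individuals=30, t_generations=10.0, seed=11)
    genotypes, haps, tracts, region_labels = ak.simulate_cohort(
        cfg, small_panel, small_map
    )
    return dict(
        config=cfg,
        genotypes=genotypes,
        haplotypes=haps,
        tracts=tracts,
        region_labels=region_labels,
        truth=ak.truth_calls(tracts, small_panel.markers),
    )


@pytest.fixture(scope="session")
def region_table():
    return ak.io.bundled_region_table()


@pytest.fixture(scope="session")
def zone_map():
    return ak.io.bundled_zone_map()


def make_markers(bps, chrom="1"):
    return pd.DataFrame({"chrom": chrom, "bp": np.asarray(bps, int), "ref": "A", "alt": "G"})
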