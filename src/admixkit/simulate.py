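"""Synthetic admixed-cohort generator.

Emulates the study design of a three-way admixed population (NAT/EUR/AFR
by default) under a hybrid-isolation (HI) model: a single admixture pulse
``T`` generations ago, after which recombination alone breaks ancestry into
tracts. On each haplotype and chromosome of map length ``g`` Morgans,
ancestry junctions form a Poisson process of rate ``T`` per Morgan and the
segment labels between junctions are drawn i.i.d. from the ancestry
proportions ``p``; adjacent same-label segments merge, so a junction is a
visible switch with probability 1 - sum_k p_k^2. This is the standard Markov
approximation to the pedigree recombination process, and the same convention
(rate T, not T-1) is used by the time-since-admixture estimator so the pair
is self-consistent.

Ancestral allele frequencies follow the Balding-Nichols model: given an
ancestral frequency p_j, population k's frequency is
Beta(p_j (1-F_k)/F_k, (1-p_j)(1-F_k)/F_k), so F_k controls differentiation
(realized pairwise Hudson FST between two tracks with the same F is ~F).

Haplotype emissions follow the standard admixture model: allele 1 at marker
j on a haplotype whose local ancestry is k with probability f_kj, flipped
with probability ``genotype_error``; missing diploid calls are injected at a
configurable rate (default 0) to exercise QC.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_ANCESTRIES,
    MISSING,
    AlleleFrequencyPanel,
    AncestryCallSet,
    GeneticMap,
    GenotypeMatrix,
    InconsistentInputError,
    InvalidParameterError,
    SimCohortConfig,
    TractSet,
    require_same_markers,
)
from .seeds import substream

__all__ = [
    "default_markers",
    "gen_frequency_panel",
    "gen_genetic_map",
    "assign_regions",
    "simulate_tracts",
    "simulate_cohort",
    "truth_calls",
    "gen_reference_haplotypes",
    "empirical_frequencies",
]


def default_markers(n_markers: int, chrom: str = "1", spacing_bp: int = 1000) -> pd.DataFrame:
    """Evenly spaced single-chromosome marker scaffold (A/G SNPs)."""
    bp = np.arange(1, n_markers + 1) * spacing_bp
    return pd.DataFrame(
        {"chrom": chrom, "bp": bp, "ref": "A", "alt": "G"}
    )


def gen_frequency_panel(
    n_markers: int | None = None,
    base_freq_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    F_per_ancestry: tuple[float, ...] = (0.15, 0.15, 0.15),
    seed: int = 0,
    markers: pd.DataFrame | None = None,
    ancestry_names: tuple[str, ...] | None = None,
) -> AlleleFrequencyPanel:
    """Balding-Nichols ancestral frequency tracks over a shared marker list.

    Parameters
    ----------
    n_markers
        Number of markers; ignored when an explicit ``markers`` table (e.g.
        from :func:`gen_genetic_map`) is supplied.
    base_freq_sampler
        Draws the ancestral frequencies p_j; default Uniform(0.05, 0.95).
    F_per_ancestry
        One differentiation parameter F_k in [0, 1) per ancestry; F_k = 0
        degenerates the Beta at its mean, i.e. f_kj = p_j exactly.
    """
    if markers is None:
        if n_markers is None or n_markers < 1:
            raise InvalidParameterError("n_markers must be >= 1")
        markers = default_markers(n_markers)
    n = len(markers)
    if ancestry_names is None:
        ancestry_names = DEFAULT_ANCESTRIES[: len(F_per_ancestry)]
    if len(ancestry_names) != len(F_per_ancestry):
        raise InvalidParameterError("one F value is required per ancestry")
    rng = substream(seed, "frequency_panel")
    if base_freq_sampler is None:
        base = rng.uniform(0.05, 0.95, size=n)
    else:
        base = np.asarray(base_freq_sampler(rng, n), dtype=float)
    if np.any(base <= 0) or np.any(base >= 1):
        raise InvalidParameterError("base frequencies must lie strictly in (0, 1)")
    freqs = np.empty((len(F_per_ancestry), n))
    for k, F in enumerate(F_per_ancestry):
        if not (0 <= F < 1):
            raise InvalidParameterError(f"F must lie in [0, 1), got {F}")
        if F == 0:
            freqs[k] = base
        else:
            c = (1.0 - F) / F
            freqs[k] = rng.beta(base * c, (1.0 - base) * c)
    return AlleleFrequencyPanel(
        markers=markers.reset_index(drop=True),
        freqs=freqs,
        ancestry_names=tuple(ancestry_names),
    )


def gen_genetic_map(
    chrom_lengths_bp: tuple[int, ...],
    morgans_per_chrom: tuple[float, ...],
    markers_per_chrom: tuple[int, ...],
    rate_profile: str = "uniform",
    seed: int = 0,
    rate_shape: float = 0.3,
) -> GeneticMap:
    """Synthetic genetic map: marker positions plus cumulative cM per chromosome.

    ``rate_profile`` is either ``"uniform"`` (cM strictly proportional to bp)
    or ``"gamma"`` (per-interval recombination rates drawn from a Gamma with
    shape ``rate_shape``, emulating hotspot-like rate variation; smaller shape
    means burstier rates). Total map length G is exactly
    ``sum(morgans_per_chrom)`` either way.
    """
    if not (len(chrom_lengths_bp) == len(morgans_per_chrom) == len(markers_per_chrom)):
        raise InvalidParameterError("per-chromosome argument lengths must agree")
    rng = substream(seed, "genetic_map")
    frames = []
    cms = []
    info_rows = []
    for c, (length, morgans, n) in enumerate(
        zip(chrom_lengths_bp, morgans_per_chrom, markers_per_chrom), start=1
    ):
        if length <= 0 or morgans <= 0:
            raise InvalidParameterError("chromosome lengths must be positive")
        if n < 2:
            raise InvalidParameterError("need at least 2 markers per chromosome")
        if n > length:
            raise InvalidParameterError("more markers than bp positions")
        # rejection-sample distinct positions (length can be ~1e9)
        pos = np.unique(rng.integers(1, length, size=n + max(10, n // 10)))
        while len(pos) < n:
            pos = np.unique(np.concatenate([pos, rng.integers(1, length, size=n)]))
        bp = np.sort(rng.choice(pos, size=n, replace=False))
        total_cm = morgans * 100.0
        if rate_profile == "uniform":
            cm = total_cm * bp / length
        elif rate_profile == "gamma":
            # per-interval rate multipliers over [0, bp_1], [bp_1, bp_2], ..., [bp_n, L]
            edges = np.concatenate(([0], bp, [length]))
            widths = np.diff(edges).astype(float)
            rates = rng.gamma(rate_shape, 1.0, size=len(widths))
            seg_cm = widths * rates
            seg_cm *= total_cm / seg_cm.sum()
            cm = np.cumsum(seg_cm)[:-1]
        else:
            raise InvalidParameterError(f"unknown rate_profile {rate_profile!r}")
        chrom = str(c)
        frames.append(pd.DataFrame({"chrom": chrom, "bp": bp, "ref": "A", "alt": "G"}))
        cms.append(cm)
        info_rows.append(
            dict(chrom=chrom, bp_start=0, bp_end=int(length), cm_start=0.0, cm_end=total_cm)
        )
    markers = pd.concat(frames, ignore_index=True)
    return GeneticMap(
        markers=markers,
        cm=np.concatenate(cms),
        chrom_info=pd.DataFrame(info_rows),
    )


def assign_regions(config: SimCohortConfig) -> list[str | None]:
    """Region label per individual, honoring region_table sample counts.

    Labels are shuffled so region does not correlate with individual index;
    deterministic given the config seed. Without a region table all labels
    are None.
    """
    if config.region_table is None:
        return [None] * config.n_individuals
    tab = config.region_table.table
    if config.region_table.total_samples != config.n_individuals:
        raise InvalidParameterError(
            "n_individuals must equal the region table's total sample count"
        )
    labels: list[str] = []
    for _, row in tab.iterrows():
        labels.extend([row["region"]] * int(row["n_sample"]))
    rng = substream(config.seed, "region_assignment")
    order = rng.permutation(len(labels))
    return [labels[i] for i in order]


def _proportions_for(config: SimCohortConfig, region: str | None) -> np.ndarray:
    if region is not None and config.region_proportions:
        p = config.region_proportions.get(region)
        if p is not None:
            return np.asarray(p, dtype=float)
    return np.asarray(config.proportions, dtype=float)


def _interp_cm_to_bp(gmap: GeneticMap, chrom, cm_points: np.ndarray) -> np.ndarray:
    """Map genetic positions (cM) to bp by linear interpolation over the map."""
    info = gmap.chrom_info[gmap.chrom_info["chrom"] == chrom].iloc[0]
    idx = gmap.marker_index_by_chrom()[chrom]
    xs = np.concatenate(([info["cm_start"]], gmap.cm[idx], [info["cm_end"]]))
    ys = np.concatenate(([info["bp_start"]], gmap.markers["bp"].to_numpy()[idx], [info["bp_end"]]))
    keep = np.concatenate(([True], np.diff(xs) > 0))
    return np.interp(cm_points, xs[keep], ys[keep])


def simulate_tracts(
    config: SimCohortConfig,
    gmap: GeneticMap,
    region_labels: list[str | None] | None = None,
) -> TractSet:
    """Hybrid-isolation ancestry tracts for the whole cohort.

    Junctions per haplotype-chromosome: Poisson(T * g) with g the chromosome
    map length in Morgans; i.i.d. segment labels from p (per-region p when
    configured); adjacent same-label segments merged. Deterministic given the
    config seed.
    """
    if region_labels is None:
        region_labels = assign_regions(config)
    rng = substream(config.seed, "tracts")
    k = len(config.ancestry_names)
    rows: dict[str, list] = {c: [] for c in ("sample", "haplotype", "chrom", "start", "end", "ancestry")}
    chrom_params = [
        (row["chrom"], (row["cm_end"] - row["cm_start"]) / 100.0,
         int(row["bp_start"]), int(row["bp_end"]))
        for _, row in gmap.chrom_info.iterrows()
    ]
    for i in range(config.n_individuals):
        sample = f"ind{i:04d}"
        p = _proportions_for(config, region_labels[i])
        for hap in (0, 1):
            for chrom, g, bp_start, bp_end in chrom_params:
                n_junc = rng.poisson(config.t_generations * g)
                labels = rng.choice(k, size=n_junc + 1, p=p)
                if n_junc:
                    cm_cuts = np.sort(rng.uniform(0, g * 100.0, size=n_junc))
                    bp_cuts = np.rint(_interp_cm_to_bp(gmap, chrom, cm_cuts)).astype(int)
                else:
                    bp_cuts = np.empty(0, dtype=int)
                edges = np.concatenate(([bp_start], bp_cuts, [bp_end]))
                # drop zero-length segments (cuts rounded onto each other),
                # then merge runs of equal labels
                s0, e0 = edges[:-1], edges[1:]
                nz = e0 > s0
                s0, e0, l0 = s0[nz], e0[nz], labels[nz]
                if len(l0) == 0:  # all segments rounded away; keep one
                    starts, ends, labs = [bp_start], [bp_end], [int(labels[0])]
                else:
                    new = np.concatenate(([True], l0[1:] != l0[:-1]))
                    starts = s0[new]
                    labs = l0[new]
                    ends = np.concatenate((starts[1:], [e0[-1]]))
                rows["sample"].extend([sample] * len(labs))
                rows["haplotype"].extend([hap] * len(labs))
                rows["chrom"].extend([chrom] * len(labs))
                rows["start"].extend(starts)
                rows["end"].extend(ends)
                rows["ancestry"].extend(labs)
    samples = [f"ind{i:04d}" for i in range(config.n_individuals)]
    return TractSet(
        tracts=pd.DataFrame(rows),
        ancestry_names=config.ancestry_names,
        samples=samples,
    )


def truth_calls(tracts: TractSet, markers: pd.DataFrame) -> AncestryCallSet:
    """Ancestry label of the tract covering each marker, as a call set."""
    n = len(tracts.samples)
    m = len(markers)
    calls = np.zeros((n, 2, m), dtype=np.int8)
    sample_idx = {s: i for i, s in enumerate(tracts.samples)}
    marker_bp_by_chrom = {
        chrom: (sub.index.to_numpy(), sub["bp"].to_numpy())
        for chrom, sub in markers.groupby("chrom", sort=False)
    }
    for (sample, hap, chrom), sub in tracts.tracts.groupby(
        ["sample", "haplotype", "chrom"], sort=False
    ):
        if chrom not in marker_bp_by_chrom:
            continue
        midx, bp = marker_bp_by_chrom[chrom]
        starts = sub["start"].to_numpy()
        labs = sub["ancestry"].to_numpy()
        # bp is 1-based; tract [start, end) 0-based covers bp if start < bp <= end
        pos = np.searchsorted(starts, bp - 1, side="right") - 1
        pos = np.clip(pos, 0, len(labs) - 1)
        calls[sample_idx[sample], hap, midx] = labs[pos]
    return AncestryCallSet(
        markers=markers.reset_index(drop=True),
        calls=calls,
        samples=list(tracts.samples),
        ancestry_names=tracts.ancestry_names,
        method="truth",
    )


def simulate_cohort(
    config: SimCohortConfig,
    panel: AlleleFrequencyPanel,
    gmap: GeneticMap,
):
    """Full synthetic cohort: genotypes, phased haplotypes, truth, regions.

    Returns ``(GenotypeMatrix, haplotypes, TractSet, region_labels)`` where
    ``haplotypes`` is an int8 array (n_individuals, 2, n_markers) of phased
    alleles. Truth tracts are retained so accuracy and parameter-recovery
    tests can compare against them.
    """
    require_same_markers(panel.markers, gmap.markers, "frequency panel and map")
    if panel.ancestry_names != config.ancestry_names:
        raise InconsistentInputError("panel and config ancestry names differ")
    region_labels = assign_regions(config)
    tracts = simulate_tracts(config, gmap, region_labels)
    truth = truth_calls(tracts, panel.markers)
    rng = substream(config.seed, "emissions")
    n, m = config.n_individuals, panel.n_markers
    # P(allele=1) per haplotype-marker given local ancestry
    f = panel.freqs[truth.calls, np.arange(m)]  # (n, 2, m)
    haps = (rng.random((n, 2, m)) < f).astype(np.int8)
    if config.genotype_error > 0:
        flip = rng.random((n, 2, m)) < config.genotype_error
        haps[flip] = 1 - haps[flip]
    calls = haps.sum(axis=1).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        calls[miss] = MISSING
    genotypes = GenotypeMatrix(
        markers=panel.markers, calls=calls, samples=list(truth.samples)
    )
    return genotypes, haps, tracts, region_labels


def gen_reference_haplotypes(
    panel: AlleleFrequencyPanel, n_haplotypes: int | dict[str, int], seed: int = 0
) -> dict[str, np.ndarray]:
    """Reference haplotype panels drawn from the ancestral frequency tracks.

    Returns one (H_k, n_markers) int8 array per ancestry; used by the
    panel-size sensitivity sweep, which subsamples these haplotypes and
    re-estimates emission frequencies from the subsample.
    """
    rng = substream(seed, "reference_haplotypes")
    out = {}
    for k, name in enumerate(panel.ancestry_names):
        h = n_haplotypes[name] if isinstance(n_haplotypes, dict) else n_haplotypes
        out[name] = (rng.random((h, panel.n_markers)) < panel.freqs[k]).astype(np.int8)
    return out


def empirical_frequencies(
    haplotypes: dict[str, np.ndarray],
    markers: pd.DataFrame,
    ancestry_names: tuple[str, ...] | None = None,
) -> AlleleFrequencyPanel:
    """Alternate-allele frequency per ancestry estimated from haplotype panels."""
    if ancestry_names is None:
        ancestry_names = tuple(haplotypes)
    freqs = np.vstack([haplotypes[name].mean(axis=0) for name in ancestry_names])
    return AlleleFrequencyPanel(
        markers=markers.reset_index(drop=True),
        freqs=freqs,
        ancestry_names=tuple(ancestry_names),
    )
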