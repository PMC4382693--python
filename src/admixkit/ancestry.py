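"""Global ancestry proportions, region weighting, zones, zone comparisons.

Per-individual global proportions are the fraction of bases assigned to each
ancestry: each marker is weighted by half the bp distance to each of its
neighbours (half-interval at chromosome ends), summed over both haplotypes.
On evenly spaced markers this degrades gracefully to plain per-marker
averaging.

Population-level estimates correct unequal regional sampling with one weight
per region, w_r = census_fraction_r / sample_fraction_r; every individual
from a region shares its weight, and the national estimate is the weighted
average sum_i w_i p_i / sum_i w_i per ancestry. Individuals of unknown
region receive weight 1 nationally and belong to no demographic zone.

Zone comparisons: one-way ANOVA plus Tukey HSD (studentized-range adjusted
pairwise p-values) on untransformed proportions, and Tukey box-plot summary
statistics per zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AncestryCallSet,
    GlobalProportions,
    InvalidParameterError,
    RegionTable,
    ZoneMap,
)

__all__ = [
    "marker_base_weights",
    "global_proportions",
    "region_weights",
    "individual_weights",
    "weighted_proportions",
    "assign_zones",
    "zone_comparison",
    "ZoneComparison",
]


def marker_base_weights(markers: pd.DataFrame) -> np.ndarray:
    """Half-interval bp weight of every marker (its approximate base coverage)."""
    w = np.zeros(len(markers), dtype=float)
    for _, sub in markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        bp = sub["bp"].to_numpy().astype(float)
        if len(bp) == 1:
            w[idx] = 1.0
            continue
        gaps = np.diff(bp)
        # end markers keep only the half-interval toward their single neighbour
        left = np.concatenate(([0.0], gaps))
        right = np.concatenate((gaps, [0.0]))
        w[idx] = 0.5 * (left + right)
    return w


def global_proportions(calls: AncestryCallSet) -> GlobalProportions:
    """Base-weighted genome-wide ancestry fraction per individual."""
    if calls.n_markers == 0:
        raise InvalidParameterError("empty call set")
    w = marker_base_weights(calls.markers)
    k = len(calls.ancestry_names)
    n = calls.n_individuals
    props = np.zeros((n, k))
    for a in range(k):
        # sum the weight of markers called `a` over both haplotypes
        props[:, a] = ((calls.calls == a) * w[None, None, :]).sum(axis=(1, 2))
    props /= 2 * w.sum()
    return GlobalProportions(
        proportions=props, samples=list(calls.samples), ancestry_names=calls.ancestry_names
    )


def region_weights(region_table: RegionTable) -> pd.DataFrame:
    """Per-region sampling weight w = census fraction / sample fraction.

    Returned at full precision with a 2-decimal display column. Regions with
    no census fraction (e.g. an 'Unknown' row) get weight 1.
    """
    tab = region_table.table
    rows = []
    for _, r in tab.iterrows():
        if pd.isna(r["census_fraction"]):
            w = 1.0
        else:
            if r["sample_fraction"] == 0:
                if r["n_sample"] > 0:
                    raise InvalidParameterError(
                        f"region {r['region']} has samples but zero sample fraction"
                    )
                continue
            w = float(r["census_fraction"]) / float(r["sample_fraction"])
        rows.append({"region": r["region"], "weight": w, "weight_2dp": round(w, 2)})
    return pd.DataFrame(rows)


def individual_weights(
    region_labels: list[str | None], region_table: RegionTable
) -> np.ndarray:
    """Expand region weights to one weight per individual (unknown region -> 1)."""
    wtab = region_weights(region_table).set_index("region")["weight"]
    return np.array(
        [1.0 if r is None or r not in wtab.index else float(wtab[r]) for r in region_labels]
    )


def weighted_proportions(
    props: GlobalProportions, weights: np.ndarray | None = None
) -> np.ndarray:
    """Population-level ancestry proportions as a weighted average of individuals."""
    p = props.proportions
    if weights is None:
        weights = np.ones(len(p))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(p),):
        raise InvalidParameterError("one weight per individual is required")
    if np.any(weights < 0) or weights.sum() == 0:
        raise InvalidParameterError("weights must be non-negative and not all zero")
    return weights @ p / weights.sum()


def assign_zones(
    region_table: RegionTable, zone_map: ZoneMap
) -> pd.DataFrame:
    """Zone membership: per-zone sample counts and member region lists.

    Regions without a zone assignment (e.g. 'Unknown') are excluded from
    every zone but stay in the national sample. A mapped zone for a region
    absent from the table is ignored; an unmapped region *with* samples and a
    census fraction is an error naming the region.
    """
    counts: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    n_unzoned = 0
    for _, r in region_table.table.iterrows():
        zone = zone_map.zone_of(r["region"])
        if zone is None:
            if not pd.isna(r["census_fraction"]) and r["n_sample"] > 0:
                raise InvalidParameterError(
                    f"region {r['region']!r} has samples but no zone assignment"
                )
            n_unzoned += int(r["n_sample"])
            continue
        counts[zone] = counts.get(zone, 0) + int(r["n_sample"])
        members.setdefault(zone, []).append(r["region"])
    rows = [
        {"zone": z, "n": counts[z], "regions": ",".join(members[z])} for z in counts
    ]
    out = pd.DataFrame(rows)
    out.attrs["n_unzoned"] = n_unzoned
    return out


@dataclass
class ZoneComparison:
    anova_F: float
    anova_p: float
    tukey: pd.DataFrame  # zone_a, zone_b, mean_diff, q, p_adj, reject
    box_stats: pd.DataFrame  # zone, n, median, q1, q3, whisker_lo, whisker_hi, n_outliers
    excluded_zones: list[str]


def _box_stats(zone: str, x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_lim) & (x <= hi_lim)]
    return dict(
        zone=zone,
        n=len(x),
        mean=float(x.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        n_outliers=int(((x < lo_lim) | (x > hi_lim)).sum()),
    )


def zone_comparison(zone_values: dict[str, np.ndarray]) -> ZoneComparison:
    """One-way ANOVA + Tukey HSD across zones, plus box-plot summaries.

    ``zone_values`` maps zone label -> the per-individual proportion values
    of one ancestry. Zones with fewer than 2 members are excluded from the
    test (but reported).
    """
    usable = {z: np.asarray(v, float) for z, v in zone_values.items() if len(v) >= 2}
    excluded = [z for z in zone_values if z not in usable]
    if len(usable) < 2:
        raise InvalidParameterError("need at least two zones with >= 2 members")
    zones = list(usable)
    groups = [usable[z] for z in zones]
    F, p = stats.f_oneway(*groups)

    # Tukey HSD: q = |diff| / sqrt(MSE/2 * (1/n_a + 1/n_b)), studentized range
    n_tot = sum(len(g) for g in groups)
    df = n_tot - len(groups)
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    rows = []
    for a in range(len(zones)):
        for b in range(a + 1, len(zones)):
            ga, gb = groups[a], groups[b]
            diff = gb.mean() - ga.mean()
            se = np.sqrt(mse / 2 * (1 / len(ga) + 1 / len(gb)))
            if se == 0:
                q = 0.0
                p_adj = 1.0
            else:
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, len(zones), df))
            rows.append(
                dict(
                    zone_a=zones[a],
                    zone_b=zones[b],
                    mean_diff=float(diff),
                    q=float(q),
                    p_adj=min(1.0, p_adj),
                    reject=bool(p_adj < 0.05),
                )
            )
    box = pd.DataFrame(
        [_box_stats(z, np.asarray(v, float)) for z, v in zone_values.items() if len(v)]
    )
    return ZoneComparison(
        anova_F=float(F),
        anova_p=float(p),
        tukey=pd.DataFrame(rows),
        box_stats=box,
        excluded_zones=excluded,
    )
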