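"""Time since admixture from ancestry-block counts (hybrid-isolation model).

Under a single admixture pulse T generations ago, recombination lays down
junctions at rate T per Morgan along each haplotype, and a junction is a
visible ancestry switch when the flanking tract labels differ — probability
1 - sum_k p_k^2 with i.i.d. labels drawn from the ancestry proportions p.
Summed over a diploid genome of total map length G Morgans:

    E[K] = 2 * T * G * (1 - sum_k p_k^2)

and in the two-way mode (European proportion q vs everything else)
E[K] = 4 * T * G * q * (1 - q). Inverting gives the per-individual moment
estimator T_hat = K / (2 G (1 - sum p^2)). Switches are counted per
haplotype and summed (never across chromosome boundaries); the estimate
should be read as an average admixing time weighted by per-generation
gene flow, since ongoing migration is not modelled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    AncestryCallSet,
    GlobalProportions,
    InvalidParameterError,
    TractSet,
)

__all__ = [
    "count_switches",
    "expected_switches",
    "estimate_admixture_time",
]


def count_switches(calls: AncestryCallSet | TractSet) -> pd.DataFrame:
    """Visible ancestry switches per individual, both haplotypes summed.

    Accepts a per-marker call set (label changes between adjacent markers
    within a chromosome) or a tract set (tract boundaries); the two agree
    after run-merging. Chromosome starts are never counted.
    """
    if isinstance(calls, TractSet):
        per = (
            calls.tracts.groupby(["sample", "haplotype", "chrom"], sort=False)
            .size()
            .sub(1)
            .groupby("sample", sort=False)
            .sum()
        )
        counts = per.reindex(calls.samples, fill_value=0).to_numpy()
        samples = list(calls.samples)
    else:
        samples = list(calls.samples)
        total = np.zeros(len(samples), dtype=int)
        for _, sub in calls.markers.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            lab = calls.calls[:, :, idx]
            total += (lab[:, :, 1:] != lab[:, :, :-1]).sum(axis=(1, 2))
        counts = total
    return pd.DataFrame({"sample": samples, "K_switches": counts})


def expected_switches(
    t: float, proportions, total_morgans: float, mode: str = "three-way"
) -> float:
    """Expected visible switch count per diploid individual.

    ``mode='three-way'`` treats ``proportions`` as the full vector p;
    ``mode='two-way'`` treats it as the scalar European proportion q and uses
    p = (q, 1-q), i.e. E[K] = 4 T G q (1-q).
    """
    if t < 0:
        raise InvalidParameterError("T must be >= 0")
    if mode == "two-way":
        q = float(proportions)
        het = 2 * q * (1 - q)
    elif mode == "three-way":
        p = np.asarray(proportions, dtype=float)
        het = 1.0 - float((p**2).sum())
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    return 2.0 * t * total_morgans * het


def estimate_admixture_time(
    switch_counts: pd.DataFrame,
    props: GlobalProportions,
    total_morgans: float,
    mode: str = "three-way",
    eur_ancestry: str = "EUR",
) -> pd.DataFrame:
    """Per-individual admixture-time estimates T_hat = K / (2 G (1 - sum p^2)).

    Output columns: sample, q_EUR, K_switches, t_hat (NaN, flagged
    ``degenerate``, for single-ancestry individuals where 1 - sum p^2 = 0).
    The frame's ``attrs['mean_t_hat']`` holds the sample average over
    non-degenerate individuals; attrs also record the switch-counting
    convention (per haplotype, summed).
    """
    if total_morgans <= 0:
        raise InvalidParameterError("total map length G must be positive")
    df = switch_counts.merge(props.to_frame(), on="sample", validate="one_to_one")
    p = df[list(props.ancestry_names)].to_numpy()
    e = list(props.ancestry_names).index(eur_ancestry)
    q = p[:, e]
    if mode == "two-way":
        het = 2 * q * (1 - q)
    else:
        het = 1.0 - (p**2).sum(axis=1)
    k = df["K_switches"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_hat = np.where(het > 0, k / (2.0 * total_morgans * het), np.nan)
    out = pd.DataFrame(
        {
            "sample": df["sample"],
            "q_EUR": q,
            "K_switches": df["K_switches"],
            "t_hat": t_hat,
            "degenerate": het <= 0,
        }
    )
    valid = out.loc[~out["degenerate"], "t_hat"]
    out.attrs["mean_t_hat"] = float(valid.mean()) if len(valid) else float("nan")
    out.attrs["mode"] = mode
    out.attrs["switch_convention"] = "per-haplotype, summed over both haplotypes"
    return out
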