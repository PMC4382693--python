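"""Reference-panel-size and SNP-density sensitivity sweeps.

Both sweeps measure how stable per-individual global ancestry proportions
are under resampling: for every axis value (panel size in haplotypes, or
number of SNPs) the resource is randomly subsampled, local ancestry is
re-inferred, and global proportions recorded; over the replicates (default
10) a per-individual, per-ancestry mean and s.d. are computed and summarized
by the median s.d. across individuals. Replicate subsamples are
reproducible from (seed, axis value, replicate index).

A stable size is then chosen either as the argmin of the median s.d.
(``min-median``, smallest size on ties) or at the curve's elbow
(``kink``): the interior size s maximizing the drop ratio
(m(s-1 step) - m(s)) / max(m(s) - m(s+1 step), delta) with a small floor
delta, i.e. the last size at which the curve still falls steeply before
flattening.

The sweeps run the built-in HMM caller by default; any callable with the
same signature (haplotypes, panel, map, config) -> AncestryCallSet can be
plugged in so external LAI tools can be swept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .ancestry import global_proportions
from .datatypes import AlleleFrequencyPanel, GeneticMap, InvalidParameterError
from .lai import HmmConfig, call_haplotypes
from .seeds import substream
from .simulate import empirical_frequencies

__all__ = ["SweepResult", "panel_size_sweep", "snp_density_sweep", "select_stable_size"]


@dataclass
class SweepResult:
    axis_name: str
    axis_values: list[int]
    ancestry_names: tuple[str, ...]
    samples: list[str]
    means: np.ndarray  # (n_axis, n_individuals, K)
    sds: np.ndarray  # (n_axis, n_individuals, K)
    n_replicates: int
    seed: int
    metadata: dict = field(default_factory=dict)

    def median_sd(self) -> pd.DataFrame:
        """Median over individuals of the replicate s.d., per axis value/ancestry."""
        rows = []
        med = np.median(self.sds, axis=1)  # (n_axis, K)
        for i, v in enumerate(self.axis_values):
            for k, name in enumerate(self.ancestry_names):
                rows.append({self.axis_name: v, "ancestry": name, "median_sd": med[i, k]})
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, v in enumerate(self.axis_values):
            for s, sample in enumerate(self.samples):
                for k, name in enumerate(self.ancestry_names):
                    rows.append(
                        {
                            self.axis_name: v,
                            "sample": sample,
                            "ancestry": name,
                            "mean": self.means[i, s, k],
                            "sd": self.sds[i, s, k],
                        }
                    )
        return pd.DataFrame(rows)


def _default_caller(haps, panel, gmap, config, samples):
    return call_haplotypes(haps, panel, gmap, config, samples=samples)


def _replicate_stats(prop_stack: np.ndarray):
    """Mean and population s.d. over the replicate axis."""
    return prop_stack.mean(axis=0), prop_stack.std(axis=0)


def panel_size_sweep(
    ref_haplotypes: dict[str, np.ndarray],
    cohort_haplotypes: np.ndarray,
    panel_markers: pd.DataFrame,
    gmap: GeneticMap,
    sizes: list[int],
    which_panel: str,
    n_replicates: int = 10,
    seed: int = 0,
    hmm_config: HmmConfig | None = None,
    caller: Callable | None = None,
    samples: list[str] | None = None,
) -> SweepResult:
    """Vary one reference panel's haplotype count, others held at full size.

    For each size and replicate the chosen ancestry's panel is subsampled
    without replacement, emission frequencies re-estimated from the
    subsample, LAI re-run on the cohort, and global proportions recorded.
    """
    if which_panel not in ref_haplotypes:
        raise InvalidParameterError(f"unknown panel {which_panel!r}")
    avail = ref_haplotypes[which_panel].shape[0]
    if max(sizes) > avail:
        raise InvalidParameterError(
            f"requested size {max(sizes)} exceeds the {avail} available haplotypes"
        )
    if n_replicates < 2:
        raise InvalidParameterError("need at least 2 replicates for an s.d.")
    caller = caller or _default_caller
    names = tuple(ref_haplotypes)
    n_ind = cohort_haplotypes.shape[0]
    k = len(names)
    means = np.empty((len(sizes), n_ind, k))
    sds = np.empty_like(means)
    for i, size in enumerate(sizes):
        stack = np.empty((n_replicates, n_ind, k))
        for rep in range(n_replicates):
            rng = substream(seed, "panel_size_sweep", which_panel, size, rep)
            sub = dict(ref_haplotypes)
            pick = rng.choice(avail, size=size, replace=False)
            sub[which_panel] = ref_haplotypes[which_panel][pick]
            panel = empirical_frequencies(sub, panel_markers, names)
            calls = caller(cohort_haplotypes, panel, gmap, hmm_config, samples)
            stack[rep] = global_proportions(calls).proportions
        means[i], sds[i] = _replicate_stats(stack)
    out_samples = samples or [f"ind{i:04d}" for i in range(n_ind)]
    return SweepResult(
        axis_name="panel_size",
        axis_values=list(sizes),
        ancestry_names=names,
        samples=out_samples,
        means=means,
        sds=sds,
        n_replicates=n_replicates,
        seed=seed,
        metadata={"which_panel": which_panel},
    )


def snp_density_sweep(
    cohort_haplotypes: np.ndarray,
    panel: AlleleFrequencyPanel,
    gmap: GeneticMap,
    densities: list[int],
    n_replicates: int = 10,
    seed: int = 0,
    hmm_config: HmmConfig | None = None,
    caller: Callable | None = None,
    samples: list[str] | None = None,
) -> SweepResult:
    """Vary the number of randomly selected SNPs; LAI re-run per subset."""
    m = panel.n_markers
    if max(densities) > m:
        raise InvalidParameterError(
            f"requested density {max(densities)} exceeds the {m} available markers"
        )
    if n_replicates < 2:
        raise InvalidParameterError("need at least 2 replicates for an s.d.")
    caller = caller or _default_caller
    n_ind = cohort_haplotypes.shape[0]
    k = panel.n_ancestries
    means = np.empty((len(densities), n_ind, k))
    sds = np.empty_like(means)
    for i, dens in enumerate(densities):
        stack = np.empty((n_replicates, n_ind, k))
        for rep in range(n_replicates):
            rng = substream(seed, "snp_density_sweep", dens, rep)
            pick = np.sort(rng.choice(m, size=dens, replace=False))
            sub_panel = panel.subset_markers(pick)
            sub_map = gmap.subset_markers(pick)
            calls = caller(
                cohort_haplotypes[:, :, pick], sub_panel, sub_map, hmm_config, samples
            )
            stack[rep] = global_proportions(calls).proportions
        means[i], sds[i] = _replicate_stats(stack)
    out_samples = samples or [f"ind{i:04d}" for i in range(n_ind)]
    return SweepResult(
        axis_name="snp_density",
        axis_values=list(densities),
        ancestry_names=panel.ancestry_names,
        samples=out_samples,
        means=means,
        sds=sds,
        n_replicates=n_replicates,
        seed=seed,
    )


def select_stable_size(
    sweep: SweepResult, ancestry: str, rule: str = "min-median", delta: float = 1e-12
) -> int:
    """Smallest axis value at which the chosen ancestry's estimate is stable.

    ``min-median``: argmin of median s.d. (smallest value on ties).
    ``kink``: interior point maximizing (m(prev) - m(s)) / max(m(s) - m(next),
    delta) — the elbow where a steep drop meets a flat tail. The kink rule is
    a documented reconstruction; metadata records which rule chose the value.
    """
    med = sweep.median_sd()
    sub = med[med["ancestry"] == ancestry].sort_values(sweep.axis_name)
    vals = sub[sweep.axis_name].to_numpy()
    m = sub["median_sd"].to_numpy()
    if rule == "min-median":
        return int(vals[np.argmin(m)])  # argmin takes the first (smallest) on ties
    if rule == "kink":
        if len(vals) < 3:
            raise InvalidParameterError("kink rule needs at least 3 axis values")
        ratios = (m[:-2] - m[1:-1]) / np.maximum(m[1:-1] - m[2:], delta)
        return int(vals[1:-1][np.argmax(ratios)])
    raise InvalidParameterError(f"unknown rule {rule!r}")
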