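"""Minimal admixture-HMM local-ancestry caller.

Hidden state: the ancestry of a phased haplotype at each marker. Over the
Morgan distance d between adjacent markers the chain either stays put, with
weight exp(-T_hmm * d), or re-draws its state from the prior proportions
(uniform 1/K by default) — the standard single-pulse admixture transition.
Emissions are Bernoulli with the ancestral alternate-allele frequency,
clamped to [eps, 1-eps] so a mispanel marker can never zero out the
likelihood. Decoding is either Viterbi (most-probable joint path, the usual
choice for tract calling) or per-marker max-posterior; the two modes double
as two distinct "methods" for the concordance analyses. Ties break to the
lowest ancestry index.

The default switch-rate parameter is 8 generations, mirroring the common
fixed-generations setting of production LAI tools.

The caller operates per haplotype (phased mode only; a K^2-state diploid
HMM is deliberately avoided — phasing happens upstream). Internally the
forward-backward and Viterbi recursions are vectorized across haplotypes,
which is what makes the sensitivity sweeps cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    AlleleFrequencyPanel,
    AncestryCallSet,
    GeneticMap,
    InconsistentInputError,
    InvalidParameterError,
    require_same_markers,
)

__all__ = [
    "HmmConfig",
    "ancestry_posteriors",
    "decode_calls",
    "call_haplotypes",
    "calls_to_tracts",
]


@dataclass
class HmmConfig:
    """Tunables of the admixture HMM.

    t_hmm: switch-rate parameter in generations (transition decay per Morgan).
    emission_error: emission clamp in (0, 0.5).
    prior: state prior at chromosome starts and at re-draws; uniform if None.
    """

    t_hmm: float = 8.0
    emission_error: float = 0.01
    decode_mode: str = "viterbi"
    prior: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.t_hmm <= 0:
            raise InvalidParameterError("t_hmm must be positive")
        if not (0 < self.emission_error < 0.5):
            raise InvalidParameterError("emission_error must lie in (0, 0.5)")
        if self.decode_mode not in ("viterbi", "max-posterior"):
            raise InvalidParameterError(f"unknown decode_mode {self.decode_mode!r}")


def _emissions(haps: np.ndarray, panel: AlleleFrequencyPanel, eps: float) -> np.ndarray:
    """P(observed allele | ancestry k) per haplotype/marker: (H, M, K)."""
    f = np.clip(panel.freqs, eps, 1 - eps)  # (K, M)
    a = haps[:, :, None]  # (H, M, 1)
    return np.where(a == 1, f.T[None], 1 - f.T[None])


def _chrom_blocks(gmap: GeneticMap):
    """(marker index array, Morgan distances within chromosome) per chromosome."""
    d = gmap.adjacent_morgans()
    return [(idx, d[idx]) for idx in gmap.marker_index_by_chrom().values()]


def forward_backward(
    haps: np.ndarray,
    panel: AlleleFrequencyPanel,
    gmap: GeneticMap,
    config: HmmConfig | None = None,
):
    """Posterior ancestry probabilities for a batch of haplotypes.

    Parameters
    ----------
    haps
        int array (n_haplotypes, n_markers) of phased alleles in {0, 1}.

    Returns
    -------
    posteriors : (n_haplotypes, n_markers, K), each marker summing to 1
    loglik : (n_haplotypes,) total log-likelihood across chromosomes
    """
    config = config or HmmConfig()
    require_same_markers(panel.markers, gmap.markers, "frequency panel and map")
    haps = np.atleast_2d(np.asarray(haps))
    if haps.shape[1] != panel.n_markers:
        raise InconsistentInputError("haplotypes and panel marker counts differ")
    k = panel.n_ancestries
    pi = (
        np.full(k, 1.0 / k)
        if config.prior is None
        else np.asarray(config.prior, dtype=float)
    )
    emit = _emissions(haps, panel, config.emission_error)  # (H, M, K)
    H = haps.shape[0]
    post = np.empty_like(emit)
    loglik = np.zeros(H)
    for idx, dists in _chrom_blocks(gmap):
        e = emit[:, idx, :]  # (H, m, K)
        m = len(idx)
        stay = np.exp(-config.t_hmm * dists)  # (m,), stay[0] unused
        alpha = np.empty((H, m, k))
        scale = np.empty((H, m))
        a = pi[None] * e[:, 0]
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0] = a / scale[:, 0, None]
        for j in range(1, m):
            s = stay[j]
            # A = s*I + (1-s) * 1 pi^T ; alpha @ A = s*alpha + (1-s)*pi
            a = (s * alpha[:, j - 1] + (1 - s) * pi[None]) * e[:, j]
            scale[:, j] = a.sum(axis=1)
            alpha[:, j] = a / scale[:, j, None]
        beta = np.empty((H, m, k))
        beta[:, -1] = 1.0
        for j in range(m - 2, -1, -1):
            s = stay[j + 1]
            b = beta[:, j + 1] * e[:, j + 1]
            # A @ b = s*b + (1-s) * (pi . b)
            beta[:, j] = (s * b + (1 - s) * (b @ pi)[:, None]) / scale[:, j + 1, None]
        g = alpha * beta
        g /= g.sum(axis=2, keepdims=True)
        post[:, idx, :] = g
        loglik += np.log(scale).sum(axis=1)
    return post, loglik


def ancestry_posteriors(
    haplotype: np.ndarray,
    panel: AlleleFrequencyPanel,
    gmap: GeneticMap,
    config: HmmConfig | None = None,
):
    """Per-marker posterior over ancestries for one phased haplotype.

    Returns ``(posteriors (n_markers, K), loglik)``.
    """
    post, ll = forward_backward(np.asarray(haplotype)[None, :], panel, gmap, config)
    return post[0], float(ll[0])


def viterbi_paths(
    haps: np.ndarray,
    panel: AlleleFrequencyPanel,
    gmap: GeneticMap,
    config: HmmConfig | None = None,
) -> np.ndarray:
    """Most-probable ancestry path per haplotype (ties to the lowest index)."""
    config = config or HmmConfig()
    require_same_markers(panel.markers, gmap.markers, "frequency panel and map")
    haps = np.atleast_2d(np.asarray(haps))
    k = panel.n_ancestries
    pi = (
        np.full(k, 1.0 / k)
        if config.prior is None
        else np.asarray(config.prior, dtype=float)
    )
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
    emit = np.log(_emissions(haps, panel, config.emission_error))
    H = haps.shape[0]
    paths = np.empty((H, haps.shape[1]), dtype=np.int8)
    for idx, dists in _chrom_blocks(gmap):
        e = emit[:, idx, :]
        m = len(idx)
        stay = np.exp(-config.t_hmm * dists)
        delta = logpi[None] + e[:, 0]  # (H, K)
        back = np.empty((H, m, k), dtype=np.int8)
        for j in range(1, m):
            s = stay[j]
            with np.errstate(divide="ignore"):
                log_stay = np.log(s) if s > 0 else -np.inf
                log_move = np.log1p(-s) if s < 1 else -np.inf
            # transition log A[i -> l] = logaddexp over the two routes
            trans = np.logaddexp(
                log_move + logpi[None, :],  # re-draw, independent of i
                np.where(np.eye(k, dtype=bool), log_stay, -np.inf),
            )  # (K, K)
            cand = delta[:, :, None] + trans[None]  # (H, i, l)
            back[:, j] = cand.argmax(axis=1)
            delta = cand.max(axis=1) + e[:, j]
        last = delta.argmax(axis=1)
        paths[:, idx[-1]] = last
        for j in range(m - 1, 0, -1):
            last = back[np.arange(H), j, last]
            paths[:, idx[j - 1]] = last
    return paths


def call_haplotypes(
    haps: np.ndarray,
    panel: AlleleFrequencyPanel,
    gmap: GeneticMap,
    config: HmmConfig | None = None,
    samples: list[str] | None = None,
    method: str | None = None,
) -> AncestryCallSet:
    """Run the HMM on a cohort of phased haplotypes and decode.

    ``haps`` has shape (n_individuals, 2, n_markers); decode mode comes from
    the config. The provenance tag defaults to ``hmm-<decode_mode>``.
    """
    config = config or HmmConfig()
    haps = np.asarray(haps)
    if haps.ndim != 3 or haps.shape[1] != 2:
        raise InconsistentInputError("haplotypes must be (n_individuals, 2, n_markers)")
    n, _, m = haps.shape
    flat = haps.reshape(n * 2, m)
    if config.decode_mode == "viterbi":
        labels = viterbi_paths(flat, panel, gmap, config)
    else:
        post, _ = forward_backward(flat, panel, gmap, config)
        # argmax breaks exact ties to the lowest index
        labels = post.argmax(axis=2).astype(np.int8)
    if samples is None:
        samples = [f"ind{i:04d}" for i in range(n)]
    return AncestryCallSet(
        markers=panel.markers,
        calls=labels.reshape(n, 2, m),
        samples=samples,
        ancestry_names=panel.ancestry_names,
        method=method or f"hmm-{config.decode_mode}",
    )


def decode_calls(
    posteriors: np.ndarray,
    markers: pd.DataFrame,
    samples: list[str] | None = None,
    ancestry_names: tuple[str, ...] | None = None,
    method: str = "max-posterior",
) -> AncestryCallSet:
    """Label each marker from precomputed posteriors (per-marker argmax).

    ``posteriors`` has shape (n_individuals, 2, n_markers, K); exact ties go
    to the lowest ancestry index.
    """
    post = np.asarray(posteriors)
    if post.ndim != 4 or post.shape[1] != 2:
        raise InconsistentInputError("posteriors must be (n, 2, n_markers, K)")
    labels = post.argmax(axis=3).astype(np.int8)
    n = post.shape[0]
    if samples is None:
        samples = [f"ind{i:04d}" for i in range(n)]
    if ancestry_names is None:
        ancestry_names = tuple(f"anc{k}" for k in range(post.shape[3]))
    return AncestryCallSet(
        markers=markers,
        calls=labels,
        samples=samples,
        ancestry_names=ancestry_names,
        method=method,
    )


def calls_to_tracts(calls: AncestryCallSet, gmap: GeneticMap | None = None) -> pd.DataFrame:
    """Merge per-marker calls into BED-style tracts (0-based half-open).

    Tract boundaries between differing adjacent calls are placed at the
    midpoint bp; chromosome ends extend to the map's chromosome span when a
    map is given, else to the terminal markers.
    """
    rows = []
    markers = calls.markers
    span = {}
    if gmap is not None:
        for _, r in gmap.chrom_info.iterrows():
            span[r["chrom"]] = (int(r["bp_start"]), int(r["bp_end"]))
    for chrom, sub in markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        bp = sub["bp"].to_numpy()
        lo, hi = span.get(chrom, (int(bp[0]) - 1, int(bp[-1])))
        mid = ((bp[:-1] + bp[1:]) // 2).astype(int)
        for i, sample in enumerate(calls.samples):
            for hap in (0, 1):
                lab = calls.calls[i, hap, idx]
                change = np.flatnonzero(lab[1:] != lab[:-1])
                starts = np.concatenate(([lo], mid[change]))
                ends = np.concatenate((mid[change], [hi]))
                for s, e, l in zip(starts, ends, lab[np.concatenate(([0], change + 1))]):
                    rows.append((sample, hap, chrom, int(s), int(e), int(l)))
    return pd.DataFrame(
        rows, columns=["sample", "haplotype", "chrom", "start", "end", "ancestry"]
    )
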