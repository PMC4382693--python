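"""Array-style SNP and sample quality control.

Filters applied, in a fixed order so reports are reproducible:
sample missingness -> SNP call rate -> MAF -> HWE -> ambiguous (A/T, C/G)
alleles -> HLA window. Marker-level rules run on the matrix after failing
samples have been dropped. MAF and the HWE exact test use non-missing calls
only. The HLA window defaults to chr6:25-35 Mb (GRCh37 convention) and is
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, InvalidParameterError

__all__ = ["QCThresholds", "QCReport", "hwe_pvalue", "qc_filter"]


@dataclass
class QCThresholds:
    maf_min: float = 0.01
    hwe_p_min: float = 1e-5
    snp_call_rate_min: float = 0.95
    sample_missing_max: float = 0.10
    drop_ambiguous: bool = True
    hla_region: tuple[str, int, int] = ("6", 25_000_000, 35_000_000)

    def __post_init__(self) -> None:
        for name in ("maf_min", "hwe_p_min", "snp_call_rate_min", "sample_missing_max"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    """Removal counts per rule plus the per-marker exclusion list."""

    n_samples_in: int
    n_markers_in: int
    removed_samples: list[str] = field(default_factory=list)
    removals_per_rule: dict[str, int] = field(default_factory=dict)
    excluded_markers: pd.DataFrame | None = None  # columns: chrom, bp, rule
    warnings: list[str] = field(default_factory=list)

    @property
    def n_markers_removed(self) -> int:
        return 0 if self.excluded_markers is None else len(self.excluded_markers)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": "sample_missingness", "n_removed": len(self.removed_samples)}]
        rows += [{"rule": r, "n_removed": n} for r, n in self.removals_per_rule.items()]
        return pd.DataFrame(rows)


def hwe_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic marker.

    Enumerates the full conditional distribution of the heterozygote count
    given the minor-allele count, and sums the probability of every
    configuration no more likely than the observed one (two-sided by
    probability mass). Monomorphic markers return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise InvalidParameterError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise InvalidParameterError("need at least one genotyped sample")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # unnormalized log-probabilities of P(n_Aa = h | n, n_minor):
    # 2^h * n! / (h! * n_hom_minor! * n_hom_major!)
    from scipy.special import gammaln

    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _marker_stats(calls: np.ndarray):
    """Per-marker non-missing count, genotype counts and MAF."""
    ok = calls != MISSING
    n_called = ok.sum(axis=0)
    n_AA = ((calls == 0) & ok).sum(axis=0)
    n_Aa = (calls == 1).sum(axis=0)
    n_aa = (calls == 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_called > 0, (n_Aa + 2 * n_aa) / (2 * n_called), 0.0)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    return n_called, n_AA, n_Aa, n_aa, maf


def qc_filter(
    genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply all QC rules and report what each removed.

    Each marker is attributed to the first rule (in application order) that
    fails it, so per-rule counts sum to the total number removed.
    """
    thr = thresholds or QCThresholds()
    report = QCReport(n_samples_in=genotypes.n_samples, n_markers_in=genotypes.n_markers)

    # 1. sample missingness
    miss = (genotypes.calls == MISSING).mean(axis=1)
    keep_samples = miss <= thr.sample_missing_max
    report.removed_samples = [
        s for s, k in zip(genotypes.samples, keep_samples) if not k
    ]
    if not keep_samples.any():
        report.warnings.append("all samples removed by missingness filter")
        empty = genotypes.subset(sample_idx=np.empty(0, dtype=int))
        report.excluded_markers = pd.DataFrame(columns=["chrom", "bp", "rule"])
        return empty, report
    g = genotypes.subset(sample_idx=np.flatnonzero(keep_samples))

    # marker rules, recomputed on the post-sample-removal matrix
    n_called, n_AA, n_Aa, n_aa, maf = _marker_stats(g.calls)
    n = g.n_samples
    rule = np.full(g.n_markers, "", dtype=object)

    call_rate = n_called / n
    rule[(rule == "") & (call_rate < thr.snp_call_rate_min)] = "call_rate"
    rule[(rule == "") & (maf <= thr.maf_min)] = "maf"

    hwe_candidates = np.flatnonzero(rule == "")
    for j in hwe_candidates:
        if hwe_pvalue(int(n_AA[j]), int(n_Aa[j]), int(n_aa[j])) <= thr.hwe_p_min:
            rule[j] = "hwe"

    if thr.drop_ambiguous:
        pairs = list(zip(g.markers["ref"], g.markers["alt"]))
        amb = np.array([p in AMBIGUOUS_PAIRS for p in pairs])
        rule[(rule == "") & amb] = "ambiguous_alleles"

    chrom, start, end = thr.hla_region
    in_hla = (
        (g.markers["chrom"].astype(str) == str(chrom))
        & (g.markers["bp"] >= start)
        & (g.markers["bp"] <= end)
    ).to_numpy()
    rule[(rule == "") & in_hla] = "hla_region"

    keep = rule == ""
    excl = g.markers.loc[~keep, ["chrom", "bp"]].copy()
    excl["rule"] = rule[~keep]
    report.excluded_markers = excl.reset_index(drop=True)
    for r in ("call_rate", "maf", "hwe", "ambiguous_alleles", "hla_region"):
        report.removals_per_rule[r] = int((rule == r).sum())
    if not keep.any():
        report.warnings.append("all markers removed by QC")
    out = g.subset(marker_idx=np.flatnonzero(keep))
    return out, report
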