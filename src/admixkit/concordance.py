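"""Agreement between two local-ancestry call sets or proportion sets.

Local concordance is the percentage of individual x haplotype x marker
assignments on which two methods coincide, with a K x K cross-tabulation
whose off-diagonal cells expose directional confusions (e.g. NAT-by-A vs
EUR-by-B). Because haplotype phase is not identifiable between two
independent call sets, haplotypes are matched per individual-marker as the
unordered pair that maximizes agreement before tabulating.

Global concordance bands count individuals whose global proportions differ
by less than a ladder of thresholds per ancestry, plus the per-ancestry
Pearson correlation of the two proportion sets.

``correlation_test`` is the Pearson test used to relate per-marker
inter-method inconsistency to local recombination rate and to ancestral
allele-frequency differentiation: t = r sqrt((n-2)/(1-r^2)), df = n-2,
two-sided p. The per-marker recombination rate is the Morgan length of a
marker's half-interval divided by its bp length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AncestryCallSet,
    GeneticMap,
    GlobalProportions,
    InconsistentInputError,
    InvalidParameterError,
)
from .ancestry import marker_base_weights

__all__ = [
    "ConcordanceReport",
    "local_concordance",
    "global_concordance_bands",
    "correlation_test",
    "marker_recombination_rates",
]


@dataclass
class ConcordanceReport:
    coincidence_pct: float
    cross_tab: pd.DataFrame  # K x K, rows = method A label, cols = method B label
    per_marker_inconsistency: np.ndarray  # haplotype-level disagreements per marker
    method_a: str
    method_b: str
    n_total: int


def _match_haplotypes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Reorder b's haplotypes per individual-marker to maximize agreement.

    a, b: (n, 2, m). Returns b with haplotypes swapped wherever the swapped
    pairing agrees at strictly more haplotypes of that individual-marker.
    """
    direct = (a[:, 0] == b[:, 0]).astype(np.int8) + (a[:, 1] == b[:, 1])
    swapped = (a[:, 0] == b[:, 1]).astype(np.int8) + (a[:, 1] == b[:, 0])
    swap = swapped > direct  # (n, m)
    out = b.copy()
    n, _, m = b.shape
    idx_n, idx_m = np.nonzero(swap)
    out[idx_n, 0, idx_m] = b[idx_n, 1, idx_m]
    out[idx_n, 1, idx_m] = b[idx_n, 0, idx_m]
    return out


def local_concordance(
    calls_a: AncestryCallSet, calls_b: AncestryCallSet, match_phase: bool = True
) -> ConcordanceReport:
    """Percentage of coinciding assignments and the K x K confusion table."""
    if calls_a.calls.shape != calls_b.calls.shape:
        raise InconsistentInputError("call sets must cover identical dimensions")
    if list(calls_a.samples) != list(calls_b.samples):
        raise InconsistentInputError("call sets must cover identical individuals")
    k = max(len(calls_a.ancestry_names), len(calls_b.ancestry_names))
    a = calls_a.calls
    b = _match_haplotypes(a, calls_b.calls) if match_phase else calls_b.calls
    pair = (a.astype(np.int64) * k + b).ravel()
    tab = np.bincount(pair, minlength=k * k).reshape(k, k)
    total = tab.sum()
    coincidence = 100.0 * np.trace(tab) / total
    names = calls_a.ancestry_names
    cross = pd.DataFrame(tab, index=list(names), columns=list(names))
    inconsistency = (a != b).sum(axis=(0, 1))
    return ConcordanceReport(
        coincidence_pct=float(coincidence),
        cross_tab=cross,
        per_marker_inconsistency=inconsistency,
        method_a=calls_a.method,
        method_b=calls_b.method,
        n_total=int(total),
    )


DEFAULT_BANDS_PCT = (0.1, 0.5, 1.0, 3.0, 6.0)


def global_concordance_bands(
    props_a: GlobalProportions,
    props_b: GlobalProportions,
    thresholds_pct: tuple[float, ...] = DEFAULT_BANDS_PCT,
) -> pd.DataFrame:
    """Individuals within each |difference| band per ancestry, plus correlation.

    Differences are in percentage points; counts are cumulative over the
    nested thresholds (hence non-decreasing). One row per ancestry; band
    columns ``within_<t>pct`` and a ``correlation`` column (Pearson r of the
    two proportion sets, the global-proportions comparison statistic).
    """
    if list(props_a.samples) != list(props_b.samples):
        raise InconsistentInputError("proportion sets must cover identical individuals")
    diff_pct = 100.0 * np.abs(props_a.proportions - props_b.proportions)
    rows = []
    for k, name in enumerate(props_a.ancestry_names):
        row: dict = {"ancestry": name}
        for t in sorted(thresholds_pct):
            row[f"within_{t}pct"] = int((diff_pct[:, k] < t).sum())
        va, vb = props_a.proportions[:, k], props_b.proportions[:, k]
        if va.std() == 0 or vb.std() == 0:
            row["correlation"] = float("nan")
        else:
            row["correlation"] = float(np.corrcoef(va, vb)[0, 1])
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_test(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson correlation with its t statistic: t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be 1-D and the same length")
    n = len(x)
    if n < 3:
        raise InvalidParameterError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidParameterError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise InvalidParameterError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        t = float(np.sign(r) * np.inf)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return {"r": r, "t": float(t), "df": df, "p": p}


def marker_recombination_rates(gmap: GeneticMap) -> np.ndarray:
    """Per-marker recombination rate: half-interval Morgans / half-interval bp."""
    morgans = np.zeros(len(gmap.markers))
    for idx in gmap.marker_index_by_chrom().values():
        cm = gmap.cm[idx]
        gaps = np.diff(cm) / 100.0
        left = np.concatenate(([0.0], gaps))
        right = np.concatenate((gaps, [0.0]))
        morgans[idx] = 0.5 * (left + right)
    bp_len = marker_base_weights(gmap.markers)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(bp_len > 0, morgans / bp_len, 0.0)
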