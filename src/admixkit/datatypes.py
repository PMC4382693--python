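"""Core in-memory containers shared by every pipeline stage.

Markers are always kept as a :class:`pandas.DataFrame` with columns
``chrom, bp, ref, alt`` sorted by (chrom, bp); every container that carries
per-marker arrays validates against that frame, so stages can only be chained
on identical marker lists.

Coordinate conventions: ``bp`` is 1-based (VCF dialect); tract intervals are
0-based half-open (BED dialect); genetic positions are centiMorgans in files
and Morgans internally wherever a rate multiplies a distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_ANCESTRIES = ("NAT", "EUR", "AFR")

MARKER_COLUMNS = ("chrom", "bp", "ref", "alt")


class InvalidParameterError(ValueError):
    """A parameter outside its documented domain."""


class InconsistentInputError(ValueError):
    """Two inputs that must share a marker/sample list do not."""


def validate_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """Check marker-table invariants and return the table itself.

    Requires columns chrom/bp/ref/alt and strictly increasing bp within each
    chromosome (hence a strict (chrom, bp) order overall).
    """
    missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing:
        raise InconsistentInputError(f"marker table lacks columns {missing}")
    for _, sub in markers.groupby("chrom", sort=False):
        bp = sub["bp"].to_numpy()
        if np.any(np.diff(bp) <= 0):
            raise InconsistentInputError(
                "marker bp positions must be strictly increasing within a chromosome"
            )
    return markers


def markers_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if len(a) != len(b):
        return False
    return bool(
        (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
        and (a["bp"].to_numpy() == b["bp"].to_numpy()).all()
    )


def require_same_markers(a: pd.DataFrame, b: pd.DataFrame, what: str = "inputs") -> None:
    if not markers_equal(a, b):
        raise InconsistentInputError(f"{what} do not share the same marker list")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

MISSING = -1  # sentinel for a missing diploid call


@dataclass
class GenotypeMatrix:
    """Diploid calls, samples x markers, coded 0/1/2 (= alt-allele dosage) or -1."""

    markers: pd.DataFrame
    calls: np.ndarray  # (n_samples, n_markers) int8
    samples: list[str]

    def __post_init__(self) -> None:
        validate_markers(self.markers)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise InconsistentInputError(
                f"genotype matrix shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise InvalidParameterError("genotype calls must be in {0,1,2,-1}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        calls = self.calls
        samples = self.samples
        markers = self.markers
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            calls = calls[sample_idx]
            samples = [self.samples[i] for i in sample_idx]
        if marker_idx is not None:
            marker_idx = np.asarray(marker_idx)
            calls = calls[:, marker_idx]
            markers = markers.iloc[marker_idx].reset_index(drop=True)
        return GenotypeMatrix(markers=markers, calls=calls.copy(), samples=list(samples))


# ---------------------------------------------------------------------------
# ancestral allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class AlleleFrequencyPanel:
    """Per-ancestry alternate-allele frequency per marker (K ancestries)."""

    markers: pd.DataFrame
    freqs: np.ndarray  # (K, n_markers) float64 in [0, 1]
    ancestry_names: tuple[str, ...] = DEFAULT_ANCESTRIES

    def __post_init__(self) -> None:
        validate_markers(self.markers)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.ancestry_names = tuple(self.ancestry_names)
        if self.freqs.ndim != 2 or self.freqs.shape != (
            len(self.ancestry_names),
            len(self.markers),
        ):
            raise InconsistentInputError(
                "freqs must be (K, n_markers) matching ancestry_names and markers"
            )
        if len(self.ancestry_names) < 1:
            raise InvalidParameterError("need at least one ancestry")
        if np.any(self.freqs < 0) or np.any(self.freqs > 1):
            raise InvalidParameterError("allele frequencies must lie in [0, 1]")

    @property
    def n_ancestries(self) -> int:
        return len(self.ancestry_names)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_markers(self, idx) -> "AlleleFrequencyPanel":
        idx = np.asarray(idx)
        return AlleleFrequencyPanel(
            markers=self.markers.iloc[idx].reset_index(drop=True),
            freqs=self.freqs[:, idx].copy(),
            ancestry_names=self.ancestry_names,
        )


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Per-marker genetic positions plus per-chromosome physical/genetic spans.

    ``chrom_info`` rows (chrom, bp_start, bp_end, cm_start, cm_end) define the
    simulation domain of each chromosome; by default they are the marker spans.
    Map lengths g_c and G are in Morgans.
    """

    markers: pd.DataFrame
    cm: np.ndarray  # (n_markers,) cumulative centiMorgans
    chrom_info: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        validate_markers(self.markers)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.cm.shape != (len(self.markers),):
            raise InconsistentInputError("cm must have one entry per marker")
        rows = []
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            cm_sub = self.cm[sub.index.to_numpy()]
            if np.any(np.diff(cm_sub) < 0):
                raise InvalidParameterError(
                    f"cM positions must be non-decreasing within chromosome {chrom}"
                )
            rows.append(
                dict(
                    chrom=chrom,
                    bp_start=int(sub["bp"].iloc[0]),
                    bp_end=int(sub["bp"].iloc[-1]),
                    cm_start=float(cm_sub[0]),
                    cm_end=float(cm_sub[-1]),
                )
            )
        derived = pd.DataFrame(rows)
        if self.chrom_info is None:
            self.chrom_info = derived
        else:
            self.chrom_info = self.chrom_info.reset_index(drop=True)
        if self.total_morgans <= 0:
            raise InvalidParameterError("total map length G must be positive")

    @property
    def chromosomes(self) -> list:
        return list(self.chrom_info["chrom"])

    def chrom_morgans(self, chrom) -> float:
        row = self.chrom_info[self.chrom_info["chrom"] == chrom].iloc[0]
        return (row["cm_end"] - row["cm_start"]) / 100.0

    @property
    def total_morgans(self) -> float:
        """Total map length G = sum of per-chromosome lengths, Morgans."""
        spans = self.chrom_info["cm_end"] - self.chrom_info["cm_start"]
        return float(spans.sum()) / 100.0

    def marker_index_by_chrom(self) -> dict:
        return {
            chrom: sub.index.to_numpy()
            for chrom, sub in self.markers.groupby("chrom", sort=False)
        }

    def adjacent_morgans(self) -> np.ndarray:
        """Morgan distance from each marker to its predecessor (0 at chromosome starts)."""
        d = np.zeros(len(self.markers))
        for idx in self.marker_index_by_chrom().values():
            d[idx[1:]] = np.diff(self.cm[idx]) / 100.0
        return d

    def subset_markers(self, idx) -> "GeneticMap":
        idx = np.asarray(idx)
        return GeneticMap(
            markers=self.markers.iloc[idx].reset_index(drop=True),
            cm=self.cm[idx].copy(),
            chrom_info=self.chrom_info.copy(),
        )


# ---------------------------------------------------------------------------
# ancestry tracts and calls
# ---------------------------------------------------------------------------


@dataclass
class TractSet:
    """Ground-truth or decoded ancestry tracts.

    ``tracts`` columns: sample, haplotype (0/1), chrom, start, end (0-based
    half-open bp), ancestry (int label). Tracts tile each chromosome of each
    haplotype with no gaps or overlaps, and adjacent tracts differ in label.
    """

    tracts: pd.DataFrame
    ancestry_names: tuple[str, ...] = DEFAULT_ANCESTRIES
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ancestry_names = tuple(self.ancestry_names)
        need = {"sample", "haplotype", "chrom", "start", "end", "ancestry"}
        missing = need - set(self.tracts.columns)
        if missing:
            raise InconsistentInputError(f"tract table lacks columns {sorted(missing)}")
        if not self.samples:
            self.samples = list(pd.unique(self.tracts["sample"]))

    def validate_tiling(self) -> None:
        """Raise if any haplotype-chromosome is not an exact tiling."""
        for (_, _, _), sub in self.tracts.groupby(
            ["sample", "haplotype", "chrom"], sort=False
        ):
            start = sub["start"].to_numpy()
            end = sub["end"].to_numpy()
            lab = sub["ancestry"].to_numpy()
            if np.any(end <= start):
                raise InvalidParameterError("empty or inverted tract interval")
            if np.any(start[1:] != end[:-1]):
                raise InvalidParameterError("tracts must tile without gaps/overlaps")
            if np.any(lab[1:] == lab[:-1]):
                raise InvalidParameterError("adjacent tracts must differ in ancestry")


@dataclass
class AncestryCallSet:
    """Per individual x haplotype x marker ancestry labels in {0..K-1}."""

    markers: pd.DataFrame
    calls: np.ndarray  # (n_individuals, 2, n_markers) int8
    samples: list[str]
    ancestry_names: tuple[str, ...] = DEFAULT_ANCESTRIES
    method: str = "unknown"

    def __post_init__(self) -> None:
        validate_markers(self.markers)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.ancestry_names = tuple(self.ancestry_names)
        if self.calls.shape != (len(self.samples), 2, len(self.markers)):
            raise InconsistentInputError(
                f"call array shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x 2 x {len(self.markers)} markers"
            )
        k = len(self.ancestry_names)
        if self.calls.size and (self.calls.min() < 0 or self.calls.max() >= k):
            raise InvalidParameterError(f"ancestry labels must be in 0..{k - 1}")

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


# ---------------------------------------------------------------------------
# cohort / region bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class RegionTable:
    """Per-region sampling scheme: counts plus sample/census percentage fractions.

    ``table`` columns: region, n_sample, sample_fraction (%), census_fraction
    (%; NaN allowed for an 'Unknown' row).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"region", "n_sample", "sample_fraction", "census_fraction"}
        missing = need - set(self.table.columns)
        if missing:
            raise InconsistentInputError(f"region table lacks columns {sorted(missing)}")
        if (self.table["n_sample"] < 0).any():
            raise InvalidParameterError("sample counts must be non-negative")
        tot = self.table["sample_fraction"].sum()
        if not np.isclose(tot, 100.0, atol=1.0):
            raise InvalidParameterError(
                f"sample fractions should sum to ~100%, got {tot:.2f}"
            )

    @property
    def total_samples(self) -> int:
        return int(self.table["n_sample"].sum())

    @property
    def regions(self) -> list[str]:
        return list(self.table["region"])


@dataclass
class ZoneMap:
    """Region name -> demographic zone label (N, C1, C2, S1, S2); Unknown unmapped."""

    mapping: dict[str, str]

    def zone_of(self, region: str) -> str | None:
        return self.mapping.get(region)

    @property
    def zones(self) -> list[str]:
        seen: list[str] = []
        for z in self.mapping.values():
            if z not in seen:
                seen.append(z)
        return seen


@dataclass
class SimCohortConfig:
    """Study conditions for the synthetic admixed cohort.

    ``proportions`` is the global ancestry vector p (sums to 1); an optional
    ``region_proportions`` dict overrides p per region to synthesize, e.g., a
    north-to-south minor-ancestry gradient. ``t_generations`` is the age of
    the single admixture pulse (hybrid isolation).
    """

    n_individuals: int = 100
    t_generations: float = 10.0
    proportions: tuple[float, ...] = (0.45, 0.52, 0.03)
    ancestry_names: tuple[str, ...] = DEFAULT_ANCESTRIES
    region_table: RegionTable | None = None
    region_proportions: dict[str, tuple[float, ...]] | None = None
    genotype_error: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.proportions = tuple(float(p) for p in self.proportions)
        self.ancestry_names = tuple(self.ancestry_names)
        if len(self.proportions) != len(self.ancestry_names):
            raise InvalidParameterError("proportions must have one entry per ancestry")
        if abs(sum(self.proportions) - 1.0) > 1e-9 or min(self.proportions) < 0:
            raise InvalidParameterError("proportions must be non-negative and sum to 1")
        if self.t_generations < 0:
            raise InvalidParameterError("admixture age T must be >= 0")
        if not (0 <= self.genotype_error < 0.5):
            raise InvalidParameterError("genotype error rate must be in [0, 0.5)")
        if not (0 <= self.missing_rate < 1):
            raise InvalidParameterError("missing rate must be in [0, 1)")
        if self.region_proportions:
            for r, p in self.region_proportions.items():
                p = tuple(float(x) for x in p)
                if len(p) != len(self.ancestry_names) or abs(sum(p) - 1) > 1e-9:
                    raise InvalidParameterError(f"invalid proportions for region {r}")
                self.region_proportions[r] = p


@dataclass
class GlobalProportions:
    """Per-individual genome-wide ancestry fractions; each row sums to 1."""

    proportions: np.ndarray  # (n_individuals, K)
    samples: list[str]
    ancestry_names: tuple[str, ...] = DEFAULT_ANCESTRIES

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=np.float64)
        self.ancestry_names = tuple(self.ancestry_names)
        if self.proportions.shape != (len(self.samples), len(self.ancestry_names)):
            raise InconsistentInputError("proportions must be (n_individuals, K)")
        sums = self.proportions.sum(axis=1)
        if self.proportions.size and not np.allclose(sums, 1.0, atol=1e-9):
            raise InvalidParameterError("each individual's proportions must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.proportions, columns=list(self.ancestry_names))
        df.insert(0, "sample", self.samples)
        return df


__all__ = [
    "DEFAULT_ANCESTRIES",
    "MISSING",
    "InvalidParameterError",
    "InconsistentInputError",
    "GenotypeMatrix",
    "AlleleFrequencyPanel",
    "GeneticMap",
    "TractSet",
    "AncestryCallSet",
    "RegionTable",
    "ZoneMap",
    "SimCohortConfig",
    "GlobalProportions",
    "validate_markers",
    "markers_equal",
    "require_same_markers",
]
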