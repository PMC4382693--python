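"""Readers and writers for the pipeline's on-disk formats.

Dialects, declared in a header comment of every file written:
  - VCF 4.2, 1-based positions, phased GT with the "|" separator (cyvcf2
    does the parsing on the way back in);
  - genetic maps as 3-column text (chrom, bp, cM), 1-based, cM cumulative
    and non-decreasing within a chromosome;
  - tracts as BED-style TSV, 0-based half-open (chrom, start, end, sample,
    haplotype, ancestry);
  - per-marker ancestry calls, region tables, zone maps, frequency panels
    and all reports as TSV with a "#"-prefixed header convention line.

Every reader validates the container invariants on entry, so a malformed
file fails at the boundary with file/line context instead of deep inside a
stage.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    AlleleFrequencyPanel,
    AncestryCallSet,
    GeneticMap,
    GenotypeMatrix,
    InconsistentInputError,
    RegionTable,
    TractSet,
    ZoneMap,
)

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_map",
    "read_map",
    "write_tracts_bed",
    "read_tracts_bed",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_frequency_panel",
    "read_frequency_panel",
    "write_region_table",
    "read_region_table",
    "write_zone_map",
    "read_zone_map",
    "bundled_region_table",
    "bundled_zone_map",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(path, genotypes: GenotypeMatrix, haplotypes: np.ndarray | None = None) -> None:
    """Plain-text VCF; phased GT when haplotypes are given, else unphased dosage."""
    m = genotypes.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixkit\n")
        for chrom, sub in m.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['bp'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        unphased = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(genotypes.n_markers):
            row = m.iloc[j]
            if haplotypes is not None:
                gts = [
                    f"{haplotypes[i, 0, j]}|{haplotypes[i, 1, j]}"
                    if genotypes.calls[i, j] != MISSING
                    else ".|."
                    for i in range(genotypes.n_samples)
                ]
            else:
                gts = [unphased[int(genotypes.calls[i, j])] for i in range(genotypes.n_samples)]
            fh.write(
                f"{row['chrom']}\t{row['bp']}\tsnp{j}\t{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path, require_phased: bool = False):
    """Read a VCF into (GenotypeMatrix, haplotypes-or-None).

    Haplotypes are returned only when every call is phased; with
    ``require_phased`` an unphased GT raises instead of degrading.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, bps, refs, alts = [], [], [], []
    geno_rows, hap_rows = [], []
    phased_all = True
    for var in vcf:
        chroms.append(var.CHROM)
        bps.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        gt = np.array(var.genotypes, dtype=object)  # rows: [a, b, phased]
        a = np.array([g[0] for g in gt])
        b = np.array([g[1] for g in gt])
        ph = np.array([bool(g[2]) for g in gt])
        missing = (a < 0) | (b < 0)
        if not ph[~missing].all():
            phased_all = False
            if require_phased:
                raise InconsistentInputError(
                    f"{path}: unphased genotype at {var.CHROM}:{var.POS}; "
                    "phased haplotypes are required"
                )
        dose = np.where(missing, MISSING, a + b).astype(np.int8)
        geno_rows.append(dose)
        hap_rows.append(np.stack([np.where(missing, 0, a), np.where(missing, 0, b)]))
    markers = pd.DataFrame({"chrom": chroms, "bp": bps, "ref": refs, "alt": alts})
    calls = np.array(geno_rows, dtype=np.int8).T  # samples x markers
    genotypes = GenotypeMatrix(markers=markers, calls=calls, samples=samples)
    haps = None
    if phased_all and hap_rows:
        stacked = np.stack(hap_rows)  # (m, 2, n)
        haps = np.transpose(stacked, (2, 1, 0)).astype(np.int8)
    return genotypes, haps


# ---------------------------------------------------------------------------
# tabular genotypes
# ---------------------------------------------------------------------------


def write_genotypes_tsv(path, genotypes: GenotypeMatrix) -> None:
    """Transposed tabular text: one row per marker, one 0/1/2/NA column per sample."""
    cols = {
        s: [("NA" if v == MISSING else int(v)) for v in genotypes.calls[i]]
        for i, s in enumerate(genotypes.samples)
    }
    df = pd.concat([genotypes.markers, pd.DataFrame(cols)], axis=1)
    with open(path, "w") as fh:
        fh.write("# genotypes: alt-allele dosage 0/1/2, NA missing; bp 1-based\n")
        df.to_csv(fh, sep="\t", index=False)


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    meta_cols = ["chrom", "bp", "ref", "alt"]
    samples = [c for c in df.columns if c not in meta_cols]
    markers = df[meta_cols].copy()
    markers["chrom"] = markers["chrom"].astype(str)
    calls = np.full((len(samples), len(df)), MISSING, dtype=np.int8)
    for i, s in enumerate(samples):
        col = df[s]
        ok = col.notna() & (col.astype(str) != "NA")
        calls[i, ok.to_numpy()] = col[ok].astype(int).to_numpy()
    return GenotypeMatrix(markers=markers, calls=calls, samples=samples)


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


def write_map(path, gmap: GeneticMap) -> None:
    with open(path, "w") as fh:
        fh.write("# genetic map: chrom, bp (1-based), cM (cumulative within chromosome)\n")
        fh.write("chrom\tbp\tcM\n")
        for (_, row), cm in zip(gmap.markers.iterrows(), gmap.cm):
            fh.write(f"{row['chrom']}\t{row['bp']}\t{cm:.8g}\n")


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"chrom", "bp", "cM"} <= set(df.columns):
        raise InconsistentInputError(f"{path}: expected columns chrom, bp, cM")
    df["chrom"] = df["chrom"].astype(str)
    for chrom, sub in df.groupby("chrom", sort=False):
        if np.any(np.diff(sub["cM"].to_numpy()) < 0):
            raise InconsistentInputError(
                f"{path}: decreasing cM within chromosome {chrom}"
            )
    markers = df[["chrom", "bp"]].copy()
    markers["ref"] = "A"
    markers["alt"] = "G"
    return GeneticMap(markers=markers, cm=df["cM"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# tracts / calls
# ---------------------------------------------------------------------------


def write_tracts_bed(path, tracts: TractSet) -> None:
    with open(path, "w") as fh:
        fh.write("# ancestry tracts: BED dialect, 0-based half-open [start, end)\n")
        fh.write("chrom\tstart\tend\tsample\thaplotype\tancestry\n")
        for _, r in tracts.tracts.iterrows():
            name = tracts.ancestry_names[int(r["ancestry"])]
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['sample']}\t{r['haplotype']}\t{name}\n"
            )


def read_tracts_bed(path, ancestry_names) -> TractSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    lookup = {n: i for i, n in enumerate(ancestry_names)}
    df["ancestry"] = df["ancestry"].map(lookup)
    if df["ancestry"].isna().any():
        raise InconsistentInputError(f"{path}: unknown ancestry label")
    df["chrom"] = df["chrom"].astype(str)
    return TractSet(
        tracts=df[["sample", "haplotype", "chrom", "start", "end", "ancestry"]],
        ancestry_names=tuple(ancestry_names),
    )


def write_calls_tsv(path, calls: AncestryCallSet) -> None:
    """Per-marker calls, one "a|b" label-pair column per individual.

    The same layout is accepted back by :func:`read_calls_tsv`, so call sets
    produced by external LAI tools can enter the pipeline.
    """
    cols = {
        s: [f"{x}|{y}" for x, y in zip(calls.calls[i, 0], calls.calls[i, 1])]
        for i, s in enumerate(calls.samples)
    }
    df = pd.concat([calls.markers[["chrom", "bp"]], pd.DataFrame(cols)], axis=1)
    with open(path, "w") as fh:
        fh.write(
            f"# local ancestry calls ({calls.method}); labels "
            + ",".join(f"{i}={n}" for i, n in enumerate(calls.ancestry_names))
            + "; bp 1-based\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_calls_tsv(path, ancestry_names, method: str = "external") -> AncestryCallSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    samples = [c for c in df.columns if c not in ("chrom", "bp")]
    markers = df[["chrom", "bp"]].copy()
    markers["chrom"] = markers["chrom"].astype(str)
    markers["ref"] = "A"
    markers["alt"] = "G"
    calls = np.zeros((len(samples), 2, len(df)), dtype=np.int8)
    for i, s in enumerate(samples):
        pairs = df[s].astype(str).str.split("|", expand=True)
        calls[i, 0] = pairs[0].astype(int).to_numpy()
        calls[i, 1] = pairs[1].astype(int).to_numpy()
    return AncestryCallSet(
        markers=markers,
        calls=calls,
        samples=samples,
        ancestry_names=tuple(ancestry_names),
        method=method,
    )


# ---------------------------------------------------------------------------
# frequency panels, region tables, zone maps
# ---------------------------------------------------------------------------


def write_frequency_panel(path, panel: AlleleFrequencyPanel) -> None:
    df = panel.markers.copy()
    for k, name in enumerate(panel.ancestry_names):
        df[name] = panel.freqs[k]
    with open(path, "w") as fh:
        fh.write("# ancestral alternate-allele frequencies per marker; bp 1-based\n")
        df.to_csv(fh, sep="\t", index=False)


def read_frequency_panel(path, ancestry_names=None) -> AlleleFrequencyPanel:
    df = pd.read_csv(path, sep="\t", comment="#")
    meta = ["chrom", "bp", "ref", "alt"]
    if ancestry_names is None:
        ancestry_names = tuple(c for c in df.columns if c not in meta)
    markers = df[meta].copy()
    markers["chrom"] = markers["chrom"].astype(str)
    freqs = np.vstack([df[n].to_numpy(dtype=float) for n in ancestry_names])
    return AlleleFrequencyPanel(
        markers=markers, freqs=freqs, ancestry_names=tuple(ancestry_names)
    )


def write_region_table(path, table: RegionTable) -> None:
    with open(path, "w") as fh:
        fh.write("# regions: sampling counts and percentage fractions\n")
        table.table.to_csv(fh, sep="\t", index=False)


def read_region_table(path) -> RegionTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return RegionTable(table=df)


def write_zone_map(path, zmap: ZoneMap) -> None:
    with open(path, "w") as fh:
        fh.write("# region -> demographic zone assignment\n")
        fh.write("region\tzone\n")
        for region, zone in zmap.mapping.items():
            fh.write(f"{region}\t{zone}\n")


def read_zone_map(path) -> ZoneMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    return ZoneMap(mapping=dict(zip(df["region"], df["zone"])))


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("admixkit").joinpath("data", name)))


def bundled_region_table() -> RegionTable:
    """The packaged 15-region Chilean sampling scheme (plus an Unknown row)."""
    return read_region_table(_data_path("regions_chile.tsv"))


def bundled_zone_map() -> ZoneMap:
    """The packaged north-to-south five-zone grouping of the Chilean regions."""
    return read_zone_map(_data_path("zones_chile.tsv"))
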