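"""End-to-end pipeline: QC -> LAI -> global ancestry -> zones -> admixture
time -> concordance -> sensitivity sweeps -> FST.

The pipeline runs either on files (phased VCF or tabular genotypes, a
3-column map, a frequency panel, region/zone tables) or, in demo mode, on a
cohort it simulates itself. One global seed governs every stage through
named substreams; two runs with the same config are byte-identical. Each
stage logs a structured line (stage, elapsed, key counts) and writes its
TSVs under the output directory together with a JSON manifest (parameters,
seed, versions, input digests) sufficient to reproduce the run. A stage
whose inputs are absent (e.g. no zone map) is skipped with a warning;
a stage failure halts the run naming the stage, keeping earlier outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as akio
from .ancestry import (
    assign_zones,
    global_proportions,
    individual_weights,
    region_weights,
    weighted_proportions,
    zone_comparison,
)
from .admixture_time import count_switches, estimate_admixture_time
from .concordance import (
    correlation_test,
    global_concordance_bands,
    local_concordance,
    marker_recombination_rates,
)
from .datatypes import RegionTable, SimCohortConfig, ZoneMap
from .lai import HmmConfig, call_haplotypes
from .popgen import fst_permutation_test, marker_differentiation
from .qc import QCThresholds, qc_filter
from .sensitivity import panel_size_sweep, select_stable_size, snp_density_sweep
from .simulate import (
    gen_frequency_panel,
    gen_genetic_map,
    gen_reference_haplotypes,
    simulate_cohort,
)

logger = logging.getLogger("admixkit")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    out_dir: str = "admixkit_out"
    seed: int = 0
    # file inputs (all optional; demo simulation fills the gaps)
    vcf: str | None = None
    map_file: str | None = None
    panel_file: str | None = None
    regions_file: str | None = None
    zones_file: str | None = None
    use_bundled_regions: bool = True
    # simulation block (used when no vcf is given)
    sim: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    hmm: dict = field(default_factory=dict)
    run_sweeps: bool = True
    sweep_sizes: list[int] = field(default_factory=lambda: [10, 20, 40, 80])
    sweep_densities: list[int] = field(default_factory=lambda: [60, 120, 240, 480])
    sweep_replicates: int = 10
    fst_permutations: int = 999


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**raw)
    for name in ("vcf", "map_file", "panel_file", "regions_file", "zones_file"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configured input {name}={p} does not exist")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Stage:
    """Context manager emitting one structured log line per stage."""

    def __init__(self, name: str, manifest: dict):
        self.name = name
        self.manifest = manifest

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage=%s elapsed=%.2fs", self.name, elapsed)
            self.manifest.setdefault("stages", {})[self.name] = round(elapsed, 3)
        else:
            logger.error("stage=%s FAILED after %.2fs: %s", self.name, elapsed, exc)
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report bundle (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "config": {k: v for k, v in vars(config).items()},
    }
    bundle: dict = {"manifest": manifest}

    # ---- inputs -----------------------------------------------------------
    with _Stage("inputs", manifest):
        regions: RegionTable | None = None
        zones: ZoneMap | None = None
        if config.regions_file:
            regions = akio.read_region_table(config.regions_file)
        elif config.use_bundled_regions:
            regions = akio.bundled_region_table()
        if config.zones_file:
            zones = akio.read_zone_map(config.zones_file)
        elif config.use_bundled_regions:
            zones = akio.bundled_zone_map()

        if config.vcf:
            genotypes, haps = akio.read_vcf(config.vcf, require_phased=True)
            gmap = akio.read_map(config.map_file)
            panel = akio.read_frequency_panel(config.panel_file)
            tracts = None
            region_labels = [None] * genotypes.n_samples
            manifest["inputs"] = {
                p: _digest(Path(p))
                for p in (config.vcf, config.map_file, config.panel_file)
            }
        else:
            sim = dict(config.sim)
            n_markers = int(sim.pop("n_markers", 600))
            n_chrom = int(sim.pop("n_chromosomes", 2))
            morgans = float(sim.pop("morgans_per_chromosome", 1.5))
            F = sim.pop("F_per_ancestry", (0.2, 0.2, 0.2))
            gmap = gen_genetic_map(
                chrom_lengths_bp=(100_000_000,) * n_chrom,
                morgans_per_chrom=(morgans,) * n_chrom,
                markers_per_chrom=(n_markers // n_chrom,) * n_chrom,
                rate_profile="gamma",
                seed=config.seed,
            )
            panel = gen_frequency_panel(
                markers=gmap.markers, F_per_ancestry=tuple(F), seed=config.seed
            )
            if regions is not None and "n_individuals" not in sim:
                sim["n_individuals"] = regions.total_samples
            cohort_cfg = SimCohortConfig(
                seed=config.seed, region_table=regions, **sim
            )
            genotypes, haps, tracts, region_labels = simulate_cohort(
                cohort_cfg, panel, gmap
            )
            akio.write_vcf(out / "cohort.vcf", genotypes, haps)
            akio.write_map(out / "map.tsv", gmap)
            akio.write_frequency_panel(out / "panel.tsv", panel)
            akio.write_tracts_bed(out / "truth_tracts.bed", tracts)
        logger.info(
            "stage=inputs n_individuals=%d n_markers=%d G=%.2fM",
            genotypes.n_samples, genotypes.n_markers, gmap.total_morgans,
        )

    # ---- qc ---------------------------------------------------------------
    with _Stage("qc", manifest):
        qc_geno, qc_report = qc_filter(genotypes, QCThresholds(**config.qc))
        qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        if qc_report.excluded_markers is not None:
            qc_report.excluded_markers.to_csv(
                out / "qc_excluded_markers.tsv", sep="\t", index=False
            )
        keep_idx = qc_geno.markers.merge(
            genotypes.markers.reset_index(), on=["chrom", "bp", "ref", "alt"]
        )["index"].to_numpy()
        haps = haps[:, :, keep_idx]
        panel = panel.subset_markers(keep_idx)
        gmap = gmap.subset_markers(keep_idx)
        bundle["qc"] = qc_report
        logger.info(
            "stage=qc markers_kept=%d markers_removed=%d",
            qc_geno.n_markers, qc_report.n_markers_removed,
        )

    # ---- lai --------------------------------------------------------------
    with _Stage("lai", manifest):
        hmm = HmmConfig(**{**config.hmm, "decode_mode": "viterbi"})
        calls_v = call_haplotypes(haps, panel, gmap, hmm, samples=qc_geno.samples)
        hmm_mp = HmmConfig(**{**config.hmm, "decode_mode": "max-posterior"})
        calls_m = call_haplotypes(haps, panel, gmap, hmm_mp, samples=qc_geno.samples)
        akio.write_calls_tsv(out / "calls_viterbi.tsv", calls_v)
        akio.write_calls_tsv(out / "calls_maxposterior.tsv", calls_m)
        bundle["calls"] = calls_v

    # ---- global ancestry --------------------------------------------------
    with _Stage("global", manifest):
        props = global_proportions(calls_v)
        props.to_frame().to_csv(out / "global_proportions.tsv", sep="\t", index=False)
        if regions is not None:
            rw = region_weights(regions)
            rw.to_csv(out / "region_weights.tsv", sep="\t", index=False)
            weights = individual_weights(region_labels, regions)
        else:
            weights = np.ones(len(props.samples))
        national = weighted_proportions(props, weights)
        pd.DataFrame(
            [dict(zip(props.ancestry_names, 100 * national))]
        ).to_csv(out / "national_ancestry_pct.tsv", sep="\t", index=False)
        bundle["proportions"] = props
        bundle["national"] = dict(zip(props.ancestry_names, national))
        logger.info(
            "stage=global national=%s",
            {k: round(100 * v, 2) for k, v in bundle["national"].items()},
        )

    # ---- zones ------------------------------------------------------------
    if zones is not None and regions is not None and any(region_labels):
        with _Stage("zones", manifest):
            zone_counts = assign_zones(regions, zones)
            zone_counts.to_csv(out / "zone_counts.tsv", sep="\t", index=False)
            zlabel = [
                zones.zone_of(r) if r is not None else None for r in region_labels
            ]
            comparisons = {}
            for k, name in enumerate(props.ancestry_names):
                vals = {
                    z: props.proportions[[i for i, zl in enumerate(zlabel) if zl == z], k]
                    for z in zones.zones
                }
                comparisons[name] = zone_comparison(vals)
                comparisons[name].tukey.to_csv(
                    out / f"zone_tukey_{name}.tsv", sep="\t", index=False
                )
                comparisons[name].box_stats.to_csv(
                    out / f"zone_box_{name}.tsv", sep="\t", index=False
                )
            bundle["zones"] = {"counts": zone_counts, "comparisons": comparisons}
    else:
        logger.warning("stage=zones skipped: no zone map / region labels")

    # ---- admixture time ---------------------------------------------------
    with _Stage("time", manifest):
        switches = count_switches(calls_v)
        tdf = estimate_admixture_time(switches, props, gmap.total_morgans)
        tdf.to_csv(out / "admixture_time.tsv", sep="\t", index=False)
        bundle["admixture_time"] = tdf
        logger.info("stage=time mean_t_hat=%.2f", tdf.attrs["mean_t_hat"])
        if tracts is not None:
            # demo mode: the unsmoothed estimate from the simulator's truth
            # tracts, to expose how much decoding shrinks switch counts
            tdf_truth = estimate_admixture_time(
                count_switches(tracts), props, gmap.total_morgans
            )
            tdf_truth.to_csv(out / "admixture_time_truth.tsv", sep="\t", index=False)
            bundle["admixture_time_truth"] = tdf_truth
            logger.info(
                "stage=time mean_t_hat_truth=%.2f", tdf_truth.attrs["mean_t_hat"]
            )

    # ---- concordance ------------------------------------------------------
    with _Stage("concordance", manifest):
        rep = local_concordance(calls_v, calls_m)
        rep.cross_tab.to_csv(out / "concordance_crosstab.tsv", sep="\t")
        props_m = global_proportions(calls_m)
        bands = global_concordance_bands(props, props_m)
        bands.to_csv(out / "concordance_bands.tsv", sep="\t", index=False)
        rates = marker_recombination_rates(gmap)
        diff = marker_differentiation(panel, panel.ancestry_names[0], panel.ancestry_names[1])
        sq = diff.sort_values("marker_index")["sq_diff"].to_numpy()
        corr = {}
        inc = rep.per_marker_inconsistency.astype(float)
        if inc.std() > 0:
            corr["recomb_rate"] = correlation_test(inc, rates)
            corr["sq_freq_diff"] = correlation_test(inc, sq)
        bundle["concordance"] = {"report": rep, "bands": bands, "correlations": corr}
        logger.info("stage=concordance coincidence_pct=%.2f", rep.coincidence_pct)

    # ---- sensitivity sweeps ----------------------------------------------
    if config.run_sweeps and config.vcf is None:
        with _Stage("sweeps", manifest):
            refs = gen_reference_haplotypes(
                panel, max(config.sweep_sizes), seed=config.seed
            )
            sweep_p = panel_size_sweep(
                refs, haps, panel.markers, gmap, config.sweep_sizes,
                which_panel=panel.ancestry_names[0],
                n_replicates=config.sweep_replicates, seed=config.seed,
            )
            sweep_p.median_sd().to_csv(out / "sweep_panel_median_sd.tsv", sep="\t", index=False)
            sweep_d = snp_density_sweep(
                haps, panel, gmap, config.sweep_densities,
                n_replicates=config.sweep_replicates, seed=config.seed,
            )
            sweep_d.median_sd().to_csv(out / "sweep_density_median_sd.tsv", sep="\t", index=False)
            bundle["sweeps"] = {
                "panel": sweep_p,
                "density": sweep_d,
                "stable_panel_size": select_stable_size(
                    sweep_p, panel.ancestry_names[0], rule="min-median"
                ),
            }
    else:
        logger.warning("stage=sweeps skipped")

    # ---- fst --------------------------------------------------------------
    with _Stage("fst", manifest):
        refs = gen_reference_haplotypes(panel, 50, seed=config.seed)
        fst_rows = []
        # pair reference haplotypes into 25 pseudo-diploids per population
        pops = {name: refs[name].reshape(25, 2, -1).sum(axis=1)
                for name in panel.ancestry_names[:2]}
        pops["COHORT"] = qc_geno.calls
        names = list(pops)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = pops[names[i]], pops[names[j]]
                labels = np.array([0] * len(a) + [1] * len(b))
                res = fst_permutation_test(
                    np.vstack([a, b]), labels,
                    n_permutations=config.fst_permutations, seed=config.seed,
                )
                fst_rows.append(
                    dict(pop_a=names[i], pop_b=names[j],
                         fst=res.fst_estimate, p_value=res.p_value)
                )
        fst_df = pd.DataFrame(fst_rows)
        fst_df.to_csv(out / "fst.tsv", sep="\t", index=False)
        bundle["fst"] = fst_df

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return bundle
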