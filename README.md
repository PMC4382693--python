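# admixkit

Local-ancestry-based admixture analysis for three-way admixed cohorts
(Native-American / European / African by default), built around the kind of
study design used for Latin-American populations: genotype a cohort sampled
unevenly across administrative regions, infer local ancestry against
reference panels, and summarize what the ancestry mosaic says about the
population's history and geography.

The package provides, as one pipeline or as independent library functions:

- **Synthetic cohort simulation** under a hybrid-isolation (HI) model —
  a single admixture pulse `T` generations ago — with Balding–Nichols
  ancestral allele-frequency panels, synthetic genetic maps (uniform or
  hotspot-like recombination), per-region sampling schemes and ground-truth
  ancestry tracts, so every downstream stage is testable without any data
  download.
- **QC**: the standard array filters (sample missingness, SNP call rate,
  MAF, exact Hardy–Weinberg test, A/T–C/G ambiguous SNPs, HLA window).
- **Local ancestry inference (LAI)**: a minimal admixture HMM on phased
  haplotypes (stay-put weight `e^(−T·d)` over `d` Morgans, clamped
  Bernoulli emissions), with Viterbi and max-posterior decoding. External
  call sets in the same TSV layout can enter the pipeline instead.
- **Global ancestry**: per-individual proportions as the fraction of bases
  assigned to each ancestry; population estimates corrected for unequal
  regional sampling with weights `w = census fraction / sample fraction`,
  i.e. `P̂_k = Σᵢ wᵢ p_{i,k} / Σᵢ wᵢ`; demographic-zone grouping with
  one-way ANOVA + Tukey HSD comparisons.
- **Time since admixture**: under the HI model the expected number of
  visible ancestry switches per diploid genome is
  `E[K] = 2·T·G·(1 − Σ_k p_k²)` (`G` = total map length in Morgans), so
  counting switches and inverting gives `T̂ = K / (2G(1 − Σp²))` per
  individual.
- **Concordance** between two call sets: percent coincidence, K×K confusion
  table, difference bands on global proportions, and Pearson tests relating
  per-marker disagreement to local recombination rate and to ancestral
  allele-frequency differentiation `(f_a − f_b)²`.
- **Sensitivity sweeps**: reference-panel-size and SNP-density resampling
  with replicate s.d. summaries and stable-size selection (min-median or
  kink rule).
- **Population differentiation**: multi-locus Hudson FST with a
  label-permutation p-value, diploid or haploid (chrX/chrY-style designs).

## Worked example

The `run` subcommand chains every stage on a simulated demo cohort whose
sampling scheme mirrors the bundled 15-region table (313 individuals, 12 of
unknown region; zones N=16, C1=159, C2=41, S1=73, S2=12):

```bash
admixkit -v run --seed 1 --out-dir demo_run
```

prints (abridged):

```
stage=inputs n_individuals=313 n_markers=600 G=3.00M
stage=qc markers_kept=578 markers_removed=22
stage=global national={'NAT': 43.91, 'EUR': 51.89, 'AFR': 4.2}
stage=time mean_t_hat=4.26
stage=time mean_t_hat_truth=10.39
stage=concordance coincidence_pct=94.44
national ancestry: NAT=43.91%, EUR=51.89%, AFR=4.20%
```

Reading those numbers: the region-weighted national estimate recovers the
simulation's configured mixture (45/52/3%) to within sampling error on a
3-Morgan demo genome. The two admixture-time lines are deliberate: from the
simulator's ground-truth tracts the HI moment estimator recovers the true
`T = 10` (10.39), while from HMM-decoded calls at this sparse marker
density it reads low (4.26) because decoding merges short tracts — the
over-smoothing bias that any block-count estimator inherits from its
caller. The two decoders agree at 94.4% of assignments, and their
disagreements concentrate at high-recombination, low-differentiation
markers (see `concordance_*` outputs).

Every output TSV states its coordinate convention in a header line, and
`manifest.json` records the seed and parameters needed to reproduce the
run byte-for-byte.

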