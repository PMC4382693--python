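# Methods

## The hybrid-isolation model and what the simulator emulates

All ancestry-tract machinery assumes hybrid isolation (HI): the admixed
population forms in a single pulse `T` generations ago from `K` ancestral
populations contributing proportions `p = (p_1..p_K)`, with no subsequent
gene flow. After `T` generations of recombination, ancestry junctions along
a haplotype are well approximated by a Poisson process of rate `T` per
Morgan, and the ancestry labels of successive segments by i.i.d. draws from
`p` (the Markov approximation to the underlying pedigree process; it
ignores the finite number of ancestors and the correlation between the two
haplotypes of an individual). We use the rate-`T` convention rather than
`T − 1`; the simulator and the time estimator share it, so parameter
recovery is exact by construction and the convention choice cannot cancel
silently against itself.

Consequences used throughout:

- a junction is *visible* (an ancestry switch) only when the flanking
  labels differ, with probability `1 − Σ_k p_k²`;
- expected visible switches per diploid genome of total map length `G`
  Morgans: `E[K] = 2·T·G·(1 − Σ_k p_k²)`; in a two-way reading with
  European share `q`, `E[K] = 4·T·G·q(1 − q)`, maximal at `q = 1/2`;
- ancestry-`k` tract lengths on long chromosomes are approximately
  exponential with mean `1/(T(1 − p_k))` Morgans.

Ancestral allele frequencies follow the Balding–Nichols model: given an
ancestral frequency `p_j`, population `k` draws
`f_kj ~ Beta(p_j(1−F_k)/F_k, (1−p_j)(1−F_k)/F_k)`. `F_k` is the
differentiation parameter; the realized Hudson FST between two tracks with
the same `F` concentrates on `F`, which is what the FST calibration checks
exploit. Haplotype emissions are `Bernoulli(f_kj)` given the local truth
ancestry, optionally flipped at a genotyping-error rate and masked at a
missingness rate.

What the simulator does *not* emulate — and hence what passing tests do not
show about real data: linkage disequilibrium within ancestral populations
(markers are independent given ancestry), continuous or multi-pulse gene
flow, sex-biased admixture, genotyping batch effects, and reference-panel
mis-specification (the panels used for calling are the very distributions
that generated the data, so real-world calling accuracy will be lower than
the simulated ~92–95%).

## Study conditions baked into the defaults

- Cohort mixture defaults to `p = (0.45, 0.52, 0.03)` for (NAT, EUR, AFR)
  and `T = 10` generations — a Chilean-like three-way profile with a small
  African component and an admixture age near ten generations.
- The bundled region table (15 regions + Unknown; 313 samples; sample and
  census percentage fractions) and the five-zone north-to-south grouping
  (N, C1, C2, S1, S2) drive region weighting, zone counts, and the
  option of per-region proportion profiles for a north-south AFR gradient.
- The HMM switch-rate parameter defaults to 8 generations, mirroring the
  fixed-generations setting common in production LAI tools; the emission
  clamp defaults to 0.01.
- Sensitivity sweeps default to 10 replicates per axis value, panel sizes
  stepped from 10 haplotypes, densities over a coarse grid.

## Estimators and numerical choices

**Global proportions.** "Fraction of bases" is implemented as half-interval
weighting: marker `j` carries weight `(gap_left + gap_right)/2` in bp, with
end markers keeping only the half-interval toward their single neighbour
(so three equally spaced markers weigh 1/4, 1/2, 1/4). On uniform spacing
this reduces to per-marker averaging.

**Region weights.** `w_r = census_fraction_r / sample_fraction_r`, computed
from the printed percentage fractions when available (matching the
published worked arithmetic), at full precision internally with a
2-decimal display column. Unknown-region individuals get weight 1
nationally and no zone. Zone summaries reuse the same weights within zones
(a flag disables this).

**Zone comparison.** One-way ANOVA plus Tukey HSD on untransformed
proportions: `q = |mean difference| / sqrt(MSE/2 · (1/n_a + 1/n_b))`
against the studentized range with `N − k` df. Zones with fewer than two
members are excluded from the test but reported. Box statistics use
quartiles and 1.5·IQR whiskers.

**HWE.** Exact test by full enumeration of the conditional distribution of
the heterozygote count given the minor-allele count, two-sided by
probability mass (summing all configurations no more likely than the one
observed, with a 1+1e-12 relative tolerance so exact ties are included).
Computed in log-space via gammaln for stability at large counts.

**QC order.** Sample missingness first, then per-marker rules on the
reduced matrix: call rate → MAF → HWE → ambiguous alleles → HLA window.
Each removed marker is attributed to the *first* rule that fails it, so
per-rule counts sum exactly to the total removed. MAF and HWE use
non-missing calls only. The HLA window defaults to chr6:25–35 Mb (GRCh37
convention) and is configurable. The order itself is a reproducibility
convention, not a statistical claim.

**HMM.** Transition over Morgan distance `d`:
`A = e^(−T·d)·I + (1 − e^(−T·d))·1πᵀ` with uniform prior π (estimating π is
out of scope); emissions clamped to `[ε, 1−ε]` so no marker can zero the
likelihood. Forward–backward uses per-marker scaling; Viterbi runs in log
space; both are vectorized across haplotypes, which is what keeps the
resampling sweeps cheap. Decode ties break to the lowest ancestry index.
Phased-haplotype mode only — a K²-state diploid HMM is deliberately
avoided; phasing is assumed upstream (the simulator emits phase).

**Switch counting.** Per haplotype, summed over the two haplotypes of an
individual; label changes between adjacent markers within a chromosome;
chromosome boundaries never counted. On tract input this equals
tract-count-minus-one per haplotype-chromosome; on marker input it can
only undercount (tracts narrower than the marker spacing are invisible),
which is one of the two sources of downward bias in the decoded `T̂` (the
other being decoder smoothing). The truth-tract estimate is therefore also
reported in demo runs; the bias on decoded calls is measured, not
corrected.

**Concordance.** Haplotype phase between two call sets is not
identifiable, so haplotype pairs are matched per individual-marker to
maximize agreement before tabulating. Per-marker recombination rate is the
Morgan length of a marker's half-interval divided by its bp length.

**FST.** Hudson's ratio-of-averages estimator with sample-size correction
(per-locus numerator `(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)`,
denominator `p1(1−p2) + p2(1−p1)`, summed before dividing). The classic
single-locus pairwise (Slatkin/Hudson) form coincides with this per-locus
ratio; the multi-locus ratio-of-averages is the standard low-bias
combination. Estimates can be slightly negative and are reported
unclamped (with a clamped copy). The permutation test shuffles population
labels and uses the add-one p-value `(1 + #exceedances)/(M + 1)`, so
`p ≥ 1/(M+1)` always. A ploidy flag supports haploid (chrY-like) input.

**Sweeps.** Replicate subsamples are drawn from named RNG substreams keyed
by (seed, axis value, replicate), so any single replicate is reproducible
in isolation and re-runs are bit-identical. The s.d. is the population
(ddof 0) standard deviation over replicates; the per-axis summary is the
median over individuals. The kink rule selects the interior axis value
maximizing `(m(prev) − m(s)) / max(m(s) − m(next), δ)` with floor
`δ = 1e−12` — an elbow criterion reconstructed from a verbal description
of "identify a kink"; output metadata flags which rule chose the value.

## Problem sizes used by the test suite and acceptance script

Chosen to keep the whole suite under a couple of minutes while leaving the
Monte-Carlo bands meaningful: switch-count consistency uses a 35-Morgan
(5 × 7 M) map with 500 replicate diploids per (T, q) cell and a 3-SE band;
time recovery uses 100 truth-tract individuals; HMM-vs-enumeration checks
100 random instances of ≤ 10 markers, K ≤ 3, at 1e−9; FST calibration uses
5,000 markers and 50+50 samples, the type-I calibration 200 null runs of
24 samples × 200 markers at 99 permutations; the correlation-sign analysis
uses 100 individuals × 1,600 markers with moderate (Gamma shape 1) rate
variation; sweeps use 15 individuals, 400 markers, 8 replicates.

## Known limitations

- The HI moment estimator attributes all switches to one pulse; under
  ongoing gene flow it returns a gene-flow-weighted average age.
- The built-in caller is a frequency-based admixture HMM, not a
  haplotype-copying model; absolute accuracies and s.d. magnitudes are not
  comparable to production LAI tools on real panels.
- Tukey HSD is applied to proportions without transformation; with very
  small zones (n ≈ 12) the normality approximation is rough, which is the
  usual caveat for box-plot-level comparisons.
- With the sample-size correction, the FST estimate of two samples drawn
  from identical frequencies is centred on zero but not exactly zero on
  identical count tables (the uncorrected form would be); this is the
  price of unbiasedness.
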