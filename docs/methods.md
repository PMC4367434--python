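# Methods

## Estimation model

The estimator treats the population as closed, panmictic and of piecewise
constant size in the recent past. At drift–recombination equilibrium the
expected squared correlation between alleles at two loci with
recombination fraction *c* is E(r²) = 1/(α + 4Ne·c); α = 1 describes pure
drift with recombination, α = 2 or 2.2 adds the standard corrections for
recurrent mutation. Because loci separated by a large *c* equilibrate
quickly while tightly linked loci retain older signal, each distance class
is interpreted as an estimate of Ne at t = 1/(2f(c)) generations ago; a
set of distance bins therefore yields a trajectory rather than a single
number. The inversion applied per bin is

    Ne(t) = (4 f(c_t))⁻¹ (1/E[r²adj | c_t] − α),

where c_t is obtained from the bin's *mean* pair distance (one mapping per
bin; mapping each pair and averaging 1/c is a deliberate non-default
because it weights short pairs disproportionately under noise).

Observed r² is inflated by finite sampling, so every pair is first
adjusted as r²adj = r² − 1/(βn) with its own pairwise-complete sample size
n; β = 2 when gametic phase is known and β = 1 otherwise. Adjusting per
pair and then averaging equals the single-n convention when no data are
missing and is less biased when they are.

## r² estimators

* **Genotype (unphased, default):** squared Pearson correlation of the two
  0/1/2 allele-count vectors over individuals complete at both loci. It is
  unaffected by double heterozygotes and reproduces PLINK's `--r2`.
* **Haplotype (phased):** (p_AB − p_A p_B)² / (p_A(1−p_A) p_B(1−p_B)) with
  frequencies counted over haplotypes complete at both loci; n is reported
  in individuals (complete haplotypes / 2).

Pairs with fewer than 3 complete individuals, or monomorphic among them,
are skipped and counted. Pairs are never formed across chromosomes (the
inversion needs a physical distance). The all-pairs scan is expressed as
blocked matrix products over presence-masked matrices, so missing data
carry no per-pair cost; a thread pool may divide leading-marker blocks,
and results are assembled in block order so output is identical for any
thread count.

## Tunable parameters

| parameter | default | units / meaning |
|---|---|---|
| MAF threshold | 0.05 | markers kept when MAF ≥ threshold; monomorphic markers always dropped (r² undefined). The ≥ convention is fixed and logged. |
| distance window | 5·10⁴ – 4·10⁶ | bp; pairs admitted when minD ≤ δ ≤ maxD |
| totBins | 30 | number of distance bins |
| bin exponent x | 1.5 | 1 = equal widths; >1 widens long-distance (recent) bins to even out pair counts |
| k | 10⁻⁸ | Morgans per bp for d = kδ (1 Mb ≙ 1 cM) |
| mapping function | linear | also haldane, kosambi; others registerable |
| α | 1 | mutation correction ∈ {1, 2, 2.2}; other values require an explicit expert flag |
| β | phase-dependent | 2 phased, 1 unphased; overridable because published analyses have used β = 2 on genotype-derived r² |
| min pair n | 3 | below this a correlation is degenerate |

The window/bin defaults were chosen once to give dense recent-generation
coverage (t from ~13 to ~1000 at the default k) with enough pairs per bin
on chip-density data; all are logged at startup and overridable.

Distance-bin edges follow the power law
lo_i = minD + (maxD−minD)((i−1)/totBins)^x, hi_i likewise with i; bins are
half-open [lo, hi) with the last closed at maxD, so a boundary distance
belongs to the upper bin and every in-range pair lands in exactly one bin.

## What the synthetic generators emulate

`simulate_wright_fisher` is a forward-in-time diploid Wright–Fisher
population: 2N haplotypes, discrete generations, random mating (selfing at
rate 1/N, as in the idealized model), recombination with Poisson crossover
counts in the map length and uniform breakpoints, no mutation, all markers
starting at frequency exactly 0.5. It generates exactly the process the
estimation model assumes — drift plus recombination at known N — which is
what makes parameter recovery a meaningful end-to-end check. It does *not*
emulate real data features such as SNP ascertainment bias, mutation,
selection, migration, admixture, population structure, genotyping error or
a non-uniform recombination map; passing recovery tests therefore
validates the estimator's statistics, not robustness to those confounders
(which the LD method is known to be sensitive to).

`generate_ld_profile` inverts the model analytically: per-bin r² values
placed exactly on 1/(α + 4Ne·f(c)) + 1/(βn) at bin midpoints. The pipeline
must return the generating Ne in every bin to ~1e−9 relative error; this
isolates the algebra (binning, correction, mapping, inversion) from all
sampling noise.

Validation problem sizes: parameter recovery uses 20 replicates of 500
markers on 50 Mb, 400 generations, sample 50, at N = 100 and N = 500; the
drift-law check uses 500 single-locus replicates at N = 50, g = 15,
comparing the allele-frequency variance with p(1−p)(1−(1−1/(2N))^g) within
Monte-Carlo error. These sizes give stable statistics at desk scale.

## Numerical choices

* Genotypes are recoded on load so columns count the per-locus minor
  allele (ties at 0.5 broken lexicographically); r² is invariant to this,
  it only standardizes reporting and makes PLINK round trips exact.
* Mapping functions are clamped just below c = 0.5 (at 0.5 − 10⁻⁹): the
  linear map exceeds it otherwise, and Haldane/Kosambi saturate to exactly
  0.5 in float64 at extreme distances although mathematically c < 0.5.
* Within-bin sd of adjusted r² uses the n−1 denominator, 0 for a
  single-pair bin.
* Bins whose mean adjusted r² or implied Ne is non-positive are flagged
  invalid, excluded from the main table and written to a diagnostics
  sidecar rather than silently dropped.
* Output formatting is fixed (1 decimal for generations/Ne/distance, 6 for
  r² statistics) so repeated runs are byte-identical.
* The Sved and Sved–Feldman mapping forms are exposed as registration
  hooks rather than built-ins; their defining formulas live in the
  original literature and any monotone c(d) < 0.5 can be plugged in.
  Linear, Haldane and Kosambi are the fully supported set.

## Known limitations

* **Recent-generation bias under intense sampling.** The 1/(βn) adjustment
  assumes the n individuals are drawn from a much larger population. When
  the sample is a sizable fraction of it (e.g. 50 of 100 in the recovery
  setting), the actual sample-vs-population r² inflation is closer to
  (1/n)(1 − n/N), so the correction over-subtracts and the most recent
  bins (largest distances, where the correction is comparable to r²
  itself) are biased upward — measured at up to ~+45% for bins dated
  t < 20 in the N = 100 recovery runs, while bins with 20 ≲ t ≲ 200 stay
  within ±30%. Recent-most and oldest bins should always be read with
  caution; the within-bin sd column exists to judge them.
* Oldest bins lose markers and pairs (and, beyond ~4Ne generations, any
  coalescent signal), so their estimates are noisy and conservative.
* A constant k converts bp to Morgans uniformly; real recombination-rate
  variation along the genome distorts the time axis accordingly.
* No confidence intervals are produced; replicate or bootstrap externally
  if needed.
* Admixture, migration, selection and ascertainment all shift LD-based Ne;
  the tool applies the standard corrections but cannot detect these
  confounders.
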