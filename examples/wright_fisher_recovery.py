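"""Recover a known constant Ne from simulated SNP genotypes.

Simulates a Wright–Fisher population of N = 100 diploids for 400
generations (500 SNPs on a 50 Mb chromosome, recombination 1e-8
Morgans/bp), samples 50 individuals, computes pairwise LD, and inverts it
into an Ne trajectory. The printed Ne values should scatter around the
true N = 100; the most recent and oldest bins are the least reliable, as
is expected for LD-based estimates.
"""

from netrend import (CorrectionSpec, LDConfig, MappingSpec, SimulationSpec,
                     compute_pair_table, maf_filter, make_bins,
                     run_trajectory, simulate_wright_fisher)

TRUE_N = 100

out = simulate_wright_fisher(SimulationSpec(
    pop_size=TRUE_N, sample_n=50, n_markers=500,
    chrom_length_bp=50_000_000, recomb_rate_per_bp=1e-8,
    generations=400, seed=12))
dataset, _ = maf_filter(out.dataset, 0.05)
print(f"{dataset.n_markers} markers remain after the MAF >= 0.05 filter "
      f"(drift fixed the rest over 400 generations)")

pairs = compute_pair_table(dataset, LDConfig())
print(f"{len(pairs)} SNP pairs in the 50 kb - 4 Mb window")

result = run_trajectory(pairs, make_bins(50_000, 4_000_000, 15, 1.5),
                        MappingSpec(), CorrectionSpec(alpha=1, beta=1))
print(f"\ntrue N = {TRUE_N}; estimated trajectory:")
print("  gen ago      Ne   pairs")
for e in result.estimates:
    print(f"{e.generations_ago:9.1f} {e.ne:7.1f} {e.n_pairs:7d}")
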