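"""End-to-end run from PLINK text files, as a library call.

Writes a small simulated fixture to ped/map, reads it back the way any
user dataset would be read, and runs the default estimation pipeline. The
same analysis is available from the shell as

    netrend simulate --pop-size 80 --sample 40 --seed 3 --out fixture
    netrend estimate --ped fixture.ped --map fixture.map --out run1

which writes run1.ne.tsv (the table printed here), run1.excluded.tsv and
run1.log.
"""

import tempfile
from pathlib import Path

from netrend import (CorrectionSpec, LDConfig, MappingSpec, SimulationSpec,
                     compute_pair_table, maf_filter, make_bins, read_plink,
                     run_trajectory, simulate_wright_fisher, write_plink,
                     write_trajectory)

workdir = Path(tempfile.mkdtemp())
sim = simulate_wright_fisher(SimulationSpec(
    pop_size=80, sample_n=40, n_markers=300, chrom_length_bp=30_000_000,
    recomb_rate_per_bp=1e-8, generations=200, seed=3))
write_plink(sim.dataset, workdir / "fixture.ped", workdir / "fixture.map")

dataset = read_plink(workdir / "fixture.ped", workdir / "fixture.map")
print(f"read {dataset.n_individuals} individuals x "
      f"{dataset.n_markers} markers from PLINK text files")

dataset, _ = maf_filter(dataset, 0.05)
pairs = compute_pair_table(dataset, LDConfig(threads=2))
result = run_trajectory(pairs, make_bins(50_000, 4_000_000, 12, 1.5),
                        MappingSpec(), CorrectionSpec(alpha=1, beta=1))

out = workdir / "run1.ne.tsv"
write_trajectory(result.estimates, out)
print(f"wrote {out} (true N was 80):\n")
print(out.read_text())
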