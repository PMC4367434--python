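"""Estimate Ne from LD values computed by other software.

Any tool that reports pairwise r² (PLINK, GenABLE, custom scripts) can
feed the estimator: write the values as a delimited table of chromosome,
the two positions and r², then invert with a global sample size. Here the
table is the analytic profile of a population of Ne = 100, so every bin
returns 100.0 exactly.

Shell equivalent: netrend from-ld --ld pairs.tsv --n 50 --out run2
"""

import tempfile
from pathlib import Path

from netrend import (CorrectionSpec, MappingSpec, generate_ld_profile,
                     make_bins, read_ld_table, run_trajectory,
                     write_ld_table)

workdir = Path(tempfile.mkdtemp())
scheme = make_bins(50_000, 4_000_000, 8, 1.5)
mapping = MappingSpec()

write_ld_table(generate_ld_profile(100, 1, 1, 50, scheme, mapping),
               workdir / "pairs.tsv")
print("input table:")
print((workdir / "pairs.tsv").read_text())

pairs = read_ld_table(workdir / "pairs.tsv")
result = run_trajectory(pairs, scheme, mapping,
                        CorrectionSpec(alpha=1, beta=1))
print("generations ago -> Ne:")
for e in result.estimates:
    print(f"  {e.generations_ago:7.1f}  {e.ne:6.1f}")
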