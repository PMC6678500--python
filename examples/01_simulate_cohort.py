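"""Simulate a synthetic NIPT cohort and write it to TSV.

Generates 100 euploid and 10 trisomy-21 samples at 3M reads with the
default CNV jitter, then prints the chr21 proportion for each group: the
trisomic mean should exceed the euploid mean by about ff/2 = 5%.
"""

import numpy as np

from adanipt import SimCohortConfig, simulate_cohort, write_chrom_counts
from adanipt.simulator import FixedDepth, FixedFF

euploid_cfg = SimCohortConfig(n_samples=100, depth_model=FixedDepth(3_000_000),
                              seed=1)
trisomy_cfg = SimCohortConfig(n_samples=10, depth_model=FixedDepth(3_000_000),
                              trisomy_chrom=21, fetal_fraction_model=FixedFF(0.1),
                              seed=2)

euploid, truth_e = simulate_cohort(euploid_cfg, id_prefix="E")
trisomic, truth_t = simulate_cohort(trisomy_cfg, id_prefix="T")

write_chrom_counts([s.counts for s in euploid + trisomic], "cohort.counts.tsv")
truth = __import__("pandas").concat([truth_e, truth_t])
truth.to_csv("cohort.truth.tsv", sep="\t", index=False)

p21_e = np.mean([s.counts.x[20] / s.counts.n for s in euploid])
p21_t = np.mean([s.counts.x[20] / s.counts.n for s in trisomic])
print(f"euploid  chr21 proportion: {p21_e:.6f}")
print(f"trisomic chr21 proportion: {p21_t:.6f}")
print(f"ratio: {p21_t / p21_e:.4f}  (expected ~1.05 at fetal fraction 0.10)")
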