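"""Train both callers on euploid controls and score test samples.

Trains FIXVAR (fixed mean/SD of the chromosome ratio) and ADAVAR
(depth-adaptive mean/SD plus the CNV bias constant) on 200 euploid
samples, then scores a euploid and a trisomic sample and prints the
z-scores and grey-zone calls.  At matched depth the two callers give
similar answers; the trisomic sample should score far above the z = 4
suspect threshold at 10% fetal fraction.
"""

from adanipt import (
    ReferenceSelector,
    SimCohortConfig,
    adavar_train,
    adavar_zscore,
    fixvar_train,
    fixvar_zscore,
    simulate_cohort,
)
from adanipt.fixvar import T21_PRODUCTION_REFERENCE
from adanipt.simulator import FixedDepth, FixedFF

selector = ReferenceSelector(21, T21_PRODUCTION_REFERENCE)

train_cfg = SimCohortConfig(n_samples=200, depth_model=FixedDepth(3_000_000),
                            seed=10)
train = [s.counts for s in simulate_cohort(train_cfg)[0]]

fix = fixvar_train(train, selector)
ada = adavar_train(train, selector, seed=10)
print(f"FIXVAR: mu={fix.mu_fix:.6f} sigma={fix.sigma_fix:.3e}")
print(f"ADAVAR: q1={ada.q1:.6f} q2={ada.q2:.6f} c={ada.c:.3e} "
      f"({ada.combine_mode} combination)")

for label, trisomy in (("euploid", None), ("trisomic", 21)):
    cfg = SimCohortConfig(n_samples=1, depth_model=FixedDepth(3_000_000),
                          trisomy_chrom=trisomy,
                          fetal_fraction_model=FixedFF(0.1), seed=99)
    (sample,) = simulate_cohort(cfg, id_prefix=label)[0]
    zf = fixvar_zscore(sample.counts, fix)
    za = adavar_zscore(sample.counts, ada)
    print(f"{label:9s} ZFIX={zf.z:7.2f} ({zf.call})   "
          f"ZADA={za.z:7.2f} ({za.call})")
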