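"""Reproduce both depth-mismatch failure directions of the fixed caller.

Shallow training / deep testing: the fixed caller inherits the shallow
cohort's large ratio SD, shrinking deep-sample z-scores (missed trisomies);
the adaptive caller rescales to each sample's own read count.  Deep
training / shallow testing: the fixed caller's small SD inflates shallow
z-scores, flooding the grey zone with euploid samples.
"""

from adanipt.experiments import deep_train_shallow_test, shallow_train_deep_test

up = shallow_train_deep_test(seed=1)
print("train 300k -> test 2M (500 trisomic samples, ff = 0.08):")
print(f"  mean trisomic z: ADAVAR {up['mean_zada_trisomic']:.2f} "
      f"vs FIXVAR {up['mean_zfix_trisomic']:.2f} "
      f"(ratio {up['z_ratio_ada_over_fix']:.2f}; >1 means FIXVAR "
      "under-estimates)")
print(f"  FIXVAR euploid z-SD at 2M: {up['zfix_sd_euploid']:.2f} "
      "(well below 1: variance over-estimated)")

down = deep_train_shallow_test(seed=1)
print("train 2M -> test 300k (2000 euploid samples):")
print(f"  flagged euploid (uninformative+suspect): "
      f"FIXVAR {100 * down['fixvar_flag_rate']:.1f}% "
      f"vs ADAVAR {100 * down['adavar_flag_rate']:.2f}%")
print(f"  ADAVAR specificity: {100 * down['adavar_specificity']:.1f}%")
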