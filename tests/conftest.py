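import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adanipt import ReferenceSelector, SimCohortConfig, simulate_cohort
from adanipt.fixvar import T21_PRODUCTION_REFERENCE
from adanipt.simulator import FixedDepth

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def t21_selector() -> ReferenceSelector:
    return ReferenceSelector(21, T21_PRODUCTION_REFERENCE)


@pytest.fixture(scope="session")
def make_cohort():
    """Factory returning per-autosome count vectors for a simulated cohort."""

    def _make(n_samples, depth, cnv_sd=0.002, seed=0, trisomy_chrom=None,
              fetal_fraction=0.1, **kwargs):
        from adanipt.simulator import FixedFF

        cfg = SimCohortConfig(
            n_samples=n_samples, depth_model=FixedDepth(depth), cnv_sd=cnv_sd,
            trisomy_chrom=trisomy_chrom,
            fetal_fraction_model=FixedFF(fetal_fraction), seed=seed, **kwargs)
        samples, _ = simulate_cohort(cfg)
        return [s.counts for s in samples]

    return _make


@pytest.fixture(scope="session")
def euploid_3m(make_cohort):
    """200 euploid control samples at 3M reads, default CNV jitter."""
    return make_cohort(200, 3_000_000, seed=11)
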