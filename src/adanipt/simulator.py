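"""Synthetic NIPT cohort generator.

Emulates the statistical structure the callers assume: each sample's n
autosomal reads are a multinomial draw over the 22 autosomes; per-sample
multiplicative proportion jitter models random individual copy-number
variation (the depth-independent excess ratio dispersion); an optional
bin-level mode splits chromosome counts over fixed-width bins with a linear
GC bias; trisomy is spiked by scaling the affected chromosome's proportion
by (1 + ff/2), the extra half-dose carried by the fetal fraction ff of
fragments.

Not modeled: fragment lengths, maternal CNV hotspots, sequencing error,
duplicate reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from adanipt.counts_io import (
    N_AUTOSOMES,
    BinCountMatrix,
    ChromCounts,
    tile_bins,
)

logger = logging.getLogger(__name__)

#: hg19 autosome lengths (bp), chr1..chr22.
HG19_AUTOSOME_LENGTHS = np.array([
    249250621, 243199373, 198022430, 191154276, 180915260, 171115067,
    159138663, 146364022, 141213431, 135534747, 135006516, 133851895,
    115169878, 107349540, 102531392, 90354753, 81195210, 78077248,
    59128983, 63025520, 48129895, 51304566,
], dtype=float)


def default_p_baseline() -> np.ndarray:
    """Autosome proportions proportional to hg19 autosome lengths."""
    return HG19_AUTOSOME_LENGTHS / HG19_AUTOSOME_LENGTHS.sum()


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FixedDepth:
    n: int


@dataclass(frozen=True)
class LogNormalDepth:
    """Depths log-normally distributed with the given median and log-SD."""

    median: float
    sigma: float


@dataclass(frozen=True)
class FixedFF:
    ff: float


@dataclass(frozen=True)
class BetaFF:
    a: float
    b: float


@dataclass
class SimCohortConfig:
    """Generative settings for one synthetic cohort.

    Defaults reflect typical shallow-WGS NIPT: ~3M autosomal reads per
    sample, fetal fraction around 10% for trisomic samples, and a small
    multiplicative proportion jitter (cnv_sd = 0.002) producing the
    depth-independent ratio-SD excess seen in euploid cohorts.  cnv_sd = 0
    recovers the exact multinomial null.
    """

    n_samples: int
    depth_model: FixedDepth | LogNormalDepth = field(
        default_factory=lambda: FixedDepth(3_000_000))
    p_baseline: np.ndarray = field(default_factory=default_p_baseline)
    cnv_sd: float = 0.002
    gc_bias_amplitude: float = 0.0
    trisomy_chrom: int | None = None
    fetal_fraction_model: FixedFF | BetaFF = field(default_factory=lambda: FixedFF(0.1))
    bins_per_chrom: int = 0  # 0 = chromosome-level output
    seed: int = 0

    def __post_init__(self):
        self.p_baseline = np.asarray(self.p_baseline, dtype=float)
        if self.p_baseline.shape != (N_AUTOSOMES,):
            raise SimConfigError(f"p_baseline must have length {N_AUTOSOMES}")
        if abs(self.p_baseline.sum() - 1.0) > 1e-9:
            raise SimConfigError("p_baseline must sum to 1")
        if self.n_samples < 0:
            raise SimConfigError("n_samples must be >= 0")
        if self.cnv_sd < 0:
            raise SimConfigError("cnv_sd must be >= 0")
        if self.trisomy_chrom is not None and not (1 <= self.trisomy_chrom <= 22):
            raise SimConfigError("trisomy_chrom must be 1..22")
        if isinstance(self.fetal_fraction_model, FixedFF):
            if not (0.0 <= self.fetal_fraction_model.ff <= 1.0):
                raise SimConfigError("fetal fraction must be in [0,1]")
        if self.bins_per_chrom < 0:
            raise SimConfigError("bins_per_chrom must be >= 0")

    def bin_gc(self) -> np.ndarray:
        """Per-bin GC fractions ~ U(0.3, 0.6), fixed at cohort creation.

        Drawn from a stream derived from the cohort seed alone, so every
        sample of the cohort shares one bin layout.
        """
        if self.bins_per_chrom == 0:
            raise SimConfigError("bin_gc undefined in chromosome-level mode")
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0xB1]))
        return rng.uniform(0.3, 0.6, size=N_AUTOSOMES * self.bins_per_chrom)


@dataclass
class SimSample:
    """One simulated sample with its generating truth."""

    sample_id: str
    truth_label: str  # euploid | trisomic
    ff_true: float
    n_true: int
    counts: ChromCounts
    bin_counts: np.ndarray | None = None  # per-bin counts in bin-level mode


def effective_proportions(p_baseline: np.ndarray, cnv_sd: float,
                          trisomy_chrom: int | None, ff: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Per-sample autosome proportions after CNV jitter and trisomy dosage.

    p'_i = p_i (1 + eps_i), eps_i ~ N(0, cnv_sd) i.i.d.; for a trisomic
    sample the affected chromosome is then scaled by (1 + ff/2); finally the
    vector is renormalized to sum 1.  Draws leaving any proportion
    non-positive are rejected and resampled.
    """
    p = np.asarray(p_baseline, dtype=float)
    for attempt in range(1000):
        eps = rng.normal(0.0, cnv_sd, size=p.shape) if cnv_sd > 0 else np.zeros_like(p)
        p_eff = p * (1.0 + eps)
        if np.all(p_eff > 0):
            break
        if attempt == 10:
            logger.warning("CNV jitter rejected >10 times; cnv_sd=%g is very large", cnv_sd)
    else:
        raise SimConfigError(f"could not draw positive proportions with cnv_sd={cnv_sd}")
    if trisomy_chrom is not None and ff > 0:
        p_eff[trisomy_chrom - 1] *= 1.0 + ff / 2.0
    return p_eff / p_eff.sum()


def _draw_depth(model: FixedDepth | LogNormalDepth, rng: np.random.Generator) -> int:
    if isinstance(model, FixedDepth):
        if model.n <= 0:
            raise SimConfigError("fixed depth must be positive")
        return int(model.n)
    n = rng.lognormal(mean=np.log(model.median), sigma=model.sigma)
    return max(1, int(round(n)))


def _draw_ff(model: FixedFF | BetaFF, rng: np.random.Generator) -> float:
    if isinstance(model, FixedFF):
        return float(model.ff)
    return float(rng.beta(model.a, model.b))


def simulate_sample(config: SimCohortConfig, rng: np.random.Generator,
                    sample_id: str = "sim") -> SimSample:
    """Draw one sample: depth, effective proportions, multinomial counts.

    In bin-level mode each chromosome's count is further split multinomially
    over its bins with weights proportional to
    1 + gc_bias_amplitude * (gc_b - mean chromosome GC).
    """
    trisomic = config.trisomy_chrom is not None
    ff = _draw_ff(config.fetal_fraction_model, rng) if trisomic else 0.0
    n = _draw_depth(config.depth_model, rng)
    p_eff = effective_proportions(config.p_baseline, config.cnv_sd,
                                  config.trisomy_chrom, ff, rng)
    x = rng.multinomial(n, p_eff).astype(float)
    bin_counts = None
    if config.bins_per_chrom > 0:
        gc = config.bin_gc()
        B = config.bins_per_chrom
        bin_counts = np.zeros(N_AUTOSOMES * B)
        for c in range(N_AUTOSOMES):
            g = gc[c * B:(c + 1) * B]
            w = 1.0 + config.gc_bias_amplitude * (g - g.mean())
            w = np.clip(w, 1e-6, None)
            bin_counts[c * B:(c + 1) * B] = rng.multinomial(int(x[c]), w / w.sum())
    return SimSample(sample_id=sample_id,
                     truth_label="trisomic" if trisomic else "euploid",
                     ff_true=ff, n_true=n,
                     counts=ChromCounts(sample_id=sample_id, x=x),
                     bin_counts=bin_counts)


def simulate_cohort(config: SimCohortConfig,
                    id_prefix: str = "S") -> tuple[list[SimSample], pd.DataFrame]:
    """Generate a cohort and its truth table, deterministic under the seed.

    One generator seeded from the cohort seed drives all samples in order,
    so the i-th sample depends only on (seed, i).  Returns the samples and a
    truth DataFrame (sample_id, label, ff_true, n_true, seed).
    """
    samples = []
    for i in range(config.n_samples):
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x5A, i]))
        samples.append(simulate_sample(config, rng, sample_id=f"{id_prefix}{i:04d}"))
    truth = pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "label": [s.truth_label for s in samples],
        "ff_true": [s.ff_true for s in samples],
        "n_true": [s.n_true for s in samples],
        "seed": config.seed,
    }) if samples else pd.DataFrame(
        columns=["sample_id", "label", "ff_true", "n_true", "seed"])
    return samples, truth


def cohort_bin_matrix(config: SimCohortConfig, samples: list[SimSample]) -> BinCountMatrix:
    """Assemble bin-level simulated samples into a BinCountMatrix.

    Bins are laid out 20 kbp wide per chromosome (synthetic coordinates)
    with the cohort's fixed per-bin GC fractions.
    """
    if config.bins_per_chrom == 0:
        raise SimConfigError("cohort was simulated at chromosome level")
    bin_size = 20_000
    bins = tile_bins({c: config.bins_per_chrom * bin_size for c in range(1, 23)},
                     bin_size)
    bins["gc"] = config.bin_gc()
    counts = np.stack([s.bin_counts for s in samples])
    return BinCountMatrix(bins=bins, samples=[s.sample_id for s in samples],
                          counts=counts)


def expected_excess_ratio_sd(p_baseline: np.ndarray, target: int,
                             reference: tuple[int, ...], cnv_sd: float) -> float:
    """Depth-independent ratio SD contributed by the CNV jitter.

    First-order in cnv_sd: Y given the jitter is (q1/q2)(1+eps_t)/(1+delta)
    with delta the reference-weighted jitter mean, so
    SD(Y) ~= (q1/q2) * cnv_sd * sqrt(1 + sum_ref (p_i/q2)^2).
    Useful as an analytic oracle for bias-constant recovery.
    """
    p = np.asarray(p_baseline, dtype=float)
    q1 = p[target - 1]
    ref = np.array([p[c - 1] for c in reference])
    q2 = ref.sum()
    return (q1 / q2) * cnv_sd * float(np.sqrt(1.0 + ((ref / q2) ** 2).sum()))
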