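"""Adaptive-variance z-score (ADAVAR).

Model the allocation of a sample's n autosomal reads as a multinomial draw
over the 22 autosomes with proportions p.  With q1 = p.u (target) and
q2 = p.v (reference set), the chromosome ratio Y = (X.u)/(X.v) has, for
large n, approximately

    mu_ADA(n)    = q1/q2 + q1 / (n q2^2)
    sigma_ADA(n) = sqrt( (1/n) (q1/q2)^2 (1/q1 + 1/q2) )

so both moments adapt to each test sample's own read count.  Real euploid
cohorts show ratio dispersion beyond this multinomial floor — attributed to
inter-individual copy-number variation — and the excess is empirically
near-constant in depth.  A bias constant c, the average gap between
observed and theoretical SD across a grid of subsampled depths, is folded
into the corrected SD (additively by default; quadrature optional):

    sigma_ADAc(n) = sigma_ADA(n) + c        (linear, default)
    sigma_ADAc(n) = sqrt(sigma_ADA(n)^2 + c^2)   (quadrature)
    Z_ADA = (Y - mu_ADA(n)) / sigma_ADAc(n)
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from adanipt.counts_io import N_AUTOSOMES, ChromCounts
from adanipt.fixvar import ModelError, ReferenceSelector, ZCall, chromosome_ratio, classify_z
from adanipt.preprocess import subsample_counts

logger = logging.getLogger(__name__)


def estimate_proportions(train: list[ChromCounts]) -> np.ndarray:
    """Autosome proportions p as the unweighted mean of per-sample proportions.

    Each training sample contributes equally regardless of its depth, which
    keeps the estimate robust to uneven coverage.  Requires >= 20 euploid
    samples; any sample with zero total reads is an error.
    """
    if len(train) < 20:
        raise ModelError(f"need >= 20 training samples, have {len(train)}")
    props = []
    for s in train:
        if s.n <= 0:
            raise ModelError(f"sample {s.sample_id} has non-positive total count")
        props.append(s.x / s.n)
    p = np.mean(props, axis=0)
    return p / p.sum()


def adavar_mean(n: float, q1: float, q2: float) -> float:
    """Approximate mean of Y at total read count n: q1/q2 + q1/(n q2^2).

    The 1/n term is negligible at production depths but included for
    fidelity to the second-order expansion.
    """
    _check_nq(n, q1, q2)
    return q1 / q2 + q1 / (n * q2 * q2)


def adavar_sigma(n: float, q1: float, q2: float) -> float:
    """Approximate SD of Y at total read count n.

    Equals the delta-method SD of a ratio of jointly multinomial sums with
    Cov(U, V) = -n q1 q2; scales as 1/sqrt(n).
    """
    _check_nq(n, q1, q2)
    return math.sqrt((1.0 / n) * (q1 / q2) ** 2 * (1.0 / q1 + 1.0 / q2))


def _check_nq(n: float, q1: float, q2: float) -> None:
    if not n >= 1:
        raise ModelError(f"n must be >= 1, got {n}")
    if not (0 < q1 < 1 and 0 < q2 < 1):
        raise ModelError(f"q1, q2 must lie in (0,1), got q1={q1}, q2={q2}")


def combine_sigma(sigma_ada: float, c: float, mode: str = "linear") -> float:
    """Fold the bias constant into the theoretical SD.

    linear (default): sigma_ada + c — since c is the *average of SD
    differences*, adding it back is the first-order-consistent correction
    whenever the multinomial floor is comparable to the excess;
    quadrature: sqrt(sigma_ada^2 + c^2) — treats c as an independent SD,
    exact only when c is estimated in a regime where it dominates the
    multinomial floor.
    """
    if not sigma_ada > 0:
        raise ModelError(f"sigma_ada must be positive, got {sigma_ada}")
    if c < 0:
        raise ModelError(f"c must be >= 0, got {c}")
    if mode == "quadrature":
        return math.sqrt(sigma_ada * sigma_ada + c * c)
    if mode == "linear":
        return sigma_ada + c
    raise ModelError(f"unknown combine mode {mode!r}")


@dataclass
class DeviationProfile:
    """Observed vs theoretical ratio SD across a grid of subsampled depths."""

    depths: np.ndarray
    observed_sd: np.ndarray
    theoretical_sd: np.ndarray

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.observed_sd = np.asarray(self.observed_sd, dtype=float)
        self.theoretical_sd = np.asarray(self.theoretical_sd, dtype=float)
        if not (len(self.depths) == len(self.observed_sd) == len(self.theoretical_sd)):
            raise ModelError("profile arrays must have equal length")
        if len(self.depths) == 0:
            raise ModelError("profile is empty")
        if np.any(np.diff(self.depths) <= 0):
            raise ModelError("depths must be strictly increasing")

    @property
    def differences(self) -> np.ndarray:
        return self.observed_sd - self.theoretical_sd


@dataclass
class AdavarModel:
    """Trained adaptive-variance model.

    Stores the selector, the autosome proportion vector p, the induced
    q1 = p.u and q2 = p.v, the bias constant c, the SD combination mode,
    and the depth grid c was estimated on.
    """

    selector: ReferenceSelector
    p: np.ndarray
    c: float
    combine_mode: str = "linear"
    depth_grid: list[int] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (N_AUTOSOMES,):
            raise ModelError(f"p must have length {N_AUTOSOMES}")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ModelError(f"p must sum to 1, sums to {self.p.sum()}")
        if self.c < 0:
            raise ModelError("c must be >= 0")
        q1, q2 = self.q1, self.q2
        if not (0 < q1 < q2 < 1 and q1 + q2 <= 1):
            raise ModelError(f"invalid q1={q1}, q2={q2}")
        if self.combine_mode not in ("quadrature", "linear"):
            raise ModelError(f"unknown combine mode {self.combine_mode!r}")

    @property
    def q1(self) -> float:
        return float(self.p @ self.selector.u)

    @property
    def q2(self) -> float:
        return float(self.p @ self.selector.v)

    def to_json(self) -> str:
        from adanipt import __version__

        return json.dumps({
            "model": "ADAVAR",
            "target": self.selector.target,
            "reference": list(self.selector.reference),
            "p": [float(v) for v in self.p],
            "q1": self.q1,
            "q2": self.q2,
            "c": self.c,
            "combine_mode": self.combine_mode,
            "depth_grid": [int(d) for d in self.depth_grid],
            "seed": self.seed,
            "version": __version__,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AdavarModel":
        d = json.loads(text)
        if d.get("model") != "ADAVAR":
            raise ModelError(f"not an ADAVAR model: {d.get('model')!r}")
        return cls(selector=ReferenceSelector(d["target"], tuple(d["reference"])),
                   p=np.array(d["p"]), c=d["c"],
                   combine_mode=d.get("combine_mode", "linear"),
                   depth_grid=list(d.get("depth_grid", [])), seed=d.get("seed"))


def _subsample_rng(seed: int, depth: int, sample_index: int) -> np.random.Generator:
    # deterministic, independent stream per (master seed, depth, sample)
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(depth),
                                                         int(sample_index)]))


def build_deviation_profile(train: list[ChromCounts], selector: ReferenceSelector,
                            p: np.ndarray, depth_grid: list[int],
                            seed: int) -> DeviationProfile:
    """Measure observed vs theoretical ratio SD at each depth of a grid.

    Every training sample is subsampled (without replacement) to each depth,
    the ratio Y computed per subsample, and its sample SD across samples
    compared with sigma_ADA at that depth.  Subsampling seeds derive
    deterministically from (seed, depth, sample index), so profiles are
    reproducible and draws are independent across depths.
    """
    depths = sorted(int(d) for d in depth_grid)
    if not depths:
        raise ModelError("depth grid is empty")
    if len(set(depths)) != len(depths):
        raise ModelError("depth grid has duplicates")
    for s in train:
        if s.n < depths[-1]:
            raise ModelError(
                f"sample {s.sample_id} has n={s.n:.0f} < max depth {depths[-1]}")
    q1 = float(p @ selector.u)
    q2 = float(p @ selector.v)
    observed, theoretical = [], []
    for d in depths:
        ys = []
        for i, s in enumerate(train):
            sub = subsample_counts(s, d, _subsample_rng(seed, d, i))
            ys.append(chromosome_ratio(sub, selector))
        observed.append(float(np.std(ys, ddof=1)))
        theoretical.append(adavar_sigma(d, q1, q2))
    return DeviationProfile(depths=np.array(depths, dtype=float),
                            observed_sd=np.array(observed),
                            theoretical_sd=np.array(theoretical))


def estimate_bias_constant(profile: DeviationProfile) -> float:
    """c = average of (observed - theoretical) SD differences, floored at 0."""
    c = float(profile.differences.mean())
    if c < 0:
        logger.warning(
            "mean deviation difference is negative (%.3g); flooring c at 0 — "
            "the multinomial SD already over-covers this cohort", c)
        return 0.0
    return c


def default_depth_grid(train: list[ChromCounts], n_depths: int = 8) -> list[int]:
    """Log-spaced depth grid for bias-constant estimation.

    Spans from 1M reads up to the cohort's shallowest sample (so every
    training sample can be subsampled to every depth); for cohorts
    shallower than 1M the lower edge falls back to a tenth of the
    shallowest sample.
    """
    hi = int(min(s.n for s in train))
    if hi < 100:
        raise ModelError(f"cohort minimum depth {hi} too shallow for a depth grid")
    lo = 1_000_000 if hi > 1_000_000 else max(hi // 10, 100)
    grid = np.unique(np.round(np.geomspace(lo, hi, n_depths)).astype(int))
    return [int(d) for d in grid]


def adavar_train(train: list[ChromCounts], selector: ReferenceSelector,
                 depth_grid: list[int] | None = None,
                 combine_mode: str = "linear",
                 seed: int = 0) -> AdavarModel:
    """Fit p, (q1, q2) and the bias constant c from euploid controls.

    All trained parameters are properties of the cohort's chromosomal
    proportions and its depth-independent excess dispersion; none depend on
    the depth of future test samples.
    """
    if not train:
        raise ModelError("empty training set")
    p = estimate_proportions(train)
    if depth_grid is None:
        depth_grid = default_depth_grid(train)
    profile = build_deviation_profile(train, selector, p, depth_grid, seed)
    c = estimate_bias_constant(profile)
    return AdavarModel(selector=selector, p=p, c=c, combine_mode=combine_mode,
                       depth_grid=[int(d) for d in sorted(depth_grid)], seed=seed)


def adavar_zscore(sample: ChromCounts, model: AdavarModel,
                  lower: float = 2.5, upper: float = 4.0) -> ZCall:
    """Z_ADA for one sample, using the sample's own total read count.

    mu and sigma are evaluated at the sample's n (never a training depth),
    sigma is combined with the bias constant, and the z-score classified
    against the grey zone.
    """
    n = sample.n
    if n <= 0:
        raise ModelError(f"sample {sample.sample_id} has non-positive total count")
    y = chromosome_ratio(sample, model.selector)
    mu = adavar_mean(n, model.q1, model.q2)
    sigma = combine_sigma(adavar_sigma(n, model.q1, model.q2), model.c,
                          model.combine_mode)
    z = (y - mu) / sigma
    call, direction = classify_z(z, lower, upper)
    return ZCall(z=z, call=call, model_tag="ADAVAR", direction=direction)
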