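"""Fixed-variance NCV z-score (FIXVAR).

The normalized chromosomal value compares a sample's chromosome ratio
Y = (X.u)/(X.v) — target autosome over a reference set — with the mean and
standard deviation of Y in a euploid training population.  The reference
set is chosen to minimize the coefficient of variation of Y over the
training samples.  Grey-zone classification (shared with ADAVAR) maps z to
euploid / uninformative / aneuploidy-suspect.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from adanipt.counts_io import N_AUTOSOMES, ChromCounts

COMMON_TRISOMY_CHROMS = (13, 18, 21)

#: Reference autosomes used in production for trisomy 21, determined by CV
#: minimization on a large clinical euploid cohort.  Provided as a sensible
#: default when no training cohort is available for selection.
T21_PRODUCTION_REFERENCE = (1, 4, 8, 10, 19, 20)


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceSelector:
    """Binary selectors u (target autosome) and v (reference set).

    Constraints: u picks exactly one autosome; v is non-empty, disjoint
    from u, and never contains the common trisomic autosomes 13, 18, 21.
    """

    target: int
    reference: tuple[int, ...]

    def __post_init__(self):
        if not (1 <= self.target <= N_AUTOSOMES):
            raise ModelError(f"target must be 1..22, got {self.target}")
        ref = tuple(sorted(set(int(c) for c in self.reference)))
        object.__setattr__(self, "reference", ref)
        if not ref:
            raise ModelError("reference set must be non-empty")
        if any(not 1 <= c <= N_AUTOSOMES for c in ref):
            raise ModelError(f"reference chromosomes out of range: {ref}")
        if self.target in ref:
            raise ModelError("target chromosome cannot be in the reference set")
        bad = set(ref) & set(COMMON_TRISOMY_CHROMS)
        if bad:
            raise ModelError(
                f"common trisomic chromosomes {sorted(bad)} are excluded from reference sets")

    @property
    def u(self) -> np.ndarray:
        u = np.zeros(N_AUTOSOMES)
        u[self.target - 1] = 1.0
        return u

    @property
    def v(self) -> np.ndarray:
        v = np.zeros(N_AUTOSOMES)
        v[[c - 1 for c in self.reference]] = 1.0
        return v


@dataclass
class ZCall:
    """A z-score with its grey-zone classification."""

    z: float
    call: str  # euploid | uninformative | aneuploidy_suspect
    model_tag: str  # FIXVAR | ADAVAR
    direction: str | None = None  # "high"/"low" for suspect calls


@dataclass
class FixvarModel:
    """Trained fixed-variance model: selector plus (mu_fix, sigma_fix)."""

    selector: ReferenceSelector
    mu_fix: float
    sigma_fix: float
    train_depths: dict = field(default_factory=dict)  # min/median/max of training n

    def __post_init__(self):
        if not self.sigma_fix > 0:
            raise ModelError(f"sigma_fix must be positive, got {self.sigma_fix}")
        if not self.mu_fix > 0:
            raise ModelError(f"mu_fix must be positive, got {self.mu_fix}")

    def to_json(self) -> str:
        from adanipt import __version__

        return json.dumps({
            "model": "FIXVAR",
            "target": self.selector.target,
            "reference": list(self.selector.reference),
            "mu_fix": self.mu_fix,
            "sigma_fix": self.sigma_fix,
            "train_depths": self.train_depths,
            "version": __version__,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FixvarModel":
        d = json.loads(text)
        if d.get("model") != "FIXVAR":
            raise ModelError(f"not a FIXVAR model: {d.get('model')!r}")
        return cls(selector=ReferenceSelector(d["target"], tuple(d["reference"])),
                   mu_fix=d["mu_fix"], sigma_fix=d["sigma_fix"],
                   train_depths=d.get("train_depths", {}))


def chromosome_ratio(sample: ChromCounts, selector: ReferenceSelector) -> float:
    """Y = (X.u)/(X.v): target autosome count over summed reference counts."""
    num = float(sample.x[selector.target - 1])
    den = float(sum(sample.x[c - 1] for c in selector.reference))
    if den <= 0:
        raise ModelError(
            f"zero or negative reference mass for sample {sample.sample_id}")
    return num / den


def _ratio_matrix(train: list[ChromCounts]) -> np.ndarray:
    return np.stack([s.x for s in train])


def select_reference_set(train: list[ChromCounts], target_chrom: int,
                         strategy: str = "exhaustive") -> ReferenceSelector:
    """Choose the reference set minimizing CV(Y) = sd(Y)/mean(Y) on training.

    Eligible reference chromosomes are all autosomes except the target and
    the common trisomic autosomes 13/18/21.  ``"exhaustive"`` enumerates
    every non-empty subset (vectorized, chunked); ``"greedy"`` does forward
    selection, stopping when CV no longer improves.  Ties are broken by
    smaller set size, then lexicographically by chromosome numbers.
    The sample standard deviation (N-1 denominator) is used throughout.
    """
    if len(train) < 20:
        raise ModelError(f"need >= 20 training samples, have {len(train)}")
    if not (1 <= target_chrom <= N_AUTOSOMES):
        raise ModelError(f"target_chrom must be 1..22, got {target_chrom}")
    eligible = [c for c in range(1, N_AUTOSOMES + 1)
                if c != target_chrom and c not in COMMON_TRISOMY_CHROMS]
    X = _ratio_matrix(train)
    t = X[:, target_chrom - 1]  # (samples,)
    E = X[:, [c - 1 for c in eligible]]  # (samples, n_eligible)

    def cv_of(S: np.ndarray) -> np.ndarray:
        """CV of Y = t/S per column of S (subsets); invalid -> inf."""
        with np.errstate(divide="ignore", invalid="ignore"):
            Y = t[:, None] / S
            mean = Y.mean(axis=0)
            sd = Y.std(axis=0, ddof=1)
            cv = sd / mean
        bad = ~np.isfinite(cv) | (S <= 0).any(axis=0) | (mean <= 0)
        cv[bad] = np.inf
        return cv

    rel_tol = 1e-12

    if strategy == "exhaustive":
        m = len(eligible)
        best_cv = np.inf
        best_key: tuple | None = None
        best_set: tuple[int, ...] | None = None
        chunk = 1 << 14
        for lo in range(1, (1 << m), chunk):
            masks = np.arange(lo, min(lo + chunk, 1 << m), dtype=np.int64)
            members = ((masks[:, None] >> np.arange(m)) & 1).astype(float)
            cv = cv_of(E @ members.T)
            # examine every subset tying (within fp tolerance) the chunk optimum
            cmin = cv.min()
            if not np.isfinite(cmin) or cmin > best_cv * (1 + rel_tol):
                continue
            for k in np.flatnonzero(cv <= cmin * (1 + rel_tol)):
                subset = tuple(eligible[b] for b in range(m) if (masks[k] >> b) & 1)
                key = (len(subset), subset)
                if cv[k] < best_cv * (1 - rel_tol) or best_key is None:
                    best_cv, best_key, best_set = cv[k], key, subset
                elif cv[k] <= best_cv * (1 + rel_tol) and key < best_key:
                    best_cv, best_key, best_set = min(best_cv, cv[k]), key, subset
        if best_set is None:
            raise ModelError("no valid reference subset found")
        return ReferenceSelector(target_chrom, best_set)

    if strategy == "greedy":
        current: list[int] = []
        current_cv = np.inf
        remaining = list(eligible)
        while remaining:
            S = np.stack([E[:, [eligible.index(c) for c in current + [r]]].sum(axis=1)
                          for r in remaining], axis=1)
            cv = cv_of(S)
            k = int(np.argmin(cv))  # argmin keeps first (smallest chromosome) on ties
            if cv[k] >= current_cv * (1 - rel_tol):
                break
            current.append(remaining.pop(k))
            current_cv = cv[k]
        if not current:
            raise ModelError("greedy selection found no improving chromosome")
        return ReferenceSelector(target_chrom, tuple(sorted(current)))

    raise ModelError(f"unknown strategy {strategy!r}")


def fixvar_train(train: list[ChromCounts], selector: ReferenceSelector) -> FixvarModel:
    """Estimate (mu_fix, sigma_fix) as mean and sample SD of Y over controls."""
    if len(train) < 3:
        raise ModelError(f"need >= 3 training samples, have {len(train)}")
    y = np.array([chromosome_ratio(s, selector) for s in train])
    mu = float(y.mean())
    sigma = float(y.std(ddof=1))
    if sigma <= 0:
        raise ModelError("training ratios have zero variance")
    depths = np.array([s.n for s in train])
    return FixvarModel(selector=selector, mu_fix=mu, sigma_fix=sigma,
                       train_depths={"min": float(depths.min()),
                                     "median": float(np.median(depths)),
                                     "max": float(depths.max())})


def classify_z(z: float, lower: float = 2.5, upper: float = 4.0) -> tuple[str, str | None]:
    """Grey-zone classification of a z-score.

    z >= upper -> aneuploidy_suspect (high); z <= -upper -> aneuploidy_suspect
    (low); |z| in the open interval (lower, upper) -> uninformative (the grey
    zone, mirrored on the negative side); otherwise euploid.  Boundaries are
    inclusive toward the definite calls: z == upper is suspect, z == lower is
    euploid.
    """
    if not (lower < upper):
        raise ModelError(f"thresholds must satisfy lower < upper, got {lower}, {upper}")
    if math.isnan(z):
        raise ModelError("z-score is NaN")
    if z >= upper:
        return "aneuploidy_suspect", "high"
    if z <= -upper:
        return "aneuploidy_suspect", "low"
    if lower < z < upper or -upper < z < -lower:
        return "uninformative", None
    return "euploid", None


def fixvar_zscore(sample: ChromCounts, model: FixvarModel,
                  lower: float = 2.5, upper: float = 4.0) -> ZCall:
    """ZFIX = (Y - mu_fix)/sigma_fix with grey-zone classification."""
    y = chromosome_ratio(sample, model.selector)
    z = (y - model.mu_fix) / model.sigma_fix
    call, direction = classify_z(z, lower, upper)
    return ZCall(z=z, call=call, model_tag="FIXVAR", direction=direction)
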