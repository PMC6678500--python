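"""Count corrections applied before z-scoring.

Per-sample GC LOESS correction, cohort-level PCA denoising fitted on
euploid controls, aggregation of bin counts to per-autosome vectors, and
uniform read subsampling to a target depth.  Intra-run normalization is
deliberately not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from adanipt.counts_io import N_AUTOSOMES, BinCountMatrix, ChromCounts


class PreprocessError(ValueError):
    pass


@dataclass
class GcCorrectionFit:
    """Per-sample LOESS fit of expected bin count versus GC fraction.

    ``gc_grid``/``fitted_grid`` tabulate the smoothed curve over the
    observed GC range (evaluation interpolates linearly between fitted
    points); ``rc_avg`` is the global mean raw count over retained bins.
    """

    loess_span: float
    gc_grid: np.ndarray
    fitted_grid: np.ndarray
    rc_avg: float

    def predict(self, gc: np.ndarray) -> np.ndarray:
        """Expected count at each GC value (flat extrapolation at the edges)."""
        return np.interp(np.asarray(gc, dtype=float), self.gc_grid, self.fitted_grid)


@dataclass
class PcaDenoiser:
    """Top principal directions of euploid-control bin proportions.

    ``components`` has shape (n_components, n_retained_bins) and is
    orthonormal; ``bin_means`` is the centering vector in proportion space.
    A denoiser with zero components is the identity.
    """

    n_components: int
    bin_means: np.ndarray
    components: np.ndarray
    mask: np.ndarray  # retained-bin mask the fit was made on


def filter_empty_bins(matrix: BinCountMatrix,
                      min_nonzero_fraction: float = 1.0) -> BinCountMatrix:
    """Mask out empty bins.

    A bin is retained when the fraction of samples with a nonzero count in
    it is at least ``min_nonzero_fraction``.  The default of 1.0 drops a bin
    that is zero in *any* sample; 0 disables filtering.  Counts themselves
    are never modified.
    """
    if not (0.0 <= min_nonzero_fraction <= 1.0):
        raise PreprocessError(
            f"min_nonzero_fraction must be in [0,1], got {min_nonzero_fraction}")
    out = matrix.copy()
    if min_nonzero_fraction > 0 and out.n_samples > 0:
        nonzero_frac = (out.counts != 0).mean(axis=0)
        out.mask &= nonzero_frac >= min_nonzero_fraction
    if not out.mask.any():
        raise PreprocessError("no informative bins after empty-bin filtering")
    return out


def fit_gc_loess(matrix: BinCountMatrix, sample: int | str = 0,
                 span: float = 0.3) -> GcCorrectionFit:
    """Fit a LOESS curve of bin count on GC fraction for one sample.

    Only retained (masked-in) bins enter the fit.  Requires at least 50
    retained bins and a non-degenerate GC range.
    """
    j = matrix.samples.index(sample) if isinstance(sample, str) else sample
    gc = matrix.bins["gc"].to_numpy(dtype=float)[matrix.mask]
    rc = matrix.counts[j, matrix.mask]
    if np.isnan(gc).any():
        raise PreprocessError("GC fractions unavailable (NaN); supply a reference FASTA")
    if gc.size < 50:
        raise PreprocessError(f"need >= 50 retained bins for LOESS, have {gc.size}")
    if np.ptp(gc) < 1e-9:
        raise PreprocessError(
            "all GC fractions identical; GC correction is undefined — skip it")
    if not (0 < span <= 1):
        raise PreprocessError(f"span must be in (0,1], got {span}")
    # delta skips near-duplicate abscissae; 1% of the GC range is far below
    # any structure the smoother can resolve at this span
    sm = lowess(rc, gc, frac=span, it=2, delta=0.01 * np.ptp(gc),
                return_sorted=True)
    gc_grid, fitted = sm[:, 0], sm[:, 1]
    # collapse duplicate grid abscissae so interpolation is well defined
    uniq, idx = np.unique(gc_grid, return_inverse=True)
    fitted_u = np.bincount(idx, weights=fitted) / np.bincount(idx)
    return GcCorrectionFit(loess_span=span, gc_grid=uniq, fitted_grid=fitted_u,
                           rc_avg=float(rc.mean()))


def apply_gc_correction(matrix: BinCountMatrix, fit: GcCorrectionFit,
                        sample: int | str = 0,
                        mode: str = "signed") -> BinCountMatrix:
    """Subtract the GC-predicted deviation from one sample's bin counts.

    ``mode="signed"`` (default) uses RCcor = RC - (RCloess - RCavg), which
    removes the GC trend in both directions; ``mode="as_printed"`` uses
    RCcor = RC - |RCloess - RCavg|, which always subtracts.  Corrected
    counts may be negative; they are not clipped, since clipping would bias
    chromosome proportions.
    """
    if mode not in ("signed", "as_printed"):
        raise PreprocessError(f"unknown GC-correction mode {mode!r}")
    j = matrix.samples.index(sample) if isinstance(sample, str) else sample
    out = matrix.copy()
    gc = out.bins["gc"].to_numpy(dtype=float)
    deviation = fit.predict(gc) - fit.rc_avg
    if mode == "as_printed":
        deviation = np.abs(deviation)
    out.counts[j] = out.counts[j] - np.where(out.mask, deviation, 0.0)
    if "gc" not in out.corrected:
        out.corrected.append("gc")
    return out


def gc_correct_matrix(matrix: BinCountMatrix, span: float = 0.3,
                      mode: str = "signed") -> BinCountMatrix:
    """GC-correct every sample of a matrix (per-sample fits)."""
    out = matrix
    for j in range(matrix.n_samples):
        fit = fit_gc_loess(out, sample=j, span=span)
        out = apply_gc_correction(out, fit, sample=j, mode=mode)
    return out


def _proportions(matrix: BinCountMatrix) -> np.ndarray:
    sub = matrix.counts[:, matrix.mask]
    totals = sub.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise PreprocessError("sample with non-positive total retained count")
    return sub / totals


def fit_pca_denoiser(train_matrix: BinCountMatrix, n_components: int = 5) -> PcaDenoiser:
    """Fit the top principal directions of euploid-control bin proportions.

    Counts are normalized per sample to proportions before fitting so that
    depth differences do not dominate the leading components.  Requires at
    least ``n_components + 2`` training samples and full numerical rank in
    the requested subspace.
    """
    if n_components < 0:
        raise PreprocessError("n_components must be >= 0")
    mask = train_matrix.mask.copy()
    if n_components == 0:
        return PcaDenoiser(0, np.zeros(int(mask.sum())),
                           np.empty((0, int(mask.sum()))), mask)
    if train_matrix.n_samples < n_components + 2:
        raise PreprocessError(
            f"need >= {n_components + 2} training samples for "
            f"{n_components} components, have {train_matrix.n_samples}")
    from sklearn.decomposition import PCA

    props = _proportions(train_matrix)
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(props)
    if np.any(pca.explained_variance_ < 1e-18):
        raise PreprocessError(
            "training matrix is rank-deficient for the requested number of components")
    return PcaDenoiser(n_components=n_components,
                       bin_means=pca.mean_.copy(),
                       components=pca.components_.copy(),
                       mask=mask)


def apply_pca_denoise(matrix: BinCountMatrix, denoiser: PcaDenoiser) -> BinCountMatrix:
    """Remove the stored principal directions from every sample.

    Each sample's retained-bin proportion vector is centered, its projection
    onto the stored components subtracted, and the result mapped back to
    count scale by the sample's retained total.  Idempotent: applying twice
    equals applying once.
    """
    if denoiser.mask.shape != matrix.mask.shape or not np.array_equal(
            denoiser.mask, matrix.mask):
        raise PreprocessError("bin set/mask differs from the one the denoiser was fit on")
    out = matrix.copy()
    if denoiser.n_components == 0:
        if "pca" not in out.corrected:
            out.corrected.append("pca")
        return out
    sub = out.counts[:, out.mask]
    totals = sub.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise PreprocessError("sample with non-positive total retained count")
    props = sub / totals
    centered = props - denoiser.bin_means
    proj = centered @ denoiser.components.T @ denoiser.components
    out.counts[:, out.mask] = (props - proj) * totals
    if "pca" not in out.corrected:
        out.corrected.append("pca")
    return out


def aggregate_to_chromosomes(matrix: BinCountMatrix) -> list[ChromCounts]:
    """Sum retained bin counts per autosome for every sample."""
    chroms = matrix.bins["chrom"].to_numpy()
    out = []
    for j, sid in enumerate(matrix.samples):
        x = np.zeros(N_AUTOSOMES)
        np.add.at(x, chroms[matrix.mask] - 1, matrix.counts[j, matrix.mask])
        out.append(ChromCounts(sample_id=sid, x=x))
    return out


def subsample_counts(sample: ChromCounts, n_target: int,
                     seed: int | np.random.Generator,
                     method: str = "hypergeometric") -> ChromCounts:
    """Uniformly subsample a sample's reads to ``n_target``.

    The default draws without replacement (multivariate hypergeometric), so
    the output sums to ``n_target`` exactly and per-chromosome variances
    carry the finite-population correction.  ``method="multinomial"`` draws
    with replacement, an approximation useful at very large n.
    Deterministic given the seed.
    """
    if not sample.is_integer():
        raise PreprocessError("subsampling requires integer read counts")
    x = np.round(sample.x).astype(np.int64)
    n = int(x.sum())
    if not (0 < n_target <= n):
        raise PreprocessError(
            f"n_target must be in (0, {n}], got {n_target} for sample {sample.sample_id}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_target == n:
        sub = x.copy()
    elif method == "hypergeometric":
        sub = rng.multivariate_hypergeometric(x, n_target)
    elif method == "multinomial":
        sub = rng.multinomial(n_target, x / n)
    else:
        raise PreprocessError(f"unknown subsampling method {method!r}")
    return ChromCounts(sample_id=sample.sample_id, x=sub.astype(float))
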