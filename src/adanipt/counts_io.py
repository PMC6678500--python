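"""Read-count ingestion and tabular I/O.

Internal conventions: autosomes only (labels 1..22), coordinates 0-based
half-open, fixed-width bins tiling each chromosome in order with the last
bin truncated at the chromosome end.  Chromosome-name dialects ``"1"`` and
``"chr1"`` are both accepted on input and normalized to bare ``1..22``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_AUTOSOMES = 22
AUTOSOME_LABELS = [str(i) for i in range(1, 23)]

BIN_TSV_FIXED_COLS = ["chrom", "start", "end", "gc"]
CHROM_TSV_COLS = ["sample_id"] + [f"chr{i}" for i in range(1, 23)]


class CountsIOError(ValueError):
    """Malformed count table or alignment input."""


def normalize_chrom(name: str) -> int | None:
    """Map a reference name to an autosome number 1..22, or None.

    Accepts "7" and "chr7"; sex chromosomes, mitochondria and scaffolds
    return None (callers skip or reject them as appropriate).
    """
    s = str(name)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.isdigit() and 1 <= int(s) <= 22:
        return int(s)
    if s in ("X", "Y", "M", "MT", "x", "y"):
        return None
    return None


@dataclass(frozen=True)
class GenomicBin:
    """A fixed-width genomic interval used as the unit of read counting.

    ``chrom`` is the autosome number (1..22), ``start``/``end`` are 0-based
    half-open base-pair coordinates, ``gc_fraction`` the G+C fraction of the
    bin's reference sequence (NaN when no reference was supplied).
    """

    chrom: int
    start: int
    end: int
    gc_fraction: float = float("nan")

    def __post_init__(self):
        if not (1 <= self.chrom <= 22):
            raise CountsIOError(f"chrom must be 1..22, got {self.chrom}")
        if self.end <= self.start:
            raise CountsIOError(
                f"bin end must exceed start: {self.chrom}:{self.start}-{self.end}")
        g = self.gc_fraction
        if not np.isnan(g) and not (0.0 <= g <= 1.0):
            raise CountsIOError(f"gc_fraction out of [0,1]: {g}")


@dataclass
class BinCountMatrix:
    """Samples x bins count matrix with a retained-bin mask.

    ``bins`` is a DataFrame with columns chrom, start, end, gc (one row per
    bin, shared by all samples); ``counts`` has shape
    (n_samples, n_bins) — integer-valued before correction, real after;
    ``mask`` marks bins retained after empty-bin filtering.  Masked-out bins
    are excluded from every downstream statistic.
    """

    bins: pd.DataFrame
    samples: list[str]
    counts: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    corrected: list[str] = field(default_factory=list)  # e.g. ["gc", "pca"]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise CountsIOError("counts must be 2-D (samples x bins)")
        if self.counts.shape != (len(self.samples), len(self.bins)):
            raise CountsIOError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.bins)} bins")
        if self.mask is None:
            self.mask = np.ones(len(self.bins), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (len(self.bins),):
            raise CountsIOError("mask length must equal number of bins")
        if not self.corrected and len(self.counts) and (self.counts < 0).any():
            raise CountsIOError("raw counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def copy(self) -> "BinCountMatrix":
        return BinCountMatrix(
            bins=self.bins.copy(),
            samples=list(self.samples),
            counts=self.counts.copy(),
            mask=self.mask.copy(),
            corrected=list(self.corrected),
        )


@dataclass
class ChromCounts:
    """Per-sample autosomal read-count vector.

    ``x`` holds reads (or corrected reads) for autosomes 1..22 in order;
    ``n`` is the total.  Sex chromosomes are deliberately absent: their
    mapping ratio differs between male and female fetuses.
    """

    sample_id: str
    x: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (N_AUTOSOMES,):
            raise CountsIOError(
                f"expected {N_AUTOSOMES} autosome counts, got shape {self.x.shape}")

    @property
    def n(self) -> float:
        return float(self.x.sum())

    def is_integer(self) -> bool:
        return bool(np.all(self.x == np.round(self.x)))


def tile_bins(chrom_lengths: dict[int, int], bin_size: int) -> pd.DataFrame:
    """Tile each autosome with fixed-width bins (last bin truncated)."""
    if bin_size < 1000:
        raise CountsIOError(f"bin_size must be >= 1000, got {bin_size}")
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e), np.nan))
    return pd.DataFrame(rows, columns=BIN_TSV_FIXED_COLS)


def _gc_from_fasta(bins: pd.DataFrame, fasta_path: str) -> np.ndarray:
    from pyfaidx import Fasta

    fa = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    name_map: dict[int, str] = {}
    for ref in fa.keys():
        c = normalize_chrom(ref)
        if c is not None:
            name_map[c] = ref
    gc = np.full(len(bins), np.nan)
    for i, row in enumerate(bins.itertuples(index=False)):
        ref = name_map.get(int(row.chrom))
        if ref is None:
            continue
        seq = str(fa[ref][int(row.start):int(row.end)])
        if not seq:
            continue
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt == 0:
            continue
        gc[i] = (seq.count("G") + seq.count("C")) / acgt
    return gc


def bin_alignments(
    alignment_path: str,
    bin_size: int = 20_000,
    mapq_min: int = 40,
    fasta_path: str | None = None,
    sample_id: str | None = None,
) -> BinCountMatrix:
    """Count retained alignments per fixed-width autosomal bin.

    Each retained alignment increments exactly one bin, chosen by its
    leftmost mapped coordinate.  Unmapped, secondary, supplementary and
    duplicate-flagged records are skipped, as are alignments below
    ``mapq_min`` (default 40) and any on sex chromosomes.  Reference names
    that are neither autosomes nor recognized non-autosomes (X/Y/M,
    scaffolds with standard prefixes) raise a named-contig error.

    If ``fasta_path`` is given, per-bin GC fractions are computed from the
    reference sequence; otherwise they are NaN and GC correction is
    unavailable.
    """
    import pysam

    try:
        af = pysam.AlignmentFile(alignment_path, check_sq=False)
    except (OSError, ValueError) as exc:
        raise CountsIOError(f"cannot open alignment file {alignment_path}: {exc}") from exc

    with af:
        chrom_lengths: dict[int, int] = {}
        ref_to_autosome: dict[str, int | None] = {}
        for ref, length in zip(af.references, af.lengths):
            c = normalize_chrom(ref)
            ref_to_autosome[ref] = c
            if c is not None:
                chrom_lengths[c] = length
            else:
                s = ref[3:] if ref.lower().startswith("chr") else ref
                if s not in ("X", "Y", "M", "MT", "x", "y") and not any(
                    tok in ref for tok in ("_", "Un", "GL", "KI", "random", "alt", "decoy", "EBV")
                ):
                    raise CountsIOError(
                        f"reference name {ref!r} is not mappable to an autosome 1..22")
        if not chrom_lengths:
            raise CountsIOError("no autosome references in alignment header")

        bins = tile_bins(chrom_lengths, bin_size)
        # index of first bin per chromosome for O(1) bin lookup
        first_bin = {c: int((bins["chrom"] < c).sum()) for c in chrom_lengths}
        counts = np.zeros(len(bins), dtype=np.int64)

        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                continue
            if rec.mapping_quality < mapq_min:
                continue
            c = ref_to_autosome.get(rec.reference_name)
            if c is None:
                continue
            counts[first_bin[c] + rec.reference_start // bin_size] += 1

    if fasta_path is not None:
        bins["gc"] = _gc_from_fasta(bins, fasta_path)

    sid = sample_id or str(alignment_path)
    return BinCountMatrix(bins=bins, samples=[sid], counts=counts[None, :].astype(float))


def _header_lines(params: dict | None = None) -> list[str]:
    from adanipt import __version__

    line = f"# adanipt v{__version__}"
    if params:
        line += " " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return [line]


def write_bin_counts(matrix: BinCountMatrix, path: str, params: dict | None = None) -> None:
    """Write a bin-count matrix as TSV (chrom, start, end, gc, one column per sample)."""
    params = dict(params or {})
    if matrix.corrected:
        params["corrected"] = ",".join(matrix.corrected)
    if not matrix.mask.all():
        params["masked_bins"] = int((~matrix.mask).sum())
    df = matrix.bins.copy()
    for j, sid in enumerate(matrix.samples):
        col = matrix.counts[j]
        if np.all(col == np.round(col)):
            df[sid] = col.astype(np.int64)
        else:
            df[sid] = col
    df["mask"] = matrix.mask.astype(int)
    with open(path, "w") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_bin_counts(path: str) -> BinCountMatrix:
    """Read a bin-count TSV written by :func:`write_bin_counts`.

    Round-trips bit-exactly for integer counts.  Ragged rows, negative raw
    counts and duplicate (chrom, start) pairs raise a located validation
    error.
    """
    corrected: list[str] = []
    with open(path) as fh:
        text_lines = []
        for line in fh:
            if line.startswith("#"):
                for tok in line.split():
                    if tok.startswith("corrected="):
                        corrected = tok.split("=", 1)[1].split(",")
                continue
            text_lines.append(line)
    if not text_lines:
        raise CountsIOError(f"{path}: no header row")
    header = text_lines[0].rstrip("\n").split("\t")
    if header[:4] != BIN_TSV_FIXED_COLS:
        raise CountsIOError(
            f"{path}: expected leading columns {BIN_TSV_FIXED_COLS}, got {header[:4]}")
    ncol = len(header)
    for i, line in enumerate(text_lines[1:], start=2):
        if len(line.rstrip("\n").split("\t")) != ncol:
            raise CountsIOError(f"{path}: ragged row at line {i}")
    try:
        df = pd.read_csv(io.StringIO("".join(text_lines)), sep="\t")
    except Exception as exc:
        raise CountsIOError(f"{path}: cannot parse: {exc}") from exc
    if df.empty:
        raise CountsIOError(f"{path}: no bins")
    has_mask = header[-1] == "mask"
    sample_cols = header[4:-1] if has_mask else header[4:]
    if not sample_cols:
        raise CountsIOError(f"{path}: no sample columns")
    dup = df.duplicated(subset=["chrom", "start"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise CountsIOError(
            f"{path}: duplicate (chrom,start) at data row {row + 1}: "
            f"{df.iloc[row]['chrom']}:{df.iloc[row]['start']}")
    counts = df[sample_cols].to_numpy(dtype=float).T
    if not corrected and (counts < 0).any():
        j, i = np.argwhere(counts < 0)[0]
        raise CountsIOError(
            f"{path}: negative count for sample {sample_cols[j]} at data row {i + 1}")
    mask = df["mask"].to_numpy(dtype=bool) if has_mask else None
    bins = df[BIN_TSV_FIXED_COLS].copy()
    bins["chrom"] = bins["chrom"].map(lambda v: normalize_chrom(v) or -1)
    if (bins["chrom"] < 0).any():
        bad = df.loc[bins["chrom"] < 0, "chrom"].iloc[0]
        raise CountsIOError(f"{path}: chromosome {bad!r} is not an autosome 1..22")
    return BinCountMatrix(bins=bins, samples=sample_cols, counts=counts,
                          mask=mask, corrected=corrected)


def write_chrom_counts(samples: list[ChromCounts], path: str,
                       params: dict | None = None) -> None:
    """Write per-autosome count vectors as TSV (sample_id, chr1..chr22)."""
    with open(path, "w") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        fh.write("\t".join(CHROM_TSV_COLS) + "\n")
        for s in samples:
            if s.is_integer():
                vals = [str(int(v)) for v in s.x]
            else:
                vals = [f"{v:.6f}" for v in s.x]
            fh.write(s.sample_id + "\t" + "\t".join(vals) + "\n")


def read_chrom_counts(path: str) -> list[ChromCounts]:
    """Read per-autosome count vectors (columns sample_id, chr1..chr22)."""
    with open(path) as fh:
        body = "".join(line for line in fh if not line.startswith("#"))
    if not body.strip():
        raise CountsIOError(f"{path}: empty file")
    try:
        df = pd.read_csv(io.StringIO(body), sep="\t")
    except Exception as exc:
        raise CountsIOError(f"{path}: cannot parse: {exc}") from exc
    missing = [c for c in CHROM_TSV_COLS if c not in df.columns]
    if missing:
        raise CountsIOError(f"{path}: missing column(s) {missing}")
    if df[CHROM_TSV_COLS[1:]].isna().any().any():
        row = int(df[CHROM_TSV_COLS[1:]].isna().any(axis=1).idxmax())
        raise CountsIOError(f"{path}: missing count cell at data row {row + 1}")
    out = []
    for row in df.itertuples(index=False):
        x = np.array([getattr(row, f"chr{i}") for i in range(1, 23)], dtype=float)
        out.append(ChromCounts(sample_id=str(row.sample_id), x=x))
    return out
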