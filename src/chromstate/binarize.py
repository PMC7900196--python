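"""Conversion of raw per-bin signals into the ternary {0,1,missing}
observation matrix the HMM consumes.

Three input dialects are covered: ATAC-type fragment counts (CPM, quantile
normalization across all biosamples, fixed threshold 0.5), ChIP-type counts
against a matched control (Poisson upper-tail test at p <= 1e-4 with the
control scaled to the treatment depth, floored at the global treatment
mean), and per-CpG percent methylation (replicate-averaged, bin-averaged,
50% threshold, bins with no CpGs marked missing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import MISSING
from .genome import BinnedGenome


@dataclass
class BinarizedTrack:
    """Ternary per-bin calls for one mark of one biosample."""

    genome: BinnedGenome
    mark: str
    values: np.ndarray  # (total_bins,) int8 in {0, 1, MISSING}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if len(self.values) != self.genome.total_bins:
            raise ValueError("track length must equal the total bin count")


def bin_fragment_counts(
    reads: list[tuple[str, int, int, str]],
    fragment_size: int,
    genome: BinnedGenome,
    cpm: bool = False,
) -> np.ndarray:
    """Per-bin fragment counts from read intervals.

    Each read is extended from its 5' end to ``fragment_size`` in strand
    direction and clipped to the chromosome; the fragment is attributed to
    the single bin containing its midpoint (midpoint rule, conserving the
    total count). With ``cpm`` the vector is scaled by 1e6 / total
    fragments.
    """
    if fragment_size <= 0:
        raise ValueError("fragment_size must be positive")
    counts = np.zeros(genome.total_bins, dtype=float)
    for chrom, start, end, strand in reads:
        length = genome.chrom_length(chrom)  # raises on unknown chrom
        if strand == "+":
            fs, fe = start, start + fragment_size
        else:
            fs, fe = end - fragment_size, end
        fs, fe = max(0, fs), min(length, fe)
        if fe <= fs:
            continue
        mid = (fs + fe) // 2
        counts[genome.bin_index(chrom, min(mid, length - 1))] += 1
    total = counts.sum()
    if cpm and total > 0:
        counts *= 1e6 / total
    return counts


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile normalization across columns (biosamples).

    After normalization every column's sorted value vector equals the
    row-wise mean of the column-sorted input. Tied values within a column
    receive the mean of the reference values across their rank span, so the
    map is well defined and idempotent.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (bins x biosamples)")
    if x.shape[1] < 2:
        warnings.warn("single column: quantile normalization is the identity")
        return x.copy()
    reference = np.sort(x, axis=0).mean(axis=1)
    ref_cum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # span [lo, hi) of equal values in sorted order -> mean of reference
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        lo = np.concatenate([[0], boundaries])
        hi = np.concatenate([boundaries, [len(col)]])
        span_mean = (ref_cum[hi] - ref_cum[lo]) / (hi - lo)
        group = np.zeros(len(col), dtype=int)
        group[lo[1:]] = 1
        group = np.cumsum(group)
        out[order, j] = span_mean[group]
    return out


def binarize_atac(
    cpm_matrix: np.ndarray,
    genome: BinnedGenome,
    biosample_names: list[str] | None = None,
    threshold: float = 0.5,
    mark: str = "ATAC",
) -> list[BinarizedTrack]:
    """Quantile-normalize CPM signal across all biosamples and call a bin
    accessible when the normalized signal strictly exceeds the threshold.
    Never produces missing values."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    x = np.asarray(cpm_matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    normalized = quantile_normalize(x) if x.shape[1] >= 2 else x
    if biosample_names is None:
        biosample_names = [f"sample{i + 1}" for i in range(x.shape[1])]
    return [
        BinarizedTrack(genome, mark, (normalized[:, j] > threshold).astype(np.int8))
        for j in range(x.shape[1])
    ]


def binarize_chip_poisson(
    treatment: np.ndarray,
    control: np.ndarray,
    genome: BinnedGenome,
    mark: str = "ChIP",
    p_threshold: float = 1e-4,
) -> BinarizedTrack:
    """Poisson upper-tail test of treatment counts against scaled control.

    Per bin the expected count is the control count scaled by the
    treatment/control depth ratio, floored at the global treatment mean; the
    bin is called present when P(X >= observed | lambda) <= p_threshold.
    """
    t = np.asarray(treatment, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.shape != c.shape:
        raise ValueError("treatment and control must have equal lengths")
    if t.sum() == 0 and c.sum() == 0:
        warnings.warn("all-zero treatment and control; returning all zeros")
        return BinarizedTrack(genome, mark, np.zeros(len(t), dtype=np.int8))
    ratio = t.sum() / c.sum() if c.sum() > 0 else 1.0
    lam = np.maximum(c * ratio, t.mean())
    # P(X >= x) = sf(x - 1); observed 0 gives p = 1
    p = stats.poisson.sf(t - 1, lam)
    return BinarizedTrack(genome, mark, (p <= p_threshold).astype(np.int8))


def binarize_wgbs(
    cpg_records: list[tuple[str, int, tuple[float, ...]]],
    genome: BinnedGenome,
    threshold_percent: float = 50.0,
    mark: str = "meCpG",
) -> BinarizedTrack:
    """Bin-average replicate-averaged per-CpG percent methylation.

    A bin is 1 when its mean percent is >= the threshold (inclusive), 0
    otherwise, and missing when it contains no CpGs.
    """
    sums = np.zeros(genome.total_bins)
    ns = np.zeros(genome.total_bins, dtype=int)
    for chrom, pos, percents in cpg_records:
        b = genome.bin_index(chrom, int(pos))  # raises if outside bounds
        sums[b] += float(np.mean(percents))
        ns[b] += 1
    values = np.full(genome.total_bins, MISSING, dtype=np.int8)
    has = ns > 0
    values[has] = (sums[has] / ns[has] >= threshold_percent).astype(np.int8)
    return BinarizedTrack(genome, mark, values)


def cpg_records_from_track(
    track: dict[str, dict[str, np.ndarray]]
) -> list[tuple[str, int, tuple[float, ...]]]:
    """Flatten a simulated methylation track (per-chrom pos/percent arrays,
    percent shaped (n_replicates, n)) into (chrom, pos, percents) records."""
    records = []
    for chrom, data in track.items():
        pos, pct = data["pos"], data["percent"]
        for i in range(len(pos)):
            records.append((chrom, int(pos[i]), tuple(float(v) for v in pct[:, i])))
    return records
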