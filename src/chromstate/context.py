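"""Conservation-by-state averages, transposon overlap, and the PRC2-bound
silencer analyses with footprint-, length-, and distance-matched controls.

Silencers are genomic intervals carrying a group label 1-4 (from an
upstream clustering of their H3K27ac profiles, consumed here as input data)
and optional target-TSS links.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import UNASSIGNED, UNASSIGNED_NAME
from .genome import BinnedGenome
from .hmm import Segmentation


@dataclass
class SilencerSet:
    """Named silencer intervals with group labels and target-TSS links.

    ``df`` columns: chrom, start, end, group, silencer_id. ``links`` maps a
    silencer id to its target TSS positions.
    """

    df: pd.DataFrame
    links: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "group", "silencer_id"}
        if not need <= set(self.df.columns):
            raise ValueError(f"silencer table needs columns {sorted(need)}")
        bad = set(self.df["group"]) - {1, 2, 3, 4}
        if bad:
            raise ValueError(f"silencer groups must be 1-4, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    def group(self, g: int) -> pd.DataFrame:
        return self.df[self.df["group"] == g]

    def centers(self) -> pd.DataFrame:
        """Interval centers: floor((start+end)/2), 0-based."""
        out = self.df.copy()
        out["center"] = (out["start"] + out["end"]) // 2
        return out


@dataclass
class ConservationTrack:
    """Per-bin mean conservation score; NaN where the source has no data."""

    genome: BinnedGenome
    scores: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom in self.genome.chrom_names:
            if chrom not in self.scores:
                raise ValueError(f"missing conservation for {chrom!r}")
            if len(self.scores[chrom]) != self.genome.n_bins(chrom):
                raise ValueError(f"conservation length mismatch on {chrom!r}")

    def all_scores(self) -> np.ndarray:
        return np.concatenate(
            [self.scores[c] for c in self.genome.chrom_names]
        ).astype(float)


def interval_bin_mask(genome: BinnedGenome, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean per-bin flag: bin overlaps >= 1 bp of any interval."""
    mask = np.zeros(genome.total_bins, dtype=bool)
    w = genome.bin_size
    for chrom, grp in intervals.groupby("chrom"):
        if chrom not in genome.chrom_names:
            raise KeyError(f"unknown chromosome {chrom!r}")
        off = genome.chrom_offset(chrom)
        nb = genome.n_bins(chrom)
        for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            if e <= s:
                continue
            b0 = max(0, int(s) // w)
            b1 = min(nb, -(-int(e) // w))
            mask[off + b0: off + b1] = True
    return mask


def state_mean_conservation(
    segmentation: Segmentation, conservation: ConservationTrack
) -> pd.Series:
    """Mean per-bin conservation per state, ignoring missing-score bins."""
    labels = segmentation.all_labels()
    scores = conservation.all_scores()
    out = {}
    for k, name in enumerate(segmentation.state_names):
        sel = scores[labels == k]
        sel = sel[~np.isnan(sel)]
        out[name] = float(sel.mean()) if len(sel) else np.nan
    return pd.Series(out)


def tissue_mean_conservation(per_biosample: list[pd.Series]) -> pd.Series:
    """Average the per-biosample state means across timepoints of a tissue."""
    return pd.concat(per_biosample, axis=1).mean(axis=1)


def tss_conservation_by_bivalency(
    tss: list[tuple[str, int]],
    segmentation: Segmentation,
    conservation: ConservationTrack,
    bivalent_state: str = "TssBiv",
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Split TSS bin scores by whether the bin is bivalent; rank-sum test.

    Returns (scores in bivalent bins, scores elsewhere, two-sided
    Mann-Whitney p or NaN if a group is empty, n skipped for missing score).
    """
    if not tss:
        raise ValueError("empty TSS list")
    k = segmentation.state_names.index(bivalent_state)
    in_biv, other, skipped = [], [], 0
    for chrom, pos in tss:
        b = pos // segmentation.genome.bin_size
        score = conservation.scores[chrom][b]
        if np.isnan(score):
            skipped += 1
            continue
        (in_biv if segmentation.labels[chrom][b] == k else other).append(score)
    a, b_ = np.array(in_biv), np.array(other)
    if len(a) == 0 or len(b_) == 0:
        return a, b_, float("nan"), skipped
    p = float(stats.mannwhitneyu(a, b_, alternative="two-sided").pvalue)
    return a, b_, p, skipped


def transposon_overlap_fraction(
    segmentation: Segmentation, state: str, transposons: pd.DataFrame
) -> tuple[float, float]:
    """Fraction of a state's bins overlapping a transposon by >= 1 bp, and
    the same fraction over all genomic bins as control."""
    mask = interval_bin_mask(segmentation.genome, transposons)
    labels = segmentation.all_labels()
    try:
        k = segmentation.state_names.index(state)
    except ValueError:
        raise ValueError(f"unknown state {state!r}") from None
    sel = labels == k
    if not sel.any():
        return float("nan"), float(mask.mean())
    return float(mask[sel].mean()), float(mask.mean())


def _center_bins(
    silencers: SilencerSet | pd.DataFrame, genome: BinnedGenome
) -> np.ndarray:
    df = silencers.centers() if isinstance(silencers, SilencerSet) else silencers
    return np.array(
        [genome.bin_index(c, int(p)) for c, p in zip(df["chrom"], df["center"])]
    )


def silencer_center_state(
    silencers: SilencerSet, segmentation: Segmentation
) -> tuple[pd.Series, pd.DataFrame]:
    """Chromatin state at each silencer's center, plus per-state center
    fractions and fold enrichment over the state's genomic footprint.

    Returns (per-silencer state names, table with columns center_fraction /
    footprint / fold). Fractions over states plus unassigned sum to 1.
    """
    genome = segmentation.genome
    centers = silencers.centers()
    if len(centers) == 0:
        names = segmentation.state_names + [UNASSIGNED_NAME]
        empty = pd.DataFrame(
            np.nan, index=names, columns=["center_fraction", "footprint", "fold"]
        )
        return pd.Series(dtype=object), empty
    bins = _center_bins(silencers, genome)
    labels = segmentation.all_labels()[bins]
    per_sil = pd.Series(
        [segmentation.label_name(v) for v in labels], index=centers["silencer_id"]
    )
    all_labels = segmentation.all_labels()
    rows = {}
    for k, name in list(enumerate(segmentation.state_names)) + [
        (UNASSIGNED, UNASSIGNED_NAME)
    ]:
        frac = float((labels == k).mean())
        footprint = float((all_labels == k).mean())
        fold = frac / footprint if footprint > 0 else np.nan
        rows[name] = (frac, footprint, fold)
    table = pd.DataFrame(rows, index=["center_fraction", "footprint", "fold"]).T
    return per_sil, table


def silencer_footprint_enrichment(
    segmentation: Segmentation,
    silencers: SilencerSet,
    reference_state: str = "TssBiv",
    n_draws: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Footprint-normalized silencer overlap percentages per state.

    For the reference state: the percentage of its bins containing >= 1
    silencer center. For every other state: the same percentage on random
    subsets of its bins matched in size to the reference state's bin count,
    reported as mean +- sd over ``n_draws`` draws. States with fewer bins
    than the reference count are sampled with replacement and flagged.
    """
    genome = segmentation.genome
    labels = segmentation.all_labels()
    if reference_state not in segmentation.state_names:
        raise ValueError(f"unknown reference state {reference_state!r}")
    has_center = np.zeros(genome.total_bins, dtype=bool)
    if len(silencers):
        has_center[_center_bins(silencers, genome)] = True
    k_ref = segmentation.state_names.index(reference_state)
    ref_bins = np.flatnonzero(labels == k_ref)
    n_ref = len(ref_bins)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for k, name in enumerate(segmentation.state_names):
        state_bins = np.flatnonzero(labels == k)
        if k == k_ref:
            pct = 100.0 * has_center[ref_bins].mean() if n_ref else np.nan
            rows.append((name, pct, 0.0, False))
            continue
        if len(state_bins) == 0 or n_ref == 0:
            rows.append((name, np.nan, np.nan, False))
            continue
        replace = len(state_bins) < n_ref
        if replace:
            warnings.warn(f"state {name}: fewer bins than reference; "
                          "sampling with replacement")
        pcts = np.empty(n_draws)
        for d in range(n_draws):
            draw = rng.choice(state_bins, size=n_ref, replace=replace)
            pcts[d] = 100.0 * has_center[draw].mean()
        rows.append((name, float(pcts.mean()), float(pcts.std()), replace))
    return pd.DataFrame(
        rows, columns=["state", "percent", "sd", "with_replacement"]
    ).set_index("state")


@dataclass
class OverlapZResult:
    """Observed overlap count against a randomized-placement null."""

    observed: int
    random_mean: float
    random_sd: float
    z: float
    n_draws: int
    seed: int


def _covered_overlap(
    starts: np.ndarray, ends: np.ndarray, q_start: np.ndarray, q_end: np.ndarray
) -> np.ndarray:
    """bp of each query interval covered by the union of (merged-input)
    intervals. ``starts/ends`` must be sorted and non-overlapping."""
    if len(starts) == 0:
        return np.zeros(len(q_start))
    cum = np.concatenate([[0], np.cumsum(ends - starts)])

    def coverage_before(x):
        i = np.searchsorted(starts, x, side="right")
        inside = np.clip(x - starts[np.maximum(i - 1, 0)], 0, None)
        inside = np.minimum(inside, (ends - starts)[np.maximum(i - 1, 0)])
        inside[i == 0] = 0
        return cum[np.maximum(i - 1, 0)] + inside

    return coverage_before(q_end) - coverage_before(q_start)


def _merge_intervals(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, grp in df.groupby("chrom"):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        order = np.argsort(s, kind="stable")
        s, e = s[order], e[order]
        ms, me = [s[0]], [e[0]]
        for a, b in zip(s[1:], e[1:]):
            if a <= me[-1]:
                me[-1] = max(me[-1], b)
            else:
                ms.append(a)
                me.append(b)
        out[chrom] = (np.array(ms), np.array(me))
    return out


def bivalent_silencer_overlap_z(
    bivalent_regions: pd.DataFrame,
    silencers: SilencerSet,
    genome: BinnedGenome,
    min_overlap_fraction: float = 0.5,
    n_random: int = 100,
    seed: int = 0,
) -> OverlapZResult:
    """Silencers overlapped by bivalent regions versus random placement.

    A silencer counts if at least ``min_overlap_fraction`` of its length is
    covered by the bivalent regions. Each random replicate re-places every
    bivalent region uniformly on its own chromosome (length preserved,
    overlaps among placements allowed) and recounts.
    """
    if n_random < 10:
        raise ValueError("n_random must be at least 10")
    sil = silencers.df
    lengths = (sil["end"] - sil["start"]).to_numpy()

    def count(regions: pd.DataFrame) -> int:
        merged = _merge_intervals(regions) if len(regions) else {}
        total = 0
        for chrom, grp in sil.groupby("chrom"):
            qs = grp["start"].to_numpy()
            qe = grp["end"].to_numpy()
            if chrom in merged:
                ov = _covered_overlap(*merged[chrom], qs, qe)
            else:
                ov = np.zeros(len(qs))
            total += int((ov >= min_overlap_fraction * (qe - qs) - 1e-9).sum())
        return total

    observed = count(bivalent_regions)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    reg_chrom = bivalent_regions["chrom"].to_numpy()
    reg_len = (bivalent_regions["end"] - bivalent_regions["start"]).to_numpy()
    counts = np.empty(n_random)
    for r in range(n_random):
        starts = np.empty(len(reg_len), dtype=int)
        for chrom in np.unique(reg_chrom):
            m = reg_chrom == chrom
            hi = genome.chrom_length(chrom) - reg_len[m]
            starts[m] = rng.integers(0, np.maximum(hi, 0) + 1)
        rand = pd.DataFrame(
            {"chrom": reg_chrom, "start": starts, "end": starts + reg_len}
        )
        counts[r] = count(rand)
    mean, sd = float(counts.mean()), float(counts.std())
    z = (observed - mean) / sd if sd > 0 else float("nan")
    del lengths
    return OverlapZResult(observed, mean, sd, z, n_random, seed)


def nearest_silencer_distance(
    tss: list[tuple[str, int]], silencers: SilencerSet
) -> np.ndarray:
    """bp distance from each TSS to the nearest silencer interval (0 if
    inside one); inf on chromosomes without silencers."""
    merged = _merge_intervals(silencers.df)
    out = np.empty(len(tss))
    for i, (chrom, pos) in enumerate(tss):
        if chrom not in merged:
            out[i] = np.inf
            continue
        s, e = merged[chrom]
        j = np.searchsorted(s, pos, side="right") - 1
        d = np.inf
        if j >= 0:
            d = 0.0 if pos < e[j] else pos - e[j] + 1
        if j + 1 < len(s):
            d = min(d, s[j + 1] - pos)
        out[i] = d
    return out


def distance_matched_tss_control(
    target_tss: list[tuple[str, int]],
    all_tss: list[tuple[str, int]],
    silencers: SilencerSet,
    seed: int = 0,
    strata_per_decade: int = 10,
) -> tuple[list[tuple[str, int]], int]:
    """Non-target TSSs matched to the targets' nearest-silencer distance
    distribution by log10-distance strata.

    Sampling is without replacement within a stratum while candidates last;
    an empty stratum is widened once by one stratum on each side, after
    which the target is reported unmatched. Returns (controls, n_unmatched).
    """
    target_set = set(target_tss)
    pool = [t for t in all_tss if t not in target_set]
    if not pool:
        raise ValueError("no non-target TSSs available")
    d_target = nearest_silencer_distance(target_tss, silencers)
    d_pool = nearest_silencer_distance(pool, silencers)
    if not np.isfinite(d_target).all():
        raise ValueError("every target TSS needs a nearest-silencer distance")

    def stratum(d: np.ndarray) -> np.ndarray:
        return np.floor(strata_per_decade * np.log10(np.maximum(d, 1.0))).astype(int)

    s_target = stratum(d_target)
    s_pool = stratum(d_pool[np.isfinite(d_pool)])
    pool = [p for p, d in zip(pool, d_pool) if np.isfinite(d)]
    by_stratum: dict[int, list[int]] = {}
    for i, s in enumerate(s_pool):
        by_stratum.setdefault(int(s), []).append(i)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for s in by_stratum:
        rng.shuffle(by_stratum[s])
    controls, unmatched = [], 0
    for s in s_target:
        cands = by_stratum.get(int(s), [])
        if not cands:
            widened = by_stratum.get(int(s) - 1, []) + by_stratum.get(int(s) + 1, [])
            cands = widened
        if not cands:
            unmatched += 1
            continue
        controls.append(pool[cands.pop()])
    return controls, unmatched


def target_tss_state_enrichment(
    target_tss: list[tuple[str, int]],
    control_tss: list[tuple[str, int]],
    segmentation: Segmentation,
) -> pd.DataFrame:
    """Per-state percentages of target vs control TSS bins."""
    if not control_tss:
        raise ValueError("empty control TSS set")
    if set(target_tss) & set(control_tss):
        raise ValueError("target and control TSS sets must be disjoint")
    genome = segmentation.genome
    labels = segmentation.all_labels()

    def pct(tss):
        bins = np.array([genome.bin_index(c, p) for c, p in tss])
        lab = labels[bins]
        return {
            name: 100.0 * float((lab == k).mean())
            for k, name in list(enumerate(segmentation.state_names))
            + [(UNASSIGNED, UNASSIGNED_NAME)]
        }

    return pd.DataFrame({"target": pct(target_tss), "control": pct(control_tss)})
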