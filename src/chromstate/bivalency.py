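"""Bivalent-domain detection and bivalency statistics.

A bivalent domain is a maximal run of TssBiv bins whose immediate left and
right neighbor bins are both repressive or quiescent (ReprPC, ReprPCWk,
Quies, Quies2, Quies3, Quies4, or QuiesG). Extraction follows the
string/regex formulation: each epigenome is converted to one character per
bin and domains are pulled out with a regular expression. Bivalent TSSs are
TSSs falling inside the cross-biosample union of domains; a bivalent gene
has at least one bivalent TSS.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import UNASSIGNED, UNASSIGNED_NAME
from .genome import BinnedGenome
from .hmm import Segmentation

#: Flanking states permitted around a bivalent run.
DEFAULT_FLANK_STATES = frozenset(
    {"ReprPC", "ReprPCWk", "Quies", "Quies2", "Quies3", "Quies4", "QuiesG"}
)


@dataclass
class GeneModel:
    """A gene with its (deduplicated) TSS positions."""

    gene_id: str
    tss: list[tuple[str, int]]
    strand: str = "+"
    is_tf: bool = False

    def __post_init__(self) -> None:
        seen, dedup = set(), []
        for t in self.tss:
            t = (t[0], int(t[1]))
            if t not in seen:
                seen.add(t)
                dedup.append(t)
        self.tss = dedup


@dataclass
class StateString:
    """One chromosome of a segmentation as a character string, one symbol
    per bin, plus the symbol->label alphabet map."""

    chromosome: str
    value: str
    alphabet: dict[str, str]  # symbol -> state name (incl. unassigned)
    symbols: dict[str, str] = field(init=False)  # state name -> symbol

    def __post_init__(self) -> None:
        if len(set(self.alphabet)) != len(set(self.alphabet.values())):
            raise ValueError("alphabet collision: symbols must map 1:1 to states")
        self.symbols = {v: k for k, v in self.alphabet.items()}


def _default_alphabet(state_names: list[str]) -> dict[str, str]:
    pool = string.ascii_uppercase + string.ascii_lowercase + string.digits
    if len(state_names) > len(pool):
        raise ValueError("too many states for the symbol pool")
    alpha = {pool[i]: name for i, name in enumerate(state_names)}
    alpha["."] = UNASSIGNED_NAME
    return alpha


def to_state_string(segmentation: Segmentation, chromosome: str,
                    alphabet: dict[str, str] | None = None) -> StateString:
    """Convert one chromosome's labels to a string (reversible)."""
    if chromosome not in segmentation.labels:
        raise KeyError(f"unknown chromosome {chromosome!r}")
    if alphabet is None:
        alphabet = _default_alphabet(segmentation.state_names)
    symbols = {v: k for k, v in alphabet.items()}
    if len(symbols) != len(alphabet):
        raise ValueError("alphabet collision: symbols must map 1:1 to states")
    labels = segmentation.labels[chromosome]
    lut = np.array(
        [symbols[name] for name in segmentation.state_names], dtype="U1"
    )
    chars = np.where(
        labels == UNASSIGNED, symbols[UNASSIGNED_NAME], lut[np.clip(labels, 0, None)]
    )
    return StateString(chromosome, "".join(chars), alphabet)


def from_state_string(s: StateString, state_names: list[str]) -> np.ndarray:
    """Inverse of :func:`to_state_string`: string back to label array."""
    index = {name: i for i, name in enumerate(state_names)}
    index[UNASSIGNED_NAME] = UNASSIGNED
    return np.array([index[s.alphabet[ch]] for ch in s.value], dtype=np.int16)


def extract_bivalent_regions(
    segmentation: Segmentation,
    bivalent_state: str = "TssBiv",
    flank_states: frozenset[str] | set[str] = DEFAULT_FLANK_STATES,
    require_both_flanks: bool = True,
) -> pd.DataFrame:
    """Extract bivalent domains by regex over the per-chromosome strings.

    Every maximal run of ``bivalent_state`` bins whose immediate neighbors
    on both sides are flank states becomes one region. Runs touching a
    chromosome end, or bordered by any other label (unassigned included),
    are excluded. Returns a DataFrame (chrom, start, end, biosample) in bp.
    """
    if bivalent_state in flank_states:
        raise ValueError("bivalent state cannot be one of its flank states")
    present = set(segmentation.state_names) | {UNASSIGNED_NAME}
    if bivalent_state not in present:
        raise ValueError(f"state {bivalent_state!r} not in segmentation labels")
    bin_size = segmentation.genome.bin_size
    rows = []
    for chrom in segmentation.genome.chrom_names:
        s = to_state_string(segmentation, chrom)
        biv = re.escape(s.symbols[bivalent_state])
        flank_syms = "".join(
            re.escape(s.symbols[f]) for f in sorted(flank_states) if f in s.symbols
        )
        if not flank_syms:
            continue
        if require_both_flanks:
            pattern = f"(?<=[{flank_syms}]){biv}+(?=[{flank_syms}])"
        else:
            pattern = f"(?:(?<=[{flank_syms}]){biv}+|{biv}+(?=[{flank_syms}]))"
        for m in re.finditer(pattern, s.value):
            rows.append(
                (chrom, m.start() * bin_size, m.end() * bin_size,
                 segmentation.biosample)
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "biosample"])


def union_bivalent_regions(regions: pd.DataFrame | list[pd.DataFrame]) -> pd.DataFrame:
    """Cross-biosample union of regions.

    Overlapping regions are unified into their coordinate union; abutting
    regions stay separate (neighboring regions are not merged). Output is
    sorted and distinct, with ``n_biosamples`` counting distinct source
    biosamples per unified region.
    """
    if isinstance(regions, list):
        regions = pd.concat(regions, ignore_index=True) if regions else pd.DataFrame(
            columns=["chrom", "start", "end", "biosample"]
        )
    if regions.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_biosamples"])
    out = []
    for chrom, grp in regions.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_s = cur_e = None
        sources: set = set()
        for _, r in grp.iterrows():
            if cur_s is None:
                cur_s, cur_e, sources = r.start, r.end, {r.get("biosample")}
            elif r.start < cur_e:  # strict: abutting intervals not merged
                cur_e = max(cur_e, r.end)
                sources.add(r.get("biosample"))
            else:
                out.append((chrom, cur_s, cur_e, len(sources - {None})))
                cur_s, cur_e, sources = r.start, r.end, {r.get("biosample")}
        out.append((chrom, cur_s, cur_e, len(sources - {None})))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_biosamples"])


def assign_bivalent_tss(
    regions: pd.DataFrame, genes: list[GeneModel]
) -> set[tuple[str, int]]:
    """TSSs lying inside a region (half-open containment)."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in regions.groupby("chrom"):
        grp = grp.sort_values("start")
        # prefix max of ends handles overlapping (pre-union) region lists
        by_chrom[chrom] = (
            grp["start"].to_numpy(),
            np.maximum.accumulate(grp["end"].to_numpy()),
        )
    out = set()
    for g in genes:
        for chrom, pos in g.tss:
            if chrom not in by_chrom:
                continue
            starts, cummax_end = by_chrom[chrom]
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and cummax_end[i] > pos:
                out.add((chrom, pos))
    return out


def call_bivalent_genes(
    bivalent_tss: set[tuple[str, int]], genes: list[GeneModel]
) -> set[str]:
    """A bivalent gene has at least one bivalent TSS."""
    return {g.gene_id for g in genes if any(t in bivalent_tss for t in g.tss)}


def genes_bivalent_in_all(per_group: dict[str, set[str]]) -> set[str]:
    """Genes bivalent in every group (e.g., every tissue)."""
    if not per_group:
        return set()
    return set.intersection(*per_group.values())


def expected_all_timepoint_bivalent(
    frequencies: list[float] | np.ndarray, n_total: int
) -> float:
    """Expected number of genes bivalent at every timepoint if timepoints
    were independent: the product of per-timepoint frequencies times the
    number of genes bivalent at one or more timepoints."""
    f = np.asarray(frequencies, dtype=float)
    if ((f < 0) | (f > 1)).any():
        raise ValueError("frequencies must be in [0, 1]")
    if n_total < 0:
        raise ValueError("n_total must be nonnegative")
    return float(np.prod(f) * n_total)


def tissue_specificity_score(
    expression: pd.DataFrame, biosample_tissue: dict[str, str]
) -> pd.Series:
    """Per-gene tissue specificity: max per-tissue mean TPM over the mean of
    per-tissue means.

    With 12 tissues a score above 6 means expression in the primary tissue
    exceeds all other tissues combined; a gene at exactly the boundary
    scores exactly 6.0. All-zero genes get NaN.
    """
    tissues = pd.Series({b: biosample_tissue[b] for b in expression.columns})
    if tissues.nunique() < 2:
        raise ValueError("need at least 2 tissues")
    per_tissue = expression.T.groupby(tissues).mean().T  # genes x tissues
    mean = per_tissue.mean(axis=1)
    score = per_tissue.max(axis=1) / mean
    score[mean == 0] = np.nan
    return score


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table of counts.

    Two-sided by summing hypergeometric point probabilities not exceeding
    the observed table's. Returns (odds ratio, p).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 nonnegative integers")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def bivalent_fraction_trajectory(
    segmentations: list[Segmentation], state: str = "TssBiv"
) -> tuple[np.ndarray, float | None, float | None]:
    """Genome fraction of a state per timepoint plus an OLS trend test.

    Returns (fractions, slope per timepoint step, two-sided t-test p); the
    trend test needs at least 3 timepoints and is None otherwise.
    """
    fracs = []
    for seg in segmentations:
        labels = seg.all_labels()
        k = seg.state_names.index(state)
        fracs.append(float((labels == k).mean()))
    fracs = np.array(fracs)
    if len(fracs) < 3:
        return fracs, None, None
    res = stats.linregress(np.arange(len(fracs)), fracs)
    return fracs, float(res.slope), float(res.pvalue)
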