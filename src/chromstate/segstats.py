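"""Segmentation-level statistics: coverage, annotation enrichment,
expression dichotomization, Jaccard comparisons, mark-dropout robustness,
temporal transitions, and signal-matrix construction."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .constants import UNASSIGNED, UNASSIGNED_NAME
from .context import interval_bin_mask
from .genome import BinnedGenome
from .hmm import (
    HMMModel,
    ObservationSequence,
    Segmentation,
    decode_with_missing_marks,
    posterior_decode,
)


def genome_coverage(segmentation: Segmentation) -> pd.Series:
    """Fraction of bins per state; with the unassigned fraction the values
    sum to 1."""
    labels = segmentation.all_labels()
    n = len(labels)
    out = {
        name: float((labels == k).sum()) / n
        for k, name in enumerate(segmentation.state_names)
    }
    out[UNASSIGNED_NAME] = float((labels == UNASSIGNED).sum()) / n
    return pd.Series(out)


def annotation_enrichment(
    segmentation: Segmentation, annotation: pd.DataFrame, name: str | None = None
) -> pd.Series:
    """Fold enrichment of each state in an annotation.

    A bin carries the annotation when it overlaps it by >= 1 bp. Enrichment
    is P(state, annotation) / (P(state) * P(annotation)) with probabilities
    over all genomic bins (unassigned bins included in the marginals).
    States with zero coverage are NaN, as is everything when the annotation
    covers no bins.
    """
    mask = interval_bin_mask(segmentation.genome, annotation)
    labels = segmentation.all_labels()
    n = len(labels)
    p_ann = mask.sum() / n
    out = {}
    if p_ann == 0:
        warnings.warn(f"annotation {name or ''} covers no bins")
    for k, nm in enumerate(segmentation.state_names):
        sel = labels == k
        p_state = sel.sum() / n
        if p_state == 0 or p_ann == 0:
            out[nm] = np.nan
            continue
        p_joint = (sel & mask).sum() / n
        out[nm] = float(p_joint / (p_state * p_ann))
    return pd.Series(out, name=name)


def scale_enrichments(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Affine rescale to [0, 1] within a scaling group (min -> 0, max -> 1);
    NaN entries propagate; a constant group degenerates to all zeros."""
    v = np.asarray(values, dtype=float)
    finite = v[~np.isnan(v)]
    if len(finite) == 0:
        return values
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        warnings.warn("constant enrichment vector; scaled values set to 0")
        scaled = np.where(np.isnan(v), np.nan, 0.0)
    else:
        scaled = (v - lo) / (hi - lo)
    if isinstance(values, pd.Series):
        return pd.Series(scaled, index=values.index, name=values.name)
    return scaled


def expression_cutoff_gmm(
    tpm: np.ndarray, seed: int = 0, pseudocount: float = 0.01
) -> float:
    """Expressed/repressed TPM cutoff from a two-component Gaussian mixture
    on log10(TPM + pseudocount).

    The threshold is the smallest evaluated log-expression value at which
    the higher-mean component's responsibility first exceeds 0.5, mapped
    back to TPM. Falls back to 1 TPM (with a warning) when the mixture is
    degenerate.
    """
    tpm = np.asarray(tpm, dtype=float)
    if (tpm > 0).sum() < 50:
        raise ValueError("need at least 50 genes with TPM > 0")
    x = np.log10(tpm + pseudocount)
    gm = GaussianMixture(
        n_components=2, n_init=3, random_state=int(seed) % (2**31)
    ).fit(x[:, None])
    means = gm.means_.ravel()
    hi = int(np.argmax(means))
    degenerate = (
        abs(means[1] - means[0]) < 0.1
        or gm.weights_.min() < 1e-3  # one component is empty
        or np.ptp(x) < 1e-9
    )
    if degenerate:
        warnings.warn("degenerate mixture; falling back to the 1 TPM cutoff")
        return 1.0
    grid = np.linspace(x.min(), x.max(), 2000)
    resp = gm.predict_proba(grid[:, None])[:, hi]
    above = np.flatnonzero(resp > 0.5)
    if len(above) == 0:
        warnings.warn("high component never dominates; falling back to 1 TPM")
        return 1.0
    return float(max(10 ** grid[above[0]] - pseudocount, 0.0))


def per_state_jaccard(seg_a: Segmentation, seg_b: Segmentation) -> pd.Series:
    """Per-state Jaccard index between two segmentations on one bin grid:
    |both s| / |either s|, NaN when the state appears in neither."""
    if seg_a.genome != seg_b.genome:
        raise ValueError("segmentations are on different bin grids")
    if seg_a.state_names != seg_b.state_names:
        raise ValueError("segmentations use different state sets")
    a = seg_a.all_labels()
    b = seg_b.all_labels()
    out = {}
    for k, name in enumerate(seg_a.state_names):
        ina, inb = a == k, b == k
        union = (ina | inb).sum()
        out[name] = float((ina & inb).sum() / union) if union else np.nan
    return pd.Series(out)


def mark_dropout_assessment(
    model: HMMModel,
    sequences: list[ObservationSequence],
    genome: BinnedGenome,
    mark: str,
) -> tuple[pd.Series, pd.Series]:
    """Robustness of state assignments to losing one mark.

    Decodes a biosample with and without the mark, computes the per-state
    Jaccard between the two segmentations, and flags states with Jaccard
    strictly below 0.5 as misassigned.
    """
    if mark not in model.mark_names:
        raise ValueError(f"unknown mark {mark!r}")
    full = posterior_decode(model, sequences, genome)
    partial = decode_with_missing_marks(model, sequences, genome, {mark})
    jac = per_state_jaccard(full, partial)
    flags = jac < 0.5  # NaN compares False: absent states are not flagged
    return jac, flags


def transition_counts(
    seg_t1: Segmentation, seg_t2: Segmentation, state_subset: set[str]
) -> pd.DataFrame:
    """State-to-state bin counts between two timepoints, restricted to bins
    labeled with a subset state at either timepoint.

    Rows are t1 labels, columns t2 labels (unassigned included); the total
    equals the number of restricted bins.
    """
    if not state_subset:
        raise ValueError("state_subset must be nonempty")
    if seg_t1.genome != seg_t2.genome:
        raise ValueError("segmentations are on different bin grids")
    names = seg_t1.state_names + [UNASSIGNED_NAME]
    codes = {name: k for k, name in enumerate(seg_t1.state_names)}
    codes[UNASSIGNED_NAME] = UNASSIGNED
    subset_codes = [codes[s] for s in state_subset]
    a = seg_t1.all_labels()
    b = seg_t2.all_labels()
    keep = np.isin(a, subset_codes) | np.isin(b, subset_codes)
    table = pd.DataFrame(0, index=names, columns=names)
    ak, bk = a[keep], b[keep]
    for i, ni in enumerate(seg_t1.state_names):
        sel = ak == i
        for j, nj in enumerate(seg_t1.state_names):
            table.loc[ni, nj] = int((sel & (bk == j)).sum())
        table.loc[ni, UNASSIGNED_NAME] = int((sel & (bk == UNASSIGNED)).sum())
    sel = ak == UNASSIGNED
    for j, nj in enumerate(seg_t1.state_names):
        table.loc[UNASSIGNED_NAME, nj] = int((sel & (bk == j)).sum())
    table.loc[UNASSIGNED_NAME, UNASSIGNED_NAME] = int(
        (sel & (bk == UNASSIGNED)).sum()
    )
    return table


def state_signal_matrix(
    segmentations: dict[str, Segmentation],
    signals: dict[str, dict[str, dict[str, np.ndarray]]],
    state: str,
    marks: list[str],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Signal matrix over bins carrying a state in >= 1 biosample.

    ``signals[biosample][mark][chrom]`` are per-bin signal vectors. Returns
    (global bin indices, DataFrame with one ``biosample:mark`` column per
    requested pair), ready to hand to an external embedding tool.
    """
    first = next(iter(segmentations.values()))
    genome = first.genome
    k = first.state_names.index(state)
    member = np.zeros(genome.total_bins, dtype=bool)
    for seg in segmentations.values():
        if seg.genome != genome:
            raise ValueError("segmentations are on different bin grids")
        member |= seg.all_labels() == k
    bins = np.flatnonzero(member)
    if len(bins) == 0:
        warnings.warn(f"state {state!r} absent in every biosample")
    cols = {}
    for b, seg in segmentations.items():
        for m in marks:
            track = np.concatenate(
                [signals[b][m][c] for c in genome.chrom_names]
            )
            cols[f"{b}:{m}"] = track[bins]
    return bins, pd.DataFrame(cols)
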