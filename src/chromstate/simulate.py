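"""Synthetic epigenomes with known ground truth.

Everything downstream of the real pipeline's inputs — binarized marks, raw
count/methylation tracks, genes with expression, silencers, conservation —
is generated here from a known-state Markov ground truth, so every stage is
testable without any download. One global seed expands into per-component
child seeds through ``numpy.random.SeedSequence`` spawning in a fixed
order, so regeneration is bit-for-bit reproducible and components are
individually reproducible.

The distributional choices (Poisson counts, Beta methylation, log-normal
expression, Gaussian conservation) are stand-ins for real data, not fits to
it; see docs/methods.md for what they do and do not emulate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .bivalency import GeneModel
from .constants import MISSING
from .context import SilencerSet
from .genome import BinnedGenome
from .hmm import HMMModel

# Role names drawn from the 18-state chromatin-state vocabulary; the first
# few cover every role the bivalent-domain extractor needs (TssBiv plus its
# repressive/quiescent flanks).
DEFAULT_ROLE_PRIORITY = [
    "Tss", "TssBiv", "ReprPC", "Quies", "Enh", "Tx", "TssFlnk", "Het",
    "QuiesG", "EnhLo", "EnhPois", "ReprPCWk", "Quies2", "Quies3", "Quies4",
    "EnhPr", "TxWk", "EnhG",
]

DEFAULT_MARKS = [
    "H3K4me1", "H3K4me2", "H3K4me3", "H3K9ac", "H3K27ac",
    "H3K36me3", "H3K9me3", "H3K27me3", "ATAC", "meCpG",
]

#: Default synthetic genome: 3 chromosomes x 50,000 bins of 200 bp.
DEFAULT_CHROMOSOMES = [("chr1", 10_000_000), ("chr2", 10_000_000), ("chr3", 10_000_000)]


@dataclass
class GroundTruthModel(HMMModel):
    """An :class:`HMMModel` whose states carry biological role labels."""

    role_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.role_map and self.state_labels is None:
            roles = [self.role_map.get(i, f"S{i + 1}") for i in range(self.n_states)]
            if len(set(roles)) == len(roles):
                self.state_labels = dict(enumerate(roles))

    def states_with_role(self, *roles: str) -> list[int]:
        return [i for i, r in self.role_map.items() if r in roles]

    def role_of(self, state: int) -> str:
        return self.role_map.get(state, f"S{state + 1}")


def _greedy_binary_code(
    n_codes: int, n_bits: int, min_hamming: int, rng: np.random.Generator
) -> np.ndarray:
    """Pick ``n_codes`` bit patterns with pairwise Hamming >= min_hamming,
    greedily in a random order over the pattern space."""
    if n_bits <= 16:
        pool = np.array(list(itertools.product((0, 1), repeat=n_bits)), dtype=np.int8)
    else:
        pool = np.unique(
            rng.integers(0, 2, size=(1 << 16, n_bits), dtype=np.int8), axis=0
        )
    # greedy first-fit can wedge itself on an unlucky order (picking two
    # far-apart words may exclude everything else), so retry with fresh
    # shuffles a bounded number of times
    for _ in range(50):
        rng.shuffle(pool)
        chosen: list[np.ndarray] = []
        for cand in pool:
            if all(int(np.sum(cand != c)) >= min_hamming for c in chosen):
                chosen.append(cand)
                if len(chosen) == n_codes:
                    return np.array(chosen)
    raise ValueError(
        "inconsistent parameters: cannot achieve the requested emission "
        f"separation for {n_codes} states over {n_bits} marks"
    )


def generate_ground_truth_model(
    n_states: int,
    mark_names: list[str],
    min_emission_separation: float = 0.3,
    self_transition: float = 0.95,
    seed: int = 0,
    roles: list[str] | None = None,
) -> GroundTruthModel:
    """Random ground-truth model with guaranteed emission-row separation.

    Emission rows are pairwise L1-separated by at least
    ``min_emission_separation * n_marks``. Rows are built from random
    presence/absence patterns with a minimum Hamming distance, then softened
    away from 0/1 and jittered only as far as the separation slack allows,
    so the guarantee is exact. Transitions have ``self_transition`` on the
    diagonal with the remaining mass spread uniformly; the initial
    distribution is uniform.
    """
    K, M = int(n_states), len(mark_names)
    sep = float(min_emission_separation)
    if K < 2:
        raise ValueError("n_states must be at least 2")
    if not 0.0 < self_transition < 1.0:
        raise ValueError("self_transition must be in (0, 1)")
    if not 0.0 <= sep <= 1.0:
        raise ValueError("min_emission_separation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    d_req = int(np.ceil(sep * M - 1e-12))
    bits = _greedy_binary_code(K, M, max(d_req, 1) if sep > 0 else 0, rng)
    diffs = bits[:, None, :] != bits[None, :, :]
    ham = diffs.sum(axis=2) + np.eye(K, dtype=int) * (M + 1)
    dmin = int(ham.min())
    # Soften 0/1 towards (s, 1-s) and jitter by +-j without breaking the
    # L1 guarantee: dmin*(1-2s) - 2*M*j >= sep*M must hold.
    slack = dmin - sep * M
    s = min(0.1, 0.4 * slack / dmin) if slack > 0 else 0.0
    remaining = dmin * (1 - 2 * s) - sep * M
    j = max(0.0, min(0.05, 0.4 * remaining / M))
    emissions = np.where(bits == 1, 1.0 - s, s).astype(float)
    emissions = np.clip(emissions + rng.uniform(-j, j, size=emissions.shape), 0.0, 1.0)
    l1 = np.abs(emissions[:, None, :] - emissions[None, :, :]).sum(axis=2)
    assert (l1 + np.eye(K) * (M + 1) >= sep * M - 1e-9).all()

    transitions = np.full((K, K), (1.0 - self_transition) / (K - 1))
    np.fill_diagonal(transitions, self_transition)
    initial = np.full(K, 1.0 / K)
    if roles is None:
        roles = [
            DEFAULT_ROLE_PRIORITY[i] if i < len(DEFAULT_ROLE_PRIORITY) else f"S{i + 1}"
            for i in range(K)
        ]
    return GroundTruthModel(
        list(mark_names), initial, transitions, emissions,
        role_map=dict(enumerate(roles[:K])),
    )


def default_biosample_names(n_tissues: int = 4, n_timepoints: int = 3) -> pd.DataFrame:
    """Biosample grid: tissues x developmental timepoints (E11.5 + daily)."""
    tissues = ["forebrain", "midbrain", "liver", "heart", "limb", "lung",
               "kidney", "stomach", "intestine", "hindbrain", "neural-tube",
               "facial-prominence"][:n_tissues]
    rows = []
    for t in tissues:
        for i in range(n_timepoints):
            rows.append({"biosample": f"{t}_E{11.5 + i:.1f}", "tissue": t,
                         "timepoint": i})
    return pd.DataFrame(rows)


def simulate_state_paths(
    model: GroundTruthModel | HMMModel,
    binned_genome: BinnedGenome,
    n_biosamples: int,
    seed: int = 0,
    biosample_names: list[str] | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Independent Markov chains per (biosample, chromosome)."""
    if binned_genome.total_bins == 0:
        raise ValueError("empty genome")
    if biosample_names is None:
        biosample_names = [f"sample{i + 1}" for i in range(n_biosamples)]
    if len(biosample_names) != n_biosamples:
        raise ValueError("biosample_names length mismatch")
    init_cdf = np.cumsum(model.initial)
    trans_cdf = np.cumsum(model.transitions, axis=1)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_biosamples * len(binned_genome.chrom_names))
    paths: dict[str, dict[str, np.ndarray]] = {}
    it = iter(children)
    for b in biosample_names:
        paths[b] = {}
        for chrom in binned_genome.chrom_names:
            rng = np.random.default_rng(next(it))
            u = rng.random(binned_genome.n_bins(chrom))
            paths[b][chrom] = _kernels.sample_markov_path(init_cdf, trans_cdf, u)
    return paths


def simulate_binary_observations(
    model: GroundTruthModel | HMMModel,
    state_paths: dict[str, dict[str, np.ndarray]],
    missing_mark: str | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, dict[str, np.ndarray]]:
    """Ternary {0,1,MISSING} observations drawn from the emission matrix.

    Entries of ``missing_mark`` are independently set to missing with
    probability ``missing_rate`` (emulating no-CpG bins of a methylation
    track).
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    if missing_mark is not None and missing_mark not in model.mark_names:
        raise ValueError(f"unknown mark {missing_mark!r}")
    col = model.mark_names.index(missing_mark) if missing_mark is not None else None
    ss = np.random.SeedSequence(seed)
    obs: dict[str, dict[str, np.ndarray]] = {}
    flat = [(b, c) for b in state_paths for c in state_paths[b]]
    for (b, chrom), child in zip(flat, ss.spawn(len(flat))):
        rng = np.random.default_rng(child)
        path = state_paths[b][chrom]
        p = model.emissions[path]  # (L, M)
        x = (rng.random(p.shape) < p).astype(np.int8)
        if col is not None and missing_rate > 0:
            mask = rng.random(len(path)) < missing_rate
            x[mask, col] = MISSING
        obs.setdefault(b, {})[chrom] = x
    return obs


@dataclass
class CountTrackSpec:
    """Poisson count track: background rate everywhere, foreground rate in
    the given states; ChIP-type tracks also get a matched background-only
    control track."""

    background_rate: float
    foreground_rate: float
    foreground_states: set[int]
    paired_control: bool = True


@dataclass
class MethylationTrackSpec:
    """Per-CpG percent methylation: CpG counts ~ Poisson(density) per bin,
    per-CpG per-replicate percents from a state-specific Beta, as integers
    in 1..100."""

    cpg_density: float
    beta_params: dict[int, tuple[float, float]]
    n_replicates: int = 2


def simulate_raw_tracks(
    model: GroundTruthModel | HMMModel,
    state_paths: dict[str, dict[str, np.ndarray]],
    track_spec: dict[str, CountTrackSpec | MethylationTrackSpec],
    seed: int = 0,
    binned_genome: BinnedGenome | None = None,
) -> dict[str, dict[str, dict]]:
    """Raw per-bin signals feeding the binarization stage.

    Returns ``tracks[biosample][mark][chrom]``: for count tracks a dict with
    ``counts`` (and ``control`` when paired); for methylation tracks a dict
    with CpG bp offsets ``pos`` and an (n_replicates, n_cpgs) ``percent``
    integer matrix. ``binned_genome`` is only needed to give methylation
    CpGs bp coordinates; without it offsets are bin-index based.
    """
    for mark, spec in track_spec.items():
        if isinstance(spec, CountTrackSpec):
            if spec.background_rate <= 0 or spec.foreground_rate <= 0:
                raise ValueError(f"nonpositive Poisson rate for {mark!r}")
        elif isinstance(spec, MethylationTrackSpec):
            if spec.cpg_density < 0:
                raise ValueError(f"negative CpG density for {mark!r}")
    ss = np.random.SeedSequence(seed)
    flat = [(b, m) for b in state_paths for m in track_spec]
    out: dict[str, dict[str, dict]] = {b: {} for b in state_paths}
    bin_size = binned_genome.bin_size if binned_genome is not None else 1
    for (b, mark), child in zip(flat, ss.spawn(len(flat))):
        rng = np.random.default_rng(child)
        spec = track_spec[mark]
        per_chrom: dict[str, dict] = {}
        for chrom, path in state_paths[b].items():
            L = len(path)
            if isinstance(spec, CountTrackSpec):
                fg = np.isin(path, list(spec.foreground_states))
                lam = np.where(fg, spec.foreground_rate, spec.background_rate)
                entry = {"counts": rng.poisson(lam)}
                if spec.paired_control:
                    entry["control"] = rng.poisson(spec.background_rate, size=L)
                per_chrom[chrom] = entry
            else:
                n_cpg = rng.poisson(spec.cpg_density, size=L)
                bins = np.repeat(np.arange(L), n_cpg)
                pos = bins * bin_size + rng.integers(0, bin_size, size=len(bins))
                a = np.empty(len(bins))
                bvec = np.empty(len(bins))
                for st, (pa, pb) in spec.beta_params.items():
                    m = path[bins] == st
                    a[m], bvec[m] = pa, pb
                pct = np.clip(
                    np.rint(
                        100 * rng.beta(a, bvec, size=(spec.n_replicates, len(bins)))
                    ),
                    1, 100,
                ).astype(np.int16) if len(bins) else np.empty(
                    (spec.n_replicates, 0), dtype=np.int16
                )
                order = np.argsort(pos, kind="stable")
                per_chrom[chrom] = {"pos": pos[order], "percent": pct[:, order]}
        out[b][mark] = per_chrom
    return out


def simulate_gene_set(
    state_paths: dict[str, dict[str, np.ndarray]],
    role_map: dict[int, str],
    n_genes: int,
    placement_bias: dict[str, float],
    expression_spec: dict[str, tuple[float, float]],
    seed: int = 0,
    binned_genome: BinnedGenome | None = None,
    reference_biosample: str | None = None,
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Genes with state-biased TSS placement and role-driven expression.

    TSS bins are sampled (on a reference biosample's path) with probability
    proportional to ``placement_bias`` of the bin's role; each biosample's
    TPM is drawn from a log-normal whose (ln-mean, ln-sd) comes from
    ``expression_spec`` keyed by the TSS bin's role in *that* biosample
    (falling back to the ``"default"`` key), so genes sitting in
    bivalent-role bins get the low-expression component there.
    """
    if any(w < 0 for w in placement_bias.values()):
        raise ValueError("placement weights must be nonnegative")
    biosamples = list(state_paths)
    ref = reference_biosample or biosamples[0]
    chroms = list(state_paths[ref])
    bin_size = binned_genome.bin_size if binned_genome is not None else 200
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if n_genes == 0:
        return [], pd.DataFrame(columns=biosamples)

    path = np.concatenate([state_paths[ref][c] for c in chroms])
    lengths = [len(state_paths[ref][c]) for c in chroms]
    offsets = np.cumsum([0] + lengths[:-1])
    default_w = placement_bias.get("default", 0.0)
    w = np.array([placement_bias.get(role_map.get(s, ""), default_w) for s in path])
    if w.sum() <= 0:
        raise ValueError("placement weights select no bins")
    idx = rng.choice(len(path), size=n_genes, p=w / w.sum())

    genes: list[GeneModel] = []
    expr = np.empty((n_genes, len(biosamples)))
    default_spec = expression_spec.get("default", (np.log(5.0), 1.0))
    for g, gi in enumerate(idx):
        ci = int(np.searchsorted(offsets, gi, side="right")) - 1
        chrom, local = chroms[ci], int(gi - offsets[ci])
        tss = local * bin_size + int(rng.integers(0, bin_size))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{g + 1:05d}", [(chrom, tss)], strand))
        for j, b in enumerate(biosamples):
            role = role_map.get(int(state_paths[b][chrom][local]), "")
            mu, sd = expression_spec.get(role, default_spec)
            expr[g, j] = np.exp(rng.normal(mu, sd))
    table = pd.DataFrame(expr, index=[g.gene_id for g in genes], columns=biosamples)
    return genes, table


def simulate_silencer_set(
    state_paths: dict[str, dict[str, np.ndarray]],
    role_map: dict[int, str],
    n_silencers: int,
    group_bias: dict[int, dict[str, float]],
    length_range: tuple[int, int] = (400, 2000),
    seed: int = 0,
    binned_genome: BinnedGenome | None = None,
    genes: list[GeneModel] | None = None,
    link_distance_bp: tuple[float, float] = (1e3, 1e6),
    group_weights: dict[int, float] | None = None,
    reference_biosample: str | None = None,
) -> SilencerSet:
    """Silencers in four groups with group-specific state bias at their
    centers, optionally linked to target TSSs at log-uniform distances.

    Default group proportions follow the published catalog's four-group
    split (371:126:683:620).
    """
    ref = reference_biosample or next(iter(state_paths))
    chroms = list(state_paths[ref])
    bin_size = binned_genome.bin_size if binned_genome is not None else 200
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if group_weights is None:
        group_weights = {1: 371, 2: 126, 3: 683, 4: 620}
    groups = sorted(group_bias)
    gw = np.array([group_weights.get(g, 1.0) for g in groups], dtype=float)

    path = np.concatenate([state_paths[ref][c] for c in chroms])
    lengths = [len(state_paths[ref][c]) for c in chroms]
    offsets = np.cumsum([0] + lengths[:-1])
    roles = np.array([role_map.get(int(s), "") for s in path])
    chrom_len = {
        c: (binned_genome.chrom_length(c) if binned_genome is not None
            else lengths[i] * bin_size)
        for i, c in enumerate(chroms)
    }

    rows, links = [], {}
    tss_by_chrom: dict[str, np.ndarray] = {}
    if genes:
        for g in genes:
            for chrom, pos in g.tss:
                tss_by_chrom.setdefault(chrom, [])
                tss_by_chrom[chrom].append(pos)
        tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    ref_path = state_paths[ref]
    for i in range(n_silencers):
        grp = groups[rng.choice(len(groups), p=gw / gw.sum())]
        bias = group_bias[grp]
        default_w = bias.get("default", 0.0)
        w = np.array([bias.get(r, default_w) for r in roles], dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"group {grp} bias selects no bins")
        gi = int(rng.choice(len(path), p=w / w.sum()))
        ci = int(np.searchsorted(offsets, gi, side="right")) - 1
        chrom, local = chroms[ci], int(gi - offsets[ci])
        center = local * bin_size + bin_size // 2
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if length > chrom_len[chrom]:
            raise ValueError("genome too small for requested silencer length")
        start = max(0, min(center - length // 2, chrom_len[chrom] - length))
        sid = f"sil{i + 1:05d}"
        rows.append((chrom, start, start + length, grp, sid))
        if chrom in tss_by_chrom and len(tss_by_chrom[chrom]):
            # Target TSS: draw a log-uniform distance, then pick among the
            # nearest TSSs with the group's own role bias (silencer targets
            # share their silencer's chromatin context, as contact-mapped
            # silencer targets do).
            lo, hi = np.log10(link_distance_bp[0]), np.log10(link_distance_bp[1])
            d = 10 ** rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
            target = center + d
            arr = tss_by_chrom[chrom]
            k = int(np.clip(np.searchsorted(arr, target), 0, len(arr) - 1))
            lo_i, hi_i = max(0, k - 8), min(len(arr), k + 8)
            cands = arr[lo_i:hi_i]
            cand_roles = [
                role_map.get(int(ref_path[chrom][int(t) // bin_size]), "")
                for t in cands
            ]
            cw = np.array(
                [bias.get(r, default_w) + 0.05 for r in cand_roles]
            )
            links[sid] = [
                (chrom, int(cands[rng.choice(len(cands), p=cw / cw.sum())]))
            ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "group", "silencer_id"])
    return SilencerSet(df, links)


def simulate_conservation(
    state_paths: dict[str, dict[str, np.ndarray]],
    role_map: dict[int, str],
    role_means: dict[str, float],
    sd: float = 0.15,
    seed: int = 0,
    reference_biosample: str | None = None,
) -> dict[str, np.ndarray]:
    """Per-bin conservation scores: Gaussian around a role-specific mean on
    a reference biosample's ground-truth path."""
    ref = reference_biosample or next(iter(state_paths))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    default = role_means.get("default", 0.0)
    out = {}
    for chrom, path in state_paths[ref].items():
        mu = np.array([role_means.get(role_map.get(int(s), ""), default) for s in path])
        out[chrom] = mu + rng.normal(0.0, sd, size=len(path))
    return out


# ---------------------------------------------------------------------------
# Default study conditions: a hand-designed role-structured ground truth.
# ---------------------------------------------------------------------------

#: Emission probabilities per role over the ten default marks. Values mimic
#: the canonical mark combinations: active promoters (H3K4me3/H3K4me2/ATAC),
#: bivalent promoters (H3K4me3 + H3K27me3), enhancers (H3K4me1/H3K27ac),
#: transcription (H3K36me3), polycomb repression (H3K27me3), H3K9me3
#: heterochromatin, and two quiescent flavors differing in CpG methylation.
DEFAULT_EMISSIONS = {
    #            K4me1 K4me2 K4me3 K9ac K27ac K36me3 K9me3 K27me3 ATAC meCpG
    "Tss":     [0.30, 0.90, 0.95, 0.85, 0.75, 0.05, 0.02, 0.05, 0.90, 0.05],
    "TssFlnk": [0.80, 0.75, 0.55, 0.60, 0.65, 0.05, 0.02, 0.08, 0.60, 0.25],
    "TssBiv":  [0.50, 0.80, 0.90, 0.40, 0.20, 0.02, 0.05, 0.90, 0.70, 0.03],
    "Enh":     [0.90, 0.50, 0.10, 0.40, 0.85, 0.10, 0.02, 0.05, 0.70, 0.55],
    "EnhLo":   [0.70, 0.30, 0.05, 0.15, 0.30, 0.08, 0.05, 0.10, 0.35, 0.70],
    "Tx":      [0.10, 0.05, 0.05, 0.05, 0.10, 0.90, 0.02, 0.03, 0.05, 0.90],
    "ReprPC":  [0.10, 0.15, 0.15, 0.05, 0.05, 0.02, 0.05, 0.90, 0.10, 0.20],
    "Het":     [0.05, 0.02, 0.02, 0.02, 0.02, 0.03, 0.90, 0.10, 0.02, 0.80],
    "Quies":   [0.03, 0.02, 0.02, 0.02, 0.02, 0.02, 0.05, 0.05, 0.03, 0.85],
    "QuiesG":  [0.05, 0.03, 0.03, 0.03, 0.03, 0.10, 0.05, 0.08, 0.05, 0.10],
}

# Sparse transition structure. TssBiv exchanges only with its repressive/
# quiescent flanks, so every ground-truth bivalent run is flanked the way
# the domain extractor expects; Quies dominates the stationary distribution
# as quiescence dominates a real genome.
DEFAULT_TRANSITIONS = {
    "Tss":     {"Tss": 0.90, "TssFlnk": 0.06, "Quies": 0.04},
    "TssFlnk": {"TssFlnk": 0.85, "Tss": 0.08, "Enh": 0.03, "Quies": 0.04},
    "TssBiv":  {"TssBiv": 0.93, "ReprPC": 0.05, "Quies": 0.015, "QuiesG": 0.005},
    "Enh":     {"Enh": 0.88, "EnhLo": 0.05, "TssFlnk": 0.02, "Quies": 0.05},
    "EnhLo":   {"EnhLo": 0.85, "Enh": 0.05, "Quies": 0.10},
    "Tx":      {"Tx": 0.95, "Quies": 0.04, "QuiesG": 0.01},
    "ReprPC":  {"ReprPC": 0.82, "TssBiv": 0.12, "Quies": 0.05, "QuiesG": 0.01},
    "Het":     {"Het": 0.93, "Quies": 0.07},
    "Quies":   {"Quies": 0.9725, "Tss": 0.002, "TssFlnk": 0.002,
                "TssBiv": 0.0005, "Enh": 0.005, "EnhLo": 0.005, "Tx": 0.005,
                "ReprPC": 0.004, "Het": 0.003, "QuiesG": 0.001},
    "QuiesG":  {"QuiesG": 0.953, "Quies": 0.03, "TssBiv": 0.002,
                "ReprPC": 0.005, "Tx": 0.01},
}

DEFAULT_EXPRESSION_SPEC = {
    "Tss": (np.log(60.0), 0.8),
    "TssFlnk": (np.log(20.0), 0.8),
    "TssBiv": (np.log(1.5), 1.0),
    "ReprPC": (np.log(1.0), 1.0),
    "Quies": (np.log(0.5), 1.0),
    "QuiesG": (np.log(0.8), 1.0),
    "default": (np.log(5.0), 1.0),
}

DEFAULT_PLACEMENT_BIAS = {
    "Tss": 40.0, "TssFlnk": 10.0, "TssBiv": 25.0, "ReprPC": 5.0,
    "Enh": 2.0, "Quies": 0.3, "QuiesG": 0.3, "default": 1.0,
}

DEFAULT_SILENCER_GROUP_BIAS = {
    1: {"Tss": 0.40, "Enh": 0.40, "TssBiv": 0.15, "ReprPC": 0.05},
    2: {"Quies": 0.80, "QuiesG": 0.20},
    3: {"TssBiv": 0.60, "ReprPC": 0.40},
    4: {"TssBiv": 0.45, "ReprPC": 0.45, "Quies": 0.10},
}

DEFAULT_CONSERVATION_MEANS = {
    "TssBiv": 0.50, "Tss": 0.35, "TssFlnk": 0.25, "Enh": 0.20, "EnhLo": 0.12,
    "Tx": 0.15, "ReprPC": 0.15, "Het": 0.02, "Quies": 0.02, "QuiesG": 0.05,
    "default": 0.05,
}


def default_ground_truth_model() -> GroundTruthModel:
    """The canonical 10-state, 10-mark synthetic epigenome model."""
    roles = list(DEFAULT_EMISSIONS)
    K = len(roles)
    emissions = np.array([DEFAULT_EMISSIONS[r] for r in roles])
    transitions = np.zeros((K, K))
    for i, r in enumerate(roles):
        for dest, p in DEFAULT_TRANSITIONS[r].items():
            transitions[i, roles.index(dest)] = p
    transitions /= transitions.sum(axis=1, keepdims=True)
    initial = np.full(K, 1.0 / K)
    return GroundTruthModel(
        list(DEFAULT_MARKS), initial, transitions, emissions,
        role_map=dict(enumerate(roles)),
    )


def default_track_specs(model: GroundTruthModel) -> dict[str, object]:
    """Raw-track generative settings matched to the default model.

    Count foreground states are those emitting the mark with probability
    >= 0.5. ChIP rates give strong (~30x) enrichment so the Poisson test
    against control recovers most foreground bins; ATAC background is
    sparse, as accessible chromatin is. Methylation Beta parameters track
    the meCpG emission so the 50% threshold reproduces it.
    """
    specs: dict[str, object] = {}
    for m, mark in enumerate(model.mark_names):
        fg = {k for k in range(model.n_states) if model.emissions[k, m] >= 0.5}
        if mark == "ATAC":
            specs[mark] = CountTrackSpec(0.02, 8.0, fg, paired_control=False)
        elif mark == "meCpG":
            beta = {
                k: (1.0 + 6.0 * model.emissions[k, m],
                    1.0 + 6.0 * (1.0 - model.emissions[k, m]))
                for k in range(model.n_states)
            }
            specs[mark] = MethylationTrackSpec(2.0, beta, n_replicates=2)
        else:
            # rates are post-pooling (two replicates summed, as the study
            # pools treatment and control libraries)
            specs[mark] = CountTrackSpec(1.0, 30.0, fg, paired_control=True)
    return specs


@dataclass
class SyntheticDataset:
    """One complete synthetic study: genome, ground truth, observations,
    raw tracks, genes with expression, silencers, and conservation."""

    genome: BinnedGenome
    model: GroundTruthModel
    biosamples: pd.DataFrame  # biosample / tissue / timepoint
    state_paths: dict[str, dict[str, np.ndarray]]
    binary_obs: dict[str, dict[str, np.ndarray]]
    raw_tracks: dict[str, dict[str, dict]]
    genes: list[GeneModel]
    expression: pd.DataFrame
    silencers: SilencerSet
    conservation: dict[str, np.ndarray]
    seed: int

    @property
    def biosample_names(self) -> list[str]:
        return list(self.biosamples["biosample"])

    def tissue_of(self) -> dict[str, str]:
        return dict(zip(self.biosamples["biosample"], self.biosamples["tissue"]))


def simulate_dataset(
    seed: int = 0,
    model: GroundTruthModel | None = None,
    chromosomes: list[tuple[str, int]] | None = None,
    bin_size: int = 200,
    n_tissues: int = 4,
    n_timepoints: int = 3,
    n_genes: int = 2000,
    n_silencers: int = 600,
    wgbs_missing_rate: float = 0.1,
    with_raw_tracks: bool = True,
) -> SyntheticDataset:
    """Generate the full default synthetic study.

    One global seed spawns per-component child seeds in a fixed order
    (paths, observations, tracks, genes, silencers, conservation), so the
    dataset is bit-for-bit reproducible and each component individually so.
    """
    if model is None:
        model = default_ground_truth_model()
    if chromosomes is None:
        chromosomes = DEFAULT_CHROMOSOMES
    genome = BinnedGenome(chromosomes, bin_size)
    table = default_biosample_names(n_tissues, n_timepoints)
    names = list(table["biosample"])
    ss = np.random.SeedSequence(seed)
    s_paths, s_obs, s_tracks, s_genes, s_sil, s_cons = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(6)
    )
    paths = simulate_state_paths(model, genome, len(names), s_paths, names)
    missing_mark = "meCpG" if "meCpG" in model.mark_names else None
    obs = simulate_binary_observations(
        model, paths, missing_mark, wgbs_missing_rate, s_obs
    )
    tracks = (
        simulate_raw_tracks(model, paths, default_track_specs(model), s_tracks, genome)
        if with_raw_tracks
        else {}
    )
    genes, expression = simulate_gene_set(
        paths, model.role_map, n_genes, DEFAULT_PLACEMENT_BIAS,
        DEFAULT_EXPRESSION_SPEC, s_genes, genome,
    )
    silencers = simulate_silencer_set(
        paths, model.role_map, n_silencers, DEFAULT_SILENCER_GROUP_BIAS,
        seed=s_sil, binned_genome=genome, genes=genes,
    )
    conservation = simulate_conservation(
        paths, model.role_map, DEFAULT_CONSERVATION_MEANS, 0.15, s_cons
    )
    return SyntheticDataset(
        genome, model, table, paths, obs, tracks, genes, expression,
        silencers, conservation, seed,
    )
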