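"""Multivariate Bernoulli hidden Markov model over binarized chromatin marks.

The observation model is ChromHMM-style: in state ``k`` each mark ``m`` is
present in a bin independently with probability ``emissions[k, m]``; a mark
recorded as missing contributes no factor to the bin's likelihood. Training
is joint Baum-Welch over many (biosample, chromosome) sequences sharing one
model, each sequence restarting from the initial distribution. Decoding
assigns each bin its maximum-posterior state only when that posterior
exceeds 0.5 strictly; otherwise the bin is "unassigned".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import _kernels
from .constants import MISSING, UNASSIGNED, UNASSIGNED_NAME
from .genome import BinnedGenome

#: Floor applied to emission probabilities before taking logs.
EMISSION_EPS = 1e-10


@dataclass
class HMMModel:
    """Model parameters: initial distribution, transition matrix, and the
    K x M Bernoulli emission matrix, with optional state names."""

    mark_names: list[str]
    initial: np.ndarray
    transitions: np.ndarray
    emissions: np.ndarray
    state_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.mark_names = list(self.mark_names)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.initial.shape[0]

    @property
    def n_marks(self) -> int:
        return len(self.mark_names)

    @property
    def state_names(self) -> list[str]:
        """Per-state display names: labels if provided, else S1..SK."""
        if self.state_labels is None:
            return [f"S{i + 1}" for i in range(self.n_states)]
        return [self.state_labels.get(i, f"S{i + 1}") for i in range(self.n_states)]

    def validate(self) -> None:
        K, M = self.n_states, self.n_marks
        if self.transitions.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        if self.emissions.shape != (K, M):
            raise ValueError("emission matrix shape mismatch")
        if abs(self.initial.sum() - 1.0) > 1e-10:
            raise ValueError("initial distribution does not sum to 1")
        if np.any(np.abs(self.transitions.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("transition rows must sum to 1")
        if np.any((self.emissions < 0) | (self.emissions > 1)):
            raise ValueError("emissions must lie in [0, 1]")
        if self.state_labels is not None:
            names = list(self.state_labels.values())
            if len(set(names)) != len(names):
                raise ValueError("state labels must be unique")


@dataclass
class ObservationSequence:
    """Ternary {0, 1, MISSING} observations for one biosample/chromosome."""

    biosample: str
    chromosome: str
    marks: list[str]
    values: np.ndarray  # (L, M) int8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.marks):
            raise ValueError("observation matrix shape does not match marks")
        bad = ~np.isin(self.values, (0, 1, MISSING))
        if bad.any():
            raise ValueError("observations must be 0, 1, or MISSING")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class Segmentation:
    """Per-bin state assignment for one biosample.

    ``labels`` maps chromosome -> int array with :data:`UNASSIGNED` (-1)
    where the max posterior did not exceed 0.5. ``max_posterior`` stores that
    maximum per bin.
    """

    genome: BinnedGenome
    state_names: list[str]
    labels: dict[str, np.ndarray]
    max_posterior: dict[str, np.ndarray]
    biosample: str | None = None

    def __post_init__(self) -> None:
        for chrom in self.genome.chrom_names:
            if chrom not in self.labels:
                raise ValueError(f"segmentation missing chromosome {chrom!r}")
            if len(self.labels[chrom]) != self.genome.n_bins(chrom):
                raise ValueError(f"label length mismatch on {chrom!r}")

    def all_labels(self) -> np.ndarray:
        """Labels concatenated over chromosomes in genome order."""
        return np.concatenate([self.labels[c] for c in self.genome.chrom_names])

    def label_name(self, value: int) -> str:
        return UNASSIGNED_NAME if value == UNASSIGNED else self.state_names[value]


def _check_marks(model: HMMModel, seq: ObservationSequence) -> None:
    if seq.marks != model.mark_names:
        raise ValueError(
            f"sequence marks {seq.marks} do not match model marks {model.mark_names}"
        )


def emission_log_prob(model: HMMModel, row: np.ndarray) -> np.ndarray:
    """Per-state log emission probability of one ternary observation row.

    Missing marks contribute no factor; with every mark missing the result
    is the zero vector.
    """
    row = np.asarray(row)
    if row.shape != (model.n_marks,):
        raise ValueError("row length must equal the number of marks")
    return _log_obs_matrix(model, row[None, :])[0]


def _log_obs_matrix(model: HMMModel, values: np.ndarray) -> np.ndarray:
    """(L, K) log emission likelihood for a ternary matrix."""
    E = np.clip(model.emissions, EMISSION_EPS, 1.0 - EMISSION_EPS)
    log_p = np.log(E)  # (K, M)
    log_q = np.log1p(-E)
    ones = (values == 1).astype(float)
    zeros = (values == 0).astype(float)
    return ones @ log_p.T + zeros @ log_q.T


def _scaled_b(model: HMMModel, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Emission likelihoods rescaled per bin to max 1, plus the log shifts."""
    log_b = _log_obs_matrix(model, values)
    shift = log_b.max(axis=1)
    return np.exp(log_b - shift[:, None]), shift


def forward_backward(
    model: HMMModel, sequence: ObservationSequence
) -> tuple[np.ndarray, float]:
    """Posterior state probabilities and log-likelihood for one sequence.

    Returns ``(posterior, log_likelihood)`` where posterior is (L, K) with
    rows summing to 1.
    """
    _check_marks(model, sequence)
    if len(sequence) == 0:
        raise ValueError("empty observation sequence")
    B, shift = _scaled_b(model, sequence.values)
    alpha, c = _kernels.forward_scaled(model.initial, model.transitions, B)
    beta = _kernels.backward_scaled(model.transitions, B, c)
    posterior = alpha * beta
    posterior /= posterior.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + shift.sum())
    return posterior, loglik


@dataclass
class TrainingLog:
    """Per-restart log-likelihood trajectories from Baum-Welch."""

    loglik_per_restart: list[list[float]] = field(default_factory=list)
    best_restart: int = -1

    @property
    def best_trajectory(self) -> list[float]:
        return self.loglik_per_restart[self.best_restart]


def _random_init(K: int, M: int, rng: np.random.Generator) -> tuple[np.ndarray, ...]:
    # Uniform(0.2, 0.8) emissions, 0.9 self-transition, uniform initial.
    emissions = rng.uniform(0.2, 0.8, size=(K, M))
    transitions = np.full((K, K), 0.1 / (K - 1))
    np.fill_diagonal(transitions, 0.9)
    initial = np.full(K, 1.0 / K)
    return initial, transitions, emissions


def _em_pass(
    model: HMMModel, sequences: list[ObservationSequence]
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One E-step over all sequences: log-likelihood plus sufficient stats."""
    K, M = model.n_states, model.n_marks
    total_ll = 0.0
    gamma0 = np.zeros(K)
    xi = np.zeros((K, K))
    emit_num = np.zeros((K, M))
    emit_den = np.zeros((K, M))
    for seq in sequences:
        B, shift = _scaled_b(model, seq.values)
        alpha, c = _kernels.forward_scaled(model.initial, model.transitions, B)
        beta = _kernels.backward_scaled(model.transitions, B, c)
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        total_ll += float(np.log(c).sum() + shift.sum())
        gamma0 += gamma[0]
        xi += _kernels.transition_expectations(
            alpha, beta, model.transitions, B, c
        )
        ones = (seq.values == 1).astype(float)
        observed = (seq.values != MISSING).astype(float)
        emit_num += gamma.T @ ones
        emit_den += gamma.T @ observed
    return total_ll, gamma0, xi, emit_num, emit_den


def baum_welch(
    sequences: list[ObservationSequence],
    K: int,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
    init_model: HMMModel | None = None,
) -> tuple[HMMModel, TrainingLog]:
    """Joint EM over independent sequences sharing one model.

    Each restart draws a fresh random initialization (unless ``init_model``
    is given, in which case a single run starts from it); the restart with
    the best final log-likelihood wins. The training log records the
    log-likelihood evaluated at the parameters entering each iteration, so
    consecutive entries are non-decreasing up to numerical slack.
    """
    if not sequences:
        raise ValueError("no observation sequences given")
    if K < 2:
        raise ValueError("K must be at least 2")
    marks = sequences[0].marks
    for s in sequences:
        if s.marks != marks:
            raise ValueError("all sequences must share one mark order")
    total_bins = sum(len(s) for s in sequences)
    if total_bins < 10 * K:
        raise ValueError("need at least 10 bins per state to train")
    M = len(marks)
    rng = np.random.default_rng(seed)
    restarts = 1 if init_model is not None else n_restarts

    log = TrainingLog()
    best_model, best_ll = None, -np.inf
    for r in range(restarts):
        if init_model is not None:
            model = HMMModel(
                marks,
                init_model.initial.copy(),
                init_model.transitions.copy(),
                init_model.emissions.copy(),
            )
        else:
            pi, A, E = _random_init(K, M, rng)
            model = HMMModel(marks, pi, A, E)
        traj: list[float] = []
        prev_ll = -np.inf
        for _ in range(max_iter):
            ll, gamma0, xi, num, den = _em_pass(model, sequences)
            traj.append(ll)
            # M-step
            pi = gamma0 / gamma0.sum()
            A = model.transitions.copy()
            row = xi.sum(axis=1)
            ok = row > 0
            A[ok] = xi[ok] / row[ok, None]
            E = model.emissions.copy()
            okd = den > 0
            E[okd] = num[okd] / den[okd]
            model = HMMModel(marks, pi, A, np.clip(E, 0.0, 1.0))
            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
                break
            prev_ll = ll
        final_ll, *_ = _em_pass(model, sequences)
        traj.append(final_ll)
        log.loglik_per_restart.append(traj)
        if final_ll > best_ll:
            best_ll, best_model, log.best_restart = final_ll, model, r
    assert best_model is not None
    return best_model, log


def posterior_decode(
    model: HMMModel,
    sequences: ObservationSequence | list[ObservationSequence],
    genome: BinnedGenome,
    biosample: str | None = None,
) -> Segmentation:
    """Posterior decoding with the strict >0.5 assignment rule.

    A bin gets the argmax-posterior state only if that posterior exceeds 0.5
    strictly; otherwise it is labeled unassigned. Ties in the argmax resolve
    to the lowest state index.
    """
    if isinstance(sequences, ObservationSequence):
        sequences = [sequences]
    by_chrom = {s.chromosome: s for s in sequences}
    labels: dict[str, np.ndarray] = {}
    maxpost: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        if chrom not in by_chrom:
            raise ValueError(f"no observation sequence for chromosome {chrom!r}")
        seq = by_chrom[chrom]
        if len(seq) != genome.n_bins(chrom):
            raise ValueError(f"sequence length mismatch on {chrom!r}")
        post, _ = forward_backward(model, seq)
        arg = post.argmax(axis=1)
        mp = post[np.arange(len(seq)), arg]
        lab = np.where(mp > 0.5, arg, UNASSIGNED).astype(np.int16)
        labels[chrom] = lab
        maxpost[chrom] = mp.astype(np.float64)
    if biosample is None:
        biosample = sequences[0].biosample
    return Segmentation(genome, model.state_names, labels, maxpost, biosample)


def decode_with_missing_marks(
    model: HMMModel,
    sequences: ObservationSequence | list[ObservationSequence],
    genome: BinnedGenome,
    dropped_marks: set[str],
    biosample: str | None = None,
) -> Segmentation:
    """Posterior decoding after masking some marks to missing.

    Emulates applying a full-mark model to a biosample that lacks assays for
    ``dropped_marks``.
    """
    if isinstance(sequences, ObservationSequence):
        sequences = [sequences]
    unknown = set(dropped_marks) - set(model.mark_names)
    if unknown:
        raise ValueError(f"unknown marks: {sorted(unknown)}")
    if set(dropped_marks) == set(model.mark_names):
        warnings.warn("all marks dropped; decoding is driven purely by transitions")
    cols = [model.mark_names.index(m) for m in dropped_marks]
    masked = []
    for seq in sequences:
        vals = seq.values.copy()
        vals[:, cols] = MISSING
        masked.append(
            ObservationSequence(seq.biosample, seq.chromosome, seq.marks, vals)
        )
    return posterior_decode(model, masked, genome, biosample)


def match_states(model_a: HMMModel, model_b: HMMModel) -> np.ndarray:
    """Optimal state matching by emission-row L1 distance.

    Returns ``perm`` with ``perm[i]`` the state of ``model_b`` assigned to
    state ``i`` of ``model_a``, minimizing the total L1 distance between
    matched emission rows.
    """
    if model_a.n_states != model_b.n_states:
        raise ValueError("models must have equal numbers of states")
    if model_a.mark_names != model_b.mark_names:
        raise ValueError("models must share a mark set and order")
    cost = np.abs(
        model_a.emissions[:, None, :] - model_b.emissions[None, :, :]
    ).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(model_a.n_states, dtype=int)
    perm[rows] = cols
    return perm
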