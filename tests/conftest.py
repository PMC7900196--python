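import numpy as np
import pytest

import chromstate.pipeline as pipeline
import chromstate.simulate as sim
from chromstate.constants import UNASSIGNED, UNASSIGNED_NAME
from chromstate.genome import BinnedGenome
from chromstate.hmm import HMMModel, Segmentation


@pytest.fixture(scope="session")
def default_model():
    return sim.default_ground_truth_model()


@pytest.fixture(scope="session")
def small_dataset():
    """A compact but complete synthetic study shared across test modules."""
    return sim.simulate_dataset(
        seed=20_240_101,
        n_tissues=2,
        n_timepoints=2,
        n_genes=800,
        n_silencers=200,
        chromosomes=[("chr1", 1_600_000), ("chr2", 1_200_000)],
    )


@pytest.fixture(scope="session")
def decoded(small_dataset):
    """Posterior decodings of every biosample with the true model."""
    ds = small_dataset
    return pipeline.decode_all(ds.model, ds.binary_obs, ds.genome)


def make_segmentation(labels_by_chrom, state_names, bin_size=200, biosample="s1"):
    """Build a Segmentation directly from label arrays (posteriors set to 1
    for assigned bins, 0.5 for unassigned)."""
    chroms = [(c, len(v) * bin_size) for c, v in labels_by_chrom.items()]
    genome = BinnedGenome(chroms, bin_size)
    labels = {c: np.asarray(v, dtype=np.int16) for c, v in labels_by_chrom.items()}
    maxpost = {
        c: np.where(v == UNASSIGNED, 0.5, 1.0).astype(float)
        for c, v in labels.items()
    }
    return Segmentation(genome, list(state_names), labels, maxpost, biosample)


# ---------------------------------------------------------------------------
# Independent oracles (brute force; never share code with the implementation)
# ---------------------------------------------------------------------------


def enumerate_posteriors(model: HMMModel, values: np.ndarray):
    """Exact posteriors and log-likelihood by summing over all K^L paths."""
    import itertools

    from chromstate.hmm import emission_log_prob

    L = values.shape[0]
    K = model.n_states
    log_b = np.array([emission_log_prob(model, values[t]) for t in range(L)])
    post = np.zeros((L, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=L):
        lp = np.log(model.initial[path[0]]) + log_b[0, path[0]]
        for t in range(1, L):
            lp += np.log(model.transitions[path[t - 1], path[t]]) + log_b[t, path[t]]
        p = np.exp(lp)
        total += p
        for t, s in enumerate(path):
            post[t, s] += p
    return post / total, float(np.log(total))


def scan_bivalent_runs(labels, biv, flanks):
    """Linear neighbor scan over a label array: maximal runs of ``biv``
    whose immediate neighbors on both sides are in ``flanks``."""
    runs = []
    n = len(labels)
    i = 0
    while i < n:
        if labels[i] == biv:
            j = i
            while j < n and labels[j] == biv:
                j += 1
            if i > 0 and j < n and labels[i - 1] in flanks and labels[j] in flanks:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs
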