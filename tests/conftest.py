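import numpy as np
import pytest

from seqdbn import (
    CPTParams,
    DBNParams,
    DBNSpec,
    NodeSpec,
    SequenceBatch,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_hmm_spec(n_states=2, n_out=2):
    """Canonical HMM: hidden discrete chain emitting a discrete output."""
    return DBNSpec(
        nodes=(NodeSpec("h", "discrete", n_states, hidden_allowed=True),
               NodeSpec("o", "discrete", n_out)),
        intra_edges=((0, 1),),
        inter_edges=((0, 0),),
    )


def make_hmm_params(spec, pi, T, E):
    """Wrap (initial, transition, emission) tables as network parameters."""
    return DBNParams(
        spec=spec,
        cpds=[CPTParams(table=np.asarray(T, dtype=float)),
              CPTParams(table=np.asarray(E, dtype=float))],
        cpds0=[CPTParams(table=np.asarray(pi, dtype=float)), None],
    )


def make_hmm_batch(spec, outputs, hidden=None):
    """One-sequence batch with observed outputs and (by default) a fully
    hidden chain."""
    outputs = np.asarray(outputs, dtype=np.int64)
    L = len(outputs)
    if hidden is None:
        h_vals = np.zeros(L, dtype=np.int64)
        h_mask = np.ones(L, dtype=bool)
    else:
        h_vals = np.asarray(hidden, dtype=np.int64)
        h_mask = np.zeros(L, dtype=bool)
    return SequenceBatch.from_arrays(
        spec,
        [([h_vals, outputs], [h_mask, np.zeros(L, dtype=bool)])],
    )


def recovery_hmm_truth(spec):
    """A strongly identifiable 5-state HMM for parameter-recovery studies:
    a noisy cyclic automaton (advance w.p. 0.7, stay 0.15, jump 0.05 to each
    other state) emitting its own symbol w.p. 0.95.  Every state has a
    distinct dynamical signature, so the likelihood is sharply curved and
    single-run EM recovers the tables."""
    n = 5
    T = np.full((n, n), 0.05)
    for i in range(n):
        T[i, i] = 0.15
        T[i, (i + 1) % n] = 0.70
    T /= T.sum(axis=1, keepdims=True)
    E = 0.95 * np.eye(n) + (0.05 / (n - 1)) * (1 - np.eye(n))
    pi = np.full(n, 1.0 / n)
    return make_hmm_params(spec, pi, T, E), T, E


@pytest.fixture
def hmm_2state():
    """A small, well-conditioned 2-state/2-symbol HMM with fixed tables."""
    spec = make_hmm_spec(2, 2)
    pi = [0.6, 0.4]
    T = [[0.7, 0.3], [0.2, 0.8]]
    E = [[0.9, 0.1], [0.3, 0.7]]
    return spec, make_hmm_params(spec, pi, T, E), np.array(pi), np.array(T), np.array(E)
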