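"""Inference: Gibbs sampling over hidden discrete values, exact forward
likelihood for HMM-shaped networks, completed-data log-likelihood.

Hidden entries are restricted to discrete nodes, so every Gibbs conditional
is a finite enumeration over the node's states: p(h | blanket) is
proportional to p(h | parents) times the product of the node's children's
densities.  The sweep uses a systematic scan (slice-major, node order within
a slice) and is vectorized across sequences — sequences are mutually
independent, so resampling the same (slice, node) entry of every sequence
simultaneously is a valid Gibbs step.
"""
from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .core import DBNSpec, SequenceBatch, Sequence, VECTOR_FAMILIES, INT_FAMILIES
from .errors import DataError, SeqDBNError, TopologyError
from .params import DBNParams

__all__ = [
    "markov_blanket",
    "GibbsSampler",
    "gibbs_sweep",
    "gibbs_infer",
    "completed_loglik",
    "forward_loglik",
    "hmm_structure",
    "ancestral_sample",
]


class UnderflowError(SeqDBNError, FloatingPointError):
    """All states of a Gibbs conditional carry zero probability."""


# ---------------------------------------------------------------------------
# Markov blanket
# ---------------------------------------------------------------------------

def markov_blanket(spec: DBNSpec, n_slices: int, t: int, i: int):
    """Blanket of node ``i`` at slice ``t`` in the unrolled network.

    Parents, children (intra and inter, across slice boundaries) and
    co-parents of children; boundary slices are truncated.  Returns sorted
    unique (slice, node) pairs excluding the node itself.
    """
    if not (0 <= t < n_slices and 0 <= i < spec.n_nodes):
        raise IndexError("slice or node index out of range")
    members: set[tuple[int, int]] = set()
    if t > 0:
        members.update((t - 1, p) for p in spec.inter_parents(i))
    members.update((t, p) for p in spec.intra_parents(i))
    children = [(t, c) for c in spec.intra_children(i)]
    if t + 1 < n_slices:
        children.extend((t + 1, c) for c in spec.inter_children(i))
    for tc, c in children:
        members.add((tc, c))
        if tc > 0:
            members.update((tc - 1, p) for p in spec.inter_parents(c))
        members.update((tc, p) for p in spec.intra_parents(c))
    members.discard((t, i))
    return sorted(members)


# ---------------------------------------------------------------------------
# Padded engine over a sequence batch
# ---------------------------------------------------------------------------

class _Engine:
    """Padded per-node value arrays plus configuration-index helpers."""

    def __init__(self, params: DBNParams, data: SequenceBatch):
        spec = data.spec
        if params.spec is not spec and params.spec != spec:
            raise DataError("params and data refer to different specifications")
        self.spec = spec
        self.params = params
        self.N = data.n_sequences
        self.lengths = np.array(data.lengths, dtype=int)
        self.T = int(self.lengths.max()) if self.N else 0
        self.valid = np.arange(self.T)[None, :] < self.lengths[:, None]
        self.vals: list[np.ndarray] = []
        self.hid: list[np.ndarray] = []
        for i, nd in enumerate(spec.nodes):
            if nd.family in VECTOR_FAMILIES:
                shape = (self.N, self.T, nd.size)
            else:
                shape = (self.N, self.T)
            dtype = np.int64 if nd.family in INT_FAMILIES else float
            v = np.zeros(shape, dtype=dtype)
            h = np.zeros((self.N, self.T), dtype=bool)
            for s, seq in enumerate(data.sequences):
                L = seq.length
                v[s, :L] = seq.values[i]
                h[s, :L] = seq.mask[i]
            self.vals.append(v)
            self.hid.append(h)

    # -- configuration indices ---------------------------------------------

    def cfg(self, i: int, t: int, rows=slice(None)) -> np.ndarray:
        """Flat parent-configuration index of node i at slice t (vector
        over the selected sequences)."""
        initial = t == 0 and self.spec.has_initial_params(i)
        parents = self.spec.parents(i, initial)
        if not parents:
            base = self.vals[i][rows]
            n = base.shape[0] if base.ndim else 1
            return np.zeros(n, dtype=int)
        sizes = self.spec.parent_sizes(i, initial)
        digits = [self.vals[p][rows, t + off] for off, p in parents]
        return np.ravel_multi_index(tuple(digits), sizes)

    def cfg_base_stride(self, c: int, t: int, wrt: tuple[int, int], rows):
        """Configuration index of child ``c`` at slice ``t`` with the digit
        of parent ``wrt`` = (slice offset, node) zeroed, plus that digit's
        stride.  Used to enumerate a hidden parent's candidate states."""
        initial = t == 0 and self.spec.has_initial_params(c)
        parents = self.spec.parents(c, initial)
        sizes = self.spec.parent_sizes(c, initial)
        j = parents.index(wrt)
        digits = []
        for k, (off, p) in enumerate(parents):
            if k == j:
                digits.append(np.zeros(1, dtype=np.int64))
            else:
                digits.append(self.vals[p][rows, t + off])
        digits = np.broadcast_arrays(*digits)
        base = np.ravel_multi_index(tuple(d.astype(np.int64) for d in digits), sizes)
        stride = int(np.prod(sizes[j + 1:], dtype=int))
        n = len(self.vals[c][rows, t])
        if base.shape != (n,):
            base = np.broadcast_to(base, (n,)).copy()
        return base, stride

    def node_values(self, i: int, t: int, rows=slice(None)) -> np.ndarray:
        return self.vals[i][rows, t]

    def cpd(self, i: int, t: int):
        return self.params.cpd(i, initial=(t == 0 and self.spec.has_initial_params(i)))

    def node_logp(self, i: int, t: int, rows) -> np.ndarray:
        cpd = self.cpd(i, t)
        return cpd.logp(self.cfg(i, t, rows), self.node_values(i, t, rows))

    # -- hidden-assignment views --------------------------------------------

    def extract_hidden(self):
        """Hidden assignment as [sequence][node] -> int array or None."""
        out = []
        for s in range(self.N):
            L = int(self.lengths[s])
            per_node = []
            for i in range(self.spec.n_nodes):
                if self.hid[i][s, :L].any():
                    per_node.append(self.vals[i][s, :L].copy())
                else:
                    per_node.append(None)
            out.append(per_node)
        return out

    def apply_hidden(self, hidden) -> None:
        for s in range(self.N):
            L = int(self.lengths[s])
            for i in range(self.spec.n_nodes):
                arr = hidden[s][i]
                if arr is None:
                    continue
                m = self.hid[i][s, :L]
                self.vals[i][s, :L][m] = np.asarray(arr)[m]

    def completed_batch(self, data: SequenceBatch) -> SequenceBatch:
        """A copy of ``data`` whose hidden entries carry current assignments."""
        out = data.copy()
        for s, seq in enumerate(out.sequences):
            L = seq.length
            for i in range(self.spec.n_nodes):
                m = seq.mask[i]
                if m.any():
                    seq.values[i][m] = self.vals[i][s, :L][m]
        return out


# ---------------------------------------------------------------------------
# Gibbs sampling
# ---------------------------------------------------------------------------

class GibbsSampler:
    """Systematic-scan Gibbs sampler over the hidden discrete entries.

    Construction initializes every hidden entry by ancestral sampling from
    the current model (children ignored), which starts the chain in a
    feasible region.  ``resample_ops`` counts state-probability evaluations
    (entries resampled times states each), the quantity that scales as
    O(total slices x node size) per sweep.
    """

    def __init__(self, params: DBNParams, data: SequenceBatch,
                 rng: np.random.Generator, init: bool = True):
        self.engine = _Engine(params, data)
        self.data = data
        self.resample_ops = 0
        self.n_sweeps = 0
        # (t, i) entries that contain at least one hidden value, in scan order
        self._scan = []
        eng = self.engine
        for t in range(eng.T):
            for i in range(eng.spec.n_nodes):
                if eng.hid[i][:, t].any():
                    self._scan.append((t, i))
        if init:
            self._ancestral_init(rng)

    @property
    def params(self) -> DBNParams:
        return self.engine.params

    @params.setter
    def params(self, new: DBNParams) -> None:
        self.engine.params = new

    def _ancestral_init(self, rng: np.random.Generator) -> None:
        eng = self.engine
        for t, i in self._scan:
            m = eng.hid[i][:, t] & eng.valid[:, t]
            rows = np.nonzero(m)[0]
            if not len(rows):
                continue
            cpd = eng.cpd(i, t)
            cfg = eng.cfg(i, t, rows)
            eng.vals[i][rows, t] = cpd.sample_vec(cfg, rng.random(len(rows)))

    def sweep(self, rng: np.random.Generator) -> "GibbsSampler":
        """One systematic scan; every hidden entry is resampled from its
        conditional given its Markov blanket."""
        eng = self.engine
        spec = eng.spec
        for t, i in self._scan:
            m = eng.hid[i][:, t] & eng.valid[:, t]
            rows = np.nonzero(m)[0]
            if not len(rows):
                continue
            s = spec.nodes[i].size
            cpd = eng.cpd(i, t)
            scores = cpd.logp_all(eng.cfg(i, t, rows)).copy()
            # intra children at t
            for c in spec.intra_children(i):
                ccpd = eng.cpd(c, t)
                base, stride = eng.cfg_base_stride(c, t, (0, i), rows)
                x = eng.node_values(c, t, rows)
                for k in range(s):
                    scores[:, k] += ccpd.logp(base + k * stride, x)
            # inter children at t+1
            if t + 1 < eng.T:
                sub = eng.valid[rows, t + 1]
                srows = rows[sub]
                if len(srows):
                    for c in spec.inter_children(i):
                        ccpd = eng.cpd(c, t + 1)
                        base, stride = eng.cfg_base_stride(c, t + 1, (-1, i), srows)
                        x = eng.node_values(c, t + 1, srows)
                        for k in range(s):
                            scores[sub, k] += ccpd.logp(base + k * stride, x)
            norm = logsumexp(scores, axis=1)
            bad = ~np.isfinite(norm)
            if bad.any():
                seq = int(rows[np.nonzero(bad)[0][0]])
                raise UnderflowError(
                    f"all states have zero probability at sequence {seq}, "
                    f"slice {t}, node {spec.nodes[i].name!r}"
                )
            probs = np.exp(scores - norm[:, None])
            cum = np.cumsum(probs, axis=1)
            u = rng.random(len(rows))
            draw = np.minimum((cum < u[:, None]).sum(axis=1), s - 1)
            eng.vals[i][rows, t] = draw
            self.resample_ops += len(rows) * s
        self.n_sweeps += 1
        return self

    def assignment(self):
        return self.engine.extract_hidden()

    def completed_batch(self) -> SequenceBatch:
        return self.engine.completed_batch(self.data)


def gibbs_sweep(params: DBNParams, data: SequenceBatch, hidden,
                rng: np.random.Generator):
    """One Gibbs sweep starting from the assignment ``hidden``; returns the
    new assignment.  Convenience wrapper around :class:`GibbsSampler`."""
    sampler = GibbsSampler(params, data, rng, init=False)
    sampler.engine.apply_hidden(hidden)
    sampler.sweep(rng)
    return sampler.assignment()


def gibbs_infer(params: DBNParams, data: SequenceBatch, n_burn: int,
                n_samples: int, rng: np.random.Generator):
    """Posterior state frequencies of every hidden entry.

    Runs ``n_burn`` burn-in sweeps then ``n_samples`` retained sweeps and
    returns ``freq[sequence][node]`` — an (L, size) frequency table for
    hidden nodes (rows sum to 1), None for nodes with no hidden entries.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    sampler = GibbsSampler(params, data, rng)
    for _ in range(n_burn):
        sampler.sweep(rng)
    eng = sampler.engine
    spec = eng.spec
    counts = [
        [np.zeros((int(eng.lengths[s]), spec.nodes[i].size))
         if eng.hid[i][s, :int(eng.lengths[s])].any() else None
         for i in range(spec.n_nodes)]
        for s in range(eng.N)
    ]
    for _ in range(n_samples):
        sampler.sweep(rng)
        for s in range(eng.N):
            L = int(eng.lengths[s])
            for i in range(spec.n_nodes):
                if counts[s][i] is not None:
                    idx = eng.vals[i][s, :L]
                    counts[s][i][np.arange(L), idx] += 1.0
    for s in range(eng.N):
        for i in range(spec.n_nodes):
            if counts[s][i] is not None:
                counts[s][i] /= n_samples
    return counts


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def completed_loglik(params: DBNParams, data: SequenceBatch, hidden=None) -> float:
    """Joint log-probability of the data with all hidden entries assigned.

    Sums every node's log-density given its (fully assigned) parents over
    all sequences and slices.  ``hidden`` may be omitted for fully observed
    data.
    """
    eng = _Engine(params, data)
    if hidden is not None:
        eng.apply_hidden(hidden)
    else:
        if any(eng.hid[i].any() for i in range(eng.spec.n_nodes)):
            raise DataError("data has hidden entries; pass their assignment")
    total = 0.0
    for t in range(eng.T):
        rows = np.nonzero(eng.valid[:, t])[0]
        for i in range(eng.spec.n_nodes):
            total += float(eng.node_logp(i, t, rows).sum())
    return total


def hmm_structure(spec: DBNSpec):
    """Return (hidden node index, output node indices) if the topology is a
    canonical HMM; raise :class:`TopologyError` otherwise."""
    if len(spec.inter_edges) != 1:
        raise TopologyError("HMM topology needs exactly one inter edge")
    p, c = spec.inter_edges[0]
    if p != c:
        raise TopologyError("the single inter edge must be hidden -> hidden")
    h = p
    if spec.nodes[h].family != "discrete":
        raise TopologyError("the hidden chain must be discrete")
    if spec.intra_parents(h):
        raise TopologyError("the hidden chain may not have intra parents")
    outputs = [i for i in range(spec.n_nodes) if i != h]
    for i in outputs:
        if spec.parents(i) != [(0, h)]:
            raise TopologyError(
                f"node {spec.nodes[i].name!r} must have the hidden chain as "
                "its only (intra) parent"
            )
    return h, outputs


def forward_loglik(params: DBNParams, data: SequenceBatch) -> float:
    """log P(observed data | parameters) for an HMM-shaped network, summing
    over all hidden state paths with the log-space forward recursion.

    Output nodes must be fully observed; observed hidden-chain entries are
    clamped.  Independent of any sampled hidden assignment.
    """
    spec = data.spec
    h, outputs = hmm_structure(spec)
    eng = _Engine(params, data)
    for i in outputs:
        if eng.hid[i].any():
            raise TopologyError("forward algorithm requires observed outputs")
    s = spec.nodes[h].size
    N, T = eng.N, eng.T
    if N == 0:
        return 0.0
    # emission log-densities per hidden state: em[n, t, k]
    em = np.zeros((N, T, s))
    flatrows = np.arange(N)
    for i in outputs:
        cpd = params.cpd(i)
        x = eng.vals[i].reshape(N * T, *eng.vals[i].shape[2:])
        for k in range(s):
            em[:, :, k] += cpd.logp(np.full(N * T, k), x).reshape(N, T)
    # clamping mask for observed hidden entries
    clamp = np.zeros((N, T, s))
    obs_h = eng.valid & ~eng.hid[h]
    if obs_h.any():
        idx = np.nonzero(obs_h)
        clamp[idx[0], idx[1], :] = -np.inf
        clamp[idx[0], idx[1], eng.vals[h][idx]] = 0.0
    log_pi = params.cpd(h, initial=True).log_flat[0]
    log_T = params.cpd(h).log_flat  # (s, s)
    alpha = log_pi[None, :] + em[:, 0, :] + clamp[:, 0, :]
    ll = np.zeros(N)
    done = eng.lengths == 1
    ll[done] = logsumexp(alpha[done], axis=1)
    for t in range(1, T):
        trans = logsumexp(alpha[:, :, None] + log_T[None, :, :], axis=1)
        new_alpha = em[:, t, :] + clamp[:, t, :] + trans
        alive = eng.valid[:, t]
        alpha = np.where(alive[:, None], new_alpha, alpha)
        fin = eng.lengths == t + 1
        if fin.any():
            ll[fin] = logsumexp(alpha[fin], axis=1)
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Ancestral sampling
# ---------------------------------------------------------------------------

def ancestral_sample(params: DBNParams, n_sequences: int, n_slices: int,
                     rng: np.random.Generator,
                     multinomial_trials: int = 10) -> SequenceBatch:
    """Sample fully observed sequences from the model, slice by slice in
    node order (a topological order by construction)."""
    spec = params.spec
    per_sequence = []
    vals = []
    for i, nd in enumerate(spec.nodes):
        if nd.family in VECTOR_FAMILIES:
            shape = (n_sequences, n_slices, nd.size)
        else:
            shape = (n_sequences, n_slices)
        dtype = np.int64 if nd.family in INT_FAMILIES else float
        vals.append(np.zeros(shape, dtype=dtype))
    for t in range(n_slices):
        for i, nd in enumerate(spec.nodes):
            initial = t == 0 and spec.has_initial_params(i)
            parents = spec.parents(i, initial)
            if parents:
                sizes = spec.parent_sizes(i, initial)
                digits = [vals[p][:, t + off] for off, p in parents]
                cfg = np.ravel_multi_index(tuple(digits), sizes)
            else:
                cfg = np.zeros(n_sequences, dtype=int)
            cpd = params.cpd(i, initial=initial)
            fam = nd.family
            if fam == "discrete":
                vals[i][:, t] = cpd.sample_vec(cfg, rng.random(n_sequences))
            elif fam == "multinomial":
                vals[i][:, t] = cpd.sample_vec(
                    cfg, np.full(n_sequences, multinomial_trials), rng)
            elif fam == "poisson":
                vals[i][:, t] = cpd.sample_vec(cfg, rng)
            elif fam in ("gaussian_uni", "gaussian_multi"):
                draw = cpd.sample_vec(cfg, rng)
                vals[i][:, t] = draw[:, 0] if fam == "gaussian_uni" else draw
            elif fam == "vonmises_uni":
                vals[i][:, t] = cpd.sample_vec(cfg, rng)
            elif fam in ("vonmises_bi", "kent"):
                vals[i][:, t] = cpd.sample_vec(cfg, rng)
    for sdx in range(n_sequences):
        values = [vals[i][sdx] for i in range(spec.n_nodes)]
        mask = [np.zeros(n_slices, dtype=bool) for _ in range(spec.n_nodes)]
        per_sequence.append((values, mask))
    return SequenceBatch.from_arrays(spec, per_sequence)
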