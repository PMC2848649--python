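"""Discrete-family nodes: categorical (CPT), multinomial counts, Poisson.

Each parameter class stores one component per configuration of the node's
discrete parents.  Conditional tables keep their natural multi-axis shape
(one axis per parent, last axis the node's own states) but expose a flat
(n_configs, ...) view for vectorized evaluation; configurations are ravelled
in row-major parent order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import ParameterError

_NORM_TOL = 1e-9


def _ravel_config(parents, parent_sizes) -> int:
    if len(parents) != len(parent_sizes):
        raise IndexError(
            f"got {len(parents)} parent states for {len(parent_sizes)} parents"
        )
    if not parent_sizes:
        return 0
    for v, s in zip(parents, parent_sizes):
        if not 0 <= v < s:
            raise IndexError(f"parent state {v} out of range [0, {s})")
    return int(np.ravel_multi_index(tuple(int(v) for v in parents), parent_sizes))


@dataclass
class CPTParams:
    """A categorical node's conditional probability table.

    ``table`` has shape ``parent_sizes + [node_size]``; every slice along the
    last axis is a probability vector.
    """

    table: np.ndarray
    _log_flat: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim < 1:
            raise ParameterError("CPT must have at least one axis")
        if np.any(self.table < 0):
            raise ParameterError("CPT entries must be >= 0")
        sums = self.table.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=_NORM_TOL, rtol=0):
            raise ParameterError("every CPT row must sum to 1")

    @property
    def node_size(self) -> int:
        return self.table.shape[-1]

    @property
    def n_configs(self) -> int:
        return int(np.prod(self.table.shape[:-1], dtype=int))

    @property
    def flat(self) -> np.ndarray:
        return self.table.reshape(self.n_configs, self.node_size)

    @property
    def log_flat(self) -> np.ndarray:
        if self._log_flat is None:
            with np.errstate(divide="ignore"):
                self._log_flat = np.log(self.flat)
        return self._log_flat

    # -- vectorized interface used by the inference engine ------------------

    def logp(self, cfg: np.ndarray, x: np.ndarray) -> np.ndarray:
        return self.log_flat[cfg, x]

    def logp_all(self, cfg: np.ndarray) -> np.ndarray:
        """Log-probability of every state per entry: shape (n, node_size)."""
        return self.log_flat[cfg]

    def sample_vec(self, cfg: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Inverse-CDF draw per row from a single uniform variate each.

        Ties break toward the lower index: the draw is the smallest state
        whose cumulative probability reaches ``u``.
        """
        cum = np.cumsum(self.flat[cfg], axis=-1)
        idx = (cum < u[..., None]).sum(axis=-1)
        return np.minimum(idx, self.node_size - 1)


def discrete_log_density(p: CPTParams, parents, value) -> float:
    """log P(value | parent states); -inf for a zero entry."""
    cfg = _ravel_config(parents, p.table.shape[:-1])
    value = int(value)
    if not 0 <= value < p.node_size:
        raise IndexError(f"state {value} out of range [0, {p.node_size})")
    return float(p.log_flat[cfg, value])


def discrete_sample(p: CPTParams, parents, rng: np.random.Generator) -> int:
    """Draw one state from the parent-conditional categorical."""
    cfg = _ravel_config(parents, p.table.shape[:-1])
    u = rng.random()
    cum = np.cumsum(p.flat[cfg])
    return int(min(int((cum < u).sum()), p.node_size - 1))


def discrete_m_step(counts: np.ndarray, pseudocount: float = 0.0) -> CPTParams:
    """Maximum-likelihood CPT from (expected) counts plus a per-cell pseudocount.

    Rows with all-zero counts at zero pseudocount become uniform.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ParameterError("counts must be >= 0")
    if pseudocount < 0:
        raise ParameterError("pseudocount must be >= 0")
    num = counts + pseudocount
    denom = num.sum(axis=-1, keepdims=True)
    k = counts.shape[-1]
    table = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 1.0 / k)
    return CPTParams(table=table)


# ---------------------------------------------------------------------------
# Multinomial count vectors
# ---------------------------------------------------------------------------

@dataclass
class MultinomialParams:
    """Category probabilities per discrete-parent configuration.

    The trial count n is per-observation (the sum of the observed count
    vector), not a parameter.
    """

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0):
            raise ParameterError("probabilities must be >= 0")
        if not np.allclose(self.probs.sum(axis=-1), 1.0, atol=_NORM_TOL, rtol=0):
            raise ParameterError("probability vectors must sum to 1")

    @property
    def n_categories(self) -> int:
        return self.probs.shape[-1]

    @property
    def flat(self) -> np.ndarray:
        return self.probs.reshape(-1, self.n_categories)

    def logp(self, cfg: np.ndarray, counts: np.ndarray) -> np.ndarray:
        p = self.flat[cfg]
        counts = np.asarray(counts, dtype=float)
        n = counts.sum(axis=-1)
        coef = gammaln(n + 1) - gammaln(counts + 1).sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(counts > 0, counts * np.log(p), 0.0)
        return coef + terms.sum(axis=-1)

    def sample_vec(self, cfg: np.ndarray, n_trials: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
        p = self.flat[cfg]
        out = np.empty_like(p, dtype=np.int64)
        for i in range(len(p)):
            out[i] = rng.multinomial(int(n_trials[i]), p[i])
        return out


def multinomial_log_density(p: MultinomialParams, parents, counts) -> float:
    """Multinomial log-pmf with n = sum(counts), including the coefficient."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (p.n_categories,):
        raise ParameterError(
            f"counts length {counts.shape} does not match {p.n_categories} categories"
        )
    if np.any(counts < 0):
        raise ParameterError("counts must be >= 0")
    cfg = _ravel_config(parents, p.probs.shape[:-1])
    return float(p.logp(np.array([cfg]), counts[None, :])[0])


def multinomial_m_step(count_sums: np.ndarray, pseudocount: float = 0.0) -> MultinomialParams:
    """ML category probabilities from summed count vectors per configuration."""
    count_sums = np.asarray(count_sums, dtype=float)
    if np.any(count_sums < 0):
        raise ParameterError("counts must be >= 0")
    num = count_sums + pseudocount
    denom = num.sum(axis=-1, keepdims=True)
    k = count_sums.shape[-1]
    probs = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 1.0 / k)
    return MultinomialParams(probs=probs)


# ---------------------------------------------------------------------------
# Poisson counts
# ---------------------------------------------------------------------------

@dataclass
class PoissonParams:
    """One positive rate per discrete-parent configuration."""

    rates: np.ndarray

    def __post_init__(self):
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if np.any(self.rates <= 0):
            raise ParameterError("Poisson rates must be > 0")

    @property
    def flat(self) -> np.ndarray:
        return self.rates.reshape(-1)

    def logp(self, cfg: np.ndarray, k: np.ndarray) -> np.ndarray:
        lam = self.flat[cfg]
        k = np.asarray(k, dtype=float)
        return k * np.log(lam) - lam - gammaln(k + 1)

    def sample_vec(self, cfg: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return rng.poisson(self.flat[cfg])


def poisson_log_density(p: PoissonParams, parents, k) -> float:
    """log pmf: k log(lambda) - lambda - log k!"""
    k = int(k)
    if k < 0:
        raise ParameterError("k must be >= 0")
    cfg = _ravel_config(parents, p.rates.shape) if len(parents) else 0
    return float(p.logp(np.array([cfg]), np.array([k]))[0])


def poisson_m_step(n: np.ndarray, sum_k: np.ndarray,
                   fallback_rate: float = 1.0) -> PoissonParams:
    """ML rates (sample means) per configuration; empty configurations get
    ``fallback_rate``."""
    n = np.asarray(n, dtype=float)
    sum_k = np.asarray(sum_k, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(n > 0, sum_k / np.where(n > 0, n, 1.0), fallback_rate)
    rates = np.maximum(rates, 1e-12)
    return PoissonParams(rates=rates)
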