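"""Gaussian nodes (uni- and multivariate) conditioned on discrete parents."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError, ParameterError

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class GaussianParams:
    """One mean vector and covariance matrix per parent configuration.

    ``means`` has shape (n_configs, d), ``covs`` (n_configs, d, d).  Each
    covariance must be symmetric positive definite; Cholesky factors and
    log-determinants are cached lazily for fast repeated evaluation.
    """

    means: np.ndarray
    covs: np.ndarray
    _chol: np.ndarray = field(init=False, repr=False, default=None)
    _logdet: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covs = np.asarray(self.covs, dtype=float)
        if self.covs.ndim == 2:
            self.covs = self.covs[None, :, :]
        C, d = self.means.shape
        if self.covs.shape != (C, d, d):
            raise ParameterError(
                f"covs shape {self.covs.shape} incompatible with means {self.means.shape}"
            )
        if not np.allclose(self.covs, np.swapaxes(self.covs, -1, -2), atol=1e-10):
            raise ParameterError("covariances must be symmetric")
        try:
            self._chol = np.linalg.cholesky(self.covs)
        except np.linalg.LinAlgError as exc:
            raise ParameterError("covariances must be positive definite") from exc
        self._logdet = 2.0 * np.log(
            np.diagonal(self._chol, axis1=-2, axis2=-1)
        ).sum(axis=-1)

    @property
    def n_configs(self) -> int:
        return self.means.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def logp(self, cfg: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Vectorized log-density; ``x`` has shape (n, d) — or (n,) when
        d == 1 — and ``cfg`` (n,)."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1 and self.dim == 1:
            x = x[:, None]
        x = np.atleast_2d(x)
        diff = x - self.means[cfg]
        # solve L z = diff per entry
        z = np.linalg.solve(self._chol[cfg], diff[..., None])[..., 0]
        maha = (z * z).sum(axis=-1)
        return -0.5 * (self.dim * _LOG_2PI + self._logdet[cfg] + maha)

    def sample_vec(self, cfg: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((len(cfg), self.dim))
        return self.means[cfg] + (self._chol[cfg] @ z[..., None])[..., 0]


def _cfg_index(parents, parent_sizes):
    if not len(parent_sizes):
        return 0
    return int(np.ravel_multi_index(tuple(int(v) for v in parents), parent_sizes))


def gaussian_log_density(p: GaussianParams, parents, x) -> float:
    """-(d/2)log 2pi - (1/2)log|S| - (1/2)(x-m)' S^-1 (x-m)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != (p.dim,):
        raise ParameterError(f"x has shape {x.shape}, expected ({p.dim},)")
    cfg = parents if np.isscalar(parents) else _cfg_flat(p, parents)
    return float(p.logp(np.array([int(cfg)]), x[None, :])[0])


def _cfg_flat(p: GaussianParams, parents) -> int:
    # parent sizes are not stored on the params; callers using multi-parent
    # state vectors should pre-ravel.  A sequence of length 1 is accepted.
    parents = list(parents)
    if len(parents) == 1:
        return int(parents[0])
    raise ParameterError(
        "pass a pre-ravelled configuration index for multi-parent nodes"
    )


def gaussian_sample(p: GaussianParams, parents, rng: np.random.Generator) -> np.ndarray:
    """Draw one vector from the selected component via its Cholesky factor."""
    cfg = parents if np.isscalar(parents) else _cfg_flat(p, parents)
    return p.sample_vec(np.array([int(cfg)]), rng)[0]


def gaussian_from_stats(n: np.ndarray, sum_x: np.ndarray, sum_xx: np.ndarray,
                        ridge: float = 1e-6) -> GaussianParams:
    """ML means/covariances from zeroth/first/second moment sums.

    Per configuration: mean = sum_x/n, covariance = sum_xx/n - mean mean' +
    ridge*I (denominator n).  Configurations with fewer than d+1 observations
    fall back to the pooled covariance (+ridge*I); empty configurations also
    take the pooled mean.
    """
    n = np.asarray(n, dtype=float)
    sum_x = np.asarray(sum_x, dtype=float)
    sum_xx = np.asarray(sum_xx, dtype=float)
    C, d = sum_x.shape
    n_tot = n.sum()
    if n_tot <= 0:
        raise EstimationError("no observations for Gaussian update")
    pooled_mean = sum_x.sum(axis=0) / n_tot
    pooled_cov = sum_xx.sum(axis=0) / n_tot - np.outer(pooled_mean, pooled_mean)
    pooled_cov = _symmetrize(pooled_cov) + ridge * np.eye(d)
    means = np.empty((C, d))
    covs = np.empty((C, d, d))
    for c in range(C):
        if n[c] > 0:
            means[c] = sum_x[c] / n[c]
        else:
            means[c] = pooled_mean
        if n[c] >= d + 1:
            cov = sum_xx[c] / n[c] - np.outer(means[c], means[c])
            covs[c] = _symmetrize(cov) + ridge * np.eye(d)
        else:
            covs[c] = pooled_cov
    # a ridge cannot rescue a pooled covariance that is itself degenerate
    # (e.g. a single repeated point); bump it until Cholesky succeeds
    for c in range(C):
        bump = 0.0
        while True:
            try:
                np.linalg.cholesky(covs[c] + bump * np.eye(d))
                break
            except np.linalg.LinAlgError:
                bump = max(2 * bump, 1e-10)
        if bump:
            covs[c] = covs[c] + bump * np.eye(d)
    return GaussianParams(means=means, covs=covs)


def _symmetrize(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + a.T)


def gaussian_m_step(assignments, ridge: float = 1e-6) -> GaussianParams:
    """ML update from a list of (configuration index, x) pairs.

    The number of configurations is taken as max index + 1.
    """
    assignments = list(assignments)
    if not assignments:
        raise EstimationError("empty input to gaussian_m_step")
    cfgs = np.array([int(c) for c, _ in assignments])
    xs = np.atleast_2d(np.array([np.atleast_1d(x) for _, x in assignments], dtype=float))
    C = int(cfgs.max()) + 1
    d = xs.shape[1]
    n = np.zeros(C)
    sx = np.zeros((C, d))
    sxx = np.zeros((C, d, d))
    np.add.at(n, cfgs, 1.0)
    np.add.at(sx, cfgs, xs)
    np.add.at(sxx, cfgs, xs[:, :, None] * xs[:, None, :])
    return gaussian_from_stats(n, sx, sxx, ridge=ridge)
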