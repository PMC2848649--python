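"""Directional-statistics nodes: von Mises (circle), bivariate von Mises
cosine model (torus) and Kent / FB5 (sphere).

These families model angular data — e.g. protein or RNA backbone dihedral
angle pairs on the torus, or C-alpha pseudo-bond directions on the sphere —
where ordinary Euclidean distributions are inappropriate because the sample
space wraps.

Conventions
-----------
* Angles are radians in [0, 2pi).
* The bivariate von Mises density (cosine variant) is
  ``exp{k1 cos(phi-mu) + k2 cos(psi-nu) - k3 cos(phi-mu-psi+nu)} / C(k1,k2,k3)``.
  Note the minus sign on the interaction term: positive k3 induces negative
  circular correlation between phi and psi.
* The Kent (FB5) density is
  ``exp{kappa g1.x + beta [(g2.x)^2 - (g3.x)^2]} / C(kappa, beta)`` with
  [g1 g2 g3] an orthonormal frame (mean direction, major axis, minor axis)
  and 2*beta < kappa (unimodal regime).  At beta = 0 it reduces to the
  von Mises-Fisher distribution.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, ive, logsumexp

from .errors import EstimationError, ParameterError

TWO_PI = 2.0 * np.pi
KAPPA_CAP = 1e4          # concentration cap when the resultant length -> 1
_GRID_N = 4096           # grid size for numeric CDF inversion


def _wrap(theta):
    return np.mod(theta, TWO_PI)


def _log_i0(x):
    """log I0(x), stable for large x via the scaled Bessel function."""
    x = np.asarray(x, dtype=float)
    return np.log(ive(0, x)) + np.abs(x)


# ===========================================================================
# Univariate von Mises
# ===========================================================================

@dataclass
class VonMisesParams:
    """Mean angle mu in [0, 2pi) and concentration kappa > 0.

    ``kappa == 0`` is accepted as an explicit uniform-distribution sentinel
    (used by conditionals of the bivariate model).
    """

    mu: float
    kappa: float

    def __post_init__(self):
        if self.kappa < 0:
            raise ParameterError("kappa must be >= 0")
        self.mu = float(_wrap(self.mu))
        self.kappa = float(self.kappa)


def vm_log_density(p: VonMisesParams, theta) -> np.ndarray:
    """kappa cos(theta - mu) - log(2 pi I0(kappa)); scalar or vectorized."""
    theta = np.asarray(theta, dtype=float)
    out = p.kappa * np.cos(theta - p.mu) - np.log(TWO_PI) - _log_i0(p.kappa)
    return out if out.ndim else float(out)


def vm_sample(p: VonMisesParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n angles (Best-Fisher envelope rejection via numpy)."""
    if p.kappa == 0:
        return rng.uniform(0.0, TWO_PI, size=n)
    return _wrap(rng.vonmises(p.mu, p.kappa, size=n))


def kappa_from_rbar(rbar: float) -> float:
    """Invert the mean-resultant-length equation A(kappa) = rbar.

    Uses the standard three-regime rational approximation; caps at
    ``KAPPA_CAP`` (with a warning) when rbar is numerically 1.
    """
    rbar = float(rbar)
    if rbar < 0:
        raise EstimationError("mean resultant length must be >= 0")
    if rbar >= 1.0 - 1e-12:
        warnings.warn("resultant length ~ 1; capping kappa", stacklevel=2)
        return KAPPA_CAP
    if rbar < 0.53:
        kappa = 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6
    elif rbar < 0.85:
        kappa = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        kappa = 1.0 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar)
    return float(min(kappa, KAPPA_CAP))


def vm_estimate(angles, weights=None) -> VonMisesParams:
    """ML fit: circular-mean direction, concentration from the resultant length."""
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        weights = np.ones_like(angles)
    w = np.asarray(weights, dtype=float)
    n = w.sum()
    if n <= 0:
        raise EstimationError("no observations")
    C = float((w * np.cos(angles)).sum() / n)
    S = float((w * np.sin(angles)).sum() / n)
    rbar = np.hypot(C, S)
    if rbar < 1e-10:
        raise EstimationError("degenerate circular data (resultant ~ 0)")
    mu = _wrap(np.arctan2(S, C))
    return VonMisesParams(mu=float(mu), kappa=kappa_from_rbar(rbar))


class VonMisesCPD:
    """Array-of-components view: one (mu, kappa) per parent configuration."""

    family = "vonmises_uni"

    def __init__(self, mu, kappa):
        self.mu = np.atleast_1d(np.asarray(mu, dtype=float))
        self.kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
        if np.any(self.kappa < 0):
            raise ParameterError("kappa must be >= 0")
        self._log_norm = np.log(TWO_PI) + _log_i0(self.kappa)

    @property
    def n_configs(self) -> int:
        return len(self.mu)

    def logp(self, cfg, theta):
        return self.kappa[cfg] * np.cos(theta - self.mu[cfg]) - self._log_norm[cfg]

    def sample_vec(self, cfg, rng):
        out = np.empty(len(cfg))
        for c in np.unique(cfg):
            sel = cfg == c
            out[sel] = rng.vonmises(self.mu[c], max(self.kappa[c], 1e-12), sel.sum())
        return _wrap(out)


# ===========================================================================
# Bivariate von Mises (cosine model)
# ===========================================================================

@dataclass
class BivariateVonMisesParams:
    """Cosine-model parameters on the torus.

    mu, nu: mean angles; kappa1, kappa2: concentrations > 0; kappa3:
    interaction coefficient (real).  The unimodal proper regime
    ``|kappa3| < min(kappa1, kappa2)`` is enforced at estimation time by
    clipping, not at construction (the density is normalizable for any
    kappa3).
    """

    mu: float
    nu: float
    kappa1: float
    kappa2: float
    kappa3: float = 0.0
    _log_c: float = field(init=False, repr=False, default=None)

    def __post_init__(self):
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise ParameterError("kappa1 and kappa2 must be > 0")
        self.mu = float(_wrap(self.mu))
        self.nu = float(_wrap(self.nu))

    @property
    def log_normalizer(self) -> float:
        if self._log_c is None:
            self._log_c = bvm_log_normalizer(self.kappa1, self.kappa2, self.kappa3)
        return self._log_c


def bvm_log_normalizer(kappa1: float, kappa2: float, kappa3: float,
                       method: str = "quadrature") -> float:
    """log C(k1, k2, k3) for the cosine model.

    ``quadrature`` (authoritative): the phi integral is analytic —
    ``C = 2 pi  int exp(k2 cos p) I0(kc(p)) dp`` with
    ``kc(p) = sqrt(k1^2 + k3^2 - 2 k1 k3 cos p)`` — and the remaining 1D
    periodic integral is evaluated on a dense trapezoid grid in log space.

    ``series``: alternating Bessel-product series
    ``C = 4 pi^2 [I0(k1)I0(k2)I0(k3) + 2 sum_p (-1)^p Ip(k1)Ip(k2)Ip(k3)]``;
    falls back to quadrature with a warning if it fails to converge.
    """
    k1, k2, k3 = float(kappa1), float(kappa2), float(kappa3)
    if k1 <= 0 or k2 <= 0:
        raise ParameterError("kappa1 and kappa2 must be > 0")
    if method == "series":
        a3 = abs(k3)
        total = float(ive(0, k1) * ive(0, k2) * ive(0, a3))
        sign_flip = k3 > 0  # Ip(-x) = (-1)^p Ip(x)
        p = 1
        while p < 20000:
            term = 2.0 * float(ive(p, k1) * ive(p, k2) * ive(p, a3))
            if sign_flip and p % 2 == 1:
                term = -term
            total += term
            if abs(term) < 1e-17 * abs(total) and p > 3:
                break
            p += 1
        else:
            warnings.warn("bvm normalizer series did not converge; "
                          "falling back to quadrature", stacklevel=2)
            return bvm_log_normalizer(k1, k2, k3, method="quadrature")
        if total <= 0:
            warnings.warn("bvm normalizer series lost precision; "
                          "falling back to quadrature", stacklevel=2)
            return bvm_log_normalizer(k1, k2, k3, method="quadrature")
        return float(np.log(4 * np.pi ** 2) + k1 + k2 + a3 + np.log(total))
    if method != "quadrature":
        raise ValueError(f"unknown method {method!r}")
    psi = np.linspace(0.0, TWO_PI, _GRID_N, endpoint=False)
    kc = np.sqrt(k1 ** 2 + k3 ** 2 - 2 * k1 * k3 * np.cos(psi))
    logf = k2 * np.cos(psi) + _log_i0(kc)
    return float(np.log(TWO_PI) + logsumexp(logf) + np.log(TWO_PI / _GRID_N))


def _bvm_logc_and_grad(k1: float, k2: float, k3: float):
    """log C and its gradient in (k1, k2, k3), from one quadrature grid.

    With the phi integral done analytically, C = 2 pi int e^{k2 cos p}
    I0(kc(p)) dp; the gradient components are expectations under the
    integrand density q(p): d logC/dk2 = E_q cos p, and the k1/k3 components
    follow from d I0 = I1 with the chain rule through kc.
    """
    psi = np.linspace(0.0, TWO_PI, _GRID_N, endpoint=False)
    cos_p = np.cos(psi)
    kc = np.sqrt(k1 ** 2 + k3 ** 2 - 2 * k1 * k3 * cos_p)
    kc_safe = np.maximum(kc, 1e-12)
    logf = k2 * cos_p + _log_i0(kc)
    log_c = float(np.log(TWO_PI) + logsumexp(logf) + np.log(TWO_PI / _GRID_N))
    q = np.exp(logf - logf.max())
    q /= q.sum()
    ratio = ive(1, kc) / np.maximum(ive(0, kc), 1e-300)   # I1/I0
    d_k1 = float((q * ratio * (k1 - k3 * cos_p) / kc_safe).sum())
    d_k2 = float((q * cos_p).sum())
    d_k3 = float((q * ratio * (k3 - k1 * cos_p) / kc_safe).sum())
    return log_c, d_k1, d_k2, d_k3


def bvm_log_density(p: BivariateVonMisesParams, phi, psi) -> np.ndarray:
    """k1 cos(phi-mu) + k2 cos(psi-nu) - k3 cos(phi-mu-psi+nu) - log C."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    dphi = phi - p.mu
    dpsi = psi - p.nu
    out = (p.kappa1 * np.cos(dphi) + p.kappa2 * np.cos(dpsi)
           - p.kappa3 * np.cos(dphi - dpsi) - p.log_normalizer)
    return out if out.ndim else float(out)


def bvm_conditional(p: BivariateVonMisesParams, psi: float) -> VonMisesParams:
    """The conditional phi | psi, which is von Mises.

    With a = k1 - k3 cos(psi - nu) and b = -k3 sin(psi - nu) the conditional
    concentration is sqrt(a^2+b^2) and mean mu + atan2(b, a).  A vanishing
    resultant yields the uniform sentinel kappa = 0.
    """
    d = float(psi) - p.nu
    a = p.kappa1 - p.kappa3 * np.cos(d)
    b = -p.kappa3 * np.sin(d)
    kc = float(np.hypot(a, b))
    if kc < 1e-300:
        return VonMisesParams(mu=p.mu, kappa=0.0)
    return VonMisesParams(mu=float(_wrap(p.mu + np.arctan2(b, a))), kappa=kc)


def _bvm_psi_marginal_log(p: BivariateVonMisesParams, psi: np.ndarray) -> np.ndarray:
    """Unnormalized log marginal of psi (phi integrated analytically)."""
    d = psi - p.nu
    kc = np.sqrt(p.kappa1 ** 2 + p.kappa3 ** 2
                 - 2 * p.kappa1 * p.kappa3 * np.cos(d))
    return p.kappa2 * np.cos(d) + _log_i0(kc)


def _grid_inverse_cdf(grid: np.ndarray, logf: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Draw from a 1D density tabulated on an even grid by linear CDF inversion."""
    f = np.exp(logf - logf.max())
    cdf = np.concatenate([[0.0], np.cumsum(f)])
    cdf /= cdf[-1]
    step = grid[1] - grid[0]
    idx = np.searchsorted(cdf, u, side="right") - 1
    idx = np.clip(idx, 0, len(grid) - 1)
    denom = cdf[idx + 1] - cdf[idx]
    frac = np.where(denom > 0, (u - cdf[idx]) / np.where(denom > 0, denom, 1.0), 0.0)
    return grid[idx] + frac * step


def bvm_sample(p: BivariateVonMisesParams, n: int,
               rng: np.random.Generator) -> np.ndarray:
    """Draw n (phi, psi) pairs: psi from its numeric-inverse-CDF marginal,
    then phi from the exact von Mises conditional.  Returns shape (n, 2)."""
    grid = np.linspace(0.0, TWO_PI, _GRID_N, endpoint=False)
    logf = _bvm_psi_marginal_log(p, grid)
    psi = _wrap(_grid_inverse_cdf(grid, logf, rng.random(n)))
    d = psi - p.nu
    a = p.kappa1 - p.kappa3 * np.cos(d)
    b = -p.kappa3 * np.sin(d)
    kc = np.hypot(a, b)
    mu_c = p.mu + np.arctan2(b, a)
    phi = np.empty(n)
    pos = kc > 1e-300
    if pos.any():
        phi[pos] = rng.vonmises(mu_c[pos], kc[pos])
    if (~pos).any():
        phi[~pos] = rng.uniform(0, TWO_PI, size=(~pos).sum())
    return np.column_stack([_wrap(phi), psi])


def bvm_suff_stats(phi, psi):
    """Sufficient statistics of the cosine model: means of
    (cos phi, sin phi, cos psi, sin psi, cos(phi-psi), sin(phi-psi))."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    d = phi - psi
    return np.array([
        np.cos(phi).sum(), np.sin(phi).sum(),
        np.cos(psi).sum(), np.sin(psi).sum(),
        np.cos(d).sum(), np.sin(d).sum(),
    ]), len(phi)


def bvm_estimate_from_stats(stats: np.ndarray, n: float) -> BivariateVonMisesParams:
    """Numeric ML from the 6 sufficient statistics (see :func:`bvm_estimate`)."""
    if n < 5:
        raise EstimationError("need at least 5 observations for a bvm fit")
    m = np.asarray(stats, dtype=float) / float(n)
    rphi = np.hypot(m[0], m[1])
    rpsi = np.hypot(m[2], m[3])
    if rphi < 1e-10 or rpsi < 1e-10:
        raise EstimationError("degenerate toroidal data (resultant ~ 0)")
    mu = float(np.arctan2(m[1], m[0]))
    nu = float(np.arctan2(m[3], m[2]))
    # moments of the centred angles, exactly recoverable from the stats
    m1 = m[0] * np.cos(mu) + m[1] * np.sin(mu)            # E cos(phi-mu)
    m2 = m[2] * np.cos(nu) + m[3] * np.sin(nu)            # E cos(psi-nu)
    dmn = mu - nu
    m3 = m[4] * np.cos(dmn) + m[5] * np.sin(dmn)          # E cos(phi-mu-psi+nu)

    def neg_avg_ll_grad(x):
        k1, k2, k3 = np.exp(x[0]), np.exp(x[1]), x[2]
        log_c, d1, d2, d3 = _bvm_logc_and_grad(k1, k2, k3)
        val = -(k1 * m1 + k2 * m2 - k3 * m3 - log_c)
        # chain rule through the log parameterization of k1, k2
        grad = np.array([-(m1 - d1) * k1, -(m2 - d2) * k2, (m3 + d3)])
        return val, grad

    k1_0 = kappa_from_rbar(min(rphi, 1 - 1e-9))
    k2_0 = kappa_from_rbar(min(rpsi, 1 - 1e-9))
    x0 = np.array([np.log(max(k1_0, 1e-2)), np.log(max(k2_0, 1e-2)), 0.0])
    res = minimize(neg_avg_ll_grad, x0, jac=True, method="L-BFGS-B",
                   bounds=[(-7, np.log(KAPPA_CAP)), (-7, np.log(KAPPA_CAP)),
                           (-KAPPA_CAP, KAPPA_CAP)],
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    if not res.success:
        # line-search failures near a flat optimum: retry derivative-free
        res = minimize(lambda x: neg_avg_ll_grad(x)[0], x0,
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
    if not res.success:
        raise EstimationError(f"bvm ML optimization failed: {res.message}")
    k1, k2, k3 = float(np.exp(res.x[0])), float(np.exp(res.x[1])), float(res.x[2])
    bound = 0.95 * min(k1, k2)
    if abs(k3) > bound:
        warnings.warn("clipping kappa3 to the unimodality bound", stacklevel=2)
        k3 = float(np.sign(k3) * bound)
    return BivariateVonMisesParams(mu=_wrap(mu), nu=_wrap(nu),
                                   kappa1=k1, kappa2=k2, kappa3=k3)


def bvm_estimate(data) -> BivariateVonMisesParams:
    """ML fit of the cosine model to (phi, psi) pairs.

    Mean angles come from the circular means; the concentrations maximize the
    exact average log-likelihood (normalizer by quadrature) starting from
    univariate moment estimates, with kappa3 clipped into the unimodal regime.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    stats, n = bvm_suff_stats(data[:, 0], data[:, 1])
    return bvm_estimate_from_stats(stats, n)


class BivariateVonMisesCPD:
    """One cosine-model component per parent configuration."""

    family = "vonmises_bi"

    def __init__(self, mu, nu, kappa1, kappa2, kappa3):
        self.mu = np.atleast_1d(np.asarray(mu, dtype=float))
        self.nu = np.atleast_1d(np.asarray(nu, dtype=float))
        self.kappa1 = np.atleast_1d(np.asarray(kappa1, dtype=float))
        self.kappa2 = np.atleast_1d(np.asarray(kappa2, dtype=float))
        self.kappa3 = np.atleast_1d(np.asarray(kappa3, dtype=float))
        if np.any(self.kappa1 <= 0) or np.any(self.kappa2 <= 0):
            raise ParameterError("kappa1 and kappa2 must be > 0")
        self._log_c = np.array([
            bvm_log_normalizer(self.kappa1[c], self.kappa2[c], self.kappa3[c])
            for c in range(len(self.mu))
        ])

    @property
    def n_configs(self) -> int:
        return len(self.mu)

    def component(self, c: int) -> BivariateVonMisesParams:
        return BivariateVonMisesParams(
            mu=self.mu[c], nu=self.nu[c], kappa1=self.kappa1[c],
            kappa2=self.kappa2[c], kappa3=self.kappa3[c])

    def logp(self, cfg, x):
        x = np.atleast_2d(x)
        dphi = x[:, 0] - self.mu[cfg]
        dpsi = x[:, 1] - self.nu[cfg]
        return (self.kappa1[cfg] * np.cos(dphi)
                + self.kappa2[cfg] * np.cos(dpsi)
                - self.kappa3[cfg] * np.cos(dphi - dpsi)
                - self._log_c[cfg])

    def sample_vec(self, cfg, rng):
        out = np.empty((len(cfg), 2))
        for c in np.unique(cfg):
            sel = cfg == c
            out[sel] = bvm_sample(self.component(int(c)), int(sel.sum()), rng)
        return out


# ===========================================================================
# Kent (FB5) distribution
# ===========================================================================

@dataclass
class KentParams:
    """FB5 parameters: concentration kappa, ellipticity beta, orthonormal
    frame [gamma1; gamma2; gamma3] (rows: mean direction, major axis, minor
    axis).  Requires kappa > 0, beta >= 0 and 2 beta < kappa (unimodal)."""

    kappa: float
    beta: float
    gammas: np.ndarray
    _log_c: float = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.gammas = np.asarray(self.gammas, dtype=float)
        if self.kappa <= 0:
            raise ParameterError("kappa must be > 0")
        if self.beta < 0:
            raise ParameterError("beta must be >= 0")
        if 2 * self.beta >= self.kappa:
            raise ParameterError("unimodality requires 2*beta < kappa")
        if self.gammas.shape != (3, 3):
            raise ParameterError("gammas must be a 3x3 matrix of row vectors")
        if not np.allclose(self.gammas @ self.gammas.T, np.eye(3), atol=1e-9):
            raise ParameterError("[gamma1 gamma2 gamma3] must be orthonormal")

    @property
    def gamma1(self):
        return self.gammas[0]

    @property
    def gamma2(self):
        return self.gammas[1]

    @property
    def gamma3(self):
        return self.gammas[2]

    @property
    def log_normalizer(self) -> float:
        if self._log_c is None:
            self._log_c = kent_log_normalizer(self.kappa, self.beta)
        return self._log_c


def kent_log_normalizer(kappa: float, beta: float, method: str = "series") -> float:
    """log C(kappa, beta) for the FB5 density.

    ``series`` (exact): C = 2 pi sum_j G(j+1/2)/G(j+1) beta^(2j)
    (2/kappa)^(2j+1/2) I_{2j+1/2}(kappa), evaluated in log space with scaled
    Bessel functions.  At beta = 0 this is the closed-form von Mises-Fisher
    normalizer 4 pi sinh(kappa)/kappa.

    ``approx``: the standard large-concentration form
    2 pi e^kappa [(kappa - 2 beta)(kappa + 2 beta)]^(-1/2); agrees with the
    series to better than 1% for kappa >= 50.
    """
    kappa = float(kappa)
    beta = float(beta)
    if kappa <= 0:
        raise ParameterError("kappa must be > 0")
    if beta < 0 or 2 * beta >= kappa:
        raise ParameterError("require 0 <= 2*beta < kappa")
    if method == "approx":
        return float(np.log(TWO_PI) + kappa
                     - 0.5 * (np.log(kappa - 2 * beta) + np.log(kappa + 2 * beta)))
    if method != "series":
        raise ValueError(f"unknown method {method!r}")
    log2k = np.log(2.0) - np.log(kappa)
    terms = []
    j = 0
    prev_max = -np.inf
    while True:
        if beta == 0 and j > 0:
            break
        order = 2 * j + 0.5
        log_bessel = np.log(ive(order, kappa)) + kappa
        log_beta_pow = 0.0 if j == 0 else 2 * j * np.log(beta)
        t = (np.log(TWO_PI) + gammaln(j + 0.5) - gammaln(j + 1.0)
             + log_beta_pow + (2 * j + 0.5) * log2k + log_bessel)
        terms.append(t)
        prev_max = max(prev_max, t)
        if j > 2 and t < prev_max - 40:
            break
        if j > 5000:
            raise EstimationError("Kent normalizer series did not converge")
        j += 1
    return float(logsumexp(np.array(terms)))


def kent_log_density(p: KentParams, x) -> np.ndarray:
    """kappa (g1.x) + beta [(g2.x)^2 - (g3.x)^2] - log C(kappa, beta)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    norms = np.linalg.norm(x, axis=-1)
    if not np.all(np.abs(norms - 1.0) < 1e-6):
        raise ParameterError("x must be a unit vector (within 1e-6)")
    t = x @ p.gamma1
    u = x @ p.gamma2
    v = x @ p.gamma3
    out = p.kappa * t + p.beta * (u ** 2 - v ** 2) - p.log_normalizer
    return float(out[0]) if single else out


def vmf_log_density(kappa: float, mean_direction, x) -> np.ndarray:
    """von Mises-Fisher log-density on the 2-sphere (the beta = 0 Kent case)."""
    kappa = float(kappa)
    mu = np.asarray(mean_direction, dtype=float)
    x = np.asarray(x, dtype=float)
    # log(4 pi sinh k / k) computed stably
    log_c = np.log(4 * np.pi) + kappa + np.log1p(-np.exp(-2 * kappa)) \
        - np.log(2.0) - np.log(kappa)
    out = kappa * (x @ mu) - log_c
    return out if np.ndim(out) else float(out)


def kent_sample(p: KentParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n unit vectors by exact rejection.

    In the frame coordinates t = g1.x, and with x = t g1 +
    sqrt(1-t^2)(cos a g2 + sin a g3), the density over (t, a) w.r.t. dt da is
    proportional to exp{kappa t + beta (1-t^2) cos 2a}.  Proposals take t
    from exp(kappa t - beta t^2) (dense-grid inverse CDF on the
    mass-carrying interval) and a uniform; acceptance probability is
    exp{beta (1-t^2)(cos 2a - 1)} <= 1, so the draw is exact up to grid
    resolution in t.
    """
    out = np.empty((n, 3))
    have = 0
    # restrict the t grid to where the proposal exp(kappa t - beta t^2) holds
    # non-negligible mass (within 50 nats of its maximum over [-1, 1])
    tt = np.linspace(-1.0, 1.0, 1024)
    ff = p.kappa * tt - p.beta * tt ** 2
    t_lo = float(tt[np.argmax(ff > ff.max() - 50.0)]) if (ff > ff.max() - 50.0).any() else -1.0
    t_lo = max(-1.0, t_lo - 2.0 / 1024)
    grid = np.linspace(t_lo, 1.0, _GRID_N)
    logf = p.kappa * grid - p.beta * grid ** 2
    while have < n:
        m = max(2 * (n - have), 64)
        t = _grid_inverse_cdf(grid, logf, rng.random(m))
        t = np.clip(t, -1.0, 1.0)
        a = rng.uniform(0.0, TWO_PI, size=m)
        logacc = p.beta * (1.0 - t ** 2) * (np.cos(2 * a) - 1.0)
        keep = np.log(rng.random(m)) < logacc
        t, a = t[keep], a[keep]
        take = min(len(t), n - have)
        s = np.sqrt(np.clip(1.0 - t[:take] ** 2, 0.0, None))
        xyz = (t[:take, None] * p.gamma1[None, :]
               + (s * np.cos(a[:take]))[:, None] * p.gamma2[None, :]
               + (s * np.sin(a[:take]))[:, None] * p.gamma3[None, :])
        out[have:have + take] = xyz
        have += take
    return out


def kent_suff_stats(x):
    """Sufficient statistics: (sum of vectors, sum of outer products, n)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return x.sum(axis=0), x.T @ x, len(x)


def _kent_refine_concentration(rbar: float, r2: float, kappa0: float,
                               beta0: float) -> tuple[float, float]:
    """Maximize kappa*rbar + beta*r2 - log C(kappa, beta) over the unimodal
    domain, parameterized as kappa = e^x0, 2*beta/kappa = 0.9999*sigmoid(x1)."""

    def neg_ll(x):
        kappa = float(np.exp(np.clip(x[0], -20, np.log(KAPPA_CAP))))
        ratio = 0.9999 / (1.0 + np.exp(-x[1]))
        beta = 0.5 * kappa * ratio
        return -(kappa * rbar + beta * r2 - kent_log_normalizer(kappa, beta))

    ratio0 = np.clip(2 * beta0 / kappa0, 1e-6, 0.999) / 0.9999
    x0 = np.array([np.log(max(kappa0, 1e-3)),
                   np.log(ratio0) - np.log1p(-ratio0)])
    res = minimize(neg_ll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-11, "maxiter": 2000})
    x = res.x if res.success else x0
    kappa = float(np.exp(np.clip(x[0], -20, np.log(KAPPA_CAP))))
    beta = 0.5 * kappa * 0.9999 / (1.0 + np.exp(-x[1]))
    return kappa, beta


def kent_estimate_from_stats(sum_x: np.ndarray, sum_xx: np.ndarray,
                             n: float) -> KentParams:
    """Moment estimation of FB5 parameters (see :func:`kent_estimate`)."""
    if n < 3:
        raise EstimationError("need at least 3 observations for a Kent fit")
    xbar = np.asarray(sum_x, dtype=float) / n
    S = np.asarray(sum_xx, dtype=float) / n
    rbar = float(np.linalg.norm(xbar))
    if rbar < 1e-8:
        raise EstimationError("degenerate spherical data (resultant ~ 0)")
    g1 = xbar / rbar
    # orthonormal completion of g1
    helper = np.eye(3)[np.argmin(np.abs(g1))]
    e2 = helper - (helper @ g1) * g1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(g1, e2)
    # scatter in the tangent plane; its eigenstructure fixes the axes
    B = np.array([[e2 @ S @ e2, e2 @ S @ e3],
                  [e3 @ S @ e2, e3 @ S @ e3]])
    B = 0.5 * (B + B.T)
    evals, evecs = np.linalg.eigh(B)       # ascending
    v_major = evecs[:, 1]
    g2 = v_major[0] * e2 + v_major[1] * e3
    g2 /= np.linalg.norm(g2)
    g3 = np.cross(g1, g2)
    r2 = float(evals[1] - evals[0])
    # high-concentration moment estimators, used as initialization
    d_minus = 2.0 - 2.0 * rbar - r2
    d_plus = 2.0 - 2.0 * rbar + r2
    if d_minus <= 1e-12 or d_plus <= 1e-12:
        warnings.warn("resultant length ~ 1; capping kappa", stacklevel=2)
        kappa = KAPPA_CAP
        beta = 0.475 * kappa if r2 > 0 else 0.0
    else:
        kappa = 1.0 / d_minus + 1.0 / d_plus
        beta = 0.5 * (1.0 / d_minus - 1.0 / d_plus)
        kappa = min(kappa, KAPPA_CAP)
    if 2 * beta >= kappa:
        beta = 0.475 * kappa
    beta = max(beta, 0.0)
    # the closed-form estimators are biased when 2*beta/kappa approaches 1;
    # refine (kappa, beta) by maximizing the exact likelihood with the axes
    # held at their moment estimates.  Sufficient statistics given the frame:
    # mean(t) = rbar (by construction of g1) and mean(u^2 - v^2) = r2.
    kappa, beta = _kent_refine_concentration(rbar, r2, kappa, beta)
    gammas = np.vstack([g1, g2, g3])
    # re-orthonormalize against accumulated rounding
    u, _, vt = np.linalg.svd(gammas)
    gammas = u @ vt
    return KentParams(kappa=float(kappa), beta=float(beta), gammas=gammas)


def kent_estimate(data) -> KentParams:
    """Moment estimation of the FB5 parameters from 3D unit vectors.

    The mean direction is the normalized resultant; the major/minor axes come
    from the eigenstructure of the scatter matrix projected on the tangent
    plane; kappa and beta use the standard high-concentration estimators
    1/(2-2R-r2) + 1/(2-2R+r2) and half their difference, with beta clipped
    below kappa/2.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    norms = np.linalg.norm(x, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ParameterError("data must be unit vectors (within 1e-6)")
    if len(x) >= 2 and np.allclose(x, x[0], atol=1e-12):
        raise EstimationError("all points identical; Kent fit undefined")
    sum_x, sum_xx, n = kent_suff_stats(x / norms[:, None])
    return kent_estimate_from_stats(sum_x, sum_xx, n)


class KentCPD:
    """One FB5 component per parent configuration."""

    family = "kent"

    def __init__(self, kappa, beta, gammas):
        self.kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
        self.beta = np.atleast_1d(np.asarray(beta, dtype=float))
        self.gammas = np.asarray(gammas, dtype=float)
        if self.gammas.ndim == 2:
            self.gammas = self.gammas[None]
        self.components = [
            KentParams(kappa=float(self.kappa[c]), beta=float(self.beta[c]),
                       gammas=self.gammas[c])
            for c in range(len(self.kappa))
        ]
        self._log_c = np.array([p.log_normalizer for p in self.components])

    @property
    def n_configs(self) -> int:
        return len(self.components)

    def logp(self, cfg, x):
        x = np.atleast_2d(x)
        g = self.gammas[cfg]                      # (n, 3, 3)
        proj = (g @ x[..., None])[..., 0]         # (n, 3): t, u, v
        return (self.kappa[cfg] * proj[:, 0]
                + self.beta[cfg] * (proj[:, 1] ** 2 - proj[:, 2] ** 2)
                - self._log_c[cfg])

    def sample_vec(self, cfg, rng):
        out = np.empty((len(cfg), 3))
        for c in np.unique(cfg):
            sel = cfg == c
            out[sel] = kent_sample(self.components[int(c)], int(sel.sum()), rng)
        return out
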