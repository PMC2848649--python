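"""Independent reference computations used only by the test suite.

Everything here is deliberately naive — dense path enumeration, brute-force
grid quadrature, direct matrix inversion — so that it shares no code path
with the implementation it checks.
"""
from __future__ import annotations

import itertools

import numpy as np
from numpy.polynomial.legendre import leggauss

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# HMM oracles (dense, log-free where possible; tiny models only)
# ---------------------------------------------------------------------------

def enumerate_paths_loglik(pi, T, em):
    """log P(observations) by summing the joint over every hidden path.

    pi: (s,) initial probabilities; T: (s, s) transitions; em: (L, s)
    per-slice emission likelihoods of the observed outputs.
    """
    L, s = em.shape
    total = 0.0
    for path in itertools.product(range(s), repeat=L):
        p = pi[path[0]] * em[0, path[0]]
        for t in range(1, L):
            p *= T[path[t - 1], path[t]] * em[t, path[t]]
        total += p
    return float(np.log(total))


def forward_backward_marginals(pi, T, em):
    """Exact per-slice posterior marginals of the hidden chain (L, s)."""
    L, s = em.shape
    alpha = np.zeros((L, s))
    beta = np.zeros((L, s))
    alpha[0] = pi * em[0]
    for t in range(1, L):
        alpha[t] = em[t] * (alpha[t - 1] @ T)
    beta[L - 1] = 1.0
    for t in range(L - 2, -1, -1):
        beta[t] = T @ (em[t + 1] * beta[t + 1])
    post = alpha * beta
    return post / post.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Quadrature oracles for the directional densities
# ---------------------------------------------------------------------------

def sphere_integral(log_density, n_t=2000, n_a=512):
    """Integral of exp(log_density(x)) over the unit sphere.

    Gauss-Legendre in the polar cosine, trapezoid in azimuth; the density
    callback receives an (n, 3) array of unit vectors.
    """
    t, w = leggauss(n_t)
    a = np.linspace(0.0, TWO_PI, n_a, endpoint=False)
    tt, aa = np.meshgrid(t, a, indexing="ij")
    s = np.sqrt(1.0 - tt ** 2)
    xyz = np.stack([s * np.cos(aa), s * np.sin(aa), tt], axis=-1)
    vals = np.exp(log_density(xyz.reshape(-1, 3))).reshape(n_t, n_a)
    return float((vals.mean(axis=1) * TWO_PI * w).sum())


def torus_integral(log_density, n=1024):
    """Integral of exp(log_density(phi, psi)) over [0, 2pi)^2 (trapezoid,
    spectrally accurate for smooth periodic integrands)."""
    g = np.linspace(0.0, TWO_PI, n, endpoint=False)
    pp, qq = np.meshgrid(g, g, indexing="ij")
    vals = np.exp(log_density(pp.ravel(), qq.ravel()))
    return float(vals.mean() * TWO_PI ** 2)


def circle_integral(log_density, n=4096):
    g = np.linspace(0.0, TWO_PI, n, endpoint=False)
    return float(np.exp(log_density(g)).mean() * TWO_PI)


def mc_sphere_log_normalizer(kappa, beta, gammas, n, rng):
    """Monte-Carlo estimate of log C for the FB5 exponent: uniform sphere
    points, average of exp(exponent), times sphere area."""
    z = rng.standard_normal((n, 3))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    expo = kappa * (z @ gammas[0]) + beta * ((z @ gammas[1]) ** 2 - (z @ gammas[2]) ** 2)
    m = expo.max()
    return float(m + np.log(np.exp(expo - m).mean()) + np.log(4 * np.pi))


# ---------------------------------------------------------------------------
# Misc
# ---------------------------------------------------------------------------

def best_permutation_error(true_tables, est_tables, n_states):
    """Smallest max-abs-entry error over all relabelings of hidden states.

    ``true_tables``/``est_tables`` are lists of (array, axes) pairs where
    ``axes`` lists which axes of the array index hidden states.
    """
    best = np.inf
    for perm in itertools.permutations(range(n_states)):
        p = np.asarray(perm)
        worst = 0.0
        for (tru, axes), (est, _) in zip(true_tables, est_tables):
            e = est
            for ax in axes:
                e = np.take(e, p, axis=ax)
            worst = max(worst, float(np.abs(tru - e).max()))
        best = min(best, worst)
    return best
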