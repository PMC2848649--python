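"""Benchmark fixture generators.

Three standard parameter-estimation workloads:

* ``discrete_hmm`` — an HMM with two discrete nodes per slice (one hidden,
  one output), all sizes 5, 50 slices.
* ``gaussian_hmm`` — a 10-state hidden chain with a 4-dimensional Gaussian
  output node, 50 slices.
* ``complex`` — two hidden chains H (size 5) and I (size 3); H parents a
  4-dimensional Gaussian node G, I parents a bivariate von Mises node V.

True parameters are drawn from documented diffuse distributions (flat
Dirichlet CPT rows, standard-normal Gaussian means with a shape-controlled
SPD covariance sampler, documented ranges for the directional
concentrations), sequences are sampled ancestrally, and every hidden-node
entry is masked.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DBNSpec, NodeSpec, SequenceBatch
from .directional import TWO_PI, BivariateVonMisesCPD
from .discrete import CPTParams
from .errors import SpecError
from .gaussian import GaussianParams
from .inference import ancestral_sample
from .params import DBNParams, n_configs

BENCHMARK_NAMES = ("discrete_hmm", "gaussian_hmm", "complex")


@dataclass
class BenchmarkSpec:
    """Which benchmark to build and at what scale."""

    name: str
    n_slices: int = 50
    n_sequences: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.name not in BENCHMARK_NAMES:
            raise SpecError(
                f"unknown benchmark {self.name!r}; choose from {BENCHMARK_NAMES}"
            )


def benchmark_spec(name: str) -> DBNSpec:
    """The network architecture of a named benchmark."""
    if name == "discrete_hmm":
        return DBNSpec(
            nodes=(NodeSpec("h", "discrete", 5, hidden_allowed=True),
                   NodeSpec("o", "discrete", 5)),
            intra_edges=((0, 1),),
            inter_edges=((0, 0),),
        )
    if name == "gaussian_hmm":
        return DBNSpec(
            nodes=(NodeSpec("h", "discrete", 10, hidden_allowed=True),
                   NodeSpec("g", "gaussian_multi", 4)),
            intra_edges=((0, 1),),
            inter_edges=((0, 0),),
        )
    if name == "complex":
        return DBNSpec(
            nodes=(NodeSpec("H", "discrete", 5, hidden_allowed=True),
                   NodeSpec("I", "discrete", 3, hidden_allowed=True),
                   NodeSpec("G", "gaussian_multi", 4),
                   NodeSpec("V", "vonmises_bi", 2)),
            intra_edges=((0, 2), (1, 3)),
            inter_edges=((0, 0), (1, 1)),
        )
    raise SpecError(name)


def _random_spd(d: int, rng: np.random.Generator) -> np.ndarray:
    """Shape-controlled SPD sampler: W W'/d + 0.2 I with W standard normal,
    giving well-conditioned covariances of O(1) scale."""
    w = rng.standard_normal((d, d))
    return w @ w.T / d + 0.2 * np.eye(d)


def _random_cpt(spec: DBNSpec, i: int, initial: bool,
                rng: np.random.Generator) -> CPTParams:
    from .core import cpt_shape

    sizes = spec.parent_sizes(i, initial)
    k = spec.nodes[i].size
    table = rng.dirichlet(np.ones(k), size=n_configs(spec, i, initial))
    return CPTParams(table=table.reshape(cpt_shape(sizes, k)))


def true_params(spec: DBNSpec, rng: np.random.Generator,
                separation: float = 3.0) -> DBNParams:
    """Draw ground-truth parameters from diffuse distributions.

    Gaussian component means are scaled by ``separation`` so that hidden
    states are identifiable from the output; concentrations for the
    bivariate von Mises components are drawn from [20, 80] with the
    interaction inside the unimodal regime.
    """
    cpds, cpds0 = [], []
    for i, nd in enumerate(spec.nodes):
        sets = []
        for initial in (False, True):
            if initial and not spec.has_initial_params(i):
                sets.append(None)
                continue
            C = n_configs(spec, i, initial)
            if nd.family == "discrete":
                sets.append(_random_cpt(spec, i, initial, rng))
            elif nd.family == "gaussian_multi":
                d = nd.size
                means = separation * rng.standard_normal((C, d))
                covs = np.stack([_random_spd(d, rng) for _ in range(C)])
                sets.append(GaussianParams(means=means, covs=covs))
            elif nd.family == "vonmises_bi":
                k1 = rng.uniform(20.0, 80.0, C)
                k2 = rng.uniform(20.0, 80.0, C)
                k3 = rng.uniform(-0.45, 0.45, C) * np.minimum(k1, k2)
                sets.append(BivariateVonMisesCPD(
                    mu=rng.uniform(0, TWO_PI, C), nu=rng.uniform(0, TWO_PI, C),
                    kappa1=k1, kappa2=k2, kappa3=k3))
            else:  # pragma: no cover - benchmarks only use these families
                raise SpecError(nd.family)
        cpds.append(sets[0])
        cpds0.append(sets[1])
    return DBNParams(spec=spec, cpds=cpds, cpds0=cpds0)


def generate_benchmark(b: BenchmarkSpec, rng: np.random.Generator | None = None):
    """Build a named benchmark: (spec, true params, masked sequence batch).

    Sequences are ancestrally sampled from the true parameters; every entry
    of every hidden-allowed node is then masked as hidden.
    """
    if rng is None:
        rng = np.random.default_rng(b.seed)
    spec = benchmark_spec(b.name)
    params = true_params(spec, rng)
    batch = ancestral_sample(params, b.n_sequences, b.n_slices, rng)
    for seq in batch.sequences:
        for i, nd in enumerate(spec.nodes):
            if nd.hidden_allowed:
                seq.mask[i][:] = True
    return spec, params, batch
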