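"""Network-level parameter containers and serialization to plain dicts.

A :class:`DBNParams` holds, per node, a conditional parameter object (CPD)
whose leading configuration index runs over the row-major ravelling of the
node's discrete-parent states (inter parents first, then intra parents).
Nodes with inter parents additionally own a slice-0 CPD conditioned on their
intra parents only, estimated jointly during EM from slice-0 data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DBNSpec
from .discrete import CPTParams, MultinomialParams, PoissonParams
from .directional import BivariateVonMisesCPD, KentCPD, VonMisesCPD
from .errors import ParameterError, SerializationError
from .gaussian import GaussianParams


def n_configs(spec: DBNSpec, i: int, initial: bool = False) -> int:
    return int(np.prod(spec.parent_sizes(i, initial), dtype=int))


def cpd_family(cpd) -> str:
    if isinstance(cpd, CPTParams):
        return "discrete"
    if isinstance(cpd, MultinomialParams):
        return "multinomial"
    if isinstance(cpd, PoissonParams):
        return "poisson"
    if isinstance(cpd, GaussianParams):
        return "gaussian"
    if isinstance(cpd, VonMisesCPD):
        return "vonmises_uni"
    if isinstance(cpd, BivariateVonMisesCPD):
        return "vonmises_bi"
    if isinstance(cpd, KentCPD):
        return "kent"
    raise ParameterError(f"unknown CPD type {type(cpd).__name__}")


@dataclass
class DBNParams:
    """All parameters of a DBN: per node a main CPD and an optional slice-0 CPD."""

    spec: DBNSpec
    cpds: list
    cpds0: list  # per node: CPD or None

    def __post_init__(self):
        if len(self.cpds) != self.spec.n_nodes or len(self.cpds0) != self.spec.n_nodes:
            raise ParameterError("need one CPD (and slice-0 slot) per node")
        for i in range(self.spec.n_nodes):
            need0 = self.spec.has_initial_params(i)
            if need0 and self.cpds0[i] is None:
                raise ParameterError(
                    f"node {self.spec.nodes[i].name!r} has inter parents and "
                    "needs a slice-0 parameter set"
                )
            if not need0 and self.cpds0[i] is not None:
                raise ParameterError(
                    f"node {self.spec.nodes[i].name!r} has no inter parents; "
                    "slice-0 parameter set must be None"
                )

    def cpd(self, i: int, initial: bool = False):
        if initial and self.cpds0[i] is not None:
            return self.cpds0[i]
        return self.cpds[i]

    # -- plain-dict (de)serialization ---------------------------------------

    def to_dict(self) -> dict:
        return {
            "cpds": [_cpd_to_dict(c) for c in self.cpds],
            "cpds0": [None if c is None else _cpd_to_dict(c) for c in self.cpds0],
        }

    @classmethod
    def from_dict(cls, spec: DBNSpec, d: dict) -> "DBNParams":
        try:
            cpds = [_cpd_from_dict(c) for c in d["cpds"]]
            cpds0 = [None if c is None else _cpd_from_dict(c) for c in d["cpds0"]]
        except (KeyError, TypeError, IndexError) as exc:
            raise SerializationError(f"malformed parameter record: {exc}") from exc
        return cls(spec=spec, cpds=cpds, cpds0=cpds0)


def _cpd_to_dict(cpd) -> dict:
    fam = cpd_family(cpd)
    if fam == "discrete":
        return {"family": fam, "shape": list(cpd.table.shape),
                "table": cpd.table.ravel().tolist()}
    if fam == "multinomial":
        return {"family": fam, "shape": list(cpd.probs.shape),
                "probs": cpd.probs.ravel().tolist()}
    if fam == "poisson":
        return {"family": fam, "shape": list(cpd.rates.shape),
                "rates": cpd.rates.ravel().tolist()}
    if fam == "gaussian":
        return {"family": fam, "means": cpd.means.tolist(),
                "covs": cpd.covs.tolist()}
    if fam == "vonmises_uni":
        return {"family": fam, "mu": cpd.mu.tolist(), "kappa": cpd.kappa.tolist()}
    if fam == "vonmises_bi":
        return {"family": fam, "mu": cpd.mu.tolist(), "nu": cpd.nu.tolist(),
                "kappa1": cpd.kappa1.tolist(), "kappa2": cpd.kappa2.tolist(),
                "kappa3": cpd.kappa3.tolist()}
    if fam == "kent":
        return {"family": fam, "kappa": cpd.kappa.tolist(),
                "beta": cpd.beta.tolist(), "gammas": cpd.gammas.tolist()}
    raise ParameterError(fam)


def _cpd_from_dict(d: dict):
    fam = d["family"]
    if fam == "discrete":
        return CPTParams(table=np.array(d["table"]).reshape(d["shape"]))
    if fam == "multinomial":
        return MultinomialParams(probs=np.array(d["probs"]).reshape(d["shape"]))
    if fam == "poisson":
        return PoissonParams(rates=np.array(d["rates"]).reshape(d["shape"]))
    if fam == "gaussian":
        return GaussianParams(means=np.array(d["means"]), covs=np.array(d["covs"]))
    if fam == "vonmises_uni":
        return VonMisesCPD(mu=np.array(d["mu"]), kappa=np.array(d["kappa"]))
    if fam == "vonmises_bi":
        return BivariateVonMisesCPD(
            mu=np.array(d["mu"]), nu=np.array(d["nu"]),
            kappa1=np.array(d["kappa1"]), kappa2=np.array(d["kappa2"]),
            kappa3=np.array(d["kappa3"]))
    if fam == "kent":
        return KentCPD(kappa=np.array(d["kappa"]), beta=np.array(d["beta"]),
                       gammas=np.array(d["gammas"]))
    raise SerializationError(f"unknown CPD family {fam!r}")
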