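"""Parameter learning by stochastic EM (S-EM) and Monte Carlo EM (MC-EM).

Both flavours alternate a Gibbs-sampling E-step with per-family
maximum-likelihood M-steps.  S-EM draws a single completion of the hidden
values per iteration (one sweep) and treats the completed data set as fully
observed; MC-EM averages sufficient statistics over many sweeps.  Hidden
components that momentarily own few or no observations fall back to pooled
estimates (and a covariance ridge / CPT pseudocount keeps every state
reachable).
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .core import DBNSpec, SequenceBatch, cpt_shape
from .discrete import (
    CPTParams,
    MultinomialParams,
    PoissonParams,
    discrete_m_step,
    multinomial_m_step,
    poisson_m_step,
)
from .directional import (
    TWO_PI,
    BivariateVonMisesCPD,
    KentCPD,
    VonMisesCPD,
    bvm_estimate_from_stats,
    kappa_from_rbar,
    kent_estimate_from_stats,
)
from .errors import EstimationError, SpecError
from .gaussian import GaussianParams, gaussian_from_stats
from .inference import GibbsSampler, _Engine, forward_loglik, hmm_structure
from .params import DBNParams, n_configs

__all__ = [
    "EMConfig",
    "TrainingState",
    "SuffStats",
    "init_params",
    "e_step_sem",
    "e_step_mcem",
    "m_step",
    "train",
]


@dataclass
class EMConfig:
    """Run configuration for EM training.

    flavour: "sem" (one completion per iteration) or "mcem"
    (``mcem_samples`` completions, statistics averaged).  ``burn_in`` sweeps
    run once before the first iteration.  Early stopping compares the mean
    completed log-likelihood over the last ``conv_window`` iterations against
    the previous window (relative change below ``conv_tol``).  The reported
    estimate is the parameter average over the final window
    (``param_estimate="average"``) or the last iterate.
    """

    flavour: str = "sem"
    n_iterations: int = 100
    mcem_samples: int = 10
    burn_in: int = 10
    pseudocount: float = 0.05
    ridge: float = 1e-6
    seed: int = 0
    conv_window: int = 10
    conv_tol: float = 0.01
    param_estimate: str = "average"
    track_forward: bool = False

    def __post_init__(self):
        if self.flavour not in ("sem", "mcem"):
            raise SpecError("flavour must be 'sem' or 'mcem'")
        if self.n_iterations < 1:
            raise SpecError("n_iterations must be >= 1")
        if self.flavour == "mcem" and self.mcem_samples < 2:
            raise SpecError("mcem requires mcem_samples >= 2")


@dataclass
class TrainingState:
    """Snapshot of training at iteration ``iteration``.

    Carries the current parameters, the current hidden assignment, the
    log-likelihood trace, the RNG state and a copy of the configuration;
    serializing and reloading it continues training bit-identically.
    """

    iteration: int
    params: DBNParams
    hidden: list
    trace: list = field(default_factory=list)
    rng_state: dict | None = None
    config: EMConfig | None = None
    params_avg: DBNParams | None = None
    _snapshots: list = field(default_factory=list, repr=False)

    @property
    def estimate(self) -> DBNParams:
        """The reported parameter estimate (averaged if configured)."""
        if self.params_avg is not None:
            return self.params_avg
        return self.params


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[2] = -q[2]
    return q


def init_params(spec: DBNSpec, rng: np.random.Generator,
                data: SequenceBatch | None = None,
                ridge: float = 1e-6) -> DBNParams:
    """Random diffuse initialization.

    CPT / multinomial rows come from a flat Dirichlet.  Continuous families
    centre on pooled data moments when data is given (component means are
    jittered by one pooled standard deviation so hidden components can
    separate); otherwise generic diffuse defaults are used.
    """
    pooled = _pooled_moments(spec, data) if data is not None else None
    cpds, cpds0 = [], []
    for i, nd in enumerate(spec.nodes):
        sets = []
        for initial in (False, True):
            if initial and not spec.has_initial_params(i):
                sets.append(None)
                continue
            C = n_configs(spec, i, initial)
            sizes = spec.parent_sizes(i, initial)
            fam = nd.family
            if fam == "discrete":
                table = rng.dirichlet(np.ones(nd.size), size=C)
                sets.append(CPTParams(table=table.reshape(cpt_shape(sizes, nd.size))))
            elif fam == "multinomial":
                probs = rng.dirichlet(np.ones(nd.size), size=C)
                sets.append(MultinomialParams(probs=probs.reshape(cpt_shape(sizes, nd.size))))
            elif fam == "poisson":
                base = pooled[i]["rate"] if pooled else 2.0
                sets.append(PoissonParams(rates=base * rng.uniform(0.5, 2.0, size=C)))
            elif fam in ("gaussian_uni", "gaussian_multi"):
                d = nd.size
                if pooled:
                    mean, cov = pooled[i]["mean"], pooled[i]["cov"]
                else:
                    mean, cov = np.zeros(d), np.eye(d)
                sd = np.sqrt(np.diag(cov))
                means = mean[None, :] + rng.standard_normal((C, d)) * sd[None, :]
                covs = np.broadcast_to(cov + ridge * np.eye(d), (C, d, d)).copy()
                sets.append(GaussianParams(means=means, covs=covs))
            elif fam == "vonmises_uni":
                sets.append(VonMisesCPD(mu=rng.uniform(0, TWO_PI, C),
                                        kappa=rng.uniform(1.0, 5.0, C)))
            elif fam == "vonmises_bi":
                sets.append(BivariateVonMisesCPD(
                    mu=rng.uniform(0, TWO_PI, C), nu=rng.uniform(0, TWO_PI, C),
                    kappa1=rng.uniform(1.0, 5.0, C), kappa2=rng.uniform(1.0, 5.0, C),
                    kappa3=np.zeros(C)))
            elif fam == "kent":
                gammas = np.stack([_random_rotation(rng) for _ in range(C)])
                sets.append(KentCPD(kappa=rng.uniform(5.0, 20.0, C),
                                    beta=np.zeros(C), gammas=gammas))
            else:  # pragma: no cover
                raise SpecError(fam)
        cpds.append(sets[0])
        cpds0.append(sets[1])
    return DBNParams(spec=spec, cpds=cpds, cpds0=cpds0)


def _pooled_moments(spec: DBNSpec, data: SequenceBatch):
    out = {}
    for i, nd in enumerate(spec.nodes):
        obs = [seq.values[i][~seq.mask[i]] for seq in data.sequences]
        x = np.concatenate(obs) if obs else np.zeros((0,))
        if nd.family == "poisson":
            out[i] = {"rate": float(x.mean()) if len(x) else 2.0}
        elif nd.family in ("gaussian_uni", "gaussian_multi"):
            if x.ndim == 1:
                x = x[:, None]
            if len(x) > 1:
                out[i] = {"mean": x.mean(axis=0),
                          "cov": np.atleast_2d(np.cov(x.T)) + 1e-6 * np.eye(x.shape[1])}
            else:
                out[i] = {"mean": np.zeros(nd.size), "cov": np.eye(nd.size)}
        else:
            out[i] = {}
    return out


# ---------------------------------------------------------------------------
# Sufficient statistics
# ---------------------------------------------------------------------------

class SuffStats:
    """Per-node, per-parameter-set accumulators of weighted sufficient
    statistics (CPT counts, Gaussian moment sums, circular resultants,
    spherical scatter)."""

    def __init__(self, spec: DBNSpec):
        self.spec = spec
        self.acc: dict[tuple[int, bool], dict] = {}
        for i, nd in enumerate(spec.nodes):
            for initial in (False, True):
                if initial and not spec.has_initial_params(i):
                    continue
                C = n_configs(spec, i, initial)
                fam = nd.family
                if fam in ("discrete", "multinomial"):
                    a = {"counts": np.zeros((C, nd.size))}
                elif fam == "poisson":
                    a = {"n": np.zeros(C), "sum": np.zeros(C)}
                elif fam in ("gaussian_uni", "gaussian_multi"):
                    d = nd.size
                    a = {"n": np.zeros(C), "sx": np.zeros((C, d)),
                         "sxx": np.zeros((C, d, d))}
                elif fam == "vonmises_uni":
                    a = {"n": np.zeros(C), "c": np.zeros(C), "s": np.zeros(C)}
                elif fam == "vonmises_bi":
                    a = {"n": np.zeros(C), "m": np.zeros((C, 6))}
                elif fam == "kent":
                    a = {"n": np.zeros(C), "sx": np.zeros((C, 3)),
                         "sxx": np.zeros((C, 3, 3))}
                else:  # pragma: no cover
                    raise SpecError(fam)
                self.acc[(i, initial)] = a

    def accumulate(self, engine: _Engine, weight: float = 1.0) -> None:
        spec = self.spec
        for t in range(engine.T):
            rows = np.nonzero(engine.valid[:, t])[0]
            if not len(rows):
                continue
            for i, nd in enumerate(spec.nodes):
                initial = t == 0 and spec.has_initial_params(i)
                a = self.acc[(i, initial)]
                cfg = engine.cfg(i, t, rows)
                x = engine.node_values(i, t, rows)
                fam = nd.family
                if fam == "discrete":
                    np.add.at(a["counts"], (cfg, x), weight)
                elif fam == "multinomial":
                    np.add.at(a["counts"], cfg, weight * x)
                elif fam == "poisson":
                    np.add.at(a["n"], cfg, weight)
                    np.add.at(a["sum"], cfg, weight * x)
                elif fam in ("gaussian_uni", "gaussian_multi"):
                    xv = x[:, None] if x.ndim == 1 else x
                    np.add.at(a["n"], cfg, weight)
                    np.add.at(a["sx"], cfg, weight * xv)
                    np.add.at(a["sxx"], cfg,
                              weight * xv[:, :, None] * xv[:, None, :])
                elif fam == "vonmises_uni":
                    np.add.at(a["n"], cfg, weight)
                    np.add.at(a["c"], cfg, weight * np.cos(x))
                    np.add.at(a["s"], cfg, weight * np.sin(x))
                elif fam == "vonmises_bi":
                    phi, psi = x[:, 0], x[:, 1]
                    m = np.column_stack([
                        np.cos(phi), np.sin(phi), np.cos(psi), np.sin(psi),
                        np.cos(phi - psi), np.sin(phi - psi)])
                    np.add.at(a["n"], cfg, weight)
                    np.add.at(a["m"], cfg, weight * m)
                elif fam == "kent":
                    np.add.at(a["n"], cfg, weight)
                    np.add.at(a["sx"], cfg, weight * x)
                    np.add.at(a["sxx"], cfg,
                              weight * x[:, :, None] * x[:, None, :])

    def scaled(self, factor: float) -> "SuffStats":
        out = SuffStats(self.spec)
        for key, a in self.acc.items():
            out.acc[key] = {k: v * factor for k, v in a.items()}
        return out


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

def _fit_vm_set(a, pooled):
    C = len(a["n"])
    mu = np.empty(C)
    kappa = np.empty(C)
    pn, pc, ps = pooled
    for c in range(C):
        n, cc, ss = a["n"][c], a["c"][c], a["s"][c]
        if n <= 0 or np.hypot(cc, ss) / max(n, 1e-300) < 1e-10:
            n, cc, ss = pn, pc, ps
        rbar = min(np.hypot(cc, ss) / n, 1.0)
        mu[c] = np.mod(np.arctan2(ss, cc), TWO_PI)
        kappa[c] = max(kappa_from_rbar(min(rbar, 1 - 1e-12)), 1e-6)
    return VonMisesCPD(mu=mu, kappa=kappa)


def _fit_bvm_set(a, pooled):
    C = len(a["n"])
    comps = {"mu": [], "nu": [], "kappa1": [], "kappa2": [], "kappa3": []}
    pn, pm = pooled
    for c in range(C):
        n, m = a["n"][c], a["m"][c]
        if n < 5:
            n, m = pn, pm
        try:
            p = bvm_estimate_from_stats(m, n)
        except EstimationError:
            p = bvm_estimate_from_stats(pm, pn)
        comps["mu"].append(p.mu)
        comps["nu"].append(p.nu)
        comps["kappa1"].append(p.kappa1)
        comps["kappa2"].append(p.kappa2)
        comps["kappa3"].append(p.kappa3)
    return BivariateVonMisesCPD(**{k: np.array(v) for k, v in comps.items()})


def _fit_kent_set(a, pooled):
    C = len(a["n"])
    kappa, beta, gammas = [], [], []
    pn, psx, psxx = pooled
    for c in range(C):
        n, sx, sxx = a["n"][c], a["sx"][c], a["sxx"][c]
        if n < 3:
            n, sx, sxx = pn, psx, psxx
        try:
            p = kent_estimate_from_stats(sx, sxx, n)
        except EstimationError:
            p = kent_estimate_from_stats(psx, psxx, pn)
        kappa.append(p.kappa)
        beta.append(p.beta)
        gammas.append(p.gammas)
    return KentCPD(kappa=np.array(kappa), beta=np.array(beta),
                   gammas=np.stack(gammas))


def m_step(spec: DBNSpec, stats: SuffStats, config: EMConfig) -> DBNParams:
    """Per-family ML updates from sufficient statistics.

    Dispatches to the closed-form CPT/multinomial/Poisson/Gaussian updates
    and the directional estimators; slice-0 parameter sets are fitted from
    slice-0 statistics only.  Empty or undersized parent configurations fall
    back to pooled estimates.
    """
    cpds, cpds0 = [], []
    for i, nd in enumerate(spec.nodes):
        fitted = []
        for initial in (False, True):
            if initial and not spec.has_initial_params(i):
                fitted.append(None)
                continue
            a = stats.acc[(i, initial)]
            fam = nd.family
            sizes = spec.parent_sizes(i, initial)
            try:
                if fam == "discrete":
                    counts = a["counts"].reshape(cpt_shape(sizes, nd.size))
                    fitted.append(discrete_m_step(counts, config.pseudocount))
                elif fam == "multinomial":
                    fitted.append(multinomial_m_step(a["counts"], config.pseudocount))
                elif fam == "poisson":
                    tot_n, tot_s = a["n"].sum(), a["sum"].sum()
                    fb = tot_s / tot_n if tot_n > 0 else 1.0
                    fitted.append(poisson_m_step(a["n"], a["sum"], fallback_rate=max(fb, 1e-9)))
                elif fam in ("gaussian_uni", "gaussian_multi"):
                    fitted.append(gaussian_from_stats(a["n"], a["sx"], a["sxx"],
                                                      ridge=config.ridge))
                elif fam == "vonmises_uni":
                    pooled = (a["n"].sum(), a["c"].sum(), a["s"].sum())
                    fitted.append(_fit_vm_set(a, pooled))
                elif fam == "vonmises_bi":
                    pooled = (a["n"].sum(), a["m"].sum(axis=0))
                    fitted.append(_fit_bvm_set(a, pooled))
                elif fam == "kent":
                    pooled = (a["n"].sum(), a["sx"].sum(axis=0), a["sxx"].sum(axis=0))
                    fitted.append(_fit_kent_set(a, pooled))
                else:  # pragma: no cover
                    raise SpecError(fam)
            except (EstimationError, FloatingPointError) as exc:
                raise EstimationError(
                    f"M-step failed for node {nd.name!r}"
                    f"{' (slice-0 set)' if initial else ''}: {exc}"
                ) from exc
        cpds.append(fitted[0])
        cpds0.append(fitted[1])
    return DBNParams(spec=spec, cpds=cpds, cpds0=cpds0)


# ---------------------------------------------------------------------------
# E-steps
# ---------------------------------------------------------------------------

def e_step_sem(sampler: GibbsSampler, rng: np.random.Generator) -> SuffStats:
    """One Gibbs sweep; sufficient statistics of the single completion."""
    sampler.sweep(rng)
    stats = SuffStats(sampler.engine.spec)
    stats.accumulate(sampler.engine, weight=1.0)
    return stats


def e_step_mcem(sampler: GibbsSampler, m: int,
                rng: np.random.Generator) -> SuffStats:
    """``m`` Gibbs sweeps; statistics averaged across the completions."""
    if m < 1:
        raise ValueError("m must be >= 1")
    stats = SuffStats(sampler.engine.spec)
    for _ in range(m):
        sampler.sweep(rng)
        stats.accumulate(sampler.engine, weight=1.0 / m)
    return stats


# ---------------------------------------------------------------------------
# Parameter averaging (post-plateau S-EM estimate)
# ---------------------------------------------------------------------------

def _circmean(angles, axis=0):
    return np.mod(np.arctan2(np.mean(np.sin(angles), axis=axis),
                             np.mean(np.cos(angles), axis=axis)), TWO_PI)


def average_params(snapshots: list[DBNParams]) -> DBNParams:
    """Elementwise average of parameter snapshots.

    Tables and probability rows are averaged and renormalized; angles use
    circular means; Kent frames are averaged then projected back to the
    nearest orthogonal matrix (axis signs aligned to the first snapshot
    first, since the FB5 density is invariant under jointly negating the
    major and minor axes).
    """
    spec = snapshots[0].spec
    cpds, cpds0 = [], []
    for i in range(spec.n_nodes):
        fitted = []
        for initial in (False, True):
            if initial and not spec.has_initial_params(i):
                fitted.append(None)
                continue
            comps = [p.cpd(i, initial) for p in snapshots]
            ref = comps[0]
            if isinstance(ref, CPTParams):
                t = np.mean([c.table for c in comps], axis=0)
                t /= t.sum(axis=-1, keepdims=True)
                fitted.append(CPTParams(table=t))
            elif isinstance(ref, MultinomialParams):
                t = np.mean([c.probs for c in comps], axis=0)
                t /= t.sum(axis=-1, keepdims=True)
                fitted.append(MultinomialParams(probs=t))
            elif isinstance(ref, PoissonParams):
                fitted.append(PoissonParams(
                    rates=np.mean([c.rates for c in comps], axis=0)))
            elif isinstance(ref, GaussianParams):
                fitted.append(GaussianParams(
                    means=np.mean([c.means for c in comps], axis=0),
                    covs=np.mean([c.covs for c in comps], axis=0)))
            elif isinstance(ref, VonMisesCPD):
                fitted.append(VonMisesCPD(
                    mu=_circmean(np.stack([c.mu for c in comps])),
                    kappa=np.mean([c.kappa for c in comps], axis=0)))
            elif isinstance(ref, BivariateVonMisesCPD):
                fitted.append(BivariateVonMisesCPD(
                    mu=_circmean(np.stack([c.mu for c in comps])),
                    nu=_circmean(np.stack([c.nu for c in comps])),
                    kappa1=np.mean([c.kappa1 for c in comps], axis=0),
                    kappa2=np.mean([c.kappa2 for c in comps], axis=0),
                    kappa3=np.mean([c.kappa3 for c in comps], axis=0)))
            elif isinstance(ref, KentCPD):
                kappa = np.mean([c.kappa for c in comps], axis=0)
                beta = np.mean([c.beta for c in comps], axis=0)
                beta = np.minimum(beta, 0.4999 * kappa)
                C = len(kappa)
                gammas = np.empty((C, 3, 3))
                for c in range(C):
                    mats = []
                    for p in comps:
                        g = p.gammas[c].copy()
                        # the density is invariant under jointly negating
                        # gamma2 and gamma3; align before averaging
                        if g[1] @ ref.gammas[c][1] < 0:
                            g[1], g[2] = -g[1], -g[2]
                        mats.append(g)
                    u, _, vt = np.linalg.svd(np.mean(mats, axis=0))
                    gammas[c] = u @ vt
                fitted.append(KentCPD(kappa=kappa, beta=beta, gammas=gammas))
            else:  # pragma: no cover
                raise SpecError(type(ref).__name__)
        cpds.append(fitted[0])
        cpds0.append(fitted[1])
    return DBNParams(spec=spec, cpds=cpds, cpds0=cpds0)


# ---------------------------------------------------------------------------
# Training driver
# ---------------------------------------------------------------------------

def _engine_loglik(engine: _Engine) -> float:
    total = 0.0
    for t in range(engine.T):
        rows = np.nonzero(engine.valid[:, t])[0]
        for i in range(engine.spec.n_nodes):
            total += float(engine.node_logp(i, t, rows).sum())
    return total


def train(spec: DBNSpec, data: SequenceBatch, config: EMConfig,
          state: TrainingState | None = None,
          callback=None) -> TrainingState:
    """Run S-EM or MC-EM until ``n_iterations`` or early convergence.

    Passing a previously saved ``state`` resumes training exactly where it
    stopped (same RNG stream, hidden assignment and trace).  ``callback``,
    if given, is called after every iteration with a dict holding the
    iteration index and log-likelihoods.
    """
    rng = np.random.default_rng(config.seed)
    if state is None:
        params = init_params(spec, rng, data=data, ridge=config.ridge)
        sampler = GibbsSampler(params, data, rng)
        for _ in range(config.burn_in):
            sampler.sweep(rng)
        start_iter = 0
        trace: list[dict] = []
        snapshots: list[DBNParams] = []
    else:
        params = state.params
        sampler = GibbsSampler(params, data, rng, init=False)
        sampler.engine.apply_hidden(state.hidden)
        rng.bit_generator.state = state.rng_state
        start_iter = state.iteration
        trace = list(state.trace)
        snapshots = list(state._snapshots)
    config = replace(config)
    is_hmm = True
    try:
        hmm_structure(spec)
    except Exception:
        is_hmm = False
    track_forward = config.track_forward and is_hmm

    window = config.conv_window
    for it in range(start_iter, config.n_iterations):
        if config.flavour == "sem":
            stats = e_step_sem(sampler, rng)
        else:
            stats = e_step_mcem(sampler, config.mcem_samples, rng)
        params = m_step(spec, stats, config)
        sampler.params = params
        ll = _engine_loglik(sampler.engine)
        rec = {"iteration": it + 1, "completed_loglik": ll}
        if track_forward:
            rec["forward_loglik"] = forward_loglik(params, data)
        trace.append(rec)
        snapshots.append(params)
        if len(snapshots) > window:
            snapshots.pop(0)
        if callback is not None:
            callback(rec)
        # sliding-window convergence on the completed log-likelihood
        lls = [r["completed_loglik"] for r in trace]
        if len(lls) >= 2 * window:
            recent = np.mean(lls[-window:])
            prev = np.mean(lls[-2 * window:-window])
            if abs(recent - prev) < config.conv_tol * abs(prev):
                break
    params_avg = None
    if config.param_estimate == "average" and snapshots:
        params_avg = average_params(snapshots)
    return TrainingState(
        iteration=len(trace),
        params=params,
        hidden=sampler.assignment(),
        trace=trace,
        rng_state=copy.deepcopy(rng.bit_generator.state),
        config=config,
        params_avg=params_avg,
        _snapshots=snapshots,
    )


def write_trace(trace: list[dict], path) -> None:
    """Training trace as delimited text: iteration, completed and (for HMMs)
    forward log-likelihood."""
    cols = ["iteration", "completed_loglik"]
    if any("forward_loglik" in r for r in trace):
        cols.append("forward_loglik")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in trace:
            fields = [str(r["iteration"]), repr(r["completed_loglik"])]
            if "forward_loglik" in cols:
                v = r.get("forward_loglik")
                fields.append("" if v is None else repr(v))
            fh.write("\t".join(fields) + "\n")
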