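# Methods

This note documents the models, estimators, numerical choices and known
limitations of `seqdbn`, in the spirit of a statistical software appendix.

## Network model

A DBN template is one *slice*: an ordered list of nodes, each with a
distribution family, plus intra-slice edges and inter-slice edges between
adjacent slices only.  Node order must topologically order the intra edges;
the loader rejects other orderings instead of silently reordering, so the
ancestral sampling order is always explicit.  All parents must be discrete —
a parent configuration indexes one component of the child's conditional
distribution — which is slightly stricter than requiring it only for
continuous children, but a CPT conditioned on a continuous parent would be
unsupported anyway.

Parameters are tied across slices.  A node with inter-slice parents cannot
use its conditional table at slice 1 (the parents do not exist), so it owns
a second, intra-parents-only parameter set for the initial slice, estimated
jointly during EM from slice-1 data.  This is the simplest correct
parameterization; the alternative (a stationarity constraint linking the
initial set to the transition set) is deliberately out of scope.

Hidden entries are restricted to discrete nodes flagged `hidden_allowed`.
Every Gibbs conditional is then a finite enumeration, and all benchmark
models (hidden chains driving observed outputs) fit this regime.
Continuous hidden nodes would require Metropolis-within-Gibbs steps and are
a known limitation.

Multidimensional tables (CPTs, counts) are numpy arrays in row-major order;
`mdarray_create`, `mdarray_slice` and `cpt_shape` expose the documented
shape conventions, with one axis per parent and the node's own states last.

## Distribution families

**Categorical / multinomial / Poisson.**  Standard forms.  The multinomial
trial count is per-observation (the sum of the observed count vector), not
a parameter.  M-steps are closed-form; CPT and multinomial updates accept a
per-cell pseudocount (default 0.05 in EM) because a zero probability makes
a hidden state unreachable for the Gibbs chain and can never be revisited.

**Gaussian (uni-/multivariate).**  Full covariance per parent
configuration, evaluated and sampled through cached Cholesky factors.  The
M-step adds a ridge (default 1e-6) to the ML covariance; configurations
with fewer than d+1 observations fall back to the pooled covariance, and
empty ones also take the pooled mean.  These fallbacks matter early in EM
when a hidden component may momentarily own almost no data.

**von Mises (circle).**  Density `kappa cos(theta-mu) - log(2 pi
I0(kappa))` with `log I0` computed from the scaled Bessel function.
Sampling uses the Best–Fisher envelope-rejection scheme (via numpy's
generator).  Estimation: circular-mean direction, concentration by the
standard three-regime rational inversion of the mean-resultant-length
equation, capped at 1e4 (with a warning) when the resultant is numerically 1.

**Bivariate von Mises, cosine model (torus).**  Density exponent
`k1 cos(phi-mu) + k2 cos(psi-nu) - k3 cos(phi-mu-psi+nu)`; with the minus
convention, positive `k3` induces negative circular correlation.  The
normalizer is computed two ways: an alternating Bessel-product series
`4 pi^2 sum_p (+-) Ip(k1) Ip(k2) Ip(k3)` (scaled Bessel functions, used in
tests), and the authoritative reduction to one dimension — integrating phi
analytically leaves `2 pi int exp(k2 cos p) I0(kc(p)) dp` with
`kc(p) = sqrt(k1^2 + k3^2 - 2 k1 k3 cos p)` — evaluated on a 4096-point
periodic trapezoid grid in log space (spectrally accurate for these smooth
integrands).  The series loses precision to cancellation at large `k3` and
then falls back to quadrature with a warning.

Sampling draws psi from its 1D marginal by inverse CDF on a 4096-point grid
(linear interpolation) and phi from the exact von Mises conditional, whose
parameters follow algebraically from the exponent (`a = k1 - k3 cos(psi-nu)`,
`b = -k3 sin(psi-nu)`, concentration `sqrt(a^2+b^2)`, mean `mu + atan2(b, a)`).

Estimation: mean angles from circular means; `(k1, k2, k3)` maximize the
exact average log-likelihood, which depends on the data only through six
sufficient statistics (means of `cos phi, sin phi, cos psi, sin psi,
cos(phi-psi), sin(phi-psi)`).  The optimizer is L-BFGS-B with analytic
gradients — the normalizer's gradient is an expectation on the same
quadrature grid — with a Nelder-Mead retry if the line search fails near a
flat optimum.  `k3` is clipped to 0.95 min(k1, k2) afterwards (with a
warning): outside that bound the density leaves the unimodal regime.

**Kent / FB5 (sphere).**  Exponent `kappa g1.x + beta [(g2.x)^2 -
(g3.x)^2]` over an orthonormal frame, `2 beta < kappa`.  The normalizer has
an exact series `2 pi sum_j G(j+1/2)/G(j+1) beta^{2j} (2/kappa)^{2j+1/2}
I_{2j+1/2}(kappa)` (log-space, scaled Bessel; at `beta = 0` it collapses to
the closed-form von Mises-Fisher normalizer `4 pi sinh(kappa)/kappa`) and a
large-concentration approximation `2 pi e^kappa [(kappa-2beta)
(kappa+2beta)]^{-1/2}`, which agrees with the series to better than 1% for
`kappa >= 50` and is available for speed-critical use; densities default to
the exact series.

Sampling works in the frame coordinates `t = g1.x`,
`x = t g1 + sqrt(1-t^2)(cos a g2 + sin a g3)`, where the density over
`(t, a)` w.r.t. `dt da` is proportional to `exp{kappa t + beta (1-t^2)
cos 2a}`.  Proposals take `t` from `exp(kappa t - beta t^2)` by dense-grid
inverse CDF restricted to the interval within 50 nats of the proposal's
maximum, and `a` uniform; the acceptance probability
`exp{beta (1-t^2)(cos 2a - 1)} <= 1` makes the draw exact up to grid
resolution.  This parameterization was chosen over a tangent-plane
exponential-envelope scheme for its simplicity and vectorizability at equal
exactness.

Estimation: the mean direction is the normalized resultant; the major and
minor axes come from the eigenstructure of the scatter matrix projected on
the tangent plane; `kappa` and `beta` start at the classical
high-concentration moment estimators `1/(2-2R-r2) + 1/(2-2R+r2)` and half
their difference.  Those closed forms are biased by up to ~30% as
`2 beta/kappa` approaches 1 (verified against an independent grid-sampling
oracle), so the pair is then refined by maximizing the exact likelihood
`kappa R + beta r2 - log C(kappa, beta)` over a domain-respecting
reparameterization (`kappa = e^x`, `2 beta/kappa = 0.9999 sigmoid(y)`,
Nelder-Mead).  With the refinement, recovery at n = 5000 is within a few
percent across the tested range, including near the unimodality boundary.

Angles live in `[0, 2 pi)`; unit vectors are renormalized on input when
within 1e-6 of unit norm and rejected otherwise.

## Inference

**Gibbs sampling.**  Systematic scan, slice-major with node order inside a
slice, resampling each hidden entry from `p(h | blanket) ∝ p(h | parents)
prod_children p(child | parents)` normalized over the node's states in log
space.  Sequences are mutually independent, so the sweep is vectorized
across sequences: the same (slice, node) entry of every sequence is
resampled simultaneously with one uniform variate per sequence
(inverse-CDF, ties toward the lower index).  Before the first sweep, hidden
entries are initialized by ancestral sampling from the current model
(children ignored) so the chain starts in a feasible region.  The
`resample_ops` counter records state-probability evaluations — entries
times states — and doubles exactly when either the total slice count or the
node size doubles.  If every state of a conditional has zero probability
the sweep raises an error naming the sequence, slice and node; log-space
accumulation makes this unreachable in practice unless the model itself
contains structural zeros.

**Likelihoods.**  The completed-data log-likelihood sums every node's
log-density given its (fully assigned) parents.  For HMM-shaped topologies
— exactly one inter edge, hidden-to-hidden, on a discrete chain whose
children are intra-slice outputs — the observed-data log-likelihood is
computed by the forward recursion entirely in log space (logsumexp),
vectorized across sequences, with observed chain entries clamped.  Any
other topology is refused with an explicit error.  Forward-backward
smoothing exists only as a test oracle, not public surface.

## Learning

S-EM draws exactly one Gibbs sweep per iteration (after a configurable
burn-in, default 10 sweeps, before the first iteration only) and treats the
completion as fully observed data; MC-EM runs `m` sweeps and averages the
per-family sufficient statistics.  Both share the same M-step dispatcher;
slice-1 parameter sets are fitted from slice-1 statistics only.

Initialization is random but data-informed: CPT rows from a flat Dirichlet;
Gaussian components centred on the pooled mean jittered by one pooled
standard deviation (so hidden components can separate), pooled covariance;
directional components with diffuse concentrations and uniform mean angles.

Convergence: training stops early when the mean completed log-likelihood
over the last `w` iterations (default 10) changes by less than 1% relative
to the previous window, with a hard iteration cap (default 100).  Because
S-EM produces a parameter *sequence* rather than a convergent point, the
reported estimate is by default the average of the last-window parameter
snapshots (probability tables renormalized after averaging; angles averaged
circularly; Kent frames sign-aligned, averaged and projected back to the
nearest orthogonal matrix); the last iterate is available as an
alternative.  Training state (parameters, hidden assignment, RNG state,
trace, configuration) serializes to a versioned JSON container and resumes
bit-identically.

### Known behaviour of S-EM worth knowing about

*Merged-state lock-in.*  Because the E-step commits to a single hard
completion, S-EM can lock into local optima in which two true states share
one learned state — especially when the true transition matrix is sticky
(strong self-transitions), since the completion then never proposes the
split.  Soft (expected-count) EM escapes such configurations more easily.
The parameter-recovery study therefore uses a non-sticky, strongly
identifiable truth (below).

*Weak identifiability at benchmark scale.*  For a 5-state, 5-symbol HMM
with tables drawn from a flat Dirichlet, 200 sequences of 50 slices do not
pin the tables to 0.05 per entry: independent exact-EM runs initialized at
the truth drift 0.04-0.14 along near-flat likelihood ridges, and restarts
reach higher likelihood than the truth at 0.2-0.5 entry distance.  This is
a property of the statistics, not of any particular optimizer.

## Benchmarks and fixtures

Three generators reproduce standard parameter-estimation workloads, each
defaulting to 50 slices and 200 sequences with every hidden entry masked:
a discrete HMM (two discrete nodes per slice, all sizes 5), a Gaussian HMM
(10 hidden states, 4-dimensional output), and a two-chain model in which
hidden H (size 5) drives a 4-dimensional Gaussian node and hidden I (size
3) drives a bivariate von Mises node.  True parameters are drawn from
documented diffuse distributions: flat Dirichlet rows; Gaussian means
`3 x N(0, 1)` with covariances `W W'/d + 0.2 I` (`W` standard normal);
torus concentrations uniform on [20, 80] with the interaction uniform
within ±0.45 of the unimodal bound.

The parameter-recovery study uses a separate, deliberately identifiable
truth: a noisy cyclic automaton (advance with probability 0.7, stay 0.15,
jump 0.05 to each other state) emitting its own symbol with probability
0.95.  Every state has a distinct dynamical signature, the likelihood is
sharply curved, and both exact EM and S-EM recover the tables to ~0.03 per
entry at the default scale.

What the synthetic benchmarks do *not* emulate about real sequence data:
ragged, heavy-tailed length distributions; missing observations in output
nodes; model misspecification (real emissions are never exactly in the
fitted family); and long-range dependencies beyond adjacent slices.
Passing recovery tests on these fixtures demonstrates correctness of the
estimators and samplers, not robustness to misspecification.

On the diffuse discrete benchmark the smoothed completed-log-likelihood
trend of S-EM is not monotone within 1% of its rise: the truth carries so
little learnable structure that the total rise (~700 nats on a −27,000 nat
likelihood) is comparable to S-EM's plateau fluctuations, and the monitor
dips a few percent of the rise during the first ~20 iterations under every
monitor variant.  The Gaussian and complex benchmarks, whose truths carry
real structure, show the expected clean rise-to-plateau from multiple
seeds.  The acceptance script reports the measured worst smoothed decline
per benchmark.

## Numerical choices, in brief

Log-space throughout for products of probabilities; logsumexp for
normalizations.  Quadrature grids: 4096 points for torus normalizers and
inverse-CDF sampling (configurable in source); Gauss-Legendre x trapezoid
product grids in the test oracles.  Categorical sampling is inverse-CDF
with a single uniform per draw, ties toward the lower index, so all
samplers are reproducible given a seed; per-run randomness flows from one
`numpy` PCG64 generator whose state is serialized for suspend/resume.
Covariance updates symmetrize before factorization and escalate the ridge
(from 1e-10) in the rare case a pooled covariance is itself degenerate.
Constraint handling at M-steps: `2 beta < kappa` and `|k3| < min(k1, k2)`
enforced by clipping at 95% of the bound, with warnings.

## File formats

Specifications are YAML (nodes with family/size/hidden flag, 0-based edge
index pairs).  Sequence data is TSV with one row per (sequence, slice), one
tab-separated field per node, vector components comma-separated, hidden
entries as the literal `?`, and a self-describing header naming nodes and
families; round trips preserve values to 1e-12 and masks exactly.  Training
state is a versioned JSON document; unsupported versions and truncated
files raise explicit errors.
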