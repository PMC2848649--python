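# seqdbn

Dynamic Bayesian networks over sequences, with Gibbs-sampling inference,
stochastic EM parameter learning, and first-class support for directional
statistics: the Kent (FB5) distribution on the sphere and the bivariate von
Mises cosine model on the torus, alongside discrete, multinomial, Poisson,
Gaussian and univariate von Mises node types.

## Who this is for

Probabilistic models of biomolecular structure are naturally sequential
(residues, nucleotides) and naturally angular (backbone dihedral-angle pairs
on the torus, C-alpha pseudo-bond directions on the sphere).  Ordinary
Euclidean distributions are wrong for such data because the sample space
wraps.  `seqdbn` lets you specify a Bayesian-network *slice* — nodes with
distribution families, edges within the slice and edges to the next slice —
replicate it along sequences with tied parameters, infer hidden discrete
states by Gibbs sampling, and fit all parameters by stochastic EM (S-EM) or
Monte Carlo EM (MC-EM).  Hidden-node chains make the familiar HMM a special
case; heterogeneous slices (a discrete hidden state driving a Gaussian
vector *and* an angle pair) are equally natural.

## The model

A DBN is defined by one slice of nodes `X_1 .. X_n`, intra-slice edges and
inter-slice edges; unrolled over `L` slices, the joint factorizes as

    P(X) = prod_{t=1..L} prod_i P(X_i^t | parents(X_i^t))

with parameters tied across `t` (nodes with inter-slice parents own a
separate, unconditional parameter set for slice 1).  All parents are
discrete; a parent configuration indexes a component of the child's
distribution, so a discrete parent yields mixtures for free.

Conditional families include the categorical CPT (a node of size 2 with
parents of sizes 3 and 4 has a 3 x 4 x 2 table), the Kent density on the
unit sphere

    f(x) = C(kappa, beta)^-1 exp{ kappa g1.x + beta [(g2.x)^2 - (g3.x)^2] },

with concentration `kappa`, ellipticity `beta` (`2 beta < kappa`; `beta = 0`
recovers the von Mises-Fisher distribution) and orthonormal axes `g1, g2,
g3`, and the bivariate von Mises cosine model on the torus

    f(phi, psi) = C^-1 exp{ k1 cos(phi-mu) + k2 cos(psi-nu)
                            - k3 cos(phi-mu-psi+nu) },

whose `k3` term couples the two angles (positive `k3` induces negative
circular correlation).

Inference over hidden discrete values uses systematic-scan Gibbs sampling
(each conditional is a finite enumeration over the node's Markov blanket;
one sweep costs O(total slices x state count) per hidden chain).  Learning
alternates a stochastic E-step (one Gibbs completion for S-EM, an average
of many for MC-EM) with closed-form or numerical maximum-likelihood
M-steps per family.  For HMM-shaped networks the exact observed-data
log-likelihood is available through the scaled forward recursion.

## Worked example

Generate a discrete-HMM benchmark fixture (5 hidden states, 5 output
symbols, 50 slices), fit it with S-EM, and evaluate log-likelihoods:

```
$ seqdbn benchmark --name discrete_hmm --n-sequences 50 --n-slices 50 \
      --seed 7 --out-prefix work/bench
wrote work/bench.spec.yaml, .data.tsv, .truth.json

$ seqdbn train --spec work/bench.spec.yaml --data work/bench.data.tsv \
      --iterations 40 --seed 1 --track-forward \
      --out work/fit.json --trace work/trace.tsv
trained 20 iterations -> work/fit.json

$ seqdbn loglik --state work/fit.json --data work/bench.data.tsv
completed_loglik        -6773.332535871167
forward_loglik          -3997.2732081319664
```

Training stopped early (iteration 20 of 40) because the sliding-window mean
of the completed-data log-likelihood plateaued.  The trace file records both
monitors per iteration; the forward log-likelihood (exact, summed over all
hidden paths) improves from -4020.1 at iteration 1 to -3997.3 at
convergence, while the completed-data value fluctuates around its plateau —
expected for S-EM, which samples a fresh completion each iteration.  The
completed value is lower than the forward value because it scores one
sampled hidden assignment rather than summing over all of them.

`seqdbn sample --state work/fit.json --n 10 --n-slices 50 --out samples.tsv`
draws new sequences from the fitted model.  Training can be suspended and
resumed: `--out` state files contain parameters, the hidden assignment, the
RNG state and the trace, and `seqdbn train --resume` continues
bit-identically.

The same functionality is available as a library; see
`seqdbn.DBNSpec`, `seqdbn.train`, `seqdbn.GibbsSampler`,
`seqdbn.kent_sample`, `seqdbn.bvm_estimate`, etc., and the method
documentation in `docs/methods.md`.

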