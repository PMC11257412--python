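# Methods

## Problem and model

`logitcp` predicts multi-type miRNA–disease associations.  The data are a
binary third-order tensor `Y ∈ {0,1}^{I×J×K}` whose entry `Y[i,j,k]` records
whether miRNA *i* is associated with disease *j* under evidence type *k*
(e.g. circulation, epigenetics, genetics, target, tissue), plus two kernel
similarity matrices: `S^m` (miRNA × miRNA) and `S^d` (disease × disease).
Known associations are sparse (≈0.7–1.0% in the public HMDD-derived
benchmarks) and the zeros are *unlabelled*, not verified negatives.

The model is a Bayesian logistic CP decomposition.  With factor matrices
`G (I×R)`, `H (J×R)`, `W (K×R)` the reconstruction is
`Ỹ[i,j,k] = Σ_r G[i,r] H[j,r] W[k,r]` and the association probability is
`P[i,j,k] = σ(Ỹ[i,j,k])`.  The likelihood is a weighted Bernoulli,

    P(Y | G,H,W) = Π_ijk σ(Ỹ)^{c·Y} (1 − σ(Ỹ))^{1−Y},

where `c ≥ 1` up-weights the experimentally verified positives relative to
the unlabelled zeros.  Auxiliary similarity enters through kernel coupling
priors: elementwise `G[i,r] ~ N( (S^m U)[i,r], σ_g^{-1} )` and
`H[j,r] ~ N( (S^d V)[j,r], σ_h^{-1} )`, with Jeffreys priors on the
precisions `σ_g, σ_h`.  Automatic rank determination (ARD) places a shared
zero-mean Gaussian prior with per-component precision `λ_r` on the columns
of `U`, `V` and `W`, and a `Gamma(α, β)` hyperprior on each `λ_r`
(`α = β = 1`, uninformative).  Components the data do not support receive
large posterior `λ_r` and their columns shrink to zero, so the initial `R`
is an upper bound rather than a tuning parameter.

## Inference

The logistic likelihood is not conjugate; each log-sigmoid is replaced by
its local quadratic (variational) lower bound with parameter `ξ[i,j,k]`,
`σ(z) ≥ σ(ξ) exp((z−ξ)/2 − λ(ξ)(z²−ξ²))`, `λ(ξ) = (σ(ξ)−½)/(2ξ)`
(`λ(0) = 1/8` by continuity).  With the bound substituted, every conditional
is conjugate and mean-field coordinate ascent applies.  One sweep updates,
in order: the noise precisions (Gamma), the rows of `G`, `H`, `W`
(Gaussian), the columns of `U`, `V` (Gaussian), the ARD precisions (Gamma),
and the local parameters (`ξ² = E[Ỹ²]`).  The surrogate evidence lower
bound is monotone non-decreasing over sweeps, which the test suite verifies
to 1e-8 relative tolerance; it is used only for convergence monitoring.
Convergence is declared when the relative objective change drops below
`tol` (default 1e-5) or after `max_iter` sweeps (default 200).  Fits are
deterministic given the seed used for the Gaussian initialization of the
posterior means.

One sweep costs `O(IJK R² + I³R + J³R)`; the `I³/J³` terms come from the
coupling-column covariances.  Since `S^m, S^d` are fixed, the
eigendecomposition of `SᵀS` is computed once per fit and reused, making the
per-sweep coupling cost `O(I² R)` after that one-time `O(I³)` step.

### Numerical choices

- Precision matrices are inverted after a Cholesky check; on failure a
  diagonal jitter starting at 1e-10 escalates tenfold up to 1e-6.
- Expected coupling residuals in the σ updates are floored at 1e-12
  (degenerate exact fits).
- `σ(x)` is evaluated in its overflow-free branch per sign; `λ(ξ)` switches
  to its series value 1/8 below |ξ| = 1e-6.
- The intercept-free prior mean of `W` (pure ARD) means ties in component
  assignment are broken by the random initialization; all reported
  quantities are invariant to the resulting column permutation.

### Effective rank

A shrunk component's posterior-mean columns collapse to zero, but the mean
precision `λ̃_r` does *not* diverge: the covariance traces contribute
`≈ n/λ` to the Gamma rate, so dead components saturate at a common,
data-independent plateau only a small factor above the live components.
The effective-rank diagnostic therefore thresholds the posterior-mean
column mass `m_r = ‖Ũ_r‖² + ‖Ṽ_r‖² + ‖W̃_r‖²`, which separates live from
dead components by hundreds of orders of magnitude: component `r` is
retained iff `m_r ≥ max(m)/threshold_ratio` (default 100).  This is purely
a report; no column is removed during inference.

## Similarity construction

- **miRNA functional similarity** from a gene functional network with
  log-likelihood scores (LLS): gene–gene similarity is the min–max scaled
  LLS (1 on the diagonal, 0 without an edge), and the miRNA-level score
  averages best-match gene similarities across both associated gene sets.
- **Interaction-profile similarity**: the mode-1 (miRNA) and mode-2
  (disease) unfoldings of `Y` are reduced to nonnegative features by NNDSVD
  (target dimension `min(50, 0.2·min(dims))` by default), then a kernel
  neighborhood similarity is applied: Gaussian kernel with bandwidth =
  median pairwise distance × a user factor, restricted to each row's
  nearest neighbors (10% of n, ≥3), symmetrized by max, unit diagonal.
  The kernel-neighborhood step is a pluggable backend; any replacement must
  return a symmetric, unit-diagonal matrix in [0,1].
- **Fusion** of per-entity sources (functional + profile for miRNAs,
  semantic + profile for diseases) defaults to a convex combination with
  weights (0.5, 0.5), re-symmetrized with a unit diagonal; alternative
  fusion callables can be swapped in.  Disease semantic similarity is
  consumed as a precomputed input file.

## Evaluation protocols

- **Type CV** (5-fold): miRNA–disease pairs with ≥1 known type are
  partitioned; all type entries of a test pair are masked in training.
  Per pair the top-scoring type is compared with the true type set:
  precision@1 is the hit indicator, recall@1 divides by the number of true
  types, F1 is their harmonic mean; means over pairs are reported.  Ties at
  the top score resolve to the lowest type index.
- **Triplet CV** (5-fold): known triples are partitioned and test triples
  zeroed in training.  For each of 20 negative-sampling seeds, as many
  unknown triples as test positives are drawn without replacement; AUPR
  (trapezoidal PR curve), AUC and maximum F1 along the PR curve are
  computed per seed and averaged.  The maximum-F1 convention is
  threshold-free; a fixed-threshold variant is a one-line change at the
  call site.
- **Hit rate**: fraction of known candidates inside the top `⌊ρ·N⌋` of the
  ranked candidate list (`N` = number of scored candidates), so uniformly
  random scoring has expectation ρ.

## Synthetic data

The generator draws what the model assumes: latent entity features (8 per
entity) whose Gaussian kernels become `S^m`/`S^d`; orthogonalized coupling
matrices `U*, V*` with `R_true` columns, scaled so the factor columns
`G* = S^m U* + noise`, `H* = S^d V* + noise` have unit RMS (the noise level
`noise_sd` trades kernel-predictable structure against idiosyncratic
structure at fixed signal scale); orthogonal type loadings of equal
strength (`w_scale` = 2.5 RMS per entry); and a rank-1 intercept component
(ones in the miRNA/disease modes, constant `b` in the type mode) whose
level is solved by root finding so the expected density of
`Y ~ Bernoulli(σ(Ỹ*))` hits the target (5% at the desk scale 40×30×4;
presets mirror the 324×169×4 / 0.68% and 713×447×5 / 1.03% benchmark
shapes).  Because the intercept is itself a CP component, the fitted model
class contains the truth exactly.

Orthogonal equal-strength components are a deliberate choice: with i.i.d.
Gaussian type loadings, individual components are frequently born too weak
or too collinear to be identifiable even in principle (the true
probabilities themselves then separate held-out draws with AUC ≈ 0.86),
which would make recovery tests measure the draw rather than the method.

What the generator does *not* emulate: real similarity matrices are noisy,
block-structured and only partially related to the association mechanism;
real tensors have strongly heterogeneous margins (hub miRNAs/diseases) and
type imbalance; and real "zeros" include false negatives beyond the
missing-at-random Bernoulli picture.  Passing recovery tests therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not biological performance.

Recovery is assessed on probabilities (held-out AUC against a fresh
Bernoulli draw from the true probabilities, and correlation with the true
probabilities), not on raw factors, which are identified only up to
permutation and scale.  In the default regime the fitted model consistently
reports 3 effective components: the intercept is absorbed into the three
informative components rather than occupying a fourth.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| `rank` (R) | 20 (8 in recovery studies) | initial component count; ARD shrinks surplus |
| `importance_weight` (c) | 2.0 | likelihood weight on known positives, ≥1 |
| `alpha`, `beta` | 1.0, 1.0 | ARD Gamma hyperprior (uninformative) |
| `tol` / `max_iter` | 1e-5 / 200 | convergence of the surrogate objective |
| `jitter` | 1e-10 | initial diagonal jitter for precision inversions |
| `threshold_ratio` | 100 | effective-rank mass threshold `max(m)/ratio` |
| `n_seeds` | 20 | negative-sampling repetitions in triplet CV |
| `rho` | 0.01, 0.05, 0.10 | hit-rate fractions |

Problem sizes in the shipped tests and in `scripts/acceptance.py` are the
desk-scale defaults above (tensors up to 40×30×5, R ≤ 8, 10–20 seeds per
stochastic check); the benchmark-shaped presets run the identical code at
larger sizes.

## Known limitations

- The zeros-as-unlabelled convention means predicted probabilities are
  calibrated to the weighted surrogate likelihood, not to real prevalence.
- Mean-field Gaussian/Gamma posteriors underestimate posterior dependence;
  credible intervals from the factor covariances are optimistic.
- The kernel-neighborhood similarity and convex fusion are documented
  defaults standing in for the richer cited algorithms they replace; both
  are pluggable.
- Coupling covariances are stored densely (R matrices of n×n), which is
  the memory bottleneck at benchmark scale (~80 MB at 713 entities, R=20).
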