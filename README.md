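# logitcp

Bayesian logistic CP tensor decomposition with automatic rank determination,
for predicting multiple types of miRNA–disease associations.

## The problem

Dysregulated miRNAs cause disease through distinct mechanisms, and databases
such as HMDD record experimentally supported miRNA–disease associations
together with an evidence *type* (circulation, epigenetics, genetics, target,
tissue).  The data form a very sparse binary third-order tensor
`Y ∈ {0,1}^{I×J×K}` (miRNA × disease × type, ≈1% known entries), and the
task is tensor completion: rank every unobserved (miRNA, disease, type)
triple by its probability of being a true association.  Because the tensor
alone carries little signal, side information enters as kernel similarity
matrices over miRNAs (functional similarity from miRNA–gene associations and
a gene network) and diseases (semantic similarity plus interaction-profile
similarity).

## The model

With CP factors `G (I×R)`, `H (J×R)`, `W (K×R)`:

    Ỹ_ijk  = Σ_r G_ir H_jr W_kr,            P_ijk = σ(Ỹ_ijk)
    P(Y|·) = Π_ijk σ(Ỹ_ijk)^{c·Y_ijk} (1 − σ(Ỹ_ijk))^{1−Y_ijk},   c ≥ 1
    G_ir ~ N((S^m U)_ir, σ_g⁻¹)    H_jr ~ N((S^d V)_jr, σ_h⁻¹)
    U_·r, V_·r, W_·r ~ N(0, λ_r⁻¹ I)        λ_r ~ Gamma(α, β)

The per-component precisions `λ_r` implement automatic rank determination:
superfluous components shrink to zero, so the initial rank is an upper bound
rather than a hyperparameter to tune.  Inference is deterministic mean-field
variational Bayes; the logistic terms are handled with the local quadratic
bound `σ(z) ≥ σ(ξ) exp((z−ξ)/2 − λ(ξ)(z²−ξ²))`, which makes every update
conjugate and the surrogate evidence bound monotone.  See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

```python
from logitcp import synthetic
from logitcp.model import BayesianLogisticCP

Y, Sm, Sd, truth = synthetic.generate(seed=0)   # 40 x 30 x 4, ~5% density
model = BayesianLogisticCP(Y, Sm, Sd, rank=8)
res = model.fit(seed=0)
print(res.summary())
```

```
Bayesian logistic CP decomposition (variational fit)
========================================================
tensor shape:        40 miRNAs x 30 diseases x 4 types
known triples:       253 (density 5.271%)
initial rank R:      8
importance weight c: 2.0
sweeps run:          200 (max_iter reached)
final objective:     -1131.3008
effective rank:      3  (components [1, 4, 6])
sigma_g / sigma_h:   6.448 / 6.93

ARD precision spectrum (lambda_r, ascending):
  component  6:       1.5760  [active]
  component  1:       1.8240  [active]
  component  4:       2.7158  [active]
  component  0:       7.3790  [shrunk]
  ...
```

The data were generated from 3 informative components (plus a sparsity
intercept); the fit started at rank 8 and the ARD spectrum shrank five
components to zero, reporting an effective rank of 3.  Checking predictions
against the generating truth:

```python
print(synthetic.recovery_report(res.predict(), truth, heldout_seed=1))
# {'heldout_auc': 0.936, 'probability_correlation': 0.919, 'generating_rank': 4}
```

Held-out AUC 0.936 means the fitted probabilities rank a *fresh* Bernoulli
draw from the true probabilities almost as well as the truth itself;
correlation 0.919 is against the true probability tensor.  Ranked
predictions come from `res.predict_frame()`:

```
   mirna  disease   type    score  known
mir-0024 dis-0017 type-0 0.976937      1
mir-0039 dis-0017 type-0 0.968176      1
mir-0024 dis-0007 type-0 0.968101      1
```

## Command line

The same pipeline is scriptable:

```sh
logitcp simulate --shape 40,30,4 --rank 3 --density 0.05 --seed 0 --outdir data
logitcp similarity --triplets data/triplets.tsv --outdir simnet
logitcp fit --triplets data/triplets.tsv --mirna-sim data/mirna_sim.tsv \
            --disease-sim data/disease_sim.tsv --rank 8 --seed 0 --out run/model
logitcp evaluate --triplets data/triplets.tsv --mirna-sim data/mirna_sim.tsv \
            --disease-sim data/disease_sim.tsv --mode triplet \
            --n-seeds 20 --rho 0.01,0.05,0.10 --outdir run/cv
```

`fit` writes a model archive, ranked predictions and a JSON manifest
(config, seed, ARD spectrum) sufficient to reproduce the run bit-for-bit;
`evaluate` runs 5-fold cross-validation in either protocol (`type`: mask all
type entries of test pairs, report Top-1 precision/recall/F1; `triplet`:
mask test triples, report AUPR/AUC/F1 over 20 negative-sampling seeds, plus
hit rates).

All biological tables are TSV: triples as 3 columns, similarities as labeled
square matrices, predictions as (miRNA, disease, type, score) sorted by
score.

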