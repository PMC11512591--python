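# stadia

Joint integration of multiple spatial transcriptomics (ST) slices:
dimension reduction, additive/multiplicative batch-effect correction, and
spatially aware clustering in one hierarchical hidden Markov random field
model, fitted by EM with iterated-conditional-modes label updates.

## Who this is for

Analysts integrating several ST slices (10x Visium, classic ST, or
Slide-seqV2) who want batch-corrected low-dimensional embeddings *and*
spatial-domain labels from a single joint model, rather than chaining a
batch-correction tool, a factor model, and a clustering step whose errors
compound.

## Model

For spot *i* of batch (slice) *b*, with preprocessed expression
*y*<sub>bi</sub> ∈ ℝ<sup>p</sup>:

- **Observation layer** (factor analysis + location/scale batch
  adjustment):
  *y*<sub>bi</sub> = *L f*<sub>bi</sub> + γ<sub>b</sub> + ε<sub>bi</sub>,
  with ε<sub>bi</sub> ~ N<sub>p</sub>(0, *T*<sub>b</sub><sup>−1</sup>).
  The p×d loading matrix *L* is shared by all batches; γ<sub>b</sub> and
  the diagonal precision *T*<sub>b</sub> are the additive and
  multiplicative batch effects.
- **Clustering layer** (robust Gaussian mixture on the factors):
  *f*<sub>bi</sub> | c<sub>bi</sub>=k, ω<sub>bi</sub> ~
  N<sub>d</sub>(μ<sub>k</sub>, ω<sub>bi</sub><sup>−1</sup>Λ<sup>−1</sup>),
  ω<sub>bi</sub> ~ Gamma(ν<sub>ω</sub>/2, ν<sub>ω</sub>/2) — marginally a
  multivariate Student-t with ν<sub>ω</sub> degrees of freedom.
- **Spatial layer** (Potts prior): the labels *c* live on a graph whose
  edges are intra-slice spatial K-nearest neighbors (K=4 for ST, K=6 for
  Visium, radius 50 for Slide-seqV2) plus inter-slice mutual nearest
  neighbors (K=2) in expression space; concordant neighbors are rewarded
  with strength η<sub>b</sub>.
- **Sparsity**: each loading entry has a spike-and-slab prior whose slab is
  the nonlocal pMOM density (*l*²/λ₁)N(*l*; 0, λ₁) — vanishing at zero, so
  retained loadings are bounded away from 0 (λ₀=0.015, λ₁=0.871).

Inference is MAP-oriented EM: conditional-mean/mode updates for
(*f*, ω, *c*) — the labels by ICM sweeps over the graph — and
conditional-mode updates for (L, γ, T, μ, Λ) plus two exact
reparameterization (PX-EM) moves, tracking the complete-data log posterior,
which never decreases across iterations.

## Worked example

A built-in generator draws data from the model's own forward process
(Potts-correlated domains on lattices, Student-t factors, sparse pMOM
loadings, per-slice batch effects) with full ground truth:

```python
import numpy as np
from stadia import simulate, data_io, graph as graph_mod, metrics
from stadia.model import STADIA

ds, truth = simulate.simulate_dataset(seed=1)       # two 40x40 slices
dsc = data_io.center_genes(ds)
g = graph_mod.assemble_adjacency(dsc)
model = STADIA(dsc, n_domains=5, n_factors=10, eta=1.5, graph=g)
res = model.fit(seed=1)
print(res.summary())
print("ARI vs truth:", round(metrics.ari(res.domains, truth.labels_true), 3))
```

which prints

```
STADIA fit summary
==========================================================
spots: 3200   genes: 200   batches: 2
factors d: 10   domains q: 5   eta: [1.5]
iterations: 30   converged: False
final objective: -243018.5135
----------------------------------------------------------
domain sizes:
  domain   0:     1332 spots
  domain   1:       95 spots
  domain   2:      809 spots
  domain   3:      578 spots
  domain   4:      386 spots
----------------------------------------------------------
loading entries with inclusion prob > 0.5: 84.4%
ARI vs truth: 0.996
```

The five recovered domains match the simulated Potts domains almost
exactly (ARI 0.996, NMI 0.990); the additive batch effects are recovered
to RMSE 0.034 on a log-expression scale, and the corrected embedding mixes
the two slices (median batch-LISI 1.88 of an attainable 2.0 for two
balanced batches).

`res.embedding` holds the batch-corrected factor scores,
`res.corrected_expression()` the batch-free reconstruction *L f*, and
`res.save(dir)` writes domains, embedding, parameters, and the objective
trace as CSV.

## Command line

```bash
stadia simulate -c sim.yaml          # write a simulated bundle + truth
stadia run -c config.yaml            # load slices, preprocess, fit, save
stadia evaluate --run OUT --labels labels.csv   # ARI/NMI + LISI metrics
```

Configs are flat YAML; `stadia run` needs at least `slices` (list of
`counts`/`coords`/`platform` entries), `q`, and `out_dir`. Every run writes
a manifest with the config hash, seed, and versions.

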