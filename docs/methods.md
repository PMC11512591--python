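# Methods

## Model

The package fits a two-layer latent model to spots pooled from B slices.
Observed (preprocessed) expression decomposes as

    y_bi = L f_bi + gamma_b + eps_bi,   eps_bi ~ N_p(0, T_b^{-1}),

a Bayesian factor model with location-and-scale batch adjustment: the
p×d loadings L are shared across slices, gamma_b shifts each gene's mean
per batch, and the diagonal precisions T_b absorb per-gene variance
differences between batches. The factors follow a Gaussian mixture with a
per-spot precision scale,

    f_bi | c_bi = k, omega_bi ~ N_d(mu_k, omega_bi^{-1} Lambda^{-1}),
    omega_bi ~ Gamma(nu_omega/2, nu_omega/2),

so that marginally f | c = k is multivariate Student-t with nu_omega
degrees of freedom; small nu_omega (default 2) makes the clustering robust
to expression outliers at the cost of infinite factor variance. The labels
carry a Potts prior on the combined graph (spatial KNN within slices,
expression MNN across slices): each spot contributes
eta_b × #{concordant neighbors} to the log prior, so an unordered edge is
counted from both endpoints (2·eta when the endpoints share a batch, the
sum of the two batches' eta otherwise). The Potts normalizing constant is
never evaluated; eta is fixed, so it is an additive constant of the
objective.

Priors (all weak unless noted): gamma_b ~ N(0, I); t_bj ~ G(nu_t/2,
nu_t/2) with nu_t = 1; mu_k ~ N(0, 100 I); Lambda ~ Wishart(d, 100 I), the
least-informative proper choice of degrees of freedom; p_j ~ Beta(1, 1).
Each loading entry has a spike-and-slab prior: with probability 1−s a
narrow normal N(0, lambda0 = 0.015), with probability s the nonlocal pMOM
slab (l²/lambda1) N(l; 0, lambda1 = 0.871), whose density vanishes at 0 —
entries kept in the model are pushed away from zero rather than merely
shrunk less.

## Inference

Hard (point-value) EM with ICM label updates, tracking the complete-data
log posterior:

1. f: per-spot conditional mean/mode, solving
   (omega Lambda + Lᵀ T_b L) f = Lᵀ T_b (y − gamma_b) + omega Lambda mu_c.
2. omega: conjugate Gamma posterior mean (nu+d)/(nu+delta²) with delta² the
   Lambda-Mahalanobis distance to the assigned cluster mean. (The mean,
   not the mode; the only update that is not an exact ascent step — in
   practice the tracked objective has never been observed to decrease.)
3. c: ICM sweeps in global-index order; each spot takes the label
   maximizing its Gaussian log density plus the local Potts field; ties go
   to the smaller label; sweeps stop when a full pass changes nothing.
4. L, s, p: coordinate ascent per factor column. For each entry the
   Gaussian likelihood reduces to quadratic statistics (a, b); the slab
   inclusion probability comes from the closed-form marginal evidences of
   the two prior components; the entry is set to the stationary point of
   the responsibility-weighted objective — the pure slab branch solves
   (a + 1/lambda1) l² − b l − 2 = 0 (the pMOM term repels zero), the pure
   spike branch is a ridge solution. p_j is the Beta posterior mode of the
   column's inclusion probabilities.
5. gamma, T: posterior mode given the current factors (gamma under its
   N(0,1) prior at the old t, then t as the Gamma full-conditional mode at
   the new gamma, floored at 1e−6).
6. mu, Lambda: omega-weighted conjugate modes; empty clusters keep their
   mean and are flagged.

Two exact reparameterization (PX-EM) moves are interleaved, both pure
coordinate ascent on the same objective:

- **Shift gauge.** The likelihood is invariant under f_i → f_i + delta_b
  (all spots of batch b), gamma_b → gamma_b − L delta_b. Only the factor
  mixture and the gamma prior resolve this valley, and the plain updates
  drain it at a rate of roughly the ratio of prior to likelihood precision
  per iteration (~10⁻³). A convex d-dimensional quadratic per batch is
  solved exactly instead. Without it the additive batch effects keep a
  spurious component inside span(L).
- **Scale gauge.** The likelihood is also invariant under L_k → s L_k,
  f_k → f_k / s (mu, Lambda rescaled accordingly). The objective's
  preference along s is set by the factor-density determinant and the
  loading/Lambda/mu priors; each factor's slice is one-dimensional and is
  maximized by a bounded line search, accepted only if it improves.
  Initialization at the PCA solution (orthonormal L) is far from the
  preferred scale; leaving it unresolved makes the gamma-prior anchor weak
  relative to the mu prior and leaks a shared span(L) error into gamma.

Initialization is moment-based and fully deterministic given the seed:
pooled PCA (SVD with sign-fixed right singular vectors) for L and f,
k-means on *winsorized* scores (each dimension clipped to its 1–99%
range) for the labels — with nu_omega = 2 the factor marginals are t₂ and
unclipped k-means regularly spends whole centroids on single outlier
spots — then residual moments for gamma and T and labeled-score moments
for mu and Lambda; omega starts at 1.

Convergence: relative change of the tracked objective below `tol`
(default 1e−5) or `max_iter` (default 30). All SPD operations use Cholesky
with a single 1e−8 jitter retry.

## Preprocessing and graph

Counts are library-size normalized to 10⁴ per spot and log1p-transformed
(the de facto standard for these platforms); the gene panel is the strict
intersection across slices (a shared L requires a common panel); highly
variable genes are scored per slice by standardized dispersion (Seurat
flavor, via scanpy) and aggregated by median rank across slices, which is
robust to one aberrant batch; genes are then centered to global mean zero,
which is what lets the cluster-mean prior sit at zero. Spatial edges use
platform defaults (KNN K=4 ST / K=6 Visium, radius 50 Slide-seqV2,
strict inequality at the boundary, KNN ties broken toward the lower
index); cross-slice MNN (K=2) is computed in the top-50 joint principal
components of each slice pair — full-dimensional Euclidean KNN on
log-expression is noise-dominated.

## Simulator

`simulate_dataset` draws from the forward model: Potts labels by
checkerboard block Gibbs on a 4-neighbor lattice (the two colors are
mutually non-adjacent, so parallel resampling is exact Gibbs;
categorical draws use the Gumbel-max trick), omega from its Gamma prior,
factors from the mixture, loadings with a configurable zero fraction and
slab entries drawn from the pMOM density by exact rejection from
N(0, 3·lambda1) (density ratio bounded by 2), then additive/multiplicative
batch effects and Gaussian noise. It emits continuous expression on the
normalized scale — count-level simulation is out of scope — plus the full
truth bundle.

Default study conditions: two 40×40 slices (n = 3200), p = 200, d = 10,
q = 5, eta = 1.5, nu_omega = 2, 60 Gibbs sweeps; noise sd per gene ~
0.3–0.7 ("medium" batch preset: additive shifts with sd 0.5, second batch
noise sd ×1.5; "small"/"large" presets scale these down/up). Cluster means
are N(0, 3²) per coordinate, Lambda = I, 20% of loading entries nonzero.
The additive effects obey the standard sum-to-zero identifiability
convention over batches: a shared additive component is indistinguishable
from a global expression offset (removed by centering), so only the
sum-to-zero part is a meaningful estimand.

What the generator does *not* emulate: count noise (negative binomial,
zero inflation), library-size variation, platform-specific spot geometry
beyond square lattices, spatially varying cell-type mixtures, or
biological covariance between genes beyond the factor structure. Passing
recovery tests therefore certifies the estimator against its own model
class, not against real tissue data.

## Evaluation

ARI and NMI (arithmetic-mean normalization; two single-class labelings
score 1.0 by convention) score label recovery. LISI — the inverse Simpson
index of the label distribution in a perplexity-calibrated Gaussian
neighborhood (default perplexity 30, bisection on the bandwidth,
uniform-weight fallback for collapsed neighborhoods) — measures batch
mixing (higher is better) or domain mixing (lower is better); both median
and mean are reported.

One measured caveat: when batch effects are moderate, the uncorrected PCA
baseline is already almost fully mixed — its embedding keeps more noise,
and LISI rewards noise — so the corrected embedding's batch-LISI can sit
marginally *below* PCA's even when it equals the value achieved by an
oracle embedding built from the true loadings and true batch effects.
Batch-LISI comparisons against a PCA baseline are therefore informative
only when the uncorrected embedding is visibly separated.

## Known limitations

- q and d are user-supplied; no model selection is automated.
- The complete-data MAP's preferred loading scale (resolved by the scale
  gauge move) is much larger than the slab scale sqrt(lambda1), so with
  the fixed spike/slab variances the inclusion probabilities saturate
  toward 1 and the reported sparsity pattern is permissive; the loading
  *subspace* is recovered accurately (principal angles < 1° in the default
  study) but per-entry support recovery is not a strength of the MAP path.
- ICM is a local optimizer; with very strong eta and a poor start it can
  freeze suboptimal label configurations.
- eta_b is fixed (default 1.0; the recovery study uses 1.5 to match its
  generator), never estimated.
- Problem sizes in the test suite (n up to 3200, p up to 200, three seeds)
  were chosen so the full study runs in about half a minute; they are
  stated here as the package's reference configuration.
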