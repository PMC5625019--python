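# Methods

## Model and inference

`tffusion.bcpf` implements fully Bayesian CP (CANDECOMP/PARAFAC)
factorization of an incomplete, noisy 3-way tensor. Observed entries are
Gaussian around the CP reconstruction with precision τ; factor rows share
a zero-mean Gaussian prior with diagonal precision Λ = diag(λ₁…λ_R)
common to all three modes; λ_r and τ carry Gamma hyperpriors
(a₀ = b₀ = c₀ = d₀ = 10⁻⁶ by default, i.e. essentially flat). The
posterior is approximated by a mean-field family that factorizes over the
three factor matrices, λ, and τ; within a mode, rows are conditionally
independent, so each row's optimal factor is a full-covariance Gaussian.

All updates are conjugate closed forms:

* **factor rows** — precision E[Λ] + E[τ]·Σ(second moments of the other
  modes' row products over that row's observed entries); the mean solves
  the matching linear system.
* **λ_r** — shape c₀ + (ΣᵢIᵢ)/2, rate d₀ + ½·E[squared column norm of
  component r across modes].
* **τ** — shape a₀ + (#observed)/2, rate b₀ + ½·E[squared residual].

Each update maximizes the evidence lower bound (ELBO) over its block, so
the ELBO trace is non-decreasing; the test suite audits this at 1e-8
relative tolerance on every fitted model. Convergence is declared when
the relative ELBO change drops below `tol` (1e-6); hitting `max_iter`
(500) flags the returned state instead of raising. Point estimation (MAP)
and sampling are deliberately out of scope: the variational posterior is
the product.

### Automatic rank determination

The rank starts overcomplete (default `min(I₁, I₂)`; the acceptance
protocol uses 10) and components whose factor-mean column power falls
below 1e-4 of the largest component's are pruned after each sweep.
Pruning intentionally ignores the covariance trace: at the shrinkage
fixed point a dead component's posterior covariance stalls near
E[Λ]⁻¹, which would mask the collapse of its means.

### Initialization

Factor means start from each mode's mask-zero-filled matricization SVD
with cube-root singular-value scaling (the three modes jointly contribute
a component's magnitude; `sqrt` scaling overshoots the data norm and the
first shrinkage sweep then kills weak components irrecoverably). Because
independent per-mode SVDs pair columns arbitrarily, three masked,
unregularized ALS sweeps then align the cross-mode pairing — without
them, every component whose paired pattern matches nothing in the data is
shrunk to zero in the first variational sweep, and exactly-zero columns
are an absorbing state of the mean updates. Row covariances start at
identity; λ posteriors at their priors; E[τ] starts at 1/var(observed Y)
(the flat-prior E[τ] = 1 causes the same first-sweep over-shrinkage
whenever the data scale implies a higher noise precision). Seeded
Gaussian draws fill columns beyond a mode's numerical rank, so the whole
fit is deterministic under the config seed.

### Scale rebalancing

CP reconstructions are invariant to rescaling a component's columns by
s₁·s₂·s₃ = 1 across modes, but the prior and entropy terms are not, and
coordinate ascent crawls along this nearly flat ridge (≈6e-6 relative
ELBO change per sweep for hundreds of sweeps in unbalanced starts). After
the factor updates, each component's scales are set to the exact maximizer
of the ELBO along these directions (a one-dimensional root-find per
component). This is itself a coordinate-ascent step, so monotonicity is
preserved; convergence then takes tens of sweeps instead of thousands.

### Prediction

An entry's predictive mean is the generalized inner product of the three
posterior-mean rows; its variance propagates the factor-row covariances
(E[⟨a,b,c⟩²] − E[⟨a,b,c⟩]²) plus the posterior-mean noise variance
(rate/(shape−1), falling back to 1/E[τ] for shape ≤ 1).

## Evidence networks

* **Co-binding.** Per-TF peaks are first merged across conditions
  (transitive overlap; merged score = mean of constituent summit scores).
  For a query peak, the overlap p-value against a reference TF's peak set
  places a same-length interval uniformly over every valid start position
  in the domain and asks how often the placement is at least as close to
  the reference set as observed (distance 0 when overlapping, else gap
  length). This is a self-contained reimplementation of the published
  distance-based overlap statistic with an explicitly defined null, so it
  is testable by exhaustive enumeration; it does not reproduce any
  external binary's output bit-for-bit. The co-binding score of a TF pair
  is the fraction of query peaks with p < 0.05 (asymmetric; symmetrized
  by averaging the two directions). The domain is per-sequence:
  reference intervals on other sequences never enter a peak's null, and
  peaks on sequences absent from the reference count as non-significant.
* **Co-expression / co-methylation.** Absolute Pearson correlation of
  TF profile rows; promoter methylation is the mean beta over CpG sites
  within ±2 kb of the TSS (closed at the boundary — the convention is
  unstated in the source and documented here). Zero-variance rows and
  empty promoter windows are masked, not zeroed: "no evidence" and
  "evidence of no interaction" are different observations.
* **Co-occupancy.** Jaccard index of the two TFs' promoter target sets in
  one cell type's directed regulatory network. Pairs with an empty union
  are masked for the same reason.

Weighted networks are normalized by truncated min-max: weights at or
above the 95th percentile (linear interpolation between order statistics,
computed over observed off-diagonal upper-triangle weights) map to 1, at
or below the 5th to 0, linearly in between. A constant network normalizes
to all zeros with a warning. Normalization is applied per evidence
channel before stacking heterogeneous slices; co-occupancy slices within
one lineage are stacked raw, since all slices are already Jaccard scores
on one common [0,1] scale and stretching the background tail over the
full range would only amplify noise.

Stacking produces the observed tensor: slice k holds network k's weights
and mask, with the diagonal masked everywhere.

## Fusion and calling

The fused network weights each rank-one TF×TF pattern by the mean of its
slice-mode column. Before symmetrization and min-max scaling this equals
the slice-mean of the reconstructed tensor exactly (a unit-tested
identity at 1e-10); it is the unique linear fusion that reduces to plain
network averaging when the factorization is exact.

Strong interactions use the per-TF outlier rule: an edge is strong when
its weight strictly exceeds Q3 + α·IQR (α = 1.5 by default) of either
endpoint's observed incident weights ("exceeds" is read as strict; the
either-endpoint union follows from the rule being a per-TF criterion).
TFs with fewer than 4 observed incident edges contribute no strong edges.
Hubs are the top `ceil(0.05 · #TFs with strong degree > 0)` TFs by
strong-edge degree; boundary ties are all kept, which means a degenerate
degree distribution (every TF tied) returns every active TF — preferable
to silently dropping tied TFs. Cross-lineage classification labels a
strong edge `specific:<lineage>` when found in exactly one lineage,
`housekeeping` when found in all, `shared` otherwise; it requires ≥ 2
lineages, since the distinction is undefined for one.

## Evaluation

The averaged gold standard scores each pair by its mean weight over the
cell-type networks where the pair is observed (pairs observed nowhere
stay masked), binarized at a threshold with ≥ (boundary inclusive — the
convention is unstated in the source). AI-Nets apply the same averaging
within one lineage and also fill missing entries of cell-type networks.
AUC is the Mann–Whitney concordance probability computed from mid-ranks
(ties ½), and the trapezoidal integral of the ROC points must agree to
1e-12 — both are computed and compared, and cross-checked against
scikit-learn in tests. Evaluation is restricted to pairs observed in both
the gold standard and the prediction; unassessable pairs are excluded,
never counted as errors.

## Synthetic worlds

The generators produce every input the pipeline consumes, with the
statistical structure the analysis assumes — and nothing more.

* `gen_cp_tensor`: factor columns i.i.d. standard normal (the model's
  prior family at unit precision), i.i.d. Gaussian noise, exactly
  `round(f·size)` entries masked uniformly at random. Rank may exceed one
  mode's dimension (a 3-slice stack can carry higher-rank structure) but
  not two.
* `gen_toy_peaks`: constant 200-unit peaks (peak geometry is unstated in
  the source; a constant keeps the overlap null analytic) placed
  uniformly on one linear domain; planted pairs share centers up to a
  jitter.
* `gen_profiles`: block members load a common latent factor with weight
  √ρ, giving expected within-block correlation ρ and zero across blocks.
* `gen_regulatory_networks`: the target universe is the TF gene set
  itself. Background edge density defaults to 0.05, matching the real
  cell-type networks' density (≈11,200 edges among 475 TFs); module
  promoter sets cover 15% of the universe and are drawn disjointly —
  at a realistic ~500-gene universe, chance overlap between module target
  sets is within background, whereas at a 40-gene desk-scale universe it
  would dominate as a pure finite-size artifact. Planted modules of 8 TFs
  in the shipped worlds match the size of interaction modules the method
  is meant to find. Each potential edge is flipped with probability
  `edge_noise`.

What a green test establishes, and what it does not: the synthetic worlds
have exactly the low-rank-plus-noise structure the model assumes, so the
tests certify the inference machinery (monotone ELBO, rank recovery,
completion, integration dominance, lineage classification) — not
performance on real genomic data, where evidence networks need not be
low-rank, missingness is not uniform, and ChIP-seq artifacts are not
i.i.d. Gaussian. No attempt is made to simulate read-level signal, genome
sequence, or motif content.

## Numerical choices

* Percentiles and quartiles everywhere use linear interpolation between
  order statistics (fixed for bit-reproducibility).
* Precision matrices get a 1e-10 ridge before solves; ELBO terms are
  computed in log space; covariances are symmetrized after inversion.
* Update order within a sweep: modes 1, 2, 3 → rescale → λ → τ → prune
  (pruning last avoids removing components mid-sweep).
* Convergence is lower-bound-based (the source's criterion is unstated).
* All randomness flows from one integer seed per config.

## Known limitations

* Three-way tensors only; the containers carry mode counts but N > 3 is
  not implemented.
* Slice symmetry is not enforced inside the factorization (the model is
  generic); fusion restores it by averaging with the transpose.
* The ARD prior is conservative near the detectability threshold: planted
  structure whose singular value sits at the random-matrix noise floor
  (≈ σ(√I₁+√I₂) per slice) is correctly — but perhaps disappointingly —
  pruned.
* Shared λ across modes assumes comparable column scales; the rebalancing
  step enforces this at each sweep.
* The per-TF strong-edge rule presumes outliers are rare among a TF's
  incident edges; when a TF's true partners exceed ~25% of its edges, Q3
  enters the partner cluster and recall degrades.
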