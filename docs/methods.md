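# Methods

## Model

The package predicts unobserved drug–target interactions from a binary
interaction matrix `Y ∈ {0,1}^{nd×nt}` (drugs as rows — the canonical
orientation everywhere in the package; the file reader transposes
target-as-row benchmark files on ingestion).

**Linear neighborhood similarity.** Drugs are points `x_i ∈ R^p` in a
feature space — interaction profiles (`p = nt`) or fingerprint bit vectors.
For each drug the `K` nearest neighbors by Euclidean distance are found
(self excluded; exact distance ties broken by ascending row index for
cross-platform determinism) and the reconstruction weights solve

    min_ω  ωᵀ(G_i + λ_i I)ω    s.t.  eᵀω = 1,  ω ≥ 0,

the ridge term `λ_i‖ω‖²` having been merged algebraically into the
quadratic form. `G_i` is computed as `DDᵀ` for the matrix `D` of stacked
difference vectors, then symmetrized exactly, so it is positive
semidefinite by construction. `λ_i = ε·ρ(G_i)` ties the regularization to
the scale of the reconstruction error; `ε = 0.01` is the default. The
weights are scattered into row `i` of `W`, giving a row-stochastic,
zero-diagonal, at-most-`K`-sparse and generally asymmetric similarity.

The underlying assumption is local linearity: a drug and its neighbors lie
near a locally linear patch of the data manifold, and the same linear
relations are assumed to hold in the interaction space. Self-exclusion from
the neighborhood is essential — `ω_ii = 1` would solve the reconstruction
problem exactly and make propagation a no-op.

**Propagation.** `F(0) = Y`, `F(k) = αWF(k−1) + (1−α)Y`. With `ρ(W) ≤ 1`
and `0 < α < 1` this converges to `F = (1−α)(I−αW)⁻¹Y`. The default mode
solves `(I−αW)F = (1−α)Y` directly (LAPACK solve, never an explicit
inverse); the iterative mode is retained for validation and very large
networks, with convergence measured in the max norm on `F` (tolerance
1e−9, cap 1000 iterations) because entries are probability-like scores.
Inputs are validated against the convergence precondition: nonnegative `W`
with row sums ≤ 1 + 1e−8.

**Baseline similarities.** Cosine (zero vectors defined to have similarity
0), Gauss `exp(−‖x_i−x_j‖²/σ)`, and Jaccard `|∩|/|∪|` of binary supports
(0 when both supports are empty; non-binary input rejected). Baselines are
zero-diagonaled and row-normalized before propagation so they satisfy the
same convergence precondition as LNS; isolated (all-zero) rows are left
zero and reported with a warning. The conventional bandwidth notation
`σ = Σ|x_i|/nd` is ambiguous between the norm and its square; the package
defaults to the mean *squared* norm, the convention of the
Gaussian-interaction-profile literature this rule descends from, and
exposes `gauss_bandwidth="norm"` for the other reading.

**Fusion (LPLNI-II).** Scores from `n` feature views are combined per pair
as `P(y=1|F) = sigmoid(Σ_k a_k F^k + b)`, fitted by maximum likelihood over
all `nd·nt` pairs (known interactions positive, everything else negative;
no negative subsampling). A ridge penalty (default 1e−6) on the slopes —
never the intercept — guarantees a unique finite optimum on separable
inputs without materially changing non-separable fits. The fit is damped
Newton–Raphson with step halving; the penalized likelihood is monotone
across iterations and the final gradient norm is recorded on the result.
By default the training covariates are *held-out* (leave-one-out) scores,
because the in-sample score of a known pair contains its own label and
would bias the slopes upward; `train="in_sample"` restores the literal
self-scored fit. Prediction always combines the full-data scores.

## Evaluation protocol

Leave-one-out cross-validation over drug–target pairs: each known pair is
set to 0 in turn, the model is rebuilt, and the pair's score recorded;
originally-zero pairs are scored once from the unmasked model, since their
training label is unchanged by masking. Two refit modes:

- `full` (default for profile features): features, neighborhoods and `W`
  are recomputed from the masked matrix per fold — the only leak-free
  protocol when the similarity itself is built from the labels.
- `fixed_w`: `W` is frozen from the unmasked data and only the label is
  masked. Masking one entry of `Y` is then a rank-one perturbation, so the
  held-out score has the exact closed form
  `F[i,j] − (1−α)·M[i,i]` with `M = (I−αW)⁻¹`, which the implementation
  uses (verified against explicit per-fold masking in the tests). For
  label-independent features (fingerprints) the two modes coincide and the
  fast path is used automatically.

AUC is the Mann–Whitney statistic (ties counted ½), identical to
trapezoidal ROC integration. AUPR uses the step (average-precision)
convention with tied scores grouped at one threshold — trapezoidal PR
interpolation is known to overestimate, so the conservative standard is
used. Both metrics are validated against O(n²) brute-force enumeration.
AUPR is the primary metric: interaction networks are sparse and AUPR
penalizes false positives among the top ranks where it matters.

Grid search sweeps `K` and `α` and reports the best cell by AUPR. The
customary grids are `α ∈ {0.1, …, 0.9}` (step 0.1) and neighborhood sizes
scaled to the network: 10/30/50 for ~50 drugs, 60/120/180 for ~200 drugs,
120/240/360 for ~450 drugs, with `K < nd` always.

## Numerical choices

- **Simplex QP.** Solved by a primal active-set method written for this
  package (the problem dimension is `K`, small): on the current free set
  the equality-constrained minimizer is `A_FF⁻¹e / (eᵀA_FF⁻¹e)`;
  infeasible steps are truncated at the first blocking bound and bound
  constraints are released while their multipliers are negative. The matrix
  is scaled to unit max entry before solving. Tiny negative outputs
  (interior-point/active-set round-off, > −1e−10) are clipped and the row
  renormalized so the row-stochasticity invariant holds exactly. Tests
  cross-check the solver against exhaustive simplex grid search (step
  1e−3, `K ≤ 3`) and scipy's SLSQP (`K = 8`).
- **Degenerate neighborhoods.** If `G = 0` (all neighbors coincide with
  the drug) then `λ = ε·ρ(G) = 0` and every simplex point is optimal; the
  symmetric uniform weights `1/K` are returned and flagged.
- **Propagation solve.** `scipy.linalg.solve` on `(I−αW)`; a singular
  system (impossible under the validated preconditions) raises a numerical
  error carrying a condition estimate.
- **Determinism.** No randomness anywhere outside the synthetic generator;
  identical inputs give byte-identical outputs (asserted for the CLI).

## Synthetic data

`BlockNetworkSpec` plants co-clusters: drugs and targets are partitioned
into `n_blocks` near-equal blocks and each cell is Bernoulli — `p_in`
within a block, `p_out` across. This emulates the clustered structure of
real target-class interaction data (drugs of one chemical family hitting
one protein family) and is exactly the "similar drugs interact with
similar targets" regularity the method exploits, making `p_in − p_out` a
clean signal dial. The fingerprint view tiles each block's one-hot code to
a configurable width (default `8·n_blocks`) and flips bits independently
at rate `noise_flip`; at 0.5 the view is pure noise and propagation on it
scores at chance, a calibration asserted in the tests. Draws are
reproducible from the seed via two fixed substreams (network, then
features), so either artifact can be regenerated independently.

What the generator does *not* emulate: real networks are far sparser
(≈1–6% density versus 18% here at the default `p_in = 0.5`), degree
distributions are heavy-tailed rather than binomial, chemical similarity
decays continuously rather than block-wise, and interactions are not
independent given the blocks. Passing the recovery tests therefore shows
the pipeline recovers planted neighborhood structure through a leak-free
protocol — not that it attains any particular accuracy on real benchmark
data.

The recovery checks run the generator at `nd = 60`, `nt = 40`, 3 blocks,
`p_in = 0.5`, `p_out = 0.02`, seeds 7–11, with `K = 10` (half a block — the
neighborhood stays within a drug's own cluster) and `α = 0.5` (mid-grid);
these sizes keep the full-refit cross-validation, which rebuilds the
similarity ~430 times per run, to a few seconds per network.

A structural consequence of this generator worth knowing when reading the
recovery numbers: within a block, entries of `Y` are i.i.d. coin flips, so
once a known pair is masked and the model rebuilt without it, that pair is
statistically indistinguishable from the within-block zeros. No leak-free
scorer can rank it above them, which caps full-refit LOOCV AUC at ≈ 0.86
under the default densities (the measured values sit at that ceiling, flat
in `K` and `α`). The frozen-similarity mode reports ≈ 0.93 on the same
fixture — the gap is exactly the held-out label leaking through the
profile-based similarity, and is why `full` is the default.

## Known limitations

- Similarity, and hence propagation, is drug-sided only; targets are never
  embedded, so a target with no interactions can never receive mass.
- A drug whose masked profile becomes all-zero is legal but unreachable by
  propagation (its row of `W` may still be defined through its features;
  with profile features its distances collapse toward the origin).
- The closed-form solve is `O(nd³)` — ideal at benchmark scale (≤ 445
  drugs), not for networks orders of magnitude larger, where the iterative
  mode with sparse `W` would be the right tool.
- Fingerprint files are consumed as precomputed bit-vector TSVs; computing
  fingerprints from chemical structures is out of scope, and drug sets in
  feature and interaction files must match exactly (mismatches raise
  rather than silently intersecting).
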