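# Methods

## Model and formulations

All estimators operate on a column-centered, unit-variance data matrix
**X** ∈ ℝ^{I×J} (standardization uses the sample standard deviation with
denominator I−1, so the score-orthogonality convention TᵀT = (I−1)·Id is
exact).  The common structure is the component model

    X = T Pᵀ + E,    T = X W,

with scores **T** (I×K), loadings **P** (J×K) and weights **W** (J×K).
`pca_core.pca_fit` exposes three equivalent solutions of the unpenalized
problem via the truncated SVD X = U D Vᵀ:

- `ls-orthP`: T = UD, P = V (orthonormal loadings);
- `ls-orthT`: T = (I−1)^{1/2} U, P = (I−1)^{−1/2} VD,
  W = (I−1)^{1/2} V D^{−1} (orthogonal scores; fails loudly when a retained
  singular value is zero, since D^{−1} is then undefined);
- `maxvar`: W = V, T = XV (maximal component variance).

The SVD is made deterministic by flipping each column of V so that its
largest-magnitude entry is positive (ties: first index), with U flipped to
match.  Exactly tied singular values receive no special handling; that
degeneracy is a documented limitation and the synthetic designs avoid exact
ties.

Sparsity breaks the equivalence of the formulations, which is the entire
point of the comparison: loadings-sparse and weights-sparse methods answer
different questions and are scored against different ground-truth matrices.

## Estimators

**Thresholded rotations.**  The fit-preserving identity
TPᵀ = T(Q^{-1})ᵀ(PQ)ᵀ allows a simple-structure transform before
thresholding.  Varimax maximizes the summed per-component variance of the
squared loadings by cyclic pairwise Jacobi rotations (convergence when a
full sweep gains < 1e-8; at most 200 sweeps; Kaiser row normalization off
by default, available as a flag — a test cross-checks the criterion value
against statsmodels' implementation).  Simplimax seeks an oblique Q whose
rotated loadings come closest in least squares to some matrix with m zeros:
alternating target updates (zero the m smallest-magnitude rotated entries)
and least-squares transform updates, with columns of (Qᵀ)^{-1} normalized
to unit length (unit diagonal of (QᵀQ)^{-1}) to remove the scale
indeterminacy.  Because that normalization can in principle undo a strict
descent step, an alternation that fails to decrease the loss reverts and
stops; 10 random non-singular starts plus a Varimax start are run and the
best loss kept — the criterion is known to be local-optimum prone.
Thresholding then zeroes the ⌊ps·J·K⌋ smallest-magnitude entries globally
(per-column splitting available as a flag; ties broken column-major), each
component keeps at least one nonzero, and — deliberately reproducing
common practice — scores are *not* re-estimated and surviving loadings
keep their rotated values.

**Sparse rank-one SVD (spca-rsvd).**  Each component minimizes
‖X − tpᵀ‖² + 𝒫(p) with ‖t‖ = 1 by alternating t ← Xp/‖Xp‖ with the
separable loading update: soft-thresholding p ← S(Xᵀt, λ/2) in lasso mode,
or keeping the r largest |Xᵀt| in cardinality mode.  Cardinality is the
default control because the benchmark protocol fixes the true sparsity
level; lasso mode maps a target cardinality to λ by bisection (support size
is non-increasing in λ).  Initialization is the leading singular pair of
the current residual; convergence at relative objective change < 1e-9
(≤ 500 iterations); components after the first are fit on the deflated
residual X − tpᵀ.  Scores are unit-norm, loadings carry the scale.

**SPCA (elastic net).**  Block minimization of
‖X − XWPᵀ‖² + λ₂Σ‖w_k‖² + Σλ₁ₖ‖w_k‖₁ s.t. PᵀP = Id.  For fixed P each w_k
is an elastic-net regression of the score Xp_k on the J variables, solved
by cyclic coordinate descent in Gram space (the kernel is numba-compiled
when numba is importable, with an identical pure-Python fallback); for
fixed W the loading update is the orthogonal Procrustes problem with
closed-form solution P = ABᵀ from XᵀXW = AΣBᵀ.  The ridge default is
λ₂ = 1e-6 when I > J and λ₂ = 1 otherwise (with J ≥ I the lasso alone
selects at most I variables).  When a per-component cardinality target is
given, λ₁ₖ is found by bisection inside each pass; re-bisecting every pass
can cycle (the objective is non-stationary while the penalty moves), so the
penalties freeze once the selected supports stop changing, after which the
alternation is plain monotone block descent.  Fitted weight columns are
unit-normalized; T = XW.

**pathSPCA.**  Greedy forward selection for max ‖Xw‖² − ρ‖w‖₀: start from
the highest-variance variable and repeatedly add the index maximizing the
leading eigenvalue of the covariance submatrix on the augmented support,
evaluated by exact symmetric eigendecomposition (desk-scale r; no
variational shortcut).  The weight vector is the leading unit eigenvector
on the final support.

**GPower.**  The J-dimensional problem max_{‖w‖=1} ‖Xw‖ − λ‖w‖₁ is solved
through its I-dimensional equivalent max_{‖z‖≤1} ‖S(Xᵀz, λ)‖² by power
iterations z ← X S(Xᵀz, λ)/‖·‖, started at the highest-norm column
direction.  Convergence is declared on the *iterate* (max|z_new − z| <
1e-9, ≤ 5000 iterations) rather than the objective: the objective plateaus
quadratically in the angle and an objective-gain rule stops one to two
digits short of the component accuracy the package promises at the
penalty-free limit.  The thresholded pattern gives the support; final
within-support weights are the leading right singular vector of the
retained columns (ordinary PCA on the selected variables).  λ is bisected
in (0, max_j‖x_j‖) to reach a target cardinality, accepting the nearest
achievable size with a warning.

**Shared conventions for weight methods.**  Deflation is the least-squares
rank-one scheme X ← X − tpᵀ with t = Xw, p = Xᵀt/‖t‖², which keeps the
residual orthogonal to the extracted score and makes explained variance
well-defined (other deflation schemes exist for GPower; this one is the
package's choice).  Loadings for variance reporting are the least-squares
P̂ = XᵀT̂(T̂ᵀT̂)^{-1}, so PEV always refers to X̂ = T̂P̂ᵀ.

## Synthetic data

Each generator starts from the truncated SVD U D Vᵀ of an i.i.d. standard
normal I×J matrix, column-centered.  An identity base covariance is the
deliberately least-informative choice; the sparse structure is injected
through the factors, not the covariance:

- `alg1-sparseP`: P = sparsify(VD), T = U (orthonormal scores),
  signal = TPᵀ;
- `alg2-sparseW`: W = sparsify(V) with unit-norm columns, T = X₀W, and —
  because the model X = XWPᵀ + E is self-referential — P is defined by
  least squares of X₀ on T, making the signal the best rank-K fit
  consistent with the sparse weights (the module's single largest
  interpretation, recorded here);
- `alg3-double`: V_s = sparsify(V) with *disjoint* supports and unit-norm
  columns, hence exactly orthogonal sparse factors; the sparse-loadings
  scenario uses P = V_s D, W = V_s D^{-1}, the sparse-weights scenario
  P = W = V_s; T = X₀W.

Zero positions are uniform at random, stratified so each column has the
same nonzero count up to one (a magnitude-based variant — zero the
smallest entries — is available behind a flag).  Noise is i.i.d. normal,
column-centered, projected to be Frobenius-orthogonal to the signal, and
scaled so the realized VAF ‖X−E‖²_F/‖X‖²_F equals the target *exactly*;
without the orthogonalization the signal–noise cross term would leave an
O(1%) discrepancy.  X is re-centered (a numerical no-op, both terms being
centered) and *not* re-standardized, so the planted factors stay exact.
Per-dataset seeds are a stable 64-bit hash of (regime, I, J, K, VAF, PS,
replicate, master seed), so any subset of a design sees the same data as
the full design.

What the generators do **not** emulate: heteroscedastic or correlated
noise, non-Gaussian margins, covariance spikes separated from the bulk, or
any real measurement structure.  In particular, an i.i.d. base matrix has
Marchenko–Pastur-spaced singular values, so the K planted components have
*near-tied strengths*.  A consequence verified directly in the tests'
failure analysis: mixtures of two near-tied sparse components can fit the
data strictly better than either planted component alone, so exact support
recovery (MR = 0) is not attainable even by an oracle optimizer of the
methods' own criteria in the random-support regimes.  Recovery becomes
near-exact in the doubly sparse regime, where disjoint orthogonal supports
remove the mixing — so passing recovery tests there says nothing about
correlated-support real data, and small nonzero MR in the random-support
regimes is expected behavior, not an optimizer defect.

## Benchmark protocol

`study.build_design` crosses I ∈ {100, 500}, J ∈ {10, 100, 1000},
K ∈ {2, 3}, VAF ∈ {0.8, 0.95, 1.0} and PS ∈ {0, 0.5, 0.8} (PS ∈
{0.7, 0.8, 0.9} for the doubly sparse regime, where disjointness needs
high sparsity): 108 conditions per regime, 10,800 datasets at 100
replicates.  Condition types pair generators and method families:
matching (type I), doubly sparse (type II), and mismatched (type III,
where loadings methods analyze weight-sparse data and vice versa and
recovery is scored by Tucker congruence against the other parameter
matrix, maximizing the mean cosine during alignment).  Methods are tuned
with the oracle protocol — true K, true sparsity level, cardinality per
component round((1−ps)·J) — so performance differences are not tuning
differences.  Alignment is exhaustive over 2^K·K! sign/permutation
combinations (K ≤ 6), computed on the condition's sparse target and
inherited by scores and masks; MR compares the estimated sparse matrix's
zero pattern with the generated mask of the same role and is not reported
when the truth has no zeros.  Failures are logged per cell and recorded as
missing rather than aborting a sweep.

The default desk-scale configuration runs the full factor *structure* at
reduced size (I = 100, J ∈ {10, 100}, K = 2, VAF = 0.8, 10 replicates) so
a sweep completes in minutes on one CPU; the full grids remain available
by passing them explicitly.  The package's own acceptance measurements use
I = J = 100, K = 2, VAF = 0.95, PS = 0.8 with 50 seeds per regime.

Sparsity tuning on empirical data follows the index of sparseness:
IS = PEV_sparse · PEV_pca · PS, maximized over a PS grid with PS mapped to
a per-component cardinality.  The PEV_sparse curve is non-increasing in PS
(nested cardinality constraints), so IS trades fit against parsimony.

## Numerical choices and edge cases

- Soft-thresholding S(x, λ) = sign(x)·max(|x| − λ, 0) rejects λ < 0.
- `center_scale` refuses constant columns (naming them) and missing
  values; raw data remain recoverable from the stored means and sds.
- Bisections (λ→cardinality) run at most 60 steps and accept the nearest
  achievable support size with a warning when the exact target is not on
  the solution path.
- An all-zero weight component raises with advice to lower the penalty; a
  penalty λ ≥ max_j‖x_j‖ in GPower raises "eliminates all variables".
- PEV is clipped to [0, 1] with a warning if a degenerate reconstruction
  exceeds the data norm.
- Reported reproducibility is bitwise: same configuration and master seed
  give identical results tables.

## Known limitations

- Exhaustive alignment is factorial in K and capped at K ≤ 6.
- Simplimax and the penalized methods converge to local optima; multi-start
  (simplimax) and deterministic warm starts (others) mitigate but do not
  remove this.
- The J = 1000 and I = 500 grid levels are supported but not exercised by
  the default configuration or the test suite.
- No missing-data support and no out-of-core or randomized SVD path.
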