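# Methods

## Model and assumptions

The package operates on a symmetric real similarity matrix `K` of size
n×n, viewed through its eigendecomposition `K = P diag(d) P′` with
eigenvalues ascending. The negative inertia index `m` counts eigenvalues
below `−tol_rel·max(max|d|, 1)`; eigenvalues within the threshold band are
"numerical zeros" and belong to neither inertia class. The projection
transform rescales the m negative eigenvalues by `(1−λ)`:

    K̃(λ) = P diag((1−λ)d₁, …, (1−λ)d_m, d_{m+1}, …, dₙ) P′.

Assumptions: the matrix is dense and small enough for a full symmetric
eigensolve (n up to a few thousand; LAPACK `syevd` via `numpy.linalg.eigh`);
no low-rank or iterative paths are provided. The transform is exact linear
algebra — there is no statistical model at this stage.

### Numerical conventions

* **Transformed kernel is rebuilt in the eigenbasis**, not as the explicit
  product `(I − λBB′)K`, which is asymmetric at round-off level in floating
  point. The two agree to round-off; the rebuild is exactly symmetric by
  construction.
* **Eigenvector sign** is fixed so the largest-magnitude entry of each
  column is positive, and sorting is ascending — this makes decompositions
  (and everything downstream) deterministic across runs.
* **PSD certification** requires the smallest transformed eigenvalue to be
  at least `−1e−8·max|d|`. For λ ≥ 1 this always holds; for λ < 1 the
  certificate reports honestly that the output may be indefinite.
* **PSD inputs are returned bit-identically** (m = 0 ⇒ `K̃(λ) = K` for
  every λ), so rectification is a no-op exactly when it should be.

## Strength selection by Bregman divergences

For a strictly convex spectral generator φ the Bregman matrix divergence is
`D_φ(K̃, K) = φ(K̃) − φ(K) − tr(∇φ(K)′(K̃ − K))`. Minimising over λ along
the projection family:

| generator | objective in λ | minimiser |
|---|---|---|
| Mahalanobis (φ = tr K²) | λ²·tr(BB′K)² | 0 |
| Frobenius (φ = ‖K‖²_F) | λ·‖BB′K‖²_F | 0 |
| von-Neumann (φ = tr(K log K − K)) | Σ_{i≤m} dᵢ((1−λ)log(1−λ)+λ) | 0 (stationary point) |
| LogDet (φ = −log det K) | stationarity −m/(1−λ) − Σ_{i≤m} dᵢtᵢ = 0 | 1 + m/Σ_{i≤m} dᵢtᵢ |

Here `tᵢ = tr(K⁺ pᵢpᵢ′)` are pseudo-inverse traces: because `pᵢ` are
eigenvectors of `K` itself, `tᵢ = 1/dᵢ` when `|dᵢ| > pinv_tol·max|d|` and 0
otherwise. The Frobenius objective is used in the linear form given above;
note it is minimised at the boundary λ = 0 of the λ ≥ 0 domain either way.

A subtlety worth documenting: for an indefinite spectrum the von-Neumann
objective above is monotone *decreasing* on [0, 1) (its negative-eigenvalue
weights flip the sign of the increasing scalar factor), so a plain grid
argmin lands at the right edge of the interval. The selector implemented
here is the unique stationary point of the derivative
`−Σ_{i≤m} dᵢ·log(1−λ)`, which is λ = 0; the test suite confirms uniqueness
on a 0.001-step grid. All three λ = 0 rules leave the kernel unperturbed
and are therefore surfaced with an explicit warning note rather than
applied silently.

The perturbed von-Neumann objective replaces `tr(K̃ log K̃ − K̃ log K)` by
the trace-factored form `tr(K̃)·tr(log K̃ − log K)`, which along the
projection family is the quadratic

    V(λ) = (T − λA)(R − λG) + A,
    A = Σ_{i≤m} dᵢ,  T = Σᵢ dᵢ,  G = Σ_{i≤m} dᵢtᵢ,  R = Σᵢ dᵢtᵢ,

stored as exact coefficients (`v2 = AG`, `v1 = −(AR + TG)`, `v0 = TR + A`)
so its vertex and values are computed without grids. The associated
selector is used in its closed form

    λ_opt1 = (R − 0.5) / G,

which reduces to `(n − 0.5)/m` at full numerical rank. The printed
derivative form of V is algebraically inconsistent with V itself (the cross
terms differ) and with λ_opt1; the closed form is treated as canonical and
V's own stationarity is available only as a diagnostic. Both printed forms
are implemented as stated, without guessing an intended derivation.

### Clamping

`λ_opt = 1 + m/G` degenerates when the pseudo-inverse truncates tiny
negative eigenvalues: a negative eigenvalue counted in m but with `tᵢ = 0`
drives `G → 0` and λ to ±∞. The conventions are: `G → 0⁺` (or exactly 0)
gives 100; `G → 0⁻` gives 1; m = 0 gives 1 (identity projection); and any
finite value outside [1, 100] is clamped into the interval. Extending the
same bounds from the infinite limits to finite overshoot is this package's
choice; the pre-clamp value is always preserved in `raw_lam` and the
denominator reported for diagnosis. Because the clamp mechanism depends on
the interplay between the inertia threshold `tol_rel` and the truncation
threshold `pinv_tol` (both default 1e−8, relative to max|d|), both are
first-class parameters.

## Kernels and features

* **GHI**: `k(x, y) = Σᵢ min(|xᵢ|^α, |yᵢ|^β)`, α, β > 0. With α ≠ β the raw
  matrix is asymmetric; the default returns the symmetric part `(K + K′)/2`
  (the canonical symmetric component, which preserves all the analytic
  special cases), and a strict mode errors instead. α = β yields a
  symmetric PSD histogram-intersection matrix, verified by test.
* **Cosine of distance**: `k(x, y) = cos(‖x − y‖₂)`; unit diagonal, usually
  indefinite. This is deliberately *not* the PSD cosine similarity.
* **q-grams**: samples are vectors of occurrence counts of all length-q
  substrings observed in the collection, vocabulary in first-occurrence
  order (kernel values are order-invariant). Only linear sequences are
  featurized; tree-structured substructure counts (e.g. for glycans) must
  be supplied as precomputed count tables.

## Evaluation harness

Transductive protocol: the full Gram matrix is projected once at the chosen
λ before fold splitting — no out-of-sample eigenvector extension exists for
this family, and none is invented; an inductive mode is deliberately
absent. Folds are stratified (5 by default), repeated (10 by default) with
repeat r seeded `seed + r`; the SVM is `sklearn.svm.SVC` with a precomputed
kernel and fixed cost C = 1 (the cost is exposed but not tuned). AUC is the
Mann–Whitney statistic computed from average ranks (ties count ½), checked
in the test suite against an O(n²) pairwise oracle. The reported spread is
the standard deviation across repeat-level means (ddof = 1). A fold drawing
a single-class training split is redrawn with an incremented sub-seed and a
warning. Strengths λ < 1 leave the kernel indefinite; the solver is run
as-is with its convergence warnings suppressed, and results there should be
read as descriptive, not guaranteed.

## Synthetic fixtures

Two generators, both pure functions of their seed:

* `make_spectrum_kernel` — a kernel with an exactly prescribed spectrum,
  `K = Q diag(d) Q′` with Q obtained by QR of a seeded Gaussian matrix
  (Haar up to sign, then sign-fixed). Round-trip through `decompose`
  recovers the spectrum and inertia to 1e−8. This exercises every spectral
  statement under fully controlled eigenvalues.
* `make_labeled_problem` — two unit-variance Gaussian clusters in p
  dimensions separated by a given mean distance along the first axis
  (default separation 2, 25 samples per class, p = 5), optionally shifted
  nonnegative for GHI use. The indefinite classification fixture pairs this
  with the cosine-of-distance kernel.

What these fixtures emulate is the *spectral* situation of real indefinite
kernels (controlled negative inertia, near-rank-deficiency, class structure
recoverable by a kernel machine). They do not emulate heavy-tailed feature
distributions, label noise, class imbalance, or the particular spectra of
real q-gram/expression data — passing tests demonstrate the algebraic and
statistical machinery, not performance claims on any real dataset. Problem
sizes in the tests and the acceptance script (kernels of order 10–60,
repeats 1–10) were chosen as the smallest sizes at which every property is
non-trivially exercised.

## Known limitations

* Dense eigensolves only; no support for n beyond a few thousand.
* Binary labels only; multi-class problems must be binarized upstream.
* The LogDet divergence evaluator requires strictly PD arguments; it does
  not extend to signed determinants. Selection for indefinite inputs goes
  through the closed form, never through the numeric evaluator.
* No joint optimisation of kernel hyper-parameters (α, β, q) and λ.
* Diffusion and shifting spectrum transforms are out of scope.
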