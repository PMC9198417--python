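# Methods

## Model

`mvhmm` models a balanced four-way panel — `I` units, each a `P × R` matrix
at `T` equally indexed occasions — as a hidden Markov model.  The latent
process `S_it` is a homogeneous first-order Markov chain on `{1,…,K}` with
initial law `π` and transition matrix `Π` (row `j` is the law of the next
state given current state `j`); chains of different units are independent
and share `(π, Π)`.  Given `S_it = k`, the observation is matrix-normal,

    X_it | S_it = k  ~  MN(M_k, Σ_k, Ψ_k),

equivalently `vec(X_it)` is multivariate normal with mean `vec(M_k)` and
covariance `Ψ_k ⊗ Σ_k`.  The model assumes conditional independence of the
observations given the state path, time-constant parameters, and balance
(every unit observed at every occasion).  Unbalanced or missing data,
covariate-dependent transitions and non-Gaussian state densities are out of
scope.

Since `(aΣ, a⁻¹Ψ)` leaves the Kronecker product unchanged, the column
covariance is normalized to `|Ψ_k| = 1`; all reported `Ψ̂_k` satisfy this to
1e-8.

## Parsimonious structures

Each covariance is carried in eigen form `Φ = λ Γ Δ Γ′` with volume
`λ = |Φ|^{1/Q}`, orthogonal orientation `Γ`, and diagonal shape `Δ` with
`|Δ| = 1`.  Equal/variable/identity constraints on the three components give
the 14 row structures `EII … VVV`; dropping the volume (fixed by the
determinant restriction) gives the 7 column structures `II … VV`, hence
98 models named `ROW-COL` (e.g. `VEE-EE`).

Internally a `CovDecomposition` always stores per-state `(λ_k, Γ_k, Δ_k)`
arrays; equality constraints are realized by identical rows.  Eigen
decompositions are made deterministic by sorting eigenvalues in descending
order and flipping each eigenvector so its largest-magnitude entry is
positive.

## Estimation

Parameters are estimated by maximum likelihood with an ECM algorithm:

* **E-step.** Scaled forward–backward recursions, vectorized over units.
  Forward vectors are normalized to sum one at each occasion; the log
  normalizers accumulate into the log-likelihood and the backward pass
  reuses them.  State log-densities are additionally max-shifted per
  (unit, occasion) before exponentiation, so sequences whose densities span
  hundreds of log-units (checked at T = 1000, 200 log-units) stay finite.
  Smoothed memberships `z_itk` and transition posteriors `zz_itjk` satisfy
  their simplex and marginalization identities to 1e-8 by construction.
* **CM-step 1** updates `π`, `Π`, the means `M_k`, and the row covariances
  `Σ_k` from the within-state row scatters
  `Y_k = Σ_it z_itk (X_it − M̈_k) Ψ̇_k⁻¹ (X_it − M̈_k)′` built with the
  *previous* column covariances.
* **CM-step 2** updates `Ψ_k` from the column scatters
  `W_k = Σ_it z_itk (X_it − M̈_k)′ Σ̈_k⁻¹ (X_it − M̈_k)` built with the new
  means and row covariances.

Spherical and diagonal structures have closed-form updates; `EEV`/`VEV`
(and column `EV`) use one eigen-decomposition update per sweep (a
conditional update, not an inner fixed point); `VEI`/`VEE`/`VEV` use the
previous-iteration volumes in their pooled scatters, again as one-sweep
conditional updates.  Structures with a shared orientation and variable
shapes (`EVE`, `VVE`, column `VE`) have no closed form for `Γ`; a
minorization–maximization loop majorizes the trace criterion by its tangent
plane (shifting each scatter by its largest eigenvalue) and minimizes the
resulting linear function over the orthogonal group through an SVD.  Two
numerical choices matter here:

* the SVD sign is fixed so each MM sweep provably does not increase the
  criterion (the update is `−V U′` for the SVD `F = U diag(s) V′` of the
  linearization);
* for `VVE` the per-state scatters enter the rotation criterion weighted by
  the previous inverse volumes `1/λ̇_k` — with a shared volume (`EVE`,
  column `VE`) the weighting is immaterial, but for variable volumes it is
  what keeps the conditional update an ascent step (an unweighted rotation
  can lower the likelihood when volumes differ markedly).

The standalone rotation solver runs to tolerance 1e-10 on the criterion
change with at most 1000 sweeps; empirically ~100 sweeps land within
1e-4 of a 10⁴-point rotation-grid optimum at Q = 2, and the larger budget
closes the remaining slow linear tail.  Inside the ECM driver the rotation
is warm-started from the previous iterate and capped at 50 sweeps per outer
iteration (10 during initialization); since every MM sweep descends from
the warm start, the capped inner loop preserves the monotone log-likelihood
while the orientation converges jointly with the outer iterations.

Scatter matrices are symmetrized after accumulation.  A state whose total
responsibility falls below 1e-8 raises a degeneracy error; the driver
restarts from a fresh initialization (up to 5 times) rather than flooring
covariances, keeping the estimators exactly the stated ones.

**Convergence.** Relative log-likelihood change below `tol` (default 1e-8),
at most 500 iterations.  The trace is monotone non-decreasing within 1e-8
for every structure.

**Initialization (short-EM).** `H` random starts (default 100): each start
assigns every (unit, occasion) a uniform random state, takes one CM sweep
from the hard assignment (identity covariances as the previous iterate),
runs `s` full ECM iterations (default 1), and is scored by its
log-likelihood (forward pass only); the best start seeds the full run.
Degenerate starts are skipped.

**Label switching.** The likelihood is invariant under state relabeling;
fitted states are reported sorted by the grand mean of `M̂_k`, with `π`,
`Π`, posteriors and decoded labels permuted consistently.

## Selection and the sojourn test

`n_params = (K−1) + K(K−1) + K·P·R + rowcount + colcount`; the covariance
counts are also verifiable numerically as Jacobian ranks of a free
parameterization (the test suite does this).  BIC is `−2ℓ + m log N` with
`N = I·T` matrix observations by default (a units-only `N = I` switch
exists; the choice of N is a convention, exposed rather than hidden).
Lower is better; ties break toward fewer parameters, then fewer states.
Grid search runs every (structure, K) pair, records failures without
aborting, and derives one seed per grid cell so results are identical for
any level of parallelism.

Under a homogeneous HMM the sojourn time in state `k` is geometric with
continuation probability `Π_kk`.  The test collects maximal decoded run
lengths per state across units, bins lengths `1, …, m` individually and the
tail `> m` together with `m` chosen as the largest cut for which every
expected count is at least 5, and computes a χ² statistic with `m` degrees
of freedom (`#bins − 1`; no reduction for the estimated parameter, since
`Π̂` comes from the full model rather than the run-length data — a
documented convention).  The `K` p-values are Holm step-down adjusted and
the global null is rejected iff the smallest adjusted p-value is below α.
Runs touching the sequence boundary are counted at their observed length
(no censoring correction).  This is a real limitation, not a cosmetic one:
when `T` is within a few mean sojourn lengths `1/(1 − Π_kk)`, truncation
shortens many observed runs and the test rejects the geometric null even
for data generated by the model (e.g. at `T = 5` with persistence 0.85 the
adjusted p-values are near zero; by `T = 50` the distortion is mild).  The
size check in the test suite therefore uses complete run ensembles, which
isolates the binning and multiplicity machinery; for short panels the
test's rejections should be read as "runs are shorter than geometric",
which truncation alone can produce.  States never
visited, or with too few runs to form two bins, are excluded with a warning
and the adjustment runs over the remainder.

## Synthetic data

The simulator draws state paths from `(π, Π)` and observations from the
state matrix-normal laws (Cholesky factors, so fixed seeds reproduce across
platforms).  Scenario presets cover matrices of size 2×2 (`D1`) and 4×8
(`D2`), T = 5 (`T1`) or 10 (`T2`), K = 2 or 4 states, I = 100 units, with a
uniform initial law and persistent chain (self-transition 0.85, remainder
split evenly).  Two generator families are provided: `EII-II` (unit
spherical covariances) and `VVE-EV` (state volumes 0.8–1.4, shared row
orientation with state-specific shapes; shared column shape with
state-specific orientations, unit determinant).  Separation levels place
adjacent state means 2 (`O1`) or 4 (`O2`) average within-state standard
deviations apart; these separations, and all covariance values above, are
this package's own presets, chosen as representative moderate/wide overlap
regimes.  Recovery conclusions are therefore trend-based (MSE shrinking in
T and I, structure recovered by BIC), not comparisons against any external
numeric table.

What the generator does *not* emulate: temporal heterogeneity of `Π`,
non-Gaussian tails, unbalanced panels, spatial dependence between units.
Passing recovery tests show the estimator is consistent under the model's
own assumptions; they say nothing about robustness when those assumptions
fail.

The MSE experiment fits the generating structure with the true K, aligns
estimated states to the truth (mean-sort rule, refined by the brute-force
permutation minimizing total squared mean error when means overlap;
K ≤ 6), and averages entrywise squared errors over states and replicates.
For `II`-column generators the column covariance is not estimated and is
omitted from the report.

## Problem sizes used by the checks

The test suite fits all 98 structures on one I = 30, T = 4, 2×2, K = 2
dataset for the ascent/coherence/conformance checks; the recovery check
uses I = 100 with 10 replicate pairs at T = 5 vs 10 per generator; the BIC
recovery check runs the full 98 × K ∈ {1, 2, 3} grid on 10 datasets of
I = 50, T = 5 (grid fits use tol 1e-6, 200 iterations — BIC gaps between
structures are orders of magnitude larger than the resulting likelihood
slack).  `scripts/acceptance.py` reports the same quantities at reduced
replication (3 recovery replicates per T, 4 BIC grids) so a full rerun
stays within a few minutes on one CPU; its JSON names say what each number
is.

## Known limitations

* One-sweep conditional updates (`VEI`, `VEE`, `VEV`, eigen and MM
  structures) maximize conditionally, not jointly, per iteration — standard
  for ECM, but per-iteration progress can be slow near ridges.
* The sojourn test ignores boundary censoring and parameter-estimation df.
* BIC's sample-size convention (`I·T` vs `I`) changes the penalty scale;
  both are exposed, only the default is tested.
* Local (posterior-mode) decoding is provided; global Viterbi decoding is
  deliberately not.
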