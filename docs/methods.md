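# Methods

## Model

Regional signals are modelled by simultaneous linear regressions
`v = Kv + u`: `K` is a p×p matrix of path coefficients with zero diagonal
(`K[i, j]` is the directed path j→i, so row i regresses region i on its
parents), and `u` has diagonal covariance `R = diag(r_1..r_p)` with residual
series independent of the interactions. Solving gives the implied matrix
`C1(θ) = (I−K)⁻¹ R (I−K)⁻ᵀ`, compared with the observed correlation matrix
`C2` through the ML discrepancy `F = log|C1| + tr(C2 C1⁻¹) − log|C2| − p`.
F is the raw objective throughout; no sample-size scaling into a χ²
statistic is applied, and the stepwise trace records raw F so any
parsimony-adjusted index can be recomputed downstream. Only directed paths
between observed regions are modelled — no latent variables, no mean
structure, and no alternative discrepancy functions (GLS/ULS).

Assumptions worth stating: residuals are mutually independent and white
(an AR(1) stress option exists in the simulator, off by default); `I−K` is
nonsingular (the implied matrix needs only invertibility, not a spectral
radius below 1); and `C2` is positive definite, checked with a relative
eigenvalue floor of 1e-10 (configurable). Log-determinants are computed via
Cholesky factors, never by exponentiating determinants, and
`tr(C2 C1⁻¹)` via triangular solves, so the objective is stable as p grows.

## Eigentimeseries extraction

Each region's m×n subjects-by-timepoints matrix is standardized row-wise
(unbiased n−1 variance denominator by default; `ddof=0` available) and
decomposed by thin SVD. The first right singular vector is the region's
eigentimeseries; its explained fraction `λ₁²/Σλ_j²` gives the residual
variance `r_i = 1 − λ₁²/Σλ_j²`, computed literally from the singular-value
spectrum of the standardized matrix. The SVD sign ambiguity is fixed
deterministically: the element of largest absolute value is made positive,
ties broken at the earliest index — data-driven and bit-reproducible, but
(like any convention) uninformative about the latent signal's true sign,
which is not identifiable. Exactly tied leading singular values are accepted
from the decomposition routine with a warning, since the leading subspace is
then ambiguous. Voxel-to-region averaging is assumed done upstream; inputs
start at regional matrices.

## Residual-variance closures

Two rules for `R` are supported when fitting:

* **fixed** — a caller-supplied vector, typically the PCA-spectrum residuals
  above. This is the literal reading of the implied-matrix formula; for an
  arbitrary θ the implied diagonal then deviates from 1, and the results
  object reports `max |diag(C1) − 1|` as a diagnostic.
* **unit_diagonal** (facade default for correlation-matrix fits) — at every
  θ, solve `(B∘B) r = 1` with `B = (I−K)⁻¹` for the unique residual vector
  making `diag(C1) = 1`. This is the standard closure for standardized path
  analysis: the observed matrix is a correlation matrix, so the implied one
  should be too. A nonpositive solution marks θ infeasible (penalty below).

For recursive (acyclic) structures the two closures give the same
coefficient estimates — `|I−K| = 1` makes the coefficient part of F a
residual-weighted regression whose optimum does not depend on `R` — but the
unit-diagonal closure additionally makes F→0 attainable at the truth, which
is what a fit-threshold stopping rule needs.

## Optimizers

`minimize_local` wraps Powell's derivative-free method (scipy), the approach
of the classic baseline implementation; it never returns a value above the
starting point's.

`hpgsa_minimize` is the hybrid global optimizer: a real-coded island-model
GA with tournament selection (size 2), BLX-0.5 blend crossover, and Gaussian
mutation with σ = 10% of the coefficient range, whose offspring replace
their parents through Metropolis acceptance `exp(−ΔF/T)` under geometric
cooling `T_g = T₀ α^g` (defaults T₀ = 1, α = 0.97). Defaults: population
1024 over 200 generations (the published run setting), 4 islands with ring
migration of the 2 best every 10 generations, coefficient bounds [−5, 5]
(standardized path coefficients rarely exceed |1|; the bound is deliberately
loose), stall stop after 30 generations without 1e-10 improvement. Elitism
restores each island's best if lost, so the best-F history is nonincreasing.
A final Powell polish of the elite (on by default) refines the winner to
local-optimum precision — the memetic step that lets a stochastic search
meet tight coefficient tolerances. Islands are executed serially; the
contract is bit-reproducibility as a pure function of (problem, config),
not a threading scheme. Infeasible coefficient vectors (singular `I−K`,
non-PD implied matrix, nonpositive closure residuals) receive a finite
penalty `1e6 + |most negative eigenvalue|`, keeping the surface finite and
weakly informative rather than raising mid-search.

`repeated_best` runs the optimizer under nested seeds (first run uses the
configured seed itself, so one repeat reproduces a single run) and keeps the
minimum F — the practical answer to a per-run failure probability: k
independent repeats all fail with probability p^k.

## Structure search

The **stepwise** search starts from the null model and, at each step, scores
every allowed-but-constrained path with the single-parameter modification
index `g²/(2h)`, where g and h are the first and second partial derivatives
of F with respect to that coefficient at zero, estimated by central
differences (step 1e-4) with the free coefficients held at their optimum. A
flat or concave direction (h ≤ 0) falls back to `g²/(2|h| + ε)` with a
warning. The top-scoring path is freed (ties broken lexicographically on
(source, target) — as are all ties in the package) and F re-minimized,
warm-started at the previous optimum with the new coefficient at zero, which
guarantees a nonincreasing F across steps. Stopping: F below a fit tolerance
(default 0.05), a free-path budget (default 12), or no candidates left. The
exact threshold any given study should use is a judgement call; the trace
keeps raw F per step so the rule can be re-evaluated afterwards.

The **exhaustive** search enumerates every q-subset of the allowed paths
with nested Powell minimization from zero — exact, and refused above a
candidate cap (default 1e5) since the full-scale problem has C(30,12) =
86,493,225 structures. The **GA structure search** optimizes subset and
coefficients jointly: the chromosome is a fixed-cardinality subset plus one
coefficient per member; crossover keeps the parents' intersection and fills
the remaining slots uniformly from the symmetric difference; mutation swaps
a member for a non-member — both preserve |subset| = q by construction —
with SA acceptance and elitism as above. The best few distinct structures
(default 3) are polished by nested local minimization before the winner is
returned. Both joint search and nested enumeration are provided because
either reading of "search the structure space" is defensible; they agree on
small instances by construction of the tests.

## Synthetic data

`generate_network` draws q distinct directed paths with coefficients uniform
on ±[0.3, 0.7] by default, resampled until the spectral radius of K is
below 1 — stricter than invertibility, adopted so coefficients stay in the
standardized-path regime — and until a positive unit-variance residual
solution exists. By default at most one direction per region pair is drawn:
a reciprocal pair with near-cancelling coefficients can be observationally
equivalent to no connection at all, a useless ground truth for recovery
benchmarks; `allow_reciprocal=True` lifts this.

`simulate_timeseries` draws the stimulus-locked residual series u(t) i.i.d.
across timepoints, forms the latent signal `v = (I−K)⁻¹ u` once per
scenario, and gives each subject that shared signal plus independent
Gaussian observation noise (default sd 0.3 against unit-variance signals —
a high-SNR stimulus-locked regime). Subjects are exchangeable replicates;
no between-subject variation in connectivity is simulated. This is what
makes pooled-subject PCA meaningful: the eigentimeseries recovers the shared
component (|correlation| > 0.9 at n = 500 in the tests). A
`subject_mode="independent"` option draws a fresh latent per subject
instead, which removes the shared component and is used to stress-test the
pooling step. Residual sds default to the unit-variance solution of
`(B∘B) sd² = 1`, so the latent signal is standardized like real regional
data and the analytic implied matrix is a true correlation matrix (returned
alongside the data for oracle checks).

What passing on this generator does **not** show: robustness to hemodynamic
convolution, scanner noise spectra, motion artefacts, between-subject
heterogeneity, or temporal autocorrelation (beyond the optional AR(1)
flag) — none of which are simulated.

## Identifiability and how recovery is assessed

Two caveats shape every ground-truth comparison:

* **Direction** — Markov-equivalent reorientations imply identical
  correlation matrices; at the null model the modification indices of a path
  and its reversal tie exactly under the unit-diagonal closure. Real
  analyses resolve this with anatomical constraints, and the benchmarks do
  the same: `anatomical_mask` allows every true path and both directions of
  unconnected pairs, but not the reversal of a true path.
* **Sign** — the sign of an eigentimeseries is arbitrary, so fitted
  coefficients equal the truth only up to `d_s·d_t` with d a ±1 vector per
  region. Recovery is therefore assessed on coefficient magnitudes
  (within ±0.1 of the true 0.6 in the end-to-end benchmark).

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale budgets chosen to finish in seconds
while leaving the conclusions unchanged: GA populations of 48–128 over
25–50 generations for p ≤ 6 problems (the full default of 1024×200 is the
published setting and remains the constructor default), 20 recovery
scenarios at n = 1000, m = 5, and the full-scale structure search at p = 6,
30 allowed paths, q = 12 with population 128 over 50 generations on the
analytic correlation of a known 12-path network — there the truth attains
F = 0, so "the search never beats the truth" is an exact rank check rather
than one hostage to sampling noise. Positive-definiteness uses a relative
eigenvalue floor of 1e-10; the penalty base is 1e6; equal-F ties everywhere
break lexicographically.

## Known limitations

* Fitting consumes correlation matrices; mean structures and raw-covariance
  fits are out of scope.
* The modification index is computed numerically; analytic derivatives would
  be faster at large p but p ≤ 10 is the intended regime.
* The stepwise fit threshold (default 0.05 on raw F) is a pragmatic default,
  not an inferential criterion; no χ² calibration is attempted.
* GPU execution is not supported; the island model is a determinism
  contract, not a parallel implementation.
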