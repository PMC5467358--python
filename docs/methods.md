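# Methods

## Model and frames

The fine system is the heterogeneous Kuramoto model on an undirected,
unweighted graph A ∈ {0,1}^{N×N}:

    dφ_i/dt = ω̂_i + (K/N) Σ_j A_ij sin(φ_j − φ_i).

All computations evolve the co-moving deviations θ_i = φ_i − mean(φ)
(i = 1..N−1, with θ_N = −Σ_{j<N} θ_j closing the zero sum), whose vector
field subtracts the mean frequency and therefore admits a genuine steady
state — the frequency-synchronized cluster — once K is large enough. θ is
evolved on the real line (unwrapped): the vector field is smooth in θ and
the polynomial surface fit requires continuity. Wrapping to the principal
branch is applied only inside diagnostics (the synchronization index, the
surface-collapse residual), where winding history is irrelevant.

The analytic Jacobian of the co-moving field, with
C_ij = A_ij cos(θ_j − θ_i) over the full N-vector, is

    J_il = (K/N) ( C_il [l ≠ i] − δ_il Σ_j C_ij − C_iN ),

the last term being the chain rule through θ_N. It is certified in the
tests against central finite differences (≤ 1e−5 relative, Frobenius) and,
independently, against the spectrum of the symmetric original-frame
Jacobian, rather than against any published formula.

## Heterogeneity and its generator

The structural coordinate is the node degree of a Chung-Lu graph with
weights w_i = N·p·(1 − q(i−1)/N)^r and edge probabilities
P_ij = min(w_i w_j / Σ w, 1); defaults p = 0.50, q = 0.90, r = 0.50. One
uniform variate per upper-triangle pair, consumed in (i, j) row-major
order from a single seeded generator, makes realizations bit-reproducible
across platforms; the diagonal is never sampled (no self-loops). Isolated
nodes are permitted but flagged with a warning — the identity surface
remains defined, though the low-degree regime weakens the premise that
degree alone summarizes connectivity. The intrinsic coordinate is a
truncated-normal natural frequency, support [−0.100, 0.100], mean 0,
parent sd 0.060 (rad/time), sampled exactly by rejection from the parent
normal (acceptance ≈ 0.90 at the defaults).

These defaults are the study conditions; named presets pin the standard
scenarios (base: N = 196, K = 1; the N = 4000, K = 0.5 collapse demo; the
N = 300 projective-integration run with τ = 0.05, h = 0.45; the τ = 0.30
continuation setting). What the generator does *not* emulate: weighted or
directed edges, degree correlations, community structure, multimodal
state-vs-identity relations, or time-varying networks. Passing tests
therefore certify the machinery on networks whose long-time states are
unimodal smooth functions of (ω, κ); they say nothing about systems where
extra identity coordinates (clustering, motif counts, cluster membership)
carry dynamical information.

## Moment-based polynomial chaos

Both identity coordinates are standardized over the fitting node set —
nodes 1..N−1, the ones carrying independent co-moving coordinates — using
the population (divide-by-n) standard deviation. The degree coordinate is
treated as continuous after normalization even though κ̂ is integer;
orthogonality is with respect to the empirical (discrete) measure either
way. A switch (`include_last`) admits node N into the sample; the default
keeps normalization, moments and fitting on the same n = N−1 nodes.

For each marginal, the degree-d monic polynomial solves the moment
conditions Σ_l c_l m_{l+k} = 0 (k < d) built from raw sample moments.
Numerical choices:

* moments are accumulated with compensated summation (`math.fsum`) — the
  Hankel moment matrix is ill-conditioned and every digit matters;
* the linear solve uses the SVD pseudo-inverse, followed by three
  iterative-refinement sweeps with extended-precision residuals, which
  restores empirical orthogonality of the family to ~1e−14 even at
  degree 6 on a 195-point sample;
* a `ConditioningWarning` fires when the moment matrix is numerically
  rank-deficient (degree too high for the sample);
* each polynomial is stored at unit empirical norm (conditions the least
  squares), with the monic norm kept so the convention can be undone.

The 2-D basis is the tensor product truncated by total degree
(a + b ≤ p_max, M = (1+p_max)(2+p_max)/2; a per-coordinate rule is exposed
but not default), ordered graded-lexicographically (ascending total
degree, ties by ascending ω-degree) — any fixed ordering would do, this
one is deterministic and matches the truncation rule.

**Which measure is the basis orthogonal under?** Each 1-D family is
orthonormal under its own marginal empirical measure, hence the tensor
products are orthogonal under the *product* of the two marginals — that is
what the construction can guarantee, and the tests verify it to 1e−8. The
Gram matrix over the *joint* per-node sample is only asymptotically
diagonal: at n = 195 its off-diagonals are O(1) for high-degree pairs
because a finite sample of independent coordinates is never exactly
uncorrelated. Consequently the closed-form coefficient ratio
Σ w f ψ / Σ w ψ² agrees with the QR least-squares solution only up to that
finite-sample cross-correlation (a few percent at N = 4000 and low degree,
tested as such); the implementation always uses the QR solve.

Distances between bases (used for the sample-size convergence study) are
2-norms of monomial-coefficient tensors after rescaling both bases to
monic 1-D factors, so the normalization convention cancels.

## Restriction, lifting, the coarse timestepper

Restriction fits θ over the N−1 fitted nodes by weighted least squares
with uniform Monte-Carlo weights 1/n (general weights are a parameter),
via QR with a rank check that raises on column-rank loss (e.g., too few
distinct degrees to resolve the κ-degree columns). Lifting evaluates the
surface at the same nodes; node N's phase follows from the zero-sum
constraint. R∘L is the identity on coefficient space to factorization
tolerance; L∘R is the least-squares projector on fine space.

The coarse timestepper Φ_{τ,C} = R ∘ Φ_{τ,F} ∘ L lifts to the *one*
network and frequency vector held by the model ("single instance"
lifting); ensemble-averaged lifting over consistent realizations is out of
scope. The fine burst integrator is adaptive RK (solve_ivp), default
tolerances 1e−8/1e−8, configurable per experiment.

## Equation-free algorithms

*Projective integration.* The chord (Φ_{τ,C}(α) − α)/τ estimates dα/dt; an
optional healing integration first relaxes the lifted state and
re-restricts before the chord is drawn (default healing = 0, exposed). The
outer integrator is projective forward Euler, explicit RK2 (Heun), or an
adaptive embedded pair driven by the chord estimator; a norm guard raises
on divergence. The empirical order of the projective RK2 scheme in the
outer step h, with fixed small inner step, is 2 (tested as 2 ± 0.15 over
five step sizes at N = 100); for small h the error saturates at the
O(τ)-induced floor, which is the practical limit of the chord estimate.

*Fixed points.* Zeros of F_τ(α) = Φ_{τ,C}(α) − α via
scipy's Newton-Krylov with GMRES inner solves, forward-difference
directional derivatives of relative step √ε, inner subspace allowed to
reach the full coarse dimension M, and outer absolute tolerance 1e−6
(max-norm). A warm start at a converged point returns immediately.

*Eigenpairs.* For M > 3 the Jacobian of F_τ is probed matrix-free:
implicitly restarted Arnoldi on the shifted operator v ↦ v + Jv, whose
largest-magnitude eigenvalues μ + 1 = e^{λτ} are exactly the slowest rate
eigenvalues; k = min(M − 2, 6) by default. For M ≤ 3 a dense
forward-difference Jacobian with fixed step 0.001 is diagonalized
directly. Rate eigenvalues come from the principal complex logarithm
λ̂ = ln(μ + 1)/τ, which aliases when |Im λ|·τ ≥ π; the defaults τ = 0.05
(integration/fixed-point/eigen experiments) and τ = 0.30 (continuation)
keep the slow modes of this system far from that bound.

*Continuation.* Pseudo-arclength in K: two natural-parameter solves at K₀
and K₀ − δK seed the secant tangent; each step solves the
arclength-augmented system by Newton-GMRES (corrector 2-norm residual
≤ 1e−8 at accepted points), halving the step on corrector failure and
growing it by 1.3 on success (initial ds = 0.01–0.02, capped). A fold is
bracketed where the secant tangent's K-component changes sign and refined
by a bounded scalar extremization of K along the bracket chord (each
evaluation one corrector solve); on the quadratic normal form
F = α² − (K − K_c) this locates the fold to ~1e−15. Stability is flagged
from the leading rate eigenvalues at each accepted point and can only flip
where a leading real part crosses zero — on the Kuramoto branch the flip
coincides with the fold, the signature of the SNIPER bifurcation. Below
the fold a rogue oscillator circulates and r(t) oscillates indefinitely;
above it r(t) settles to a constant. Left of the fold the surface ansatz
itself degrades (the rogue's phase is not a smooth function of identity),
so continued unstable solutions are meaningful only near the fold;
augmenting the coarse variables with the rogue phase is out of scope.

## Problem sizes used by the test suite

Chosen so the whole battery runs comfortably on one CPU: the
polynomial-convergence study compares bases from N ∈ {250, 1000}
realizations (16 replicates) against an N = 4000 reference; the
fixed-point accuracy sweep uses polynomials from one N = 2000 realization
observed on 8 independent N = 196 networks for M ∈ {3, 6, 10, 15, 21, 28};
the collapse demonstration runs the N = 4000, K = 0.5 ensemble to t = 120;
the projective-order experiment uses N = 100. These are reduced-scale
versions of the same experiments the larger presets describe; trends
(monotone error decay, order of convergence, fold + stability exchange)
are size-stable in our runs.

## Known limitations

* The degree-6 surface truncation leaves a systematic gap between coarse
  and fine slow eigenvalues at the base settings (~8% relative at M = 28,
  N = 196, K = 1). This is genuine model reduction error, not solver
  error: the matrix-free Arnoldi result coincides with a dense
  finite-difference Jacobian and with the explicit Galerkin projection
  R·J_fine·L of the analytic fine Jacobian, and the polynomial space — and
  hence the projected spectrum — is independent of which sample built the
  basis.
* The ratio of the two slowest fine eigenvalues at the synchronized state
  is ~0.9 at K = 1 across realizations; it falls through ~0.6 only just
  above the fold, where the slow rogue-susceptible mode separates from the
  bulk (its lifted eigensurface then peaks at the extreme-(ω, κ)
  oscillator).
* Restriction quality degrades whenever states stop being unimodal smooth
  functions of identity — multimodal splits, rogue oscillators, strong
  clustering — which is visible as a large fit residual in the
  `FitReport` rather than silently wrong coefficients.
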