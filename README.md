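# netpce

Polynomial-chaos coarse-graining and equation-free computation for networks
of heterogeneous coupled oscillators.

## The problem

Large networks of dynamical units are expensive to simulate and hard to
analyze unit by unit. When every unit's long-time behavior is determined by
its *identity* — here an intrinsic parameter (its natural frequency ω̂) and
a structural one (its degree κ̂ in the network) — the whole state collapses
onto a smooth surface over identity space, and a handful of surface
coefficients summarize thousands of phases. `netpce` builds that reduced
description for the heterogeneous Kuramoto model

    dφ_i/dt = ω̂_i + (K/N) Σ_j A_ij sin(φ_j − φ_i),

on undirected Chung-Lu random graphs (weights w_i = N·p·(1 − q(i−1)/N)^r,
edge probabilities P_ij = min(w_i w_j / Σ w, 1)), with frequencies drawn
from a truncated normal. Dynamics are evolved in a co-moving frame
θ_i = φ_i − mean(φ), which has a true steady state (the synchronized
cluster) for large enough coupling K.

The reduced state is a polynomial-chaos expansion over the normalized
identity pair (ω, κ):

    θ(t; ω, κ) ≈ Σ_{k=1..M} α_k(t) ψ^(k)(ω, κ),
    ψ^(k) = ξ^(a_k)(ω) ζ^(b_k)(κ),   a_k + b_k ≤ p_max,
    M = (1 + p_max)(2 + p_max)/2.

The 1-D families ξ, ζ are built *from the raw sample moments* of the one
network realization at hand (arbitrary polynomial chaos): the degree-d
monic polynomial solves Σ_l c_l m_{l+k} = 0, k < d, via an SVD
pseudo-inverse of the moment matrix, so no closed-form distribution is ever
needed — the same construction recovers Hermite polynomials from Gaussian
samples, Legendre from uniform, and Charlier from Poisson.

Restriction R (fine → coarse) is a uniform-weight least-squares fit of θ
onto the basis, solved by QR; lifting L (coarse → fine) evaluates the
surface at the node identities. Their sandwich around a short burst of fine
integration is the coarse timestepper Φ_{τ,C} = R ∘ Φ_{τ,F} ∘ L, the only
object the *equation-free* algorithms ever touch:

* **Coarse projective integration** — estimate dα/dt from the chord
  (Φ_{τ,C}(α) − α)/τ and take large outer steps (forward Euler, RK2, or an
  adaptive pair), optionally after a short *healing* integration.
* **Coarse fixed points** — zeros of F_τ(α) = Φ_{τ,C}(α) − α by matrix-free
  Newton-Krylov (GMRES).
* **Coarse stability** — leading eigenpairs of the Jacobian of F_τ by
  implicitly restarted Arnoldi (dense finite differences for M ≤ 3),
  mapped to rate eigenvalues through λ̂ = ln(μ + 1)/τ.
* **Coarse bifurcation diagrams** — pseudo-arclength continuation in K with
  secant predictor, Newton-GMRES corrector, fold refinement, and stability
  flags; the synchronized branch ends in a SNIPER (saddle-node
  infinite-period) fold below which a rogue oscillator orbits the phase
  ring.

## Worked example

```python
import numpy as np
from netpce import *
from netpce.coarse_map import CoarsePCEModel

fx = make_fixture(preset("base", seed=0))        # N=196 Chung-Lu, K=1
s = fx.sample                                    # normalized (omega, kappa)
basis = tensor_basis(apc_1d(s.omega, 6), apc_1d(s.kappa, 6), 6)
model = CoarsePCEModel(fx.ensemble, basis, s)
print("basis size M:", basis.M)

steady = fine_steady_state(fx.ensemble)          # synchronized cluster
print("sync index r at steady state:", round(sync_index(steady.full_theta).r, 4))

alpha_star = coarse_fixed_point(model, model.restrict(steady), tau=0.05)
print("||F_tau(alpha*)||:", f"{np.linalg.norm(model.difference(alpha_star, 0.05)):.2e}")

res = coarse_eigs(model, alpha_star, tau=0.05, k=6)
lam_fine = np.sort(np.linalg.eigvals(fine_jacobian(fx.ensemble, steady)).real)[::-1]
print("slowest coarse rate eigenvalues:", np.round(res.lambda_hat.real[:3], 4))
print("slowest fine eigenvalues:       ", np.round(lam_fine[:3], 4))
```

prints

```
basis size M: 28
sync index r at steady state: 0.9854
||F_tau(alpha*)||: 2.71e-08
slowest coarse rate eigenvalues: [-0.143  -0.147  -0.1551]
slowest fine eigenvalues:        [-0.1322 -0.1391 -0.1413]
```

So the 28-coefficient surface carries a genuine fixed point of the coarse
map (residual below the 10⁻⁶ Newton tolerance), the synchronized cluster is
tight (r ≈ 0.985), and the coarse spectrum tracks the slow end of the fine
spectrum to within the truncation error of a total-degree-6 surface
(≈ 8% here; see `docs/methods.md`).

## Command line

`netpce` exposes `simulate`, `cpi`, `fixedpoint`, `eigs`, `continue`, and
`reproduce-figure {2,4,5,6,7,8}`; every run logs seeds, tolerances and
timings, and writes CSV (optionally PNG with `--plot`):

```bash
netpce eigs --preset base --pmax 6 --out out/
netpce continue --preset fig8 --k-start 0.7 --out out/
netpce reproduce-figure 8 --plot --out out/
```

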