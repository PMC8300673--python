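# Methods

## The reconstruction problem

A dynamical system resting near a stable steady state `x*` and driven by
weak white noise produces fluctuations whose stationary covariance `Γ`
carries information about the local Jacobian `J`.  For the linearized
(Ornstein–Uhlenbeck) dynamics the three matrices are tied together by the
continuous Lyapunov relation

    J Γ + Γ Jᵀ = −2 D,

where `D` is the fluctuation matrix of the driving noise (for additive noise
of per-variable amplitude `σ_i`, `D = diag(σ_i²)/2` under this
normalization).  Read forward the relation gives `Γ` from a known `J` — the
package's validation oracle.  Read backward it is underdetermined: both
sides are symmetric, so it fixes only `N(N+1)/2` of the `N²` entries of `J`.

Structural zeros close the gap.  In networked systems, variables that are
not wired together cannot enter each other's equations of motion, so the
corresponding Jacobian entries vanish identically.  With at least
`N(N−1)/2` known zeros the system becomes (generically) determined.

## The closed-form solve

Vectorizing (column-stacking, `vec(X)[kN+i] = X[i,k]`) turns the relation
into a linear system

    B vec(J) = −2 vec(D),   B = Γ⊗I + (I⊗Γ)C,

with `C` the commutation matrix (`C vec(X) = vec(Xᵀ)`).  Each structural
zero appends one elementary row (a single 1 at the constrained vec-position,
weight 1 by default) with right-hand side 0.  The stacked system is solved
in the least-squares sense; constrained entries are then set exactly to zero
(`enforce_zeros=True`, the default), which measurably improves the accuracy
of the reconstructed eigenvalues.  The leading eigenvalue (largest real
part; ties broken by ascending |Im|, nonnegative Im first) is the
early-warning statistic: its real part approaches zero as a bifurcation
nears, and the real-vs-complex tag distinguishes fold-type from Hopf-type
instabilities.

### Solvers

Two equivalent paths solve the stacked least squares:

- **Dense orthogonal factorization** (SVD-based `lstsq`) for small systems
  and whenever the problem may be rank-deficient; rank deficiency is
  flagged and the minimum-norm solution returned.
- **Structured normal equations** for `N ≥ 24`: using
  `BᵀB = 2(Γ²⊗I) + (Γ⊗Γ)C + C(Γ⊗Γ)`, the `N²×N²` normal matrix is
  assembled in `O(N⁴)` without ever forming the stacked system, factorized
  by Cholesky, and polished with two iterative-refinement sweeps whose
  residuals are evaluated exactly through the `O(N³)` Lyapunov form.  This
  is ~25× faster than the dense factorization at `N = 60` and reaches the
  same ~1e−12 round-trip accuracy.  If the normal matrix is not positive
  definite (underdetermined pattern) the code falls back to the dense path.

Both paths agree with the normal-equations closed form
`(B̂ᵀB̂)⁻¹B̂ᵀd̂` on full-rank systems to numerical tolerance (tested).

### Identifiability

`|pattern| ≥ N(N−1)/2` is necessary but not sufficient.  The unconstrained
solution set of the Lyapunov relation is `J + WΓ⁻¹` with `W` skew-symmetric;
a pattern fails to pin `W` down when, for example, a densely coupled block
of variables carries no internal zeros (a dense 2×2 block retains one gauge
degree of freedom no matter how many zeros sit elsewhere).  Network-derived
patterns on connected, reasonably sparse graphs — the intended use case —
are generically identifiable.  The random-fixture generator therefore
samples a *connected* Erdős–Rényi interaction graph and zeroes both ordered
entries of every non-adjacent pair, rather than scattering zeros uniformly.
Rank deficiency, when it occurs, is detected and reported.

### Numerical choices

- Covariances are validated for symmetry: relative asymmetry above 1e−8
  warns and symmetrizes, above 1e−3 raises (sample covariances are symmetric
  by construction, so larger asymmetry indicates a user error).
- A covariance that is identically zero (constant or noiseless series) is a
  degenerate input and raises rather than returning a meaningless matrix.
- Covariance estimation uses the unbiased `1/(n−1)` normalization —
  immaterial at the study's `n = 2×10⁵`, documented for short-window use.
- Indices are 0-based; Jacobian row = affected variable, column = perturbed
  variable; multilayer states flatten species-fastest
  (`variable = species + S·patch`); matrix files carry 17 significant
  digits so file round trips are exact.

## Structural zeros from topology

For a single-species network, every ordered pair of distinct non-adjacent
nodes is a zero.  For an `S`-species food web replicated over `P` patches
coupled by dispersal, the default pattern is the union of

- *cross-layer* zeros — a different species in a different patch can never
  be affected directly: exactly `S·P(S−1)(P−1)` ordered pairs, independent
  of topology; and
- *spatial* zeros — the same species in non-adjacent distinct patches.

Trophic zeros (unlinked species pairs within one patch) are available but
off by default: prey switching and shared predators make unlinked species
interact dynamically, so an absent trophic link does not guarantee a
Jacobian zero.  Sufficiency is checked by explicit enumeration of the
pattern rather than by closed-form mean-degree or species/patch-count
inequalities, which misstate the available zeros on small topologies.

## Ground-truth models

**Linear (OU) surrogate.**  `dx = Jx dt + σ dW` for an arbitrary Hurwitz
`J`: the Jacobian is exact by construction and the stationary covariance is
the forward Lyapunov solution, enabling closed-loop validation.

**Rosenzweig–MacArthur metacommunity.**  Per patch `p`, prey `b` and
predator `c` follow

    db/dt = r b (1 − b/K) − a b c/(1 + a h b) + δ_b Σ_q A_pq (b_q − b_p)
    dc/dt = ε a b c/(1 + a h b) − m c − g c² + δ_c Σ_q A_pq (c_q − c_p)

— logistic prey growth, Holling type II predation, quadratic predator
mortality, diffusive dispersal along the patch network `A`.  Defaults
(`r=1, a=2, h=1, ε=0.5, m=0.3, g=0.05, δ_b=δ_c=0.05`, time in units of the
prey growth rate) were fixed by a coarse numeric scan so that enrichment
(raising the carrying capacity `K`) drives the coexistence state through a
Hopf bifurcation inside the scanned range: with these values the
coexistence state exists for `K ≲ 11` and loses stability at `K* ≈ 3.11`
(identical for the single patch and the homogeneous 6-patch state, because
equal prey and predator dispersal shifts every non-uniform Laplacian mode
further into the stable half-plane and rules out Turing-type modes
preceding the Hopf).  The package default `K = 2.5` sits one typical
transect step inside the stable regime (leading eigenvalue −0.053 ± 0.244i).

At a homogeneous steady state the full Jacobian block-diagonalizes over the
Laplacian eigenmodes (`master stability function`):
`spec(J_full) = ∪_k spec(J_intra − λ_k diag(δ))`, an identity the test
suite verifies to 1e−10 against direct eigendecomposition.

**Simulation.**  Euler–Maruyama,
`x_{k+1} = x_k + f(x_k)dt + σ_eff √dt ξ_k`, with additive
(`σ_eff = σ`) or multiplicative (`σ_eff = σ·x`) noise.  States are never
clipped: the covariance-based inversion assumes the trajectory stays in the
linearization regime, and clipping would bias the covariance.  A run in
which an ecological variable crosses below zero is discarded and re-seeded
(counted and warned); a non-finite state aborts with its step index.
Identical seed and configuration give bit-identical series.

## Study conditions and scale

The stochastic validation experiments use, throughout:

- series length `n = 2×10⁵` samples, stride 1 (no thinning);
- additive noise `σ = 0.01` — a few-percent perturbation of the O(1)
  steady-state biomasses, small enough for the linearization to hold;
- integration step `dt = 0.1`, set by a calibration on the linear
  surrogate: the record then spans `T = 2×10⁴` time units, i.e. ~10³
  correlation times of the leading mode at the default operating point,
  while the fastest eigenvalue satisfies `|λ_max|·dt ≈ 0.03`, keeping the
  Euler–Maruyama covariance bias below the statistical error.  (For
  surrogates with O(1) eigenvalues, e.g. random Hurwitz matrices, tests use
  `dt = 0.01`–`0.05` by the same criterion.)

The accuracy-near-bifurcation experiment pools three transects toward the
Hopf boundary (in `K`, in predator mortality `m`, and in attack rate `a`),
three seeds each, on OU surrogates built from the exact metacommunity
Jacobians, and compares leading-eigenvalue errors in the nearest- and
farthest-from-bifurcation thirds of the stable grid points.

## Sliding windows and transects

Sliding-window estimation reconstructs in windows of `τ` samples (anchor at
the window end or centre), each window mean-centered individually so that
the slow drift of the operating point under a parameter ramp is removed.
The noise matrix `D` is held fixed across windows (the noise specification
is treated as known; estimating a drifting `D` is out of scope).  Default
window geometry where none is given: `τ = n/10`, stride `τ/4`.

Transect experiments flag grid points whose steady state is unstable:
there the simulated system has departed to another attractor, so the
difference between the reconstruction (which sees the new dynamics) and the
analytic eigenvalue of the unstable state is not a reconstruction error.
Post-bifurcation estimates are reported, never suppressed.

## Behaviour at and beyond the Hopf point

Two findings from the validation runs are worth recording:

- **Accuracy improves toward the bifurcation.**  On the enrichment
  transect the leading-eigenvalue error falls from ~2×10⁻² at `K = 2.0` to
  ~10⁻³ at the last stable grid points.
- **The limit-cycle zero is recovered from below.**  Past the Hopf the
  trajectory orbits a stable limit cycle whose leading Lyapunov exponent is
  exactly zero, and the reconstruction returns values of ~−10⁻⁴…−3×10⁻⁴,
  robust to `dt ∈ [0.02, 0.2]` and to mean- vs steady-state-centering.  The
  residual negativity is phase diffusion: noise decorrelates the
  oscillation phase at rate ∝ σ², which looks like a very weakly damped
  mode.  Consequently the reconstructed leading real part *approaches* zero
  across the bifurcation but does not change sign under these conditions —
  a sign-based change detector never fires, while the collapse of the
  signal to |Re λ̂| < 10⁻³ localizes the transition to within one grid step
  of the true crossing.  Detectors built on this signal should therefore
  threshold its magnitude, not its sign.

## What the synthetic data do and do not show

The generators emulate stationary fluctuations of systems whose Jacobian,
noise amplitude and zero pattern are known exactly.  Real data differ in
ways the passing tests do not probe: the fluctuation matrix `D` must be
assumed or measured (estimation of `D` from data is out of scope);
observation noise is absent; sampling here is regular and dense relative to
the system time scales; the structural zeros are exact rather than
approximate.  Misspecified zeros and observational error degrade the
inversion in ways not quantified here.

## Known limitations

- Normal-form coefficients and finer bifurcation sub-classification (beyond
  the real-vs-complex-pair tag) are not computed.
- The generalized-modelling parameterization of meta-foodwebs is not
  implemented; the explicit Rosenzweig–MacArthur metacommunity plays the
  role of the nonlinear test system.
- Data demand is intrinsic to the method: at `n ≪ 10⁵` samples the
  leading-eigenvalue estimate is noisy even with exact structural
  information (the convergence test quantifies the trend).
- Dispersal networks are undirected and unweighted; `D` is diagonal.
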