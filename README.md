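# jacrec — Jacobian reconstruction from stationary fluctuations

`jacrec` estimates the Jacobian matrix of a dynamical system from a
multivariate time series of its noise-driven fluctuations about a steady
state, and uses the leading eigenvalue of the reconstructed Jacobian as an
early-warning signal for bifurcations (critical transitions).

It is aimed at people studying networked dynamical systems — ecological
metacommunities, metabolic or regulatory networks, power grids — who can
observe fluctuations of all state variables and who know, from the wiring
of the system, which pairs of variables cannot interact directly.

## The method

Near a stable steady state, the stationary covariance `Γ` of the
fluctuations, the Jacobian `J` and the fluctuation matrix `D` of the
driving noise satisfy the Lyapunov relation

```
J Γ + Γ Jᵀ = −2 D .
```

Both sides are symmetric, so the relation alone fixes only `N(N+1)/2` of
the `N²` entries of `J`.  Structural zeros close the gap: variables that
are not wired together contribute entries known to be exactly zero, and
with at least `N(N−1)/2` of them the inversion becomes determined.
Vectorizing with the commutation matrix `C` (`C vec(X) = vec(Xᵀ)`) gives a
linear least-squares problem

```
[ Γ⊗I + (I⊗Γ)C ]            [ −2 vec(D) ]
[     U        ]  vec(J)  ≈ [     0     ]
```

(`U` holds one elementary row per structural zero), solved in closed form.
The real part of the leading eigenvalue of the reconstructed `J` is the
warning signal: it rises toward zero as a bifurcation approaches, and its
imaginary part distinguishes fold-type (real) from Hopf-type
(complex-pair) instabilities.

The package bundles ground-truth generators for validation: linear
(Ornstein–Uhlenbeck) surrogates, and a Rosenzweig–MacArthur predator–prey
metacommunity (Holling type II predation, quadratic predator mortality,
diffusive dispersal on a patch network) whose coexistence state crosses a
Hopf bifurcation under enrichment.  See `docs/methods.md` for the model,
parameter defaults and numerical choices.

## Worked example

Reconstruct the 12-dimensional Jacobian of the two-species, six-patch
metacommunity from a simulated noisy series (2×10⁵ samples, additive noise
σ = 0.01), using only the covariance, the noise matrix, and the structural
zeros implied by the multilayer topology:

```python
import numpy as np
import jacrec as jr
from jacrec.fixtures import asym6

net = asym6()                                     # 6-patch fixture graph
model = jr.rm_metacommunity_model(net)            # default K = 2.5 (stable)
ss = jr.find_steady_state(model, np.tile([0.8, 0.5], 6))
truth = jr.spectrum(jr.numeric_jacobian(model, ss))

pattern = jr.multilayer_zero_pattern(jr.MultilayerIndex(2, 6), net)
report = jr.sufficiency_check(pattern)
print(f"structural zeros: {report.count} (need {report.required}) -> "
      f"{'determined' if report.sufficient else 'underdetermined'}")

noise = jr.NoiseSpec("additive", 0.01)
series = jr.euler_maruyama(
    model, noise, jr.SimulationConfig(dt=0.1, n_samples=200_000, seed=0), ss.x
)
d = jr.fluctuation_from_noise(noise, ss.x)
rec = jr.reconstruct_from_series(series, pattern, d)
print(f"true leading eigenvalue:          {truth.leading:.4f} ({truth.tag})")
print(f"reconstructed leading eigenvalue: {rec.leading_eigenvalue:.4f} "
      f"({rec.bifurcation_tag})")
```

prints

```
structural zeros: 96 (need 66) -> determined
true leading eigenvalue:          -0.0528+0.2438j (complex-pair)
reconstructed leading eigenvalue: -0.0525+0.2205j (complex-pair)
```

The 96 topology-derived zeros (cross-layer plus non-adjacent-patch pairs)
exceed the 66 required, so the inversion is determined; the reconstructed
leading real part −0.0525 recovers the true −0.0528 to well within 1%,
i.e. the system is correctly diagnosed as stable but only ~0.05 inverse
time units away from instability.  Complex leading pair: the impending
transition is Hopf-type (onset of oscillations).

## Command line

The same pipeline is scriptable via the `jacrec` CLI:

```
jacrec simulate config.json -o series.tsv     # model + noise -> series + sidecar
jacrec reconstruct series.tsv --pattern p.json --fluctuation d.tsv -o report.json
jacrec ews series.tsv --pattern p.json --fluctuation d.tsv -o trajectory.tsv
jacrec check-pattern p.json                   # is the pattern sufficient?
jacrec fixtures asym6 --out fixtures/         # deterministic fixture files
```

Exit codes distinguish validation errors (2), underdetermined patterns (3),
degenerate inputs (4) and I/O failures (5); all formats are plain text
(TSV matrices/series, JSON patterns/reports, edge lists).

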