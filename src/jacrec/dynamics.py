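"""Ground-truth dynamical systems and noisy time-series generation.

Validation of the Jacobian reconstruction needs systems whose Jacobian is
known exactly.  Two families are provided:

- a linear (Ornstein--Uhlenbeck) test bed whose drift matrix *is* its
  Jacobian, for which the stationary covariance is known in closed form; and
- a Rosenzweig--MacArthur predator--prey metacommunity: Holling type II
  predation, logistic prey growth and quadratic predator mortality in each
  habitat patch, with diffusive dispersal of both species along the edges of
  a patch network.  Enrichment (raising the prey carrying capacity K) drives
  the coexistence state through a Hopf bifurcation, providing the critical
  transition the early-warning signal is tested against.

Noisy series are generated with the Euler--Maruyama scheme,

    x[k+1] = x[k] + f(x[k]) dt + sigma_eff(x[k]) sqrt(dt) xi[k],

with independent standard-normal ``xi``; additive noise has
``sigma_eff = sigma``, multiplicative ``sigma_eff = sigma * x``.  Under the
``J Gamma + Gamma J.T = -2 D`` normalization the matching fluctuation matrix
is ``D = diag(sigma**2) / 2`` (additive), so the simulated linear system
satisfies the Lyapunov relation exactly in the ``dt -> 0`` limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import scipy.optimize

from .constraints import MultilayerIndex, PatchNetwork
from .exceptions import (
    DimensionError,
    NonConvergenceError,
    RestartWarning,
    SimulationError,
    ValidationError,
)

__all__ = [
    "DynamicalModel",
    "SteadyState",
    "NoiseSpec",
    "SimulationConfig",
    "TimeSeries",
    "RampResult",
    "DEFAULT_RM_PARAMS",
    "linear_model",
    "rm_metacommunity_model",
    "rm_single_patch_model",
    "find_steady_state",
    "numeric_jacobian",
    "msf_spectrum",
    "laplacian_matrix",
    "euler_maruyama",
    "fluctuation_from_noise",
    "parameter_ramp",
]

# Rosenzweig-MacArthur defaults.  r: prey growth rate [1/time]; K: carrying
# capacity (the enrichment dial; Hopf near K ~ 3.1 with these values);
# a: attack rate; h: handling time; eps: conversion efficiency; m: linear
# predator mortality; g: quadratic predator mortality; delta_b/delta_c:
# prey/predator dispersal rates.  Equal dispersal keeps the homogeneous Hopf
# the first instability (no Turing mode can precede it).
DEFAULT_RM_PARAMS: dict[str, float] = {
    "r": 1.0,
    "K": 2.5,
    "a": 2.0,
    "h": 1.0,
    "eps": 0.5,
    "m": 0.3,
    "g": 0.05,
    "delta_b": 0.05,
    "delta_c": 0.05,
}


@dataclass(frozen=True)
class DynamicalModel:
    """Deterministic vector field ``dx/dt = rhs(x, params)`` with metadata."""

    dimension: int
    rhs: Callable[[np.ndarray, dict], np.ndarray]
    params: dict
    labels: tuple[str, ...]
    name: str = "model"
    nonnegative: bool = False

    def f(self, x: np.ndarray) -> np.ndarray:
        """Vector field at ``x`` under the model's current parameters."""
        return self.rhs(np.asarray(x, dtype=float), self.params)

    def with_params(self, **updates: float) -> "DynamicalModel":
        """Copy of the model with selected parameters replaced."""
        unknown = set(updates) - set(self.params)
        if unknown:
            raise ValidationError(f"unknown parameters {sorted(unknown)}")
        return replace(self, params={**self.params, **updates})


@dataclass(frozen=True)
class SteadyState:
    """Root of the vector field with its residual norm."""

    x: np.ndarray
    residual: float


@dataclass(frozen=True)
class NoiseSpec:
    """Driving-noise specification: mode and per-variable amplitudes.

    ``sigma`` has units variable/sqrt(time) for additive noise and 1/sqrt(time)
    for multiplicative noise; a scalar is broadcast across variables.
    """

    mode: str = "additive"
    sigma: float | np.ndarray = 0.01

    def __post_init__(self):
        if self.mode not in ("additive", "multiplicative"):
            raise ValidationError(f"unknown noise mode {self.mode!r}")
        if np.any(np.asarray(self.sigma) < 0):
            raise ValidationError("noise amplitudes must be nonnegative")

    def sigma_vector(self, n: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.sigma, dtype=float), (n,)).copy()


@dataclass(frozen=True)
class SimulationConfig:
    """Euler--Maruyama run configuration."""

    dt: float = 1e-2
    n_samples: int = 200_000
    stride: int = 1
    burn_in: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if self.n_samples < 2:
            raise ValidationError(f"need at least 2 samples, got {self.n_samples}")
        if self.stride < 1 or self.burn_in < 0:
            raise ValidationError("stride must be >= 1 and burn_in >= 0")


@dataclass(frozen=True)
class TimeSeries:
    """Sampled trajectory: monotone times, one column per variable."""

    times: np.ndarray
    values: np.ndarray
    labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.shape[0] != self.times.shape[0]:
            raise DimensionError(
                f"{self.values.shape[0]} rows vs {self.times.shape[0]} times"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def dimension(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class RampResult:
    """Output of :func:`parameter_ramp`: series plus the parameter trace."""

    series: TimeSeries
    parameter: str
    parameter_values: np.ndarray


# ---------------------------------------------------------------------------
# Model library
# ---------------------------------------------------------------------------


def linear_model(j: np.ndarray, labels: tuple[str, ...] | None = None) -> DynamicalModel:
    """Linear system ``dx/dt = J x``: an Ornstein--Uhlenbeck test bed.

    The steady state is the origin and the Jacobian equals ``J`` everywhere,
    so the stationary covariance of the noisy simulation is exactly the
    forward Lyapunov solution.
    """
    j = np.asarray(j, dtype=float)
    if j.ndim != 2 or j.shape[0] != j.shape[1]:
        raise DimensionError(f"drift matrix must be square, got {j.shape}")
    n = j.shape[0]
    if labels is None:
        labels = tuple(f"x{i}" for i in range(n))

    def rhs(x: np.ndarray, params: dict) -> np.ndarray:
        return params["_j"] @ x

    return DynamicalModel(n, rhs, {"_j": j}, tuple(labels), name="linear")


def _rm_rhs_factory(laplacian: np.ndarray | None):
    """Rosenzweig-MacArthur metacommunity right-hand side.

    Per patch p (prey b, predator c, Holling II functional response F):

        db/dt = r b (1 - b/K) - F(b) c + delta_b * sum_q A[p,q] (b_q - b_p)
        dc/dt = eps F(b) c - m c - g c**2 + delta_c * sum_q A[p,q] (c_q - c_p)

    with F(b) = a b / (1 + a h b); the dispersal sums equal ``-L @ b`` etc.
    for the graph Laplacian L.
    """

    def rhs(x: np.ndarray, p: dict) -> np.ndarray:
        b = x[0::2]
        c = x[1::2]
        fr = p["a"] * b / (1.0 + p["a"] * p["h"] * b)
        db = p["r"] * b * (1.0 - b / p["K"]) - fr * c
        dc = p["eps"] * fr * c - p["m"] * c - p["g"] * c * c
        if laplacian is not None:
            db = db - p["delta_b"] * (laplacian @ b)
            dc = dc - p["delta_c"] * (laplacian @ c)
        out = np.empty_like(x)
        out[0::2] = db
        out[1::2] = dc
        return out

    return rhs


def laplacian_matrix(net: PatchNetwork) -> np.ndarray:
    """Combinatorial graph Laplacian ``L = degree - adjacency`` (PSD)."""
    n = net.n_nodes
    lap = np.zeros((n, n))
    for u, v in net.edges:
        lap[u, u] += 1.0
        lap[v, v] += 1.0
        lap[u, v] -= 1.0
        lap[v, u] -= 1.0
    return lap


def rm_metacommunity_model(
    net: PatchNetwork, params: dict | None = None
) -> DynamicalModel:
    """Rosenzweig--MacArthur predator--prey metacommunity on a patch network.

    Two species (prey, predator) per patch, flattened species-fastest
    (prey of patch p at index ``2*p``, predator at ``2*p + 1``), diffusively
    coupled along the network edges with rates ``delta_b`` and ``delta_c``.
    Parameter defaults come from :data:`DEFAULT_RM_PARAMS`.
    """
    p = {**DEFAULT_RM_PARAMS, **(params or {})}
    for key in ("r", "K", "a", "h", "eps"):
        if p[key] <= 0:
            raise ValidationError(f"parameter {key} must be positive, got {p[key]}")
    for key in ("m", "g", "delta_b", "delta_c"):
        if p[key] < 0:
            raise ValidationError(f"parameter {key} must be nonnegative, got {p[key]}")
    npatch = net.n_nodes
    lap = laplacian_matrix(net) if npatch > 1 else None
    labels = []
    for patch in range(npatch):
        labels += [f"prey_p{patch}", f"pred_p{patch}"]
    return DynamicalModel(
        2 * npatch,
        _rm_rhs_factory(lap),
        p,
        tuple(labels),
        name=f"rm_metacommunity_P{npatch}",
        nonnegative=True,
    )


def rm_single_patch_model(params: dict | None = None) -> DynamicalModel:
    """Single-patch Rosenzweig--MacArthur model (dispersal terms vanish)."""
    return rm_metacommunity_model(PatchNetwork(1, []), params)


def rm_multilayer_index(net: PatchNetwork) -> MultilayerIndex:
    """Species/patch index of the two-species metacommunity on ``net``."""
    return MultilayerIndex(2, net.n_nodes)


# ---------------------------------------------------------------------------
# Steady states and Jacobians
# ---------------------------------------------------------------------------


def find_steady_state(
    model: DynamicalModel,
    x0: np.ndarray,
    tolerance: float = 1e-10,
) -> SteadyState:
    """Newton-type root of the vector field near ``x0``.

    Raises :class:`NonConvergenceError` when the residual stays above
    ``tolerance`` and :class:`ValidationError` when a nonnegative model
    converges to a state with negative components (reporting which).
    """
    x0 = np.asarray(x0, dtype=float)
    if not np.all(np.isfinite(x0)):
        raise ValidationError("initial guess contains non-finite values")
    sol = scipy.optimize.root(lambda x: model.f(x), x0, method="hybr", tol=1e-14)
    resid = float(np.linalg.norm(model.f(sol.x)))
    if not np.all(np.isfinite(sol.x)) or resid > tolerance:
        raise NonConvergenceError(
            f"steady-state search from {x0!r} did not converge "
            f"(residual {resid:.3g} > {tolerance:.3g}): {sol.message}"
        )
    if model.nonnegative and np.any(sol.x < -1e-9):
        bad = np.flatnonzero(sol.x < -1e-9).tolist()
        raise ValidationError(
            f"steady state has negative components at indices {bad}: "
            f"{sol.x[bad]!r}"
        )
    return SteadyState(sol.x, resid)


def numeric_jacobian(
    model: DynamicalModel,
    x: np.ndarray | SteadyState,
    step: float = 1e-6,
) -> np.ndarray:
    """Central finite-difference Jacobian at ``x`` (error O(step**2)).

    The per-variable step is ``step * max(1, |x_i|)``.
    """
    if isinstance(x, SteadyState):
        x = x.x
    x = np.asarray(x, dtype=float)
    n = x.size
    jac = np.empty((n, n))
    for col in range(n):
        h = step * max(1.0, abs(x[col]))
        e = np.zeros(n)
        e[col] = h
        jac[:, col] = (model.f(x + e) - model.f(x - e)) / (2.0 * h)
    return jac


def msf_spectrum(
    intra_jacobian: np.ndarray,
    coupling: np.ndarray,
    laplacian_eigenvalues: np.ndarray,
) -> np.ndarray:
    """Master-stability spectrum of a homogeneous state on a network.

    At a steady state replicated identically across P patches the full
    ``S*P x S*P`` Jacobian ``I_P (x) P_intra - L (x) diag(coupling)`` block
    diagonalizes over the Laplacian eigenmodes: its spectrum is the union of
    ``eig(P_intra - lam_k * diag(coupling))`` over Laplacian eigenvalues
    ``lam_k``.  Returns all ``S * P`` eigenvalues sorted by descending real
    part (ties by ascending |Im|, nonnegative Im first).
    """
    intra = np.asarray(intra_jacobian, dtype=float)
    coupling = np.asarray(coupling, dtype=float).reshape(-1)
    if intra.ndim != 2 or intra.shape[0] != intra.shape[1]:
        raise DimensionError(f"intra-patch Jacobian must be square, got {intra.shape}")
    if coupling.size != intra.shape[0]:
        raise DimensionError(
            f"{coupling.size} coupling rates for {intra.shape[0]} species"
        )
    evs = []
    for lam in np.asarray(laplacian_eigenvalues, dtype=float).reshape(-1):
        evs.append(np.linalg.eigvals(intra - lam * np.diag(coupling)))
    allev = np.concatenate(evs)
    order = sorted(
        range(allev.size),
        key=lambda k: (-allev[k].real, abs(allev[k].imag), -allev[k].imag),
    )
    return allev[order]


# ---------------------------------------------------------------------------
# Stochastic simulation
# ---------------------------------------------------------------------------

_NOISE_CHUNK = 65536


def _em_run(
    model: DynamicalModel,
    noise: NoiseSpec,
    config: SimulationConfig,
    x0: np.ndarray,
    rng: np.random.Generator,
    floor: float | None,
    param_schedule: tuple[str, np.ndarray] | None = None,
):
    """Single Euler-Maruyama attempt; returns samples or the violating step."""
    n = model.dimension
    sigma = noise.sigma_vector(n)
    multiplicative = noise.mode == "multiplicative"
    dt, stride, burn = config.dt, config.stride, config.burn_in
    sqdt = np.sqrt(dt)
    total = burn + (config.n_samples - 1) * stride
    out = np.empty((config.n_samples, n))
    params = dict(model.params)
    rhs = model.rhs
    pname, pvals = (None, None) if param_schedule is None else param_schedule

    x = np.asarray(x0, dtype=float).copy()
    if x.size != n:
        raise DimensionError(f"x0 has {x.size} entries for dimension {n}")
    k_out = 0
    if burn == 0:
        out[0] = x
        k_out = 1
    # the per-step guard is a single min(): NaN fails any comparison, and a
    # +inf state turns NaN within a step; a final isfinite sweep backstops it
    low = -np.inf if floor is None else floor
    step = 0
    while step < total:
        m = min(_NOISE_CHUNK, total - step)
        xi = rng.standard_normal((m, n))
        for r in range(m):
            if pname is not None:
                params[pname] = pvals[step]
            drift = rhs(x, params)
            if multiplicative:
                x = x + drift * dt + sigma * x * sqdt * xi[r]
            else:
                x = x + drift * dt + sigma * sqdt * xi[r]
            step += 1
            if not x.min() >= low:
                if not np.all(np.isfinite(x)):
                    raise SimulationError(
                        f"state became non-finite at step {step}"
                    )
                return None, step
            if step >= burn and (step - burn) % stride == 0:
                out[k_out] = x
                k_out += 1
    assert k_out == config.n_samples
    if not np.all(np.isfinite(out)):
        raise SimulationError("trajectory contains non-finite samples")
    return out, None


def euler_maruyama(
    model: DynamicalModel,
    noise: NoiseSpec,
    config: SimulationConfig,
    x0: np.ndarray,
    floor: float | None = None,
    max_restarts: int = 10,
    _param_schedule: tuple[str, np.ndarray] | None = None,
) -> TimeSeries:
    """Simulate the model with Euler--Maruyama and sample the trajectory.

    After ``burn_in`` steps every ``stride``-th state is retained until
    ``n_samples`` rows are collected; the run is reproducible from
    ``config.seed``.

    Fluctuation-based reconstruction assumes the trajectory stays in the
    linearization regime around the steady state, so for nonnegative models
    states are not clipped at zero: a run in which any variable crosses below
    ``floor`` (default 0 for nonnegative models, off otherwise) is discarded
    and re-seeded, up to ``max_restarts`` times, with a warning counting the
    restarts.  Clipping instead would bias the covariance.
    """
    if floor is None and model.nonnegative:
        floor = 0.0
    attempts = 0
    while True:
        rng = np.random.default_rng((config.seed, attempts))
        samples, bad_step = _em_run(
            model, noise, config, x0, rng, floor, _param_schedule
        )
        if samples is not None:
            break
        attempts += 1
        if attempts > max_restarts:
            raise SimulationError(
                f"simulation left the admissible region (floor {floor}) in "
                f"{max_restarts + 1} consecutive attempts (last at step {bad_step})"
            )
    if attempts:
        warnings.warn(
            f"simulation re-seeded {attempts} time(s) after crossing the "
            f"floor {floor}",
            RestartWarning,
            stacklevel=2,
        )
    times = config.dt * (config.burn_in + config.stride * np.arange(config.n_samples))
    meta = {
        "model": model.name,
        "seed": config.seed,
        "dt": config.dt,
        "stride": config.stride,
        "burn_in": config.burn_in,
        "noise_mode": noise.mode,
        "restarts": attempts,
        "params": {
            k: v for k, v in model.params.items() if not isinstance(v, np.ndarray)
        },
    }
    return TimeSeries(times, samples, model.labels, meta)


def fluctuation_from_noise(
    noise: NoiseSpec, xstar: np.ndarray | SteadyState | None = None, n: int | None = None
) -> np.ndarray:
    """Fluctuation matrix D implied by a noise specification.

    Under the ``J Gamma + Gamma J.T = -2 D`` normalization the simulated
    linear system matches the Lyapunov relation with ``D = diag(sigma**2)/2``
    for additive noise and ``D = diag((sigma * x*)**2)/2`` for multiplicative
    noise linearized at the steady state ``x*``.
    """
    if isinstance(xstar, SteadyState):
        xstar = xstar.x
    if noise.mode == "multiplicative":
        if xstar is None:
            raise ValidationError("multiplicative noise needs the steady state")
        xstar = np.asarray(xstar, dtype=float)
        sig = noise.sigma_vector(xstar.size) * xstar
    else:
        if n is None:
            if xstar is None:
                raise ValidationError("additive noise needs the dimension or x*")
            n = np.asarray(xstar).size
        sig = noise.sigma_vector(n)
    return np.diag(0.5 * sig ** 2)


def parameter_ramp(
    model: DynamicalModel,
    parameter: str,
    start: float,
    end: float,
    noise: NoiseSpec,
    config: SimulationConfig,
    x0: np.ndarray,
    floor: float | None = None,
    max_restarts: int = 10,
) -> RampResult:
    """Simulate while one parameter drifts linearly over the whole run.

    The parameter is interpolated linearly over all integration steps
    (burn-in included); the trace aligned with the retained samples is
    returned alongside the series.  With ``start == end`` the run is
    bit-identical to :func:`euler_maruyama` at that fixed parameter.
    """
    if parameter not in model.params:
        raise ValidationError(
            f"unknown parameter {parameter!r}; model has {sorted(model.params)}"
        )
    total = config.burn_in + (config.n_samples - 1) * config.stride
    sched = np.linspace(start, end, max(total, 1) + 1)
    series = euler_maruyama(
        model.with_params(**{parameter: float(start)}),
        noise,
        config,
        x0,
        floor=floor,
        max_restarts=max_restarts,
        _param_schedule=(parameter, sched),
    )
    keep = config.burn_in + config.stride * np.arange(config.n_samples)
    trace = sched[keep]
    series.meta["ramp"] = {"parameter": parameter, "start": start, "end": end}
    return RampResult(series, parameter, trace)
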