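"""Early-warning signals from reconstructed Jacobian eigenvalues.

The pipeline turns a fluctuation time series into an estimate of the leading
Jacobian eigenvalue: estimate the covariance, invert the Lyapunov relation
under the structural zero pattern, read off the spectrum.  As a driving
parameter approaches a bifurcation the reconstructed leading real part
approaches zero — the early-warning signal — and sliding windows trace this
drift through time on a single long run with slowly changing parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lyap_core
from .dynamics import (
    DynamicalModel,
    NoiseSpec,
    SimulationConfig,
    TimeSeries,
    euler_maruyama,
    find_steady_state,
    fluctuation_from_noise,
    numeric_jacobian,
)
from .exceptions import DimensionError, NonConvergenceError, ValidationError
from .lyap_core import ReconstructionResult, ZeroPattern, spectrum

__all__ = [
    "WindowSpec",
    "EWSTrajectory",
    "estimate_covariance",
    "reconstruct_from_series",
    "sliding_window_ews",
    "transect_experiment",
    "locate_bifurcation",
    "linear_trend",
    "plot_trajectory",
    "plot_transect",
]


def estimate_covariance(
    ts: TimeSeries | np.ndarray,
    center: str | np.ndarray = "mean",
) -> np.ndarray:
    """Sample covariance of the fluctuations, with the unbiased 1/(n-1) norm.

    ``center`` is either ``"mean"`` (sample mean, the default) or an explicit
    reference state (e.g. a known steady state) the fluctuations are measured
    about.  The result is symmetric positive semidefinite by construction.
    """
    values = ts.values if isinstance(ts, TimeSeries) else np.asarray(ts, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n = values.shape[0]
    if n < 2:
        raise ValidationError(f"need at least 2 samples, got {n}")
    if not np.all(np.isfinite(values)):
        raise ValidationError("time series contains non-finite values")
    if isinstance(center, str):
        if center != "mean":
            raise ValidationError(f"unknown centering {center!r}")
        mu = values.mean(axis=0)
    else:
        mu = np.asarray(center, dtype=float).reshape(-1)
        if mu.size != values.shape[1]:
            raise DimensionError(
                f"center has {mu.size} entries for {values.shape[1]} variables"
            )
    dx = values - mu
    return (dx.T @ dx) / (n - 1)


def reconstruct_from_series(
    ts: TimeSeries | np.ndarray,
    pattern: ZeroPattern,
    d: np.ndarray,
    center: str | np.ndarray = "mean",
    **options,
) -> ReconstructionResult:
    """Covariance estimation followed by constrained Jacobian reconstruction.

    Keyword options are forwarded to :func:`jacrec.lyap_core.reconstruct_jacobian`
    (``enforce_zeros``, ``constraint_weight``, ``solver``).
    """
    gamma = estimate_covariance(ts, center=center)
    n = ts.n_samples if isinstance(ts, TimeSeries) else np.asarray(ts).shape[0]
    return lyap_core.reconstruct_jacobian(
        gamma, d, pattern, n_samples=n, **options
    )


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: length and stride in samples, anchor placement."""

    length: int
    stride: int = 1
    placement: str = "end"  # "end" or "centre"

    def __post_init__(self):
        if self.length < 2:
            raise ValidationError(f"window length must be > 1, got {self.length}")
        if self.stride < 1:
            raise ValidationError(f"stride must be >= 1, got {self.stride}")
        if self.placement not in ("end", "centre"):
            raise ValidationError(f"placement must be 'end' or 'centre'")


@dataclass(frozen=True)
class EWSTrajectory:
    """Per-window reconstruction summaries along a series."""

    anchor_times: np.ndarray
    anchor_indices: np.ndarray
    leading_eigenvalues: np.ndarray  # complex
    residual_norms: np.ndarray
    window: WindowSpec
    parameter_values: np.ndarray | None = None

    def __len__(self) -> int:
        return self.anchor_times.size

    def to_frame(self) -> pd.DataFrame:
        data = {
            "anchor_time": self.anchor_times,
            "anchor_index": self.anchor_indices,
            "leading_re": self.leading_eigenvalues.real,
            "leading_im": self.leading_eigenvalues.imag,
            "residual_norm": self.residual_norms,
        }
        if self.parameter_values is not None:
            data["parameter"] = self.parameter_values
        return pd.DataFrame(data)


def sliding_window_ews(
    ts: TimeSeries,
    window: WindowSpec,
    pattern: ZeroPattern,
    d: np.ndarray,
    parameter_values: np.ndarray | None = None,
    **options,
) -> EWSTrajectory:
    """Reconstruct the Jacobian in a sliding window along the series.

    Each window is mean-centered individually, which removes the slow drift
    of the operating point when parameters are ramped during the run.  The
    anchor of a window is its last sample (``placement="end"``) or its middle
    sample (``"centre"``).  ``parameter_values`` (aligned with the series,
    e.g. from a parameter ramp) are sampled at the anchors when given.

    The noise matrix ``d`` is held fixed across windows: the noise
    specification is treated as known, and estimating a drifting ``D`` is out
    of scope.
    """
    n = ts.n_samples
    if window.length > n:
        raise ValidationError(
            f"window length {window.length} exceeds series length {n}"
        )
    if parameter_values is not None:
        parameter_values = np.asarray(parameter_values)
        if parameter_values.size != n:
            raise DimensionError(
                f"{parameter_values.size} parameter values for {n} samples"
            )
    starts = np.arange(0, n - window.length + 1, window.stride)
    anchors = np.empty(starts.size, dtype=np.intp)
    leads = np.empty(starts.size, dtype=complex)
    resids = np.empty(starts.size)
    for k, s in enumerate(starts):
        block = ts.values[s : s + window.length]
        res = lyap_core.reconstruct_jacobian(
            estimate_covariance(block),
            d,
            pattern,
            n_samples=window.length,
            **options,
        )
        anchors[k] = (
            s + window.length - 1 if window.placement == "end" else s + window.length // 2
        )
        leads[k] = res.leading_eigenvalue
        resids[k] = res.residual_norm
    return EWSTrajectory(
        anchor_times=ts.times[anchors],
        anchor_indices=anchors,
        leading_eigenvalues=leads,
        residual_norms=resids,
        window=window,
        parameter_values=None
        if parameter_values is None
        else parameter_values[anchors],
    )


def linear_trend(traj: EWSTrajectory) -> float:
    """Least-squares slope of the reconstructed leading real part over time."""
    t = traj.anchor_times
    y = traj.leading_eigenvalues.real
    t = t - t.mean()
    denom = float(t @ t)
    if denom == 0:
        return 0.0
    return float(t @ (y - y.mean())) / denom


# ---------------------------------------------------------------------------
# Transect experiments against ground truth
# ---------------------------------------------------------------------------


def transect_experiment(
    model_factory,
    grid: np.ndarray,
    noise: NoiseSpec,
    config: SimulationConfig,
    pattern: ZeroPattern,
    x0_guess: np.ndarray,
    seeds: tuple[int, ...] = (0,),
    **options,
) -> pd.DataFrame:
    """Reconstruction accuracy along a parameter transect with known truth.

    For each grid value the factory builds the model; the steady state is
    continued from the previous grid point, the exact Jacobian is taken by
    finite differences (the analytic ground truth), noisy series are simulated
    from the steady state for each seed, and the Jacobian is reconstructed
    from each series.

    Grid points whose steady state is unstable are flagged
    (``comparison_valid = False``): past the bifurcation the simulated system
    departs from the analytic steady state, so truth and estimate describe
    different states and their difference is not a reconstruction error.
    Points where the steady-state search fails are recorded with status
    ``"no-steady-state"`` and skipped.

    Returns a tidy frame with one row per (grid value, seed).
    """
    rows = []
    x_prev = np.asarray(x0_guess, dtype=float)
    for value in np.asarray(grid, dtype=float).reshape(-1):
        model: DynamicalModel = model_factory(value)
        try:
            ss = find_steady_state(model, x_prev)
        except (NonConvergenceError, ValidationError) as exc:
            for seed in seeds:
                rows.append(
                    {
                        "parameter": value,
                        "seed": seed,
                        "status": "no-steady-state",
                        "true_re": np.nan,
                        "true_im": np.nan,
                        "est_re": np.nan,
                        "est_im": np.nan,
                        "error_re": np.nan,
                        "stable": False,
                        "comparison_valid": False,
                    }
                )
            continue
        x_prev = ss.x
        truth = spectrum(numeric_jacobian(model, ss))
        stable = truth.leading.real < 0
        d = fluctuation_from_noise(noise, ss.x)
        for seed in seeds:
            cfg = SimulationConfig(
                dt=config.dt,
                n_samples=config.n_samples,
                stride=config.stride,
                burn_in=config.burn_in,
                seed=seed,
            )
            series = euler_maruyama(model, noise, cfg, ss.x)
            rec = reconstruct_from_series(series, pattern, d, **options)
            rows.append(
                {
                    "parameter": value,
                    "seed": seed,
                    "status": "ok",
                    "true_re": truth.leading.real,
                    "true_im": truth.leading.imag,
                    "est_re": rec.leading_eigenvalue.real,
                    "est_im": rec.leading_eigenvalue.imag,
                    "error_re": abs(rec.leading_eigenvalue.real - truth.leading.real),
                    "stable": stable,
                    "comparison_valid": stable,
                }
            )
    return pd.DataFrame(rows)


def locate_bifurcation(
    model_factory,
    lo: float,
    hi: float,
    x0_guess: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> float:
    """Bisect the parameter value where the true leading real part crosses zero.

    ``model_factory(value)`` must give a model whose steady state continues
    smoothly over ``[lo, hi]`` with a sign change of the leading eigenvalue's
    real part across the interval.
    """

    def lead_re(value: float, x_start: np.ndarray) -> tuple[float, np.ndarray]:
        model = model_factory(value)
        ss = find_steady_state(model, x_start)
        return spectrum(numeric_jacobian(model, ss)).leading.real, ss.x

    f_lo, x_lo = lead_re(lo, np.asarray(x0_guess, dtype=float))
    f_hi, _ = lead_re(hi, x_lo)
    if f_lo == 0:
        return lo
    if f_hi == 0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValidationError(
            f"no sign change of the leading eigenvalue on [{lo}, {hi}] "
            f"({f_lo:.3g} vs {f_hi:.3g})"
        )
    a, b, xa = lo, hi, x_lo
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        f_mid, x_mid = lead_re(mid, xa)
        if f_mid == 0 or (b - a) < tol:
            return mid
        if np.sign(f_mid) == np.sign(f_lo):
            a, xa, f_lo = mid, x_mid, f_mid
        else:
            b = mid
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# Optional plotting hooks (matplotlib imported lazily)
# ---------------------------------------------------------------------------


def plot_trajectory(traj: EWSTrajectory, ax=None, truth: np.ndarray | None = None):
    """Leading real part over time (or the ramped parameter when present).

    ``truth``, if given, is plotted as a reference line over the same
    abscissa.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = (
        traj.parameter_values
        if traj.parameter_values is not None
        else traj.anchor_times
    )
    ax.plot(x, traj.leading_eigenvalues.real, "o-", label="reconstructed")
    if truth is not None:
        ax.plot(x, truth, "-", color="k", lw=1, label="ground truth")
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel(
        "parameter" if traj.parameter_values is not None else "time"
    )
    ax.set_ylabel(r"Re $\lambda_{\max}$")
    ax.legend()
    return ax


def plot_transect(df: pd.DataFrame, ax=None):
    """Reconstructed vs analytic leading real part along a parameter transect.

    Unstable grid points (where the analytic steady state no longer describes
    the simulated dynamics) are shaded.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = df[df.status == "ok"]
    med = ok.groupby("parameter").agg(
        est=("est_re", "median"), true=("true_re", "first"), stable=("stable", "first")
    )
    ax.plot(med.index, med.true, "k-", label="analytic")
    ax.plot(med.index, med.est, "o", label="reconstructed (median)")
    unstable = med.index[~med.stable]
    if len(unstable):
        ax.axvspan(unstable.min(), med.index.max(), color="0.85", zorder=0)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("parameter")
    ax.set_ylabel(r"Re $\lambda_{\max}$")
    ax.legend()
    return ax
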