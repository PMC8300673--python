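"""Closed-form constrained reconstruction of a Jacobian from stationary fluctuations.

A linear stochastic system fluctuating about a stable steady state obeys the
continuous Lyapunov relation

    J @ Gamma + Gamma @ J.T == -2 * D,

where ``J`` is the Jacobian (drift) matrix, ``Gamma`` the stationary covariance
of the fluctuations and ``D`` the fluctuation (noise) matrix.  Read forward,
the relation yields ``Gamma`` from a known ``J`` (the validation oracle,
:func:`forward_lyapunov`).  Read backward it determines ``J`` from measured
``Gamma`` and ``D`` — but only up to the N(N+1)/2 constraints of a symmetric
matrix equation.  Structural zeros of ``J`` (pairs of variables that cannot
interact directly) supply the missing information: with at least N(N-1)/2 of
them the vectorized relation becomes an overdetermined linear least-squares
problem with a closed-form solution.

Vectorization is column-stacking throughout: ``vec(X)[k*N + i] == X[i, k]``.
All indices are 0-based; Jacobian row = affected variable, column = perturbed
variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg

from .exceptions import (
    AsymmetryWarning,
    DegenerateSystemError,
    DimensionError,
    UnderdeterminedWarning,
    UnstableSystemError,
    ValidationError,
)

__all__ = [
    "ZeroPattern",
    "DesignSystem",
    "LstsqSolution",
    "SpectrumResult",
    "ReconstructionResult",
    "vec",
    "unvec",
    "commutation_matrix",
    "build_design",
    "stack_constraints",
    "solve_reconstruction",
    "forward_lyapunov",
    "spectrum",
    "reconstruct_jacobian",
    "required_constraints",
]

# Relative asymmetry of a covariance above which we warn / refuse.  Sample
# covariances are symmetric by construction, so asymmetry beyond round-off
# signals a user error upstream.
ASYM_WARN_TOL = 1e-8
ASYM_FAIL_TOL = 1e-3

# |Im(lambda)| below this (relative to the eigenvalue scale) is treated as a
# real leading eigenvalue when tagging the bifurcation type.
REAL_EIG_TOL = 1e-8

# Dimension above which reconstruct_jacobian switches from a dense orthogonal
# least-squares factorization of the stacked system to the Kronecker-structured
# normal equations (Cholesky + iterative refinement); see _solve_structured.
_STRUCTURED_SOLVER_MIN_N = 24


def required_constraints(n: int) -> int:
    """Number of structural zeros needed for a determined reconstruction.

    The Lyapunov relation equates two symmetric matrices and therefore fixes
    only ``n*(n+1)//2`` of the ``n**2`` Jacobian entries; the deficit is
    ``n*(n-1)//2``.
    """
    return n * (n - 1) // 2


# ---------------------------------------------------------------------------
# Zero patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZeroPattern:
    """Set of Jacobian positions known to be structurally zero.

    Parameters
    ----------
    positions
        Ordered ``(row, col)`` pairs, 0-based.
    dimension
        Linear dimension N of the Jacobian the pattern refers to.
    """

    positions: tuple[tuple[int, int], ...]
    dimension: int

    def __init__(self, positions: Iterable[Sequence[int]], dimension: int):
        pos = tuple((int(i), int(j)) for i, j in positions)
        n = int(dimension)
        if n < 1:
            raise ValidationError(f"dimension must be >= 1, got {n}")
        seen = set()
        for i, j in pos:
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(
                    f"pattern entry ({i}, {j}) out of range for dimension {n}"
                )
            if (i, j) in seen:
                raise ValidationError(f"duplicate pattern entry ({i}, {j})")
            seen.add((i, j))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "dimension", n)

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self):
        return iter(self.positions)

    def __contains__(self, pos) -> bool:
        return tuple(pos) in set(self.positions)

    @property
    def vec_indices(self) -> np.ndarray:
        """Positions mapped to column-stacked vector indices ``j*N + i``."""
        n = self.dimension
        return np.array([j * n + i for i, j in self.positions], dtype=np.intp)

    def is_sufficient(self) -> bool:
        """Whether the pattern alone can make the inversion determined."""
        return len(self) >= required_constraints(self.dimension)

    def permuted(self, perm: Sequence[int]) -> "ZeroPattern":
        """Pattern after relabelling variable ``k`` as ``perm[k]``."""
        perm = list(perm)
        return ZeroPattern(
            [(perm[i], perm[j]) for i, j in self.positions], self.dimension
        )


# ---------------------------------------------------------------------------
# Vectorization and the commutation matrix
# ---------------------------------------------------------------------------


def vec(x: np.ndarray) -> np.ndarray:
    """Column-stacking vectorization of a square matrix.

    ``vec(X) = (X[0,0], X[1,0], ..., X[N-1,0], X[0,1], ...)``.
    """
    x = np.asarray(x)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise DimensionError(f"vec expects a square matrix, got shape {x.shape}")
    return x.reshape(-1, order="F")


def unvec(v: np.ndarray, n: int | None = None) -> np.ndarray:
    """Inverse of :func:`vec`: reshape a length-``n**2`` vector to ``n x n``."""
    v = np.asarray(v).reshape(-1)
    if n is None:
        n = int(round(np.sqrt(v.size)))
    if n * n != v.size:
        raise DimensionError(
            f"vector of length {v.size} is not a vectorized {n}x{n} matrix"
        )
    return v.reshape((n, n), order="F")


def commutation_matrix(n: int) -> np.ndarray:
    """Permutation matrix ``C`` with ``C @ vec(X) == vec(X.T)`` for N x N ``X``.

    Blockwise, ``C[n*N:(n+1)*N, m*N:(m+1)*N][i, j] = delta(i, m) * delta(n, j)``.
    ``C`` is symmetric and self-inverse.
    """
    n = int(n)
    if n < 1:
        raise DimensionError(f"commutation matrix needs n >= 1, got {n}")
    c = np.zeros((n * n, n * n))
    # vec(X)[j*n+i] = X[i,j] maps to vec(X.T)[i*n+j]
    idx = np.arange(n * n)
    i, j = idx % n, idx // n
    c[i * n + j, idx] = 1.0
    return c


def _transpose_perm(n: int) -> np.ndarray:
    """Permutation p with vec(X.T) = vec(X)[p] (index form of the commutation)."""
    idx = np.arange(n * n)
    i, j = idx % n, idx // n
    return j + i * n


# ---------------------------------------------------------------------------
# Design system
# ---------------------------------------------------------------------------


def _check_symmetric(gamma: np.ndarray, what: str = "covariance") -> np.ndarray:
    """Validate symmetry and return the symmetrized matrix."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
        raise DimensionError(f"{what} must be square, got shape {gamma.shape}")
    scale = np.linalg.norm(gamma)
    asym = np.linalg.norm(gamma - gamma.T)
    rel = asym / scale if scale > 0 else 0.0
    if rel > ASYM_FAIL_TOL:
        raise ValidationError(
            f"{what} asymmetric beyond tolerance (relative asymmetry {rel:.2e})"
        )
    if rel > ASYM_WARN_TOL:
        warnings.warn(
            f"{what} asymmetric (relative asymmetry {rel:.2e}); symmetrized",
            AsymmetryWarning,
            stacklevel=3,
        )
    return 0.5 * (gamma + gamma.T)


def build_design(gamma: np.ndarray) -> np.ndarray:
    """Design matrix ``B = Gamma (x) I + (I (x) Gamma) C`` of the vectorized relation.

    Satisfies ``B @ vec(J) == vec(J @ Gamma + Gamma @ J.T)`` for every N x N
    ``J``; ``(x)`` is the Kronecker product and ``C`` the commutation matrix.
    """
    gamma = _check_symmetric(gamma)
    n = gamma.shape[0]
    eye = np.eye(n)
    b = np.kron(gamma, eye)
    # right-multiplying by C permutes columns with the transpose permutation
    b[:, _transpose_perm(n)] += np.kron(eye, gamma)
    return b


@dataclass(frozen=True)
class DesignSystem:
    """Stacked least-squares system ``design @ j ~= rhs``.

    The top ``dimension**2`` rows are the data block ``B``; below them sit one
    elementary row per structural zero (a single 1 in the vec-position of the
    constrained entry, scaled by ``constraint_weight``), with rhs 0.
    """

    design: np.ndarray
    rhs: np.ndarray
    dimension: int
    pattern: ZeroPattern
    constraint_weight: float = 1.0

    @property
    def n_data_rows(self) -> int:
        return self.dimension ** 2


def stack_constraints(
    b: np.ndarray,
    d: np.ndarray,
    pattern: ZeroPattern,
    constraint_weight: float = 1.0,
) -> DesignSystem:
    """Append structural-zero rows to the data block.

    Parameters
    ----------
    b
        Data block, ``N**2 x N**2`` (from :func:`build_design`).
    d
        Right-hand side of the data block, i.e. ``-2 * vec(D)``.
    pattern
        Structural zeros; each contributes an elementary row forcing the
        corresponding entry of ``vec(J)`` toward zero.
    constraint_weight
        Scalar weight of the constraint rows in the least-squares stack
        (default 1, i.e. plain unweighted rows in the stack).
    """
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float).reshape(-1)
    n2 = b.shape[1]
    n = int(round(np.sqrt(n2)))
    if b.shape != (n2, n2) or n * n != n2:
        raise DimensionError(f"design block must be N^2 x N^2, got {b.shape}")
    if d.size != n2:
        raise DimensionError(f"rhs length {d.size} does not match design {b.shape}")
    if pattern.dimension != n:
        raise ValidationError(
            f"pattern dimension {pattern.dimension} does not match system size {n}"
        )
    m = len(pattern)
    u = np.zeros((m, n2))
    if m:
        u[np.arange(m), pattern.vec_indices] = constraint_weight
    design = np.vstack([b, u])
    rhs = np.concatenate([d, np.zeros(m)])
    return DesignSystem(design, rhs, n, pattern, constraint_weight)


# ---------------------------------------------------------------------------
# Least-squares solve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LstsqSolution:
    """Least-squares solution of a :class:`DesignSystem`."""

    j: np.ndarray
    residual_norm: float
    rank: int
    rank_deficient: bool


def solve_reconstruction(system: DesignSystem) -> LstsqSolution:
    """Minimize ``||design @ j - rhs||`` over ``j`` (vectorized Jacobian).

    Uses an SVD-based orthogonal factorization; on full-column-rank systems the
    result coincides with the normal-equations closed form
    ``(B^T B)^-1 B^T d`` to numerical tolerance, and on rank-deficient systems
    the minimum-norm solution is returned with ``rank_deficient`` set.
    ``residual_norm`` is measured over the data rows only (the fit to the
    Lyapunov relation, excluding the constraint rows).
    """
    a = np.asarray(system.design, dtype=float)
    if not np.any(a):
        raise DegenerateSystemError("design matrix is identically zero")
    j, _, rank, _ = scipy.linalg.lstsq(a, system.rhs, lapack_driver="gelsd")
    nd = system.n_data_rows
    resid = float(np.linalg.norm(a[:nd] @ j - system.rhs[:nd]))
    return LstsqSolution(j, resid, int(rank), rank < a.shape[1])


def _solve_structured(
    gamma: np.ndarray,
    d_vec: np.ndarray,
    pattern: ZeroPattern,
    constraint_weight: float,
    refine_steps: int = 2,
) -> LstsqSolution | None:
    """Solve the stacked least squares via Kronecker-structured normal equations.

    With ``B = Gamma (x) I + (I (x) Gamma) C`` and symmetric ``Gamma``,

        B^T B = 2 (Gamma^2 (x) I) + (Gamma (x) Gamma) C + C (Gamma (x) Gamma)

    and the constraint block adds ``w**2`` on the diagonal at constrained
    vec-positions, so the (N^2 x N^2) normal matrix is assembled in O(N^4)
    without forming the stacked system.  A Cholesky solve plus a couple of
    iterative-refinement sweeps (residuals evaluated exactly through the
    Lyapunov form, O(N^3) each) recovers orthogonal-factorization accuracy at
    a fraction of the cost for large N.  Returns ``None`` when the normal
    matrix is not positive definite (underdetermined pattern); callers then
    fall back to the dense minimum-norm path.
    """
    n = gamma.shape[0]
    n2 = n * n
    # (Gamma (x) Gamma) C in 4-index form [p,k,j,i] = G[p,i] G[k,j]; its
    # transpose is C (Gamma (x) Gamma); the first term is block-diagonal.
    m1 = np.einsum("pi,kj->pkji", gamma, gamma)
    a = m1 + m1.transpose(2, 3, 0, 1)
    g2 = 2.0 * (gamma @ gamma)
    for i in range(n):
        a[:, i, :, i] += g2
    a = a.reshape(n2, n2)
    idx = pattern.vec_indices
    a[idx, idx] += constraint_weight ** 2

    # rhs of the normal equations: B^T d with d = -2 vec(D)
    dmat = unvec(d_vec, n)
    b_rhs = vec(dmat @ gamma + dmat.T @ gamma)

    try:
        cho = scipy.linalg.cho_factor(a, check_finite=False)
    except np.linalg.LinAlgError:
        return None
    except scipy.linalg.LinAlgError:  # pragma: no cover - alias on some scipy
        return None
    j = scipy.linalg.cho_solve(cho, b_rhs, check_finite=False)

    def normal_residual(jv: np.ndarray) -> np.ndarray:
        jm = unvec(jv, n)
        bj = vec(jm @ gamma + gamma @ jm.T)  # B @ j
        r = bj - d_vec
        bt_r = vec(unvec(r, n) @ gamma + unvec(r, n).T @ gamma)  # B^T r
        bt_r[idx] += (constraint_weight ** 2) * jv[idx]
        return bt_r

    for _ in range(refine_steps):
        j = j - scipy.linalg.cho_solve(cho, normal_residual(j), check_finite=False)

    jm = unvec(j, n)
    resid = float(np.linalg.norm(vec(jm @ gamma + gamma @ jm.T) - d_vec))
    return LstsqSolution(j, resid, n2, False)


# ---------------------------------------------------------------------------
# Forward oracle and spectrum
# ---------------------------------------------------------------------------


def forward_lyapunov(j: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Stationary covariance of the linear system with drift ``J`` and noise ``D``.

    Solves ``J @ Gamma + Gamma @ J.T = -2 D`` for ``Gamma``.  Requires ``J``
    Hurwitz (all eigenvalue real parts negative); otherwise no stationary
    covariance exists and :class:`UnstableSystemError` is raised.
    """
    j = np.asarray(j, dtype=float)
    d = np.asarray(d, dtype=float)
    if j.ndim != 2 or j.shape[0] != j.shape[1]:
        raise DimensionError(f"Jacobian must be square, got shape {j.shape}")
    if d.shape != j.shape:
        raise DimensionError(
            f"fluctuation matrix shape {d.shape} does not match Jacobian {j.shape}"
        )
    max_re = float(np.max(np.linalg.eigvals(j).real))
    if max_re >= 0:
        raise UnstableSystemError(
            f"Jacobian is not Hurwitz (max eigenvalue real part {max_re:.3g}); "
            "no stationary covariance exists"
        )
    gamma = scipy.linalg.solve_continuous_lyapunov(j, -2.0 * d)
    gamma = 0.5 * (gamma + gamma.T)
    resid = np.linalg.norm(j @ gamma + gamma @ j.T + 2.0 * d)
    if resid > 1e-10 * max(np.linalg.norm(d), 1e-300):
        raise ValidationError(
            f"Lyapunov solve residual {resid:.3g} exceeds tolerance; "
            "system may be near-singular"
        )
    return gamma


@dataclass(frozen=True)
class SpectrumResult:
    """Eigenvalues sorted by descending real part, with bifurcation-type tag."""

    eigenvalues: np.ndarray
    leading: complex
    tag: str  # "real" (fold-type) or "complex-pair" (Hopf-type)


def spectrum(j: np.ndarray) -> SpectrumResult:
    """Eigenvalues of ``J`` in deterministic order plus the leading one.

    Order: descending real part, ties by ascending ``|Im|``, conjugates with
    nonnegative imaginary part first.  The tag distinguishes a real leading
    eigenvalue (fold-type instability when it crosses zero) from a complex
    pair (Hopf-type).
    """
    j = np.asarray(j, dtype=float)
    if not np.all(np.isfinite(j)):
        raise ValidationError("Jacobian contains non-finite entries")
    ev = np.linalg.eigvals(j)
    order = sorted(range(len(ev)), key=lambda k: (-ev[k].real, abs(ev[k].imag), -ev[k].imag))
    ev = ev[order]
    leading = complex(ev[0])
    scale = max(1.0, abs(leading))
    tag = "real" if abs(leading.imag) <= REAL_EIG_TOL * scale else "complex-pair"
    return SpectrumResult(ev, leading, tag)


# ---------------------------------------------------------------------------
# Full reconstruction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReconstructionResult:
    """Output of :func:`reconstruct_jacobian`."""

    jacobian: np.ndarray
    residual_norm: float
    rank_deficient: bool
    eigenvalues: np.ndarray
    leading_eigenvalue: complex
    bifurcation_tag: str
    zeros_enforced: bool
    underdetermined: bool
    n_constraints: int
    n_samples: int | None = None

    def to_dict(self) -> dict:
        """JSON-serializable report."""
        return {
            "jacobian": self.jacobian.tolist(),
            "residual_norm": self.residual_norm,
            "rank_flag": "rank-deficient" if self.rank_deficient else "full-rank",
            "eigenvalues": [[z.real, z.imag] for z in self.eigenvalues],
            "leading_eigenvalue": [
                self.leading_eigenvalue.real,
                self.leading_eigenvalue.imag,
            ],
            "bifurcation_tag": self.bifurcation_tag,
            "zeros_enforced": self.zeros_enforced,
            "underdetermined": self.underdetermined,
            "n_constraints": self.n_constraints,
            "n_samples": self.n_samples,
        }


def reconstruct_jacobian(
    gamma: np.ndarray,
    d: np.ndarray,
    pattern: ZeroPattern,
    enforce_zeros: bool = True,
    constraint_weight: float = 1.0,
    solver: str = "auto",
    n_samples: int | None = None,
) -> ReconstructionResult:
    """Reconstruct the Jacobian from covariance, noise matrix and structural zeros.

    Orchestrates the closed-form pipeline: build the vectorized design
    ``B = Gamma (x) I + (I (x) Gamma) C``, stack one elementary row per
    structural zero, solve the least-squares system with rhs
    ``(-2 vec(D), 0)``, and reshape the solution.  With ``enforce_zeros``
    (default), constrained entries are set exactly to zero afterwards, which
    in practice improves the accuracy of the reconstructed eigenvalues.

    Parameters
    ----------
    gamma
        Measured stationary covariance (symmetric within tolerance).
    d
        Fluctuation matrix of the driving noise (symmetric PSD).
    pattern
        Structural zeros of the Jacobian.  Fewer than ``N(N-1)/2`` of them
        leave the system underdetermined; a warning is issued and the
        minimum-norm solution returned.
    constraint_weight
        Weight of constraint rows in the stack (default 1).
    solver
        ``"auto"`` (structured normal equations for large N, dense orthogonal
        factorization otherwise), ``"lstsq"`` or ``"normal"``.
    n_samples
        Optional sample count the covariance was estimated from (propagated
        into the result for reporting).
    """
    gamma = _check_symmetric(gamma)
    n = gamma.shape[0]
    d = np.asarray(d, dtype=float)
    if d.shape != gamma.shape:
        raise DimensionError(
            f"fluctuation matrix shape {d.shape} does not match covariance {gamma.shape}"
        )
    if pattern.dimension != n:
        raise ValidationError(
            f"pattern dimension {pattern.dimension} does not match system size {n}"
        )
    if solver not in ("auto", "lstsq", "normal"):
        raise ValueError(f"unknown solver {solver!r}")
    if not np.any(gamma):
        raise DegenerateSystemError(
            "covariance is identically zero (degenerate input: constant or "
            "noiseless series carries no fluctuation information)"
        )

    underdetermined = not pattern.is_sufficient()
    if underdetermined:
        warnings.warn(
            f"{len(pattern)} structural zeros < {required_constraints(n)} required "
            f"for N={n}: reconstruction is underdetermined (minimum-norm solution)",
            UnderdeterminedWarning,
            stacklevel=2,
        )

    d_vec = -2.0 * vec(d)
    sol: LstsqSolution | None = None
    use_structured = solver == "normal" or (
        solver == "auto" and n >= _STRUCTURED_SOLVER_MIN_N and not underdetermined
    )
    if use_structured:
        sol = _solve_structured(gamma, d_vec, pattern, constraint_weight)
    if sol is None:
        system = stack_constraints(build_design(gamma), d_vec, pattern, constraint_weight)
        sol = solve_reconstruction(system)

    jac = unvec(sol.j, n)
    if enforce_zeros and len(pattern):
        rows, cols = zip(*pattern.positions)
        jac[list(rows), list(cols)] = 0.0
    spec = spectrum(jac)
    return ReconstructionResult(
        jacobian=jac,
        residual_norm=sol.residual_norm,
        rank_deficient=sol.rank_deficient or underdetermined,
        eigenvalues=spec.eigenvalues,
        leading_eigenvalue=spec.leading,
        bifurcation_tag=spec.tag,
        zeros_enforced=bool(enforce_zeros),
        underdetermined=underdetermined,
        n_constraints=len(pattern),
        n_samples=n_samples,
    )
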