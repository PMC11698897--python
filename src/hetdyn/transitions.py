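"""Conservative transition matrices and their spectral analysis.

The linear part of the model is ``A x`` where ``A`` has non-negative
off-diagonal entries (transition rates between cell types) and zero column
sums (cell flow out of each type equals flow into other types), i.e.
``1^T A = 0^T``.  Two consequences drive everything downstream:

* the spectrum of ``A`` lies in the closed left half-plane and 0 is always
  an eigenvalue (Gershgorin disks centered at the non-positive diagonal
  entries all touch the origin);
* when the zero eigenvalue is simple, the normalized right null vector is
  the stationary cell-type distribution, the limit composition of the
  linear flow.

The Yakubovich convergence criterion consumes three spectral integers from
``A``: the largest real part ``mu`` (always 0 here), the largest algebraic
multiplicity ``m`` among eigenvalues attaining ``mu``, and the largest
multiplicity ``q`` among purely neutral eigenvalues; the polynomial degree
in the criterion is ``p = m + q - 2``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "DegenerateTransitionError",
    "ValidationReport",
    "SpectralSummary",
    "transition_matrix",
    "validate_transition_matrix",
    "spectral_summary",
    "gershgorin_disks",
    "stationary_distribution",
    "random_transition_matrix",
]


class DegenerateTransitionError(ValueError):
    """Raised when the zero eigenvalue of A is not (numerically) simple."""


@dataclasses.dataclass(frozen=True)
class ValidationReport:
    """Violations of the conservative-matrix contract (empty report == valid)."""

    negative_offdiagonal: tuple[tuple[int, int, float], ...]
    column_sum_errors: tuple[tuple[int, float], ...]

    @property
    def ok(self) -> bool:
        return not self.negative_offdiagonal and not self.column_sum_errors


@dataclasses.dataclass(frozen=True)
class SpectralSummary:
    """Eigenvalues of A with the multiplicities entering the Yakubovich bound."""

    eigenvalues: tuple[complex, ...]
    mu: float
    m: int
    q: int

    @property
    def p(self) -> int:
        return self.m + self.q - 2


def transition_matrix(n: int, off_diagonal) -> np.ndarray:
    """Build A from off-diagonal rate triples ``(i, j, rate)``.

    The diagonal is derived (``a_jj = -sum_i a_ij``) so the column-sum
    condition holds exactly by construction.
    """
    A = np.zeros((n, n), dtype=float)
    for i, j, rate in off_diagonal:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError(f"diagonal entry ({i},{j}) may not be specified; it is derived")
        if not 0 <= i < n and 0 <= j < n:
            raise ValueError(f"index ({i},{j}) out of range for n={n}")
        if rate < 0:
            raise ValueError(f"off-diagonal rate A[{i},{j}]={rate} must be non-negative")
        A[i, j] = float(rate)
    np.fill_diagonal(A, 0.0)
    A[np.diag_indices(n)] = -A.sum(axis=0)
    return A


def validate_transition_matrix(A, tol: float = 1e-12) -> ValidationReport:
    """Check non-negative off-diagonals and zero column sums."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {A.shape}")
    n = A.shape[0]
    negative = tuple(
        (int(i), int(j), float(A[i, j]))
        for i in range(n)
        for j in range(n)
        if i != j and A[i, j] < 0
    )
    colsums = A.sum(axis=0)
    bad_cols = tuple(
        (int(j), float(colsums[j])) for j in range(n) if abs(colsums[j]) > tol
    )
    return ValidationReport(negative_offdiagonal=negative, column_sum_errors=bad_cols)


def _cluster_sizes(eigs: np.ndarray, tol: float) -> list[tuple[complex, int]]:
    """Greedy clustering of eigenvalues within ``tol``; returns (center, size).

    Algebraic multiplicity is not robustly computable in floating point;
    cluster size is the standard surrogate.
    """
    k = len(eigs)
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(k):
        for b in range(a + 1, k):
            if abs(eigs[a] - eigs[b]) <= tol:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for a in range(k):
        groups.setdefault(find(a), []).append(a)
    return [(complex(np.mean(eigs[idx])), len(idx)) for idx in groups.values()]


def spectral_summary(A, cluster_tol: float | None = None) -> SpectralSummary:
    """Eigenvalues plus (mu, m, q) with tolerance-based eigenvalue clustering.

    Raises ``ValueError`` when the spectrum contradicts the conservative
    structure (an eigenvalue with real part significantly above 0, or no
    eigenvalue near 0), which signals an invalid input matrix.
    """
    A = np.asarray(A, dtype=float)
    eigs = np.linalg.eigvals(A)
    norm1 = float(np.abs(A).sum(axis=0).max()) if A.size else 0.0
    tol = cluster_tol if cluster_tol is not None else 1e-7 * max(1.0, norm1)

    mu = float(eigs.real.max())
    if mu > tol:
        raise ValueError(f"eigenvalue with positive real part {mu:.3e} exceeds tolerance {tol:.1e}")
    if float(np.abs(eigs).min()) > tol:
        raise ValueError("no eigenvalue near 0; matrix is not conservative")

    clusters = _cluster_sizes(eigs, tol)
    m = max(size for center, size in clusters if center.real >= mu - tol)
    neutral = [size for center, size in clusters if abs(center.real) <= tol]
    q = max(neutral) if neutral else 1
    return SpectralSummary(eigenvalues=tuple(map(complex, eigs)), mu=mu, m=m, q=q)


def gershgorin_disks(A) -> list[tuple[float, float]]:
    """Column Gershgorin disks ``(center, radius)`` containing the spectrum."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    disks = []
    for j in range(n):
        radius = float(sum(abs(A[i, j]) for i in range(n) if i != j))
        disks.append((float(A[j, j]), radius))
    return disks


def stationary_distribution(A, *, gap_factor: float = 1e3) -> np.ndarray:
    """Normalized right null vector pi of A (A pi = 0, pi >= 0, sum pi = 1).

    Computed from the singular vector of the smallest singular value, which
    is more robust than eigendecomposition near defectiveness.  Fails with
    :class:`DegenerateTransitionError` when the null space is not
    numerically one-dimensional (second-smallest singular value less than
    ``gap_factor`` times the smallest), e.g. for reducible chains split into
    independent components.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if n == 1:
        return np.array([1.0])
    _, s, Vt = np.linalg.svd(A)
    scale = max(1.0, float(s[0]))
    if s[-2] < max(gap_factor * s[-1], 1e-12 * scale):
        raise DegenerateTransitionError(
            f"zero eigenvalue of A is not simple (singular values {s[-2]:.3e}, {s[-1]:.3e})"
        )
    v = Vt[-1]
    if v.sum() < 0:
        v = -v
    if v.min() < -1e-8 * max(1.0, abs(v).max()):
        raise DegenerateTransitionError("null vector of A is not sign-consistent")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def random_transition_matrix(
    n: int,
    density: float = 1.0,
    rate_scale: float = 1.0,
    seed=None,
    *,
    require_simple: bool = True,
    rng: np.random.Generator | None = None,
    max_tries: int = 200,
) -> np.ndarray:
    """Seeded random conservative matrix for scenario generation and tests.

    Off-diagonal rates are uniform on ``[0.2, 2] * rate_scale``, zeroed with
    probability ``1 - density``; diagonals are derived.  By default samples
    are rejected until the zero eigenvalue is simple.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        M = rng.uniform(0.2, 2.0, size=(n, n)) * rate_scale
        M *= rng.random(size=(n, n)) < density
        np.fill_diagonal(M, 0.0)
        A = M.copy()
        A[np.diag_indices(n)] = -M.sum(axis=0)
        if not require_simple:
            return A
        try:
            stationary_distribution(A)
        except DegenerateTransitionError:
            continue
        return A
    raise RuntimeError(
        f"no transition matrix with simple zero eigenvalue found in {max_tries} draws "
        f"(n={n}, density={density})"
    )
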