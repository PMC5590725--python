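"""Gaussian graphical model (GGM) primitives.

A GGM encodes conditional-independence structure of a multivariate normal
vector in the zeros of its precision (inverse covariance) matrix Omega:
variables j and j' share an edge iff Omega[j, j'] != 0.  The scaled negative
off-diagonal entries are partial correlations,

    rho_{jj'} = -Omega_{jj'} / sqrt(Omega_{jj} * Omega_{j'j'}),

the correlations between pairs of variables conditional on all remaining ones.

This module provides the shared primitives: covariance estimation, the
graphical lasso (l1-penalized sparse precision estimation), maximum
likelihood on a fixed sparsity pattern, the Gaussian log-likelihood,
partial correlations, per-group standardization and merging of highly
correlated variables.

Conventions, fixed once for the whole package:

* Covariance matrices use maximum-likelihood 1/n scaling.  This keeps
  likelihood-ratio algebra exact (twice the fitted log-likelihood difference
  is the LRT statistic without correction factors).
* ``standardize_by_group`` divides by the (n-1)-denominator sample standard
  deviation, matching the convention of common preprocessing tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import cho_solve
from scipy.optimize import minimize
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

# Numerical tolerances used across the package.
SYMMETRY_TOL = 1e-10
PD_EIG_TOL = 1e-8
ACTIVE_TOL = 1e-8
GLASSO_TOL = 1e-4
GLASSO_MAX_ITER = 100

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DataMatrix:
    """An n x p continuous data matrix with named variables.

    Parameters
    ----------
    values
        Sample-by-variable matrix; no missing values allowed.
    variable_names
        Unique names for the p columns.
    sample_labels
        Optional per-sample group identifiers (known groups, e.g. cancer
        types); ``None`` for unlabeled data.
    """

    values: np.ndarray
    variable_names: list[str] = field(default_factory=list)
    sample_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValueError(f"need n >= 2 and p >= 2, got n={n}, p={p}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            r, c = bad[0]
            raise ValueError(
                f"non-finite value at row {r}, column {c} "
                f"({len(bad)} non-finite cells in total)"
            )
        if not self.variable_names:
            self.variable_names = [f"V{j}" for j in range(p)]
        if len(self.variable_names) != p:
            raise ValueError("variable_names length must equal number of columns")
        if len(set(self.variable_names)) != p:
            raise ValueError("variable_names must be unique")
        if self.sample_labels is not None:
            self.sample_labels = np.asarray(self.sample_labels)
            if len(self.sample_labels) != n:
                raise ValueError("sample_labels length must equal number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class GGMFit:
    """A fitted Gaussian graphical model for one group.

    ``active_set`` holds the unordered off-diagonal index pairs (j < j') with
    nonzero precision entries; diagonal entries are always free.
    """

    mu: np.ndarray
    omega: np.ndarray
    active_set: frozenset[tuple[int, int]]
    loglik: float
    lam: float = 0.0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        check_precision(self.omega)
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")

    @property
    def p(self) -> int:
        return self.omega.shape[0]


def check_precision(omega: np.ndarray, eig_tol: float = PD_EIG_TOL) -> None:
    """Validate that ``omega`` is symmetric positive definite."""
    omega = np.asarray(omega)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError("precision matrix must be square")
    if not np.allclose(omega, omega.T, atol=SYMMETRY_TOL, rtol=0.0):
        raise ValueError("precision matrix is not symmetric")
    w = np.linalg.eigvalsh(omega)
    if w[0] <= eig_tol:
        raise ValueError(
            f"precision matrix is not positive definite (min eigenvalue {w[0]:.3e})"
        )


def active_set_of(omega: np.ndarray, tol: float = ACTIVE_TOL) -> frozenset[tuple[int, int]]:
    """Off-diagonal sparsity pattern of a precision matrix as unordered pairs."""
    omega = np.asarray(omega)
    p = omega.shape[0]
    pairs = [
        (j, jp)
        for j in range(p)
        for jp in range(j + 1, p)
        if abs(omega[j, jp]) > tol
    ]
    return frozenset(pairs)


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def standardize_by_group(data: DataMatrix, groups: Sequence | None = None) -> DataMatrix:
    """Z-score every variable within every group.

    After this step each variable has zero mean and unit (n-1)-denominator
    standard deviation within each group, so downstream network comparisons
    concern dependence structure rather than differential abundance.
    """
    if groups is None:
        groups = data.sample_labels
    if groups is None:
        raise ValueError("no group labels supplied")
    groups = np.asarray(groups)
    if len(groups) != data.n:
        raise ValueError("groups length must equal number of samples")
    out = np.empty_like(data.values)
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        block = data.values[mask]
        sd = block.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"zero variance for variable {data.variable_names[zero[0]]!r} "
                f"in group {g!r}"
            )
        out[mask] = (block - block.mean(axis=0)) / sd
    return DataMatrix(out, list(data.variable_names), groups.copy())


def sample_covariance(data: DataMatrix | np.ndarray) -> np.ndarray:
    """Maximum-likelihood (1/n) covariance of the columns, centered at the mean."""
    X = data.values if isinstance(data, DataMatrix) else np.asarray(data, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / X.shape[0]
    return (S + S.T) / 2.0


def second_moment(X: np.ndarray) -> np.ndarray:
    """Uncentered 1/n second-moment matrix (the MLE covariance when mu = 0)."""
    X = np.asarray(X, dtype=float)
    S = X.T @ X / X.shape[0]
    return (S + S.T) / 2.0


# ---------------------------------------------------------------------------
# Likelihood and estimation
# ---------------------------------------------------------------------------

def gaussian_loglik(data: DataMatrix | np.ndarray, mu: np.ndarray, omega: np.ndarray) -> float:
    """Multivariate normal log-likelihood of the rows of ``data``.

    sum_i [ 0.5 log det(Omega) - (p/2) log 2*pi
            - 0.5 (x_i - mu)^T Omega (x_i - mu) ]
    """
    X = data.values if isinstance(data, DataMatrix) else np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    mu = np.asarray(mu, dtype=float)
    check_precision(omega)
    n, p = X.shape
    sign, logdet = np.linalg.slogdet(omega)
    Xc = X - mu
    quad = np.einsum("ij,jk,ik->", Xc, omega, Xc)
    return 0.5 * n * (logdet - p * _LOG_2PI) - 0.5 * quad


def loglik_from_suffstats(S: np.ndarray, n: int, omega: np.ndarray) -> float:
    """Gaussian log-likelihood given the (mean-zero) 1/n second-moment matrix."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(omega)
    return 0.5 * n * (logdet - np.sum(S * omega) - p * _LOG_2PI)


def fit_glasso(
    data: DataMatrix | np.ndarray,
    lam: float,
    tol: float = GLASSO_TOL,
    max_iter: int = GLASSO_MAX_ITER,
) -> GGMFit:
    """Graphical-lasso estimate of a sparse precision matrix.

    Maximizes  log det(Omega) - tr(S Omega) - lam * sum_{j != j'} |Omega_{jj'}|
    with S the 1/n sample covariance; lam = 0 requires invertible S.
    ``tol`` is the coordinate-descent duality-gap tolerance; pattern-only
    uses (screening) can afford a much looser value than estimation.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    X = data.values if isinstance(data, DataMatrix) else np.asarray(data, dtype=float)
    mu = X.mean(axis=0)
    S = sample_covariance(X)
    if lam == 0:
        try:
            omega = np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError("sample covariance singular; lambda = 0 needs invertible S") from exc
        omega = (omega + omega.T) / 2.0
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, omega = _sk_graphical_lasso(
                    S, alpha=lam, mode="cd", tol=tol, max_iter=max_iter
                )
        except FloatingPointError as exc:
            raise RuntimeError(
                f"graphical lasso failed to converge (lambda={lam}, max_iter={max_iter})"
            ) from exc
        omega = (omega + omega.T) / 2.0
    active = active_set_of(omega)
    # zero the below-tolerance entries exactly so the pattern contract holds
    omega = _enforce_pattern(omega, active)
    try:
        check_precision(omega)
    except ValueError as exc:
        raise RuntimeError(
            f"graphical lasso returned a non-PD estimate at lambda={lam} "
            f"(tol={tol}, max_iter={max_iter}): {exc}"
        ) from exc
    ll = gaussian_loglik(X, mu, omega)
    return GGMFit(mu=mu, omega=omega, active_set=active, loglik=ll, lam=lam)


def _enforce_pattern(omega: np.ndarray, active: frozenset[tuple[int, int]]) -> np.ndarray:
    p = omega.shape[0]
    mask = np.eye(p, dtype=bool)
    for j, jp in active:
        mask[j, jp] = mask[jp, j] = True
    out = np.where(mask, omega, 0.0)
    return (out + out.T) / 2.0


def restricted_mle(
    S: np.ndarray,
    n: int,
    active_set: Iterable[tuple[int, int]],
    tol: float = 1e-9,
) -> GGMFit:
    """Maximum-likelihood precision matrix on a fixed sparsity pattern.

    Maximizes log det(Omega) - tr(S Omega) subject to Omega_{jj'} = 0 for all
    off-diagonal pairs outside ``active_set``.  The problem is concave in the
    free entries; it is solved by L-BFGS-B with the analytic gradient
    (Omega^{-1} - S restricted to the free coordinates).  The returned
    ``loglik`` is the maximized mean-zero Gaussian log-likelihood for ``n``
    samples.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    active = frozenset((min(j, jp), max(j, jp)) for j, jp in active_set)
    for j, jp in active:
        if j == jp or not (0 <= j < p and 0 <= jp < p):
            raise ValueError(f"invalid active-set pair ({j}, {jp})")

    pairs = sorted(active)
    rows = np.array([j for j in range(p)] + [j for j, _ in pairs], dtype=int)
    cols = np.array([j for j in range(p)] + [jp for _, jp in pairs], dtype=int)
    offdiag = np.array([False] * p + [True] * len(pairs))

    diag_S = np.diag(S)
    if np.any(diag_S <= 0):
        raise ValueError("S has nonpositive diagonal entries")

    # closed forms for the two easy cases
    if len(pairs) == p * (p - 1) // 2:
        try:
            omega = np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError("S singular with full active set: MLE does not exist") from exc
        omega = (omega + omega.T) / 2.0
        check_precision(omega)
        return GGMFit(np.zeros(p), omega, active, loglik_from_suffstats(S, n, omega), 0.0)
    if not pairs:
        omega = np.diag(1.0 / diag_S)
        return GGMFit(np.zeros(p), omega, active, loglik_from_suffstats(S, n, omega), 0.0)

    def unpack(x: np.ndarray) -> np.ndarray:
        O = np.zeros((p, p))
        O[rows, cols] = x
        O[cols, rows] = x
        return O

    def fg(x: np.ndarray):
        O = unpack(x)
        try:
            L = np.linalg.cholesky(O)
            Oi = cho_solve((L, True), np.eye(p))
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            return 1e12, np.zeros_like(x)
        diag_L = np.diag(L)
        if np.any(diag_L <= 0) or not np.all(np.isfinite(Oi)):
            return 1e12, np.zeros_like(x)
        logdet = 2.0 * np.log(diag_L).sum()
        f = -(logdet - np.sum(S * O))
        G = S - Oi  # gradient of -objective wrt Omega
        g = G[rows, cols] * np.where(offdiag, 2.0, 1.0)
        return f, g

    x0 = np.concatenate([1.0 / diag_S, np.zeros(len(pairs))])
    res = minimize(fg, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": tol, "gtol": 1e-8})
    omega = unpack(res.x)
    omega = (omega + omega.T) / 2.0
    try:
        check_precision(omega)
    except ValueError as exc:
        raise RuntimeError(f"restricted MLE failed: {exc} (status={res.status})") from exc
    grad_norm = np.max(np.abs(fg(res.x)[1]))
    if not res.success and grad_norm > 1e-4:
        raise RuntimeError(
            f"restricted MLE did not converge: {res.message} "
            f"(iterations={res.nit}, |grad|={grad_norm:.2e})"
        )
    return GGMFit(np.zeros(p), omega, active, loglik_from_suffstats(S, n, omega), 0.0)


# ---------------------------------------------------------------------------
# Partial correlations and feature merging
# ---------------------------------------------------------------------------

def partial_correlations(omega: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix implied by a precision matrix.

    rho_{jj'} = -Omega_{jj'} / sqrt(Omega_{jj} Omega_{j'j'}); diagonal 1.
    """
    omega = np.asarray(omega, dtype=float)
    d = np.diag(omega)
    if np.any(d <= 0):
        raise ValueError("precision matrix has nonpositive diagonal entries")
    scale = np.sqrt(np.outer(d, d))
    rho = -omega / scale
    np.fill_diagonal(rho, 1.0)
    return rho


def merge_correlated_features(
    data: DataMatrix, threshold: float = 0.9
) -> tuple[DataMatrix, dict[str, list[str]]]:
    """Greedily merge variables whose absolute Pearson correlation exceeds ``threshold``.

    Merging is transitive (union-find over all pairs above the threshold);
    each merged cluster is represented by its first variable in column order
    and its profile is the mean of the member z-scores.  Needed before
    network estimation when near-duplicate variables (e.g. a protein and its
    phosphorylated form) would otherwise dominate the partial-correlation
    structure with trivial edges.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    X = data.values
    p = data.p
    R = np.corrcoef(X, rowvar=False)

    parent = list(range(p))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for j in range(p):
        for jp in range(j + 1, p):
            if abs(R[j, jp]) > threshold:
                ra, rb = find(j), find(jp)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    clusters: dict[int, list[int]] = {}
    for j in range(p):
        clusters.setdefault(find(j), []).append(j)

    reps = sorted(clusters)
    if len(reps) < 2:
        raise ValueError("merging collapsed the data below 2 variables; raise the threshold")
    names = [data.variable_names[r] for r in reps]
    merge_map = {
        data.variable_names[r]: [data.variable_names[m] for m in clusters[r]]
        for r in reps
    }
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    # singleton clusters keep their original profile; merged ones average z-scores
    merged = np.column_stack([
        X[:, clusters[r][0]] if len(clusters[r]) == 1 else Z[:, clusters[r]].mean(axis=1)
        for r in reps
    ])
    out = DataMatrix(merged, names, data.sample_labels)
    return out, merge_map
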