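"""Penalized mixture of Gaussian graphical models for network-based clustering.

Samples are modeled as draws from a K-component Gaussian mixture in which
every component k has its own mean mu_k and sparse precision matrix
Omega_k (a cluster-specific network).  Fitting maximizes the penalized
log-likelihood

    l(Theta; X) - lambda * pen(Theta),
    pen(Theta) = sum_k pi_k^{1/2} sum_{j != j'}
                 |Omega_{k;jj'}| / sqrt(Omega_{k;jj} Omega_{k;j'j'}),

by expectation-maximization.  Two features of the penalty matter in
practice: the pi_k^{1/2} factor adapts the effective regularization to the
(unknown) cluster sizes, and the 1/sqrt(Omega_jj Omega_j'j') scaling makes
it act on partial correlations, hence invariant to variable scale.  The
regularization level is fixed at a universal value

    lambda_uni = sqrt(2 n log p) / 2,

removing the need for cross-validation.  The number of clusters is chosen
by minimizing a BIC score whose degrees of freedom count the fitted
nonzero precision entries.

The module also provides stability assessment by repeated subsampling and
an adjusted-Rand-index wrapper for comparing partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .ggm_core import (
    DataMatrix,
    active_set_of,
    check_precision,
    _enforce_pattern,
)
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
import warnings

EM_TOL = 1e-6
EM_MAX_ITER = 500
RESP_FLOOR = 1e-12
_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MixtureParams:
    """Parameters of a K-component Gaussian graphical mixture."""

    pi: np.ndarray
    mu: np.ndarray
    omega: np.ndarray  # K x p x p

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if np.any(self.pi <= 0) or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("mixture weights must be positive and sum to 1")
        for k in range(self.K):
            check_precision(self.omega[k])

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def p(self) -> int:
        return self.mu.shape[1]


@dataclass
class MixGlassoFit:
    """A fitted penalized Gaussian graphical mixture."""

    params: MixtureParams
    responsibilities: np.ndarray
    labels: np.ndarray
    penalized_loglik: float
    loglik: float
    lam: float
    bic: float
    n_iter: int
    converged: bool
    n: int
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        rs = self.responsibilities.sum(axis=1)
        if np.any(np.abs(rs - 1.0) > 1e-10):
            raise ValueError("responsibility rows must sum to 1")
        if not np.array_equal(self.labels, self.responsibilities.argmax(axis=1)):
            raise ValueError("labels must be the rowwise argmax of responsibilities")


# ---------------------------------------------------------------------------
# Penalty and regularization level
# ---------------------------------------------------------------------------

def penalty_value(params: MixtureParams) -> float:
    """Adaptive penalty: sum_k pi_k^{1/2} sum_{j != j'} |rho-scaled Omega entries|.

    The inner sum runs over ordered pairs, so each unordered pair counts
    twice; the value is invariant to rescaling any Omega_k by a constant.
    """
    total = 0.0
    for k in range(params.K):
        O = params.omega[k]
        d = np.sqrt(np.diag(O))
        scaled = np.abs(O) / np.outer(d, d)
        total += np.sqrt(params.pi[k]) * (scaled.sum() - np.trace(scaled))
    return float(total)


def _lasso_penalty_value(params: MixtureParams) -> float:
    """Non-adaptive l1 penalty: sum_k sum_{j != j'} |Omega_{k;jj'}| (baseline)."""
    total = 0.0
    for k in range(params.K):
        A = np.abs(params.omega[k])
        total += A.sum() - np.trace(A)
    return float(total)


def lambda_uni(n: int, p: int) -> float:
    """Universal regularization level sqrt(2 n log p) / 2."""
    if p < 2:
        raise ValueError("need p >= 2")
    if n < 1:
        raise ValueError("need n >= 1")
    return float(np.sqrt(2.0 * n * np.log(p)) / 2.0)


# ---------------------------------------------------------------------------
# EM steps
# ---------------------------------------------------------------------------

def _log_densities(X: np.ndarray, params: MixtureParams) -> np.ndarray:
    """n x K matrix of log pi_k + log N(x_i | mu_k, Omega_k^{-1})."""
    n, p = X.shape
    out = np.empty((n, params.K))
    for k in range(params.K):
        O = params.omega[k]
        sign, logdet = np.linalg.slogdet(O)
        Xc = X - params.mu[k]
        quad = np.einsum("ij,jk,ik->i", Xc, O, Xc)
        out[:, k] = np.log(params.pi[k]) + 0.5 * (logdet - p * _LOG_2PI) - 0.5 * quad
    return out


def e_step(data, params: MixtureParams) -> np.ndarray:
    """Posterior component probabilities (responsibilities), in log space."""
    X = data.values if isinstance(data, DataMatrix) else np.asarray(data, dtype=float)
    logd = _log_densities(X, params)
    norm = logsumexp(logd, axis=1)
    if np.any(~np.isfinite(norm)):
        bad = int(np.flatnonzero(~np.isfinite(norm))[0])
        raise FloatingPointError(
            f"all components underflow for sample {bad}; data may be degenerate"
        )
    resp = np.exp(logd - norm[:, None])
    resp = np.maximum(resp, RESP_FLOOR)
    return resp / resp.sum(axis=1, keepdims=True)


def loglik_value(X: np.ndarray, params: MixtureParams) -> float:
    """Unpenalized mixture log-likelihood."""
    return float(logsumexp(_log_densities(X, params), axis=1).sum())


def penalized_loglik_value(X: np.ndarray, params: MixtureParams, lam: float,
                           penalty: str = "adaptive") -> float:
    pen = penalty_value(params) if penalty == "adaptive" else _lasso_penalty_value(params)
    return loglik_value(X, params) - lam * pen


class EmptyClusterError(RuntimeError):
    """Raised when a component's effective sample size collapses."""

    def __init__(self, k: int, n_eff: float):
        super().__init__(f"component {k} collapsed (effective n = {n_eff:.2f})")
        self.k = k
        self.n_eff = n_eff


def _glasso_weighted(S: np.ndarray, alpha: float, diag_prev: np.ndarray) -> np.ndarray:
    """One reweighted-glasso cycle for the partial-correlation-scaled penalty.

    The entrywise weights 1/sqrt(Omega_jj Omega_j'j') (from the previous
    iterate's diagonal) are separable, so the weighted problem reduces
    exactly to a scalar-alpha graphical lasso on the rescaled covariance
    D^{-1} S D^{-1} with D = diag(Omega_jj^{-1/2}).
    """
    s = np.sqrt(diag_prev)  # D^{-1} = diag(sqrt(Omega_jj))
    S_t = S * np.outer(s, s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, omega_t = _sk_graphical_lasso(S_t, alpha=alpha, mode="cd",
                                         tol=1e-3, max_iter=30)
    omega = omega_t * np.outer(s, s)
    return (omega + omega.T) / 2.0


def m_step(
    data,
    responsibilities: np.ndarray,
    lam: float,
    penalty: str = "adaptive",
    prev_params: MixtureParams | None = None,
) -> MixtureParams:
    """Maximize the penalized expected complete-data log-likelihood.

    pi_k and mu_k have closed forms; each Omega_k solves a graphical-lasso
    subproblem with effective scalar penalty 2*lambda*pi_k^{1/2}/n_k^eff
    ("adaptive", two reweighting cycles for the partial-correlation scaling)
    or 2*lambda/n_k^eff ("lasso" baseline, no adaptation).
    """
    X = data.values if isinstance(data, DataMatrix) else np.asarray(data, dtype=float)
    n, p = X.shape
    R = np.asarray(responsibilities, dtype=float)
    if np.any(np.abs(R.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("responsibility rows must sum to 1")
    K = R.shape[1]
    n_eff = R.sum(axis=0)
    floor = p / 2.0
    for k in range(K):
        if n_eff[k] < floor:
            raise EmptyClusterError(k, n_eff[k])
    pi = n_eff / n
    mu = (R.T @ X) / n_eff[:, None]
    omegas = np.empty((K, p, p))
    for k in range(K):
        Xc = X - mu[k]
        Sk = (Xc * R[:, k:k + 1]).T @ Xc / n_eff[k]
        Sk = (Sk + Sk.T) / 2.0
        if lam == 0:
            try:
                Ok = np.linalg.inv(Sk)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(
                    f"component {k}: weighted covariance singular with lambda = 0"
                ) from exc
            omegas[k] = (Ok + Ok.T) / 2.0
            continue
        if penalty == "adaptive":
            alpha = 2.0 * lam * np.sqrt(pi[k]) / n_eff[k]
            diag_prev = (np.diag(prev_params.omega[k]) if prev_params is not None
                         else 1.0 / np.maximum(np.diag(Sk), 1e-10))
            Ok = _glasso_weighted(Sk, alpha, diag_prev)
            Ok = _glasso_weighted(Sk, alpha, np.diag(Ok))
        elif penalty == "lasso":
            alpha = 2.0 * lam / n_eff[k]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, Ok = _sk_graphical_lasso(Sk, alpha=alpha, mode="cd",
                                            tol=1e-3, max_iter=30)
            Ok = (Ok + Ok.T) / 2.0
        else:
            raise ValueError(f"unknown penalty {penalty!r}")
        omegas[k] = _enforce_pattern(Ok, active_set_of(Ok))
    return MixtureParams(pi=pi, mu=mu, omega=omegas)


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

def _init_responsibilities(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """K-means initialization smoothed to soft responsibilities (0.9 / 0.1)."""
    n = X.shape[0]
    if K == 1:
        return np.ones((n, 1))
    km = KMeans(n_clusters=K, n_init=5, random_state=int(rng.integers(2**31 - 1)))
    labels = km.fit_predict(X)
    R = np.full((n, K), 0.1 / max(K - 1, 1))
    R[np.arange(n), labels] = 0.9
    return R / R.sum(axis=1, keepdims=True)


def em_fit(
    data,
    K: int,
    lam: float | None = None,
    init: str = "kmeans",
    n_restarts: int = 1,
    seed: int = 0,
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
    penalty: str = "adaptive",
) -> MixGlassoFit:
    """Fit the penalized mixture by (generalized) EM, best of ``n_restarts``.

    ``lam=None`` uses lambda_uni.  The penalized log-likelihood trace is
    non-decreasing by construction: if an M-step ever fails to improve it
    (possible because the pi-coupled penalty and the reweighting cycles make
    the step approximate), the previous parameters are kept and the fit is
    declared converged.  A component whose effective size drops below p/2
    is re-seeded once from the most ambiguous samples; on a second collapse
    it is dropped with a warning.
    """
    X = data.values if isinstance(data, DataMatrix) else np.asarray(data, dtype=float)
    n, p = X.shape
    if K < 1 or n <= K:
        raise ValueError(f"need 1 <= K < n (got K={K}, n={n})")
    if lam is None:
        lam = lambda_uni(n, p)
    if init != "kmeans":
        raise ValueError(f"unknown init {init!r}")
    rng = np.random.default_rng(seed)
    best: MixGlassoFit | None = None
    errors: list[str] = []
    for _ in range(max(1, n_restarts)):
        try:
            fit = _em_once(X, K, lam, rng, max_iter, tol, penalty)
        except (RuntimeError, FloatingPointError, np.linalg.LinAlgError) as exc:
            errors.append(str(exc))
            continue
        if best is None or fit.penalized_loglik > best.penalized_loglik:
            best = fit
    if best is None:
        raise RuntimeError(f"all EM restarts failed: {errors}")
    return best


def _em_once(X, K, lam, rng, max_iter, tol, penalty) -> MixGlassoFit:
    n, p = X.shape
    R = _init_responsibilities(X, K, rng)
    params: MixtureParams | None = None
    reseeded: set[int] = set()
    trace: list[float] = []
    prev_pll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            new_params = m_step(X, R, lam, penalty=penalty, prev_params=params)
        except EmptyClusterError as exc:
            if exc.k in reseeded or K == 1:
                warnings.warn(
                    f"dropping collapsed mixture component {exc.k} (K -> {K - 1})",
                    RuntimeWarning,
                )
                keep = [k for k in range(K) if k != exc.k]
                R = R[:, keep]
                R = R / R.sum(axis=1, keepdims=True)
                K -= 1
                if K < 1:
                    raise RuntimeError("all components collapsed") from exc
                params = None
                prev_pll = -np.inf
                trace = []
                continue
            reseeded.add(exc.k)
            ambiguous = np.argsort(R.max(axis=1))[: max(p, 10)]
            R[ambiguous] = RESP_FLOOR
            R[ambiguous, exc.k] = 1.0
            R = np.maximum(R, RESP_FLOOR)
            R = R / R.sum(axis=1, keepdims=True)
            continue
        pll = penalized_loglik_value(X, new_params, lam, penalty)
        if params is not None and pll < prev_pll - 1e-9:
            # approximate M-step failed to improve: keep previous iterate
            converged = True
            break
        params = new_params
        trace.append(pll)
        if prev_pll > -np.inf and abs(pll - prev_pll) <= tol * (abs(prev_pll) + 1.0):
            prev_pll = pll
            converged = True
            break
        prev_pll = pll
        R = e_step(X, params)
    if params is None:
        raise RuntimeError("EM produced no valid parameters")
    R = e_step(X, params)
    ll = loglik_value(X, params)
    labels = R.argmax(axis=1)
    fit = MixGlassoFit(
        params=params,
        responsibilities=R,
        labels=labels,
        penalized_loglik=prev_pll,
        loglik=ll,
        lam=lam,
        bic=np.nan,
        n_iter=it,
        converged=converged,
        n=n,
        trace=np.asarray(trace),
    )
    fit.bic = bic_score(fit)
    return fit


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def df_cluster(omega: np.ndarray) -> int:
    """Degrees of freedom of one component: p means + upper-triangle nonzeros
    of the precision matrix (diagonal included)."""
    omega = np.asarray(omega)
    p = omega.shape[0]
    iu = np.triu_indices(p)
    return int(p + np.count_nonzero(np.abs(omega[iu]) > 1e-12))


def bic_score(fit: MixGlassoFit) -> float:
    """BIC = -l + 0.5 log(n) (K-1) + 0.5 log(n) sum_k Df(k).

    ``l`` is the *unpenalized* mixture log-likelihood at the fitted
    parameters; lower is better.
    """
    n = fit.n
    K = fit.params.K
    df_total = sum(df_cluster(fit.params.omega[k]) for k in range(K))
    return float(-fit.loglik + 0.5 * np.log(n) * (K - 1) + 0.5 * np.log(n) * df_total)


def select_K(
    data,
    K_range: Sequence[int],
    lam: float | None = None,
    seed: int = 0,
    **em_kwargs,
) -> tuple[int, dict[int, MixGlassoFit], pd.DataFrame]:
    """Fit every K in ``K_range`` and pick the BIC minimizer (smallest K on ties)."""
    K_range = sorted(set(int(K) for K in K_range))
    if not K_range:
        raise ValueError("K_range must be nonempty")
    rng = np.random.default_rng(seed)
    fits: dict[int, MixGlassoFit] = {}
    rows = []
    for K in K_range:
        fit = em_fit(data, K, lam=lam, seed=int(rng.integers(2**31 - 1)), **em_kwargs)
        fits[K] = fit
        rows.append({"K": K, "bic": fit.bic, "loglik": fit.loglik,
                     "K_fitted": fit.params.K, "converged": fit.converged})
    table = pd.DataFrame(rows)
    K_star = int(table.loc[table["bic"].idxmin(), "K"])
    return K_star, fits, table


# ---------------------------------------------------------------------------
# Stability and partition comparison
# ---------------------------------------------------------------------------

def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two partitions (1 = identical)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length ({a.size} vs {b.size})")
    return float(adjusted_rand_score(a, b))


def stability_subsample(
    data,
    K: int,
    fraction: float = 0.25,
    n_rep: int = 10,
    seed: int = 0,
    lam: float | None = None,
    **em_kwargs,
) -> tuple[float, float]:
    """Clustering stability under random subsampling.

    Repeatedly removes ``fraction`` of the samples, refits with the same K,
    and scores the adjusted Rand index between every pair of refits on their
    shared samples.  Returns (mean, sd) over all pairs; values near 1
    indicate a stable clustering.
    """
    X = data.values if isinstance(data, DataMatrix) else np.asarray(data, dtype=float)
    n = X.shape[0]
    keep = int(round(n * (1.0 - fraction)))
    if keep <= K:
        raise ValueError("subsample too small for K clusters")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(n_rep):
        idx = np.sort(rng.choice(n, size=keep, replace=False))
        fit = em_fit(X[idx], K, lam=lam, seed=int(rng.integers(2**31 - 1)), **em_kwargs)
        assignments.append(dict(zip(idx.tolist(), fit.labels.tolist())))
    aris = []
    for i in range(n_rep):
        for j in range(i + 1, n_rep):
            shared = sorted(assignments[i].keys() & assignments[j].keys())
            if len(shared) < 2:
                continue
            la = [assignments[i][s] for s in shared]
            lb = [assignments[j][s] for s in shared]
            aris.append(adjusted_rand_index(la, lb))
    aris = np.asarray(aris)
    return float(aris.mean()), float(aris.std(ddof=1) if len(aris) > 1 else 0.0)
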