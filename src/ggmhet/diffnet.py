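"""Two-sample testing of differences between Gaussian graphical models.

The null hypothesis is equality of the two groups' precision matrices,
H0: Omega_1 = Omega_2.  A classical likelihood-ratio test breaks down when
the number of precision parameters p(p+1)/2 is large relative to the sample
size; the split-based test implemented here stays valid in that regime by

1. estimating sparsity patterns (active sets) with the graphical lasso on a
   random half of each group's samples, and
2. computing a likelihood-ratio statistic from maximum-likelihood fits
   *restricted to those patterns* on the held-out half, whose null
   distribution is a weighted sum of chi-square(1) variables.

Because a single random split introduces extra randomness, the test is also
run over many independent splits (50 by default) and the per-split P-values
are combined with a quantile aggregation rule that preserves validity.

Baselines for comparison: the classical asymptotic LRT, its permutation
version, and a multiplicity-corrected Fisher-Z test on all pairwise partial
correlations.  ``pairwise_group_tests`` applies any of the tests to all
pairs of known groups with Benjamini-Hochberg FDR correction.

The split tests standardize each group internally (exactly, on the
held-out halves), so they are sensitive to dependence structure rather
than mean or scale differences, and means are fixed at zero in the
restricted fits.  The classical baselines use centered covariance MLEs
(means profiled out); per-group standardization for them is applied by
``pairwise_group_tests`` or left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ggm_core import (
    DataMatrix,
    GGMFit,
    fit_glasso,
    restricted_mle,
    sample_covariance,
    second_moment,
)

DEFAULT_N_SPLITS = 50
DEFAULT_GAMMA_MIN = 0.05
DEFAULT_N_DRAWS_ASYMPTOTIC = 100_000
DEFAULT_N_DRAWS_BOOTSTRAP = 1000
DEFAULT_N_LAMBDAS = 20


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Reproducible 50/50 split of each group's samples into two halves."""

    seed: int
    first_half: tuple[np.ndarray, np.ndarray]
    second_half: tuple[np.ndarray, np.ndarray]


@dataclass
class DiffNetResult:
    """Outcome of a network-difference test."""

    statistic: float | np.ndarray
    pvalue: float
    method: str
    weights: np.ndarray | None = None
    per_split_pvalues: np.ndarray | None = None
    n_splits: int = 1
    active_set_sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"pvalue {self.pvalue} outside [0, 1]")


# ---------------------------------------------------------------------------
# Splitting and screening
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> np.ndarray:
    """Column z-scores ((n-1)-denominator), applied within one group."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance variable; cannot standardize")
    return (X - X.mean(axis=0)) / sd


def _standardize_exact(X: np.ndarray) -> np.ndarray:
    """Exact unit-second-moment scaling: mean 0, 1/n variance exactly 1.

    Applied to the held-out halves so diag(S) = 1 holds by construction;
    the null-distribution weights condition on exactly this constraint.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    sd = np.sqrt((Xc ** 2).mean(axis=0))
    if np.any(sd == 0):
        raise ValueError("zero-variance variable; cannot standardize")
    return Xc / sd


def _as_array(X) -> np.ndarray:
    return X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)


def split_data(X1, X2, seed: int) -> SplitPlan:
    """Stratified 50/50 random split of each group's sample indices."""
    n1, n2 = _as_array(X1).shape[0], _as_array(X2).shape[0]
    if n1 < 4 or n2 < 4:
        raise ValueError(f"each group needs >= 4 samples (got {n1}, {n2})")
    rng = np.random.default_rng(seed)
    firsts, seconds = [], []
    for n in (n1, n2):
        perm = rng.permutation(n)
        firsts.append(np.sort(perm[: n // 2]))
        seconds.append(np.sort(perm[n // 2:]))
    return SplitPlan(seed=seed, first_half=tuple(firsts), second_half=tuple(seconds))


def _glasso_bic_active_set(X: np.ndarray, n_lambdas: int = DEFAULT_N_LAMBDAS) -> frozenset:
    """Active set of the BIC-best graphical-lasso fit over a log-spaced grid.

    The grid runs downward from lambda_max (the value at which the estimate
    is fully diagonal) to lambda_max / 20; ties favor the sparser
    (larger-lambda) fit.  Only the sparsity pattern is consumed downstream,
    so the solver runs at a loose duality-gap tolerance.
    """
    n, p = X.shape
    S = sample_covariance(X)
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = max(off.max(), 1e-3)
    grid = np.geomspace(lam_max, lam_max * 0.05, n_lambdas)
    best_bic, best_active = np.inf, frozenset()
    for lam in grid:
        try:
            fit = fit_glasso(X, lam, tol=5e-3, max_iter=30)
        except RuntimeError:
            continue
        df = p + len(fit.active_set)
        bic = -2.0 * fit.loglik + np.log(n) * df
        if bic < best_bic:
            best_bic, best_active = bic, fit.active_set
    return best_active


def screen_active_sets(X1_h1, X2_h1, n_lambdas: int = DEFAULT_N_LAMBDAS):
    """Estimate per-group and joint sparsity patterns on first-half data.

    Returns (A1, A2, A_joint): graphical-lasso active sets with per-fit
    BIC-tuned lambda for each group and for the pooled first halves.
    """
    X1, X2 = _as_array(X1_h1), _as_array(X2_h1)
    if X1.shape[0] < 2 or X2.shape[0] < 2:
        raise ValueError("each first half needs >= 2 samples")
    A1 = _glasso_bic_active_set(X1, n_lambdas)
    A2 = _glasso_bic_active_set(X2, n_lambdas)
    A_joint = _glasso_bic_active_set(np.vstack([X1, X2]), n_lambdas)
    return A1, A2, A_joint


# ---------------------------------------------------------------------------
# Test statistic
# ---------------------------------------------------------------------------

def diffnet_statistic(X1_h2, X2_h2, A1, A2, A_joint):
    """Restricted likelihood-ratio statistic on held-out data.

    2 * [l(Omega1_hat; X1) + l(Omega2_hat; X2) - l(Omega0_hat; pooled)],
    with each Omega a maximum-likelihood fit restricted to its screened
    active set and means fixed at zero.  May be negative in finite samples
    because the three patterns are not nested; returned unclipped.

    Both halves are first scaled to exact zero mean and unit (1/n) second
    moments, so the test concerns dependence structure only and the
    unit-diagonal conditioning used by :func:`null_weights` holds exactly.
    """
    X1 = _standardize_exact(_as_array(X1_h2))
    X2 = _standardize_exact(_as_array(X2_h2))
    n1, n2 = X1.shape[0], X2.shape[0]
    S1, S2 = second_moment(X1), second_moment(X2)
    S0 = (n1 * S1 + n2 * S2) / (n1 + n2)
    fit1 = restricted_mle(S1, n1, A1)
    fit2 = restricted_mle(S2, n2, A2)
    fit0 = restricted_mle(S0, n1 + n2, A_joint)
    stat = 2.0 * (fit1.loglik + fit2.loglik - fit0.loglik)
    return stat, {"fit1": fit1, "fit2": fit2, "fit0": fit0, "n1": n1, "n2": n2}


# ---------------------------------------------------------------------------
# Null distribution
# ---------------------------------------------------------------------------

def _sym_basis_index(p: int):
    """Index maps for the vech parameterization: diagonal first, then pairs."""
    pairs = list(combinations(range(p), 2))
    pair_index = {pr: p + i for i, pr in enumerate(pairs)}
    return pairs, pair_index


def _fisher_information(sigma: np.ndarray) -> np.ndarray:
    """Per-sample Fisher information for the free entries of Omega (mean known).

    With theta = (diag entries, off-diagonal pairs) and basis matrices J_a,
    I_{ab} = 0.5 * tr(Sigma J_a Sigma J_b), assembled via the duplication map.
    """
    p = sigma.shape[0]
    pairs, _ = _sym_basis_index(p)
    d = p + len(pairs)
    B = np.zeros((p * p, d))
    for j in range(p):
        B[j * p + j, j] = 1.0
    for i, (j, jp) in enumerate(pairs):
        B[j * p + jp, p + i] = 1.0
        B[jp * p + j, p + i] = 1.0
    K = np.kron(sigma, sigma)
    return 0.5 * B.T @ K @ B


def _model_coords(active, p: int, pair_index) -> np.ndarray:
    return np.array(list(range(p)) + sorted(pair_index[pr] for pr in active), dtype=int)


def null_weights(fits: dict) -> np.ndarray:
    """Chi-square(1) mixture weights of the statistic's null distribution.

    Expanding the three restricted fits around the joint null model, the
    statistic is asymptotically a quadratic form in the (Gaussian) score
    vectors of the two groups; its distribution is sum_i w_i chi2_1 with
    weights the eigenvalues of that form's covariance-weighted matrix, the
    Fisher information being evaluated at the joint restricted MLE.

    Because each held-out half is scaled to exact unit second moments, the
    diagonal score components vanish identically; the score covariance used
    here is therefore the conditional (Schur-complement) covariance of the
    off-diagonal coordinates given the diagonal constraint.
    """
    fit0: GGMFit = fits["fit0"]
    n1, n2 = fits["n1"], fits["n2"]
    p = fit0.p
    sigma0 = np.linalg.inv(fit0.omega)
    sigma0 = (sigma0 + sigma0.T) / 2.0
    info = _fisher_information(sigma0)
    _, pair_index = _sym_basis_index(p)
    d = info.shape[0]

    def projected_inverse(active, n_total):
        c = _model_coords(active, p, pair_index)
        sub = info[np.ix_(c, c)]
        inv = np.linalg.inv(sub)
        M = np.zeros((d, d))
        M[np.ix_(c, c)] = inv / n_total
        return M

    B1 = projected_inverse(fits["fit1"].active_set, n1)
    B2 = projected_inverse(fits["fit2"].active_set, n2)
    D0 = projected_inverse(fit0.active_set, n1 + n2)

    Q = np.zeros((2 * d, 2 * d))
    Q[:d, :d] = B1 - D0
    Q[d:, d:] = B2 - D0
    Q[:d, d:] = -D0
    Q[d:, :d] = -D0

    # Score covariance after exact standardization.  Scaling to unit sample
    # variances maps the covariance fluctuations u = S - Sigma to
    # u~_jk = u_jk - rho_jk (u_jj + u_kk) (delta method; the p=2 case
    # reproduces Var(r) = (1 - rho^2)^2 / n), so the diagonal score
    # coordinates vanish and the off-diagonal ones have covariance T I T'.
    pairs, _ = _sym_basis_index(p)
    r = d - p
    T = np.zeros((r, d))
    for a, (j, jp) in enumerate(pairs):
        T[a, p + a] = 1.0
        T[a, j] = -sigma0[j, jp]
        T[a, jp] = -sigma0[j, jp]
    V = T @ info @ T.T
    V = (V + V.T) / 2.0
    L = np.linalg.cholesky(V + 1e-12 * np.eye(r))
    E = np.zeros((d, r))
    E[p:, :] = L
    A = np.zeros((2 * d, 2 * r))
    A[:d, :r] = np.sqrt(n1) * E
    A[d:, r:] = np.sqrt(n2) * E
    W = A.T @ Q @ A
    w = np.linalg.eigvalsh((W + W.T) / 2.0)
    w = w[np.abs(w) > 1e-8]
    if w.size and np.all(w <= 0):
        raise ValueError("all null-mixture weights are nonpositive")
    return w


# cached chi-square(1) draws shared by all Monte Carlo P-value evaluations;
# a fixed internal seed keeps asymptotic P-values deterministic
_MC_SEED = 161_803_398
_mc_cache: dict = {}


def _chi2_draw_matrix(k: int, n_draws: int) -> np.ndarray:
    key = "chi2"
    mat = _mc_cache.get(key)
    if mat is None or mat.shape[0] < n_draws or mat.shape[1] < k:
        rng = np.random.default_rng(_MC_SEED)
        shape = (max(n_draws, 10_000), max(k, 64))
        _mc_cache[key] = rng.chisquare(1.0, size=shape).astype(np.float32)
        mat = _mc_cache[key]
    return mat[:n_draws, :k]


def null_pvalue(
    statistic: float,
    fits: dict,
    method: str = "asymptotic",
    n_draws: int | None = None,
    seed: int = 0,
) -> tuple[float, np.ndarray | None]:
    """P-value of the restricted LRT statistic under H0: Omega1 = Omega2.

    ``asymptotic``: Monte Carlo evaluation (n_draws >= 1e5) of the weighted
    chi-square(1) mixture from :func:`null_weights`.  ``bootstrap``:
    parametric bootstrap from the fitted joint null model, re-estimating the
    restricted MLEs on each draw with the active sets held fixed; add-one
    rule so P > 0.
    """
    if not np.isfinite(statistic):
        raise ValueError("statistic must be finite")
    if method == "asymptotic":
        n_draws = DEFAULT_N_DRAWS_ASYMPTOTIC if n_draws is None else n_draws
        w = null_weights(fits)
        if w.size == 0:
            # all three restricted models coincide (e.g. fully screened-out
            # patterns); the statistic is degenerate at zero
            return (1.0 if statistic <= 1e-9 else 0.0), w
        draws = _chi2_draw_matrix(len(w), n_draws) @ w.astype(np.float32)
        return float(np.mean(draws >= statistic)), w
    if method == "bootstrap":
        n_draws = DEFAULT_N_DRAWS_BOOTSTRAP if n_draws is None else n_draws
        fit0 = fits["fit0"]
        n1, n2 = fits["n1"], fits["n2"]
        sigma0 = np.linalg.inv(fit0.omega)
        chol = np.linalg.cholesky((sigma0 + sigma0.T) / 2.0)
        rng = np.random.default_rng(seed)
        A1, A2, A0 = (fits["fit1"].active_set, fits["fit2"].active_set,
                      fit0.active_set)
        count = 0
        for _ in range(n_draws):
            Y1 = rng.standard_normal((n1, fit0.p)) @ chol.T
            Y2 = rng.standard_normal((n2, fit0.p)) @ chol.T
            stat_b, _ = diffnet_statistic(Y1, Y2, A1, A2, A0)
            if stat_b >= statistic:
                count += 1
        return (1.0 + count) / (n_draws + 1.0), None
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Single- and multi-split tests
# ---------------------------------------------------------------------------

def diffnet_single_split(
    X1,
    X2,
    seed: int = 0,
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    pvalue_method: str = "asymptotic",
    n_draws: int | None = None,
) -> DiffNetResult:
    """Single-split network-difference test.

    Standardizes each group, splits it 50/50, screens active sets on the
    first halves and computes the restricted-LRT P-value on the second.
    """
    Z1, Z2 = _standardize(_as_array(X1)), _standardize(_as_array(X2))
    plan = split_data(Z1, Z2, seed)
    i1, i2 = plan.first_half
    j1, j2 = plan.second_half
    A1, A2, A0 = screen_active_sets(Z1[i1], Z2[i2], n_lambdas)
    stat, fits = diffnet_statistic(Z1[j1], Z2[j2], A1, A2, A0)
    pval, w = null_pvalue(stat, fits, method=pvalue_method, n_draws=n_draws, seed=seed)
    return DiffNetResult(
        statistic=stat,
        pvalue=pval,
        method="single_split",
        weights=w,
        n_splits=1,
        active_set_sizes={"A1": len(A1), "A2": len(A2), "A_joint": len(A0)},
    )


def aggregate_pvalues(pvals, gamma_min: float = DEFAULT_GAMMA_MIN) -> float:
    """Quantile aggregation of per-split P-values.

    P_agg = min{1, (1 - log gamma_min) * inf_{gamma in [gamma_min, 1]}
                 min(1, q_gamma(pvals) / gamma)}
    evaluated on a dense 100-point gamma grid; valid for arbitrarily
    dependent splits.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty P-value vector")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("P-values must lie in [0, 1]")
    if not 0.0 < gamma_min < 1.0:
        raise ValueError("gamma_min must lie in (0, 1)")
    gammas = np.linspace(gamma_min, 1.0, 100)
    q = np.quantile(pvals, gammas)
    inner = np.minimum(1.0, q / gammas)
    return float(min(1.0, (1.0 - np.log(gamma_min)) * inner.min()))


def diffnet_multi_split(
    X1,
    X2,
    n_splits: int = DEFAULT_N_SPLITS,
    gamma_min: float = DEFAULT_GAMMA_MIN,
    seed: int = 0,
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    pvalue_method: str = "asymptotic",
    n_draws: int | None = None,
) -> DiffNetResult:
    """Multi-split test: aggregate P-values over independent random splits."""
    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(0, 2**31 - 1, size=n_splits)
    stats_, pvals = [], []
    for s in split_seeds:
        res = diffnet_single_split(
            X1, X2, seed=int(s), n_lambdas=n_lambdas,
            pvalue_method=pvalue_method, n_draws=n_draws,
        )
        stats_.append(res.statistic)
        pvals.append(res.pvalue)
    pvals = np.array(pvals)
    return DiffNetResult(
        statistic=np.array(stats_),
        pvalue=aggregate_pvalues(pvals, gamma_min),
        method="multi_split",
        per_split_pvalues=pvals,
        n_splits=n_splits,
    )


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def _lrt_statistic(X1: np.ndarray, X2: np.ndarray) -> float:
    """Classical Gaussian covariance-equality LRT statistic.

    Means are profiled out (each covariance is the centered 1/n MLE), so
    the statistic compares covariance structure only.
    """
    n1, n2 = X1.shape[0], X2.shape[0]
    S1, S2 = sample_covariance(X1), sample_covariance(X2)
    S0 = (n1 * S1 + n2 * S2) / (n1 + n2)
    sign0, ld0 = np.linalg.slogdet(S0)
    sign1, ld1 = np.linalg.slogdet(S1)
    sign2, ld2 = np.linalg.slogdet(S2)
    if min(sign0, sign1, sign2) <= 0:
        raise ValueError("singular covariance matrix; classical LRT needs n_k > p")
    return (n1 + n2) * ld0 - n1 * ld1 - n2 * ld2


def lrt_asym(X1, X2) -> float:
    """Classical LRT with an asymptotic chi-square P-value.

    Degrees of freedom p(p+1)/2, the free parameters of one covariance
    matrix (group means are profiled out under both hypotheses and cancel).
    Known to be anti-conservative when p is not small relative to n.
    """
    Z1, Z2 = _as_array(X1), _as_array(X2)
    p = Z1.shape[1]
    if Z1.shape[0] <= p or Z2.shape[0] <= p:
        raise ValueError("classical LRT requires n_k > p in both groups")
    stat = _lrt_statistic(Z1, Z2)
    df = p * (p + 1) // 2
    return float(stats.chi2.sf(stat, df))


def lrt_perm(X1, X2, n_perm: int = 999, seed: int = 0) -> float:
    """Permutation version of the classical LRT (add-one P-value rule).

    Group labels are permuted on the pooled samples; exchangeability under
    the null is the caller's responsibility (standardize groups first when
    mean or scale differences are possible).
    """
    if n_perm < 99:
        raise ValueError("need n_perm >= 99")
    Z1, Z2 = _as_array(X1), _as_array(X2)
    n1 = Z1.shape[0]
    obs = _lrt_statistic(Z1, Z2)
    pooled = np.vstack([Z1, Z2])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        stat = _lrt_statistic(pooled[perm[:n1]], pooled[perm[n1:]])
        if stat >= obs:
            count += 1
    return (1.0 + count) / (n_perm + 1.0)


def fisherz_test(X1, X2) -> float:
    """Multiplicity-corrected Fisher-Z test on all pairwise partial correlations.

    Each group's partial correlations come from the inverted (centered)
    sample covariance — a scale-invariant quantity; each pair is compared
    via (z1 - z2) / sqrt(1/(n1-p-1) + 1/(n2-p-1)) with z = atanh(rho), and
    the global P-value is the Bonferroni-corrected minimum over the
    p(p-1)/2 pairs.
    """
    Z1, Z2 = _as_array(X1), _as_array(X2)
    n1, n2 = Z1.shape[0], Z2.shape[0]
    p = Z1.shape[1]
    if n1 <= p + 2 or n2 <= p + 2:
        raise ValueError("Fisher-Z test requires n_k > p + 2 in both groups")
    from .ggm_core import partial_correlations

    rhos = []
    for Z in (Z1, Z2):
        omega = np.linalg.inv(sample_covariance(Z))
        rhos.append(partial_correlations((omega + omega.T) / 2.0))
    iu = np.triu_indices(p, k=1)
    z1 = np.arctanh(np.clip(rhos[0][iu], -1 + 1e-12, 1 - 1e-12))
    z2 = np.arctanh(np.clip(rhos[1][iu], -1 + 1e-12, 1 - 1e-12))
    se = np.sqrt(1.0 / (n1 - p - 1) + 1.0 / (n2 - p - 1))
    pair_p = 2.0 * stats.norm.sf(np.abs(z1 - z2) / se)
    m = len(pair_p)
    return float(min(1.0, m * pair_p.min()))


_METHODS = {
    "ss": lambda X1, X2, seed, kw: diffnet_single_split(X1, X2, seed=seed, **kw).pvalue,
    "ms": lambda X1, X2, seed, kw: diffnet_multi_split(X1, X2, seed=seed, **kw).pvalue,
    "lrt-asym": lambda X1, X2, seed, kw: lrt_asym(X1, X2),
    "lrt-perm": lambda X1, X2, seed, kw: lrt_perm(X1, X2, seed=seed, **kw),
    "fisherz": lambda X1, X2, seed, kw: fisherz_test(X1, X2),
}


def pairwise_group_tests(
    data: DataMatrix,
    groups=None,
    method: str = "ss",
    alpha_fdr: float = 0.01,
    seed: int = 0,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test all pairs of known groups for network differences.

    Standardizes per group, runs the chosen test on every pair, adjusts the
    K(K-1)/2 raw P-values with Benjamini-Hochberg, and flags pairs
    significant at ``alpha_fdr`` (default 1% FDR).  Returns symmetric
    (adjusted-P, significance-mask) DataFrames indexed by group.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    if groups is None:
        groups = data.sample_labels
    if groups is None:
        raise ValueError("group labels required")
    groups = np.asarray(groups)
    labels = list(np.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    from .ggm_core import standardize_by_group

    std = standardize_by_group(data, groups)
    run = _METHODS[method]
    pairs = list(combinations(labels, 2))
    raw = []
    rng = np.random.default_rng(seed)
    for a, b in pairs:
        Xa = std.values[groups == a]
        Xb = std.values[groups == b]
        raw.append(run(Xa, Xb, int(rng.integers(2**31 - 1)), kwargs))
    if len(raw) == 1:
        adj = np.asarray(raw)
    else:
        adj = multipletests(raw, method="fdr_bh")[1]
    P = pd.DataFrame(np.nan, index=labels, columns=labels)
    for (a, b), q in zip(pairs, adj):
        P.loc[a, b] = P.loc[b, a] = q
    mask = P < alpha_fdr
    for g in labels:
        mask.loc[g, g] = False
    return P, mask
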