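"""Synthetic data from sparse-precision Gaussian (and heavy-tailed) mixtures,
plus the two simulation-study harnesses.

The generators draw from K-component mixtures in which every component has
its own mean vector and a randomly generated sparse precision matrix, the
same generative family the testing and clustering methods assume.  Default
scenario parameters are fixed here once: p = 30 variables, K = 9 components
with Dirichlet(5)-distributed proportions, edge density 0.1, partial
correlations of magnitude 0.2-0.5, and component means separated by about
4 units of (roughly Mahalanobis) distance.  Two-group scenarios for the
testing study use equal precision matrices under the null and a stated
number of perturbed edges under the alternative.

``run_diffnet_study`` measures type-I error, power and AUROC of the
two-sample tests across sample sizes; ``run_mixglasso_study`` measures
adjusted Rand index against the generating labels for the mixture methods
and standard clustering baselines across sample sizes.  Both return tidy
DataFrames and are reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score
from sklearn.mixture import GaussianMixture

from .diffnet import (
    diffnet_multi_split,
    diffnet_single_split,
    fisherz_test,
    lrt_asym,
    lrt_perm,
)
from .ggm_core import DataMatrix
from .mixglasso import adjusted_rand_index, em_fit, lambda_uni

# Default scenario: the study conditions used throughout the package.
DEFAULT_P = 30
DEFAULT_K = 9
DEFAULT_EDGE_DENSITY = 0.1
DEFAULT_PARTIAL_CORR_RANGE = (0.2, 0.5)
DEFAULT_DIRICHLET_CONCENTRATION = 5.0
DEFAULT_MEAN_SEPARATION = 4.0
DEFAULT_T_DOF = 5.0


# ---------------------------------------------------------------------------
# Scenario construction
# ---------------------------------------------------------------------------

@dataclass
class SimulationScenario:
    """Generative ground truth for one synthetic dataset."""

    K: int
    p: int
    n_per_component: np.ndarray
    means: np.ndarray
    precisions: np.ndarray
    family: str = "gaussian"
    t_dof: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_per_component = np.asarray(self.n_per_component, dtype=int)
        self.means = np.asarray(self.means, dtype=float)
        self.precisions = np.asarray(self.precisions, dtype=float)
        if np.any(self.n_per_component < 1):
            raise ValueError("all component sample sizes must be >= 1")
        if self.family not in ("gaussian", "multivariate_t"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "multivariate_t" and (self.t_dof is None or self.t_dof <= 2):
            raise ValueError("multivariate_t needs t_dof > 2 (finite covariance)")
        for k in range(self.K):
            w = np.linalg.eigvalsh(self.precisions[k])
            if w[0] <= 0:
                raise ValueError(f"precision {k} is not positive definite")

    @property
    def n_total(self) -> int:
        return int(self.n_per_component.sum())


def make_sparse_precision(
    p: int,
    edge_density: float = DEFAULT_EDGE_DENSITY,
    partial_corr_range: tuple[float, float] = DEFAULT_PARTIAL_CORR_RANGE,
    seed: int = 0,
) -> np.ndarray:
    """Random sparse positive-definite precision with controlled partial correlations.

    Edges are sampled independently with probability ``edge_density`` and
    given partial correlations of magnitude in ``partial_corr_range`` with
    random sign.  If the raw matrix is not safely positive definite the
    off-diagonal is damped; the result is rescaled so the implied covariance
    has unit diagonal (which leaves partial correlations unchanged).  Fails
    if damping pushes realized magnitudes more than 20% below the requested
    range after 100 attempts.
    """
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must lie in [0, 1]")
    lo, hi = partial_corr_range
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p, k=1)
    for _ in range(100):
        mask = rng.random(len(iu[0])) < edge_density
        if not mask.any():
            return np.eye(p)
        vals = np.zeros(len(iu[0]))
        mags = rng.uniform(lo, hi, size=mask.sum())
        signs = rng.choice([-1.0, 1.0], size=mask.sum())
        vals[mask] = mags * signs
        omega = np.eye(p)
        omega[iu] = -vals  # unit diagonal: off-diagonal = -partial correlation
        omega.T[iu] = -vals
        # damp until safely positive definite
        damp = 1.0
        for _ in range(60):
            w = np.linalg.eigvalsh(omega)
            if w[0] > 0.05:
                break
            damp *= 0.9
            omega[iu] = -vals * damp
            omega.T[iu] = -vals * damp
        else:
            continue
        if damp * lo < 0.8 * lo:  # realized magnitudes fell >20% below request
            continue
        sigma = np.linalg.inv(omega)
        d = np.sqrt(np.diag(sigma))
        omega = omega * np.outer(d, d)  # unit-diagonal implied covariance
        return (omega + omega.T) / 2.0
    raise RuntimeError(
        f"could not build a PD precision with density {edge_density} and "
        f"partial correlations in {partial_corr_range} after 100 attempts"
    )


def perturb_precision(omega: np.ndarray, n_edges_changed: int, seed: int = 0) -> np.ndarray:
    """Alter exactly ``n_edges_changed`` edges of a precision matrix.

    Existing edges are removed or sign-flipped; absent edges are added with
    a magnitude resampled from the existing ones (or 0.3 if the matrix is
    diagonal).  Positive definiteness is restored by damping the changed
    entries only, so the pattern difference from the input is exactly the
    selected set; the result is rescaled to a unit-diagonal implied
    covariance.
    """
    omega = np.asarray(omega, dtype=float).copy()
    p = omega.shape[0]
    iu = np.triu_indices(p, k=1)
    edges = [i for i in range(len(iu[0])) if omega[iu[0][i], iu[1][i]] != 0]
    non_edges = [i for i in range(len(iu[0])) if omega[iu[0][i], iu[1][i]] == 0]
    if n_edges_changed > len(edges) + len(non_edges):
        raise ValueError("n_edges_changed exceeds available pairs")
    if n_edges_changed == 0:
        return omega
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(edges) + len(non_edges), size=n_edges_changed, replace=False)
    mags = np.abs(omega[iu][edges]) if edges else np.array([0.3])
    changed: list[tuple[int, int, float]] = []
    for c in chosen:
        if c < len(edges):
            i = edges[c]
            j, jp = iu[0][i], iu[1][i]
            if rng.random() < 0.5:
                new = 0.0  # remove
            else:
                new = -omega[j, jp]  # flip
        else:
            i = non_edges[c - len(edges)]
            j, jp = iu[0][i], iu[1][i]
            new = float(rng.choice(mags) * rng.choice([-1.0, 1.0]))
        changed.append((j, jp, new))
    base = omega.copy()
    for damp_iter in range(60):
        damp = 0.9 ** damp_iter
        out = base.copy()
        for j, jp, new in changed:
            out[j, jp] = out[jp, j] = new * damp
        if np.linalg.eigvalsh(out)[0] > 0.02:
            sigma = np.linalg.inv(out)
            d = np.sqrt(np.diag(sigma))
            out = out * np.outer(d, d)
            return (out + out.T) / 2.0
    raise RuntimeError("could not restore positive definiteness after edge changes")


def default_scenario(
    K: int = DEFAULT_K,
    p: int = DEFAULT_P,
    n_total: int = 1800,
    seed: int = 0,
    family: str = "gaussian",
    t_dof: float | None = None,
    edge_density: float = DEFAULT_EDGE_DENSITY,
    partial_corr_range: tuple[float, float] = DEFAULT_PARTIAL_CORR_RANGE,
    mean_separation: float = DEFAULT_MEAN_SEPARATION,
    dirichlet_concentration: float = DEFAULT_DIRICHLET_CONCENTRATION,
) -> SimulationScenario:
    """The package's standard heterogeneous-mixture scenario.

    Component proportions are Dirichlet(concentration) draws (unequal
    cluster sizes), each component gets an independent sparse precision,
    and means are isotropic Gaussian draws rescaled so the average pairwise
    distance equals ``mean_separation`` (the implied covariances have unit
    diagonal, so this is approximately a Mahalanobis separation).
    """
    if family == "multivariate_t" and t_dof is None:
        t_dof = DEFAULT_T_DOF
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(np.full(K, dirichlet_concentration))
    n_k = np.maximum(1, np.round(props * n_total).astype(int))
    n_k[-1] += n_total - n_k.sum()
    if n_k[-1] < 1:
        deficit = 1 - n_k[-1]
        n_k[np.argmax(n_k)] -= deficit
        n_k[-1] = 1
    means = rng.standard_normal((K, p))
    if K > 1:
        dists = [np.linalg.norm(means[a] - means[b])
                 for a in range(K) for b in range(a + 1, K)]
        means *= mean_separation / np.mean(dists)
    precisions = np.stack([
        make_sparse_precision(p, edge_density, partial_corr_range,
                              seed=int(rng.integers(2**31 - 1)))
        for _ in range(K)
    ])
    return SimulationScenario(
        K=K, p=p, n_per_component=n_k, means=means, precisions=precisions,
        family=family, t_dof=t_dof, seed=seed,
    )


def sample_scenario(scenario: SimulationScenario) -> tuple[DataMatrix, np.ndarray]:
    """Draw one dataset (and its true labels) from a scenario.

    The multivariate-t family scales each component so its covariance
    matches the Gaussian case (Sigma * (dof-2)/dof inside the t draw).
    """
    rng = np.random.default_rng(scenario.seed)
    blocks, labels = [], []
    for k in range(scenario.K):
        n_k = int(scenario.n_per_component[k])
        sigma = np.linalg.inv(scenario.precisions[k])
        sigma = (sigma + sigma.T) / 2.0
        chol = np.linalg.cholesky(sigma)
        Z = rng.standard_normal((n_k, scenario.p)) @ chol.T
        if scenario.family == "multivariate_t":
            dof = float(scenario.t_dof)
            g = rng.chisquare(dof, size=n_k) / dof
            Z = Z * np.sqrt((dof - 2.0) / dof) / np.sqrt(g)[:, None]
        blocks.append(scenario.means[k] + Z)
        labels.append(np.full(n_k, k))
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    perm = rng.permutation(len(y))
    names = [f"V{j}" for j in range(scenario.p)]
    return DataMatrix(X[perm], names, y[perm]), y[perm]


def two_group_scenario(
    p: int = 10,
    n_per_group: int = 500,
    n_edges_changed: int = 0,
    seed: int = 0,
    edge_density: float = 0.25,
    partial_corr_range: tuple[float, float] = (0.3, 0.45),
) -> tuple[np.ndarray, np.ndarray]:
    """Two-group data with equal (null) or edge-perturbed (alternative) precisions."""
    rng = np.random.default_rng(seed)
    omega1 = make_sparse_precision(p, edge_density, partial_corr_range,
                                   seed=int(rng.integers(2**31 - 1)))
    if n_edges_changed > 0:
        omega2 = perturb_precision(omega1, n_edges_changed,
                                   seed=int(rng.integers(2**31 - 1)))
    else:
        omega2 = omega1
    out = []
    for omega in (omega1, omega2):
        sigma = np.linalg.inv(omega)
        chol = np.linalg.cholesky((sigma + sigma.T) / 2.0)
        out.append(rng.standard_normal((n_per_group, p)) @ chol.T)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Testing study (type-I error / power / AUROC vs sample size)
# ---------------------------------------------------------------------------

_TEST_RUNNERS = {
    "diffnet_ss": lambda X1, X2, seed: diffnet_single_split(X1, X2, seed=seed).pvalue,
    "diffnet_ms": lambda X1, X2, seed: diffnet_multi_split(X1, X2, seed=seed).pvalue,
    "lrt_asym": lambda X1, X2, seed: lrt_asym(X1, X2),
    "lrt_perm": lambda X1, X2, seed: lrt_perm(X1, X2, seed=seed),
    "fisherz": lambda X1, X2, seed: fisherz_test(X1, X2),
}


def run_diffnet_study(
    sample_sizes=(100, 250, 500),
    p: int = 10,
    n_replicates: int = 100,
    alpha: float = 0.05,
    methods=("diffnet_ss", "diffnet_ms", "lrt_asym", "lrt_perm", "fisherz"),
    n_edges_changed: int = 10,
    edge_density: float = 0.25,
    partial_corr_range: tuple[float, float] = (0.3, 0.45),
    seed: int = 0,
    ms_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Type-I error, power and AUROC of the two-sample tests per sample size.

    Each replicate draws one null pair (shared precision) and one
    alternative pair (``n_edges_changed`` perturbed edges); a method whose
    preconditions fail at a given n (e.g. the classical LRT when n <= p) is
    recorded as missing there.
    """
    unknown = set(methods) - set(_TEST_RUNNERS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for n in sample_sizes:
        pvals: dict[str, dict[str, list[float]]] = {
            m: {"null": [], "alt": []} for m in methods
        }
        failed: set[str] = set()
        for _ in range(n_replicates):
            rep_seed = int(rng.integers(2**31 - 1))
            for scen, changed in (("null", 0), ("alt", n_edges_changed)):
                X1, X2 = two_group_scenario(
                    p=p, n_per_group=n, n_edges_changed=changed,
                    seed=int(rng.integers(2**31 - 1)),
                    edge_density=edge_density,
                    partial_corr_range=partial_corr_range,
                )
                for m in methods:
                    if m in failed:
                        continue
                    try:
                        pv = _TEST_RUNNERS[m](X1, X2, rep_seed)
                    except ValueError:
                        failed.add(m)
                        continue
                    pvals[m][scen].append(pv)
        for m in methods:
            if m in failed or not pvals[m]["null"]:
                rows.append({"method": m, "n": n, "type_I_error": np.nan,
                             "power": np.nan, "auroc": np.nan,
                             "n_replicates": 0})
                continue
            null_p = np.array(pvals[m]["null"])
            alt_p = np.array(pvals[m]["alt"])
            scores = np.concatenate([-null_p, -alt_p])
            truth = np.concatenate([np.zeros(len(null_p)), np.ones(len(alt_p))])
            rows.append({
                "method": m,
                "n": n,
                "type_I_error": float((null_p <= alpha).mean()),
                "power": float((alt_p <= alpha).mean()),
                "auroc": float(roc_auc_score(truth, scores)),
                "n_replicates": len(null_p),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clustering study (ARI vs sample size, K selection)
# ---------------------------------------------------------------------------

def baseline_cluster(data, K: int, method: str, seed: int = 0) -> np.ndarray:
    """Labels from one of the clustering baselines.

    ``gmm_penalized_nonadaptive`` runs the same EM engine with the plain l1
    penalty (no pi_k^{1/2} factor, no partial-correlation scaling) at
    lambda_uni; ``gmm_unpenalized`` is a classical full-covariance Gaussian
    mixture; ``kmeans`` and ``hclust`` (Ward linkage) ignore covariance
    structure.
    """
    X = data.values if isinstance(data, DataMatrix) else np.asarray(data, dtype=float)
    if method in ("kmeans", "hclust") and K < 2:
        raise ValueError(f"{method} needs K >= 2")
    if method == "kmeans":
        return KMeans(n_clusters=K, n_init=5, random_state=seed).fit_predict(X)
    if method == "hclust":
        return fcluster(linkage(X, method="ward"), K, criterion="maxclust") - 1
    if method == "gmm_unpenalized":
        gm = GaussianMixture(n_components=K, covariance_type="full",
                             reg_covar=1e-9, n_init=2, random_state=seed)
        return gm.fit_predict(X)
    if method == "gmm_penalized_nonadaptive":
        fit = em_fit(X, K, lam=lambda_uni(*X.shape), penalty="lasso", seed=seed)
        return fit.labels
    if method == "mixglasso":
        fit = em_fit(X, K, lam=lambda_uni(*X.shape), penalty="adaptive", seed=seed)
        return fit.labels
    raise ValueError(f"unknown clustering method {method!r}")


def run_mixglasso_study(
    sample_sizes=(450, 900, 1800),
    K_true: int = DEFAULT_K,
    p: int = DEFAULT_P,
    n_replicates: int = 10,
    methods=("mixglasso", "kmeans", "hclust", "gmm_unpenalized",
             "gmm_penalized_nonadaptive"),
    seed: int = 0,
) -> pd.DataFrame:
    """Adjusted Rand index vs truth for each clustering method and sample size.

    K is treated as known.  Replicates are paired in both directions: within
    a replicate every method sees the same dataset, and across sample sizes
    the datasets are nested subsamples of one draw from a single scenario,
    so ARI-vs-n curves are not confounded by scenario-to-scenario
    variability.  The unpenalized Gaussian mixture is recorded as missing
    whenever the smallest true cluster has no more samples than variables
    (its covariance MLEs do not exist there).
    """
    rng = np.random.default_rng(seed)
    sizes = sorted(sample_sizes)
    n_max = sizes[-1]
    aris: dict[tuple[str, int], list[float]] = {
        (m, n): [] for m in methods for n in sizes
    }
    for _ in range(n_replicates):
        scen = default_scenario(K=K_true, p=p, n_total=n_max,
                                seed=int(rng.integers(2**31 - 1)))
        data, truth = sample_scenario(scen)
        rep_seed = int(rng.integers(2**31 - 1))
        for n in sizes:
            if n == n_max:
                keep = np.arange(n_max)
            else:
                keep = np.sort(rng.choice(n_max, size=n, replace=False))
            X_n, truth_n = data.values[keep], truth[keep]
            counts = np.bincount(truth_n, minlength=K_true)
            for m in methods:
                if m == "gmm_unpenalized" and counts.min() <= p:
                    continue
                try:
                    labels = baseline_cluster(X_n, K_true, m, seed=rep_seed)
                except (ValueError, RuntimeError, np.linalg.LinAlgError):
                    continue
                aris[(m, n)].append(adjusted_rand_index(truth_n, labels))
    rows = []
    for m in methods:
        for n in sizes:
            vals = np.asarray(aris[(m, n)])
            rows.append({
                "method": m,
                "n": n,
                "ari": float(vals.mean()) if vals.size else np.nan,
                "ari_sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "n_replicates": int(vals.size),
            })
    return pd.DataFrame(rows)
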