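"""Shared fixtures.

The expensive simulation-based fixtures are session-scoped so that the
null-calibration, uniformity and ordering checks reuse one set of
replicates.
"""

from __future__ import annotations

import numpy as np
import pytest

from ggmhet.diffnet import diffnet_multi_split, diffnet_single_split, lrt_perm
from ggmhet.simulate import two_group_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ss_null_pvalues():
    """Single-split P-values over 400 null replicates (n=500/group, p=10)."""
    pvals = []
    for s in range(400):
        X1, X2 = two_group_scenario(p=10, n_per_group=500, n_edges_changed=0,
                                    seed=s)
        pvals.append(diffnet_single_split(X1, X2, seed=s).pvalue)
    return np.asarray(pvals)


@pytest.fixture(scope="session")
def ms_null_pvalues():
    """Multi-split P-values over 12 null replicates (n=500/group, p=10)."""
    pvals = []
    for s in range(12):
        X1, X2 = two_group_scenario(p=10, n_per_group=500, n_edges_changed=0,
                                    seed=7000 + s)
        pvals.append(diffnet_multi_split(X1, X2, seed=s).pvalue)
    return np.asarray(pvals)


@pytest.fixture(scope="session")
def paired_power_pvalues():
    """Paired alternative-scenario P-values (MS, SS, permutation LRT).

    12 replicates of the alternative with 10 perturbed edges at
    n=500/group, p=10; each method sees the same datasets.
    """
    out = {"ms": [], "ss": [], "lrt_perm": []}
    for s in range(12):
        X1, X2 = two_group_scenario(p=10, n_per_group=500, n_edges_changed=10,
                                    seed=9000 + s)
        out["ms"].append(diffnet_multi_split(X1, X2, seed=s).pvalue)
        out["ss"].append(diffnet_single_split(X1, X2, seed=s).pvalue)
        out["lrt_perm"].append(lrt_perm(X1, X2, n_perm=199, seed=s))
    return {k: np.asarray(v) for k, v in out.items()}
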