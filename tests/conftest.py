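"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pytest

from fflnet.config import PipelineConfig
from fflnet.pipeline import run_pipeline
from fflnet.simulate import SimulationParams, generate, null_dataset


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)

def hypergeom_pmf_by_enumeration(N: int, K: int, n: int) -> np.ndarray:
    """P(X = j) for j = 0..n by enumerating every size-n draw from an N-item
    population whose first K items are 'marked'.  Feasible only for small N.
    """
    counts = np.zeros(n + 1)
    total = 0
    for draw in itertools.combinations(range(N), n):
        counts[sum(1 for x in draw if x < K)] += 1
        total += 1
    return counts / total if total else counts


def hypergeom_tail_by_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) from the enumeration pmf."""
    pmf = hypergeom_pmf_by_enumeration(N, K, n)
    return float(pmf[k:].sum()) if k <= n else 0.0


def bh_by_definition(pvals) -> np.ndarray:
    """adjusted p_i = min over j with p_(j) >= p_(i) of m * p_(j) / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(m * p[order[j]] / (j + 1) for j in range(i, m))
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def betweenness_by_path_counting(graph) -> dict:
    """Unnormalized betweenness via explicit shortest-path enumeration."""
    import networkx as nx
    nodes = list(graph.nodes)
    btw = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            try:
                paths = list(nx.all_shortest_paths(graph, s, t))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for v in path[1:-1]:
                    btw[v] += 1.0 / len(paths)
    return btw


def branch_recovery(labels, truth_branch) -> float:
    """Fraction of genes whose hard cluster label matches the planted branch,
    maximized over the two possible label-to-branch assignments."""
    common = [g for g in truth_branch if g in labels.index]
    if not common:
        return 0.0
    best = max(
        sum((truth_branch[g] == "A") == (labels[g] == v) for g in common)
        for v in (0, 1)
    )
    return best / len(common)


# ---------------------------------------------------------------------------
# fixtures

SMALL = dict(n_genes=600, n_mirnas=24, n_tfs=6, n_de_mirnas=8, n_de_down=4,
             n_enriched_mirnas=6, n_planted_ffl3=3, n_planted_ffl4=2,
             targets_per_mirna=20, ffl4_secondaries=6,
             n_background_annotated=80)


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A scaled-down parameter set for fast structural tests."""
    return SimulationParams(seed=0, **SMALL)


@pytest.fixture(scope="session")
def small_bundle(small_params):
    return generate(small_params)


@pytest.fixture(scope="session")
def study_bundle():
    """The default (study-condition) synthetic dataset, seed 0."""
    return generate(SimulationParams(seed=0))


@pytest.fixture(scope="session")
def study_result(study_bundle):
    """Full pipeline run on the study-condition dataset."""
    bundle, _ = study_bundle
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(bundle, PipelineConfig(seed=0, n_permutations=200))


@pytest.fixture(scope="session")
def null_bundle():
    return null_dataset(SimulationParams(seed=0))
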