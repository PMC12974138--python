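import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import microstab as ms


@pytest.fixture
def tiny_table():
    counts = np.array([[5, 3, 0, 2], [1, 0, 4, 5], [2, 2, 2, 2]])
    return ms.CountTable(counts, ["s1", "s2", "s3"], ["t1", "t2", "t3", "t4"])


@pytest.fixture
def tiny_metadata():
    df = pd.DataFrame(
        {
            "subject": ["a", "a", "b", "b"],
            "treatment": ["CON", "CON", "DF", "DF"],
            "timepoint": ["G0", "G30", "G0", "G30"],
            "total_born": [14.0, 14.0, 18.0, 18.0],
        },
        index=["a_G0", "a_G30", "b_G0", "b_G30"],
    )
    return ms.SampleMetadata(df)


@pytest.fixture
def small_study():
    """A compact but complete longitudinal study used across modules."""
    cfg = ms.SimulationConfig(
        n_subjects_per_arm=6,
        n_taxa=25,
        depth_mean=4000,
        n_correlated_pairs=3,
        subject_sd=0.2,
        seed=42,
        diff_taxa_spec=[ms.DiffSpec(0, "DF", ("G30", "G109"), 2.0)],
        outcome_spec=[ms.OutcomeSpec("total_born", (0,), (1.0,), 0.5)],
    )
    return ms.simulate_study(cfg)


def random_graph(rng: np.random.Generator, n: int, p: float) -> nx.Graph:
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    return g


def brute_force_mcc(g: nx.Graph) -> dict:
    """Exhaustive maximal-clique MCC for graphs with <= ~15 nodes.

    Enumerates every vertex subset, keeps cliques that are maximal, and sums
    (|C|-1)! over cliques of size >= 2 through each vertex.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    adj = {v: set(g.neighbors(v)) for v in nodes}
    scores = dict.fromkeys(nodes, 0.0)
    for size in range(2, n + 1):
        for sub in itertools.combinations(nodes, size):
            sset = set(sub)
            if not all(sset - {v} <= adj[v] for v in sub):
                continue
            if any(sset <= adj[w] for w in nodes if w not in sset):
                continue  # extendable, not maximal
            contrib = float(np.prod(np.arange(1, size)))
            for v in sub:
                scores[v] += contrib
    return scores


def topology_oracle(g: nx.Graph) -> dict:
    """Independent per-metric recomputation from the raw adjacency matrix."""
    from scipy.sparse.csgraph import shortest_path

    nodes = list(g.nodes)
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    deg = a.sum(axis=1)
    e = int(a.sum() / 2)
    sp = shortest_path(a, method="D", unweighted=True)
    finite = np.isfinite(sp) & ~np.eye(n, dtype=bool)
    cpl = sp[finite].mean() if finite.any() else float("nan")
    local = []
    for i in range(n):
        k = deg[i]
        if k < 2:
            local.append(0.0)
            continue
        nbrs = np.flatnonzero(a[i])
        links = a[np.ix_(nbrs, nbrs)].sum() / 2
        local.append(2.0 * links / (k * (k - 1)))
    density = 2.0 * e / (n * (n - 1))
    return {
        "n_nodes": n,
        "n_edges": e,
        "avg_neighbors": 2.0 * e / n,
        "characteristic_path_length": cpl,
        "clustering_coefficient": float(np.mean(local)),
        "density": density,
        "heterogeneity": float(np.sqrt(deg.var()) / deg.mean()),
        "centralization": (n / (n - 2)) * (deg.max() / (n - 1) - density),
    }
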