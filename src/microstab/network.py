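"""Co-occurrence network topology, natural-connectivity robustness and
maximal-clique-centrality (MCC) keystone ranking.

All spectral quantities use the unweighted 0/1 adjacency matrix: the
natural-connectivity formula references adjacency eigenvalues, and keystone
ranking in the source tooling (CytoHubba-style MCC) is likewise unweighted.
A weighted variant of natural connectivity (|r| as edge weight) is available
behind a flag for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import CliqueLimitError


@dataclass
class TopologySummary:
    """The standard network-analyzer metric bundle (one row per network)."""

    n_nodes: int
    n_edges: int
    avg_neighbors: float
    characteristic_path_length: float
    clustering_coefficient: float
    density: float
    heterogeneity: float
    centralization: float

    def to_series(self, name: str | None = None) -> pd.Series:
        return pd.Series(vars(self), name=name)


@dataclass
class RobustnessCurve:
    """Natural connectivity against the fraction of removed nodes."""

    curve: pd.DataFrame  # columns: fraction, mean_nc, sd_nc
    strategy: str
    n_reps: int
    seed: int | None


def topology_summary(net: nx.Graph) -> TopologySummary:
    """Eight-metric topology bundle.

    Characteristic path length averages shortest paths over *connected*
    ordered pairs only (the convention of common network analyzers, needed
    because thresholded co-occurrence networks are usually disconnected).
    Local clustering of degree<2 nodes counts as 0 in the mean.
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("topology summary needs >= 2 nodes")
    e = net.number_of_edges()
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    avg_neighbors = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1))

    total, pairs = 0.0, 0
    for _, dists in nx.all_pairs_shortest_path_length(net):
        total += sum(dists.values())
        pairs += len(dists) - 1  # exclude self
    cpl = total / pairs if pairs else float("nan")

    clustering = float(np.mean(list(nx.clustering(net).values())))
    mean_deg = degrees.mean()
    heterogeneity = float(np.sqrt(degrees.var()) / mean_deg) if mean_deg > 0 else float("nan")
    centralization = (n / (n - 2)) * (degrees.max() / (n - 1) - density) if n > 2 else 0.0
    return TopologySummary(n, e, avg_neighbors, cpl, clustering, density,
                           heterogeneity, float(centralization))


def _adjacency(net: nx.Graph, weighted: bool) -> np.ndarray:
    nodes = list(net.nodes)
    a = np.zeros((len(nodes), len(nodes)))
    idx = {v: k for k, v in enumerate(nodes)}
    for u, v, d in net.edges(data=True):
        w = abs(d.get("weight", 1.0)) if weighted else 1.0
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = w
    return a


def natural_connectivity(net: nx.Graph, weighted: bool = False) -> float:
    """ln of the mean of e^{k_i} over adjacency eigenvalues k_i.

    This is the log of the average Estrada-index term — a closed-walk
    redundancy score that strictly increases with every added edge.
    Stabilised via log-sum-exp; an edgeless graph scores exactly 0.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity undefined on an empty node set")
    if net.number_of_edges() == 0:
        return 0.0
    evals = np.linalg.eigvalsh(_adjacency(net, weighted))
    return float(logsumexp(evals) - np.log(n))


def robustness_curve(net: nx.Graph, strategy: str = "random", max_fraction: float = 0.8,
                     step: float = 0.05, n_reps: int = 100,
                     seed: int | None = None) -> RobustnessCurve:
    """Natural connectivity of the induced subgraph after removing a growing
    fraction of nodes.

    ``random``: uniform node removal without replacement, averaged over
    ``n_reps`` replicates.  ``degree``: deterministic removal in descending
    degree order (ties broken by node insertion order).
    """
    if net.number_of_nodes() < 3:
        raise ValueError("robustness curve needs >= 3 nodes")
    if not 0 <= max_fraction < 1:
        raise ValueError("max_fraction must lie in [0, 1)")
    if strategy not in ("random", "degree"):
        raise ValueError("strategy must be 'random' or 'degree'")
    nodes = list(net.nodes)
    n = len(nodes)
    fractions = np.arange(0.0, max_fraction + 1e-9, step)
    rng = np.random.default_rng(seed)
    if strategy == "degree":
        order = sorted(range(n), key=lambda i: -net.degree(nodes[i]))
        removal_orders = [order]
    else:
        removal_orders = [rng.permutation(n) for _ in range(n_reps)]

    rows = []
    for f in fractions:
        k = int(round(f * n))
        vals = []
        for order in removal_orders:
            keep = [nodes[i] for i in np.setdiff1d(np.arange(n), order[:k], assume_unique=True)]
            if not keep:
                vals.append(0.0)
                continue
            vals.append(natural_connectivity(net.subgraph(keep)))
        vals = np.asarray(vals)
        rows.append({"fraction": float(f), "mean_nc": float(vals.mean()),
                     "sd_nc": float(vals.std(ddof=0))})
    return RobustnessCurve(pd.DataFrame(rows), strategy,
                           n_reps if strategy == "random" else 1, seed)


def mcc_scores(net: nx.Graph, max_cliques: int = 2_000_000) -> pd.DataFrame:
    """Maximal-clique-centrality keystone scores and competition ranks.

    MCC(v) = sum over maximal cliques C (|C| >= 2) containing v of (|C|-1)!.
    When v's neighbourhood has no internal edges every maximal clique through
    v is a single edge, so the score reduces to degree(v); isolated nodes
    score 0.  Ranking is descending-score competition ranking ("1, 2, 2, 4"),
    reported with the network size as "rank/N".  Enumeration is
    Bron-Kerbosch (networkx ``find_cliques``) with a hard cap: exceeding
    ``max_cliques`` raises rather than hanging silently.
    """
    nodes = list(net.nodes)
    scores = dict.fromkeys(nodes, 0.0)
    gen = nx.find_cliques(net)
    count = 0
    for clique in islice(gen, max_cliques + 1):
        count += 1
        if count > max_cliques:
            raise CliqueLimitError(f"more than {max_cliques} maximal cliques; aborting")
        if len(clique) < 2:
            continue
        contrib = float(np.prod(np.arange(1, len(clique))))  # (|C|-1)!
        for v in clique:
            scores[v] += contrib
    df = pd.DataFrame({"node": nodes, "mcc": [scores[v] for v in nodes]})
    df = df.sort_values("mcc", ascending=False, kind="mergesort").reset_index(drop=True)
    # competition ranking: ties share the smallest rank
    ranks, last_score, last_rank = [], None, 0
    for i, s in enumerate(df["mcc"], start=1):
        if s != last_score:
            last_rank, last_score = i, s
        ranks.append(last_rank)
    df["rank"] = ranks
    df["n_nodes"] = len(nodes)
    df["rank_label"] = [f"{r}/{len(nodes)}" for r in ranks]
    return df
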