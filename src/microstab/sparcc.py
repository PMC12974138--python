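"""SparCC basis-correlation inference for compositional count data.

Counts only carry relative information; naive correlations on fractions are
distorted by closure.  SparCC works on the variation matrix
``t_ij = Var[log(f_i / f_j)]``, which is invariant to per-sample scaling,
and solves for latent ("basis") variances ``w_i^2`` under a sparsity
assumption (most taxa uncorrelated), giving

    rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j).

Strongly correlated pairs violate the sparsity approximation, so the
strongest pair above a threshold is iteratively excluded from the linear
system and the variances re-solved.  Fraction uncertainty is propagated by
averaging (element-wise median) over Dirichlet posterior draws of the
fractions.  Significance is a per-taxon permutation null with the add-one
pseudo-p rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SingularSystemError
from .io import CountTable

logger = logging.getLogger(__name__)

_VARIANCE_FLOOR = 1e-10


@dataclass
class SparccResult:
    """Median basis correlations, optional permutation pseudo-p values."""

    r: pd.DataFrame
    p: pd.DataFrame | None = None
    excluded_pairs: list[tuple[str, str]] | None = None
    n_inner: int = 20
    n_null: int = 0
    seed: int | None = None


def estimate_fractions(table: CountTable, n_draws: int, seed: int | None = None,
                       pseudocount: float = 1.0) -> list[np.ndarray]:
    """Per-sample taxon fractions.

    ``n_draws >= 1``: that many Dirichlet(counts + pseudocount) posterior
    draws.  ``n_draws == 0``: the single deterministic estimate
    (c_i + pseudocount) / (n + pseudocount * D); with ``pseudocount=0``
    (zero-free tables only) this is plain closure, exactly invariant to
    per-sample count scaling.
    """
    if table.n_taxa == 0 or table.n_samples == 0:
        raise ValueError("empty count table")
    if n_draws < 0:
        raise ValueError("n_draws must be >= 0")
    if pseudocount == 0 and (table.counts == 0).any():
        raise ValueError("pseudocount=0 requires a zero-free table")
    alpha = table.counts.astype(float) + pseudocount
    if n_draws == 0:
        return [alpha / alpha.sum(axis=1, keepdims=True)]
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        g = rng.standard_gamma(alpha)
        draws.append(g / g.sum(axis=1, keepdims=True))
    return draws


def variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """t_ij = sample variance (n-1 denominator) of log(f_i / f_j).

    Computed through the covariance of log fractions:
    t_ij = C_ii + C_jj - 2 C_ij.
    """
    f = np.asarray(fractions, dtype=float)
    if (f <= 0).any():
        raise ValueError("variation matrix requires strictly positive fractions")
    logf = np.log(f)
    c = np.cov(logf, rowvar=False, ddof=1)
    v = np.diag(c)
    t = v[:, None] + v[None, :] - 2.0 * c
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def basis_correlations(t: np.ndarray, exclusion_threshold: float = 0.1,
                       max_exclusions: int = 10, return_excluded: bool = False):
    """Solve the sparsity-approximation system for basis variances and
    convert log-ratio variances to correlations, iteratively excluding the
    strongest pair above ``exclusion_threshold`` (up to ``max_exclusions``
    rounds).  Negative solved variances are floored at 1e-10 with a warning.
    """
    t = np.asarray(t, dtype=float)
    d = t.shape[0]
    if d < 4:
        raise ValueError("SparCC needs >= 4 taxa for an identifiable system")
    m = np.ones((d, d)) + (d - 2) * np.eye(d)
    t_work = t.copy()
    excluded: list[tuple[int, int]] = []
    rho = np.eye(d)
    for _round in range(max_exclusions + 1):
        try:
            omega2 = np.linalg.solve(m, t_work.sum(axis=1))
        except np.linalg.LinAlgError as exc:
            raise SingularSystemError(
                "basis-variance system is singular (degenerate variation matrix)"
            ) from exc
        if (omega2 <= 0).any():
            n_bad = int((omega2 <= 0).sum())
            warnings.warn(f"{n_bad} non-positive basis variance(s) floored at {_VARIANCE_FLOOR}")
            omega2 = np.maximum(omega2, _VARIANCE_FLOOR)
        omega = np.sqrt(omega2)
        rho = (omega2[:, None] + omega2[None, :] - t) / (2.0 * np.outer(omega, omega))
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        if _round == max_exclusions:
            break
        # strongest not-yet-excluded pair above threshold
        a = np.abs(rho.copy())
        np.fill_diagonal(a, 0.0)
        for i, j in excluded:
            a[i, j] = a[j, i] = 0.0
        i, j = np.unravel_index(int(np.argmax(a)), a.shape)
        if a[i, j] <= exclusion_threshold:
            break
        excluded.append((int(i), int(j)))
        m[i, i] -= 1
        m[j, j] -= 1
        m[i, j] -= 1
        m[j, i] -= 1
        t_work[i, j] = t_work[j, i] = 0.0
    if return_excluded:
        return rho, excluded
    return rho


def sparcc(table: CountTable, n_inner: int = 20, seed: int | None = None,
           exclusion_threshold: float = 0.1, max_exclusions: int = 10,
           pseudocount: float = 1.0) -> SparccResult:
    """Median basis correlations over ``n_inner`` Dirichlet-draw pipelines.

    ``n_inner == 0`` runs the single deterministic pseudocount pipeline,
    which is useful for exact invariance checks.
    """
    if table.n_taxa < 4:
        raise ValueError("SparCC needs >= 4 taxa")
    if table.n_samples < 10:
        logger.warning("SparCC on %d samples; estimates will be unstable", table.n_samples)
    draws = estimate_fractions(table, n_inner, seed=seed, pseudocount=pseudocount)
    rhos = np.empty((len(draws), table.n_taxa, table.n_taxa))
    excluded_names: list[tuple[str, str]] = []
    for k, f in enumerate(draws):
        rho, excl = basis_correlations(variation_matrix(f), exclusion_threshold,
                                       max_exclusions, return_excluded=True)
        rhos[k] = rho
        if k == 0:
            excluded_names = [(table.taxon_ids[i], table.taxon_ids[j]) for i, j in excl]
    r = np.median(rhos, axis=0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    rdf = pd.DataFrame(r, index=table.taxon_ids, columns=table.taxon_ids)
    return SparccResult(r=rdf, excluded_pairs=excluded_names, n_inner=n_inner, seed=seed)


def sparcc_pvalues(table: CountTable, r_obs: pd.DataFrame, n_null: int = 100,
                   seed: int | None = None, n_inner: int = 20) -> pd.DataFrame:
    """Two-sided permutation pseudo-p values for observed correlations.

    Null datasets permute each taxon's counts independently across samples
    (destroying co-occurrence while keeping marginals); the full SparCC
    pipeline is rerun per null; p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_null).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    robs = np.abs(r_obs.to_numpy())
    exceed = np.zeros_like(robs)
    for _ in range(n_null):
        perm = np.empty_like(table.counts)
        for j in range(table.n_taxa):
            perm[:, j] = table.counts[rng.permutation(table.n_samples), j]
        null_table = CountTable(perm, list(table.sample_ids), list(table.taxon_ids))
        rnull = sparcc(null_table, n_inner=n_inner,
                       seed=int(rng.integers(2**31 - 1))).r.to_numpy()
        exceed += np.abs(rnull) >= robs
    p = (1.0 + exceed) / (1.0 + n_null)
    np.fill_diagonal(p, 1.0)
    p = np.minimum(p, p.T)
    return pd.DataFrame(p, index=r_obs.index, columns=r_obs.columns)


def run_sparcc(table: CountTable, n_inner: int = 20, n_null: int = 100,
               seed: int | None = None) -> SparccResult:
    """Convenience: correlations plus permutation pseudo-p in one call."""
    ss = np.random.SeedSequence(entropy=seed if seed is not None else 0)
    s_r, s_p = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2))
    res = sparcc(table, n_inner=n_inner, seed=s_r)
    res.p = sparcc_pvalues(table, res.r, n_null=n_null, seed=s_p, n_inner=n_inner)
    res.n_null = n_null
    res.seed = seed
    return res


def build_network(res: SparccResult, r_threshold: float = 0.5, p_threshold: float = 0.05,
                  keep_isolates: bool = True, stratum: str | None = None) -> nx.Graph:
    """Threshold a SparCC result into an undirected signed-weighted graph.

    Edge (i, j) iff |r_ij| > r_threshold and p_ij < p_threshold (strict).
    Node set is all taxa unless ``keep_isolates=False``.
    """
    for name, th in (("r_threshold", r_threshold), ("p_threshold", p_threshold)):
        if not 0 < th <= 1:
            raise ValueError(f"{name} must lie in (0, 1]")
    if res.p is None:
        raise ValueError("SparccResult carries no p-values; run sparcc_pvalues first")
    taxa = list(res.r.index)
    g = nx.Graph(stratum=stratum)
    if keep_isolates:
        g.add_nodes_from(taxa)
    r, p = res.r.to_numpy(), res.p.to_numpy()
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            if abs(r[i, j]) > r_threshold and p[i, j] < p_threshold:
                g.add_edge(taxa[i], taxa[j], weight=float(r[i, j]), p=float(p[i, j]))
    return g


def network_edge_list(g: nx.Graph) -> pd.DataFrame:
    rows = [{"source": u, "target": v, "r": d.get("weight", np.nan), "p": d.get("p", np.nan)}
            for u, v, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["source", "target", "r", "p"])
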