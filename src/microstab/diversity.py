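"""Alpha diversity, Bray-Curtis / PCoA ordination, PERMANOVA and the
Firmicutes-to-Bacteroidetes ratio.

Shannon uses natural log by default (values for gut communities typically
fall in the 3-5 range); Chao1 is the bias-corrected form, robust when no
doubletons are observed.  PERMANOVA permutes sample labels freely (one-way);
for repeated-measures designs invoke it per timepoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ZeroSumSampleError
from .io import CountTable, relative_abundance


@dataclass
class DistanceMatrix:
    """Symmetric sample dissimilarity matrix with zero diagonal."""

    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.sample_ids),) * 2:
            raise ValueError("distance matrix shape inconsistent with sample_ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(d, 0.0)
        self.data = d

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class Ordination:
    """PCoA embedding: axes ordered by descending eigenvalue."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray    # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over positive eigenvalues, per kept axis


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i (natural log unless ``base``)."""
    vec = np.asarray(counts, dtype=float)
    total = vec.sum()
    if total <= 0:
        raise ZeroSumSampleError("Shannon index undefined for an all-zero sample")
    p = vec[vec > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness from singleton/doubleton counts; >= observed richness."""
    vec = np.asarray(counts)
    if vec.sum() <= 0:
        raise ZeroSumSampleError("Chao1 undefined for an all-zero sample")
    s_obs = int((vec > 0).sum())
    f1 = int((vec == 1).sum())
    f2 = int((vec == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return float(s_obs) if f1 == 0 else s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1 * f1 / (2.0 * f2)


def alpha_diversity_table(table: CountTable) -> pd.DataFrame:
    """Per-sample Shannon, Chao1, observed richness and Good's coverage."""
    from .io import goods_coverage

    rows = {}
    for sid, row in zip(table.sample_ids, table.counts):
        rows[sid] = {
            "shannon": shannon(row),
            "chao1": chao1(row),
            "observed": int((row > 0).sum()),
            "goods_coverage": goods_coverage(row),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on counts: 1 - 2 sum min / (sum x + sum y)."""
    if (table.sample_sums() <= 0).any():
        raise ZeroSumSampleError("Bray-Curtis undefined for zero-sum samples")
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Classical scaling: eigendecompose the Gower-centred -d^2/2 matrix.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); only positive
    eigenvalues yield axes (no Cailliez/Lingoes correction — negatives are
    reported so callers can opt in to corrections elsewhere).  Each axis is
    flipped so its largest-|coordinate| sample is positive, fixing the sign
    indeterminacy.
    """
    dm = d.data
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(abs(evals[0]), 1.0) * 1e-12 if n else 0.0
    pos = evals > tol
    n_keep = min(n_axes, int(pos.sum()))
    coords = evecs[:, :n_keep] * np.sqrt(evals[:n_keep]) if n_keep else np.zeros((n, 0))
    for k in range(n_keep):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] *= -1
    pos_sum = evals[pos].sum()
    prop = evals[:n_keep] / pos_sum if n_keep and pos_sum > 0 else np.zeros(n_keep)
    cols = [f"PC{k + 1}" for k in range(n_keep)]
    return Ordination(pd.DataFrame(coords, index=d.sample_ids, columns=cols), evals, prop)


def _permanova_f(d2: np.ndarray, groups: np.ndarray, uniq: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(groups == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(uniq)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(d: DistanceMatrix, grouping, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """One-way PERMANOVA pseudo-F with permutation p = (1+#{F* >= F})/(1+n_perm)."""
    groups = np.asarray(pd.Series(grouping, index=d.sample_ids)
                        if not isinstance(grouping, pd.Series) else grouping.loc[d.sample_ids])
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 samples")
    d2 = d.data**2
    f_obs = _permanova_f(d2, groups, uniq)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _permanova_f(d2, rng.permutation(groups), uniq) >= f_obs:
            hits += 1
    return f_obs, (1 + hits) / (1 + n_perm)


_FIRMICUTES = ("Firmicutes", "Bacillota")
_BACTEROIDETES = ("Bacteroidetes", "Bacteroidota")


def fb_ratio(phylum_table: CountTable,
             firmicutes_names=_FIRMICUTES, bacteroidetes_names=_BACTEROIDETES) -> pd.Series:
    """Per-sample Firmicutes/Bacteroidetes relative-abundance ratio.

    Samples with zero Bacteroidetes get NaN with a warning rather than inf.
    """
    cols = {c.lower(): c for c in phylum_table.taxon_ids}
    f_col = next((cols[n.lower()] for n in firmicutes_names if n.lower() in cols), None)
    b_col = next((cols[n.lower()] for n in bacteroidetes_names if n.lower() in cols), None)
    if f_col is None and b_col is None:
        raise KeyError("neither Firmicutes nor Bacteroidetes found in phylum table")
    rel = relative_abundance(phylum_table)
    f = rel[f_col] if f_col else pd.Series(0.0, index=rel.index)
    b = rel[b_col] if b_col else pd.Series(0.0, index=rel.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = f / b
    bad = ~np.isfinite(ratio)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} sample(s) with zero Bacteroidetes; ratio set to NaN")
        ratio[bad] = np.nan
    ratio.name = "fb_ratio"
    return ratio
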