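"""Feature-outcome association statistics: Spearman matrices with star
annotations, two-group comparisons, and the metabolite volcano filter.

Correlation heatmaps in this kind of study are conventionally reported with
raw-p stars (* < 0.05, ** < 0.01, *** < 0.001); a BH-adjusted q matrix is
emitted alongside for rigor, clearly labelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateGroupError

_STAR_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    for cut, mark in _STAR_TIERS:
        if p < cut:
            return mark
    return ""


@dataclass
class AssociationMatrix:
    rho: pd.DataFrame  # features x outcomes
    p: pd.DataFrame
    stars: pd.DataFrame
    q: pd.DataFrame | None = None

    def to_long(self) -> pd.DataFrame:
        rows = []
        for f in self.rho.index:
            for o in self.rho.columns:
                rows.append({
                    "feature": f, "outcome": o,
                    "rho": self.rho.loc[f, o], "p": self.p.loc[f, o],
                    "q": self.q.loc[f, o] if self.q is not None else np.nan,
                    "stars": self.stars.loc[f, o],
                })
        return pd.DataFrame(rows)


@dataclass
class VolcanoResult:
    table: pd.DataFrame  # index feature: log2_fc, p, q, direction, kept

    def kept(self) -> set[str]:
        return set(self.table.index[self.table["kept"]])


def spearman_matrix(x: pd.DataFrame, y: pd.DataFrame, adjust: bool = False,
                    min_pairs: int = 4) -> AssociationMatrix:
    """Spearman rank correlations of every X feature against every Y outcome.

    Average ranks for ties, p from the t approximation, pairwise-complete
    handling of missing outcome values; constant columns give NaN with a
    warning.  ``adjust=True`` adds BH q-values computed across the whole
    matrix.
    """
    common = x.index.intersection(y.index)
    x, y = x.loc[common], y.loc[common]
    rho = pd.DataFrame(np.nan, index=x.columns, columns=y.columns, dtype=float)
    p = rho.copy()
    n_constant = 0
    for f in x.columns:
        xv = x[f].to_numpy(dtype=float)
        for o in y.columns:
            yv = y[o].to_numpy(dtype=float)
            ok = ~(np.isnan(xv) | np.isnan(yv))
            if ok.sum() < min_pairs:
                continue
            if np.all(xv[ok] == xv[ok][0]) or np.all(yv[ok] == yv[ok][0]):
                n_constant += 1
                continue
            res = stats.spearmanr(xv[ok], yv[ok])
            rho.loc[f, o], p.loc[f, o] = float(res.statistic), float(res.pvalue)
    if n_constant:
        warnings.warn(f"{n_constant} constant feature/outcome pair(s); correlation undefined")
    q = None
    if adjust:
        flat = p.to_numpy().ravel()
        qv = np.full_like(flat, np.nan)
        ok = ~np.isnan(flat)
        if ok.any():
            qv[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        q = pd.DataFrame(qv.reshape(p.shape), index=p.index, columns=p.columns)
    stars = p.map(_stars)
    return AssociationMatrix(rho, p, stars, q)


def group_compare(values, groups, method: str = "welch_t") -> tuple[float, float]:
    """Two-sided two-group comparison; returns (statistic, p).

    ``welch_t`` / ``student_t``: t tests (unequal / pooled variance);
    ``wilcoxon``: the rank-sum (Mann-Whitney) test.  Zero within-group
    variance in both groups is a degenerate case for the t methods.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    a, b = values[groups == labels[0]], values[groups == labels[1]]
    if min(len(a), len(b)) < 2:
        raise DegenerateGroupError("each group needs >= 2 values")
    if method in ("welch_t", "student_t"):
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            raise DegenerateGroupError("zero variance in both groups; t-test undefined")
        res = stats.ttest_ind(a, b, equal_var=(method == "student_t"))
    elif method == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def volcano_filter(features: pd.DataFrame, groups, q_threshold: float = 0.05,
                   fc_threshold: float = 1.0, floor: float | None = None) -> VolcanoResult:
    """Differential-feature volcano filter: keep features with BH q <
    ``q_threshold`` and |log2 fold change| > ``fc_threshold``.

    Fold change is the ratio of raw group-mean intensities (group2/group1 in
    sorted label order); the test is Welch's t on log intensities.  Features
    containing zeros are floored at half the smallest positive value (with a
    warning) so both scales stay defined.
    """
    groups = pd.Series(groups).reindex(features.index)
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    mat = features.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("feature intensities must be non-negative")
    if (mat == 0).any():
        pos = mat[mat > 0]
        fl = floor if floor is not None else (pos.min() / 2.0 if pos.size else 1.0)
        warnings.warn(f"zero intensities floored at {fl:g}")
        mat = np.maximum(mat, fl)
    ga = (groups == labels[0]).to_numpy()
    gb = (groups == labels[1]).to_numpy()
    rows = {}
    for j, f in enumerate(features.columns):
        a, b = mat[ga, j], mat[gb, j]
        log2_fc = float(np.log2(b.mean() / a.mean()))
        try:
            _, pval = group_compare(np.log(np.concatenate([a, b])),
                                    np.concatenate([np.zeros(len(a)), np.ones(len(b))]),
                                    method="welch_t")
        except DegenerateGroupError:
            pval = 1.0
        rows[f] = {"log2_fc": log2_fc, "p": pval}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["direction"] = np.where(out["log2_fc"] > 0, "up", np.where(out["log2_fc"] < 0, "down", "flat"))
    out["kept"] = (out["q"] < q_threshold) & (out["log2_fc"].abs() > fc_threshold)
    return VolcanoResult(out)
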