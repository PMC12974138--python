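"""Differential-genus screening: longitudinal mixed models, a two-class
LEfSe-style effect-size screen, and their intersection.

The mixed model is ``log10(relative abundance + delta) ~ treatment * time``
with a random intercept per subject (REML), delta being half the smallest
nonzero relative abundance of that taxon — a variance-stabilising transform
that keeps zero-heavy taxa in play.  Treatment, time and interaction blocks
are tested with Wald chi-square tests on the fitted fixed effects.

The LEfSe screen follows the classic two-stage recipe for a two-class
design with no subclass tier: a Kruskal-Wallis test on abundances scaled to
1e6, then a bootstrapped one-feature linear discriminant whose effect size
(|difference of class means on the discriminant axis|) is reported as
log10 ("LDA score"), thresholded at 2 by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io import CountTable, SampleMetadata, relative_abundance


@dataclass
class LmmFit:
    """One taxon's (or one alpha metric's) mixed-model fit."""

    p_treatment: float
    p_time: float
    p_interaction: float
    converged: bool
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    delta: float | None = None

    def interaction_coefficient(self, treatment: str, timepoint: str) -> str:
        """Name of the treatment x timepoint interaction coefficient."""
        for name in self.params.index:
            if f"[T.{treatment}]" in name and f"[T.{timepoint}]" in name and ":" in name:
                return name
        raise KeyError(f"no interaction coefficient for {treatment} x {timepoint}")


@dataclass
class LmmResult:
    """Per-taxon mixed-model screening table."""

    table: pd.DataFrame  # index taxon: p_treatment, p_time, p_interaction, converged, delta
    fits: dict[str, LmmFit] = field(default_factory=dict)

    def significant(self, alpha: float = 0.05, require_interaction: bool = False) -> set[str]:
        """Taxa simultaneously affected by treatment and time (raw p < alpha);
        optionally also requiring a significant interaction."""
        t = self.table
        mask = (t["p_treatment"] < alpha) & (t["p_time"] < alpha)
        if require_interaction:
            mask &= t["p_interaction"] < alpha
        return set(t.index[mask])


@dataclass
class LefseResult:
    table: pd.DataFrame  # index taxon: kw_p, lda_score, enriched_class, passed

    def passed(self) -> set[str]:
        return set(self.table.index[self.table["passed"]])


@dataclass
class DifferentialSets:
    lmm_set: set[str]
    lefse_set: set[str]
    intersection: set[str]
    floored: set[str]
    mean_relative_abundance: pd.Series

    def membership(self) -> pd.DataFrame:
        taxa = sorted(self.lmm_set | self.lefse_set)
        return pd.DataFrame({
            "lmm": [t in self.lmm_set for t in taxa],
            "lefse": [t in self.lefse_set for t in taxa],
            "intersection": [t in self.intersection for t in taxa],
            "floored": [t in self.floored for t in taxa],
        }, index=taxa)


def _wald_block_p(result, pattern_treat: str, pattern_time: str) -> tuple[float, float, float]:
    """Type-III-style marginal Wald chi-square tests for a dummy-coded
    treatment*time design.

    With treatment (dummy) coding the raw main-effect coefficients describe
    the reference cell only, so each main-effect contrast averages its
    interaction terms over the other factor's levels: the treatment test asks
    whether the DF-vs-CON difference, averaged over timepoints, is zero; the
    time test likewise averages over arms.  The interaction block is tested
    as-is.
    """
    names = list(result.params.index)
    treat_main = [i for i, n in enumerate(names)
                  if pattern_treat in n and ":" not in n]
    time_main = [i for i, n in enumerate(names)
                 if pattern_time in n and ":" not in n]
    inter = [i for i, n in enumerate(names)
             if ":" in n and pattern_treat in n and pattern_time in n]
    n_time_levels = len(time_main) + 1
    n_treat_levels = len(treat_main) + 1
    k = len(names)

    def level_token(name: str, pattern: str) -> str:
        start = name.index(pattern)
        return name[start:].split(":")[0]

    rows_treat = []
    for i in treat_main:
        row = np.zeros(k)
        row[i] = 1.0
        tok = level_token(names[i], pattern_treat)
        for j in inter:
            if tok in names[j]:
                row[j] = 1.0 / n_time_levels
        rows_treat.append(row)
    rows_time = []
    for i in time_main:
        row = np.zeros(k)
        row[i] = 1.0
        tok = level_token(names[i], pattern_time)
        for j in inter:
            if tok in names[j]:
                row[j] = 1.0 / n_treat_levels
        rows_time.append(row)
    rows_inter = []
    for j in inter:
        row = np.zeros(k)
        row[j] = 1.0
        rows_inter.append(row)

    out = []
    for rows in (rows_treat, rows_time, rows_inter):
        if not rows:
            out.append(np.nan)
            continue
        wt = result.wald_test(np.vstack(rows), scalar=True, use_f=False)
        out.append(float(wt.pvalue))
    return tuple(out)


def fit_lmm_single(y: pd.Series, metadata: SampleMetadata, delta: float | None = None) -> LmmFit:
    """REML mixed model ``y ~ treatment * time + (1 | subject)`` for one
    response series aligned to metadata sample IDs."""
    df = metadata.df.copy()
    df["y"] = pd.Series(y).reindex(df.index)
    df = df.dropna(subset=["y"])
    if df["timepoint"].nunique() < 2 or df.groupby("treatment")["subject"].nunique().min() < 2:
        raise ValueError("need >= 2 timepoints and >= 2 subjects per arm")
    order = [t for t in metadata.timepoint_order if t in set(df["timepoint"])]
    df["timepoint"] = pd.Categorical(df["timepoint"], categories=order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # boundary fits (zero subject variance) are legitimate here
        warnings.filterwarnings("ignore", message=".*Random effects covariance is singular.*")
        warnings.filterwarnings("ignore", message=".*The MLE may be on the boundary.*")
        model = smf.mixedlm("y ~ C(treatment) * C(timepoint)", df, groups=df["subject"])
        result = model.fit(reml=True)
    p_t, p_time, p_int = _wald_block_p(result, "C(treatment)", "C(timepoint)")
    fe = result.fe_params
    return LmmFit(
        p_treatment=p_t, p_time=p_time, p_interaction=p_int,
        converged=bool(result.converged),
        params=fe, bse=result.bse.loc[fe.index],
        conf_int=result.conf_int().loc[fe.index],
        delta=delta,
    )


def fit_lmm(table: CountTable, metadata: SampleMetadata,
            keep_fits: bool = False) -> LmmResult:
    """Mixed-model screen over every taxon of a count table.

    Response per taxon is log10(relative abundance + delta), delta = half the
    taxon's smallest nonzero relative abundance; all-zero taxa are skipped
    with a flag row (NaN p-values, converged=False).
    """
    rel = relative_abundance(table)
    rows, fits = {}, {}
    for taxon in table.taxon_ids:
        x = rel[taxon].to_numpy()
        nz = x[x > 0]
        if nz.size == 0:
            rows[taxon] = {"p_treatment": np.nan, "p_time": np.nan,
                           "p_interaction": np.nan, "converged": False, "delta": np.nan}
            continue
        delta = float(nz.min()) / 2.0
        y = pd.Series(np.log10(x + delta), index=table.sample_ids)
        fit = fit_lmm_single(y, metadata, delta=delta)
        rows[taxon] = {"p_treatment": fit.p_treatment, "p_time": fit.p_time,
                       "p_interaction": fit.p_interaction, "converged": fit.converged,
                       "delta": delta}
        if keep_fits:
            fits[taxon] = fit
    out = pd.DataFrame.from_dict(rows, orient="index")
    # BH-adjusted columns alongside the raw p-values used for screening
    for col in ("p_treatment", "p_time", "p_interaction"):
        p = out[col].to_numpy()
        q = np.full_like(p, np.nan, dtype=float)
        ok = ~np.isnan(p)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        out["q" + col[1:]] = q
    return LmmResult(out, fits)


def lefse(table: CountTable, classes: pd.Series, alpha: float = 0.05,
          lda_threshold: float = 2.0, n_boot: int = 30, boot_fraction: float = 2 / 3,
          seed: int | None = None) -> LefseResult:
    """Two-class LEfSe-style screen on one timepoint's samples.

    ``classes`` maps sample ID -> class label (exactly two labels, >= 3
    samples each).  Abundances are per-sample proportions scaled to 1e6.
    """
    classes = pd.Series(classes).reindex(table.sample_ids)
    labels = sorted(classes.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"LEfSe needs exactly two classes, got {labels}")
    idx = {lab: np.flatnonzero((classes == lab).to_numpy()) for lab in labels}
    if min(len(v) for v in idx.values()) < 3:
        raise ValueError("each class needs >= 3 samples")
    # iterate classes by smallest sample position, not by label, so that
    # relabeling the classes flips enriched_class but preserves the scores
    ordered = sorted(labels, key=lambda lab: int(idx[lab].min()))
    ia, ib = idx[ordered[0]], idx[ordered[1]]
    scaled = relative_abundance(table).to_numpy() * 1e6
    rng = np.random.default_rng(seed)
    rows = {}
    for j, taxon in enumerate(table.taxon_ids):
        a, b = scaled[ia, j], scaled[ib, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            rows[taxon] = {"kw_p": 1.0, "lda_score": np.nan,
                           "enriched_class": "", "passed": False}
            continue
        kw_p = float(stats.kruskal(a, b).pvalue)
        if kw_p >= alpha:
            rows[taxon] = {"kw_p": kw_p, "lda_score": np.nan,
                           "enriched_class": "", "passed": False}
            continue
        effects = []
        for _ in range(n_boot):
            sa = a[rng.choice(len(a), max(1, int(round(boot_fraction * len(a)))), replace=False)]
            sb = b[rng.choice(len(b), max(1, int(round(boot_fraction * len(b)))), replace=False)]
            # one-feature discriminant: the unit-norm axis is the feature
            # itself, so the projected effect is the class-mean difference
            effects.append(abs(sa.mean() - sb.mean()))
        lda_score = float(np.log10(max(np.mean(effects), 1.0)))
        enriched = ordered[0] if a.mean() >= b.mean() else ordered[1]
        rows[taxon] = {"kw_p": kw_p, "lda_score": lda_score,
                       "enriched_class": enriched,
                       "passed": lda_score > lda_threshold}
    return LefseResult(pd.DataFrame.from_dict(rows, orient="index"))


def intersect_differential(lmm: LmmResult, lefse_res: LefseResult, table: CountTable,
                           floor: float = 0.001, alpha: float = 0.05) -> DifferentialSets:
    """Key-genus logic: (treatment AND time significant in the LMM) ∩
    (LEfSe passed), then filtered to overall mean relative abundance >
    ``floor``.  All tiers are reported, not just the final subset."""
    lmm_set = lmm.significant(alpha=alpha)
    lefse_set = lefse_res.passed()
    inter = lmm_set & lefse_set
    mean_rel = relative_abundance(table).mean(axis=0)
    floored = {t for t in inter if mean_rel.get(t, 0.0) > floor}
    return DifferentialSets(lmm_set, lefse_set, inter, floored, mean_rel)
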