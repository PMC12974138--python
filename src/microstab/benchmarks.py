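"""Ground-truth recovery experiments.

Each function simulates data with the synthetic-study generator, runs one
inference stage of the package on it, and scores the result against the
planted truth.  They are the package's built-in calibration/validation
battery: edge recovery for SparCC networks, type-I error for PERMANOVA,
confidence-interval coverage and null calibration for the mixed model, and
detection rates for the LEfSe screen.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import diversity as dv
from . import differential as da
from .io import relative_abundance
from .simulate import DiffSpec, GroundTruth, SimulationConfig, simulate_counts
from .sparcc import build_network, run_sparcc


def sparcc_recovery(seed: int = 1, n_taxa: int = 50, n_samples: int = 200,
                    depth: int = 50_000, n_pairs: int = 10, rho: float = 0.8,
                    n_inner: int = 20, n_null: int = 100,
                    r_threshold: float = 0.5, p_threshold: float = 0.05) -> dict:
    """Edge-recovery experiment: planted correlated pairs vs the thresholded
    SparCC network.  Returns sensitivity, specificity and the mean |r| over
    truly uncorrelated pairs."""
    cfg = SimulationConfig(n_subjects_per_arm=n_samples // 2, timepoints=("T0",),
                           n_taxa=n_taxa, depth_mean=depth, depth_dispersion=0.0,
                           n_correlated_pairs=n_pairs, pair_rho=rho,
                           subject_sd=0.0, seed=seed)
    table, _, truth = simulate_counts(cfg)
    res = run_sparcc(table, n_inner=n_inner, n_null=n_null, seed=seed)
    g = build_network(res, r_threshold=r_threshold, p_threshold=p_threshold)
    planted = truth.correlated_index_pairs()
    taxa = table.taxon_ids
    edges = {frozenset(e) for e in g.edges}
    r = res.r.to_numpy()
    tp = fp = fn = tn = 0
    null_r = []
    for i, j in itertools.combinations(range(n_taxa), 2):
        found = frozenset({taxa[i], taxa[j]}) in edges
        if (i, j) in planted:
            tp += found
            fn += not found
        else:
            fp += found
            tn += not found
            null_r.append(abs(r[i, j]))
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "mean_abs_null_r": float(np.mean(null_r)),
        "n_edges": g.number_of_edges(),
    }


def permanova_type_i_error(n_datasets: int = 500, n_perm: int = 199,
                           alpha: float = 0.05, seed: int = 0,
                           n_per_arm: int = 16, n_taxa: int = 40,
                           depth: int = 5_000) -> dict:
    """Share of null datasets (one homogeneous cloud, arbitrary two-arm
    labels) rejected at ``alpha`` by Bray-Curtis PERMANOVA."""
    rejections = 0
    for rep in range(n_datasets):
        cfg = SimulationConfig(n_subjects_per_arm=n_per_arm, timepoints=("G0",),
                               n_taxa=n_taxa, depth_mean=depth,
                               n_correlated_pairs=0, subject_sd=0.0,
                               seed=seed * 1_000_003 % (2**31 - 1) + rep)
        table, meta, _ = simulate_counts(cfg)
        dm = dv.bray_curtis(table)
        _, p = dv.permanova(dm, meta.df.loc[dm.sample_ids, "treatment"],
                            n_perm=n_perm, seed=rep)
        rejections += p <= alpha
    return {"type_i_error": rejections / n_datasets, "n_datasets": n_datasets}


def true_interaction_coefficient(truth: GroundTruth, taxon_idx: int, log2_effect: float,
                                 n_mc: int = 20_000, seed: int = 0) -> float:
    """Planted treatment x timepoint effect on the log10 relative-abundance
    scale, closure included: difference of E[log10 rel] with and without the
    boost, by Monte Carlo on the abundance model.  This is the parameter the
    mixed model actually estimates (the raw log2 effect is attenuated because
    boosting one taxon shrinks every other relative abundance)."""
    rng = np.random.default_rng(seed)
    mu = truth.taxon_log_means
    z = rng.standard_normal((n_mc, len(mu)))
    base = mu + z
    boosted = base.copy()
    boosted[:, taxon_idx] += log2_effect * np.log(2)

    def mean_log10_rel(log_abund):
        return float(np.mean(log_abund[:, taxon_idx] / np.log(10)
                             - np.log10(np.exp(log_abund).sum(axis=1))))

    return mean_log10_rel(boosted) - mean_log10_rel(base)


def _lmm_fit_taxon(table, meta, taxon):
    rel = relative_abundance(table)
    x = rel[taxon].to_numpy()
    delta = x[x > 0].min() / 2
    y = pd.Series(np.log10(x + delta), index=table.sample_ids)
    return da.fit_lmm_single(y, meta)


def lmm_interaction_coverage(n_reps: int = 200, seed: int = 0, n_taxa: int = 40,
                             n_per_arm: int = 16, depth: int = 20_000,
                             log2_effect: float = 2.0) -> dict:
    """95% CI coverage of the planted (closure-adjusted) interaction
    coefficient over repeated studies."""
    covered = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(n_subjects_per_arm=n_per_arm, n_taxa=n_taxa,
                               depth_mean=depth, n_correlated_pairs=0,
                               subject_sd=0.3, seed=seed * 7 + 1000 + rep,
                               diff_taxa_spec=[DiffSpec(0, "DF", ("G30",), log2_effect)])
        table, meta, truth = simulate_counts(cfg)
        fit = _lmm_fit_taxon(table, meta, "g__Genus_000")
        name = fit.interaction_coefficient("DF", "G30")
        lo, hi = fit.conf_int.loc[name]
        target = true_interaction_coefficient(truth, 0, log2_effect, seed=rep)
        covered += lo <= target <= hi
    return {"coverage": covered / n_reps, "n_reps": n_reps}


def lmm_null_pvalues(n_reps: int = 200, seed: int = 0, n_taxa: int = 20,
                     n_per_arm: int = 16, depth: int = 20_000) -> dict:
    """Interaction-test p-values under the global null, plus their KS
    uniformity p-value."""
    ps = []
    for rep in range(n_reps):
        cfg = SimulationConfig(n_subjects_per_arm=n_per_arm, n_taxa=n_taxa,
                               depth_mean=depth, n_correlated_pairs=0,
                               subject_sd=0.3, seed=seed * 13 + 5000 + rep)
        table, meta, _ = simulate_counts(cfg)
        fit = _lmm_fit_taxon(table, meta, "g__Genus_003")
        ps.append(fit.p_interaction)
    ks = stats.kstest(ps, "uniform")
    return {"pvalues": ps, "ks_p": float(ks.pvalue)}


def lefse_detection(seed: int = 7, n_planted: int = 10, n_taxa: int = 100,
                    n_per_arm: int = 16, depth: int = 30_000,
                    log2_effect: float = 3.0, n_null_reps: int = 20) -> dict:
    """Detection of planted 8-fold (2^3) DF-enriched taxa plus the average
    pass rate over exchangeable-null replicate studies."""
    cfg = SimulationConfig(n_subjects_per_arm=n_per_arm, timepoints=("G109",),
                           n_taxa=n_taxa, depth_mean=depth, n_correlated_pairs=0,
                           subject_sd=0.0, seed=seed,
                           diff_taxa_spec=[DiffSpec(i, "DF", ("G109",), log2_effect)
                                           for i in range(n_planted)])
    table, meta, _ = simulate_counts(cfg)
    res = da.lefse(table, meta.df["treatment"], seed=seed)
    planted = [table.taxon_ids[i] for i in range(n_planted)]
    detected = sum(bool(res.table.loc[t, "passed"]) for t in planted)
    correct_class = sum(res.table.loc[t, "enriched_class"] == "DF"
                        for t in planted if res.table.loc[t, "passed"])

    null_rates = []
    for rep in range(n_null_reps):
        cfg_null = SimulationConfig(n_subjects_per_arm=n_per_arm, timepoints=("G109",),
                                    n_taxa=n_taxa, depth_mean=depth,
                                    n_correlated_pairs=0, subject_sd=0.0,
                                    seed=seed * 17 + 900 + rep)
        tb, m, _ = simulate_counts(cfg_null)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = da.lefse(tb, m.df["treatment"], seed=rep)
        null_rates.append(float(r.table["passed"].mean()))
    return {
        "detected": detected,
        "n_planted": n_planted,
        "correct_class": correct_class,
        "null_pass_rate": float(np.mean(null_rates)),
    }
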