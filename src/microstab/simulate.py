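"""Synthetic longitudinal two-arm compositional count studies with known truth.

The generator emulates the design of a two-diet sow cohort: two treatment
arms (CON / DF), six sampling timepoints spanning gestation and lactation,
16 subjects per arm, genus-level compositional counts.  On the log scale the
community is multivariate normal with heterogeneous taxon means (strongly
uneven communities), a sparse planted basis-correlation structure, optional
arm x timepoint differential effects, and per-subject random intercepts;
reads are multinomial at a log-normally varying depth.  Litter outcomes are
linear in the log relative abundances of designated taxa.  Every planted
feature is recorded in a :class:`GroundTruth` so downstream inference can be
scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import CountTable, SampleMetadata, TaxonomyTable, TIMEPOINTS, TREATMENTS

_LN2 = float(np.log(2.0))

# stage indices for child-seed derivation (fixed arithmetic on the one seed)
_STAGES = {"means": 1, "basis": 2, "subject": 3, "depth": 4, "counts": 5, "outcomes": 6, "taxonomy": 7}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the single study seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES[stage],)))


class DiffSpec(NamedTuple):
    """A planted differential effect: taxon gets ``log2_effect`` added (log2
    scale) in ``arm`` at the listed ``timepoints``."""

    taxon: int
    arm: str
    timepoints: tuple[str, ...]
    log2_effect: float


class OutcomeSpec(NamedTuple):
    """A per-subject outcome linked linearly to log relative abundances of
    ``taxa`` (coefficients ``coefs``) at ``timepoint``, plus Gaussian noise."""

    name: str
    taxa: tuple[int, ...]
    coefs: tuple[float, ...]
    noise_sd: float
    timepoint: str = "G109"
    intercept: float = 16.0


@dataclass
class SimulationConfig:
    """Study-design knobs; defaults are the emulated cohort's conditions."""

    n_subjects_per_arm: int = 16
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_taxa: int = 150
    depth_mean: int = 30_000
    depth_dispersion: float = 0.3  # SD of log depth
    n_correlated_pairs: int = 10
    pair_rho: float = 0.8
    diff_taxa_spec: tuple[DiffSpec, ...] = ()
    subject_sd: float = 0.3
    outcome_spec: tuple[OutcomeSpec, ...] = ()
    taxon_mean_sd: float = 1.5  # spread of log taxon means (community unevenness)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_subjects_per_arm < 1 or not self.timepoints:
            raise ValueError("degenerate design: need >=1 taxon, subject and timepoint")
        if self.n_taxa < 2 * self.n_correlated_pairs:
            raise ValueError("n_taxa must be >= 2 * n_correlated_pairs")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.depth_dispersion < 0 or self.subject_sd < 0:
            raise ValueError("dispersions must be non-negative")
        self.diff_taxa_spec = tuple(DiffSpec(*d) if not isinstance(d, DiffSpec) else d
                                    for d in self.diff_taxa_spec)
        self.outcome_spec = tuple(OutcomeSpec(*o) if not isinstance(o, OutcomeSpec) else o
                                  for o in self.outcome_spec)
        for d in self.diff_taxa_spec:
            if not 0 <= d.taxon < self.n_taxa:
                raise ValueError(f"differential taxon index {d.taxon} out of range")
            if d.arm not in TREATMENTS:
                raise ValueError(f"unknown arm {d.arm!r}")
        for o in self.outcome_spec:
            if any(not 0 <= t < self.n_taxa for t in o.taxa):
                raise ValueError(f"outcome {o.name!r} links a taxon out of range")
            if len(o.taxa) != len(o.coefs):
                raise ValueError(f"outcome {o.name!r}: taxa/coefs length mismatch")

    # YAML round-trip for the CLI ----------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["diff_taxa_spec"] = [list(x) for x in self.diff_taxa_spec]
        d["outcome_spec"] = [list(x) for x in self.outcome_spec]
        d["timepoints"] = list(self.timepoints)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        d["timepoints"] = tuple(d.get("timepoints", TIMEPOINTS))
        d["diff_taxa_spec"] = tuple(
            DiffSpec(int(t), str(a), tuple(tp), float(e)) for t, a, tp, e in d.get("diff_taxa_spec", [])
        )
        d["outcome_spec"] = tuple(
            OutcomeSpec(str(x[0]), tuple(int(i) for i in x[1]), tuple(float(c) for c in x[2]),
                        float(x[3]), *[str(v) if k == 0 else float(v) for k, v in enumerate(x[4:])])
            for x in d.get("outcome_spec", [])
        )
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything planted by the simulator, for recovery scoring."""

    basis_correlation: np.ndarray
    correlated_pairs: list[tuple[int, int, float]]
    differential_taxa: list[DiffSpec]
    outcome_spec: list[OutcomeSpec]
    subject_effects: pd.DataFrame  # subjects x taxa random intercepts (log scale)
    taxon_log_means: np.ndarray
    taxon_ids: list[str] = field(default_factory=list)

    def correlated_index_pairs(self) -> set[tuple[int, int]]:
        return {(min(i, j), max(i, j)) for i, j, _ in self.correlated_pairs}

    def to_json(self, path) -> None:
        payload = {
            "correlated_pairs": [[int(i), int(j), float(r)] for i, j, r in self.correlated_pairs],
            "differential_taxa": [[d.taxon, d.arm, list(d.timepoints), d.log2_effect]
                                  for d in self.differential_taxa],
            "outcome_spec": [[o.name, list(o.taxa), list(o.coefs), o.noise_sd, o.timepoint, o.intercept]
                             for o in self.outcome_spec],
            "taxon_log_means": [float(x) for x in self.taxon_log_means],
            "taxon_ids": list(self.taxon_ids),
            "subject_effects": {s: [float(v) for v in row]
                                for s, row in self.subject_effects.iterrows()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def generate_basis_correlation(n_taxa: int, n_pairs: int, rho: float, seed: int) -> np.ndarray:
    """Identity correlation matrix with ``n_pairs`` disjoint off-diagonal
    pairs set to ``rho``; positive definite for |rho| < 1 (2x2 blocks have
    eigenvalues 1 +/- rho)."""
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1 for a valid correlation matrix")
    if 2 * n_pairs > n_taxa:
        raise ValueError("need n_taxa >= 2 * n_pairs for disjoint pairs")
    rng = np.random.default_rng(seed)
    corr = np.eye(n_taxa)
    chosen = rng.permutation(n_taxa)[: 2 * n_pairs]
    for k in range(n_pairs):
        i, j = int(chosen[2 * k]), int(chosen[2 * k + 1])
        corr[i, j] = corr[j, i] = rho
    return corr


def _planted_pairs(corr: np.ndarray) -> list[tuple[int, int, float]]:
    iu = np.triu_indices_from(corr, k=1)
    mask = corr[iu] != 0
    return [(int(i), int(j), float(corr[i, j]))
            for i, j in zip(iu[0][mask], iu[1][mask])]


def simulate_counts(config: SimulationConfig) -> tuple[CountTable, SampleMetadata, GroundTruth]:
    """Draw the full count table plus metadata and ground truth.

    Per sample: correlated log-normal basis abundances -> arm/time/subject
    effects on the log scale -> closure to fractions -> multinomial counts at
    a log-normal depth.  Bit-identical for identical (config, seed).
    """
    D, S, T = config.n_taxa, config.n_subjects_per_arm, len(config.timepoints)
    taxon_ids = [f"g__Genus_{i:03d}" for i in range(D)]
    subjects = [f"{arm}_s{k + 1:02d}" for arm in TREATMENTS for k in range(S)]
    arms = {s: s.split("_")[0] for s in subjects}

    mu = stage_rng(config.seed, "means").normal(0.0, config.taxon_mean_sd, size=D)
    corr = generate_basis_correlation(D, config.n_correlated_pairs, config.pair_rho,
                                      seed=int(stage_rng(config.seed, "basis").integers(2**31 - 1)))
    chol = np.linalg.cholesky(corr)

    subj_fx = stage_rng(config.seed, "subject").normal(0.0, config.subject_sd, size=(len(subjects), D)) \
        if config.subject_sd > 0 else np.zeros((len(subjects), D))
    subject_effects = pd.DataFrame(subj_fx, index=subjects, columns=taxon_ids)

    n_samples = len(subjects) * T
    rng_depth = stage_rng(config.seed, "depth")
    if config.depth_dispersion > 0:
        depths = np.round(np.exp(rng_depth.normal(np.log(config.depth_mean),
                                                  config.depth_dispersion, size=n_samples))).astype(int)
        depths = np.maximum(depths, 1)
    else:
        depths = np.full(n_samples, int(config.depth_mean))

    # planted effects as a (arm, timepoint) -> additive log vector lookup
    effect = {(a, tp): np.zeros(D) for a in TREATMENTS for tp in config.timepoints}
    for d in config.diff_taxa_spec:
        for tp in d.timepoints:
            effect[(d.arm, tp)][d.taxon] += d.log2_effect * _LN2

    rng = stage_rng(config.seed, "counts")
    counts = np.empty((n_samples, D), dtype=np.int64)
    sample_ids, meta_rows = [], []
    row = 0
    for si, subj in enumerate(subjects):
        for tp in config.timepoints:
            z = chol @ rng.standard_normal(D)
            log_abund = mu + z + subj_fx[si] + effect[(arms[subj], tp)]
            frac = np.exp(log_abund - log_abund.max())
            frac /= frac.sum()
            counts[row] = rng.multinomial(depths[row], frac)
            sid = f"{subj}_{tp}"
            sample_ids.append(sid)
            meta_rows.append({"subject": subj, "treatment": arms[subj], "timepoint": tp})
            row += 1

    table = CountTable(counts, sample_ids, taxon_ids)
    meta = SampleMetadata(pd.DataFrame(meta_rows, index=sample_ids), tuple(config.timepoints))
    truth = GroundTruth(
        basis_correlation=corr,
        correlated_pairs=_planted_pairs(corr),
        differential_taxa=list(config.diff_taxa_spec),
        outcome_spec=list(config.outcome_spec),
        subject_effects=subject_effects,
        taxon_log_means=mu,
        taxon_ids=taxon_ids,
    )
    return table, meta, truth


def simulate_outcomes(table: CountTable, truth: GroundTruth, metadata: SampleMetadata,
                      seed: int) -> SampleMetadata:
    """Attach per-subject outcomes = linear combination of log relative
    abundances of the linked taxa at the designated timepoint + noise."""
    if not truth.outcome_spec:
        raise ValueError("ground truth carries no outcome_spec")
    df = metadata.df.copy()
    rel = table.counts / table.counts.sum(axis=1, keepdims=True)
    rel_df = pd.DataFrame(rel, index=table.sample_ids, columns=table.taxon_ids)
    rng = np.random.default_rng(seed)
    subjects = list(dict.fromkeys(df["subject"]))
    for spec in truth.outcome_spec:
        for t in spec.taxa:
            if table.taxon_ids[t] not in rel_df.columns:
                raise KeyError(f"linked taxon index {t} absent from table")
        vals = {}
        for subj in subjects:
            mask = (df["subject"] == subj) & (df["timepoint"] == spec.timepoint)
            sids = df.index[mask]
            if len(sids) == 0:
                vals[subj] = np.nan
                continue
            logrel = np.log(rel_df.loc[sids].iloc[:, list(spec.taxa)].to_numpy() + 1e-12)
            signal = float(np.mean(logrel, axis=0) @ np.asarray(spec.coefs))
            vals[subj] = spec.intercept + signal + rng.normal(0.0, spec.noise_sd)
        df[spec.name] = df["subject"].map(vals)
    return SampleMetadata(df, metadata.timepoint_order)


# ---------------------------------------------------------------------------
# Taxonomy + full-study convenience
# ---------------------------------------------------------------------------

_PHYLA = ("Firmicutes", "Bacteroidota", "Proteobacteria", "Spirochaetota", "Actinobacteriota")
_PHYLUM_W = (0.50, 0.25, 0.12, 0.06, 0.07)


def make_taxonomy(taxon_ids: Sequence[str], seed: int) -> TaxonomyTable:
    """Assign plausible genus-level lineages (phyla dominated by Firmicutes
    and Bacteroidota, as in mammalian gut communities)."""
    rng = np.random.default_rng(seed)
    phyla = rng.choice(_PHYLA, size=len(taxon_ids), p=_PHYLUM_W)
    lineages = {}
    for tid, ph in zip(taxon_ids, phyla):
        genus = str(tid)[3:] if str(tid).startswith("g__") else str(tid)
        fam = f"Family_{ph[:4]}_{rng.integers(1, 30):02d}"
        lineages[str(tid)] = (
            f"k__Bacteria;p__{ph};c__Class_{ph[:4]};o__Order_{ph[:4]};f__{fam};g__{genus}"
        )
    return TaxonomyTable.from_lineage_strings(lineages)


@dataclass
class SimulatedStudy:
    table: CountTable
    metadata: SampleMetadata
    taxonomy: TaxonomyTable
    truth: GroundTruth


def default_config(seed: int = 0) -> SimulationConfig:
    """The emulated cohort: 2 arms x 16 sows x 6 timepoints, 150 genera,
    10 correlated pairs at rho 0.8, a handful of DF-enriched / CON-enriched
    genera, litter outcomes linked to two of them at late gestation."""
    diffs = (
        DiffSpec(0, "DF", ("G30", "G90", "G109"), 1.5),
        DiffSpec(1, "DF", ("G0", "G30"), 1.0),
        DiffSpec(2, "CON", ("G30", "G90", "G109"), 1.2),
        DiffSpec(3, "DF", ("G90", "G109"), 2.0),
        DiffSpec(4, "CON", ("G109",), 1.0),
        DiffSpec(5, "DF", ("G30", "G109", "L3", "L14"), 1.0),
    )
    outcomes = (
        OutcomeSpec("total_born", (0, 2), (1.2, -1.2), 1.0, "G109", 17.0),
        OutcomeSpec("born_alive", (0, 2), (1.0, -1.0), 1.0, "G109", 16.0),
        OutcomeSpec("healthy", (0,), (1.0,), 1.0, "G109", 15.0),
    )
    return SimulationConfig(diff_taxa_spec=diffs, outcome_spec=outcomes, seed=seed)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    table, meta, truth = simulate_counts(config)
    if config.outcome_spec:
        meta = simulate_outcomes(table, truth, meta,
                                 seed=int(stage_rng(config.seed, "outcomes").integers(2**31 - 1)))
    tax = make_taxonomy(table.taxon_ids,
                        seed=int(stage_rng(config.seed, "taxonomy").integers(2**31 - 1)))
    return SimulatedStudy(table, meta, tax, truth)
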