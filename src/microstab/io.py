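"""Tabular containers and IO for feature tables, taxonomy and sample metadata.

All on-disk formats are plain TSV (UTF-8, tab-separated, ``#`` comment lines
ignored, first column = identifier).  Feature tables are samples x taxa;
a transposed table is auto-detected from ID overlap with the metadata and
flipped with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIDError,
    MissingColumnError,
    NonIntegerCountError,
    UnknownRankError,
    ZeroSumSampleError,
)

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

#: lineage tokens treated as unresolved assignments
_UNRESOLVED = {"", "norank", "unclassified", "uncultured", "un"}

TREATMENTS = ("CON", "DF")
TIMEPOINTS = ("G0", "G30", "G90", "G109", "L3", "L14")


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise DuplicateIDError(f"duplicate {what} IDs: {dups}")


@dataclass
class CountTable:
    """Integer sample x taxon count matrix with ordered identifiers."""

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if arr.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"counts shape {arr.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                bad = arr[np.mod(arr, 1) != 0].flat[0]
                raise NonIntegerCountError(f"non-integer count cell: {bad!r}")
            arr = arr.astype(np.int64)
        if arr.size and arr.min() < 0:
            raise NonIntegerCountError("negative counts are not allowed")
        self.counts = arr.astype(np.int64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def select_samples(self, sample_ids) -> "CountTable":
        pos = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(self.counts[pos], list(sample_ids), list(self.taxon_ids))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountTable)
            and self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class TaxonomyTable:
    """Per-taxon lineages as a taxon x rank frame; unresolved ranks are ''."""

    lineages: pd.DataFrame  # index: taxon_id, columns: RANKS (subset prefix)

    def __post_init__(self) -> None:
        _check_unique(self.lineages.index, "taxon")
        unknown = [c for c in self.lineages.columns if c not in RANKS]
        if unknown:
            raise UnknownRankError(f"unknown rank columns: {unknown}")

    @classmethod
    def from_lineage_strings(cls, lineages: dict[str, str] | pd.Series) -> "TaxonomyTable":
        rows = {}
        for taxon, lin in dict(lineages).items():
            vals = dict.fromkeys(RANKS, "")
            for tok in str(lin).split(";"):
                tok = tok.strip()
                for rank, pref in zip(RANKS, RANK_PREFIXES):
                    if tok.startswith(pref):
                        name = tok[len(pref):].strip()
                        if name.lower() not in _UNRESOLVED:
                            vals[rank] = name
                        break
            rows[str(taxon)] = vals
        return cls(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))

    def lineage_string(self, taxon: str) -> str:
        row = self.lineages.loc[taxon]
        return ";".join(p + str(row[r]) for r, p in zip(RANKS, RANK_PREFIXES))

    def taxon_ids(self) -> list[str]:
        return list(self.lineages.index)


@dataclass
class SampleMetadata:
    """Per-sample design frame: subject, treatment, timepoint plus outcomes.

    Outcome columns are any numeric columns beyond the mandatory three; they
    are constant within subject (one litter record per sow).
    """

    df: pd.DataFrame
    timepoint_order: tuple[str, ...] = field(default=TIMEPOINTS)

    REQUIRED = ("subject", "treatment", "timepoint")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise MissingColumnError(f"metadata lacks mandatory column(s): {missing}")
        _check_unique(self.df.index, "sample")
        for col in self.outcome_columns:
            by_subj = self.df.groupby("subject")[col].nunique(dropna=True)
            if (by_subj > 1).any():
                bad = by_subj[by_subj > 1].index.tolist()
                raise ValueError(f"outcome {col!r} varies within subject(s) {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.df.index]

    @property
    def outcome_columns(self) -> list[str]:
        extra = [c for c in self.df.columns if c not in self.REQUIRED]
        return [c for c in extra if pd.api.types.is_numeric_dtype(self.df[c])]

    def subset(self, treatment: str | None = None, timepoint: str | None = None) -> "SampleMetadata":
        df = self.df
        if treatment is not None:
            df = df[df["treatment"] == treatment]
        if timepoint is not None:
            df = df[df["timepoint"] == timepoint]
        return SampleMetadata(df.copy(), self.timepoint_order)


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return df


def read_count_table(path, metadata: SampleMetadata | None = None) -> CountTable:
    """Read a samples x taxa TSV feature table.

    If ``metadata`` is given and the row IDs share no samples with it while
    the column IDs do, the table is assumed transposed and flipped (warning).
    """
    raw = _read_tsv(path)
    _check_unique(raw.index, "sample")
    _check_unique(raw.columns, "taxon")
    if metadata is not None:
        meta_ids = set(metadata.sample_ids)
        if not (set(raw.index) & meta_ids) and (set(raw.columns) & meta_ids):
            warnings.warn("feature table appears transposed (taxa as rows); flipping")
            raw = raw.T
    try:
        vals = raw.to_numpy(dtype=float)
    except ValueError as exc:
        raise NonIntegerCountError(f"non-numeric count cell in {path}: {exc}") from exc
    return CountTable(vals, list(raw.index), list(raw.columns))


def write_count_table(table: CountTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        table.to_dataframe().rename_axis("sample_id").to_csv(fh, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    df = _read_tsv(path)
    if "lineage" not in df.columns:
        raise MissingColumnError("taxonomy TSV requires a 'lineage' column")
    return TaxonomyTable.from_lineage_strings(df["lineage"])


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    out = pd.DataFrame(
        {"lineage": [tax.lineage_string(t) for t in tax.taxon_ids()]},
        index=pd.Index(tax.taxon_ids(), name="taxon_id"),
    )
    out.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = _read_tsv(path)
    for col in df.columns:
        if col not in SampleMetadata.REQUIRED:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.df.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Rank collapsing, rarefaction, coverage, closure
# ---------------------------------------------------------------------------

def collapse_rank(table: CountTable, taxonomy: TaxonomyTable, rank: str) -> CountTable:
    """Sum counts over taxa sharing their lineage down to ``rank``.

    Taxa unresolved at ``rank`` are pooled per deepest resolved parent into a
    bucket labelled ``un_<parent-prefix>__<parent-name>`` (e.g.
    ``un_f__Lachnospiraceae``); taxa with nothing resolved pool into
    ``unclassified``.  Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise UnknownRankError(f"unknown rank {rank!r}; expected one of {RANKS}")
    rank_i = RANKS.index(rank)
    missing = [t for t in table.taxon_ids if t not in taxonomy.lineages.index]
    if missing:
        raise KeyError(f"taxa absent from taxonomy: {missing[:5]}")

    labels = []
    for taxon in table.taxon_ids:
        row = taxonomy.lineages.loc[taxon]
        name = str(row.iloc[rank_i]) if rank_i < len(row) else ""
        if name:
            labels.append(name)
            continue
        # fall back to the deepest resolved ancestor
        parent = None
        for j in range(rank_i - 1, -1, -1):
            if str(row.iloc[j]):
                parent = (RANK_PREFIXES[j][0], str(row.iloc[j]))
                break
        labels.append(f"un_{parent[0]}__{parent[1]}" if parent else "unclassified")

    order = list(dict.fromkeys(labels))
    out = np.zeros((table.n_samples, len(order)), dtype=np.int64)
    col = {lab: i for i, lab in enumerate(order)}
    for j, lab in enumerate(labels):
        out[:, col[lab]] += table.counts[:, j]
    return CountTable(out, list(table.sample_ids), order)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped (logged, not an
    error).  Uses a multivariate hypergeometric draw, reproducible from seed.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    keep_rows, keep_ids = [], []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        total = int(row.sum())
        if total < depth:
            logger.info("rarefy: dropping sample %s (total %d < depth %d)", sid, total, depth)
            continue
        if total == depth:
            keep_rows.append(row.copy())
        else:
            keep_rows.append(rng.multivariate_hypergeometric(row, depth))
        keep_ids.append(sid)
    counts = np.vstack(keep_rows) if keep_rows else np.zeros((0, table.n_taxa), dtype=np.int64)
    return CountTable(counts, keep_ids, list(table.taxon_ids))


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/n: fraction of reads from already-seen taxa."""
    vec = np.asarray(counts)
    n = vec.sum()
    if n <= 0:
        raise ZeroSumSampleError("Good's coverage undefined for an all-zero sample")
    return float(1.0 - (vec == 1).sum() / n)


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Row-normalise counts to proportions (rows sum to 1)."""
    sums = table.sample_sums().astype(float)
    if (sums <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t <= 0]
        raise ZeroSumSampleError(f"zero-sum sample(s): {bad}")
    return pd.DataFrame(
        table.counts / sums[:, None], index=table.sample_ids, columns=table.taxon_ids
    )
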