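"""Feature tables, sample metadata, contaminant scores: data model, I/O, preprocessing.

The central container is :class:`FeatureTable`, a samples x features abundance
matrix tagged with a ``kind`` ("counts", "relative" or "log").  Features are
identified by strings -- ASV nucleotide sequences for 16S tables, metabolite
names for metabolomics tables.  On-disk layout follows the QIIME2 / BIOM TSV
export convention: features in rows, samples in columns, with an optional
leading ``# Constructed from biom file`` comment line.

Preprocessing implemented here:

* prevalence filtering -- drop features observed (nonzero) in fewer than a
  given fraction of samples (strict ``<``; boundary features are kept);
* contaminant filtering -- drop ASVs whose mean environmental f-score
  (water, soil, mouse) strictly exceeds their human-association f-score;
* rarefaction -- per-sample subsampling without replacement to a common depth;
* metabolite sum-normalization and correlation prep (zero replacement by a
  fifth of the per-metabolite minimum, natural log, 4-SD trimming).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FeatureTable",
    "FilterReport",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_contaminant_scores",
    "write_contaminant_scores",
    "read_fasta_ids",
    "write_fasta",
    "filter_prevalence",
    "filter_contaminants",
    "rarefy",
    "normalize_metabolites",
    "prep_metabolites_for_correlation",
]

KINDS = ("counts", "relative", "log")

SCORE_COLUMNS = ("f_water", "f_soil", "f_mouse", "f_human")


class TableError(ValueError):
    """Raised for malformed tables or invalid preprocessing requests."""


@dataclass(frozen=True)
class FilterReport:
    """What a filtering/rarefaction step removed and why."""

    operation: str
    n_before: int
    n_after: int
    removed: tuple[str, ...]
    details: Mapping[str, object] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_before - self.n_after


@dataclass
class FeatureTable:
    """Samples x features abundance matrix with a kind tag.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and feature ids as columns.
    kind:
        "counts" (non-negative integers), "relative" (rows sum to 1) or
        "log" (unconstrained reals, e.g. log-transformed metabolites).
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise TableError(f"unknown table kind {self.kind!r}; expected one of {KINDS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise TableError(f"duplicate feature ids: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise TableError("table contains non-finite values")
        if self.kind in ("counts", "relative") and values.size and (values < 0).any():
            bad = self.data.index[(values < 0).any(axis=1)][0]
            raise TableError(f"negative value in sample {bad!r}")
        if self.kind == "counts" and values.size and not np.allclose(values, np.round(values)):
            raise TableError("kind='counts' requires integer values")
        if self.kind == "relative" and values.size:
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.data.index[np.argmax(np.abs(sums - 1.0))]
                raise TableError(f"relative table rows must sum to 1; sample {bad!r} sums to {sums.max():g}")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.kind)

    def to_relative(self) -> "FeatureTable":
        """Convert counts to per-sample relative abundances (rows sum to 1)."""
        if self.kind == "relative":
            return self.copy()
        if self.kind != "counts":
            raise TableError("only count tables can be converted to relative abundances")
        sums = self.data.sum(axis=1)
        if (sums == 0).any():
            bad = sums.index[sums == 0][0]
            raise TableError(f"sample {bad!r} has zero total count")
        return FeatureTable(self.data.div(sums, axis=0), "relative")

    def select_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(sample_ids)], self.kind)

    def select_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        return FeatureTable(self.data[list(feature_ids)], self.kind)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_kind(values: np.ndarray) -> str:
    if values.size == 0:
        return "counts"
    if np.allclose(values, np.round(values)) and (values >= 0).all():
        return "counts"
    sums = values.sum(axis=1)
    if (values >= 0).all() and np.allclose(sums, 1.0, atol=1e-9):
        return "relative"
    return "log"


def read_feature_table(path: str | Path, kind: str | None = None) -> FeatureTable:
    """Read a feature table TSV (features in rows, samples in columns).

    A leading ``# Constructed from biom file`` comment (QIIME2 export dialect)
    is skipped; the header row holds sample ids and the first column feature
    ids.  ``kind`` is inferred when not given: integer-valued -> counts,
    rows-sum-to-one -> relative, otherwise log.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        # QIIME2 exports prepend "# Constructed from biom file" before the header
        skip = 1 if first.startswith("# Constructed") else 0
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise TableError(f"{path}: duplicate feature ids {dups[:3]}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise TableError(f"{path}: ragged or missing values in row {bad!r}")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        bad = df.index[(values < 0).any(axis=1)][0]
        raise TableError(f"{path}: negative value in row {bad!r}")
    data = df.T  # -> samples x features
    data.index = data.index.astype(str)
    data.columns = data.columns.astype(str)
    if kind is None:
        kind = _infer_kind(data.to_numpy(dtype=float))
    if kind == "counts":
        data = data.astype(np.int64)
    else:
        data = data.astype(float)
    return FeatureTable(data, kind)


def write_feature_table(table: FeatureTable, path: str | Path, qiime2_comment: bool = False) -> None:
    """Write a feature table TSV (features in rows, samples in columns)."""
    path = Path(path)
    out = table.data.T
    out.index.name = "feature_id"
    with open(path, "w") as fh:
        if qiime2_comment:
            fh.write("# Constructed from biom file\n")
        out.to_csv(fh, sep="\t")


METADATA_REQUIRED = ("sample_id", "group")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV into a DataFrame indexed by sample_id.

    Mandatory columns: ``sample_id``, ``group``.  Optional: ``age`` (years),
    ``gender``, ``site``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise TableError(f"{path}: metadata missing required columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise TableError(f"{path}: duplicate sample ids {dups[:3]}")
    if df["group"].isna().any() or (df["group"].astype(str).str.len() == 0).any():
        raise TableError(f"{path}: empty group labels")
    if "age" in df.columns:
        ages = pd.to_numeric(df["age"], errors="coerce")
        if (ages.dropna() < 0).any():
            raise TableError(f"{path}: negative ages")
        df["age"] = ages
    return df.set_index("sample_id")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_contaminant_scores(path: str | Path) -> pd.DataFrame:
    """Read per-ASV dbBact-style f-score table (feature_id + four scores in [0,1])."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    missing = [c for c in ("feature_id", *SCORE_COLUMNS) if c not in df.columns]
    if missing:
        raise TableError(f"{path}: contaminant score table missing columns {missing}")
    df = df.set_index("feature_id")
    vals = df[list(SCORE_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise TableError(f"{path}: missing f-score values")
    if ((vals < 0) | (vals > 1)).any():
        raise TableError(f"{path}: f-scores must lie in [0, 1]")
    return df
def write_contaminant_scores(scores: pd.DataFrame, path: str | Path) -> None:
    out = scores.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def write_fasta(sequences: Iterable[str], path: str | Path, prefix: str = "ASV") -> None:
    """Write ASV sequences to FASTA, ids ``{prefix}{i:05d}``."""
    records = [
        SeqRecord(Seq(seq), id=f"{prefix}{i:05d}", description="")
        for i, seq in enumerate(sequences, start=1)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_ids(path: str | Path) -> list[str]:
    """Read sequences from a FASTA file (sequence strings are the feature ids)."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_prevalence(table: FeatureTable, min_fraction: float = 0.01) -> tuple[FeatureTable, FilterReport]:
    """Remove features present (nonzero) in less than ``min_fraction`` of samples.

    The bound is strict: a feature nonzero in exactly ``min_fraction`` of the
    samples is kept.  Samples are untouched.
    """
    if table.kind not in ("counts", "relative"):
        raise TableError("prevalence filter applies to counts or relative tables")
    if table.n_samples == 0 or table.n_features == 0:
        raise TableError("cannot prevalence-filter an empty table")
    frac = (table.data.to_numpy() > 0).mean(axis=0)
    keep = frac >= min_fraction
    removed = tuple(f for f, k in zip(table.feature_ids, keep) if not k)
    kept = [f for f, k in zip(table.feature_ids, keep) if k]
    report = FilterReport(
        operation="filter_prevalence",
        n_before=table.n_features,
        n_after=len(kept),
        removed=removed,
        details={"min_fraction": min_fraction},
    )
    return table.select_features(kept), report


def filter_contaminants(table: FeatureTable, scores: pd.DataFrame) -> tuple[FeatureTable, FilterReport]:
    """Remove ASVs whose mean (water, soil, mouse) f-score exceeds the human f-score.

    Strict inequality: ties are kept.  Features without a score row are kept
    and listed in the report under ``unscored``.
    """
    env = scores[["f_water", "f_soil", "f_mouse"]].mean(axis=1)
    is_contaminant = env > scores["f_human"]
    removed, kept, unscored = [], [], []
    for f in table.feature_ids:
        if f not in scores.index:
            unscored.append(f)
            kept.append(f)
        elif bool(is_contaminant.loc[f]):
            removed.append(f)
        else:
            kept.append(f)
    report = FilterReport(
        operation="filter_contaminants",
        n_before=table.n_features,
        n_after=len(kept),
        removed=tuple(removed),
        details={"unscored": tuple(unscored)},
    )
    return table.select_features(kept), report


def rarefy(table: FeatureTable, depth: int, seed: int) -> tuple[FeatureTable, FilterReport]:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped and reported.
    Deterministic for a fixed seed.
    """
    if table.kind != "counts":
        raise TableError("rarefaction requires a count table")
    if depth <= 0:
        raise TableError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    counts = table.data.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    keep_mask = totals >= depth
    out_rows = []
    kept_ids = []
    for i, sid in enumerate(table.sample_ids):
        if not keep_mask[i]:
            continue
        out_rows.append(rng.multivariate_hypergeometric(counts[i], depth))
        kept_ids.append(sid)
    dropped = tuple(s for s, k in zip(table.sample_ids, keep_mask) if not k)
    data = pd.DataFrame(np.asarray(out_rows, dtype=np.int64).reshape(len(kept_ids), table.n_features),
                        index=kept_ids, columns=table.feature_ids)
    report = FilterReport(
        operation="rarefy",
        n_before=table.n_samples,
        n_after=len(kept_ids),
        removed=dropped,
        details={"depth": depth, "seed": seed},
    )
    return FeatureTable(data, "counts"), report


# ---------------------------------------------------------------------------
# Metabolite preprocessing
# ---------------------------------------------------------------------------

def normalize_metabolites(table: FeatureTable) -> FeatureTable:
    """Sum-normalize: divide each metabolite value by the sample's total."""
    values = table.data.to_numpy(dtype=float)
    if (values < 0).any():
        raise TableError("metabolite table must be non-negative")
    sums = values.sum(axis=1)
    if (sums == 0).any():
        bad = table.data.index[np.argmax(sums == 0)]
        raise TableError(f"sample {bad!r} has all-zero metabolite values")
    return FeatureTable(table.data.div(pd.Series(sums, index=table.data.index), axis=0), "relative")


def prep_metabolites_for_correlation(table: FeatureTable, n_sd: float = 4.0) -> FeatureTable:
    """Clean metabolite values for correlation analyses.

    Per metabolite: zeros are replaced by one fifth of the smallest nonzero
    value, values are natural-log transformed, and log values further than
    ``n_sd`` standard deviations from the metabolite's mean are clipped to
    that bound.  Output kind is "log".
    """
    values = table.data.to_numpy(dtype=float).copy()
    if (values < 0).any():
        raise TableError("metabolite table must be non-negative")
    for j, name in enumerate(table.feature_ids):
        col = values[:, j]
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise TableError(f"metabolite {name!r} is zero in every sample")
        col[col == 0] = nonzero.min() / 5.0
        values[:, j] = col
    logged = np.log(values)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1) if logged.shape[0] > 1 else np.zeros(logged.shape[1])
    lo, hi = mean - n_sd * sd, mean + n_sd * sd
    clipped = np.clip(logged, lo, hi)
    return FeatureTable(pd.DataFrame(clipped, index=table.data.index, columns=table.data.columns), "log")
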