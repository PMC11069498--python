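"""Signed-ASV indices: definition, cross-cohort matching and log-rank-ratio scoring.

A microbial index (a "rural index" or a "health index") is defined by two
disjoint ASV sequence sets: a numerator set associated with the reference
condition (e.g. rural residence, health) and a denominator set associated
with the opposite condition.  A sample's score is the natural log of the
ratio of its mean rank-transformed abundance over the numerator set to that
over the denominator set -- higher scores mean the sample's community looks
more like the reference condition.

Ranks are computed per feature across the scored samples (average ties), so
scores are invariant to any strictly monotone per-feature transform and
always finite (average ranks are >= 1).  Index features absent from a sample
still contribute their (low) across-sample rank; zeros are informative.

Because ASVs are sequence-identified, an index derived on one cohort is
applied to another by exact sequence matching after truncating both sides to
their common prefix length (sequences below 150 nt are not matched; ASV
pipelines discard shorter reads).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .diffabund import DAConfig, differential_features
from .tables import FeatureTable, FilterReport, TableError, filter_prevalence, rarefy

__all__ = [
    "IndexDefinition",
    "IndexError_",
    "build_index_definition",
    "match_features",
    "score_index",
    "compare_index_between_groups",
    "run_index_pipeline",
]

MIN_MATCH_LENGTH = 150


class IndexError_(ValueError):
    """Raised when an index cannot be built, matched or scored."""


@dataclass(frozen=True)
class IndexDefinition:
    """Two disjoint signed ASV sets plus provenance."""

    name: str
    positive_features: frozenset[str]
    negative_features: frozenset[str]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.positive_features or not self.negative_features:
            raise IndexError_(f"index {self.name!r}: both feature sets must be nonempty")
        if self.positive_features & self.negative_features:
            raise IndexError_(f"index {self.name!r}: positive and negative sets overlap")

    def swapped(self) -> "IndexDefinition":
        """Exchange numerator and denominator sets (negates all scores)."""
        return IndexDefinition(
            name=f"{self.name}_swapped",
            positive_features=self.negative_features,
            negative_features=self.positive_features,
            provenance=dict(self.provenance),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "positive_features": sorted(self.positive_features),
            "negative_features": sorted(self.negative_features),
            "provenance": dict(self.provenance),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "IndexDefinition":
        payload = json.loads(Path(path).read_text())
        return cls(
            name=payload["name"],
            positive_features=frozenset(payload["positive_features"]),
            negative_features=frozenset(payload["negative_features"]),
            provenance=payload.get("provenance", {}),
        )


def build_index_definition(da: pd.DataFrame, name: str, provenance: Mapping[str, object] | None = None) -> IndexDefinition:
    """Turn a differential abundance result into a signed index.

    Positive set: features significantly higher in group A (the reference
    group of the contrast); negative set: significantly lower.  Raises when
    either direction has no significant feature (relax alpha or increase
    sample size).
    """
    sig = da[da["significant"]]
    pos = frozenset(sig.index[sig["effect"] > 0])
    neg = frozenset(sig.index[sig["effect"] < 0])
    if not pos or not neg:
        raise IndexError_(
            f"cannot build index {name!r}: need significant features in both directions "
            f"(got {len(pos)} higher, {len(neg)} lower); consider relaxing alpha"
        )
    prov = dict(provenance or {})
    prov.setdefault("n_positive", len(pos))
    prov.setdefault("n_negative", len(neg))
    return IndexDefinition(name=name, positive_features=pos, negative_features=neg, provenance=prov)


def match_features(index: IndexDefinition, table: FeatureTable) -> tuple[IndexDefinition, dict[str, float]]:
    """Map an index's ASV sequences onto a table's feature universe.

    Sequences match when identical after truncation to the shorter of the two
    lengths (minimum 150 nt).  Returns the index re-expressed in the table's
    feature ids plus a coverage report (matched fraction per set).  Raises if
    either matched set comes out empty.
    """
    table_seqs = table.feature_ids
    # index sequences by 150-nt prefix for near-constant-time lookup
    prefix_map: dict[str, list[str]] = {}
    for s in table_seqs:
        if len(s) >= MIN_MATCH_LENGTH:
            prefix_map.setdefault(s[:MIN_MATCH_LENGTH], []).append(s)

    def match_set(seqs: frozenset[str]) -> dict[str, str]:
        out = {}
        for seq in seqs:
            if len(seq) < MIN_MATCH_LENGTH:
                continue
            for cand in prefix_map.get(seq[:MIN_MATCH_LENGTH], []):
                n = min(len(seq), len(cand))
                if seq[:n] == cand[:n]:
                    out[seq] = cand
                    break
        return out

    pos_map = match_set(index.positive_features)
    neg_map = match_set(index.negative_features)
    coverage = {
        "positive_matched_fraction": len(pos_map) / len(index.positive_features),
        "negative_matched_fraction": len(neg_map) / len(index.negative_features),
    }
    if not pos_map or not neg_map:
        raise IndexError_(
            f"index {index.name!r} does not match the table's feature universe "
            f"(coverage: {coverage})"
        )
    matched = IndexDefinition(
        name=index.name,
        positive_features=frozenset(pos_map.values()),
        negative_features=frozenset(neg_map.values()),
        provenance={**dict(index.provenance), "matched_to_table": True, **coverage},
    )
    return matched, coverage


def score_index(table: FeatureTable, index: IndexDefinition, rank_within_sample: bool = False) -> pd.Series:
    """Per-sample log-rank-ratio index scores.

    Default ("rank transforming the samples" read as per-feature ranking):
    each feature's relative abundance is ranked across samples with average
    ties; score(sample) = ln(mean rank over the positive set / mean rank over
    the negative set).  ``rank_within_sample=True`` switches to ranking
    features within each sample instead (the alternative reading).
    """
    missing = (index.positive_features | index.negative_features) - set(table.feature_ids)
    if missing:
        raise IndexError_(
            f"index {index.name!r} has {len(missing)} features absent from the table; "
            "run match_features first"
        )
    t = table.to_relative() if table.kind == "counts" else table
    values = t.data.to_numpy(dtype=float)
    ranks = rankdata(values, method="average", axis=1 if rank_within_sample else 0)
    rank_df = pd.DataFrame(ranks, index=t.data.index, columns=t.data.columns)
    pos_mean = rank_df[sorted(index.positive_features)].mean(axis=1)
    neg_mean = rank_df[sorted(index.negative_features)].mean(axis=1)
    scores = np.log(pos_mean / neg_mean)
    scores.name = index.name
    return scores


def compare_index_between_groups(
    scores: pd.Series, metadata: pd.DataFrame, group_a: str, group_b: str, method: str = "auto"
) -> dict[str, object]:
    """Two-sided Mann-Whitney comparison of index scores between two groups.

    ``method`` is passed through to the rank-sum test ("auto", "exact" or
    "asymptotic"); "exact" enumerates the tail when there are no ties.
    """
    groups = metadata["group"].reindex(scores.index)
    a = scores[groups == group_a]
    b = scores[groups == group_b]
    if len(a) < 2 or len(b) < 2:
        raise IndexError_(f"groups {group_a!r}/{group_b!r} need >= 2 scored samples each")
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "group_a": group_a,
        "group_b": group_b,
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "median_a": float(a.median()),
        "median_b": float(b.median()),
        "direction": "A_higher" if a.median() > b.median() else "B_higher",
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
    }


def run_index_pipeline(
    reference_table: FeatureTable,
    reference_metadata: pd.DataFrame,
    target_table: FeatureTable,
    target_metadata: pd.DataFrame,
    index_name: str = "rural_index",
    min_prevalence: float = 0.01,
    rarefaction_depth: int | None = None,
    da_config: DAConfig | None = None,
    group_comparisons: list[tuple[str, str]] | None = None,
) -> dict[str, object]:
    """Derive an index on a reference cohort and score a target cohort with it.

    Stages: prevalence filter -> (optional) rarefaction -> rank-mean/dsFDR
    differential abundance on the reference two-group contrast -> index
    construction -> sequence matching to the target -> per-sample scoring ->
    Mann-Whitney group comparisons on the target.  Returns a report dict with
    every stage's artifacts.
    """
    da_config = da_config or DAConfig()
    reports: list[FilterReport] = []

    ref, rep = filter_prevalence(reference_table, min_prevalence)
    reports.append(rep)
    if rarefaction_depth is not None:
        ref, rep = rarefy(ref, rarefaction_depth, seed=da_config.seed)
        reports.append(rep)

    labels = reference_metadata["group"].reindex(ref.sample_ids)
    da = differential_features(ref, labels, da_config)
    index = build_index_definition(
        da,
        index_name,
        provenance={
            "reference_contrast": f"{da.attrs['group_a']} vs {da.attrs['group_b']}",
            "alpha": da_config.alpha,
            "seed": da_config.seed,
        },
    )
    matched, coverage = match_features(index, target_table)
    scores = score_index(target_table, matched)

    comparisons = []
    if group_comparisons is None:
        groups = list(pd.unique(target_metadata["group"]))
        group_comparisons = [(groups[i], groups[i + 1]) for i in range(len(groups) - 1)]
    for ga, gb in group_comparisons:
        comparisons.append(compare_index_between_groups(scores, target_metadata, ga, gb))

    return {
        "filter_reports": reports,
        "differential_abundance": da,
        "index": index,
        "matched_index": matched,
        "coverage": coverage,
        "scores": scores,
        "comparisons": comparisons,
    }
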