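"""Rank-mean permutation test with discrete FDR (dsFDR) control.

The two-group test used to derive signed ASV sets for index construction.
Per feature, abundances are ranked across samples (ties receive average
ranks); the statistic is the difference of group mean ranks.  Significance
comes from permuting group labels; multiplicity is controlled with the
discrete-FDR procedure suited to sparse count data: scan effect-size
thresholds ``t`` and pick the smallest one whose permutation-estimated FDR

    FDR(t) = mean over permutations of #{ |null stat| >= t }
             -----------------------------------------------
                     max(1, #{ |observed effect| >= t })

is at or below the target level (default 0.1).  When the number of distinct
label assignments is small the permutation null is enumerated exhaustively;
otherwise labels are resampled and p-values use the add-one convention
(p = (1 + hits) / (1 + n_permutations)) so sampled p-values are never zero.

Being rank-based, the statistic is invariant to any strictly monotone
per-feature transform of the abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tables import FeatureTable, TableError

__all__ = [
    "DAConfig",
    "DAResult",
    "rank_mean_statistic",
    "permutation_null",
    "dsfdr_select",
    "differential_features",
]


@dataclass(frozen=True)
class DAConfig:
    """Settings for the rank-mean permutation test.

    alpha is the dsFDR level (0.1 by default), n_permutations the number of
    label permutations (exhaustive enumeration replaces sampling whenever the
    number of distinct label assignments does not exceed it).
    """

    n_permutations: int = 1000
    alpha: float = 0.1
    seed: int = 0
    two_sided: bool = True
    allow_exhaustive: bool = True  # False forces label resampling even when enumeration is feasible

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass(frozen=True)
class DAResult:
    """Per-feature outcome of the differential abundance analysis."""

    feature_id: str
    effect: float  # mean rank in group A minus mean rank in group B
    p_raw: float
    significant: bool
    direction: str  # "higher_in_A" | "higher_in_B"


def _ranks_matrix(table: FeatureTable) -> np.ndarray:
    """Per-feature across-sample ranks (average ties) on relative abundances.

    Count tables are converted to relative abundances first so uneven
    sequencing depth does not masquerade as abundance differences; relative
    and log tables are ranked as given (ranks are invariant to monotone
    per-feature transforms).
    """
    t = table.to_relative() if table.kind == "counts" else table
    return rankdata(t.data.to_numpy(dtype=float), method="average", axis=0)


def _group_masks(
    table: FeatureTable, labels: pd.Series, groups: tuple[str, str] | None = None
) -> tuple[np.ndarray, str, str]:
    labels = labels.reindex(table.sample_ids)
    if labels.isna().any():
        missing = [s for s, v in labels.items() if pd.isna(v)]
        raise TableError(f"samples without group labels: {missing[:5]}")
    observed = list(pd.unique(labels))
    if len(observed) != 2:
        raise TableError(f"rank-mean test needs exactly two groups, got {observed}")
    if groups is None:
        groups = observed  # group A = first label encountered
    elif set(groups) != set(observed):
        raise TableError(f"groups {groups} do not match the labels present {observed}")
    mask = (labels == groups[0]).to_numpy()
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise TableError("each group needs at least 2 samples")
    return mask, str(groups[0]), str(groups[1])


def _effects(ranks: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    return ranks[mask_a].mean(axis=0) - ranks[~mask_a].mean(axis=0)


def rank_mean_statistic(
    table: FeatureTable, labels: pd.Series, groups: tuple[str, str] | None = None
) -> pd.Series:
    """Difference of group mean ranks per feature (group A minus group B).

    Group A is the first label encountered in ``labels`` unless ``groups``
    fixes the (A, B) order explicitly; reversing the order negates every
    effect.  A feature constant across all samples has every rank tied and an
    effect of exactly zero.
    """
    mask_a, _, _ = _group_masks(table, labels, groups)
    ranks = _ranks_matrix(table)
    return pd.Series(_effects(ranks, mask_a), index=table.feature_ids, name="effect")


def _permutation_masks(n: int, n_a: int, config: DAConfig) -> tuple[np.ndarray, bool]:
    """Boolean matrix of group-A assignments, one row per permutation.

    Returns (masks, exhaustive).  Exhaustive mode enumerates every distinct
    assignment of n_a samples to group A (the identity assignment included).
    """
    n_distinct = comb(n, n_a)
    if config.allow_exhaustive and n_distinct <= config.n_permutations:
        masks = np.zeros((n_distinct, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n_a)):
            masks[i, list(idx)] = True
        return masks, True
    rng = np.random.default_rng(config.seed)
    masks = np.zeros((config.n_permutations, n), dtype=bool)
    base = np.arange(n)
    for i in range(config.n_permutations):
        masks[i, rng.permutation(base)[:n_a]] = True
    return masks, False


def permutation_null(
    table: FeatureTable,
    labels: pd.Series,
    config: DAConfig | None = None,
    groups: tuple[str, str] | None = None,
) -> tuple[pd.Series, np.ndarray, bool]:
    """Permutation p-values plus the retained null statistic matrix.

    Returns ``(p_raw, null_stats, exhaustive)`` where ``null_stats`` has one
    row per permutation and one column per feature.  Two-sided by default:
    p is the fraction of permuted \\|effect\\| at or above the observed
    \\|effect\\| (exact fraction when exhaustive, add-one corrected when
    sampled).
    """
    config = config or DAConfig()
    mask_a, _, _ = _group_masks(table, labels, groups)
    ranks = _ranks_matrix(table)
    observed = _effects(ranks, mask_a)

    n = ranks.shape[0]
    n_a = int(mask_a.sum())
    masks, exhaustive = _permutation_masks(n, n_a, config)
    # mean rank in A = (M @ ranks)/n_a ; in B = ((1-M) @ ranks)/n_b
    m = masks.astype(float)
    sums = ranks.sum(axis=0)
    sum_a = m @ ranks
    null = sum_a / n_a - (sums[None, :] - sum_a) / (n - n_a)

    if config.two_sided:
        obs_cmp, null_cmp = np.abs(observed), np.abs(null)
    else:
        obs_cmp, null_cmp = observed, null
    hits = (null_cmp >= obs_cmp[None, :] - 1e-12).sum(axis=0)
    if exhaustive:
        p = hits / masks.shape[0]
    else:
        p = (1 + hits) / (1 + masks.shape[0])
    return pd.Series(p, index=table.feature_ids, name="p_raw"), null, exhaustive


def dsfdr_select(observed: np.ndarray | pd.Series, null_stats: np.ndarray, alpha: float) -> np.ndarray:
    """Discrete-FDR feature selection by effect-size threshold scan.

    Candidate thresholds are the distinct observed \\|effect\\| values; the
    smallest threshold with estimated FDR <= alpha is chosen and features at
    or above it are called significant.  Returns a boolean mask aligned with
    ``observed``; all-False when no threshold qualifies.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    obs = np.abs(np.asarray(observed, dtype=float))
    null_abs = np.abs(null_stats)
    candidates = np.unique(obs)
    candidates = candidates[candidates > 0]
    best_t = None
    for t in candidates:  # ascending: first hit is the smallest qualifying threshold
        n_called = int((obs >= t).sum())
        mean_null = (null_abs >= t - 1e-12).sum(axis=1).mean()
        fdr = mean_null / max(1, n_called)
        if fdr <= alpha:
            best_t = t
            break
    if best_t is None:
        return np.zeros_like(obs, dtype=bool)
    return obs >= best_t


def differential_features(
    table: FeatureTable,
    labels: pd.Series,
    config: DAConfig | None = None,
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Run the full rank-mean + dsFDR analysis.

    Returns a DataFrame indexed by feature id with columns ``effect``,
    ``p_raw``, ``significant`` and ``direction`` ("higher_in_A" for positive
    effects, group A being the first label seen).
    """
    config = config or DAConfig()
    mask_a, group_a, group_b = _group_masks(table, labels, groups)
    ranks = _ranks_matrix(table)
    observed = _effects(ranks, mask_a)
    p_raw, null, _ = permutation_null(table, labels, config, groups)
    sig = dsfdr_select(observed, null, config.alpha)
    out = pd.DataFrame(
        {
            "effect": observed,
            "p_raw": p_raw.to_numpy(),
            "significant": sig,
            "direction": np.where(observed >= 0, "higher_in_A", "higher_in_B"),
        },
        index=pd.Index(table.feature_ids, name="feature_id"),
    )
    out.attrs["group_a"] = group_a
    out.attrs["group_b"] = group_b
    return out
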