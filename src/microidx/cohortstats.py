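"""Cohort-level statistics: age matching, coefficient concordance, consistency test.

* ``age_match`` equalizes the age composition of two sample groups by binning
  ages into fixed-width bins (10 years by default, anchored at 0) and randomly
  dropping samples from the larger group within each bin.
* ``concordance`` compares per-feature contrast coefficients (e.g. from two
  independent two-group comparisons of the same metabolites) by direction
  agreement and Spearman correlation.
* ``consistency_binomial_test`` is an exact binomial test for the number of
  correlations keeping their sign between a full sample set and a subset,
  with success probability p_all*p_cd + (1-p_all)*(1-p_cd) -- the chance two
  independent draws with positive-rates p_all and p_cd agree in sign, which
  accounts for an unbalanced positive:negative ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, spearmanr

__all__ = [
    "ConsistencyInput",
    "age_match",
    "concordance",
    "consistency_success_probability",
    "consistency_binomial_test",
    "read_contrast_coefficients",
]


@dataclass(frozen=True)
class ConsistencyInput:
    """Counts and sign-rates feeding the consistency binomial test."""

    n_total: int
    n_consistent: int
    p_all: float  # fraction of positive correlations over all samples
    p_cd: float  # fraction of positive correlations in the subset

    def __post_init__(self) -> None:
        if not 0 <= self.n_consistent <= self.n_total:
            raise ValueError(f"need 0 <= n_consistent <= n_total, got {self.n_consistent}/{self.n_total}")
        for name in ("p_all", "p_cd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def age_match(
    metadata: pd.DataFrame,
    group_a: str,
    group_b: str,
    bin_width: float = 10.0,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Equalize per-age-bin sample counts between two groups.

    Ages are binned into [0, w), [w, 2w), ... ; in each bin both groups retain
    ``min(count_A, count_B)`` samples, the surplus dropped uniformly at random
    (seed-deterministic).  Samples outside the two groups are untouched and
    not returned.  Returns (retained sample ids, per-bin audit table).
    """
    sub = metadata[metadata["group"].isin([group_a, group_b])]
    if "age" not in sub.columns or sub["age"].isna().any():
        missing = [] if "age" not in sub.columns else list(sub.index[sub["age"].isna()])
        raise ValueError(f"age matching requires ages for all samples; missing: {missing[:5] or 'age column'}")
    rng = np.random.default_rng(seed)
    bins = np.floor(sub["age"].to_numpy(dtype=float) / bin_width).astype(int)
    sub = sub.assign(_bin=bins)
    retained: list[str] = []
    audit_rows = []
    for b in sorted(sub["_bin"].unique()):
        in_bin = sub[sub["_bin"] == b]
        ids_a = list(in_bin.index[in_bin["group"] == group_a])
        ids_b = list(in_bin.index[in_bin["group"] == group_b])
        keep = min(len(ids_a), len(ids_b))
        keep_a = sorted(rng.choice(ids_a, size=keep, replace=False)) if len(ids_a) > keep else ids_a
        keep_b = sorted(rng.choice(ids_b, size=keep, replace=False)) if len(ids_b) > keep else ids_b
        retained.extend(keep_a)
        retained.extend(keep_b)
        audit_rows.append(
            {
                "bin_start": b * bin_width,
                "bin_end": (b + 1) * bin_width,
                f"n_{group_a}": len(ids_a),
                f"n_{group_b}": len(ids_b),
                "retained_per_group": keep,
            }
        )
    return retained, pd.DataFrame(audit_rows)


def read_contrast_coefficients(path: str) -> pd.DataFrame:
    """Read a per-feature contrast coefficient TSV (feature, coefficient, p, q)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("feature", "coefficient") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: coefficient table missing columns {missing}")
    return df.set_index("feature")


def concordance(
    coefs_a: pd.DataFrame | pd.Series,
    coefs_b: pd.DataFrame | pd.Series,
    feature_subset: list[str] | None = None,
) -> dict[str, object]:
    """Direction agreement and Spearman correlation between two contrasts' coefficients.

    Coefficients sharing a strict sign agree; zero coefficients count as
    disagreement (and are reported).  Spearman rho is computed over the paired
    coefficient values of the shared (or requested) features.
    """
    a = coefs_a["coefficient"] if isinstance(coefs_a, pd.DataFrame) else coefs_a
    b = coefs_b["coefficient"] if isinstance(coefs_b, pd.DataFrame) else coefs_b
    features = list(feature_subset) if feature_subset is not None else sorted(set(a.index) & set(b.index))
    missing = [f for f in features if f not in a.index or f not in b.index]
    if missing:
        raise ValueError(f"features absent from one of the contrasts: {missing[:5]}")
    if len(features) < 3:
        raise ValueError(f"need >= 3 shared features for a rank correlation, got {len(features)}")
    av = a.loc[features].to_numpy(dtype=float)
    bv = b.loc[features].to_numpy(dtype=float)
    agree = (np.sign(av) == np.sign(bv)) & (np.sign(av) != 0)
    rho, p = spearmanr(av, bv)
    return {
        "n_features": len(features),
        "agreement": pd.Series(agree, index=features, name="direction_agrees"),
        "agreement_fraction": float(agree.mean()),
        "zero_coefficients": [f for f, x, y in zip(features, av, bv) if x == 0 or y == 0],
        "spearman_rho": float(rho),
        "spearman_p": float(p),
    }


def consistency_success_probability(inp: ConsistencyInput) -> float:
    """Chance a correlation keeps its sign by accident: p_all*p_cd + (1-p_all)*(1-p_cd)."""
    return inp.p_all * inp.p_cd + (1.0 - inp.p_all) * (1.0 - inp.p_cd)


def consistency_binomial_test(inp: ConsistencyInput, two_sided: bool = False) -> float:
    """Exact binomial p-value for the observed number of sign-consistent correlations.

    One-sided upper tail by default (the hypothesis is *excess* consistency):
    P[X >= n_consistent] for X ~ Binomial(n_total, success probability).
    """
    p_success = consistency_success_probability(inp)
    alternative = "two-sided" if two_sided else "greater"
    return float(binomtest(inp.n_consistent, inp.n_total, p_success, alternative=alternative).pvalue)
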