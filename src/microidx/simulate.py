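"""Synthetic cohort generation for the rural/urban/CD index pipeline.

Count tables are drawn from a Dirichlet-multinomial: each feature gets a base
Dirichlet concentration (lognormal weights, so a few ASVs dominate, most are
rare -- the typical 16S shape), a sample's composition is a Dirichlet draw
from its group's concentration vector, and reads are a multinomial draw at a
negative-binomial sequencing depth.  Group effects act multiplicatively on
concentrations: in the affected group, planted "positive" features have their
concentration multiplied by 2**log2fc and planted "negative" features by
2**(-log2fc), preserving compositionality.

The reference cohort has two groups (rural vs urban); the target cohort
re-uses the reference's feature universe and planted sets, with a per-group
multiplier on the planted effect so a monotone index gradient
(rural > rural-urban > urban > CD) can be planted.  Contaminant ASVs receive
dbBact-style f-score rows with environmental scores exceeding the human
score.  ``simulate_coupled_omics`` generates two feature blocks sharing a
single latent component at a chosen shared-variance fraction, for the
paired-omics permutation test.

Feature ids are synthetic 150-nt sequences, since real ASVs are identified by
their (>=150 nt) denoised sequence and cross-cohort matching works on the
sequence string.  Every generator is bit-deterministic given its config/seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import SCORE_COLUMNS, FeatureTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_reference_cohort",
    "simulate_target_cohort",
    "simulate_contaminant_scores",
    "simulate_coupled_omics",
]

_NT = np.array(list("ACGT"))
SEQUENCE_LENGTH = 150

# age ranges mirror the study design: rural controls skew older than urban
DEFAULT_AGE_RANGES: Mapping[str, tuple[float, float]] = {
    "rural": (40.0, 65.0),
    "rural_urban": (35.0, 60.0),
    "urban": (20.0, 40.0),
    "CD": (18.0, 40.0),
}


class ConfigurationError(ValueError):
    """Raised for invalid simulation settings, naming the offending field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort simulation settings.

    Defaults are sized like a small two-group 16S study: 50 samples/group,
    300 ASVs of which 30 are planted higher and 20 lower in the first group
    at 4-fold (log2fc=2) concentration shifts, sequencing depth around 50k
    reads (negative-binomial), 5% planted contaminants.
    """

    n_samples_per_group: int = 50
    n_features: int = 300
    n_pos_effect: int = 30
    n_neg_effect: int = 20
    effect_log2fc: float = 2.0
    depth_mean: float = 50_000.0
    depth_dispersion: float = 30.0  # NB size parameter; var = mu + mu^2/size
    base_concentration: float = 100.0  # total Dirichlet mass; lower = more overdispersion
    contaminant_fraction: float = 0.05
    age_range_per_group: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_RANGES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 2:
            raise ConfigurationError("n_samples_per_group must be >= 2")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if self.n_pos_effect < 0 or self.n_neg_effect < 0:
            raise ConfigurationError("n_pos_effect and n_neg_effect must be >= 0")
        if self.n_pos_effect + self.n_neg_effect > self.n_features:
            raise ConfigurationError("n_pos_effect + n_neg_effect must not exceed n_features")
        if self.effect_log2fc < 0:
            raise ConfigurationError("effect_log2fc must be >= 0")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        if self.depth_dispersion <= 0:
            raise ConfigurationError("depth_dispersion must be > 0")
        if self.base_concentration <= 0:
            raise ConfigurationError("base_concentration must be > 0")
        if not 0 <= self.contaminant_fraction < 1:
            raise ConfigurationError("contaminant_fraction must be in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    planted_positive: tuple[str, ...]
    planted_negative: tuple[str, ...]
    planted_contaminants: tuple[str, ...]
    base_alpha: tuple[float, ...] = ()
    feature_ids: tuple[str, ...] = ()
    latent_scores: tuple[float, ...] = ()


def _random_sequences(rng: np.random.Generator, n: int) -> list[str]:
    seqs = ["".join(rng.choice(_NT, size=SEQUENCE_LENGTH)) for _ in range(n)]
    # 4^150 possibilities: collisions are practically impossible, but stay safe
    while len(set(seqs)) < n:  # pragma: no cover
        seqs = list(dict.fromkeys(seqs))
        seqs += ["".join(rng.choice(_NT, size=SEQUENCE_LENGTH)) for _ in range(n - len(seqs))]
    return seqs


def _draw_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    depths = rng.negative_binomial(dispersion, p, size=n)
    return np.maximum(depths, 1)


def _sample_counts(
    rng: np.random.Generator, alpha: np.ndarray, depths: np.ndarray
) -> np.ndarray:
    rows = []
    for d in depths:
        probs = rng.dirichlet(alpha)
        rows.append(rng.multinomial(int(d), probs))
    return np.asarray(rows, dtype=np.int64)


def _age_range(config: SimulationConfig, group: str) -> tuple[float, float]:
    return tuple(config.age_range_per_group.get(group, (20.0, 60.0)))


def _metadata(
    rng: np.random.Generator, config: SimulationConfig, sample_ids: list[str], groups: list[str], site: str
) -> pd.DataFrame:
    rows = []
    for sid, g in zip(sample_ids, groups):
        lo, hi = _age_range(config, g)
        rows.append(
            {
                "group": g,
                "age": float(np.round(rng.uniform(lo, hi), 1)),
                "gender": str(rng.choice(["female", "male"])),
                "site": site,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))


def _effect_alpha(base: np.ndarray, truth_pos: np.ndarray, truth_neg: np.ndarray, log2fc: float) -> np.ndarray:
    alpha = base.copy()
    alpha[truth_pos] *= 2.0**log2fc
    alpha[truth_neg] *= 2.0**-log2fc
    return alpha


def simulate_reference_cohort(
    config: SimulationConfig, groups: tuple[str, str] = ("rural", "urban")
) -> tuple[FeatureTable, pd.DataFrame, GroundTruth]:
    """Two-group reference cohort with planted signed features.

    Planted positive features are elevated (and negative features depleted)
    in the *first* group.  Returns the count table, metadata, and ground
    truth (including the base concentrations needed to simulate a matching
    target cohort).
    """
    rng = np.random.default_rng(config.seed)
    feature_ids = _random_sequences(rng, config.n_features)

    weights = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_features)
    base_alpha = config.base_concentration * weights / weights.sum()

    perm = rng.permutation(config.n_features)
    pos_idx = perm[: config.n_pos_effect]
    neg_idx = perm[config.n_pos_effect : config.n_pos_effect + config.n_neg_effect]
    n_contam = int(round(config.contaminant_fraction * config.n_features))
    contam_idx = perm[config.n_pos_effect + config.n_neg_effect :][:n_contam]

    group_a, group_b = groups
    alpha_a = _effect_alpha(base_alpha, pos_idx, neg_idx, config.effect_log2fc)

    n = config.n_samples_per_group
    depths = _draw_depths(rng, 2 * n, config.depth_mean, config.depth_dispersion)
    counts_a = _sample_counts(rng, alpha_a, depths[:n])
    counts_b = _sample_counts(rng, base_alpha, depths[n:])

    sample_ids = [f"ref_{group_a}_{i:03d}" for i in range(n)] + [f"ref_{group_b}_{i:03d}" for i in range(n)]
    data = pd.DataFrame(np.vstack([counts_a, counts_b]), index=sample_ids, columns=feature_ids)
    table = FeatureTable(data, "counts")
    metadata = _metadata(rng, config, sample_ids, [group_a] * n + [group_b] * n, site="reference")
    truth = GroundTruth(
        planted_positive=tuple(feature_ids[i] for i in pos_idx),
        planted_negative=tuple(feature_ids[i] for i in neg_idx),
        planted_contaminants=tuple(feature_ids[i] for i in contam_idx),
        base_alpha=tuple(base_alpha),
        feature_ids=tuple(feature_ids),
    )
    return table, metadata, truth


def simulate_target_cohort(
    config: SimulationConfig,
    truth: GroundTruth,
    group_effect_scale: Mapping[str, float],
) -> tuple[FeatureTable, pd.DataFrame]:
    """Multi-group target cohort sharing the reference feature universe.

    ``group_effect_scale`` maps each target group to a multiplier on the
    planted log2 fold-change (e.g. rural=1, rural_urban=0.5, urban=0.4, CD=0
    plants a monotone index gradient).  Multipliers must be >= 0; scale 0
    means the group sits at the baseline composition.
    """
    if not truth.feature_ids or not truth.base_alpha:
        raise ConfigurationError("truth must come from simulate_reference_cohort")
    for g, s in group_effect_scale.items():
        if s < 0:
            raise ConfigurationError(f"group_effect_scale[{g!r}] must be >= 0")

    rng = np.random.default_rng([config.seed, 0x7A26])  # distinct stream from the reference
    feature_ids = list(truth.feature_ids)
    base_alpha = np.asarray(truth.base_alpha)
    idx = {f: i for i, f in enumerate(feature_ids)}
    pos_idx = np.array([idx[f] for f in truth.planted_positive], dtype=int)
    neg_idx = np.array([idx[f] for f in truth.planted_negative], dtype=int)

    n = config.n_samples_per_group
    blocks, sample_ids, group_col = [], [], []
    for g, scale in group_effect_scale.items():
        alpha_g = _effect_alpha(base_alpha, pos_idx, neg_idx, config.effect_log2fc * scale)
        depths = _draw_depths(rng, n, config.depth_mean, config.depth_dispersion)
        blocks.append(_sample_counts(rng, alpha_g, depths))
        sample_ids += [f"tgt_{g}_{i:03d}" for i in range(n)]
        group_col += [g] * n

    data = pd.DataFrame(np.vstack(blocks), index=sample_ids, columns=feature_ids)
    table = FeatureTable(data, "counts")
    metadata = _metadata(rng, config, sample_ids, group_col, site="target")
    return table, metadata


def simulate_contaminant_scores(truth: GroundTruth, feature_ids: list[str], seed: int = 0) -> pd.DataFrame:
    """dbBact-style f-score rows: planted contaminants look environmental.

    Planted contaminants get mean(water, soil, mouse) f-scores above their
    human f-score; every other feature the reverse.  Scores lie in [0, 1].
    """
    if not feature_ids:
        raise ValueError("feature_ids must be nonempty")
    rng = np.random.default_rng([seed, 0xC0F])
    contaminants = set(truth.planted_contaminants)
    rows = []
    for f in feature_ids:
        if f in contaminants:
            env = rng.uniform(0.6, 0.95, size=3)
            human = rng.uniform(0.0, min(0.5, env.mean() - 0.05))
        else:
            human = rng.uniform(0.5, 0.95)
            env = rng.uniform(0.0, human - 0.05, size=3)
        rows.append(dict(zip(SCORE_COLUMNS, [*env, human])))
    return pd.DataFrame(rows, index=pd.Index(feature_ids, name="feature_id"))


def simulate_coupled_omics(
    n_samples: int,
    p_features_x: int,
    p_features_y: int,
    shared_variance_fraction: float,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Two omics blocks sharing one latent component.

    Each block is ``sqrt(f) * latent x loading + sqrt(1-f) * noise`` where
    ``f`` is the shared-variance fraction; f=0 gives independent blocks, f=1
    (with noise_sd fixed) rank-one coupled blocks.  The latent sample scores
    are returned in the ground truth.
    """
    if n_samples < 3 or p_features_x < 1 or p_features_y < 1:
        raise ValueError("need n_samples >= 3 and positive feature counts")
    if not 0.0 <= shared_variance_fraction <= 1.0:
        raise ValueError("shared_variance_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_samples)
    load_x = rng.standard_normal(p_features_x)
    load_y = rng.standard_normal(p_features_y)
    f = shared_variance_fraction
    x = np.sqrt(f) * np.outer(z, load_x) + np.sqrt(1 - f) * noise_sd * rng.standard_normal((n_samples, p_features_x))
    y = np.sqrt(f) * np.outer(z, load_y) + np.sqrt(1 - f) * noise_sd * rng.standard_normal((n_samples, p_features_y))
    truth = GroundTruth(
        planted_positive=(),
        planted_negative=(),
        planted_contaminants=(),
        latent_scores=tuple(z),
    )
    return x, y, truth
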