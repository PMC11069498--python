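"""End-to-end pipeline: config validation, staged execution, artifact writing.

A YAML config drives the whole workflow (synthetic simulation or user-supplied
tables -> preprocessing filters -> rank-mean/dsFDR differential abundance ->
index construction and scoring -> group comparisons).  A single global seed
fans out to per-stage seeds by stable hashing of stage names, so adding a
stage never perturbs an earlier stage's randomness.  Every artifact directory
gets a JSON run log recording the resolved config, seeds and package version.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .diffabund import DAConfig
from .index import run_index_pipeline
from .simulate import SimulationConfig, simulate_reference_cohort, simulate_target_cohort
from .tables import (
    FeatureTable,
    read_feature_table,
    read_metadata,
    write_feature_table,
    write_metadata,
)

__all__ = ["PipelineConfig", "ConfigError", "stage_seed", "validate_config", "run_all"]


class ConfigError(ValueError):
    """Aggregated configuration problems."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from the global seed."""
    return (zlib.crc32(f"{global_seed}:{stage}".encode()) ^ global_seed) & 0x7FFFFFFF


_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "output_dir": "microidx_run",
    "min_prevalence": 0.01,
    "rarefaction_depth": None,
    "alpha": 0.1,
    "n_permutations": 1000,
    "index_name": "rural_index",
    "bin_width": 10.0,
    "simulate": None,  # mapping of SimulationConfig overrides, or None
    "group_effect_scale": {"rural": 1.0, "rural_urban": 0.5, "urban": 0.4, "CD": 0.0},
    "reference_table": None,
    "reference_metadata": None,
    "target_table": None,
    "target_metadata": None,
    "group_comparisons": None,
}

_PATH_KEYS = ("reference_table", "reference_metadata", "target_table", "target_metadata")


@dataclass(frozen=True)
class PipelineConfig:
    """Fully-resolved pipeline settings (defaults applied, paths checked)."""

    seed: int = 0
    output_dir: str = "microidx_run"
    min_prevalence: float = 0.01
    rarefaction_depth: int | None = None
    alpha: float = 0.1
    n_permutations: int = 1000
    index_name: str = "rural_index"
    bin_width: float = 10.0
    simulate: Mapping[str, Any] | None = None
    group_effect_scale: Mapping[str, float] = field(default_factory=dict)
    reference_table: str | None = None
    reference_metadata: str | None = None
    target_table: str | None = None
    target_metadata: str | None = None
    group_comparisons: list[tuple[str, str]] | None = None

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["group_effect_scale"] = dict(self.group_effect_scale)
        if self.simulate is not None:
            d["simulate"] = dict(self.simulate)
        return d


def resolve_config(raw: Mapping[str, Any]) -> PipelineConfig:
    """Apply defaults and validate a raw config mapping; aggregate all problems."""
    problems: list[str] = []
    unknown = sorted(set(raw) - set(_DEFAULTS))
    if unknown:
        problems.append(f"unknown config keys: {unknown}")
    merged = {**_DEFAULTS, **{k: v for k, v in raw.items() if k in _DEFAULTS}}

    if merged["simulate"] is None:
        for key in _PATH_KEYS:
            if merged[key] is None:
                problems.append(f"missing required key {key!r} (or set 'simulate')")
            elif not Path(merged[key]).exists():
                problems.append(f"{key}: file not found: {merged[key]}")
    if not 0 < float(merged["alpha"]) < 1:
        problems.append(f"alpha must be in (0, 1), got {merged['alpha']}")
    if int(merged["n_permutations"]) < 1:
        problems.append("n_permutations must be >= 1")
    if problems:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))
    if merged["group_comparisons"] is not None:
        merged["group_comparisons"] = [tuple(pair) for pair in merged["group_comparisons"]]
    return PipelineConfig(**merged)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: config must be a key-value mapping")
    return resolve_config(raw)


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        sim = SimulationConfig(**{**dict(config.simulate), "seed": stage_seed(config.seed, "simulate")})
        ref_table, ref_meta, truth = simulate_reference_cohort(sim)
        tgt_table, tgt_meta = simulate_target_cohort(sim, truth, config.group_effect_scale)
        write_feature_table(ref_table, outdir / "reference_table.tsv")
        write_metadata(ref_meta, outdir / "reference_metadata.tsv")
        write_feature_table(tgt_table, outdir / "target_table.tsv")
        write_metadata(tgt_meta, outdir / "target_metadata.tsv")
        (outdir / "ground_truth.json").write_text(
            json.dumps(
                {
                    "planted_positive": list(truth.planted_positive),
                    "planted_negative": list(truth.planted_negative),
                    "planted_contaminants": list(truth.planted_contaminants),
                },
                indent=2,
            )
        )
        return ref_table, ref_meta, tgt_table, tgt_meta
    return (
        read_feature_table(config.reference_table),
        read_metadata(config.reference_metadata),
        read_feature_table(config.target_table),
        read_metadata(config.target_metadata),
    )


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full workflow and write per-stage artifacts.

    Returns the in-memory report (differential abundance table, index, scores,
    group comparisons).  Reruns with the same config and seed are
    byte-identical.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        ref_table, ref_meta, tgt_table, tgt_meta = _load_inputs(config, outdir)
        stage = "index_pipeline"
        report = run_index_pipeline(
            ref_table,
            ref_meta,
            tgt_table,
            tgt_meta,
            index_name=config.index_name,
            min_prevalence=config.min_prevalence,
            rarefaction_depth=config.rarefaction_depth,
            da_config=DAConfig(
                n_permutations=config.n_permutations,
                alpha=config.alpha,
                seed=stage_seed(config.seed, "diffabund"),
            ),
            group_comparisons=config.group_comparisons,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "artifacts"
    report["differential_abundance"].to_csv(outdir / "differential_abundance.tsv", sep="\t")
    report["index"].to_json(outdir / "index_definition.json")
    scores = report["scores"].to_frame()
    scores["group"] = tgt_meta["group"].reindex(scores.index)
    scores.to_csv(outdir / "index_scores.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(report["comparisons"]).to_csv(outdir / "group_comparisons.tsv", sep="\t", index=False)
    (outdir / "run_log.json").write_text(
        json.dumps(
            {
                "package_version": __version__,
                "config": config.to_dict(),
                "stage_seeds": {s: stage_seed(config.seed, s) for s in ("simulate", "diffabund")},
                "filter_reports": [
                    {
                        "operation": r.operation,
                        "n_before": r.n_before,
                        "n_after": r.n_after,
                        "n_removed": r.n_removed,
                    }
                    for r in report["filter_reports"]
                ],
                "coverage": report["coverage"],
            },
            indent=2,
        )
    )
    return report
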