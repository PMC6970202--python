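"""End-to-end orchestration: generate -> score -> statistics -> model.

A :class:`RunConfig` (constructible from YAML) drives the full analysis on
a synthetic cohort and writes every artifact — cohort CSV, score matrix,
count-summary and statistics tables, model report — plus a manifest with a
content hash per file and a config hash, so identical config + seed yields
an identical manifest. One master seed is fanned out per stage by name, so
each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .harness import (
    FeatureMode,
    FeatureSet,
    ModelFamily,
    ModelSpec,
    assemble_design,
    enumerate_feature_sets,
    run_experiment,
)
from .records import write_cohort
from .scores import default_registry, export_heatmap_matrix, read_registry
from .simulate import GeneratorConfig, generate_cohort, summarize_cohort
from .stats import run_score_stats, run_table3

logger = logging.getLogger("mmrimmune.pipeline")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage name mixed into the
    master seed, kept below 2**31."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    out_dir: Path
    master_seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    score_registry_path: Optional[Path] = None
    feature_set: str = "CD8_CT"
    feature_mode: FeatureMode = FeatureMode.TWO_CLASS
    model_family: ModelFamily = ModelFamily.FISHER_DISCRIMINANT
    n_repeats: int = 20
    stats_route: str = "nonparametric"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen_kwargs = raw.get("generator", {})
        if "cohort_sizes" in gen_kwargs:
            from .records import CohortLabel

            gen_kwargs["cohort_sizes"] = {
                CohortLabel(k): v for k, v in gen_kwargs["cohort_sizes"].items()
            }
        if "biopsy_fraction" in gen_kwargs:
            from .records import CohortLabel

            gen_kwargs["biopsy_fraction"] = {
                CohortLabel(k): v for k, v in gen_kwargs["biopsy_fraction"].items()
            }
        return cls(
            out_dir=Path(raw["out_dir"]),
            master_seed=int(raw.get("master_seed", 0)),
            generator=GeneratorConfig(**gen_kwargs),
            score_registry_path=Path(raw["score_registry"]) if "score_registry" in raw else None,
            feature_set=raw.get("feature_set", "CD8_CT"),
            feature_mode=FeatureMode(raw.get("feature_mode", "TWO_CLASS")),
            model_family=ModelFamily(raw.get("model_family", "FISHER_DISCRIMINANT")),
            n_repeats=int(raw.get("n_repeats", 20)),
            stats_route=raw.get("stats_route", "nonparametric"),
        )

    def config_hash(self) -> str:
        payload = {
            "master_seed": self.master_seed,
            "cohort_sizes": {k.value: v for k, v in self.generator.cohort_sizes.items()},
            "biopsy_fraction": {k.value: v for k, v in self.generator.biopsy_fraction.items()},
            "latent_corr": self.generator.latent_corr,
            "count_family": self.generator.count_family,
            "feature_set": self.feature_set,
            "feature_mode": self.feature_mode.value,
            "model_family": self.model_family.value,
            "n_repeats": self.n_repeats,
            "stats_route": self.stats_route,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis and return the manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    logger.info("stage=generate seed=%d", stage_seed(config.master_seed, "generate"))
    gen_config = config.generator
    gen_config.seed = stage_seed(config.master_seed, "generate")
    cohort = generate_cohort(gen_config)
    outputs["cohort"] = out / "cohort.csv"
    write_cohort(cohort, outputs["cohort"])

    outputs["count_summary"] = out / "count_summary.csv"
    summarize_cohort(cohort).to_csv(outputs["count_summary"], index=False)

    logger.info("stage=score")
    registry = (
        read_registry(config.score_registry_path)
        if config.score_registry_path
        else default_registry()
    )
    known = {d.score_id for d in registry}
    heatmap = export_heatmap_matrix(cohort, registry)
    outputs["score_matrix"] = out / "score_matrix.csv"
    heatmap.to_csv(outputs["score_matrix"])

    logger.info("stage=stats route=%s", config.stats_route)
    outputs["count_stats"] = out / "count_stats.csv"
    run_table3(cohort, route=config.stats_route).to_csv(outputs["count_stats"], index=False)
    outputs["score_stats"] = out / "score_stats.csv"
    run_score_stats(heatmap).to_csv(outputs["score_stats"], index=False)

    logger.info("stage=model family=%s features=%s", config.model_family.value, config.feature_set)
    design = assemble_design(cohort, registry)
    if config.feature_set in known:
        feature_set = FeatureSet(config.feature_set, (config.feature_set,))
    else:
        candidates = {
            s.name: s for s in enumerate_feature_sets(config.feature_mode)
        }
        if config.feature_set not in candidates and config.feature_set not in design.columns:
            raise ValueError(
                f"unknown feature set or score id {config.feature_set!r}; "
                f"registry offers {sorted(known)} and {sorted(candidates)}"
            )
        feature_set = candidates.get(
            config.feature_set, FeatureSet(config.feature_set, (config.feature_set,))
        )
    result = run_experiment(
        design,
        feature_set,
        ModelSpec(config.model_family, seed=stage_seed(config.master_seed, "model")),
        mode=config.feature_mode,
        n_repeats=config.n_repeats,
        seed=stage_seed(config.master_seed, "model"),
    )
    outputs["model_report"] = out / "model_report.json"
    outputs["model_report"].write_text(
        json.dumps(
            {
                "feature_set": feature_set.name,
                "columns": list(feature_set.columns),
                "mode": config.feature_mode.value,
                "family": config.model_family.value,
                "summary": result.summary(),
                "per_repeat": [
                    {"auc": r.auc, "accuracy": r.accuracy} for r in result.reports
                ],
            },
            indent=2,
        )
    )

    manifest = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "config_hash": config.config_hash(),
        "stage_seeds": {s: stage_seed(config.master_seed, s) for s in ("generate", "model")},
        "files": {name: _sha256(path) for name, path in sorted(outputs.items())},
        "n_excluded_missing_im": result.n_excluded,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("stage=done artifacts=%d", len(outputs))
    return manifest
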