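"""End-to-end orchestration: cohort -> features -> comparisons -> windows ->
classification -> report bundle.

Every stage writes a plain CSV under the output directory; a JSON manifest
records the configuration, seed, package version and per-stage row counts,
which suffices to reproduce any output. A single seed is fanned out to
stages through named sub-streams so adding a stage never perturbs another
stage's randomness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import TreeSpec, exhaustive_search, export_tree_dot, ranking_frame
from .cohort import Cohort, read_cohort, write_cohort
from .compare import compare_all
from .metrics import DIGITS, FOD_DIFFS, feature_table
from .rqa import rqa_table
from .simulate import GroupScenario, default_scenario, sample_cohort
from .windows import WindowSpec, group_trajectory_contrast, trajectory_table

logger = logging.getLogger(__name__)

#: Sequence-descriptor variables ("group 2"): the default classifier pool,
#: which contains the published best subset (FOD_8, FOD_-8).
GROUP2_FEATURES = tuple(
    [f"RF_{k}" for k in DIGITS]
    + [f"r_RF_{k}" for k in DIGITS]
    + [f"FOD_{d}" for d in FOD_DIFFS]
    + [f"r_FOD_{d}" for d in FOD_DIFFS]
    + ["Cf", "r_Cf"]
)

GROUP1_FEATURES = (
    "R", "RNG", "RNG2", "NSQ",
    "adjacency_asc", "adjacency_desc", "adjacency_combined", "TPI",
)


@dataclass
class PipelineConfig:
    """One pipeline run. Exactly one of ``input_path`` / ``scenario``."""

    output_dir: str | Path
    input_path: str | Path | None = None
    scenario: GroupScenario | None = None
    window: WindowSpec = field(default_factory=WindowSpec)
    window_metrics: tuple[str, ...] = ("NSQ", "R", "adjacency_combined")
    alpha: float = 0.05
    tree: TreeSpec = field(default_factory=TreeSpec)
    feature_pool: str = "group2"  # group2 | group1+2 | all
    max_subset_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.scenario is None):
            raise ValueError("provide exactly one of input_path or scenario")


def _pool_columns(config: PipelineConfig, features: pd.DataFrame, rqa: pd.DataFrame):
    if config.feature_pool == "fod":
        # the 19 first-order-difference counts: a bounded pool holding the
        # published best subset (FOD_8, FOD_-8); ~1.2k subsets at k = 3
        # instead of ~36k for the full descriptor pool
        pool = [f"FOD_{d}" for d in FOD_DIFFS]
    elif config.feature_pool in ("group2", "group1+2", "all"):
        pool = list(GROUP2_FEATURES)
        if config.feature_pool in ("group1+2", "all"):
            pool = list(GROUP1_FEATURES) + pool
        if config.feature_pool == "all":
            pool += [c for c in rqa.columns if c not in ("participant_id", "group")]
    else:
        raise ValueError(f"unknown feature_pool {config.feature_pool!r}")
    return [c for c in pool if c in features.columns]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle.

    Returns the manifest dict. Any stage failure aborts with the stage name;
    artifacts from completed stages remain on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "config": {
            "input": str(config.input_path) if config.input_path else "simulation",
            "window_fraction": config.window.fraction,
            "window_step": config.window.step,
            "alpha": config.alpha,
            "feature_pool": config.feature_pool,
            "max_subset_size": config.max_subset_size,
            "tree": vars(config.tree) | {},
        },
    }

    stage = "ingest"
    try:
        if config.scenario is not None:
            cohort = sample_cohort(config.scenario)
            write_cohort(cohort, out / "cohort.csv")
        else:
            cohort = read_cohort(config.input_path)
        manifest["stages"][stage] = {"participants": len(cohort)}
        logger.info("ingest: %d participants %s", len(cohort), cohort.group_sizes())

        stage = "features"
        features = feature_table(cohort.sequences)
        rqa = rqa_table(cohort.sequences)
        features.to_csv(out / "features.csv", index=False)
        rqa.to_csv(out / "rqa.csv", index=False)
        manifest["stages"][stage] = {"rows": len(features)}

        stage = "comparison"
        merged = features.drop(columns=["participant_id"]).join(
            rqa.drop(columns=["participant_id", "group"])
        )
        comparison = compare_all(merged, alpha=config.alpha)
        comparison.to_csv(out / "comparison.csv", index=False)
        manifest["stages"][stage] = {"rows": len(comparison)}

        stage = "windows"
        trajectories = trajectory_table(cohort, config.window)
        trajectories.to_csv(out / "trajectories.csv", index=False)
        contrasts = []
        for metric in config.window_metrics:
            c = group_trajectory_contrast(cohort, config.window, metric)
            c = c.reset_index()
            c.insert(0, "metric", metric)
            contrasts.append(c)
        contrast = pd.concat(contrasts, ignore_index=True)
        contrast.to_csv(out / "trajectory_contrast.csv", index=False)
        manifest["stages"][stage] = {
            "rows": len(trajectories),
            "contrast_rows": len(contrast),
        }

        stage = "classification"
        small = len(features) < 10
        if small:
            logger.warning(
                "classification on %d participants: accuracies are unstable",
                len(features),
            )
        pool = _pool_columns(config, features, rqa)
        class_table = features if config.feature_pool != "all" else features.join(
            rqa[[c for c in rqa.columns if c not in ("participant_id", "group")]]
        )
        results = exhaustive_search(
            class_table,
            max_subset_size=config.max_subset_size,
            spec=config.tree,
            feature_cols=pool,
        )
        ranking = ranking_frame(results)
        ranking.to_csv(out / "ranking.csv", index=False)
        best = results[0]
        (out / "best_tree.dot").write_text(
            export_tree_dot(class_table, best.feature_subset, config.tree)
        )
        manifest["stages"][stage] = {
            "subsets": len(results),
            "best_features": list(best.feature_subset),
            "best_loo_accuracy": best.loo_accuracy,
            "small_n_warning": small,
        }
    except Exception as err:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def simulate_and_run(output_dir, seed: int = 0, **kwargs) -> dict:
    """Convenience: default published-cohort-like simulation plus full run."""
    config = PipelineConfig(
        output_dir=output_dir, scenario=default_scenario(seed=seed), seed=seed, **kwargs
    )
    return run_pipeline(config)
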