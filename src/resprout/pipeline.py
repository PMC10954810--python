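"""End-to-end orchestration: simulate -> detect -> label -> fuse -> predict.

A single JSON-serializable configuration drives every stage; one global
seed deterministically derives per-stage seeds, so a rerun with the same
config produces byte-identical artifacts. Each run directory receives
the resolved config, per-stage outputs, a log file and a manifest of
artifact checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import change_detection as cd
from . import fusion, labelling, prediction, synthetic
from .qsm import QSM, read_qsm_csv, write_qsm_csv

__all__ = ["PipelineConfig", "run_all", "detect_stage", "label_stage", "fuse_stage"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters in one structured document."""

    n_trees: int = 20
    seed: int = 0
    synthetic: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig
    )
    sor_k: int = 6
    sor_sigma: float = 1.0
    tau_t1: float = 0.030
    tau_t2: float = 0.030
    labelling: labelling.LabellingParams = field(
        default_factory=labelling.LabellingParams
    )
    max_attach_dist: float = fusion.DEFAULT_MAX_ATTACH_DIST
    n_eval_trees: int = 2
    test_fraction: float = 0.2
    features: list[str] = field(
        default_factory=lambda: list(prediction.DEFAULT_FEATURES)
    )
    tasks: tuple[str, ...] = ("binary", "multiclass")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=str)

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the global seed, deterministically."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def detect_stage(
    cloud_t1: cd.PointCloud,
    cloud_t2: cd.PointCloud,
    config: PipelineConfig,
) -> tuple[cd.ChangedPointSet, cd.ChangedPointSet]:
    """SOR-filter both clouds, then segment changed points."""
    f1 = cd.sor_filter(cloud_t1, k=config.sor_k, sigma_mult=config.sor_sigma)
    f2 = cd.sor_filter(cloud_t2, k=config.sor_k, sigma_mult=config.sor_sigma)
    return cd.detect_changes(f1, f2, tau_t1=config.tau_t1, tau_t2=config.tau_t2)


def label_stage(
    qsm_t1: QSM,
    qsm_t2: QSM,
    changes: tuple[cd.ChangedPointSet, cd.ChangedPointSet],
    config: PipelineConfig,
) -> tuple[QSM, QSM]:
    return labelling.label_qsm_pair(
        qsm_t1, qsm_t2, changes[0], changes[1], config.labelling
    )


def fuse_stage(qsm_t1: QSM, qsm_t2: QSM, config: PipelineConfig) -> fusion.MergedQSM:
    return fusion.fuse(qsm_t1, qsm_t2, max_attach_dist=config.max_attach_dist)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, out_dir, scenarios=None) -> Path:
    """Run the whole pipeline into ``out_dir`` and return that path.

    When ``scenarios`` is None they are simulated from the config;
    otherwise the given list of :class:`GroundTruthScenario` is used
    (e.g. pre-loaded from disk). Identical config and seed produce
    identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("resprout")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    artifacts: list[Path] = []
    try:
        (out / "config.json").write_text(config.to_json())
        artifacts.append(out / "config.json")

        if scenarios is None:
            logger.info("simulate: %d trees, seed %d", config.n_trees, config.seed)
            scenarios = synthetic.generate_scenarios(
                config.n_trees, config.synthetic, seed=config.stage_seed("simulate")
            )

        merged_models = []
        for sc in scenarios:
            changes = detect_stage(sc.cloud_t1, sc.cloud_t2, config)
            lab1, lab2 = label_stage(sc.qsm_t1.copy(), sc.qsm_t2.copy(), changes, config)
            merged = fuse_stage(lab1, lab2, config)
            merged_models.append(merged)
            tree_dir = out / "trees" / sc.tree_id
            tree_dir.mkdir(parents=True, exist_ok=True)
            write_qsm_csv(merged.qsm, tree_dir / "merged.csv")
            artifacts.append(tree_dir / "merged.csv")

        table = prediction.build_feature_table(merged_models)
        table_path = out / "features.csv"
        table.to_csv(table_path, index=False)
        artifacts.append(table_path)

        split = prediction.make_splits(
            table,
            n_eval_trees=config.n_eval_trees,
            test_fraction=config.test_fraction,
            seed=config.stage_seed("split"),
        )
        results = {"eval_tree_ids": split.eval_tree_ids, "tasks": {}}
        for task in config.tasks:
            report = prediction.run_model_suite(
                split,
                task=task,
                features=config.features,
                seed=config.stage_seed("models"),
            )
            report.scores.to_csv(out / f"benchmark_{task}.csv", index=False)
            artifacts.append(out / f"benchmark_{task}.csv")
            task_result = {
                "skipped": report.skipped,
                "scores": report.scores.drop(columns=["fit_seconds"], errors="ignore")
                .to_dict(orient="records"),
            }
            if len(report.scores) and len(split.eval):
                best = report.scores.iloc[0]["name"]
                cm, per_class, summary = prediction.evaluate_holdout(
                    report.models[best], split.eval, config.features, task=task
                )
                task_result["evaluation"] = {
                    "model": best,
                    "confusion_matrix": cm.to_dict(),
                    "per_class": per_class.to_dict(orient="records"),
                    "summary": summary,
                }
            results["tasks"][task] = task_result
        (out / "report.json").write_text(json.dumps(results, indent=2, default=float))
        artifacts.append(out / "report.json")

        manifest = {str(p.relative_to(out)): _sha256(p) for p in artifacts}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
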