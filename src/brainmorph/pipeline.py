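"""End-to-end experiment orchestration under one seeded configuration.

``run_experiment`` chains cohort generation, feature extraction for the
requested methods, and LOOCV evaluation for the requested tasks (plus
optional subgroups), writing a JSON report, a metrics CSV and ROC plots.
Everything is deterministic given the configuration seed; volumes are
generated streaming (one subject in memory at a time).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortSpec,
    build_atrophy_model,
    default_parcellation,
    generate_subject_table,
    generate_tissue_maps,
    records_to_frame,
)
from .evaluate import EvalReport, SvmConfig, METHOD_NORMALIZE, run_task
from .features import FeatureMatrix, HogConfig, make_extractor
from .stats import build_table1
from .volumes import load_parcellation, make_patch_grid

log = logging.getLogger("brainmorph")

ALL_METHODS = ("VOR", "PBM", "LEP", "DTL")
ALL_TASKS = ("CI_vs_NC", "T2DM_vs_NT")


class ConfigError(ValueError):
    """Raised for invalid run configurations."""


@dataclass
class RunConfig:
    """Full experiment configuration (all defaults are study constants)."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    atlas: str = "synthetic:116"  # "synthetic:<R>" or a NIfTI path
    hog: HogConfig = field(default_factory=HogConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    methods: tuple[str, ...] = ALL_METHODS
    tasks: tuple[str, ...] = ALL_TASKS
    subgroups: tuple[str, ...] = ()  # e.g. ("ci_only",) applied to T2DM_vs_NT
    crop_shape: tuple[int, int, int] = (144, 192, 128)
    patch_size: int = 16
    mask_threshold: float = 0.5
    output_dir: str = "brainmorph_out"

    def validate(self) -> "RunConfig":
        if not self.methods:
            raise ConfigError("at least one method is required")
        if not self.tasks:
            raise ConfigError("at least one task is required")
        bad = [m for m in self.methods if m not in ALL_METHODS]
        if bad:
            raise ConfigError(f"unknown methods {bad}; choose from {ALL_METHODS}")
        bad = [t for t in self.tasks if t not in ALL_TASKS]
        if bad:
            raise ConfigError(f"unknown tasks {bad}; choose from {ALL_TASKS}")
        if self.seed is None:
            raise ConfigError("seed must be set")
        self.svm.validate()
        self.cohort.validate()
        if not 0 < self.mask_threshold < 1:
            raise ConfigError("mask_threshold must be in (0, 1)")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["methods"] = list(self.methods)
        d["tasks"] = list(self.tasks)
        d["subgroups"] = list(self.subgroups)
        d["crop_shape"] = list(self.crop_shape)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


_TOP_KEYS = {
    "seed",
    "cohort",
    "atlas",
    "hog",
    "svm",
    "methods",
    "tasks",
    "subgroups",
    "crop_shape",
    "patch_size",
    "mask_threshold",
    "output_dir",
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown keys in '{section}': {unknown}")
    return data


def config_from_dict(data: dict) -> RunConfig:
    """Build and validate a RunConfig from a plain dict (e.g. parsed YAML).

    Unknown keys are rejected exhaustively so typos cannot silently fall
    back to defaults.
    """
    data = dict(data or {})
    errors = []
    unknown = sorted(set(data) - _TOP_KEYS)
    if unknown:
        errors.append(f"unknown top-level keys: {unknown}")
    kwargs: dict = {}
    if "cohort" in data:
        cohort_data = dict(data.pop("cohort") or {})
        try:
            _build_section(CohortSpec, cohort_data, "cohort")
            kwargs["cohort"] = CohortSpec.from_dict(cohort_data)
        except (ConfigError, ValueError) as exc:
            errors.append(str(exc))
    if "hog" in data:
        hog_data = dict(data.pop("hog") or {})
        try:
            _build_section(HogConfig, hog_data, "hog")
            for key in ("cell_size", "cells_per_block"):
                if key in hog_data:
                    hog_data[key] = tuple(hog_data[key])
            kwargs["hog"] = HogConfig(**hog_data)
        except (ConfigError, TypeError) as exc:
            errors.append(str(exc))
    if "svm" in data:
        svm_data = dict(data.pop("svm") or {})
        try:
            _build_section(SvmConfig, svm_data, "svm")
            kwargs["svm"] = SvmConfig(**svm_data)
        except (ConfigError, TypeError) as exc:
            errors.append(str(exc))
    for key in ("methods", "tasks", "subgroups"):
        if key in data:
            kwargs[key] = tuple(data.pop(key))
    if "crop_shape" in data:
        kwargs["crop_shape"] = tuple(data.pop("crop_shape"))
    for key in ("seed", "atlas", "patch_size", "mask_threshold", "output_dir"):
        if key in data:
            kwargs[key] = data.pop(key)
    if errors:
        raise ConfigError("; ".join(errors))
    cfg = RunConfig(**kwargs)
    if "seed" in kwargs and "cohort" not in kwargs:
        cfg.cohort.seed = int(kwargs["seed"])
    try:
        cfg.validate()
    except (ConfigError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def validate_config(path: str | Path) -> RunConfig:
    """Parse, default and validate a YAML run configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def _resolve_atlas(cfg: RunConfig, shape, mask):
    from .volumes import synthetic_parcellation

    if cfg.atlas.startswith("synthetic:"):
        n_regions = int(cfg.atlas.split(":", 1)[1])
        return synthetic_parcellation(mask, n_regions=n_regions, seed=cfg.seed)
    return load_parcellation(cfg.atlas, expected_shape=shape)


def _plot_roc(reports: list[EvalReport], task: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for rep in reports:
        fpr = [p[0] for p in rep.roc]
        tpr = [p[1] for p in rep.roc]
        ax.plot(fpr, tpr, label=f"{rep.method} (AUC={rep.auc:.4f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False-positive rate")
    ax.set_ylabel("True-positive rate")
    ax.set_title(task.replace("_", " "))
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_experiment(cfg: RunConfig) -> dict:
    """Run the full experiment and write report artifacts to ``output_dir``.

    Returns the experiment report dict: per method x task (x subgroup)
    evaluation reports, the clinical comparison table, config echo and
    provenance hashes.
    """
    cfg.validate()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log.info("config %s", cfg.config_hash())

    records = generate_subject_table(cfg.cohort)
    table = records_to_frame(records)
    table.to_csv(out_dir / "cohort.csv", index=False)
    log.info("cohort: %d subjects [%.1fs]", len(records), time.time() - t0)

    parc, mask = default_parcellation(
        cfg.cohort.shape, seed=cfg.seed, mask_threshold=cfg.mask_threshold
    )
    if not cfg.atlas.startswith("synthetic:") or cfg.atlas != "synthetic:116":
        parc = _resolve_atlas(cfg, cfg.cohort.shape, mask)
    grid = make_patch_grid(cfg.cohort.shape, cfg.crop_shape, cfg.patch_size)
    extractors = {}
    for method in cfg.methods:
        if method == "VOR":
            extractors[method] = make_extractor("VOR", parcellation=parc)
        elif method == "PBM":
            extractors[method] = make_extractor("PBM", grid=grid)
        elif method == "LEP":
            extractors[method] = make_extractor("LEP", grid=grid, hog=cfg.hog)
        else:
            extractors[method] = make_extractor("DTL", seed=cfg.seed)

    atrophy = build_atrophy_model(cfg.cohort, parc)
    rows: dict[str, list[np.ndarray]] = {m: [] for m in cfg.methods}
    fitted = False
    for rec in records:
        maps = generate_tissue_maps(rec, parc, cfg.cohort, atrophy)
        if not fitted:
            for ext in extractors.values():
                ext.fit([maps])
            fitted = True
        for method, ext in extractors.items():
            rows[method].append(ext.transform_one(maps))
    subject_ids = [r.subject_id for r in records]
    matrices = {
        m: FeatureMatrix(np.vstack(v), subject_ids, m) for m, v in rows.items()
    }
    for m, fm in matrices.items():
        fm.to_csv(out_dir / f"features_{m.lower()}.csv")
    log.info("features extracted [%.1fs]", time.time() - t0)

    cells = [(task, None) for task in cfg.tasks]
    cells += [("T2DM_vs_NT", sg) for sg in cfg.subgroups]
    reports: list[EvalReport] = []
    metric_rows = []
    for task, subgroup in cells:
        for method, fm in matrices.items():
            svm = SvmConfig(
                C=cfg.svm.C,
                normalize=METHOD_NORMALIZE.get(method, "none")
                if cfg.svm.normalize == "none"
                else cfg.svm.normalize,
            )
            rep = run_task(fm, table, task, subgroup=subgroup, cfg=svm)
            reports.append(rep)
            metric_rows.append(
                {
                    "task": task,
                    "subgroup": subgroup or "",
                    "method": method,
                    "n": rep.n,
                    **rep.metrics(),
                }
            )
            log.info(
                "%s %s %s: AUC=%.4f ACC=%.4f [%.1fs]",
                task,
                subgroup or "all",
                method,
                rep.auc,
                rep.acc,
                time.time() - t0,
            )
    metrics_df = pd.DataFrame(metric_rows)
    metrics_df.to_csv(out_dir / "metrics.csv", index=False, float_format="%.6f")
    for task in cfg.tasks:
        task_reps = [r for r in reports if r.task == task and r.subgroup is None]
        if task_reps:
            _plot_roc(task_reps, task, out_dir / f"roc_{task.lower()}.png")

    table1 = build_table1(records)
    table1.to_csv(out_dir / "table1.csv")

    report = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "cohort_hash": hashlib.sha256(
            table.to_csv(index=False).encode()
        ).hexdigest()[:16],
        "evaluations": [r.to_dict() for r in reports],
        "runtime_s": round(time.time() - t0, 2),
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
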