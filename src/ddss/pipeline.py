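"""End-to-end orchestration: records -> trajectories -> decoupling -> prediction.

A :class:`RunConfig` (YAML/JSON) names exactly one input source — a records CSV or a
synthetic generator config — plus the method parameters; :func:`run_ddss` executes the
stages in order and writes deterministic text artifacts (sequences, partition, merge
history, metrics, manifest) so a run can be reproduced byte-identically from its
manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoupler import SequencePartitioner, group_duration_test
from .exceptions import PipelineError, ValidationError
from .predictor import (
    DIFFICULTY_CLASSES,
    SplitSpec,
    evaluate,
    predict,
    split_dataset,
    train_models,
)
from .records import impute_missing, label_dataset, read_records, write_records
from .schema import Dataset
from .synthetic import GeneratorConfig, default_config, generate_dataset
from .trajectory import monthly_trajectories, surgeon_sequences

__all__ = ["RunConfig", "run_ddss", "run_learning_curve"]


@dataclass(frozen=True)
class RunConfig:
    """One input source plus the knobs of every stage."""

    records_csv: str | None = None
    generator: dict | None = None  # GeneratorConfig mapping; None -> records_csv
    lambda0: float = 0.01
    tau: float = 0.05
    grid_size: int = 200
    linkage: str = "average"
    k: int = 2
    model_kind: str = "svm"
    test_fraction: float = 0.2
    routing: str = "surgeon"
    seed: int = 0
    months: int = 10
    out_dir: str = "ddss_run"

    def __post_init__(self) -> None:
        if (self.records_csv is None) == (self.generator is None):
            raise ValidationError(
                "config must name exactly one input source "
                "(records_csv or generator)"
            )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"[{name}] {exc}") from exc

    return wrap


def load_input(cfg: RunConfig) -> Dataset:
    if cfg.records_csv is not None:
        ds = read_records(cfg.records_csv)
    else:
        gen = (
            default_config(seed=cfg.seed)
            if cfg.generator in ({}, {"default": True})
            else GeneratorConfig.from_dict(cfg.generator)
        )
        ds = generate_dataset(gen)
    return impute_missing(ds)


def _manifest(cfg: RunConfig) -> dict:
    doc = cfg.to_dict()
    digest = hashlib.sha256(
        json.dumps(doc, sort_keys=True).encode("utf-8")
    ).hexdigest()
    return {"config": doc, "config_sha256": digest, "ddss_version": __version__}


def run_ddss(cfg: RunConfig) -> dict:
    """Execute the full decoupling-prediction workflow; return artifact paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = _stage("records")(load_input, cfg)
    if len(ds.surgeon_ids) < 2:
        raise PipelineError("[decoupler] need >=2 surgeons to decouple")

    if cfg.records_csv is None:
        _stage("records")(write_records, ds, out / "records.csv")

    train, test = _stage("predictor")(
        split_dataset, ds, SplitSpec(test_fraction=cfg.test_fraction, seed=cfg.seed)
    )
    seqs = _stage("trajectory")(surgeon_sequences, train, cfg.grid_size)
    part_est = _stage("decoupler")(
        SequencePartitioner(k=cfg.k, linkage=cfg.linkage).fit, seqs
    )
    partition = part_est.partition_

    bundle = _stage("predictor")(
        train_models, train, partition, cfg.model_kind, 5, cfg.seed
    )
    frame = _stage("predictor")(predict, bundle, test, partition, train, cfg.routing)
    y_true = label_dataset(test)
    scores = frame[[f"score_{c}" for c in DIFFICULTY_CLASSES]].to_numpy()
    report = _stage("predictor")(evaluate, y_true, frame["pred"].to_numpy(), scores)
    ttest = _stage("decoupler")(group_duration_test, ds, partition)

    pd.DataFrame(
        {
            "surgeon_id": [s.surgeon_id for s in seqs],
            "sequence": [",".join(s.tokens) for s in seqs],
        }
    ).to_csv(out / "sequences.csv", index=False)
    pd.DataFrame(
        sorted(partition.assignment.items()), columns=["surgeon_id", "cluster"]
    ).to_csv(out / "partition.csv", index=False)
    pd.DataFrame(
        [
            {"height": h, "members_a": "|".join(a), "members_b": "|".join(b)}
            for h, a, b in partition.merges
        ]
    ).to_csv(out / "merges.csv", index=False)
    frame.to_csv(out / "predictions.csv", index=False)
    metrics = {
        "metrics": report.to_dict(),
        "group_duration_test": {
            "t": ttest.t,
            "p": ttest.p,
            "group_means": {str(k): v for k, v in ttest.group_means.items()},
        },
        "hyperparameters": {str(c): p for c, p in bundle.best_params.items()},
        "cv_macro_auc": {str(c): v for c, v in bundle.cv_scores.items()},
        "seed": cfg.seed,
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(
        json.dumps(_manifest(cfg), indent=2, sort_keys=True)
    )
    return {
        "dataset": ds,
        "partition": partition,
        "report": report,
        "out_dir": str(out),
        "artifacts": sorted(p.name for p in out.iterdir()),
    }


def run_learning_curve(cfg: RunConfig) -> dict:
    """Monthly pooled Lasso trajectories; emits plot-data CSVs (no rendering)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = _stage("records")(load_input, cfg)
    if not len(ds):
        raise PipelineError("[trajectory] no records with month data")
    table = _stage("trajectory")(
        monthly_trajectories, ds, cfg.months, cfg.lambda0, cfg.tau, cfg.grid_size
    )
    rows = []
    for m in table.months:
        beta = table.coefficients[m]
        row = {"month": m, "n_records": table.n_records[m]}
        for j, name in enumerate(table.feature_names):
            row[name] = np.nan if beta is None else float(beta[j])
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "monthly_coefficients.csv", index=False)
    kept = []
    for m in table.months:
        ret = table.retained[m]
        kept.append(
            {
                "month": m,
                "retained": ""
                if ret is None
                else ",".join(f"{n}:{v:.4f}" for n, v in sorted(ret.entries.items())),
                "n_retained": 0 if ret is None else len(ret.entries),
            }
        )
    pd.DataFrame(kept).to_csv(out / "retained_timeline.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(_manifest(cfg), indent=2, sort_keys=True)
    )
    return {"table": table, "out_dir": str(out)}
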