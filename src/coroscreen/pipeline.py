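"""End-to-end orchestration: simulate -> crop -> preprocess -> train ->
predict -> evaluate, with deterministic per-stage seeds and resumable
stage outputs.

Every stochastic stage derives its seed from ``master_seed`` via a named
SeedSequence, so a run is reproducible from its config alone.  Each stage
persists its outputs under ``<output_root>/<run_id>/<stage>/``; a completed
stage is reloaded instead of recomputed, and deleting a stage directory
forces just that stage to re-execute (downstream results are unchanged by
determinism).
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

from .evaluate import cutoff_sweep, metrics_report
from .localize import naive_segment
from .model import (TensorCase, TrainConfig, cases_to_tensors, fine_tune, predict_case,
                    predict_cases, train_task)
from .nn import NetworkConfig, load_checkpoint, save_checkpoint
from .phantom import PhantomConfig, generate_cohort_records
from .preprocess import PreprocessConfig

__all__ = ["PipelineConfig", "derive_seed", "run_end_to_end", "run_screening"]

log = logging.getLogger(__name__)

DEFAULT_CLASS_MIX = {
    "normal": 0.5,
    "R-AAOCA/interarterial": 0.10, "R-AAOCA/prepulmonic": 0.05,
    "R-AAOCA/retroaortic": 0.05, "R-AAOCA/high_takeoff": 0.025,
    "R-AAOCA/subpulmonic": 0.025,
    "L-AAOCA/interarterial": 0.10, "L-AAOCA/prepulmonic": 0.05,
    "L-AAOCA/retroaortic": 0.05, "L-AAOCA/high_takeoff": 0.025,
    "L-AAOCA/subpulmonic": 0.025,
}


@dataclass
class PipelineConfig:
    run_id: str = "run"
    output_root: str = "runs"
    master_seed: int = 0
    n_train_cases: int = 60
    n_test_cases: int = 20
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = field(default_factory=lambda: PreprocessConfig(
        target_dims=(32, 32, 24)))
    network: NetworkConfig = field(default_factory=lambda: NetworkConfig.tiny((32, 32, 24)))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(total_epochs=15, n_members=3))
    tasks: tuple = ("anomaly", "origin", "risk")
    cutoff: float = 0.5
    n_boot: int = 1000
    use_naive_segmentation: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        sub = {"phantom": PhantomConfig, "preprocess": PreprocessConfig,
               "network": NetworkConfig, "train": TrainConfig}
        for key, value in raw.items():
            if key in sub:
                value = {k: tuple(v) if isinstance(v, list) else v for k, v in value.items()}
                kwargs[key] = sub[key](**value)
            elif key == "tasks":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _phantom_for(cfg: PipelineConfig) -> PhantomConfig:
    return cfg.phantom


def _make_tensors(cfg: PipelineConfig, records) -> list[TensorCase]:
    segmenter = naive_segment if cfg.use_naive_segmentation else None
    return cases_to_tensors(records, cfg.preprocess, segmenter=segmenter)


def run_end_to_end(config: PipelineConfig) -> dict:
    """Execute the full phantom pipeline; returns the run summary dict."""
    out = Path(config.output_root) / config.run_id
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage_times = {}
    summary_path = out / "run_summary.json"

    def stage(name):
        d = out / name
        return d, d.joinpath(".done").exists()

    try:
        # ------------------------------------------------------------ cohort
        d, done = stage("cohort")
        t0 = time.time()
        train_records = generate_cohort_records(
            config.n_train_cases, config.class_mix, _phantom_for(config),
            seed=derive_seed(config.master_seed, "cohort-train"))
        test_records = generate_cohort_records(
            config.n_test_cases, config.class_mix, _phantom_for(config),
            seed=derive_seed(config.master_seed, "cohort-test"))
        for r in test_records:
            r.case_id = "test-" + r.case_id
        if not done:
            d.mkdir(exist_ok=True)
            rows = [{"case_id": r.case_id, "split": split, "y_anomaly": r.y_anomaly,
                     "y_origin": r.y_origin or "", "y_risk": r.y_risk or "",
                     "sex": r.group.get("sex", "")}
                    for split, recs in (("train", train_records), ("test", test_records))
                    for r in recs]
            pd.DataFrame(rows).to_csv(d / "manifest.csv", index=False)
            (d / ".done").touch()
        stage_times["cohort"] = time.time() - t0

        # ----------------------------------------------------------- tensors
        d, done = stage("tensors")
        t0 = time.time()
        if done:
            cached = np.load(d / "tensors.npz", allow_pickle=True)
            train_cases = list(cached["train"])
            test_cases = list(cached["test"])
        else:
            train_cases = _make_tensors(config, train_records)
            test_cases = _make_tensors(config, test_records)
            d.mkdir(exist_ok=True)
            np.savez_compressed(d / "tensors.npz",
                                train=np.asarray(train_cases, dtype=object),
                                test=np.asarray(test_cases, dtype=object))
            (d / ".done").touch()
        stage_times["tensors"] = time.time() - t0

        # ------------------------------------------------------------- train
        d, done = stage("train")
        t0 = time.time()
        trained = {}
        if done:
            for task in config.tasks:
                members = [load_checkpoint(p) for p in sorted(d.glob(f"{task}_member*.npz"))]
                trained[task] = dataclasses.replace(
                    _empty_trained(task, config), members=members)
        else:
            d.mkdir(exist_ok=True)
            tcfg = dataclasses.replace(config.train,
                                       seed=derive_seed(config.master_seed, "train"))
            anomaly = None
            for task in config.tasks:
                if task == "anomaly" or anomaly is None:
                    trained[task] = train_task(train_cases, task, config.network, tcfg)
                    if task == "anomaly":
                        anomaly = trained[task].members[0]
                else:
                    trained[task] = fine_tune(anomaly, train_cases, task, config.network, tcfg)
                for m, model in enumerate(trained[task].members):
                    save_checkpoint(model, d / f"{task}_member{m}.npz")
                for m, hist in enumerate(trained[task].histories):
                    hist.to_csv(d / f"{task}_member{m}_history.csv", index=False)
            (d / ".done").touch()
        stage_times["train"] = time.time() - t0

        # ----------------------------------------------------------- predict
        d, done = stage("predict")
        t0 = time.time()
        preds = {}
        if done:
            for task in config.tasks:
                preds[task] = pd.read_csv(d / f"{task}_predictions.csv")
        else:
            d.mkdir(exist_ok=True)
            for task in config.tasks:
                cases = test_cases if task == "anomaly" else [
                    c for c in test_cases if c.y_anomaly == 1]
                preds[task] = predict_cases(trained[task], cases)
                preds[task].to_csv(d / f"{task}_predictions.csv", index=False)
            (d / ".done").touch()
        stage_times["predict"] = time.time() - t0

        # ---------------------------------------------------------- evaluate
        d, done = stage("evaluate")
        t0 = time.time()
        d.mkdir(exist_ok=True)
        metrics = {}
        for task in config.tasks:
            df = preds[task]
            metrics[task] = metrics_report(df["ensemble_prob"], df["y_true"],
                                           cutoff=config.cutoff, n_boot=config.n_boot,
                                           seed=derive_seed(config.master_seed, "boot"))
            cutoff_sweep(df["ensemble_prob"], df["y_true"]).to_csv(
                d / f"{task}_cutoff_sweep.csv", index=False)
            if 0 < int(df["y_true"].sum()) < len(df):
                from .plots import save_confusion_plot, save_roc_plot
                save_roc_plot(df["ensemble_prob"], df["y_true"], d / f"{task}_roc.png",
                              n_boot=min(config.n_boot, 200),
                              seed=derive_seed(config.master_seed, "boot"), title=task)
                save_confusion_plot(df["ensemble_prob"], df["y_true"],
                                    d / f"{task}_confusion.png", cutoff=config.cutoff)
        (d / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))
        (d / ".done").touch()
        stage_times["evaluate"] = time.time() - t0
    except Exception as exc:  # persist partial logs, then re-raise with stage name
        failed = [s for s in ("cohort", "tensors", "train", "predict", "evaluate")
                  if s not in stage_times]
        summary = {"status": "failed", "failed_stage": failed[0] if failed else "unknown",
                   "error": str(exc), "stage_times_s": stage_times}
        summary_path.write_text(json.dumps(summary, indent=2))
        raise RuntimeError(f"pipeline failed in stage {failed[0] if failed else '?'}: {exc}") from exc

    summary = {
        "status": "ok",
        "run_id": config.run_id,
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "stage_seeds": {s: derive_seed(config.master_seed, s)
                        for s in ("cohort-train", "cohort-test", "train", "boot")},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stage_times_s": {k: round(v, 2) for k, v in stage_times.items()},
        "wall_time_s": round(time.time() - t_start, 2),
        "metrics": metrics,
    }
    summary_path.write_text(json.dumps(summary, indent=2, default=float))
    return summary


def _empty_trained(task, config):
    from .model import TrainedTask
    return TrainedTask(task, [], [], [], [], config.network, config.train)


def run_screening(cases, trained: dict, cutoff: float = 0.5,
                  phase_aggregate: str = "mean") -> pd.DataFrame:
    """Cascaded screening report for a cohort.

    Every case gets an anomaly probability; cases flagged at the cutoff
    (ensemble probability >= cutoff) additionally get origin and risk
    probabilities from the cascade heads, and the report is ranked by
    anomaly probability as a human review list.
    """
    if "anomaly" not in trained or not trained["anomaly"].members:
        raise ValueError("screening requires trained anomaly checkpoints")
    rows = []
    for case in cases:
        ps = predict_case(trained["anomaly"].members, case, "anomaly", phase_aggregate)
        row = {"case_id": case.case_id, "anomaly_prob": ps.ensemble_prob,
               "flagged": ps.ensemble_prob >= cutoff,
               "origin_prob": np.nan, "risk_prob": np.nan}
        if row["flagged"]:
            for task in ("origin", "risk"):
                if task in trained and trained[task].members:
                    row[f"{task}_prob"] = predict_case(
                        trained[task].members, case, task, phase_aggregate).ensemble_prob
                else:
                    raise ValueError(f"missing checkpoint for requested task {task!r}")
        rows.append(row)
    report = pd.DataFrame(rows).sort_values("anomaly_prob", ascending=False)
    return report.reset_index(drop=True)
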