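"""End-to-end orchestration: simulate/load -> pretreat -> select -> fit -> validate.

A RunConfig (flat YAML) drives the whole pipeline; a master seed
deterministically derives every stage seed, so reruns with the same config
reproduce all stochastic outputs bit for bit.  Each run writes its
artifacts plus a manifest (config echo, version, stage seeds, timings,
file checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ann import ANNConfig, multi_restart, select_architecture
from .dataset_io import (
    DatasetError,
    load_descriptor_table,
    make_partition,
    write_table,
)
from .ga import GAConfig, ga_select
from .latent_models import choose_sigma, fit_kpls, fit_pls
from .pretreatment import pretreat
from .synthetic import SyntheticSpec, generate
from .validation import evaluate_model, lgo_cv

log = logging.getLogger("qsrr")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "compare_models", "derive_seed"]


def derive_seed(master: int, stage: str, index: int = 0) -> int:
    """Independent per-stage seed stream from the master seed."""
    h = hashlib.blake2b(f"{master}:{stage}:{index}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31)


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run (YAML round-trippable)."""

    # data source: either a CSV path or a synthetic spec
    dataset_path: str | None = None
    response_column: str = "rt_min"
    id_column: str = "id"
    synthetic: dict[str, Any] | None = None      # SyntheticSpec kwargs

    # pretreatment
    r_threshold: float = 0.90
    near_constant_fraction: float = 0.95

    # selection
    run_ga: bool = True
    ga: dict[str, Any] = field(default_factory=dict)     # GAConfig overrides

    # model
    model: str = "pls"             # pls | kpls | ann
    n_lv: int = 4
    sigma: float | None = None     # kpls; None -> CV over the multiplier grid
    ann: dict[str, Any] = field(default_factory=dict)    # ANNConfig overrides
    scan_hidden: bool = False
    hidden: int = 4

    # validation
    partition_scheme: str = "fixed_80_20"
    lgo_group_size: int = 7

    master_seed: int = 0
    out_dir: str = "qsrr_run"

    def validate(self) -> None:
        if self.model not in ("pls", "kpls", "ann"):
            raise DatasetError(f"unknown model: {self.model!r}")
        if (self.dataset_path is None) == (self.synthetic is None):
            raise DatasetError("exactly one of dataset_path / synthetic must be set")
        if self.partition_scheme not in ("fixed_80_20", "stratified_70_15_15"):
            raise DatasetError(f"unknown partition scheme: {self.partition_scheme!r}")
        if self.model == "ann" and self.partition_scheme != "stratified_70_15_15":
            raise DatasetError("the ann model requires the stratified_70_15_15 scheme")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DatasetError(f"invalid config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class RunManifest:
    config: dict[str, Any]
    version: str
    stage_seeds: dict[str, int]
    timings: dict[str, float]
    files: dict[str, str]          # name -> sha256

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_fn_for(config: RunConfig, n_lv: int, sigma: float | None):
    if config.model == "pls":
        return lambda X, y: fit_pls(X, y, min(n_lv, X.shape[1], X.shape[0] - 1))
    if config.model == "kpls":
        return lambda X, y: fit_kpls(X, y, sigma, min(n_lv, X.shape[0] - 1))
    raise DatasetError("lgo_cv fit function undefined for ann")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order, writing artifacts and a manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        s: derive_seed(config.master_seed, s)
        for s in ("simulate", "partition", "select", "fit", "validate")
    }
    timings: dict[str, float] = {}
    files: dict[str, Path] = {}

    def stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    def done(name, t0):
        timings[name] = round(time.perf_counter() - t0, 4)

    # --- data ---------------------------------------------------------
    t0 = stage("data")
    if config.synthetic is not None:
        spec = SyntheticSpec(**{**config.synthetic, "seed": seeds["simulate"]})
        ds = generate(spec)
        table = ds.table
        write_table(table, out / "dataset.csv",
                    response_column=config.response_column, id_column=config.id_column)
        truth = pd.DataFrame(
            {
                "descriptor_name": table.descriptor_names,
                "is_true": ds.true_mask.astype(int),
                "coefficient": [
                    (ds.true_coefficients[list(np.flatnonzero(ds.true_mask)).index(j)]
                     if ds.true_mask[j] else 0.0)
                    for j in range(table.k)
                ],
            }
        )
        truth.to_csv(out / "truth.csv", index=False, float_format="%.17g")
        files["truth.csv"] = out / "truth.csv"
    else:
        table = load_descriptor_table(
            config.dataset_path, config.response_column, config.id_column
        )
        write_table(table, out / "dataset.csv",
                    response_column=config.response_column, id_column=config.id_column)
    files["dataset.csv"] = out / "dataset.csv"
    done("data", t0)

    # --- partition (before pretreat so the correlation filter sees train only)
    t0 = stage("partition")
    part = make_partition(table, config.partition_scheme, seed=seeds["partition"])
    done("partition", t0)

    # --- pretreat -----------------------------------------------------
    t0 = stage("pretreat")
    labels = np.full(table.n, "test", dtype=object)
    labels[part.train_idx] = "train"
    labels[part.val_idx] = "val"
    labeled = dataclasses.replace(table, partition_labels=labels)
    reduced, report = pretreat(
        labeled, config.r_threshold, config.near_constant_fraction
    )
    rep_rows = (
        [{"descriptor": d, "action": "removed_constant", "partner": "", "r": ""}
         for d in report.removed_constant]
        + [{"descriptor": d, "action": "removed_near_constant", "partner": "", "r": ""}
           for d in report.removed_near_constant]
        + [{"descriptor": d, "action": "removed_correlated", "partner": kept, "r": f"{r:.6f}"}
           for kept, d, r in report.removed_correlated]
        + [{"descriptor": d, "action": "kept", "partner": "", "r": ""}
           for d in report.surviving]
    )
    pd.DataFrame(rep_rows).to_csv(out / "pretreat_report.csv", index=False)
    files["pretreat_report.csv"] = out / "pretreat_report.csv"
    done("pretreat", t0)

    # --- GA selection on training rows --------------------------------
    t0 = stage("select")
    train_rows = np.concatenate([part.train_idx, part.val_idx]).astype(int)
    train_rows.sort()
    X_sel = reduced.values[train_rows]
    y_sel = reduced.response[train_rows]
    if config.run_ga:
        ga_cfg = GAConfig(**{**config.ga, "seed": seeds["select"],
                             "estimator": "kpls" if config.model == "kpls" else "pls"})
        report_ga = ga_select(X_sel, y_sel, ga_cfg, reduced.descriptor_names)
        selected = [
            d for d, m in zip(reduced.descriptor_names, report_ga.final_mask) if m
        ]
        report_ga.selection_frequency.to_csv(
            out / "consensus.csv", index=False, float_format="%.17g"
        )
        (out / "consensus.json").write_text(
            json.dumps(
                {
                    "final_descriptors": selected,
                    "final_cv_fitness": report_ga.final_cv_fitness,
                    "n_runs": len(report_ga.per_run),
                },
                indent=2,
                sort_keys=True,
            )
        )
        files["consensus.csv"] = out / "consensus.csv"
        files["consensus.json"] = out / "consensus.json"
    else:
        selected = reduced.descriptor_names
    model_table = reduced.select_columns(selected)
    done("select", t0)

    # --- fit ----------------------------------------------------------
    t0 = stage("fit")
    Xtr = model_table.values[train_rows]
    ytr = model_table.response[train_rows]
    sigma = config.sigma
    if config.model == "pls":
        n_lv = min(config.n_lv, Xtr.shape[1], Xtr.shape[0] - 1)
        model = fit_pls(Xtr, ytr, n_lv, descriptor_names=selected)
        summary = {
            "model": "pls",
            "n_lv": n_lv,
            "descriptors": selected,
            "coefficients": model.coefficients.tolist(),
            "intercept": model.intercept,
        }
    elif config.model == "kpls":
        n_lv = min(config.n_lv, Xtr.shape[0] - 1)
        if sigma is None:
            sigma = choose_sigma(Xtr, ytr, n_lv=n_lv, seed=seeds["fit"])
        model = fit_kpls(Xtr, ytr, sigma, n_lv, descriptor_names=selected)
        summary = {
            "model": "kpls",
            "n_lv": n_lv,
            "sigma": sigma,
            "descriptors": selected,
        }
    else:
        ann_cfg = ANNConfig(**{**config.ann, "seed": seeds["fit"]})
        Xv = model_table.values[part.val_idx]
        yv = model_table.response[part.val_idx]
        Xt = model_table.values[part.train_idx]
        yt = model_table.response[part.train_idx]
        hidden = config.hidden
        if config.scan_hidden:
            hidden, scan_tbl = select_architecture(Xt, yt, Xv, yv, ann_cfg)
            scan_tbl.to_csv(out / "hidden_scan.csv", index=False, float_format="%.17g")
            files["hidden_scan.csv"] = out / "hidden_scan.csv"
        model, restarts = multi_restart(Xt, yt, Xv, yv, hidden, ann_cfg)
        restarts.to_csv(out / "restarts.csv", index=False, float_format="%.17g")
        files["restarts.csv"] = out / "restarts.csv"
        summary = {
            "model": "ann",
            "hidden": hidden,
            "descriptors": selected,
            "input_weights": model.input_weights.tolist(),
            "output_weights": model.output_weights.tolist(),
            "n_parameters": model.n_parameters,
        }
    (out / "model.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    files["model.json"] = out / "model.json"
    done("fit", t0)

    # --- validate -----------------------------------------------------
    t0 = stage("validate")
    # lgo/metrics use the fit partition; ann validates on its external test set
    eval_part = part
    m_train, m_test, residuals = evaluate_model(model, model_table, eval_part)
    metric_rows = [{"partition": "train", **m_train.as_dict()}]
    if m_test is not None:
        metric_rows.append({"partition": "test", **m_test.as_dict()})
    if config.model != "ann" and len(train_rows) >= 2 * config.lgo_group_size:
        cv = lgo_cv(
            Xtr,
            ytr,
            _fit_fn_for(config, config.n_lv, sigma),
            group_size=config.lgo_group_size,
            seed=seeds["validate"],
        )
        metric_rows.append(
            {"partition": "lgo_cv", "n": len(ytr), "p": len(selected),
             "r2": cv.q2, "adj_r2": float("nan"), "rmse": cv.rmsecv,
             "se": float("nan"), "mse": cv.rmsecv**2, "pearson_r": float("nan")}
        )
    pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False,
                                     float_format="%.17g")
    residuals.to_csv(out / "residuals.csv", index=False, float_format="%.17g")
    files["metrics.csv"] = out / "metrics.csv"
    files["residuals.csv"] = out / "residuals.csv"
    done("validate", t0)

    config.to_yaml(out / "config.yaml")
    files["config.yaml"] = out / "config.yaml"
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        stage_seeds=seeds,
        timings=timings,
        files={name: _sha256(p) for name, p in sorted(files.items())},
    )
    manifest.write(out / "manifest.json")
    return manifest


def compare_models(manifests: list[RunManifest | str | Path]) -> pd.DataFrame:
    """Side-by-side metric table for >= 2 runs on the same dataset.

    Rows are ordered by test RMSE (best first).  Raises when the runs were
    not computed on the identical dataset file.
    """
    loaded: list[tuple[RunManifest, Path]] = []
    for m in manifests:
        if isinstance(m, (str, Path)):
            p = Path(m)
            loaded.append((RunManifest.read(p), p.parent))
        else:
            loaded.append((m, Path(m.config["out_dir"])))
    if len(loaded) < 2:
        raise DatasetError("compare_models requires at least 2 manifests")
    checks = {m.files.get("dataset.csv") for m, _ in loaded}
    if len(checks) != 1:
        raise DatasetError("manifests refer to different datasets")
    rows = []
    for m, run_dir in loaded:
        metrics = pd.read_csv(run_dir / "metrics.csv")
        row: dict[str, Any] = {"model": m.config["model"], "run_dir": str(run_dir)}
        for _, r in metrics.iterrows():
            for col in ("r2", "adj_r2", "rmse", "se", "mse", "pearson_r"):
                row[f"{r['partition']}_{col}"] = r[col]
        rows.append(row)
    df = pd.DataFrame(rows)
    if "test_rmse" in df.columns:
        df = df.sort_values("test_rmse", kind="stable").reset_index(drop=True)
    return df
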