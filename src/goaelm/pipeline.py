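"""Top-level experiments, configuration schema, and artifact handling.

Two experiments are exposed:

* :func:`run_benchmark_validation` — the optimizer validation protocol:
  GOA and AGOA each run repeatedly (default 35 seeded trials, population
  50, 100 iterations) on the five benchmark functions, summarized in a
  mean/std comparison table with per-run convergence histories on disk.
* :func:`run_diagnosis_experiment` — the end-to-end synthetic diagnosis:
  generate (or load) a labeled image set, preprocess and extract
  convolutional features, split 80/20 stratified, tune an ELM's hidden
  layer with AGOA on the training split, and report test-set confusion
  metrics alongside a plain random-weight ELM baseline on the same split.

Every experiment directory receives the resolved configuration, the seed,
and outputs sufficient to rerun bit-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .benchmarks import FUNCTION_NAMES, get_benchmark, run_trials, summarize_table
from .elm import (
    ELMModel,
    TrainingSet,
    predict,
    save_model,
    train_elm_agoa,
    train_elm_random,
)
from .features import ConvFeatureExtractor, extract_feature_matrix
from .metrics import MetricsReport, confusion_counts, metric_report
from .optimizers import OptimizerConfig, agoa_config, goa_config
from .synthdata import ImageDatasetSpec, generate_synthetic_images, split_dataset

logger = logging.getLogger("goaelm")

__all__ = [
    "ExperimentConfig",
    "OptimizerSettings",
    "ElmSettings",
    "BenchSettings",
    "SynthSettings",
    "load_config",
    "run_benchmark_validation",
    "run_diagnosis_experiment",
    "standardize_features",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OptimizerSettings(_StrictModel):
    population_size: int = 50
    max_iterations: int = 100
    c_max: float = 1.0
    c_min: float = 0.01
    attraction_intensity: float = 0.5
    attraction_length_scale: float = 1.5

    def to_config(self, variant: str, seed: int) -> OptimizerConfig:
        factory = {"goa": goa_config, "agoa": agoa_config}[variant]
        return factory(
            population_size=self.population_size,
            max_iterations=self.max_iterations,
            c_max=self.c_max,
            c_min=self.c_min,
            attraction_intensity=self.attraction_intensity,
            attraction_length_scale=self.attraction_length_scale,
            rng_seed=seed,
        )


class ElmSettings(_StrictModel):
    # hidden_count and the swarm sizes are desk-scale defaults for the
    # high-dimensional feature space; see docs/methods.md
    hidden_count: int = 20
    activation: str = "sigmoid"
    weight_bound: float = 1.0
    population_size: int = 10
    max_iterations: int = 20


class BenchSettings(_StrictModel):
    functions: list[str] = Field(default_factory=lambda: list(FUNCTION_NAMES))
    optimizers: list[str] = Field(default_factory=lambda: ["goa", "agoa"])
    dimension: int = 30
    n_runs: int = 35


class SynthSettings(_StrictModel):
    n_images: int = 200
    tumor_fraction: float = 0.5
    blob_intensity_lift: float = 0.45
    noise_sd: float = 0.02


class ExperimentConfig(_StrictModel):
    mode: str = "diagnose"  # bench | diagnose | synth
    seed: int = 0
    output_dir: str = "runs/experiment"
    train_fraction: float = 0.8
    image_manifest: Optional[str] = None
    feature_csv: Optional[str] = None
    optimizer: OptimizerSettings = Field(default_factory=OptimizerSettings)
    elm: ElmSettings = Field(default_factory=ElmSettings)
    bench: BenchSettings = Field(default_factory=BenchSettings)
    synth: SynthSettings = Field(default_factory=SynthSettings)


def load_config(path: Union[str, Path]) -> ExperimentConfig:
    """Parse, default, and schema-validate a YAML config file.

    An empty file yields the all-defaults configuration; unknown keys are
    rejected by name.
    """
    raw = yaml.safe_load(Path(path).read_text())
    return ExperimentConfig.model_validate(raw or {})


def _write_resolved(config: ExperimentConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.model_dump())
    )


def run_benchmark_validation(
    config: ExperimentConfig, out_dir: Optional[Union[str, Path]] = None
) -> pd.DataFrame:
    """Repeated-trial optimizer comparison; returns the summary table."""
    out = Path(out_dir) if out_dir is not None else Path(config.output_dir)
    _write_resolved(config, out)
    histories_dir = out / "convergence"
    histories_dir.mkdir(exist_ok=True)

    summaries = []
    for fname in config.bench.functions:
        function = get_benchmark(fname, config.bench.dimension)
        for opt in config.bench.optimizers:
            cfg = config.optimizer.to_config(opt, seed=config.seed)

            def dump_history(seed, result, fname=fname, opt=opt):
                df = pd.DataFrame(
                    {
                        "iteration": np.arange(result.convergence_history.size),
                        "best_fitness": result.convergence_history,
                    }
                )
                df.to_csv(histories_dir / f"{fname}_{opt}_seed{seed}.csv", index=False)

            summary = run_trials(
                opt,
                function,
                n_runs=config.bench.n_runs,
                config=cfg,
                seed_base=config.seed,
                run_hook=dump_history,
            )
            logger.info(
                "bench %s/%s: ave=%.3e std=%.3e",
                fname, opt, summary.mean_best, summary.std_best,
            )
            summaries.append(summary)
    table = summarize_table(summaries)
    table.to_csv(out / "comparison_table.csv", index=False)
    return table


def standardize_features(
    train: np.ndarray, test: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Z-score with train statistics, then scale by 1/sqrt(d).

    The 1/sqrt(d) factor keeps hidden pre-activations w.x + b at O(1) for
    weights drawn from the unit box, so sigmoid units stay responsive.
    """
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    scale = np.sqrt(train.shape[1])
    return (train - mu) / sd / scale, (test - mu) / sd / scale


def run_diagnosis_experiment(
    config: ExperimentConfig, out_dir: Optional[Union[str, Path]] = None
) -> dict:
    """Full synthetic-diagnosis pipeline; returns a result dictionary with
    the AGOA-ELM test report, the plain-ELM baseline report, and paths of
    the artifacts written (model, predictions CSV, metrics JSON)."""
    out = Path(out_dir) if out_dir is not None else Path(config.output_dir)
    _write_resolved(config, out)

    if config.feature_csv is not None:
        df = pd.read_csv(config.feature_csv)
        X = df.iloc[:, :-1].to_numpy(dtype=float)
        y = df.iloc[:, -1].to_numpy(dtype=int)
    else:
        if config.image_manifest is not None:
            manifest = pd.read_csv(config.image_manifest)
            root = Path(config.image_manifest).parent
        else:
            spec = ImageDatasetSpec(
                n_images=config.synth.n_images,
                tumor_fraction=config.synth.tumor_fraction,
                blob_intensity_lift=config.synth.blob_intensity_lift,
                noise_sd=config.synth.noise_sd,
                seed=config.seed,
            )
            root = out / "images"
            manifest = generate_synthetic_images(spec, root)
        extractor = ConvFeatureExtractor(seed=config.seed)
        X, y = extract_feature_matrix(manifest, extractor, image_root=root)

    if len(np.unique(y)) < 2:
        raise ValueError("diagnosis experiment needs two classes present")

    frame = pd.DataFrame({"filepath": [str(i) for i in range(len(y))], "label": y})
    frame["row"] = np.arange(len(y))
    train_idx, test_idx = split_dataset(
        frame, train_fraction=config.train_fraction, seed=config.seed
    )
    Xtr, Xte = X[train_idx["row"]], X[test_idx["row"]]
    ytr, yte = y[train_idx["row"].to_numpy()], y[test_idx["row"].to_numpy()]
    if len(np.unique(ytr)) < 2:
        raise ValueError("training split ended up single-class")
    Xtr, Xte = standardize_features(Xtr, Xte)

    training = TrainingSet.from_class_labels(Xtr, ytr)
    opt_cfg = agoa_config(
        population_size=config.elm.population_size,
        max_iterations=config.elm.max_iterations,
        rng_seed=config.seed,
    )
    model, result = train_elm_agoa(
        training,
        hidden_count=config.elm.hidden_count,
        activation=config.elm.activation,
        weight_bound=config.elm.weight_bound,
        optimizer_config=opt_cfg,
    )
    pred, _ = predict(model, Xte)
    report = metric_report(confusion_counts(yte, pred))

    baseline = train_elm_random(
        training,
        hidden_count=config.elm.hidden_count,
        activation=config.elm.activation,
        weight_bound=config.elm.weight_bound,
        seed=config.seed,
    )
    base_pred, _ = predict(baseline, Xte)
    base_report = metric_report(confusion_counts(yte, base_pred))

    save_model(model, out / "model")
    pd.DataFrame(
        {"index": test_idx["row"], "true": yte, "predicted": pred}
    ).to_csv(out / "predictions.csv", index=False)
    report.to_json(out / "metrics.json")
    base_report.to_json(out / "metrics_baseline.json")
    logger.info(
        "diagnosis: accuracy=%.3f (baseline %.3f), training SSE=%.4f",
        report.accuracy, base_report.accuracy, result.best_fitness,
    )
    return {
        "report": report,
        "baseline_report": base_report,
        "model": model,
        "optimization": result,
        "n_train": len(ytr),
        "n_test": len(yte),
        "output_dir": out,
    }
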