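"""End-to-end comparison protocols on phantom data.

These reproduce, at configurable scale, the study's three experiment shapes:
the two-method quality comparison (mean +/- std PSNR/SSIM per direction with a
paired signed-rank test), the dataset-size robustness sweep, and the
parameter/time-economy bookkeeping of the two architectures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import MetricConfig, MetricTable, combine_tables, evaluate, \
    paired_signed_rank
from .networks import GeneratorConfig, build_discriminator
from .phantom import DatasetManifest, subsample_manifest
from .trainer import TrainConfig, TrainResult, build_model, train


def train_model(manifest: DatasetManifest, kind: str,
                gen_config: GeneratorConfig | None = None,
                train_config: TrainConfig | None = None,
                disc_base_channels: int | None = None) -> TrainResult:
    """Build a model of the given kind plus both discriminators and train."""
    gen_config = gen_config or GeneratorConfig()
    train_config = train_config or TrainConfig()
    if disc_base_channels is None:
        disc_base_channels = gen_config.base_channels
    model = build_model(kind, gen_config, seed=train_config.seed)
    d_a = build_discriminator(seed=train_config.seed + 1,
                              base_channels=disc_base_channels)
    d_b = build_discriminator(seed=train_config.seed + 2,
                              base_channels=disc_base_channels)
    return train(manifest, model, d_a, d_b, train_config)


def synthesis_pairs(model, manifest: DatasetManifest, split: str = "test",
                    max_pairs: int | None = None) -> dict:
    """(synthesized, registered target) pairs for both directions."""
    pairs = manifest.paired_slices(split)
    if max_pairs is not None:
        pairs = pairs[:max_pairs]
    if not pairs:
        raise ValueError(f"no registered pairs in split {split!r}")
    return {
        "a2b": [(model.a2b(a), b) for a, b in pairs],
        "b2a": [(model.b2a(b), a) for a, b in pairs],
    }


def identity_baseline_pairs(manifest: DatasetManifest, split: str = "test",
                            max_pairs: int | None = None) -> dict:
    """Input-as-prediction baseline: score the source against the target."""
    pairs = manifest.paired_slices(split)
    if max_pairs is not None:
        pairs = pairs[:max_pairs]
    return {
        "a2b": [(a, b) for a, b in pairs],
        "b2a": [(b, a) for a, b in pairs],
    }


def evaluate_model(model, manifest: DatasetManifest, split: str = "test",
                   metric_config: MetricConfig = MetricConfig(),
                   max_pairs: int | None = None,
                   method: str | None = None) -> MetricTable:
    pairs = synthesis_pairs(model, manifest, split, max_pairs)
    return evaluate(pairs, metric_config, method=method or model.kind)


def compare_methods(table: MetricTable, method_a: str, method_b: str) -> pd.DataFrame:
    """Two-sided signed-rank p-values per direction and metric."""
    rows = []
    for direction in sorted(table.records.direction.unique()):
        for metric in ("psnr", "ssim"):
            a = table.per_image(method_a, direction, metric)
            b = table.per_image(method_b, direction, metric)
            rows.append({
                "direction": direction, "metric": metric,
                "method_a": method_a, "method_b": method_b,
                "p_value": paired_signed_rank(a, b),
            })
    return pd.DataFrame(rows)


@dataclass
class BenchmarkResult:
    table: MetricTable
    pvalues: pd.DataFrame
    results: dict  # kind -> TrainResult


def benchmark(manifest: DatasetManifest,
              gen_config: GeneratorConfig | None = None,
              train_config: TrainConfig | None = None,
              kinds=("cyclegan", "switchable"),
              metric_config: MetricConfig = MetricConfig(),
              max_pairs: int | None = None) -> BenchmarkResult:
    """Train every model kind on the same data and tabulate PSNR/SSIM."""
    tables, results = [], {}
    for kind in kinds:
        res = train_model(manifest, kind, gen_config, train_config)
        results[kind] = res
        tables.append(evaluate_model(res.model, manifest, "test",
                                     metric_config, max_pairs))
    table = combine_tables(tables)
    pvalues = (compare_methods(table, kinds[0], kinds[1])
               if len(kinds) == 2 else pd.DataFrame())
    return BenchmarkResult(table=table, pvalues=pvalues, results=results)


def robustness_experiment(manifest: DatasetManifest, sizes,
                          gen_config: GeneratorConfig | None = None,
                          train_config: TrainConfig | None = None,
                          kinds=("cyclegan", "switchable"),
                          metric_config: MetricConfig = MetricConfig(),
                          max_pairs: int | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """Dataset-size sweep: retrain each model kind on subsampled training
    sets (test set untouched) and record SSIM per direction."""
    rows = []
    for size in sizes:
        sub = subsample_manifest(manifest, size, seed=seed)
        for kind in kinds:
            res = train_model(sub, kind, gen_config, train_config)
            table = evaluate_model(res.model, sub, "test", metric_config,
                                   max_pairs)
            for direction in ("a2b", "b2a"):
                ss = table.per_image(kind, direction, "ssim")
                rows.append({
                    "data_size": size, "method": kind, "direction": direction,
                    "ssim_mean": float(np.mean(ss)),
                    "ssim_std": float(np.std(ss)),
                    "n_records": len(ss),
                })
    return pd.DataFrame(rows)
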