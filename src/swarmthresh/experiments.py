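"""Benchmark harness: algorithm x threshold-count x seed sweeps.

Reproduces the evaluation protocol shape used for swarm-thresholding
studies: for each image, algorithm and number of thresholds k, the
optimizer is run ``n_runs`` times with seeds ``base_seed + run``; per-run
thresholds, objective values and quality metrics are logged row by row,
and summary tables report the mean and sample standard deviation
(n-1 denominator) per (algorithm, k).  Restricting ``algorithms`` to
{scso, woa, scsowoa} yields the ablation comparison of the hybrid against
its two components.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import MetricReport, correlation_diagnostics, fsim, psnr, ssim
from .optimizers import BASELINES, FitnessTrace, HybridConfig, run_baseline, run_scsowoa
from .otsu import Histogram, ThresholdSet, compute_histogram
from .segmentation import apply_thresholds
from .synthetic import fixture_suite

__all__ = ["ExperimentConfig", "run_algorithm", "evaluate_segmentation", "run_benchmark"]

ALGORITHMS = ("scsowoa",) + BASELINES


@dataclass(frozen=True)
class ExperimentConfig:
    """Sweep definition for the benchmark harness."""

    algorithms: tuple[str, ...] = ("scsowoa", "scso", "woa")
    k_values: tuple[int, ...] = (2, 4, 6, 8, 10, 12)
    n_runs: int = 10
    base_seed: int = 0
    optimizer: HybridConfig = field(default_factory=HybridConfig)
    input_dir: str | None = None  # None -> synthetic fixture suite
    compute_metrics: bool = True
    output_dir: str = "benchmark_out"

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for name in self.algorithms:
            if name not in ALGORITHMS:
                raise ValueError(f"unknown algorithm {name!r}")
        for k in self.k_values:
            if not 1 <= k <= 20:
                raise ValueError("k_values must lie in [1, 20]")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        opt = HybridConfig(**raw.pop("optimizer", {}))
        for key in ("algorithms", "k_values"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(optimizer=opt, **raw)


def run_algorithm(
    name: str, hist: Histogram, k: int, cfg: HybridConfig
) -> tuple[ThresholdSet, float, FitnessTrace]:
    """Dispatch to the hybrid or a named baseline."""
    if name == "scsowoa":
        return run_scsowoa(hist, k, cfg)
    return run_baseline(name, hist, k, cfg)


def evaluate_segmentation(
    image: np.ndarray, thresholds: ThresholdSet, with_correlations: bool = True
) -> MetricReport:
    """Segment an image with the given thresholds and score the result."""
    seg = apply_thresholds(image, thresholds)
    rec = seg.reconstruction
    report = MetricReport(
        psnr=psnr(image, rec), ssim=ssim(image, rec), fsim=fsim(image, rec)
    )
    if with_correlations:
        r, rho, nr, nrho = correlation_diagnostics(image, rec)
        report.pearson_r, report.spearman_rho = r, rho
        report.neighbor_pearson, report.neighbor_spearman = nr, nrho
    return report


def _load_images(cfg: ExperimentConfig) -> dict[str, np.ndarray]:
    if cfg.input_dir is None:
        suite = fixture_suite(seed=cfg.base_seed)
        return {name: rec["image"] for name, rec in suite.items()}
    from .segmentation import preprocess

    images = {}
    for path in sorted(Path(cfg.input_dir).iterdir()):
        if path.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg"):
            images[path.stem] = preprocess(path)
    if not images:
        raise FileNotFoundError(f"no raster images found in {cfg.input_dir}")
    return images


def run_benchmark(cfg: ExperimentConfig, write: bool = True) -> dict[str, pd.DataFrame]:
    """Execute the full sweep; returns raw rows and both summary tables.

    ``summary_pooled`` aggregates all (image, run) rows per (algorithm, k)
    jointly; ``summary_per_image`` averages per image first, then across
    images.  Failures of individual runs are logged and itemized, not
    fatal.
    """
    images = _load_images(cfg)
    rows, failures = [], []
    for image_id, image in images.items():
        hist = compute_histogram(image)
        for name in cfg.algorithms:
            for k in cfg.k_values:
                for run in range(cfg.n_runs):
                    seed = cfg.base_seed + run
                    t0 = time.perf_counter()
                    try:
                        ts, j, trace = run_algorithm(
                            name, hist, k, replace(cfg.optimizer, rng_seed=seed)
                        )
                    except Exception as exc:  # pragma: no cover - defensive
                        failures.append(
                            {"image": image_id, "algorithm": name, "k": k,
                             "seed": seed, "error": repr(exc)}
                        )
                        continue
                    elapsed = time.perf_counter() - t0
                    row = {
                        "image": image_id,
                        "algorithm": name,
                        "k": k,
                        "seed": seed,
                        "J": j,
                        "thresholds": " ".join(f"{v:.4f}" for v in ts.values),
                        "n_evals": trace.total_evaluations,
                        "wall_clock_s": elapsed,
                    }
                    if cfg.compute_metrics:
                        rep = evaluate_segmentation(image, ts, with_correlations=False)
                        row.update(psnr=rep.psnr, ssim=rep.ssim, fsim=rep.fsim)
                    rows.append(row)
    raw = pd.DataFrame(rows)
    metric_cols = [
        c for c in ("J", "psnr", "ssim", "fsim", "wall_clock_s") if c in raw.columns
    ]
    pooled = (
        raw.groupby(["algorithm", "k"])[metric_cols]
        .agg(["mean", "std"])
        .reset_index()
    )
    pooled.columns = ["_".join(c).rstrip("_") for c in pooled.columns]
    per_image = (
        raw.groupby(["algorithm", "k", "image"])[metric_cols]
        .mean()
        .groupby(["algorithm", "k"])
        .agg(["mean", "std"])
        .reset_index()
    )
    per_image.columns = ["_".join(c).rstrip("_") for c in per_image.columns]
    out = {
        "raw": raw,
        "summary_pooled": pooled,
        "summary_per_image": per_image,
        "failures": pd.DataFrame(failures),
    }
    if write:
        out_dir = Path(cfg.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for key, df in out.items():
            df.to_csv(out_dir / f"{key}.csv", index=False)
    return out
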