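"""Benchmark orchestration: the rate x correlation condition grid.

The benchmark sweeps a grid of firing rates {5, 10, 15} Hz and pairwise
correlation levels {0, 10, 20}% with several replicate recordings per
condition (five at full scale, 45 runs in total). Within a condition the
spike trains are held fixed across replicates while the templates and
unit positions are redrawn, which populates the template-similarity axis
without changing the collision structure of the spike trains.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import ConfigurationError, derive_seed
from . import collision_metrics as cm
from . import gt_compare
from .probe_templates import make_probe, synthesize_templates, cosine_similarity
from .recording import assemble_recording
from .ref_sorters import oracle_sorter, greedy_tm_sorter
from .spike_trains import generate_correlated

__all__ = ["BenchmarkConfig", "RunSpec", "enumerate_runs", "run_single", "run_grid",
           "aggregate_report"]

logger = logging.getLogger(__name__)

SORTERS = ("oracle", "greedy_tm")


@dataclass
class BenchmarkConfig:
    """Parameters of a benchmark grid.

    Defaults are a desk-scale profile (300 s, 2 replicates); the
    full-scale grid is 1800 s with 5 replicates per condition.
    """

    rates_hz: list[float] = field(default_factory=lambda: [5.0, 10.0, 15.0])
    correlations: list[float] = field(default_factory=lambda: [0.0, 0.1, 0.2])
    n_seeds: int = 2
    duration_s: float = 300.0
    n_units: int = 20
    n_channels: int = 32
    n_columns: int = 3
    pitch_x_um: float = 18.0
    pitch_y_um: float = 22.0
    sampling_rate_hz: float = 32000.0
    noise_sd_uv: float = 5.0
    refractory_ms: float = 4.0
    jitter_sd_ms: float = 0.5
    master_seed: int = 0
    output_dir: str = "benchmark_output"

    def __post_init__(self):
        if any(r <= 0 for r in self.rates_hz):
            raise ConfigurationError("all rates must be > 0")
        if any(not (0 <= c < 1) for c in self.correlations):
            raise ConfigurationError("correlations must be in [0, 1)")
        if self.n_seeds < 1:
            raise ConfigurationError("n_seeds must be >= 1")

    @classmethod
    def full_scale(cls, **overrides) -> "BenchmarkConfig":
        """The full benchmark grid: 3 rates x 3 correlations x 5 replicates,
        30-minute recordings."""
        params = dict(duration_s=1800.0, n_seeds=5)
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(f"bad config file: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass(frozen=True)
class RunSpec:
    """One cell of the grid: a (rate, correlation, replicate) triple with
    derived seeds."""

    rate_hz: float
    correlation: float
    replicate: int
    spike_seed: int      # fixed per condition: replicates share spike times
    template_seed: int   # varies per replicate: templates/positions redrawn
    noise_seed: int

    @property
    def name(self) -> str:
        return (f"rate{self.rate_hz:g}_corr{int(round(self.correlation * 100))}"
                f"_rep{self.replicate}")


def enumerate_runs(config: BenchmarkConfig) -> list[RunSpec]:
    """List every run of the grid without executing anything."""
    runs = []
    for rate in config.rates_hz:
        for corr in config.correlations:
            spike_seed = derive_seed(config.master_seed, "spikes", int(rate * 1000),
                                     int(corr * 1000))
            for rep in range(config.n_seeds):
                runs.append(RunSpec(
                    rate_hz=float(rate),
                    correlation=float(corr),
                    replicate=rep,
                    spike_seed=spike_seed,
                    template_seed=derive_seed(config.master_seed, "templates",
                                              int(rate * 1000), int(corr * 1000), rep),
                    noise_seed=derive_seed(config.master_seed, "noise",
                                           int(rate * 1000), int(corr * 1000), rep),
                ))
    return runs


def run_single(
    config: BenchmarkConfig,
    spec: RunSpec,
    sorter: str = "greedy_tm",
    out_dir: str | Path | None = None,
) -> dict:
    """Execute one grid cell end to end and return its summary.

    Generates templates, spike trains and traces, runs the requested
    built-in sorter, compares against ground truth, and computes the
    collision-recall and correlogram-error profiles. If ``out_dir`` is
    given, all outputs are written there.
    """
    if sorter not in SORTERS:
        raise ConfigurationError(f"unknown sorter {sorter!r}; choose from {SORTERS}")
    t_start = time.time()
    probe = make_probe(config.n_channels, config.n_columns,
                       config.pitch_x_um, config.pitch_y_um)
    templates = synthesize_templates(
        probe, n_units=config.n_units, seed=spec.template_seed,
        sampling_rate=config.sampling_rate_hz,
    )
    gt = generate_correlated(
        n_units=config.n_units, rate=spec.rate_hz, correlation=spec.correlation,
        jitter_sd_ms=config.jitter_sd_ms, duration=config.duration_s,
        refractory_ms=config.refractory_ms, seed=spec.spike_seed,
    )
    similarity = cosine_similarity(templates)

    if sorter == "oracle":
        sorting = oracle_sorter(gt)
    else:
        rec = assemble_recording(
            templates, gt, noise_sd=config.noise_sd_uv, seed=spec.noise_seed,
            probe=probe,
        )
        sorting = greedy_tm_sorter(rec, templates)

    match = gt_compare.compare_sorting(gt, sorting)
    events = cm.find_synchronous_events(gt)
    profiles = cm.collision_recall_by_lag(events, match)
    pooled = cm.pool_profiles_by_similarity(profiles, similarity)
    by_sim = cm.collision_recall_by_similarity(profiles, similarity)
    try:
        ccg_err = cm.correlogram_relative_error(
            gt, sorting, match.assignment, similarity, sim_threshold=0.5,
        )
    except ConfigurationError:
        ccg_err = None

    summary = {
        "run": spec.name,
        "rate_hz": spec.rate_hz,
        "correlation": spec.correlation,
        "replicate": spec.replicate,
        "sorter": sorter,
        "n_events": int(len(events)),
        "mean_accuracy": float(match.metrics["accuracy"].mean()),
        "mean_precision": float(match.metrics["precision"].mean()),
        "mean_recall": float(match.metrics["recall"].mean()),
        "unit_class_counts": pd.Series(match.unit_classes).value_counts().to_dict(),
        "elapsed_s": time.time() - t_start,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")
        (out_dir / "run_spec.json").write_text(json.dumps(asdict(spec), indent=2))
        gt.save(out_dir / "gt_spikes.csv")
        sorting.save(out_dir / "sorted_spikes.csv")
        (out_dir / "comparison.json").write_text(json.dumps(match.to_dict(), indent=2))
        match.spike_labels().to_csv(out_dir / "spike_labels.csv", index=False)
        pd.concat(
            [p.to_frame().assign(sim_lo=lo, sim_hi=hi)
             for (lo, hi), p in pooled.items()],
            ignore_index=True,
        ).to_csv(out_dir / "collision_recall_by_lag.csv", index=False)
        by_sim.to_csv(out_dir / "collision_recall_by_similarity.csv", index=False)
        if ccg_err is not None:
            ccg_err.to_frame().to_csv(out_dir / "ccg_relative_error.csv", index=False)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))

    summary["pooled_profiles"] = pooled
    summary["recall_by_similarity"] = by_sim
    summary["ccg_error"] = ccg_err
    return summary


def run_grid(
    config: BenchmarkConfig,
    sorter: str = "greedy_tm",
    dry_run: bool = False,
) -> pd.DataFrame:
    """Execute (or enumerate) the full grid.

    Returns one row per run. With ``dry_run`` the runs are only
    enumerated, nothing is simulated. Failures in individual runs are
    logged and the grid continues.
    """
    runs = enumerate_runs(config)
    base = Path(config.output_dir)
    rows = []
    for spec in runs:
        if dry_run:
            rows.append({"run": spec.name, "rate_hz": spec.rate_hz,
                         "correlation": spec.correlation,
                         "replicate": spec.replicate, "status": "planned"})
            continue
        try:
            summary = run_single(config, spec, sorter=sorter, out_dir=base / spec.name)
            rows.append({k: v for k, v in summary.items()
                         if k not in ("pooled_profiles", "recall_by_similarity",
                                      "ccg_error", "unit_class_counts")}
                        | {"status": "ok"})
        except Exception:
            logger.exception("run %s failed; continuing", spec.name)
            rows.append({"run": spec.name, "rate_hz": spec.rate_hz,
                         "correlation": spec.correlation,
                         "replicate": spec.replicate, "status": "failed"})
    df = pd.DataFrame(rows)
    if not dry_run:
        base.mkdir(parents=True, exist_ok=True)
        df.to_csv(base / "grid_summary.csv", index=False)
    return df


def aggregate_report(result_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Aggregate per-run outputs into cross-condition summary tables.

    Produces the mean and sample SD (ddof=1) of the collision-recall
    curves over runs, the mean unit metrics, and the average correlogram
    error curve over all runs; mirrors averaging the grid "over the nine
    conditions".
    """
    result_dir = Path(result_dir)
    run_dirs = sorted(d for d in result_dir.iterdir()
                      if d.is_dir() and (d / "summary.json").exists())
    if not run_dirs:
        raise ConfigurationError(f"no completed runs under {result_dir}")

    recall_frames, sim_frames, ccg_frames, summaries = [], [], [], []
    for d in run_dirs:
        summaries.append(json.loads((d / "summary.json").read_text()))
        f = d / "collision_recall_by_lag.csv"
        if f.exists():
            recall_frames.append(pd.read_csv(f).assign(run=d.name))
        f = d / "collision_recall_by_similarity.csv"
        if f.exists():
            sim_frames.append(pd.read_csv(f).assign(run=d.name))
        f = d / "ccg_relative_error.csv"
        if f.exists():
            ccg_frames.append(pd.read_csv(f).assign(run=d.name))

    out: dict[str, pd.DataFrame] = {}
    out["runs"] = pd.DataFrame(summaries)
    if recall_frames:
        lag = pd.concat(recall_frames, ignore_index=True)
        bins = {len(g["bin_center_ms"].unique()) for _, g in lag.groupby("run")}
        if len(bins) > 1:
            raise ConfigurationError("runs use different lag-bin configurations")
        out["collision_recall_by_lag"] = (
            lag.groupby(["sim_lo", "sim_hi", "bin_center_ms"])["recall"]
            .agg(mean="mean", sd=lambda s: s.std(ddof=1))
            .reset_index()
        )
    if sim_frames:
        sim = pd.concat(sim_frames, ignore_index=True)
        out["collision_recall_by_similarity"] = (
            sim.groupby(["sim_lo", "sim_hi"])["recall"]
            .agg(mean="mean", sd=lambda s: s.std(ddof=1))
            .reset_index()
        )
    if ccg_frames:
        ccg = pd.concat(ccg_frames, ignore_index=True)
        out["ccg_relative_error"] = (
            ccg.groupby("lag_ms")["mean_relative_error"]
            .agg(mean="mean", sd=lambda s: s.std(ddof=1))
            .reset_index()
        )
    for name, df in out.items():
        df.to_csv(result_dir / f"aggregate_{name}.csv", index=False)
    return out
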