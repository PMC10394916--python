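"""End-to-end orchestration: simulate/load -> train -> predict -> merge -> evaluate.

``run_pipeline`` drives every stage from a single config, writes all
artifacts (value table, raw and merged predictions, threshold sweep,
evaluation report, convergence history, density-value diagnostics) into a
run directory, and records a manifest sufficient for an exact re-run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

from . import network_io
from .evaluation import evaluate_all
from .network_io import ComplexCollection, WeightedNetwork
from .postprocess import default_threshold_grid, merge_candidates, sweep_thresholds
from .prediction import CandidateComplex, predict_all
from .state_value import ValueTable
from .synthetic import PlantedNetworkConfig, generate
from .training import TrainingConfig, TrainingHistory, train

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report_diagnostics"]


@dataclass
class PipelineConfig:
    out_dir: str
    network_path: str | None = None
    complexes_path: str | None = None
    simulate: PlantedNetworkConfig | None = None
    value_table_path: str | None = None  # transfer-learning mode
    training: TrainingConfig = field(default_factory=TrainingConfig)
    workers: int = 1
    max_size: int | None = 100
    thresholds: list[float] | None = None
    qi_tau: float = 0.25
    k_max: int = 10
    size_cap: int = 20
    min_size: int = 3
    jaccard_merge_threshold: float = 0.6

    def __post_init__(self) -> None:
        if self.simulate is None and (
            self.network_path is None or self.complexes_path is None
        ):
            raise ValueError(
                "either a simulation config or network+complex paths required"
            )

    def to_manifest(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _load_inputs(
    config: PipelineConfig, out: Path
) -> tuple[WeightedNetwork, ComplexCollection, ComplexCollection]:
    """Returns (network, known collection, training subset)."""
    if config.simulate is not None:
        net, known, split = generate(config.simulate)
        network_io.write_network(net, out / "network.tsv")
        network_io.write_complexes(known, out / "complexes.txt")
        (out / "train_complexes.txt").write_text(
            "\n".join(split.train_names) + "\n"
        )
        (out / "test_complexes.txt").write_text(
            "\n".join(split.test_names) + "\n"
        )
        training_subset = known.subset(split.train_names)
    else:
        net = network_io.read_network(config.network_path)
        known = network_io.read_complexes(config.complexes_path)
        training_subset = known
    return net, known, training_subset


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of artifact paths and summaries."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"out_dir": str(out)}

    def stage(name: str):
        logger.info("pipeline stage: %s", name)

    try:
        stage("inputs")
        net, known, training_subset = _load_inputs(config, out)

        stage("preprocess")
        known_clean = network_io.preprocess_complexes(
            known, net,
            min_size=config.min_size,
            jaccard_merge_threshold=config.jaccard_merge_threshold,
        )
        train_clean = network_io.preprocess_complexes(
            training_subset, net,
            min_size=config.min_size,
            jaccard_merge_threshold=config.jaccard_merge_threshold,
        )

        history: TrainingHistory | None = None
        if config.value_table_path is not None:
            stage("load value table (transfer mode)")
            table = network_io.load_value_table(config.value_table_path)
        else:
            stage("train")
            table, history = train(train_clean, net, config.training)
            bins_df, epochs_df, rho = report_diagnostics(history, table)
            bins_df.to_csv(out / "diagnostics.tsv", sep="\t", index=False)
            epochs_df.to_csv(out / "history.tsv", sep="\t", index=False)
            series_rows = [
                {"bin": b, "update": i, "value": v}
                for b, series in sorted(history.bin_series.items())
                for i, v in enumerate(series)
            ]
            pd.DataFrame(
                series_rows, columns=["bin", "update", "value"]
            ).to_csv(out / "value_series.tsv", sep="\t", index=False)
            artifacts["density_value_rank_correlation"] = rho
            artifacts["converged"] = history.converged
            artifacts["n_epochs"] = history.n_epochs
        network_io.save_value_table(table, out / "value_table.json")

        stage("predict")
        candidates = predict_all(
            net, table, workers=config.workers, max_size=config.max_size
        )
        network_io.write_predictions(candidates, out / "predictions_raw.txt")
        artifacts["n_raw_candidates"] = len(candidates)

        stage("sweep")
        thresholds = config.thresholds or default_threshold_grid()
        sweep = sweep_thresholds(candidates, known_clean, table, net, thresholds)
        pd.DataFrame(
            {"threshold": sweep.thresholds, "fmmf": sweep.fmmf_per_threshold}
        ).to_csv(out / "sweep.tsv", sep="\t", index=False)
        best_t = sweep.best_threshold
        artifacts["best_threshold"] = best_t

        stage("merge")
        merged = merge_candidates(candidates, best_t, table, net)
        network_io.write_predictions(merged, out / "predictions_merged.txt")
        artifacts["n_merged_candidates"] = len(merged)

        stage("evaluate")
        report = evaluate_all(
            [c.members for c in merged],
            known_clean,
            qi_tau=config.qi_tau,
            k_max=config.k_max,
            size_cap=config.size_cap,
            min_size=config.min_size,
        )
        report_dict = report.as_dict()
        with (out / "report.json").open("w") as fh:
            json.dump(report_dict, fh, indent=1)
            fh.write("\n")
        pd.DataFrame([report_dict]).to_csv(
            out / "report.tsv", sep="\t", index=False
        )
        artifacts["report"] = report_dict
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    stage("manifest")
    manifest = {"config": config.to_manifest(), "artifacts": artifacts}
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
        fh.write("\n")
    return artifacts


def report_diagnostics(
    history: TrainingHistory, table: ValueTable
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Tables behind the convergence and density-value diagnostics.

    Returns a per-bin frame (bin, density midpoint, final value, update
    count), a per-epoch frame of max absolute changes, and the Spearman
    rank correlation between bin density midpoints and final values.
    """
    mids = table.bin_midpoints
    bins_df = pd.DataFrame(
        {
            "bin": range(table.n_bins),
            "density_mid": mids,
            "value": table.values,
            "n_updates": [
                len(history.bin_series.get(b, [])) for b in range(table.n_bins)
            ],
        }
    )
    epochs_df = pd.DataFrame(
        {
            "epoch": range(1, len(history.epoch_max_change) + 1),
            "max_abs_change": history.epoch_max_change,
        }
    )
    if len(set(table.values.tolist())) < 2:
        rho = 0.0  # constant table: correlation undefined
    else:
        rho = float(spearmanr(mids, table.values).statistic)
    return bins_df, epochs_df, rho
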