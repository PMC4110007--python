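"""End-to-end pipeline: preprocess -> decompose -> features -> train ->
closed-loop evaluation, with a single seed feeding every random draw."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .closed_loop import AnnPolicy, SimulationConfig, evaluate_closed_loop
from .decompose import DecompositionConfig, decompose_dataset
from .features import build_training_tables
from .io import Dataset, load_dataset, preprocess_dataset
from .nets import TrainingConfig, crossval_evaluate, train_nets
from .synthetic import GeneratorConfig, generate_corpus


@dataclass
class RunConfig:
    """All stage configurations plus the master seed.

    Exactly one of ``input_csv`` (a recorded dataset) or ``generator``
    (synthetic corpus parameters) provides the input reaches.
    """

    seed: int = 0
    input_csv: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    decomposition: DecompositionConfig = field(default_factory=DecompositionConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str | None = None

    def __post_init__(self):
        # one master seed drives every stage
        self.generator.seed = self.seed
        self.decomposition.seed = self.seed
        self.training.seed = self.seed

    def to_dict(self) -> dict:
        return asdict(self)


class ConfigError(ValueError):
    pass


def _table2_report(cv: dict, cl: dict, decomps: dict, dataset: Dataset) -> dict:
    """Assemble the evaluation report with the standard metric names."""

    def _vaf(section, key):
        entry = cv[section].get(key)
        return entry["vaf"] if entry else float("nan")

    n_stars = np.array([d.n_star for d in decomps.values()])
    dists = np.array([tr.distance for tr in dataset.retained])
    return {
        "dataset": {
            "n_reaches": len(dataset.retained),
            "n_excluded": len(dataset.trials) - len(dataset.retained),
            "mean_start_target_distance_cm": float(dists.mean()),
            "sd_start_target_distance_cm": float(dists.std()),
        },
        "decomposition": {
            "mean_n_submovements": float(n_stars.mean()),
            "n_submovements_range": [int(n_stars.min()), int(n_stars.max())],
            "mean_recon_vaf": float(np.mean([d.recon_vaf for d in decomps.values()])),
        },
        "initiation_time_ann": {
            "vaf_2nd_submovement": _vaf("initiation", 2),
            "vaf_3rd_submovement": _vaf("initiation", 3),
            "vaf_overall": _vaf("initiation", "overall"),
            "sensitivity": cv["initiation"]["sensitivity"],
            "specificity": cv["initiation"]["specificity"],
        },
        "duration_ann": {
            "vaf_1st_submovement": _vaf("duration", 1),
            "vaf_2nd_submovement": _vaf("duration", 2),
            "vaf_3rd_submovement": _vaf("duration", 3),
            "vaf_overall": _vaf("duration", "overall"),
        },
        "amplitude_ann": {
            "vaf_1st_submovement": _vaf("amplitude", 1),
            "vaf_2nd_submovement": _vaf("amplitude", 2),
            "vaf_3rd_submovement": _vaf("amplitude", 3),
            "vaf_overall": _vaf("amplitude", "overall"),
        },
        "closed_loop_model": {
            "target_acquisition_rate": cl["target_acquisition_rate"],
            "dist_at_trajectory_end_cm": cl["end_distance_mean"],
            "dist_at_trajectory_end_sd_cm": cl["end_distance_sd"],
            "dist_at_failed_trajectory_end_cm": cl["end_distance_failed_mean"],
            "rmse_vs_actual_trajectory_cm": cl["trajectory_rmse"],
            "vaf_vs_actual_trajectory": cl["trajectory_vaf"],
            "mean_n_submovements": cl["mean_n_submovements"],
        },
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return (and optionally write) the
    artifacts: decompositions, cross-validation metrics, trained networks,
    closed-loop evaluation and the assembled report."""
    if cfg.input_csv is not None and not Path(cfg.input_csv).exists():
        raise ConfigError(f"input file not found: {cfg.input_csv}")

    if cfg.input_csv is not None:
        dataset = load_dataset(cfg.input_csv)
        truths = None
    else:
        dataset, truths = generate_corpus(cfg.generator)
    dataset = preprocess_dataset(dataset)

    decomps = decompose_dataset(dataset, cfg.decomposition)
    init_t, amp_t, dur_t = build_training_tables(dataset, decomps)
    cv = crossval_evaluate(init_t, amp_t, dur_t, cfg.training)
    nets = train_nets(init_t, amp_t, dur_t, cfg.training)
    cl = evaluate_closed_loop(AnnPolicy(nets), dataset, cfg.simulation)
    report = _table2_report(cv, cl["summary"], decomps, dataset)

    artifacts = {
        "dataset": dataset,
        "truths": truths,
        "decompositions": decomps,
        "tables": (init_t, amp_t, dur_t),
        "crossval": cv,
        "nets": nets,
        "closed_loop": cl,
        "report": report,
    }
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        with open(out / "run_config.json", "w") as fh:
            json.dump(_jsonable(cfg.to_dict()), fh, indent=1)
        with open(out / "decomposition.json", "w") as fh:
            json.dump(decompositions_to_json(decomps), fh, indent=1)
        nets.save(out / "model.json")
    return artifacts


def decompositions_to_json(decomps: dict) -> dict:
    return {
        tid: {
            "n_star": int(d.n_star),
            "cost_curve": d.cost_curve.tolist(),
            "n_range": list(d.n_range),
            "recon_vaf": float(d.recon_vaf),
            "submovements": [list(s.as_tuple()) for s in d.submovements],
        }
        for tid, d in decomps.items()
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
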