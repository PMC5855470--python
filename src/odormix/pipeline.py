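"""End-to-end study driver: simulate -> select -> finalize -> detect -> report.

One master seed feeds a SeedSequence; each stage (data generation, fold
split, per-target training) consumes its own spawned child, so no stage
touches global RNG state and rerunning a config reproduces every artifact
byte for byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .ann import ANNStructure, DAEConfig, TANH, ActivationKind, STRUCTURE_GRID, TrainConfig
from .errors import ConfigError
from .interactions import detect_interactions, interaction_agreement, parse_rule
from .io_tables import write_study
from .pca_contrib import compute_pca_loadings, rank_sensor_contributions
from .selection import (
    FinalModel,
    finalize_and_test,
    make_split,
    run_structure_grid,
    select_best,
)
from .synthetic import CHANNELS, StudyConfig, build_compound_library, generate_study

_SEED_MASK = 0x7FFFFFFF

DEFAULT_ACTIVATIONS = ("tanh", "leaky_relu:0.03")


def parse_activation(label: str) -> ActivationKind:
    if label == "tanh":
        return TANH
    if label.startswith("leaky_relu"):
        leak = float(label.split(":")[1]) if ":" in label else 0.03
        return ActivationKind("leaky_relu", leak)
    if label == "linear":
        return ActivationKind("linear")
    raise ConfigError(f"unknown activation label: {label!r}")


@dataclass
class PipelineConfig:
    synthetic: StudyConfig = field(default_factory=StudyConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    dae: DAEConfig = field(default_factory=DAEConfig)
    pretrain: bool = True
    n_folds: int = 5
    grid: tuple = STRUCTURE_GRID
    activations: tuple = DEFAULT_ACTIVATIONS
    targets: tuple = ("oi", "ht")
    rule: str = "margin:0.5"

    def __post_init__(self):
        if not self.grid or not self.activations:
            raise ConfigError("structure grid and activation list must be nonempty")
        parse_rule(self.rule)
        for t in self.targets:
            if t not in ("oi", "ht"):
                raise ConfigError(f"unknown target {t!r}")

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc or {})
        kwargs = {}
        if "synthetic" in doc:
            kwargs["synthetic"] = StudyConfig(**doc.pop("synthetic"))
        if "train" in doc:
            kwargs["train"] = TrainConfig(**doc.pop("train"))
        if "dae" in doc:
            kwargs["dae"] = DAEConfig(**doc.pop("dae"))
        for key in ("pretrain", "n_folds", "rule"):
            if key in doc:
                kwargs[key] = doc.pop(key)
        for key in ("grid", "activations", "targets"):
            if key in doc:
                kwargs[key] = tuple(doc.pop(key))
        if doc:
            raise ConfigError(f"unknown config keys: {sorted(doc)}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            if str(path).endswith(".json"):
                doc = json.load(fh)
            else:
                doc = yaml.safe_load(fh)
        return cls.from_dict(doc)


@dataclass
class StudyReport:
    dataset: object
    selection: dict  # target -> list of StructureResult
    chosen: dict  # target -> StructureResult
    final: dict  # target -> FinalModel
    agreement: dict  # target -> AgreementTable
    loadings: object


def _spawn_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] & _SEED_MASK) for c in ss.spawn(n)]


def run_full_study(
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir=None,
) -> StudyReport:
    """Execute the full workflow and (optionally) write the report bundle."""
    if config is None:
        config = PipelineConfig()
    data_seed, split_seed, train_seed = _spawn_seeds(seed, 3)

    library = build_compound_library()
    dataset = generate_study(config.synthetic, seed=data_seed, library=library)
    plan = make_split(dataset, n_folds=config.n_folds, seed=split_seed)

    structures = {
        label: [ANNStructure.from_string(s, parse_activation(label)) for s in config.grid]
        for label in config.activations
    }

    selection = {}
    chosen = {}
    final = {}
    agreement = {}
    interactions_rows = []
    for t_index, target in enumerate(config.targets):
        train_cfg = TrainConfig(
            max_epochs=config.train.max_epochs,
            initial_step=config.train.initial_step,
            step_up=config.train.step_up,
            step_down=config.train.step_down,
            step_min=config.train.step_min,
            step_max=config.train.step_max,
            tol=config.train.tol,
            batch=config.train.batch,
            seed=(train_seed + 7 * t_index) & _SEED_MASK,
        )
        results = []
        for label in config.activations:
            results.extend(
                run_structure_grid(
                    plan, dataset, target, structures[label],
                    train_config=train_cfg, dae_config=config.dae,
                    pretrain=config.pretrain,
                )
            )
        selection[target] = results
        best = select_best(results)
        chosen[target] = best
        fm = finalize_and_test(
            best, dataset, target,
            train_config=train_cfg, dae_config=config.dae, pretrain=config.pretrain,
        )
        final[target] = fm

        quantity = target.upper()
        panel_calls, ann_calls = detect_interactions(
            dataset.test_samples, library, fm.predictions, quantity, config.rule
        )
        counts = {r.mixture.sample_id: r.mixture.n_components for r in dataset.test_samples}
        agreement[target] = interaction_agreement(panel_calls, ann_calls, counts)
        ann_by_id = {c.sample_id: c for c in ann_calls}
        recs_by_id = {r.mixture.sample_id: r for r in dataset.test_samples}
        for pc in panel_calls:
            rec = recs_by_id[pc.sample_id]
            observed = rec.panel.oi_mean if quantity == "OI" else rec.panel.ht_mean
            interactions_rows.append(
                {
                    "sample_id": pc.sample_id,
                    "quantity": quantity,
                    "n_components": rec.mixture.n_components,
                    "theoretical": observed - pc.effect,  # scale-clipped theoretical
                    "observed": observed,
                    "predicted": fm.predictions[pc.sample_id],
                    "verdict_panel": pc.verdict,
                    "verdict_ann": ann_by_id[pc.sample_id].verdict,
                }
            )

    sensor_matrix = np.stack(
        [r.sensors.as_array() for r in dataset.train_val_samples + dataset.test_samples]
    )
    loadings = compute_pca_loadings(sensor_matrix, n_components=2)

    report = StudyReport(
        dataset=dataset,
        selection=selection,
        chosen=chosen,
        final=final,
        agreement=agreement,
        loadings=loadings,
    )
    if out_dir is not None:
        _write_bundle(report, config, seed, out_dir, interactions_rows)
    return report


def _agreement_doc(table) -> dict:
    return {
        "quantity": table.quantity,
        "per_count": {
            str(k): {"panel_flagged": f, "ann_matched": m, "percent": p}
            for k, (f, m, p) in table.per_count.items()
        },
        "average_percent": table.average_percent,
        "total_flagged": table.total_flagged,
        "total_matched": table.total_matched,
    }


def _write_bundle(report: StudyReport, config, seed, out_dir, interactions_rows):
    os.makedirs(out_dir, exist_ok=True)
    write_study(report.dataset, os.path.join(out_dir, "data"))

    rows = []
    for target, results in report.selection.items():
        for res in results:
            rows.append(
                {
                    "target": target,
                    "structure": res.structure.name,
                    "activation": res.structure.hidden_activation.label,
                    "rmsecv": res.rmsecv,
                    "r2_cv": res.r2_cv,
                }
            )
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "selection_report.csv"), index=False)

    for target, fm in report.final.items():
        doc = {
            "target": target,
            "structure": report.chosen[target].structure.name,
            "activation": report.chosen[target].structure.hidden_activation.label,
            "rmsecv": report.chosen[target].rmsecv,
            "r2_cv": report.chosen[target].r2_cv,
            "rmsep_overall": fm.rmsep_overall,
            "rmsep_by_component_count": {str(k): v for k, v in fm.rmsep_by_component_count.items()},
            "r2_test": fm.r2_test,
        }
        with open(os.path.join(out_dir, f"final_report_{target}.json"), "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
        fm.model.save(os.path.join(out_dir, f"model_{target}.json"))

    pd.DataFrame(interactions_rows).to_csv(
        os.path.join(out_dir, "interactions.csv"), index=False
    )
    with open(os.path.join(out_dir, "agreement.json"), "w", encoding="utf-8") as fh:
        json.dump(
            {t: _agreement_doc(a) for t, a in report.agreement.items()},
            fh, indent=2, sort_keys=True,
        )

    loadings_df = pd.DataFrame(
        report.loadings.loadings,
        index=list(report.loadings.channel_names),
        columns=[f"PC{j+1}" for j in range(report.loadings.loadings.shape[1])],
    )
    loadings_df.index.name = "channel"
    loadings_df.to_csv(os.path.join(out_dir, "loadings.csv"))

    manifest = {
        "seed": seed,
        "n_folds": config.n_folds,
        "grid": list(config.grid),
        "activations": list(config.activations),
        "targets": list(config.targets),
        "rule": config.rule,
        "pretrain": config.pretrain,
        "synthetic": asdict(config.synthetic),
        "train": asdict(config.train),
        "dae": asdict(config.dae),
        "channels": list(CHANNELS),
        "ranking_pc1": rank_sensor_contributions(report.loadings, 0),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
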