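"""Data division, K-fold architecture selection, and held-out evaluation.

The held-out test phase is split off first and never touches normalization
statistics or training; the learning+validation phase is partitioned into K
near-equal folds. For every candidate architecture the network is trained K
times, each time on K-1 folds with the remaining fold as validation;
per-fold validation MSE (in original scale units) is pooled into RMSECV and
the per-fold R² values are averaged. The structure with the lowest RMSECV
wins (ties: higher R², then fewer weights). The winner is refit on the full
learning+validation phase and scored on the test phase as RMSEP, overall
and by mixture component count.

By default the per-fold normalizer/output scaler are fitted on the K-1
training folds only (leak-free); fitting them on the whole
learning+validation phase is available via ``normalize_on_all_folds``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ann import (
    ANNModel,
    ANNStructure,
    DAEConfig,
    TrainConfig,
    pretrain_sdae,
    train_network,
)
from .errors import ConfigError, DataError
from .preprocessing import (
    apply_normalizer,
    fit_input_normalizer,
    fit_output_scaler,
    scale_output,
)

_SEED_MASK = 0x7FFFFFFF


@dataclass(frozen=True)
class CVPlan:
    test_ids: tuple
    fold_assignments: dict  # sample id -> fold index in 1..n_folds
    n_folds: int

    def __post_init__(self):
        folds = set(self.fold_assignments.values())
        if folds and not folds <= set(range(1, self.n_folds + 1)):
            raise ConfigError("fold indices must lie in 1..n_folds")
        if set(self.test_ids) & set(self.fold_assignments):
            raise DataError("test ids must not appear in any fold")
        sizes = self.fold_sizes()
        if sizes and max(sizes) - min(sizes) > 1:
            raise ConfigError("fold sizes must differ by at most 1")

    def fold_sizes(self) -> list:
        return [
            sum(1 for f in self.fold_assignments.values() if f == i)
            for i in range(1, self.n_folds + 1)
        ]

    def fold_ids(self, fold: int) -> list:
        return [sid for sid, f in self.fold_assignments.items() if f == fold]


@dataclass(frozen=True)
class StructureResult:
    structure: ANNStructure
    rmsecv: float
    r2_cv: float
    per_fold_mse: tuple
    per_fold_r2: tuple
    target: str  # {"oi", "ht"}


@dataclass
class FinalModel:
    model: ANNModel
    rmsep_overall: float
    rmsep_by_component_count: dict  # {2,3,4,5} -> value
    r2_test: float
    predictions: dict = field(default_factory=dict)  # sample id -> prediction


def make_split(dataset, n_folds: int = 5, seed: int = 0) -> CVPlan:
    """Seeded shuffle of the learning+validation ids into K near-equal folds."""
    if n_folds < 2:
        raise ConfigError("n_folds must be >= 2")
    train_ids = [r.mixture.sample_id for r in dataset.train_val_samples]
    if n_folds > len(train_ids):
        raise ConfigError("n_folds exceeds the learning+validation sample count")
    rng = np.random.default_rng(seed)
    order = list(train_ids)
    rng.shuffle(order)
    assignments = {sid: (i % n_folds) + 1 for i, sid in enumerate(order)}
    return CVPlan(
        test_ids=tuple(r.mixture.sample_id for r in dataset.test_samples),
        fold_assignments=assignments,
        n_folds=n_folds,
    )


def mse_metric(y, y_hat) -> float:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise DataError("mse requires equal, nonzero-length inputs")
    return float(np.mean((y_hat - y) ** 2))


def r2_metric(y, y_hat) -> float:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise DataError("r2 requires equal, nonzero-length inputs")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DataError("r2 undefined for zero-variance targets")
    return 1.0 - float(np.sum((y_hat - y) ** 2)) / ss_tot


def _target_value(record, target: str) -> float:
    if target == "oi":
        return record.panel.oi_mean
    if target == "ht":
        return record.panel.ht_mean
    raise ConfigError(f"unknown target: {target!r}")


def _arrays(records, target: str):
    X = np.stack([r.sensors.as_array() for r in records])
    y = np.array([_target_value(r, target) for r in records])
    return X, y


def _fit_and_train(
    structure,
    train_records,
    target,
    train_config,
    dae_config,
    pretrain,
    seed,
):
    X, y = _arrays(train_records, target)
    normalizer = fit_input_normalizer(X)
    scaler = fit_output_scaler(y, target.upper())
    X_nn = apply_normalizer(normalizer, X)
    y_s = scale_output(scaler, y, "forward")
    cfg = TrainConfig(
        max_epochs=train_config.max_epochs,
        initial_step=train_config.initial_step,
        step_up=train_config.step_up,
        step_down=train_config.step_down,
        step_min=train_config.step_min,
        step_max=train_config.step_max,
        tol=train_config.tol,
        batch=train_config.batch,
        seed=seed,
    )
    init = None
    if pretrain:
        dcfg = dae_config or DAEConfig()
        dcfg = DAEConfig(
            corruption_kind=dcfg.corruption_kind,
            corruption_sd=dcfg.corruption_sd,
            masking_fraction=dcfg.masking_fraction,
            epochs=dcfg.epochs,
            initial_step=dcfg.initial_step,
            step_up=dcfg.step_up,
            step_down=dcfg.step_down,
            seed=seed,
        )
        init = pretrain_sdae(structure, X_nn, dcfg)
    return train_network(
        structure,
        X_nn,
        y_s,
        cfg,
        init_weights=init,
        normalizer=normalizer,
        output_scaler=scaler,
    )


def cross_validate_structure(
    structure: ANNStructure,
    plan: CVPlan,
    dataset,
    target: str,
    train_config: TrainConfig | None = None,
    dae_config: DAEConfig | None = None,
    pretrain: bool = True,
    normalize_on_all_folds: bool = False,
) -> StructureResult:
    """K-fold RMSECV / mean validation R² for one candidate architecture."""
    if train_config is None:
        train_config = TrainConfig()
    by_id = {r.mixture.sample_id: r for r in dataset.train_val_samples}
    per_fold_mse = []
    per_fold_r2 = []
    for fold in range(1, plan.n_folds + 1):
        val_ids = plan.fold_ids(fold)
        learn_ids = [sid for sid in by_id if plan.fold_assignments[sid] != fold]
        learn = [by_id[sid] for sid in learn_ids]
        val = [by_id[sid] for sid in val_ids]
        fit_pool = list(by_id.values()) if normalize_on_all_folds else learn
        try:
            model = _cv_fit(
                structure, learn, fit_pool, target, train_config, dae_config,
                pretrain, seed=(train_config.seed * 1000003 + fold) & _SEED_MASK,
            )
        except Exception as exc:
            raise type(exc)(f"fold {fold}: {exc}") from exc
        Xv, yv = _arrays(val, target)
        pred = model.predict(Xv)
        per_fold_mse.append(mse_metric(yv, pred))
        per_fold_r2.append(r2_metric(yv, pred))
    return StructureResult(
        structure=structure,
        rmsecv=float(np.sqrt(np.mean(per_fold_mse))),
        r2_cv=float(np.mean(per_fold_r2)),
        per_fold_mse=tuple(per_fold_mse),
        per_fold_r2=tuple(per_fold_r2),
        target=target,
    )


def _cv_fit(structure, learn, fit_pool, target, train_config, dae_config, pretrain, seed):
    if fit_pool is learn:
        return _fit_and_train(
            structure, learn, target, train_config, dae_config, pretrain, seed
        )
    # statistics from the pool, training samples from `learn`
    Xp, yp = _arrays(fit_pool, target)
    normalizer = fit_input_normalizer(Xp)
    scaler = fit_output_scaler(yp, target.upper())
    X, y = _arrays(learn, target)
    X_nn = apply_normalizer(normalizer, X)
    y_s = scale_output(scaler, y, "forward")
    cfg = TrainConfig(
        max_epochs=train_config.max_epochs,
        initial_step=train_config.initial_step,
        step_up=train_config.step_up,
        step_down=train_config.step_down,
        step_min=train_config.step_min,
        step_max=train_config.step_max,
        tol=train_config.tol,
        batch=train_config.batch,
        seed=seed,
    )
    init = pretrain_sdae(structure, X_nn, dae_config or DAEConfig(seed=seed)) if pretrain else None
    return train_network(
        structure, X_nn, y_s, cfg, init_weights=init,
        normalizer=normalizer, output_scaler=scaler,
    )


def run_structure_grid(
    plan: CVPlan,
    dataset,
    target: str,
    structures,
    train_config: TrainConfig | None = None,
    dae_config: DAEConfig | None = None,
    pretrain: bool = True,
) -> list:
    return [
        cross_validate_structure(
            s, plan, dataset, target, train_config, dae_config, pretrain
        )
        for s in structures
    ]


def select_best(results) -> StructureResult:
    """Lowest RMSECV; ties broken by higher R², then fewer weights."""
    if not results:
        raise ConfigError("no structure results to select from")
    return min(
        results,
        key=lambda r: (r.rmsecv, -r.r2_cv, r.structure.n_weights),
    )


def finalize_and_test(
    chosen: StructureResult | ANNStructure,
    dataset,
    target: str | None = None,
    train_config: TrainConfig | None = None,
    dae_config: DAEConfig | None = None,
    pretrain: bool = True,
) -> FinalModel:
    """Refit on all learning+validation samples; score RMSEP on the test phase."""
    if isinstance(chosen, StructureResult):
        structure = chosen.structure
        target = target or chosen.target
    else:
        structure = chosen
        if target is None:
            raise ConfigError("target required when passing a bare structure")
    if train_config is None:
        train_config = TrainConfig()
    model = _fit_and_train(
        structure,
        list(dataset.train_val_samples),
        target,
        train_config,
        dae_config,
        pretrain,
        seed=train_config.seed,
    )
    test = list(dataset.test_samples)
    if not test:
        return FinalModel(model, float("nan"), {}, float("nan"))
    Xt, yt = _arrays(test, target)
    pred = model.predict(Xt)
    by_count = {}
    for count in (2, 3, 4, 5):
        idx = [i for i, r in enumerate(test) if r.mixture.n_components == count]
        if idx:
            by_count[count] = float(
                np.sqrt(mse_metric(yt[idx], np.asarray(pred)[idx]))
            )
    return FinalModel(
        model=model,
        rmsep_overall=float(np.sqrt(mse_metric(yt, pred))),
        rmsep_by_component_count=by_count,
        r2_test=r2_metric(yt, pred),
        predictions={
            r.mixture.sample_id: float(p) for r, p in zip(test, np.asarray(pred))
        },
    )
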