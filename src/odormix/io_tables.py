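"""CSV/JSON persistence for study tables and model artifacts.

Three tables describe one phase of a study: ``samples.csv`` (composition and
ground-truth labels), ``sensors.csv`` (8 named channels), ``panel.csv``
(per-assessor scores plus means). Floats round-trip losslessly because
pandas writes shortest-repr decimals. Schema problems raise DataError
naming the offending column.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import DataError
from .synthetic import (
    CHANNELS,
    COMPOUNDS,
    N_ASSESSORS,
    MixtureSample,
    PanelScore,
    SampleRecord,
    SensorVector,
    StudyDataset,
)

_CONC_COLS = [f"conc_{name}" for name in COMPOUNDS]
SAMPLES_COLUMNS = (
    ["sample_id"]
    + _CONC_COLS
    + [
        "n_components",
        "truth_oi_interaction",
        "truth_ht_interaction",
        "synergy_factor",
        "neutralization_factor",
        "oi_ramp",
        "ht_ramp",
    ]
)
SENSORS_COLUMNS = ["sample_id"] + list(CHANNELS)
PANEL_COLUMNS = (
    ["sample_id"]
    + [f"oi_{i+1}" for i in range(N_ASSESSORS)]
    + [f"ht_{i+1}" for i in range(N_ASSESSORS)]
    + ["oi_mean", "ht_mean"]
)


def records_to_frames(records) -> tuple:
    samples = pd.DataFrame(
        [
            {
                "sample_id": r.mixture.sample_id,
                **{f"conc_{n}": r.mixture.concentrations.get(n, 0.0) for n in COMPOUNDS},
                "n_components": r.mixture.n_components,
                "truth_oi_interaction": r.mixture.truth_oi_interaction,
                "truth_ht_interaction": r.mixture.truth_ht_interaction,
                "synergy_factor": r.mixture.synergy_factor,
                "neutralization_factor": r.mixture.neutralization_factor,
                "oi_ramp": r.mixture.oi_ramp,
                "ht_ramp": r.mixture.ht_ramp,
            }
            for r in records
        ],
        columns=SAMPLES_COLUMNS,
    )
    sensors = pd.DataFrame(
        [
            {"sample_id": r.mixture.sample_id, **dict(zip(CHANNELS, r.sensors.channels))}
            for r in records
        ],
        columns=SENSORS_COLUMNS,
    )
    panel = pd.DataFrame(
        [
            {
                "sample_id": r.mixture.sample_id,
                **{f"oi_{i+1}": v for i, v in enumerate(r.panel.per_assessor_oi)},
                **{f"ht_{i+1}": v for i, v in enumerate(r.panel.per_assessor_ht)},
                "oi_mean": r.panel.oi_mean,
                "ht_mean": r.panel.ht_mean,
            }
            for r in records
        ],
        columns=PANEL_COLUMNS,
    )
    return samples, sensors, panel


def _check_schema(df: pd.DataFrame, expected, kind: str):
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DataError(f"{kind}: missing column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataError(f"{kind}: duplicate sample_id {dup!r}")
    numeric = [c for c in expected if c not in ("sample_id", "truth_oi_interaction", "truth_ht_interaction")]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0]) + 2  # header is line 1
            raise DataError(f"{kind}: non-numeric or missing value in column '{col}' (line {row})")


def frames_to_records(samples: pd.DataFrame, sensors: pd.DataFrame, panel: pd.DataFrame) -> list:
    _check_schema(samples, SAMPLES_COLUMNS, "samples")
    _check_schema(sensors, SENSORS_COLUMNS, "sensors")
    _check_schema(panel, PANEL_COLUMNS, "panel")
    sensors_by_id = sensors.set_index("sample_id")
    panel_by_id = panel.set_index("sample_id")
    records = []
    for _, row in samples.iterrows():
        sid = row["sample_id"]
        if sid not in sensors_by_id.index:
            raise DataError(f"sensors: missing sample_id {sid!r}")
        if sid not in panel_by_id.index:
            raise DataError(f"panel: missing sample_id {sid!r}")
        mixture = MixtureSample(
            sample_id=sid,
            concentrations={n: float(row[f"conc_{n}"]) for n in COMPOUNDS},
            n_components=int(row["n_components"]),
            truth_oi_interaction=row["truth_oi_interaction"],
            truth_ht_interaction=row["truth_ht_interaction"],
            synergy_factor=float(row["synergy_factor"]),
            neutralization_factor=float(row["neutralization_factor"]),
            oi_ramp=float(row["oi_ramp"]),
            ht_ramp=float(row["ht_ramp"]),
        )
        srow = sensors_by_id.loc[sid]
        sensor = SensorVector(sample_id=sid, channels=tuple(float(srow[c]) for c in CHANNELS))
        prow = panel_by_id.loc[sid]

        def _score(v):
            v = float(v)
            return int(v) if v.is_integer() else v  # zero-noise panels are continuous

        score = PanelScore(
            per_assessor_oi=tuple(_score(prow[f"oi_{i+1}"]) for i in range(N_ASSESSORS)),
            per_assessor_ht=tuple(_score(prow[f"ht_{i+1}"]) for i in range(N_ASSESSORS)),
            oi_mean=float(prow["oi_mean"]),
            ht_mean=float(prow["ht_mean"]),
        )
        records.append(SampleRecord(mixture=mixture, sensors=sensor, panel=score))
    return records


def write_records(records, directory):
    os.makedirs(directory, exist_ok=True)
    samples, sensors, panel = records_to_frames(records)
    samples.to_csv(os.path.join(directory, "samples.csv"), index=False)
    sensors.to_csv(os.path.join(directory, "sensors.csv"), index=False)
    panel.to_csv(os.path.join(directory, "panel.csv"), index=False)


def read_records(directory) -> list:
    frames = []
    for kind in ("samples", "sensors", "panel"):
        path = os.path.join(directory, f"{kind}.csv")
        if not os.path.exists(path):
            raise DataError(f"missing table: {path}")
        frames.append(pd.read_csv(path, float_precision="round_trip"))
    return frames_to_records(*frames)


def write_study(dataset: StudyDataset, directory):
    write_records(dataset.train_val_samples, os.path.join(directory, "train"))
    write_records(dataset.test_samples, os.path.join(directory, "test"))


def read_study(directory, seed: int = -1) -> StudyDataset:
    return StudyDataset(
        train_val_samples=tuple(read_records(os.path.join(directory, "train"))),
        test_samples=tuple(read_records(os.path.join(directory, "test"))),
        seed=seed,
    )
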