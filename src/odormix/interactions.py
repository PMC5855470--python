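"""Odour-interaction detection against additive mixture theory.

The theoretical mixture intensity is the Patte-Laffort value: the Euclidean
norm of the component intensities each compound would have on its own. The
theoretical hedonic tone is the algebraic sum of component tones. A sample
shows an interaction when the panel-observed (or ANN-predicted) value
differs significantly from the theoretical one — by default when the
difference exceeds half a verbal-scale class (margin rule, delta = 0.5); a
one-sample t-test over the four assessors is available instead. For
intensity, a significant excess is synergism; for hedonic tone, significant
attenuation toward zero is neutralization and significant amplification
away from zero is synergism.

Agreement between the panel path and the ANN path is tabulated per mixture
component count: of the samples the panel flags, how many does the ANN flag
with the same verdict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError
from .synthetic import HT_SCALE, OI_SCALE, CompoundSpec

log = logging.getLogger(__name__)

VERDICTS = ("none", "synergism", "neutralization")


@dataclass(frozen=True)
class PerceptionValues:
    sample_id: str
    quantity: str  # {"OI", "HT"}
    theoretical: float
    observed: float  # panel mean or ANN prediction
    per_assessor: tuple = ()  # raw assessor values, for the t-test rule


@dataclass(frozen=True)
class InteractionCall:
    sample_id: str
    quantity: str
    verdict: str  # {"none", "synergism", "neutralization"}
    effect: float  # observed - theoretical (theoretical clipped to scale)
    decision_stat: float  # |effect| for margin rule, p-value for t-test

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise DataError(f"unknown verdict: {self.verdict!r}")


@dataclass(frozen=True)
class AgreementTable:
    quantity: str
    per_count: dict  # count -> (panel_flagged, ann_matched, percent or None)
    average_percent: float  # mean over counts with panel_flagged > 0
    total_flagged: int
    total_matched: int


def theoretical_mixture_oi(component_ois) -> float:
    """Patte-Laffort Euclidean additivity of component intensities."""
    ois = np.asarray(list(component_ois), dtype=float)
    if ois.size > 5:
        raise DataError("at most 5 components")
    if (ois < 0).any():
        raise DataError("component intensities must be nonnegative")
    return float(np.sqrt(np.sum(ois**2)))


def theoretical_mixture_ht(component_hts) -> float:
    """Algebraic sum of component hedonic tones (unclipped)."""
    hts = np.asarray(list(component_hts), dtype=float)
    if hts.size > 5:
        raise DataError("at most 5 components")
    return float(np.sum(hts)) if hts.size else 0.0


@dataclass(frozen=True)
class WeberCalibration:
    """Fitted dose-intensity law for one compound: OI = k*(log10 C - log10 OT)."""

    weber_coeff: float
    log10_threshold: float

    def component_oi(self, concentration: float) -> float:
        if concentration <= 0:
            return 0.0
        raw = self.weber_coeff * (math.log10(concentration) - self.log10_threshold)
        return float(np.clip(raw, *OI_SCALE))


def calibrate_weber(concentrations, intensities) -> WeberCalibration:
    """Least-squares Weber-Fechner fit from single-compound measurements.

    Points at the scale limits (0 or 6) are excluded from the fit since they
    are censored by clipping.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(intensities, dtype=float)
    keep = (c > 0) & (y > 0) & (y < OI_SCALE[1])
    if keep.sum() < 2:
        raise DataError("need at least 2 un-censored points to calibrate")
    slope, intercept = np.polyfit(np.log10(c[keep]), y[keep], 1)
    if slope <= 0:
        raise DataError("calibrated Weber coefficient is not positive")
    return WeberCalibration(weber_coeff=float(slope), log10_threshold=float(-intercept / slope))


def component_perception(
    concentration: float,
    compound: CompoundSpec,
    source: str = "generator_truth",
    calibration: WeberCalibration | None = None,
) -> tuple:
    """(OI_i, HT_i) of one compound alone at the given concentration."""
    if concentration < 0:
        raise DataError("concentration must be >= 0")
    if source == "generator_truth":
        return compound.component_oi(concentration), compound.component_ht(concentration)
    if source == "calibrated":
        if calibration is None:
            raise ConfigError("calibrated mode requires a WeberCalibration")
        oi = calibration.component_oi(concentration)
        ht = compound.hedonic_unit * oi / 3.2
        return oi, ht
    raise ConfigError(f"unknown perception source: {source!r}")


def parse_rule(rule) -> tuple:
    """Accept ('margin', 0.5), ('ttest', 0.05), or 'margin:0.5' strings."""
    if isinstance(rule, str):
        parts = rule.split(":")
        kind = parts[0]
        value = float(parts[1]) if len(parts) > 1 else None
    else:
        kind, value = rule
    if kind == "margin":
        value = 0.5 if value is None else float(value)
        if value < 0:
            raise ConfigError("margin delta must be >= 0")
    elif kind == "ttest":
        value = 0.05 if value is None else float(value)
        if not 0 < value < 1:
            raise ConfigError("t-test alpha must be in (0, 1)")
    else:
        raise ConfigError(f"unknown decision rule: {kind!r}")
    return kind, value


def classify_interaction(values: PerceptionValues, rule=("margin", 0.5)) -> InteractionCall:
    """Call {none, synergism, neutralization} for one sample and quantity.

    The theoretical value is clipped to the reporting scale before the
    comparison (observations cannot leave the scale, so an off-scale
    additive prediction would otherwise always look like an interaction).
    """
    kind, param = parse_rule(rule)
    scale = OI_SCALE if values.quantity == "OI" else HT_SCALE
    theo = float(np.clip(values.theoretical, *scale))
    obs = values.observed
    effect = obs - theo

    if kind == "ttest":
        arr = np.asarray(values.per_assessor, dtype=float)
        if arr.size < 2 or np.allclose(arr.std(), 0.0):
            log.info(
                "%s/%s: zero assessor variance, falling back to margin rule",
                values.sample_id, values.quantity,
            )
            kind, param = "margin", 0.5
        else:
            t_res = stats.ttest_1samp(arr, popmean=theo)
            significant = t_res.pvalue < param
            decision_stat = float(t_res.pvalue)
    if kind == "margin":
        significant = abs(effect) > param
        decision_stat = abs(effect)

    verdict = "none"
    if significant:
        if values.quantity == "OI":
            verdict = "synergism" if effect > 0 else "neutralization"
        else:
            if abs(obs) < abs(theo):
                verdict = "neutralization"
            elif abs(obs) > abs(theo):
                verdict = "synergism"
    return InteractionCall(
        sample_id=values.sample_id,
        quantity=values.quantity,
        verdict=verdict,
        effect=effect,
        decision_stat=decision_stat,
    )


def detect_interactions(
    records,
    library,
    predictions: dict,
    quantity: str,
    rule=("margin", 0.5),
    source: str = "generator_truth",
    calibrations: dict | None = None,
) -> tuple:
    """Panel-vs-theory and ANN-vs-theory calls for a set of samples.

    ``predictions`` maps sample id -> ANN prediction for the quantity.
    Returns (panel_calls, ann_calls), aligned by sample.
    """
    if quantity not in ("OI", "HT"):
        raise ConfigError("quantity must be 'OI' or 'HT'")
    lib = {spec.name: spec for spec in library}
    panel_calls = []
    ann_calls = []
    for rec in records:
        sid = rec.mixture.sample_id
        if sid not in predictions:
            raise DataError(f"no ANN prediction for sample {sid}")
        ois, hts = [], []
        for name, conc in rec.mixture.concentrations.items():
            if conc <= 0:
                continue
            calib = calibrations.get(name) if calibrations else None
            oi_i, ht_i = component_perception(conc, lib[name], source, calib)
            ois.append(oi_i)
            hts.append(ht_i)
        if quantity == "OI":
            theo = theoretical_mixture_oi(ois)
            observed = rec.panel.oi_mean
            per_assessor = rec.panel.per_assessor_oi
        else:
            theo = theoretical_mixture_ht(hts)
            observed = rec.panel.ht_mean
            per_assessor = rec.panel.per_assessor_ht
        panel_calls.append(
            classify_interaction(
                PerceptionValues(sid, quantity, theo, observed, tuple(per_assessor)),
                rule,
            )
        )
        ann_calls.append(
            classify_interaction(
                PerceptionValues(sid, quantity, theo, float(predictions[sid])), rule
            )
        )
    return panel_calls, ann_calls


def interaction_agreement(panel_calls, ann_calls, component_counts: dict) -> AgreementTable:
    """Tabulate ANN-vs-panel verdict agreement by mixture component count.

    ``component_counts`` maps sample id -> number of mixture components.
    Counts with no panel flags report percent None and are excluded from
    the average.
    """
    ann_by_id = {c.sample_id: c for c in ann_calls}
    if set(ann_by_id) != {c.sample_id for c in panel_calls}:
        raise DataError("panel and ANN calls are not paired by sample id")
    quantity = panel_calls[0].quantity if panel_calls else "OI"
    per_count = {}
    for count in (2, 3, 4, 5):
        flagged = 0
        matched = 0
        for pc in panel_calls:
            if component_counts.get(pc.sample_id) != count or pc.verdict == "none":
                continue
            flagged += 1
            if ann_by_id[pc.sample_id].verdict == pc.verdict:
                matched += 1
        percent = 100.0 * matched / flagged if flagged else None
        per_count[count] = (flagged, matched, percent)
    defined = [p for _, _, p in per_count.values() if p is not None]
    return AgreementTable(
        quantity=quantity,
        per_count=per_count,
        average_percent=float(np.mean(defined)) if defined else float("nan"),
        total_flagged=sum(f for f, _, _ in per_count.values()),
        total_matched=sum(m for _, m, _ in per_count.values()),
    )
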