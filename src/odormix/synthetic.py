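"""In-silico study generator for e-nose odour-interaction experiments.

Emulates a two-phase laboratory study on aqueous mixtures of five odorants
(toluene, acetone, triethylamine, alpha-pinene, n-butanol): an 8-channel
sensor array (1 PID, 2 electrochemical, 5 metal-oxide channels), a trained
4-person sensory panel scoring odour intensity (OI, 0..6) and hedonic tone
(HT, -4..+4) on the VDI 3940 verbal scales, and ground-truth odour
interactions — intensity synergism and hedonic neutralization driven by
alpha-pinene.

Component psychophysics follow the Weber-Fechner law
``OI_i = k * log10(C / OT)`` above the effective perceptual threshold OT;
the no-interaction mixture intensity is the Patte-Laffort (Euclidean) sum
of component intensities and the mixture hedonic tone is the algebraic sum
of component tones. Interactions are deterministic functions of the
mixture composition, so they are in principle recoverable from sensor
data: intensity synergism is level-dependent hyperadditivity (the additive
intensity is amplified once it passes a fixed onset, with a narrow linear
ramp keeping the effect continuous), and hedonic neutralization occurs
when alpha-pinene sits high enough in its concentration range, with the
per-count threshold set from the configured prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DataError

# Sensor channel order is fixed across the whole package.
CHANNELS = (
    "MiniPID",
    "FECS44",
    "FECS50",
    "TGS2600",
    "TGS823",
    "TGS2602",
    "TGS2603",
    "TGS8100",
)
N_CHANNELS = len(CHANNELS)
#: indices of the metal-oxide (power-law) channels; PID/EC channels are linear
MOS_CHANNELS = (3, 4, 5, 6, 7)

OI_SCALE = (0.0, 6.0)
HT_SCALE = (-4.0, 4.0)
N_ASSESSORS = 4

#: aqueous concentration ranges, ppm v/v
CONC_RANGES = {
    "toluene": (5.0, 80.0),
    "acetone": (200.0, 3200.0),
    "triethylamine": (5.0, 80.0),
    "alpha-pinene": (1.0, 16.0),
    "n-butanol": (20.0, 320.0),
}
COMPOUNDS = tuple(CONC_RANGES)

#: olfactory thresholds in aqueous solution, ppm w/v
ODOUR_THRESHOLDS_AQ = {
    "toluene": 0.042,
    "acetone": 20.0,
    "triethylamine": 0.42,
    "alpha-pinene": 4.2,
    "n-butanol": 7.1,
}

#: component intensity at the bottom/top of each concentration range (scale
#: units); the Weber coefficient and the effective perceptual threshold are
#: calibrated against these so that single components span a realistic
#: dynamic range and mixtures cover the study's stated OI window instead of
#: saturating the 0-6 scale (the literature aqueous thresholds sit orders of
#: magnitude below the working ranges and would pin every mixture at the
#: ceiling)
OI_SPAN = (0.3, 4.0)
REFERENCE_OI = OI_SPAN[1]

#: hedonic contribution (scale units) of each compound at REFERENCE_OI;
#: positive only for the pleasant odour types (pine/resinous, light aromatic)
HEDONIC_UNITS = {
    "toluene": 0.5,
    "acetone": -0.8,
    "triethylamine": -2.5,
    "alpha-pinene": 1.5,
    "n-butanol": -1.8,
}

# Relative channel selectivity of each compound (rows) on each channel
# (columns, CHANNELS order).  Patterns reflect the sensors' target gases —
# the PID sees all VOCs, FECS44 (ammonia cell) mostly the amine, the MOS
# channels have broad, overlapping selectivities — while keeping the 5x8
# matrix well conditioned (minimum singular value ~0.26) so the array can
# actually discriminate the compounds, which is what an array is built for.
_SELECTIVITY = {
    #                PID   F44   F50  2600  T823  2602  2603  8100
    "toluene":       (1.0, 0.0, 0.0, 0.2, 1.0, 0.7, 0.1, 0.4),
    "acetone":       (0.5, 0.0, 0.0, 0.7, 0.6, 0.2, 0.1, 1.0),
    "triethylamine": (0.4, 1.0, 0.2, 0.3, 0.2, 0.8, 1.0, 0.1),
    "alpha-pinene":  (1.0, 0.0, 0.0, 0.1, 0.3, 1.0, 0.5, 0.1),
    "n-butanol":     (0.6, 0.0, 0.1, 1.0, 0.5, 0.3, 0.7, 0.8),
}
_MOS_EXPONENT = 0.5

#: intensity synergism sets in once the additive (Patte-Laffort) mixture
#: intensity exceeds this level — level-dependent hyperadditivity with a
#: fixed onset; the ramp half-width makes the amplification continuous
DEFAULT_SYNERGY_ONSET = 3.5
DEFAULT_ONSET_WIDTH = 0.1

#: default hedonic-neutralization prevalence per component count, rising with
#: mixture complexity (fractions of flagged samples per count in the study
#: this emulates); neutralization additionally requires alpha-pinene
DEFAULT_PREVALENCE_HT = {2: 0.30, 3: 0.45, 4: 0.55, 5: 0.70}
DEFAULT_HT_RAMP_WIDTH = 0.12

#: assessors rate complex mixtures less consistently: the per-assessor noise
#: SD is the configured base value scaled by (1 + slope*(n_components - 2)),
#: calibrated so the panel noise floor grows across 2..5 components roughly
#: like the prediction errors the emulated study reports
DEFAULT_COMPLEXITY_NOISE_SLOPE = 1.0 / 3.0

#: windows the sampled mixtures must fall into (noise-free baseline values)
OI_WINDOW = (0.5, 5.5)
HT_WINDOW = (-3.5, 1.0)

_SEED_MASK = 0x7FFFFFFF


@dataclass(frozen=True)
class CompoundSpec:
    """Physico-chemical and perceptual parameters of one odorant.

    ``odour_threshold_aq`` is the literature aqueous olfactory threshold
    (a documented property of the compound); ``perceptual_threshold`` is
    the effective in-solution detection level the Weber-Fechner law uses,
    which absorbs headspace partitioning and panel conditions. They
    coincide only if the caller says so.
    """

    name: str
    odour_threshold_aq: float  # ppm w/v in water (literature value)
    weber_coeff: float  # slope k of OI = k*log10(C/OT_eff)
    hedonic_unit: float  # HT contribution at REFERENCE_OI
    sensor_affinity: tuple  # 8 per-channel response coefficients
    sensor_exponent: tuple  # 8 per-channel power-law exponents
    perceptual_threshold: float | None = None  # ppm v/v; defaults to odour_threshold_aq

    def __post_init__(self):
        if self.perceptual_threshold is None:
            object.__setattr__(self, "perceptual_threshold", self.odour_threshold_aq)
        if self.odour_threshold_aq <= 0 or self.perceptual_threshold <= 0:
            raise ConfigError(f"{self.name}: odour thresholds must be positive")
        if self.weber_coeff <= 0:
            raise ConfigError(f"{self.name}: Weber coefficient must be positive")
        if len(self.sensor_affinity) != N_CHANNELS or len(self.sensor_exponent) != N_CHANNELS:
            raise ConfigError(f"{self.name}: affinity/exponent vectors must have length 8")
        if any(a < 0 for a in self.sensor_affinity):
            raise ConfigError(f"{self.name}: sensor affinities must be nonnegative")

    def component_oi(self, concentration: float) -> float:
        """Weber-Fechner intensity of this compound alone, clipped to the scale."""
        if concentration <= 0:
            return 0.0
        raw = self.weber_coeff * math.log10(concentration / self.perceptual_threshold)
        return float(np.clip(raw, *OI_SCALE))

    def component_ht(self, concentration: float) -> float:
        """Hedonic contribution, proportional to the component intensity."""
        return self.hedonic_unit * self.component_oi(concentration) / REFERENCE_OI


@dataclass(frozen=True)
class MixtureSample:
    sample_id: str
    concentrations: dict  # compound name -> ppm v/v (0 means absent)
    n_components: int
    truth_oi_interaction: str = "none"  # {none, synergism}
    truth_ht_interaction: str = "none"  # {none, neutralization}
    synergy_factor: float = 1.3
    neutralization_factor: float = 0.4
    # effect strengths in [0,1]; the binary flags above are ramp >= 0.5
    oi_ramp: float = 0.0
    ht_ramp: float = 0.0

    def __post_init__(self):
        if not (2 <= self.n_components <= 5):
            raise DataError(f"{self.sample_id}: n_components must be in 2..5")
        if self.synergy_factor < 1:
            raise DataError(f"{self.sample_id}: synergy_factor must be >= 1")
        for name, conc in self.concentrations.items():
            if conc == 0:
                continue
            lo, hi = CONC_RANGES[name]
            if not (lo <= conc <= hi):
                raise DataError(
                    f"{self.sample_id}: {name} concentration {conc} outside [{lo}, {hi}]"
                )
        if (
            self.truth_ht_interaction == "neutralization"
            and self.concentrations.get("alpha-pinene", 0.0) <= 0
        ):
            raise DataError(
                f"{self.sample_id}: hedonic neutralization requires alpha-pinene"
            )

    @property
    def present(self) -> tuple:
        return tuple(n for n, c in self.concentrations.items() if c > 0)


@dataclass(frozen=True)
class PanelScore:
    per_assessor_oi: tuple  # 4 ints in [0, 6]
    per_assessor_ht: tuple  # 4 ints in [-4, 4]
    oi_mean: float
    ht_mean: float


@dataclass(frozen=True)
class SensorVector:
    sample_id: str
    channels: tuple  # 8 floats, CHANNELS order

    def __post_init__(self):
        if len(self.channels) != N_CHANNELS:
            raise DataError(f"{self.sample_id}: expected {N_CHANNELS} channels")
        if not all(math.isfinite(c) for c in self.channels):
            raise DataError(f"{self.sample_id}: non-finite sensor reading")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.channels, dtype=float)


@dataclass(frozen=True)
class SampleRecord:
    """One fully simulated sample: composition, instrument reading, panel score."""

    mixture: MixtureSample
    sensors: SensorVector
    panel: PanelScore


@dataclass(frozen=True)
class StudyDataset:
    train_val_samples: tuple  # SampleRecords, the learning+validation phase
    test_samples: tuple  # SampleRecords, the interaction-study phase
    seed: int

    def __post_init__(self):
        ids_a = {r.mixture.sample_id for r in self.train_val_samples}
        ids_b = {r.mixture.sample_id for r in self.test_samples}
        if ids_a & ids_b:
            raise DataError("train_val and test sample ids overlap")


@dataclass(frozen=True)
class StudyConfig:
    n_train: int = 150
    n_test: int = 80
    sensor_noise_sd: float = 0.05
    assessor_noise_sd: float = 0.25
    complexity_noise_slope: float = DEFAULT_COMPLEXITY_NOISE_SLOPE
    synergy_factor: float = 1.3
    neutralization_factor: float = 0.4
    synergy_onset: float = DEFAULT_SYNERGY_ONSET
    onset_width: float = DEFAULT_ONSET_WIDTH
    ht_ramp_width: float = DEFAULT_HT_RAMP_WIDTH
    prevalence_oi: dict | float | None = None  # None: fixed synergy_onset
    prevalence_ht: dict | float | None = None  # None: per-count defaults
    component_count_weights: dict = field(
        default_factory=lambda: {2: 0.25, 3: 0.25, 4: 0.25, 5: 0.25}
    )
    stratify_counts: bool = True  # equal component counts within each phase


def build_compound_library(
    weber_coeffs: dict | None = None,
    hedonic_units: dict | None = None,
    oi_span: tuple = OI_SPAN,
) -> list:
    """Default five-compound library.

    The dose-intensity law is calibrated per compound so the single-compound
    intensity runs from ``oi_span[0]`` at the bottom of its concentration
    range to ``oi_span[1]`` at the top: the Weber coefficient is
    ``(hi - lo) / log10(Cmax/Cmin)`` (~2.4 for the 16-fold ranges) and the
    effective perceptual threshold sits just below the range bottom. This
    reproduces the study design — mixtures spanning intensities 0.5-5.5 —
    which is impossible under the literature aqueous thresholds alone (a
    toluene solution at the bottom of its range is ~100x its literature
    threshold). The literature thresholds are still carried on each spec.
    """
    hedonic = dict(HEDONIC_UNITS)
    if hedonic_units:
        hedonic.update(hedonic_units)
    oi_lo, oi_hi = oi_span
    if not 0 <= oi_lo < oi_hi:
        raise ConfigError("oi_span must satisfy 0 <= lo < hi")
    specs = []
    for name in COMPOUNDS:
        cmin, cmax = CONC_RANGES[name]
        k = (oi_hi - oi_lo) / math.log10(cmax / cmin)
        if weber_coeffs and name in weber_coeffs:
            k = weber_coeffs[name]
        perceptual_threshold = cmin / 10.0 ** (oi_lo / k)
        sel = _SELECTIVITY[name]
        exponent = tuple(
            _MOS_EXPONENT if j in MOS_CHANNELS else 1.0 for j in range(N_CHANNELS)
        )
        # affinity scaled so the contribution at Cmax equals the selectivity,
        # making channels comparable across compounds with very different
        # concentration scales (headspace partitioning is folded in here)
        affinity = tuple(
            sel[j] / (cmax ** exponent[j]) for j in range(N_CHANNELS)
        )
        specs.append(
            CompoundSpec(
                name=name,
                odour_threshold_aq=ODOUR_THRESHOLDS_AQ[name],
                weber_coeff=k,
                hedonic_unit=hedonic[name],
                sensor_affinity=affinity,
                sensor_exponent=exponent,
                perceptual_threshold=perceptual_threshold,
            )
        )
    return specs


def _library_map(library) -> dict:
    return {spec.name: spec for spec in library}


def _ramp(x: float, x0: float, width: float) -> float:
    """Linear 0->1 ramp centred at x0; collapses to a step when width = 0."""
    if math.isinf(x0):
        return 0.0 if x0 > 0 else 1.0
    if width <= 0:
        return 1.0 if x >= x0 else 0.0
    return float(np.clip((x - (x0 - width)) / (2.0 * width), 0.0, 1.0))


def _normalize_prevalence(prevalence, default: dict) -> dict:
    if prevalence is None:
        table = dict(default)
    elif isinstance(prevalence, (int, float)):
        table = {k: float(prevalence) for k in (2, 3, 4, 5)}
    else:
        table = dict(default)
        table.update({int(k): float(v) for k, v in dict(prevalence).items()})
    for k, p in table.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"interaction prevalence for {k} components not in [0,1]: {p}")
    return table


def _count_weights(weights) -> tuple:
    if weights is None:
        weights = {2: 0.25, 3: 0.25, 4: 0.25, 5: 0.25}
    counts = (2, 3, 4, 5)
    w = np.array([float(weights.get(k, 0.0)) for k in counts])
    if (w < 0).any() or w.sum() <= 0:
        raise ConfigError("component_count_weights must be nonnegative and sum > 0")
    return counts, w / w.sum()


def noise_free_perception(mixture: MixtureSample, library) -> tuple:
    """Noise-free (OI, HT) the panel would report on average, incl. interactions."""
    lib = _library_map(library)
    ois = [lib[n].component_oi(c) for n, c in mixture.concentrations.items() if c > 0]
    hts = [lib[n].component_ht(c) for n, c in mixture.concentrations.items() if c > 0]
    base_oi = math.sqrt(sum(v * v for v in ois))
    amp = 1.0 + (mixture.synergy_factor - 1.0) * mixture.oi_ramp
    oi = float(np.clip(base_oi * amp, *OI_SCALE))
    shrink = 1.0 - (1.0 - mixture.neutralization_factor) * mixture.ht_ramp
    ht = float(np.clip(sum(hts) * shrink, *HT_SCALE))
    return oi, ht


def _component_bounds(spec: CompoundSpec) -> tuple:
    lo, hi = CONC_RANGES[spec.name]
    return spec.component_oi(lo), spec.component_oi(hi)


def _concentration_for_oi(spec: CompoundSpec, oi: float) -> float:
    """Invert the Weber-Fechner law, clipped into the compound's range."""
    conc = spec.perceptual_threshold * 10.0 ** (oi / spec.weber_coeff)
    lo, hi = CONC_RANGES[spec.name]
    return float(np.clip(conc, lo, hi))


def _draw_mixture(rng, names, lib, oi_window, n_direction_tries: int = 60):
    """One designed-intensity composition draw (may be infeasible -> None).

    The target mixture intensity u is uniform over the count's feasible
    window and split over components by a random (Dirichlet) direction on
    the squared intensities — emulating a panel-calibrated sample design
    that covers the whole intensity window at every mixture size, rather
    than concentrations drawn independently (which concentrate the summed
    intensity of large mixtures in a narrow band). Directions are redrawn
    for the same intensity target until every component stays inside its
    concentration range, so the realized intensity distribution stays
    (near-)uniform rather than being thinned where feasible directions are
    scarce (e.g. strong binary mixtures need roughly balanced components).
    """
    k = len(names)
    bounds = [_component_bounds(lib[n]) for n in names]
    u_lo = max(oi_window[0], math.sqrt(sum(b[0] ** 2 for b in bounds)) + 0.05)
    u_hi = min(oi_window[1], math.sqrt(sum(b[1] ** 2 for b in bounds)) - 0.05)
    if u_lo >= u_hi:
        return None
    u = rng.uniform(u_lo, u_hi)
    for _ in range(n_direction_tries):
        direction = rng.dirichlet(np.ones(k))
        ois = u * np.sqrt(direction)
        if all(lo <= oi <= hi for oi, (lo, hi) in zip(ois, bounds)):
            break
    else:
        return None
    conc = {n: _concentration_for_oi(lib[n], oi) for n, oi in zip(names, ois)}
    return u, ois, conc, u_lo, u_hi


def _onset_table(prevalence, library, oi_window, seed=987654321, n_mc=3000):
    """Per-count synergism onsets matching explicit prevalence targets.

    Monte-Carlo quantiles of the designed mixture intensity; prevalence 0
    maps to an unreachable onset, prevalence 1 to an always-active one.
    """
    lib = _library_map(library)
    rng = np.random.default_rng(seed)
    onsets = {}
    for k, p in prevalence.items():
        if p <= 0.0:
            onsets[k] = math.inf
            continue
        if p >= 1.0:
            onsets[k] = -math.inf
            continue
        us = []
        while len(us) < n_mc:
            subset = sorted(rng.choice(len(COMPOUNDS), size=k, replace=False))
            drawn = _draw_mixture(rng, [COMPOUNDS[j] for j in subset], lib, oi_window)
            if drawn is not None:
                us.append(drawn[0])
        onsets[k] = float(np.quantile(us, 1.0 - p))
    return onsets


def generate_mixture_set(
    n_samples: int,
    component_count_weights=None,
    interaction_prevalence=None,
    seed: int = 0,
    library=None,
    synergy_factor: float = 1.3,
    neutralization_factor: float = 0.4,
    synergy_onset: float = DEFAULT_SYNERGY_ONSET,
    onset_width: float = DEFAULT_ONSET_WIDTH,
    ht_ramp_width: float = DEFAULT_HT_RAMP_WIDTH,
    oi_window: tuple = OI_WINDOW,
    ht_window: tuple = HT_WINDOW,
    component_counts=None,
    id_prefix: str = "S",
) -> list:
    """Draw mixture compositions with ground-truth interaction labels.

    Each sample targets a mixture intensity drawn uniformly inside the study
    window and splits it over a random component subset (rejection-sampled
    so every single-component intensity stays inside its concentration
    range and the perceived, post-interaction values stay inside the study
    windows and below the scale ceiling).

    Intensity synergism is level-dependent: the Patte-Laffort intensity is
    amplified by ``synergy_factor`` once it passes ``synergy_onset`` (linear
    ramp of half-width ``onset_width``). Hedonic neutralization requires
    alpha-pinene prominent in its range (threshold set per component count
    from the configured prevalence). ``interaction_prevalence`` may be a
    scalar, a per-count map, or ``{"oi": ..., "ht": ...}``; when an explicit
    intensity-interaction prevalence is given the onset is recalibrated per
    count to the matching intensity quantile, and prevalence 0 disables the
    interaction entirely.
    """
    if n_samples < 1:
        raise ConfigError("n_samples must be >= 1")
    if library is None:
        library = build_compound_library()
    lib = _library_map(library)

    prev_oi = None
    prev_ht = _normalize_prevalence(None, DEFAULT_PREVALENCE_HT)
    if isinstance(interaction_prevalence, dict) and (
        "oi" in interaction_prevalence or "ht" in interaction_prevalence
    ):
        if interaction_prevalence.get("oi") is not None:
            prev_oi = _normalize_prevalence(interaction_prevalence["oi"], {})
        if interaction_prevalence.get("ht") is not None:
            prev_ht = _normalize_prevalence(interaction_prevalence["ht"], DEFAULT_PREVALENCE_HT)
    elif interaction_prevalence is not None:
        prev_oi = _normalize_prevalence(interaction_prevalence, {})
        prev_ht = _normalize_prevalence(interaction_prevalence, DEFAULT_PREVALENCE_HT)

    if prev_oi is None:
        onsets = {k: synergy_onset for k in (2, 3, 4, 5)}
    else:
        onsets = _onset_table(prev_oi, library, oi_window)

    # neutralization thresholds on alpha-pinene's position in its range;
    # the flag also requires alpha-pinene present (probability k/5)
    t_thresh = {}
    for k in (2, 3, 4, 5):
        p = prev_ht[k]
        t_thresh[k] = math.inf if p <= 0.0 else max(0.0, 1.0 - 5.0 * p / k)

    counts, weights = _count_weights(component_count_weights)
    rng = np.random.default_rng(seed)

    if component_counts is not None:
        if len(component_counts) != n_samples:
            raise ConfigError("component_counts length must equal n_samples")
        chosen_counts = [int(c) for c in component_counts]
    else:
        chosen_counts = [int(c) for c in rng.choice(counts, size=n_samples, p=weights)]

    samples = []
    for i, k in enumerate(chosen_counts):
        for _attempt in range(10000):
            subset = sorted(rng.choice(len(COMPOUNDS), size=k, replace=False))
            names = [COMPOUNDS[j] for j in subset]
            drawn = _draw_mixture(rng, names, lib, oi_window)
            if drawn is None:
                continue
            u, ois, conc, u_lo, u_hi = drawn
            hts = [lib[n].component_ht(c) for n, c in conc.items()]

            oi_ramp = _ramp(u, onsets[k], onset_width)
            if "alpha-pinene" in conc and not math.isinf(t_thresh[k]):
                spec = lib["alpha-pinene"]
                b_lo, b_hi = _component_bounds(spec)
                t_pin = (ois[names.index("alpha-pinene")] - b_lo) / (b_hi - b_lo)
                ht_ramp = _ramp(float(t_pin), t_thresh[k], ht_ramp_width)
            else:
                ht_ramp = 0.0

            amp = 1.0 + (synergy_factor - 1.0) * oi_ramp
            shrink = 1.0 - (1.0 - neutralization_factor) * ht_ramp
            mix_oi = u * amp
            mix_ht = sum(hts) * shrink
            # amplified intensity must stay on-scale (no ceiling clipping)
            if mix_oi <= OI_SCALE[1] and ht_window[0] <= mix_ht <= ht_window[1]:
                break
        else:
            raise DataError(f"could not sample a {k}-component mixture inside the windows")

        full_conc = {name: conc.get(name, 0.0) for name in COMPOUNDS}
        samples.append(
            MixtureSample(
                sample_id=f"{id_prefix}{i:04d}",
                concentrations=full_conc,
                n_components=k,
                truth_oi_interaction="synergism" if oi_ramp >= 0.5 else "none",
                truth_ht_interaction="neutralization" if ht_ramp >= 0.5 else "none",
                synergy_factor=synergy_factor,
                neutralization_factor=neutralization_factor,
                oi_ramp=oi_ramp,
                ht_ramp=ht_ramp,
            )
        )
    return samples


def simulate_sensor_array(
    mixture: MixtureSample,
    library=None,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> SensorVector:
    """8-channel array response: summed per-compound power laws, relative noise."""
    if library is None:
        library = build_compound_library()
    lib = _library_map(library)
    for name, conc in mixture.concentrations.items():
        if conc > 0 and name not in lib:
            raise DataError(f"unknown compound in mixture: {name}")
    rng = np.random.default_rng(seed)
    response = np.zeros(N_CHANNELS)
    for name, conc in mixture.concentrations.items():
        if conc <= 0:
            continue
        spec = lib[name]
        aff = np.asarray(spec.sensor_affinity)
        exp = np.asarray(spec.sensor_exponent)
        response += aff * conc ** exp
    if noise_sd > 0:
        response = response * (1.0 + rng.normal(0.0, noise_sd, size=N_CHANNELS))
    return SensorVector(sample_id=mixture.sample_id, channels=tuple(float(v) for v in response))


def simulate_panel_scores(
    mixture: MixtureSample,
    library=None,
    assessor_noise_sd: float = 0.25,
    seed: int = 0,
    n_assessors: int = N_ASSESSORS,
    complexity_noise_slope: float = DEFAULT_COMPLEXITY_NOISE_SLOPE,
) -> PanelScore:
    """Discrete VDI 3940 scores from ``n_assessors`` assessors plus their means.

    Each assessor reports ``round(value + Normal(0, sd))`` clipped to the
    verbal scale, where ``sd`` is the base ``assessor_noise_sd`` scaled up
    with mixture complexity (``1 + complexity_noise_slope*(k-2)`` for a
    k-component sample): panels rate complex mixtures less consistently.
    Discretization is part of the stochastic assessor model, so in the exact
    zero-noise limit the idealized panel reports the continuous perceived
    value (no rounding).
    """
    if assessor_noise_sd < 0:
        raise ConfigError("assessor_noise_sd must be >= 0")
    if library is None:
        library = build_compound_library()
    oi_true, ht_true = noise_free_perception(mixture, library)
    assessor_noise_sd = assessor_noise_sd * (
        1.0 + complexity_noise_slope * (mixture.n_components - 2)
    )
    if assessor_noise_sd == 0:
        oi = float(np.clip(oi_true, *OI_SCALE))
        ht = float(np.clip(ht_true, *HT_SCALE))
        return PanelScore(
            per_assessor_oi=(oi,) * n_assessors,
            per_assessor_ht=(ht,) * n_assessors,
            oi_mean=oi,
            ht_mean=ht,
        )
    rng = np.random.default_rng(seed)
    oi_scores = []
    ht_scores = []
    for _ in range(n_assessors):
        oi = round(oi_true + rng.normal(0.0, assessor_noise_sd))
        ht = round(ht_true + rng.normal(0.0, assessor_noise_sd))
        oi_scores.append(int(np.clip(oi, *OI_SCALE)))
        ht_scores.append(int(np.clip(ht, *HT_SCALE)))
    return PanelScore(
        per_assessor_oi=tuple(oi_scores),
        per_assessor_ht=tuple(ht_scores),
        oi_mean=float(np.mean(oi_scores)),
        ht_mean=float(np.mean(ht_scores)),
    )


def _stratified_counts(n: int, rng: np.random.Generator) -> list:
    """n component counts with sizes as equal as possible, shuffled."""
    base = [2, 3, 4, 5] * (n // 4)
    extra = list(rng.choice([2, 3, 4, 5], size=n % 4, replace=False)) if n % 4 else []
    counts = base + [int(e) for e in extra]
    rng.shuffle(counts)
    return counts


def generate_study(
    config: StudyConfig | None = None,
    seed: int = 0,
    library=None,
    out_dir=None,
) -> StudyDataset:
    """Compose the generators into a two-phase (train_val/test) dataset."""
    if config is None:
        config = StudyConfig()
    if library is None:
        library = build_compound_library()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] & _SEED_MASK) for s in ss.spawn(4)]
    mix_seed_train, mix_seed_test, sensor_seed, panel_seed = seeds

    prevalence = None
    if config.prevalence_oi is not None or config.prevalence_ht is not None:
        prevalence = {"oi": config.prevalence_oi, "ht": config.prevalence_ht}

    def _phase(n, mix_seed, prefix):
        if n == 0:
            return ()
        counts = None
        if config.stratify_counts:
            counts = _stratified_counts(n, np.random.default_rng(mix_seed + 1))
        mixtures = generate_mixture_set(
            n,
            component_count_weights=config.component_count_weights,
            interaction_prevalence=prevalence,
            seed=mix_seed,
            library=library,
            synergy_factor=config.synergy_factor,
            neutralization_factor=config.neutralization_factor,
            synergy_onset=config.synergy_onset,
            onset_width=config.onset_width,
            ht_ramp_width=config.ht_ramp_width,
            component_counts=counts,
            id_prefix=prefix,
        )
        records = []
        for j, mix in enumerate(mixtures):
            sv = simulate_sensor_array(
                mix, library, noise_sd=config.sensor_noise_sd,
                seed=(sensor_seed + 7919 * j + (0 if prefix == "TR" else 104729)) & _SEED_MASK,
            )
            ps = simulate_panel_scores(
                mix, library, assessor_noise_sd=config.assessor_noise_sd,
                seed=(panel_seed + 7919 * j + (0 if prefix == "TR" else 104729)) & _SEED_MASK,
                complexity_noise_slope=config.complexity_noise_slope,
            )
            records.append(SampleRecord(mixture=mix, sensors=sv, panel=ps))
        return tuple(records)

    dataset = StudyDataset(
        train_val_samples=_phase(config.n_train, mix_seed_train, "TR"),
        test_samples=_phase(config.n_test, mix_seed_test, "TE"),
        seed=seed,
    )
    if out_dir is not None:
        from .io_tables import write_study  # local import: avoid cycle

        write_study(dataset, out_dir)
    return dataset


def with_sample_id(mixture: MixtureSample, sample_id: str) -> MixtureSample:
    return replace(mixture, sample_id=sample_id)
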