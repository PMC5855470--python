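"""Synthetic study generator: compound library, mixtures, sensors, panel."""

import math

import numpy as np
import pytest

from odormix.errors import ConfigError
from odormix.synthetic import (
    CHANNELS,
    COMPOUNDS,
    CONC_RANGES,
    CompoundSpec,
    MixtureSample,
    StudyConfig,
    build_compound_library,
    generate_mixture_set,
    generate_study,
    noise_free_perception,
    simulate_panel_scores,
    simulate_sensor_array,
)


def make_compound(name="toluene", weber=2.0, threshold=1.0, hedonic=-1.0,
                  affinity=(1.0,) * 8, exponent=(1.0,) * 8):
    return CompoundSpec(
        name=name,
        odour_threshold_aq=threshold,
        weber_coeff=weber,
        hedonic_unit=hedonic,
        sensor_affinity=affinity,
        sensor_exponent=exponent,
        perceptual_threshold=threshold,
    )


class TestCompoundLibrary:
    def test_five_unique_compounds(self, library):
        assert len(library) == 5
        assert len({s.name for s in library}) == 5

    @pytest.mark.parametrize(
        "name,threshold",
        [("alpha-pinene", 4.2), ("acetone", 20.0), ("toluene", 0.042),
         ("triethylamine", 0.42), ("n-butanol", 7.1)],
    )
    def test_literature_aqueous_thresholds(self, library, name, threshold):
        spec = next(s for s in library if s.name == name)
        assert spec.odour_threshold_aq == threshold

    def test_hedonic_signs(self, library):
        units = {s.name: s.hedonic_unit for s in library}
        assert units["alpha-pinene"] > 0 and units["toluene"] > 0
        assert units["triethylamine"] < 0 and units["n-butanol"] < 0
        assert units["acetone"] <= 0

    def test_intensity_spans_range(self, library):
        # each compound runs ~0.3 -> 4.0 intensity over its concentration range
        for spec in library:
            lo, hi = CONC_RANGES[spec.name]
            assert spec.component_oi(lo) == pytest.approx(0.3, abs=1e-9)
            assert spec.component_oi(hi) == pytest.approx(4.0, abs=1e-9)

    def test_weber_law_examples(self):
        spec = make_compound(weber=2.0, threshold=5.0)
        assert spec.component_oi(5.0) == 0.0  # log10(1) = 0 at the threshold
        assert spec.component_oi(50.0) == pytest.approx(2.0)  # one decade, k=2


class TestMixtureGeneration:
    def test_counts_and_ranges(self, library):
        samples = generate_mixture_set(150, seed=1, library=library)
        assert len(samples) == 150
        for m in samples:
            nonzero = [(n, c) for n, c in m.concentrations.items() if c > 0]
            assert 2 <= len(nonzero) <= 5
            assert len(nonzero) == m.n_components
            for name, conc in nonzero:
                lo, hi = CONC_RANGES[name]
                assert lo <= conc <= hi

    def test_zero_prevalence_means_no_flags(self, library):
        samples = generate_mixture_set(
            10, component_count_weights={2: 1.0}, interaction_prevalence=0.0,
            seed=7, library=library,
        )
        assert len(samples) == 10
        assert all(m.n_components == 2 for m in samples)
        assert all(m.truth_oi_interaction == "none" for m in samples)
        assert all(m.truth_ht_interaction == "none" for m in samples)

    def test_seeded_determinism(self, library):
        a = generate_mixture_set(25, seed=42, library=library)
        b = generate_mixture_set(25, seed=42, library=library)
        assert a == b

    def test_invalid_weights_rejected(self, library):
        with pytest.raises(ConfigError):
            generate_mixture_set(5, component_count_weights={2: -1.0}, library=library)

    def test_neutralization_requires_pinene(self, library):
        samples = generate_mixture_set(200, seed=3, library=library)
        for m in samples:
            if m.truth_ht_interaction == "neutralization":
                assert m.concentrations["alpha-pinene"] > 0


class TestSensorArray:
    def test_no_analyte_no_signal(self, library):
        m = MixtureSample("Z0", dict.fromkeys(COMPOUNDS, 0.0), 2)
        sv = simulate_sensor_array(m, library, noise_sd=0.0)
        assert all(c == 0.0 for c in sv.channels)

    def test_linear_channel_doubles(self):
        lib = [
            make_compound("toluene", affinity=(0.1,) * 8),
            make_compound("acetone", threshold=200.0, affinity=(0.0,) * 8),
        ]
        base = {n: 0.0 for n in COMPOUNDS}
        m1 = MixtureSample("L1", {**base, "toluene": 10.0, "acetone": 300.0}, 2)
        m2 = MixtureSample("L2", {**base, "toluene": 20.0, "acetone": 300.0}, 2)
        r1 = simulate_sensor_array(m1, lib, noise_sd=0.0).as_array()
        r2 = simulate_sensor_array(m2, lib, noise_sd=0.0).as_array()
        np.testing.assert_allclose(r2, 2 * r1)

    def test_noise_is_zero_mean(self, library):
        m = generate_mixture_set(1, seed=5, library=library)[0]
        clean = simulate_sensor_array(m, library, noise_sd=0.0).as_array()
        means = []
        for seed in (3, 4):
            draws = np.stack([
                simulate_sensor_array(m, library, noise_sd=0.05, seed=seed * 100000 + i).as_array()
                for i in range(1000)
            ])
            means.append(draws.mean(axis=0))
        se = 0.05 * np.abs(clean) / np.sqrt(1000)
        assert not np.allclose(means[0], means[1])
        for mean in means:
            assert np.all(np.abs(mean - clean) < 3 * se + 1e-12)


class TestPanelScores:
    def test_component_at_threshold_scores_zero(self):
        lib = [make_compound("toluene", threshold=5.0),
               make_compound("acetone", threshold=200.0)]
        base = {n: 0.0 for n in COMPOUNDS}
        m = MixtureSample("P0", {**base, "toluene": 5.0, "acetone": 200.0}, 2)
        oi, _ = noise_free_perception(m, lib)
        assert oi == 0.0

    def _pair_345_library(self):
        # toluene at 10 ppm -> OI 3, acetone at 2000 ppm -> OI 4 (k=2, one/two decades)
        return [
            make_compound("toluene", weber=3.0, threshold=1.0),
            make_compound("acetone", weber=2.0, threshold=20.0),
        ]

    def test_euclidean_pair_345(self):
        lib = self._pair_345_library()
        base = {n: 0.0 for n in COMPOUNDS}
        m = MixtureSample("P1", {**base, "toluene": 10.0, "acetone": 2000.0}, 2)
        score = simulate_panel_scores(m, lib, assessor_noise_sd=0.0)
        assert score.oi_mean == pytest.approx(5.0)

    def test_synergy_multiplier_then_clip(self):
        lib = self._pair_345_library()
        base = {n: 0.0 for n in COMPOUNDS}
        m = MixtureSample(
            "P2", {**base, "toluene": 10.0, "acetone": 2000.0}, 2,
            truth_oi_interaction="synergism", synergy_factor=1.2, oi_ramp=1.0,
        )
        score = simulate_panel_scores(m, lib, assessor_noise_sd=0.0)
        assert score.oi_mean == pytest.approx(6.0)  # 5 * 1.2, at the scale edge

    def test_noisy_scores_are_integers_in_range(self, library):
        mixtures = generate_mixture_set(50, seed=9, library=library)
        for i, m in enumerate(mixtures):
            s = simulate_panel_scores(m, library, assessor_noise_sd=0.5, seed=i)
            assert all(isinstance(v, int) and 0 <= v <= 6 for v in s.per_assessor_oi)
            assert all(isinstance(v, int) and -4 <= v <= 4 for v in s.per_assessor_ht)
            assert s.oi_mean == pytest.approx(np.mean(s.per_assessor_oi))
            assert s.ht_mean == pytest.approx(np.mean(s.per_assessor_ht))


class TestGeneratorProperties:
    def test_panel_means_in_scale_ranges(self, library):
        rng = np.random.default_rng(0)
        mixtures = generate_mixture_set(250, seed=21, library=library)
        for i, m in enumerate(mixtures * 4):  # 1000 noisy panel draws
            sd = float(rng.uniform(0.0, 1.0))
            s = simulate_panel_scores(m, library, assessor_noise_sd=sd, seed=i)
            assert 0.0 <= s.oi_mean <= 6.0
            assert -4.0 <= s.ht_mean <= 4.0

    def test_null_matches_euclidean_additivity(self, library):
        mixtures = generate_mixture_set(
            60, interaction_prevalence=0.0, seed=13, library=library
        )
        lib = {s.name: s for s in library}
        for m in mixtures:
            ois = [lib[n].component_oi(c) for n, c in m.concentrations.items() if c > 0]
            expected = math.sqrt(sum(v * v for v in ois))
            oi, _ = noise_free_perception(m, library)
            assert oi == pytest.approx(min(expected, 6.0), abs=1e-12)

    def test_increasing_concentration_never_decreases_oi(self, library):
        mixtures = generate_mixture_set(40, seed=17, library=library)
        for m in mixtures:
            base_oi, _ = noise_free_perception(m, library)
            name = m.present[0]
            lo, hi = CONC_RANGES[name]
            bumped = dict(m.concentrations)
            bumped[name] = min(hi, bumped[name] * 1.2)
            m2 = MixtureSample(
                "B" + m.sample_id, bumped, m.n_components,
                m.truth_oi_interaction, m.truth_ht_interaction,
                m.synergy_factor, m.neutralization_factor, m.oi_ramp, m.ht_ramp,
            )
            oi2, _ = noise_free_perception(m2, library)
            assert oi2 >= base_oi - 1e-12


class TestStudyComposition:
    def test_default_sizes_and_disjoint_ids(self, library):
        ds = generate_study(seed=0, library=library)
        assert len(ds.train_val_samples) == 150
        assert len(ds.test_samples) == 80
        ids_a = {r.mixture.sample_id for r in ds.train_val_samples}
        ids_b = {r.mixture.sample_id for r in ds.test_samples}
        assert not ids_a & ids_b

    def test_empty_test_phase(self, library):
        ds = generate_study(StudyConfig(n_train=12, n_test=0), seed=2, library=library)
        assert len(ds.test_samples) == 0
        assert len(ds.train_val_samples) == 12

    def test_seed_repeat_gives_identical_csv(self, library, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_study(StudyConfig(n_train=16, n_test=8), seed=5, library=library, out_dir=d1)
        generate_study(StudyConfig(n_train=16, n_test=8), seed=5, library=library, out_dir=d2)
        for sub in ("train", "test"):
            for name in ("samples.csv", "sensors.csv", "panel.csv"):
                assert (d1 / sub / name).read_bytes() == (d2 / sub / name).read_bytes()

    def test_channel_names(self):
        assert CHANNELS == (
            "MiniPID", "FECS44", "FECS50", "TGS2600",
            "TGS823", "TGS2602", "TGS2603", "TGS8100",
        )
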