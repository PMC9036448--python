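import numpy as np
import pandas as pd
import pytest

from spectraits.spectra_io import LAYERS, STAGES
from spectraits.synthetic_data import (
    LatentLeafState, TrialConfig, default_wavelengths, generate_field_trial,
    spectral_forward_model, trait_from_latents, _TARGETS,
)


def _state_at_cell_means(config, layer, stage):
    return LatentLeafState(
        chlorophyll=config.cell("SPAD", layer, stage)[0] / 50.0,
        nitrogen=config.cell("N", layer, stage)[0],
        water=1.0,
        dry_matter=config.cell("LMA", layer, stage)[0] / 0.05,
    )


class TestConfig:
    def test_defaults_hold_all_traits_and_cells(self):
        config = TrialConfig()
        for trait in _TARGETS:
            for stage in STAGES:
                for layer in LAYERS:
                    mean, sd = config.cell(trait, layer, stage)
                    assert sd >= 0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="layers"):
            TrialConfig(layers=("bottom", "middle", "top"))
        with pytest.raises(ValueError, match="unknown trait"):
            TrialConfig(trait_means={"NotATrait": {("top", "InB"): 1.0}})
        with pytest.raises(ValueError, match="positive"):
            TrialConfig(n_genotypes=0)
        with pytest.raises(ValueError, match="negative SD"):
            TrialConfig(trait_sds={"Asat": {("top", "InB"): -1.0}})

    def test_yaml_round_trip(self, tmp_path):
        config = TrialConfig(n_genotypes=5, seed=9, rue_true=2.7)
        path = tmp_path / "trial.yaml"
        config.to_yaml(path)
        back = TrialConfig.from_yaml(path)
        assert back == config


class TestForwardModel:
    def test_zero_latents_returns_baseline(self):
        state = LatentLeafState(0.0, 0.0, 0.0, 0.0)
        refl = spectral_forward_model(state, noise_sd=0.0)
        wl = default_wavelengths()
        np.testing.assert_allclose(refl, 0.50 - 0.10 * (wl - 350) / 2150)

    def test_more_chlorophyll_darkens_red_band(self):
        lo = LatentLeafState(0.5, 4.0, 1.0, 1.0)
        hi = LatentLeafState(1.0, 4.0, 1.0, 1.0)
        wl = default_wavelengths()
        i670 = int(np.flatnonzero(wl == 670)[0])
        r_lo = spectral_forward_model(lo)[i670]
        r_hi = spectral_forward_model(hi)[i670]
        assert r_hi < r_lo

    def test_noiseless_calls_identical(self):
        state = LatentLeafState(0.9, 4.2, 1.0, 1.0)
        np.testing.assert_array_equal(spectral_forward_model(state),
                                      spectral_forward_model(state))

    def test_negative_latent_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            LatentLeafState(-0.1, 4.0, 1.0, 1.0)

    def test_noise_requires_rng(self):
        with pytest.raises(ValueError, match="rng"):
            spectral_forward_model(LatentLeafState(1, 4, 1, 1), noise_sd=0.01)


class TestTraitMap:
    def test_deterministic_pure_function(self):
        config = TrialConfig()
        state = LatentLeafState(0.93, 4.3, 1.0, 1.05)
        a = trait_from_latents(state, "middle", "InB", config)
        b = trait_from_latents(state, "middle", "InB", config)
        assert a == b

    def test_grain_filling_asat_gradient_top_down(self):
        config = TrialConfig()
        values = [trait_from_latents(_state_at_cell_means(config, l, "A7"),
                                     l, "A7", config)["Asat"]
                  for l in LAYERS]
        assert values[0] > values[1] > values[2]

    def test_booting_middle_exceeds_top(self):
        config = TrialConfig()
        asat = {l: trait_from_latents(_state_at_cell_means(config, l, "InB"),
                                      l, "InB", config)["Asat"]
                for l in LAYERS}
        assert asat["middle"] > asat["top"]

    def test_unknown_layer_rejected(self):
        config = TrialConfig()
        with pytest.raises(ValueError, match="unknown layer"):
            trait_from_latents(LatentLeafState(1, 4, 1, 1), "apex", "InB",
                               config)


class TestTrialGeneration:
    def test_default_sample_count(self, default_trial):
        _, (spectra, traits, _, _) = default_trial
        assert spectra.n_samples == 11 * 3 * 3 * 2 * 3 == 594
        assert len(traits.data) == 594 * 10

    def test_same_seed_bit_identical(self):
        config = TrialConfig(n_genotypes=3, n_reps=2, years=("Y1",), seed=17)
        s1, t1, w1, b1 = generate_field_trial(config)
        s2, t2, w2, b2 = generate_field_trial(config)
        np.testing.assert_array_equal(s1.reflectance, s2.reflectance)
        pd.testing.assert_frame_equal(t1.data, t2.data)
        pd.testing.assert_frame_equal(w1.data, w2.data)
        pd.testing.assert_frame_equal(b1, b2)

    def test_reflectance_bounded(self, default_trial):
        _, (spectra, _, _, _) = default_trial
        assert spectra.reflectance.min() >= 0.0
        assert spectra.reflectance.max() <= 1.0

    def test_cell_means_calibrated(self):
        """Every trait x layer x stage mean sits within 3 standard errors of
        its target, where the SE accounts for the shared genotype and year
        effects (which do not average out at 1/sqrt(n))."""
        config = TrialConfig(seed=11, n_reps=7)   # 231 samples per cell
        spectra, traits, _, _ = generate_field_trial(config)
        meta = spectra.meta.set_index("sample_id")
        fg, fy = config.genotype_effect_frac, config.year_effect_frac
        G, Y = config.n_genotypes, len(config.years)
        for trait in _TARGETS:
            values = traits.trait(trait)
            for stage in STAGES:
                for layer in LAYERS:
                    sel = (meta["layer"] == layer) & (meta["stage"] == stage)
                    v = values.loc[meta.index[sel]]
                    mean, sd = config.cell(trait, layer, stage)
                    se = sd * np.sqrt(2 * (fg ** 2 / G + fy ** 2 / Y)
                                      + 1.0 / len(v))
                    assert abs(v.mean() - mean) <= 3 * se, \
                        f"{trait} {layer} {stage}"

    def test_booting_top_asat_near_target(self, default_trial):
        config, (spectra, traits, _, _) = default_trial
        meta = spectra.meta.set_index("sample_id")
        sel = (meta["layer"] == "top") & (meta["stage"] == "InB")
        v = traits.trait("Asat").loc[meta.index[sel]]
        se = 3.07 * np.sqrt(2 * (0.4 ** 2 / 11 + 0.3 ** 2 / 3) + 1 / len(v))
        assert abs(v.mean() - 25.5) <= 2 * se

    def test_chlorophyll_latent_tracks_spad(self, default_trial):
        _, (spectra, traits, _, _) = default_trial
        spad = traits.trait("SPAD").loc[spectra.meta["sample_id"]]
        r = np.corrcoef(spectra.meta["chlorophyll"], spad)[0, 1]
        assert r > 0.8

    def test_asat_gs_positively_correlated_within_cell(self, default_trial):
        _, (spectra, traits, _, _) = default_trial
        meta = spectra.meta.set_index("sample_id")
        sel = (meta["layer"] == "middle") & (meta["stage"] == "InB")
        ids = meta.index[sel]
        a = traits.trait("Asat").loc[ids]
        g = traits.trait("gs").loc[ids]
        assert np.corrcoef(a, g)[0, 1] > 0.1

    def test_biomass_exact_without_noise(self):
        config = TrialConfig(n_genotypes=3, n_reps=1, years=("Y1",),
                             biomass_cv=0.0, seed=2)
        _, _, _, biomass = generate_field_trial(config)
        np.testing.assert_allclose(biomass["biomass"],
                                   biomass["rue_true"] * biomass["cum_ipar"],
                                   rtol=1e-12)

    def test_weather_dates_increase_and_irradiance_positive(self, small_trial):
        _, (_, _, weather, _) = small_trial
        assert weather.data["date"].is_monotonic_increasing
        assert (weather.data["irradiance"] > 0).all()
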