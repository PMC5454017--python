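import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluorospec import pipeline
from fluorospec.photophysics import PhotophysicsParams, fret_efficiency
from fluorospec.synthetic_data import (
    STANDARD_EXCITATIONS,
    FluorophoreBand,
    SimulationConfig,
    band_profile,
    default_presets,
    effective_amplitudes,
    simulate_group,
    simulate_spectrum,
)


def single_band_config(**overrides):
    kwargs = dict(
        excitation_nm=266,
        condition="AD",
        grid=(280.0, 650.0, 1.0),
        band_amplitudes={"tryptophan": 1.0},
        photophysics={"tryptophan": PhotophysicsParams(r0=3.0, r=4.8)},
        replicate_cv=0.0,
        noise_sd=0.0,
        seed=0,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


class TestBandProfile:
    def test_argmax_at_center(self):
        band = FluorophoreBand("NADH", 435.0, 40.0)
        grid = np.arange(300.0, 651.0, 1.0)
        profile = band_profile(band, grid)
        assert grid[np.argmax(profile)] == 435.0
        assert profile.max() == 1.0

    def test_gaussian_value_at_one_sigma(self):
        band = FluorophoreBand("NADH", 435.0, 40.0)
        grid = np.arange(300.0, 651.0, 1.0)
        profile = band_profile(band, grid)
        value = profile[np.where(grid == 475.0)[0][0]]
        assert value == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_gaussian_symmetry(self):
        band = FluorophoreBand("tryptophan", 430.0, 25.0)
        grid = np.arange(300.0, 651.0, 2.0)
        profile = band_profile(band, grid)
        left = profile[np.where(grid == 420.0)[0][0]]
        right = profile[np.where(grid == 440.0)[0][0]]
        assert left == pytest.approx(right, rel=1e-12)

    def test_values_in_unit_interval(self):
        band = FluorophoreBand("FAD", 557.0, 30.0, shape="lognormal")
        profile = band_profile(band, np.arange(350.0, 651.0, 2.0))
        assert profile.min() >= 0.0
        assert profile.max() == 1.0

    def test_lognormal_mode_at_center(self):
        band = FluorophoreBand("NADH", 462.0, 35.0, shape="lognormal")
        grid = np.arange(352.0, 651.0, 2.0)
        profile = band_profile(band, grid)
        assert grid[np.argmax(profile)] == 462.0

    def test_center_outside_grid_warns(self):
        band = FluorophoreBand("tryptophan", 331.0, 25.0)
        with pytest.warns(UserWarning, match="outside"):
            band_profile(band, np.arange(400.0, 651.0, 2.0))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"name": "x", "center_nm": 200.0, "width_nm": 10.0},
            {"name": "x", "center_nm": 400.0, "width_nm": 0.0},
            {"name": "x", "center_nm": 400.0, "width_nm": 10.0, "shape": "boxcar"},
        ],
    )
    def test_invalid_band_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FluorophoreBand(**kwargs)


class TestSimulateSpectrum:
    def test_degenerate_config_is_pure_band(self):
        config = single_band_config()
        spectrum = simulate_spectrum(config, 1)
        band = config.resolved_bands()[0]
        expected = band_profile(band, config.wavelength_grid())
        assert np.allclose(spectrum.intensities, expected, atol=1e-12)
        grid = config.wavelength_grid()
        assert grid[np.argmax(spectrum.intensities)] == 331.0

    def test_fret_off_matches_no_acceptor_case(self):
        # r >> r0 makes the transfer negligible
        far = PhotophysicsParams(r0=3.0, r=300.0)
        with_acceptor = single_band_config(
            band_amplitudes={"tryptophan": 1.0, "NADH": 0.0},
            photophysics={"tryptophan": far},
        )
        without = single_band_config(photophysics={"tryptophan": far})
        a = simulate_spectrum(with_acceptor, 1)
        b = simulate_spectrum(without, 1)
        trp = pytest.approx(1.0, abs=1e-10)
        grid = with_acceptor.wavelength_grid()
        idx = np.where(grid == 331.0)[0][0]
        assert a.intensities[idx] == trp
        assert b.intensities[idx] == trp

    def test_determinism(self):
        config = default_presets(266, "AD", seed=11)
        assert simulate_spectrum(config, 2) == simulate_spectrum(config, 2)

    def test_replicates_differ_when_noisy(self):
        config = default_presets(266, "AD", seed=11)
        a, b = simulate_spectrum(config, 1), simulate_spectrum(config, 2)
        assert not np.array_equal(a.intensities, b.intensities)

    def test_unknown_excitation_needs_custom_bands(self):
        with pytest.raises(ValueError, match="band"):
            SimulationConfig(excitation_nm=488, condition="AD",
                             band_amplitudes={"FAD": 1.0})
        config = SimulationConfig(
            excitation_nm=488,
            condition="AD",
            grid=(500.0, 650.0, 1.0),
            band_amplitudes={"FAD": 1.0},
            bands=[FluorophoreBand("FAD", 557.0, 30.0)],
            replicate_cv=0.0,
            noise_sd=0.0,
        )
        spectrum = simulate_spectrum(config, 1)
        assert spectrum.wavelengths[np.argmax(spectrum.intensities)] == 557.0

    def test_noise_free_replicates_identical(self):
        config = replace(default_presets(300, "N", seed=5), noise_sd=0.0, replicate_cv=0.0)
        group = simulate_group(config)
        ref = group.spectra[0].intensities
        for spec in group:
            assert np.array_equal(spec.intensities, ref)

    def test_donor_monotone_in_distance(self):
        # larger donor-acceptor distance -> brighter donor, less acceptor enhancement
        def peaks(r):
            config = single_band_config(
                band_amplitudes={"tryptophan": 1.0, "NADH": 0.2},
                photophysics={"tryptophan": PhotophysicsParams(r0=3.0, r=r)},
            )
            amps = effective_amplitudes(config)
            return amps["tryptophan"], amps["NADH"]

        radii = [3.0, 3.5, 4.0, 4.5, 5.0]
        donor = [peaks(r)[0] for r in radii]
        acceptor = [peaks(r)[1] for r in radii]
        assert all(a < b for a, b in zip(donor, donor[1:]))
        assert all(a > b for a, b in zip(acceptor, acceptor[1:]))

    def test_clipping_inactive_at_moderate_noise(self):
        # additive noise below 5% never drives the band cores (amplitudes
        # >= 0.1) negative; far tails where the signal itself vanishes are
        # exempt -- additive noise is always clipped there eventually
        config0 = default_presets(266, "N")
        centers = {b.name: (b.center_nm, b.width_nm) for b in config0.resolved_bands()}
        for seed in range(20):
            config = replace(config0, noise_sd=0.04, seed=seed)
            group = simulate_group(config)
            for spec in group:
                assert np.all(spec.intensities >= 0)
                for name, amp in config.band_amplitudes.items():
                    if amp < 0.1:
                        continue
                    center, width = centers[name]
                    core = np.abs(spec.wavelengths - center) < 1.5 * width
                    assert np.all(spec.intensities[core] > 0), (seed, name)


class TestSimulateGroup:
    def test_group_shape(self):
        group = simulate_group(default_presets(266, "AD", seed=3))
        assert len(group) == 5
        assert [s.replicate_id for s in group] == ["1", "2", "3", "4", "5"]
        for spec in group:
            assert np.array_equal(spec.wavelengths, group.wavelengths)

    def test_seed_streams_isolated_per_condition(self):
        ad = simulate_group(default_presets(266, "AD", seed=7))
        n = simulate_group(default_presets(266, "N", seed=7))
        assert not np.allclose(ad.spectra[0].intensities, n.spectra[0].intensities)

    def test_adding_replicates_preserves_existing(self):
        config = default_presets(266, "AD", seed=9)
        five = simulate_group(config)
        config7 = replace(config, n_replicates=7)
        seven = simulate_group(config7)
        for a, b in zip(five, seven):
            assert np.array_equal(a.intensities, b.intensities)

    def test_calibration_against_published_means(self):
        # mean Trp/NADH ratio at 266 nm over 200 seeds within +/-0.4 of the
        # published 3.73 (AD) and 2.93 (N)
        num, den = pipeline.ratio_pair(266)
        for condition, target in (("AD", 3.73), ("N", 2.93)):
            means = []
            for seed in range(200):
                group = simulate_group(default_presets(266, condition, seed=seed))
                means.append(pipeline.ratio_statistic(group, num, den).mean)
            assert abs(float(np.mean(means)) - target) < 0.4


class TestParameterRecovery:
    def test_ratio_recovery_bias_below_2pct(self):
        # average-then-extract (the analysis order used on real scans):
        # mean over 500 seeds converges to the noiseless implied ratio
        num, den = pipeline.ratio_pair(266)
        for condition in ("AD", "N"):
            base = default_presets(266, condition)
            noiseless = replace(base, noise_sd=0.0, replicate_cv=0.0)
            ref = simulate_spectrum(noiseless, 1)
            implied = (
                pipeline.extract_peak(ref, num).intensity
                / pipeline.extract_peak(ref, den).intensity
            )
            estimates = []
            for seed in range(500):
                config = replace(base, noise_sd=0.01, seed=seed)
                mean_spectrum, _ = pipeline.average_group(simulate_group(config))
                estimates.append(
                    pipeline.extract_peak(mean_spectrum, num).intensity
                    / pipeline.extract_peak(mean_spectrum, den).intensity
                )
            bias = abs(float(np.mean(estimates)) / implied - 1.0)
            assert bias < 0.02, f"{condition}: bias {bias:.3%}"


class TestDefaultPresets:
    def test_ad_tryptophan_amplitude_about_double_n(self):
        ad = default_presets(266, "AD").band_amplitudes["tryptophan"]
        n = default_presets(266, "N").band_amplitudes["tryptophan"]
        assert 1.8 < ad / n < 2.2

    def test_ad_nadh_amplitude_about_1p65x_n_at_340(self):
        ad = default_presets(340, "AD").band_amplitudes["NADH"]
        n = default_presets(340, "N").band_amplitudes["NADH"]
        assert ad / n == pytest.approx(1.65, abs=0.01)

    @pytest.mark.parametrize("excitation", STANDARD_EXCITATIONS)
    def test_ad_distance_exceeds_n(self, excitation):
        ad = default_presets(excitation, "AD")
        n = default_presets(excitation, "N")
        for name in ad.photophysics:
            assert ad.photophysics[name].r > n.photophysics[name].r
            assert ad.photophysics[name].knr < n.photophysics[name].knr

    @pytest.mark.parametrize("excitation", STANDARD_EXCITATIONS)
    def test_ad_amplitudes_exceed_n(self, excitation):
        ad = default_presets(excitation, "AD").band_amplitudes
        n = default_presets(excitation, "N").band_amplitudes
        for name in ad:
            assert ad[name] > n[name]

    def test_unknown_excitation_rejected(self):
        with pytest.raises(ValueError):
            default_presets(500, "AD")

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            default_presets(266, "XX")

    def test_nadh_center_follows_excitation(self):
        centers = {
            ex: {b.name: b.center_nm for b in default_presets(ex, "AD").resolved_bands()}
            for ex in STANDARD_EXCITATIONS
        }
        assert centers[266]["NADH"] == 435.0
        assert centers[300]["NADH"] == 492.0
        assert centers[340]["NADH"] == 462.0
        assert centers[266]["tryptophan"] == 331.0
        assert centers[340]["FAD"] == 557.0


class TestConfigYaml:
    def test_roundtrip(self):
        config = default_presets(300, "N", seed=42)
        assert SimulationConfig.from_yaml(config.to_yaml()) == config

    def test_roundtrip_with_custom_bands(self):
        config = SimulationConfig(
            excitation_nm=488,
            condition="other",
            grid=(500.0, 650.0, 1.0),
            band_amplitudes={"FAD": 0.4},
            bands=[FluorophoreBand("FAD", 557.0, 30.0, shape="lognormal")],
        )
        assert SimulationConfig.from_yaml(config.to_yaml()) == config

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_seed_roundtrip(self, seed):
        config = default_presets(266, "AD", seed=seed)
        assert SimulationConfig.from_yaml(config.to_yaml()).seed == seed

    @pytest.mark.parametrize(
        "overrides",
        [
            {"n_replicates": 0},
            {"replicate_cv": -0.1},
            {"noise_sd": -0.1},
            {"grid": (650.0, 300.0, 2.0)},
            {"grid": (300.0, 650.0, 0.0)},
        ],
    )
    def test_invalid_config_rejected(self, overrides):
        with pytest.raises(ValueError):
            single_band_config(**overrides)
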