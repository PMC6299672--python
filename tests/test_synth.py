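"""Synthetic generator: determinism, closed forms, population statistics."""

import dataclasses

import numpy as np
import pytest

from nirsfq import ConfigurationError, SimulationConfig, make_component_library, simulate_dataset
from nirsfq.datasets import COMPOSITION_INDICATORS
from nirsfq.synth import (
    INFORMATIVE_WINDOW,
    MATRIX,
    WATER,
    WATER_BAND,
    IndicatorDistribution,
    _truncated_normal,
)


def library_components(lib):
    return set(lib.bands)


class TestComponentLibrary:
    def test_grid_spans_range_with_requested_points(self):
        lib = make_component_library(seed=1, grid_points=1557)
        assert lib.wavenumbers.size == 1557
        assert lib.wavenumbers[0] == 4000.0
        assert lib.wavenumbers[-1] == 10000.0
        assert np.all(np.diff(lib.wavenumbers) > 0)
        spacing = np.diff(lib.wavenumbers)
        assert np.allclose(spacing, spacing[0])

    def test_same_seed_identical(self):
        a = make_component_library(seed=3)
        b = make_component_library(seed=3)
        assert a.bands == b.bands
        c = make_component_library(seed=4)
        assert a.bands != c.bands

    def test_absorptivity_matches_gaussian_sum(self):
        """Component absorptivity equals the closed-form Gaussian sum."""
        lib = make_component_library(seed=2, n_bands=(4, 4))
        rng = np.random.default_rng(0)
        points = rng.choice(lib.wavenumbers.size, size=5, replace=False)
        for name in lib.components:
            assert len(lib.bands[name]) == (4 if name != WATER else 2)
            s = lib.absorptivity(name)
            for j in points:
                v = lib.wavenumbers[j]
                expected = sum(
                    b.amplitude * np.exp(-((v - b.center) ** 2) / (2 * b.width**2))
                    for b in lib.bands[name]
                )
                assert s[j] == pytest.approx(expected, abs=1e-12)

    def test_band_placement_windows(self):
        lib = make_component_library(seed=5)
        for name in COMPOSITION_INDICATORS + (MATRIX,):
            total = sum(b.amplitude for b in lib.bands[name])
            inside = sum(
                b.amplitude
                for b in lib.bands[name]
                if INFORMATIVE_WINDOW[0] <= b.center <= INFORMATIVE_WINDOW[1]
            )
            assert inside >= 0.8 * total
        for b in lib.bands[WATER]:
            assert WATER_BAND[0] <= b.center <= WATER_BAND[1]

    def test_support_indices_nonempty(self):
        lib = make_component_library(seed=6)
        for name in lib.components:
            assert lib.support_indices(name).size > 0

    @pytest.mark.parametrize("grid_points", [0, -5, 3])
    def test_bad_grid_points_rejected(self, grid_points):
        with pytest.raises(ConfigurationError):
            make_component_library(seed=1, grid_points=grid_points)


class TestSimulate:
    def test_noiseless_identity(self):
        """With every nuisance off, spectra equal the exact mixture sum."""
        lib = make_component_library(seed=1, grid_points=200)
        cfg = SimulationConfig(
            n=5, seed=9, noise_sd=0.0, scatter_slope_sd=0.0,
            scatter_offset_sd=0.0, baseline_amplitude=0.0,
        )
        spectra, ref = simulate_dataset(lib, cfg)
        # independently reconstruct from the reference chemistry; water and
        # matrix concentrations are recovered by least squares on the known
        # pure spectra (the mixture is exactly linear, so this is exact)
        S = np.vstack([lib.absorptivity(c) for c in lib.components])
        C_known = ref.values[list(COMPOSITION_INDICATORS)].to_numpy()
        rest = np.clip(100.0 - C_known.sum(axis=1), 0.0, None)
        comp_part = C_known @ S[: len(COMPOSITION_INDICATORS)]
        comp_part += np.outer(rest, lib.absorptivity(MATRIX))
        residual = spectra.absorbance - comp_part
        water = lib.absorptivity(WATER)
        w_conc = residual @ water / (water @ water)
        recon = comp_part + np.outer(w_conc, water)
        assert np.allclose(spectra.absorbance, recon, atol=1e-10)

    def test_same_seed_bit_identical(self):
        lib = make_component_library(seed=1, grid_points=120)
        cfg = SimulationConfig(n=8, seed=4)
        s1, r1 = simulate_dataset(lib, cfg)
        s2, r2 = simulate_dataset(lib, cfg)
        assert np.array_equal(s1.absorbance, s2.absorbance)
        assert r1.values.equals(r2.values)

    def test_population_means_match_configuration(self):
        """Large-n sample means land on the configured population values."""
        lib = make_component_library(seed=1, grid_points=50)
        cfg = SimulationConfig(n=2000, seed=11)
        _, ref = simulate_dataset(lib, cfg)
        assert ref.values["soluble_sugars"].mean() == pytest.approx(18.2, abs=0.5)
        assert ref.values["cellulose"].mean() == pytest.approx(28.3, abs=0.5)
        assert ref.values["hemicellulose"].mean() == pytest.approx(14.0, abs=0.5)

    def test_total_carbohydrate_range_plausible(self):
        lib = make_component_library(seed=1, grid_points=50)
        cfg = SimulationConfig(n=500, seed=12)
        _, ref = simulate_dataset(lib, cfg)
        total = ref.values["total_carbohydrates"]
        assert 55.0 < total.min() and total.max() < 92.0
        assert 60.0 < total.mean() < 80.0

    def test_digestibility_coupling_exact_when_noiseless(self):
        """Without coupling noise the yield is an exact linear map of lignin/ash."""
        lib = make_component_library(seed=1, grid_points=50)
        cfg = SimulationConfig(n=40, seed=13, digest_noise_sd=0.0, yield_offset_sd=0.0)
        _, ref = simulate_dataset(lib, cfg)
        total = ref.values["total_carbohydrates"].to_numpy()
        expected = (cfg.digest_intercept + cfg.lignin_slope * ref.values["lignin"]
                    + cfg.ash_slope * ref.values["ash"]).to_numpy()
        assert np.allclose(total, np.clip(expected, 1e-6, 100.0), atol=1e-12)
        assert np.allclose(ref.values["hexoses"], total)
        # monotone: higher lignin at equal ash means lower yield
        assert np.corrcoef(ref.values["lignin"], total)[0, 1] < 0

    def test_water_independent_of_targets(self):
        """The water amplitude shares no information with any response."""
        lib = make_component_library(seed=2, grid_points=400)
        cfg = SimulationConfig(n=600, seed=14, noise_sd=0.0, scatter_slope_sd=0.0,
                               scatter_offset_sd=0.0, baseline_amplitude=0.0)
        spectra, ref = simulate_dataset(lib, cfg)
        peak = lib.support_indices(WATER)
        water_level = spectra.absorbance[:, peak].mean(axis=1)
        # regress out the composition signal at the water band, then check
        # the residual (the water contribution) is uncorrelated with targets
        C = ref.values.to_numpy()
        resid = water_level - C @ np.linalg.lstsq(C, water_level, rcond=None)[0]
        for col in ref.values.columns:
            r = np.corrcoef(resid, ref.values[col])[0, 1]
            assert abs(r) < 0.15

    def test_inverted_bounds_rejected(self):
        cfg = SimulationConfig(n=5)
        cfg.composition["ash"] = IndicatorDistribution(4.0, 1.0, 8.0, 2.0)
        with pytest.raises(ConfigurationError, match="inverted"):
            cfg.validate()

    def test_n_too_small_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n=1).validate()

    def test_truncated_normal_respects_bounds_and_fails_loudly(self):
        rng = np.random.default_rng(0)
        dist = IndicatorDistribution(10.0, 5.0, 8.0, 12.0)
        x = _truncated_normal(rng, dist, 200)
        assert np.all((x >= 8.0) & (x <= 12.0))
        hopeless = IndicatorDistribution(0.0, 0.001, 50.0, 51.0)
        with pytest.raises(ConfigurationError, match="rejection failed"):
            _truncated_normal(rng, hopeless, 1)


def test_fixture_round_trip(tmp_path):
    from nirsfq.io import read_reference_csv, read_spectra_csv
    from nirsfq.synth import write_fixture

    lib = make_component_library(seed=1, grid_points=30)
    cfg = SimulationConfig(n=4, seed=2)
    spectra, ref = simulate_dataset(lib, cfg)
    write_fixture(tmp_path / "fx", lib, cfg, spectra, ref)
    assert (tmp_path / "fx" / "manifest.yaml").exists()
    sp2 = read_spectra_csv(tmp_path / "fx" / "spectra.csv")
    rf2 = read_reference_csv(tmp_path / "fx" / "reference.csv")
    assert np.array_equal(sp2.absorbance, spectra.absorbance)
    assert np.allclose(rf2.values.to_numpy(), ref.values.to_numpy())
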