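"""Forward simulator: Beer-Lambert mixing, CDOM background, noise, design."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uvnitro.reference import reference_design
from uvnitro.spectra import Composition
from uvnitro.synth import (
    CDOMParams,
    NoiseSpec,
    cdom_absorbance,
    default_cdom_sampler,
    default_grid,
    default_library,
    gaussian_interferent,
    simulate_dataset,
    simulate_spectrum,
)


class TestDefaultLibrary:
    def test_configured_peaks_and_salt_decay(self, grid, library):
        i205 = grid.index_of(205.0)
        assert library.eps_no3[i205] == pytest.approx(9600.0)
        ratio = library.eps_salt[grid.index_of(240.0)] / library.eps_salt[grid.index_of(200.0)]
        assert ratio == pytest.approx(np.exp(-5.0), rel=1e-12)

    def test_all_curves_negligible_at_300(self, grid, library):
        i = grid.index_of(300.0)
        for eps in (library.eps_no3, library.eps_no2, library.eps_salt):
            assert eps[i] < 0.01 * eps.max()

    def test_requires_full_uv_range(self):
        from uvnitro.spectra import WavelengthGrid

        with pytest.raises(ValueError, match="200-300"):
            default_library(WavelengthGrid(np.arange(210.0, 301.0)))


class TestSimulateSpectrum:
    def test_zero_composition_zero_background_is_zero(self, library):
        s = simulate_spectrum(
            Composition(0, 0, 0), library, cdom=CDOMParams(0.0, 0.02, 0.0),
            noise=NoiseSpec(0.0, 1),
        )
        np.testing.assert_array_equal(s.absorbance, 0.0)

    def test_linearity_of_mixing(self, library):
        cdom = CDOMParams(0.03, 0.02, 0.001)
        mix = simulate_spectrum(Composition(10, 2, 20), library, cdom=cdom)
        parts = [
            simulate_spectrum(c, library, cdom=cdom)
            for c in (Composition(10, 0, 0), Composition(0, 2, 0), Composition(0, 0, 20))
        ]
        zero = simulate_spectrum(Composition(0, 0, 0), library, cdom=cdom)
        total = sum(p.absorbance for p in parts) - 2 * zero.absorbance
        np.testing.assert_allclose(mix.absorbance, total, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        no3=st.floats(0, 80), no2=st.floats(0, 20), sal=st.floats(0, 34),
        no3b=st.floats(0, 80), no2b=st.floats(0, 20), salb=st.floats(0, 34),
    )
    def test_additivity_property(self, library, no3, no2, sal, no3b, no2b, salb):
        cdom = CDOMParams(0.05, 0.018, 0.002)

        def spec(c):
            return simulate_spectrum(c, library, cdom=cdom).absorbance

        lhs = spec(Composition(no3 + no3b, no2 + no2b, sal + salb))
        rhs = (
            spec(Composition(no3, no2, sal))
            + spec(Composition(no3b, no2b, salb))
            - spec(Composition(0, 0, 0))
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_pathlength_scales_mixing_but_not_cdom(self, library):
        c = Composition(10, 2, 20)
        cdom = CDOMParams(0.05, 0.018, 0.002)
        bg = cdom_absorbance(cdom, library.grid.values)
        a1 = simulate_spectrum(c, library, cdom=cdom, pathlength=1.0).absorbance
        a2 = simulate_spectrum(c, library, cdom=cdom, pathlength=2.0).absorbance
        np.testing.assert_allclose(a2 - bg, 2.0 * (a1 - bg), atol=1e-12)

    def test_seed_determinism(self, library):
        c = Composition(10, 2, 20)
        a = simulate_spectrum(c, library, noise=NoiseSpec(5e-4, 7)).absorbance
        b = simulate_spectrum(c, library, noise=NoiseSpec(5e-4, 7)).absorbance
        other = simulate_spectrum(c, library, noise=NoiseSpec(5e-4, 8)).absorbance
        np.testing.assert_array_equal(a, b)
        assert np.abs(a - other).max() < 10 * 5e-4
        assert np.any(a != other)

    def test_negative_concentration_rejected(self, library):
        with pytest.raises(ValueError, match=">= 0"):
            simulate_spectrum(Composition(-1.0, 0, 0), library)


class TestReferenceDesign:
    def test_counts_and_spot_values(self):
        cal, pred = reference_design()
        assert (len(cal), len(pred)) == (34, 20)
        assert cal[4].as_array() == pytest.approx([49.61, 0.0, 0.0])
        assert pred[10].as_array() == pytest.approx([67.18, 11.04, 7.04])

    def test_ranges_span_study_domain(self):
        cal, _ = reference_design()
        Y = np.vstack([c.as_array() for c in cal])
        np.testing.assert_allclose(Y.max(axis=0), [85.62, 20.12, 33.90])
        assert Y.min() == 0.0


class TestSimulateDataset:
    def test_matrix_product_oracle_when_noiseless(self, library, design):
        cal, _ = design
        sim = simulate_dataset(cal, lib=library, cdom=None, noise_sd=0.0, seed=0)
        C = np.vstack([c.as_array() for c in cal]) * [1e-6, 1e-6, 1.0]
        expected = 3.0 * (C @ library.as_matrix().T)
        np.testing.assert_allclose(sim.spectra.X, expected, atol=1e-12)

    def test_dataset_determinism_and_cdom_log(self, design):
        cal, _ = design
        a = simulate_dataset(cal, cdom=default_cdom_sampler, seed=5)
        b = simulate_dataset(cal, cdom=default_cdom_sampler, seed=5)
        np.testing.assert_array_equal(a.spectra.X, b.spectra.X)
        assert len(a.cdom) == 34
        assert all(p.a0 == q.a0 for p, q in zip(a.cdom, b.cdom))

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            simulate_dataset([], seed=0)


def test_interferent_band_shape(grid):
    band = gaussian_interferent(grid, amplitude=0.01, center=225.0, sd=10.0)
    assert band[grid.index_of(225.0)] == pytest.approx(0.01)
    assert band[grid.index_of(235.0)] == pytest.approx(0.01 * np.exp(-0.5), rel=1e-12)
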