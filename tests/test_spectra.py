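"""Data model and I/O: grids, windows, resampling, file dialects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uvnitro.spectra import (
    AbsorbanceSpectrum,
    Composition,
    GridRangeError,
    ParseError,
    SpectraSet,
    WavelengthGrid,
    read_spectra,
    resample,
    window,
    write_spectra,
)


def make_set(n=3, lo=200.0, hi=300.0, seed=0, pathlength=3.0):
    g = WavelengthGrid(np.arange(lo, hi + 1.0))
    r = np.random.default_rng(seed)
    return SpectraSet(
        [
            AbsorbanceSpectrum(g, r.uniform(0, 1, len(g)), pathlength, f"s{i}")
            for i in range(n)
        ]
    )


class TestWavelengthGrid:
    def test_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            WavelengthGrid([200.0, 200.0, 201.0])
        with pytest.raises(ValueError, match="uniformly spaced"):
            WavelengthGrid([200.0, 201.0, 203.0])
        with pytest.raises(ValueError, match="within"):
            WavelengthGrid(np.arange(150.0, 250.0))

    def test_window_slice_inclusive_counting(self):
        g = WavelengthGrid(np.arange(200.0, 301.0))
        sl = g.window_slice(215.0, 240.0)
        assert sl.stop - sl.start == 26  # inclusive endpoints at 1 nm
        with pytest.raises(GridRangeError):
            g.window_slice(215.5, 240.0)  # off-grid, no silent snapping
        with pytest.raises(ValueError):
            g.window_slice(240.0, 215.0)


class TestIO:
    @pytest.mark.parametrize("dialect", ["wide", "long"])
    def test_roundtrip_bit_exact(self, tmp_path, dialect):
        sset = make_set(seed=3)
        path = tmp_path / f"{dialect}.csv"
        write_spectra(sset, str(path), dialect=dialect)
        back = read_spectra(str(path), dialect=dialect)
        assert back.sample_ids == sset.sample_ids
        assert back.pathlength == sset.pathlength
        np.testing.assert_array_equal(back.X, sset.X)
        np.testing.assert_array_equal(back.grid.values, sset.grid.values)

    def test_descending_wavelengths_resorted(self, tmp_path):
        p = tmp_path / "desc.csv"
        p.write_text(
            "wavelength_nm,a\n202,0.3\n201,0.2\n200,0.1\n"
        )
        s = read_spectra(str(p))
        np.testing.assert_array_equal(s.grid.values, [200.0, 201.0, 202.0])
        np.testing.assert_array_equal(s.spectra[0].absorbance, [0.1, 0.2, 0.3])

    def test_non_monotone_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("wavelength_nm,a\n200,0.1\n202,0.2\n201,0.3\n")
        with pytest.raises(ParseError, match="monotone"):
            read_spectra(str(p))

    def test_missing_cell_names_sample_and_wavelength(self, tmp_path):
        p = tmp_path / "gap.csv"
        p.write_text("wavelength_nm,s1,s2\n200,0.1,0.4\n201,,0.5\n202,0.3,0.6\n")
        with pytest.raises(ParseError, match=r"'s1' at 201"):
            read_spectra(str(p))

    def test_non_numeric_cell_named(self, tmp_path):
        p = tmp_path / "txt.csv"
        p.write_text("wavelength_nm,s1\n200,0.1\n201,oops\n202,0.3\n")
        with pytest.raises(ParseError, match="oops"):
            read_spectra(str(p))

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("wavelength_nm,s1,s1\n200,0.1,0.2\n201,0.2,0.3\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_spectra(str(p))

    def test_pathlength_comment(self, tmp_path):
        p = tmp_path / "pl.csv"
        p.write_text("# pathlength_cm=1.0\nwavelength_nm,a\n200,0.1\n201,0.2\n")
        assert read_spectra(str(p)).pathlength == 1.0


class TestWindow:
    def test_window_then_window_idempotent(self):
        s = make_set()
        w1 = window(s, 215.0, 240.0)
        w2 = window(w1, 215.0, 240.0)
        np.testing.assert_array_equal(w1.X, w2.X)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        lo=st.integers(200, 270),
        span=st.integers(2, 30),
        inner_off=st.integers(0, 5),
        inner_span=st.integers(1, 10),
    )
    def test_nested_window_equals_direct(self, lo, span, inner_off, inner_span):
        hi = lo + span
        ilo = lo + min(inner_off, span - 1)
        ihi = min(ilo + inner_span, hi)
        if ihi <= ilo:
            return
        s = make_set()
        via = window(window(s, lo, hi), ilo, ihi)
        direct = window(s, ilo, ihi)
        np.testing.assert_array_equal(via.X, direct.X)

    def test_mixed_pathlengths_refused_in_matrix(self):
        g = WavelengthGrid(np.arange(200.0, 211.0))
        s = SpectraSet(
            [
                AbsorbanceSpectrum(g, np.ones(11), 3.0, "a"),
                AbsorbanceSpectrum(g, np.ones(11), 1.0, "b"),
            ]
        )
        with pytest.raises(ValueError, match="pathlength"):
            _ = s.X


class TestResample:
    def test_identity_on_same_grid(self):
        s = make_set().spectra[0]
        out = resample(s, s.grid)
        np.testing.assert_array_equal(out.absorbance, s.absorbance)

    def test_interpolation_through_nodes(self):
        fine = WavelengthGrid(np.arange(200.0, 210.5, 0.5))
        vals = np.sin(fine.values / 7.0)
        s = AbsorbanceSpectrum(fine, vals, 3.0, "x")
        coarse = WavelengthGrid(np.arange(200.0, 211.0))
        out = resample(s, coarse)
        np.testing.assert_allclose(out.absorbance, vals[::2], atol=1e-14)

    def test_no_extrapolation(self):
        s = make_set().spectra[0]
        g = WavelengthGrid(np.arange(199.0, 211.0))
        with pytest.raises(GridRangeError):
            resample(s, g)


def test_composition_array_order():
    c = Composition(1.0, 2.0, 3.0)
    np.testing.assert_array_equal(c.as_array(), [1.0, 2.0, 3.0])
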