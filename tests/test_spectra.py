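"""Spectrum container, text I/O, interpolation and CD bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specbind import (
    SecondaryStructureRow,
    Spectrum,
    SpectrumKind,
    intensity_at,
    interpolate_to_grid,
    read_spectrum,
    validate_secondary_structure,
    write_spectrum,
)
from specbind.errors import ParseError, RangeError, ValidationError
from specbind.spectra import TitrationSeries


class TestSpectrumInvariants:
    def test_requires_strictly_increasing_wavelengths(self):
        with pytest.raises(ValidationError):
            Spectrum([300, 290, 310], [1, 2, 3], SpectrumKind.EMISSION)

    def test_rejects_length_mismatch_and_short_traces(self):
        with pytest.raises(ValidationError):
            Spectrum([300, 310], [1, 2, 3], SpectrumKind.EMISSION)
        with pytest.raises(ValidationError):
            Spectrum([300], [1], SpectrumKind.EMISSION)

    def test_rejects_negative_signal_for_nonnegative_kinds(self):
        with pytest.raises(ValidationError):
            Spectrum([300, 310], [1.0, -0.1], SpectrumKind.ABSORPTION)
        # CD ellipticity is legitimately signed
        Spectrum([300, 310], [1.0, -0.1], SpectrumKind.CD)


class TestReadWrite:
    def test_reads_two_column_text(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("300 0.0\n330 100.0\n360 0.0\n")
        s = read_spectrum(p, SpectrumKind.EMISSION)
        assert len(s) == 3
        assert s.peak_wavelength_nm() == 330.0
        assert intensity_at(s, 330.0) == 100.0

    def test_out_of_order_rows_are_sorted(self, tmp_path):
        a = tmp_path / "a.txt"
        b = tmp_path / "b.txt"
        a.write_text("300 1.0\n330 2.0\n360 3.0\n")
        b.write_text("360 3.0\n300 1.0\n330 2.0\n")
        sa = read_spectrum(a, SpectrumKind.EMISSION)
        sb = read_spectrum(b, SpectrumKind.EMISSION)
        np.testing.assert_array_equal(sa.wavelengths_nm, sb.wavelengths_nm)
        np.testing.assert_array_equal(sa.values, sb.values)

    def test_duplicate_wavelengths_rejected(self, tmp_path):
        p = tmp_path / "dup.txt"
        p.write_text("300 1.0\n300 2.0\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_spectrum(p, SpectrumKind.EMISSION)

    @pytest.mark.parametrize("bad,lineno", [
        ("300 1.0\nfoo bar\n310 2.0\n", 2),
        ("300\n310 2.0\n", 1),
        ("300 1.0 2.0\n310 2.0\n", 1),
    ])
    def test_malformed_rows_report_line_number(self, tmp_path, bad, lineno):
        p = tmp_path / "bad.txt"
        p.write_text(bad)
        with pytest.raises(ParseError) as exc:
            read_spectrum(p, SpectrumKind.EMISSION)
        assert exc.value.line_number == lineno

    def test_comments_and_commas_accepted(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("# header\n300, 1.5\n310\t2.5  # inline\n")
        s = read_spectrum(p, SpectrumKind.EMISSION)
        assert list(s.values) == [1.5, 2.5]

    def test_write_read_roundtrip_full_precision(self, tmp_path):
        rng = np.random.default_rng(7)
        wl = np.sort(300 + 100 * rng.random(40))
        vals = rng.random(40) * 1234.5678
        s = Spectrum(wl, vals, SpectrumKind.EMISSION, "arb")
        p = tmp_path / "rt.txt"
        write_spectrum(s, p)
        s2 = read_spectrum(p, SpectrumKind.EMISSION)
        np.testing.assert_array_equal(s2.wavelengths_nm, s.wavelengths_nm)
        np.testing.assert_array_equal(s2.values, s.values)


class TestInterpolation:
    def test_linear_midpoint(self):
        s = Spectrum([300, 360], [0.0, 60.0], SpectrumKind.EMISSION)
        out = interpolate_to_grid(s, [330.0, 345.0])
        assert out.values[0] == pytest.approx(30.0)
        assert out.values[1] == pytest.approx(45.0)
        assert intensity_at(s, 330.0) == pytest.approx(30.0)

    def test_native_grid_is_identity(self):
        s = Spectrum([300, 315, 360], [1.0, 5.0, 2.0], SpectrumKind.EMISSION)
        out = interpolate_to_grid(s, s.wavelengths_nm)
        np.testing.assert_array_equal(out.values, s.values)

    def test_out_of_span_grid_rejected(self):
        s = Spectrum([300, 360], [0.0, 60.0], SpectrumKind.EMISSION)
        with pytest.raises(RangeError):
            interpolate_to_grid(s, [299.0, 320.0])
        with pytest.raises(RangeError):
            intensity_at(s, 361.0)

    def test_matches_dense_nearest_neighbor_oracle_on_gaussian(self):
        """Linear interpolation vs a 0.001 nm nearest-neighbour oracle."""
        grid = np.arange(250.0, 450.0, 0.5)
        band = 100.0 * np.exp(-0.5 * ((grid - 330.0) / 25.0) ** 2)
        s = Spectrum(grid, band, SpectrumKind.EMISSION)
        fine = np.arange(250.0, 449.5, 0.001)
        fine_vals = 100.0 * np.exp(-0.5 * ((fine - 330.0) / 25.0) ** 2)
        rng = np.random.default_rng(3)
        for lam in rng.uniform(260, 420, size=25):
            oracle = fine_vals[np.argmin(np.abs(fine - lam))]
            assert intensity_at(s, lam) == pytest.approx(oracle, rel=1e-3)

    @given(
        x=st.lists(
            st.floats(min_value=300, max_value=400, allow_nan=False),
            min_size=3, max_size=12, unique=True,
        ),
        vals=st.lists(st.floats(min_value=0, max_value=1e4), min_size=12, max_size=12),
        t=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_piecewise_linear_between_samples(self, x, vals, t):
        """Any interpolated value lies between its bracketing sample values."""
        wl = np.sort(np.asarray(x))
        v = np.asarray(vals[: len(wl)])
        s = Spectrum(wl, v, SpectrumKind.EMISSION)
        i = len(wl) // 2 - 1
        lam = wl[i] + t * (wl[i + 1] - wl[i])
        y = intensity_at(s, lam)
        lo, hi = min(v[i], v[i + 1]), max(v[i], v[i + 1])
        assert lo - 1e-9 <= y <= hi + 1e-9


class TestTitrationSeries:
    def test_zero_first_concentration_required(self, noiseless_sv_series):
        s = noiseless_sv_series
        with pytest.raises(ValidationError, match="must be 0"):
            TitrationSeries(
                protein_conc_M=s.protein_conc_M,
                quencher_concs_M=s.quencher_concs_M[1:],
                spectra=s.spectra[1:],
                temperature_K=s.temperature_K,
                excitation_nm=s.excitation_nm,
            )

    def test_fixed_readout_is_zero_quencher_peak(self, noiseless_sv_series):
        s = noiseless_sv_series
        assert s.readout_wavelength_nm("fixed") == s.f0_spectrum.peak_wavelength_nm()
        assert s.readout_wavelength_nm(335.0) == 335.0


class TestSecondaryStructure:
    # CONTINLL-deconvolved compositions of the free and ligand-bound enzyme.
    FREE = {"H(r)": 0.3, "H(d)": 5.2, "S(r)": 23.9, "S(d)": 12.8,
            "Trn": 22.6, "Unrd": 35.2}
    BOUND = {"H(r)": 0.9, "H(d)": 5.8, "S(r)": 21.4, "S(d)": 12.6,
             "Trn": 23.1, "Unrd": 36.2}

    def test_published_compositions_sum_to_100(self):
        rows = [
            SecondaryStructureRow("apo", self.FREE),
            SecondaryStructureRow("complex", self.BOUND),
        ]
        report = validate_secondary_structure(rows)
        assert report["total_percent"].tolist() == pytest.approx([100.0, 100.0])
        assert report["sum_ok"].all()
        assert report.loc[1, "delta_Unrd"] == pytest.approx(1.0)
        assert report.loc[1, "delta_S(r)"] == pytest.approx(-2.5)

    def test_zero_row_flagged(self):
        zeros = {k: 0.0 for k in self.FREE}
        report = validate_secondary_structure([SecondaryStructureRow("z", zeros)])
        assert report.loc[0, "total_percent"] == 0.0
        assert not report.loc[0, "sum_ok"]

    def test_fraction_bounds_enforced(self):
        bad = dict(self.FREE, Unrd=105.0)
        with pytest.raises(ValidationError):
            SecondaryStructureRow("bad", bad)
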