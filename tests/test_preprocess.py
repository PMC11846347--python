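"""Spectral I/O and the four-step preprocessing chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imfstat import (
    PreprocessConfig,
    SpectraMatrix,
    add_water_reference,
    l2_normalize,
    preprocess,
    read_spectra,
    truncate_and_remove_silent,
    write_spectra,
)
from imfstat.preprocess import retained_mask

from conftest import make_matrix


def default_grid():
    return 950.0 + 4.0 * np.arange(526)


class TestIO:
    def test_round_trip_identity(self, toy_matrix, tmp_path):
        path = tmp_path / "spectra.csv"
        write_spectra(toy_matrix, path)
        back = read_spectra(path)
        assert back.subject_ids == toy_matrix.subject_ids
        np.testing.assert_allclose(back.wavenumbers, toy_matrix.wavenumbers, atol=1e-9)
        np.testing.assert_allclose(back.absorbance, toy_matrix.absorbance, atol=1e-9)

    def test_tab_delimited_sniffed(self, toy_matrix, tmp_path):
        path = tmp_path / "spectra.tsv"
        write_spectra(toy_matrix, path, delimiter="\t")
        back = read_spectra(path)
        np.testing.assert_allclose(back.absorbance, toy_matrix.absorbance)

    def test_duplicate_id_names_offender(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("id,1000.0,1004.0\nS1,1,2\nS1,3,4\n")
        with pytest.raises(ValueError, match="S1"):
            read_spectra(path)

    def test_non_increasing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,1004.0,1000.0\nS1,1,2\n")
        with pytest.raises(ValueError, match="increasing"):
            read_spectra(path)

    def test_ragged_row_reports_row_number(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text("id,1000.0,1004.0\nS1,1,2\nS2,3\n")
        with pytest.raises(ValueError, match="row 3"):
            read_spectra(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = tmp_path / "nan.csv"
        path.write_text("id,1000.0,1004.0\nS1,1,oops\n")
        with pytest.raises(ValueError, match="row 2"):
            read_spectra(path)


class TestWaterCorrection:
    def test_zero_scale_is_identity(self, toy_matrix):
        cfg = PreprocessConfig(water_reference=np.ones(3), water_scale=0.0)
        out = add_water_reference(toy_matrix, cfg)
        np.testing.assert_array_equal(out.absorbance, toy_matrix.absorbance)

    def test_exact_inverse_of_overcompensation(self, rng):
        mat = make_matrix(rng, n=5)
        water = rng.random(mat.n_wavenumbers)
        c = 0.37
        overcompensated = SpectraMatrix(
            mat.subject_ids, mat.wavenumbers, mat.absorbance - c * water
        )
        cfg = PreprocessConfig(water_reference=water, water_scale=c)
        restored = add_water_reference(overcompensated, cfg)
        np.testing.assert_allclose(restored.absorbance, mat.absorbance, atol=1e-12)

    def test_applying_twice_adds_exactly_once_more(self, rng):
        mat = make_matrix(rng, n=3)
        water = rng.random(mat.n_wavenumbers)
        cfg = PreprocessConfig(water_reference=water, water_scale=0.2)
        once = add_water_reference(mat, cfg)
        twice = add_water_reference(once, cfg)
        np.testing.assert_allclose(
            twice.absorbance - once.absorbance,
            np.broadcast_to(0.2 * water, once.absorbance.shape),
            atol=1e-12,
        )

    def test_grid_mismatch_rejected(self, toy_matrix):
        cfg = PreprocessConfig(water_reference=np.ones(5), water_scale=1.0)
        with pytest.raises(ValueError, match="grid"):
            add_water_reference(toy_matrix, cfg)


class TestTruncation:
    def test_default_grid_enumeration_oracle(self, rng):
        """Independent enumeration of the retained points on the default grid."""
        grid = default_grid()
        cfg = PreprocessConfig()
        expected = [
            w
            for w in grid
            if 1000.0 <= w <= 3000.0 and not (1850.0 < w < 2800.0)
        ]
        assert len(expected) == 263
        mat = make_matrix(rng, n=3, wavenumbers=grid)
        out = truncate_and_remove_silent(mat, cfg)
        np.testing.assert_array_equal(out.wavenumbers, expected)

    def test_grid_fully_inside_retained_band_unchanged(self, rng):
        grid = 1000.0 + 4.0 * np.arange(213)  # 1000..1848
        mat = make_matrix(rng, n=2, wavenumbers=grid)
        out = truncate_and_remove_silent(mat, PreprocessConfig())
        np.testing.assert_array_equal(out.wavenumbers, grid)

    def test_silent_endpoints_are_retained(self, rng):
        # 1850 and 2800 sit on the open interval's boundary -> kept
        grid = np.array([1846.0, 1850.0, 1854.0, 2796.0, 2800.0, 2804.0])
        mat = make_matrix(rng, n=2, wavenumbers=grid)
        out = truncate_and_remove_silent(mat, PreprocessConfig())
        np.testing.assert_array_equal(out.wavenumbers, [1846.0, 1850.0, 2800.0, 2804.0])

    def test_empty_result_is_error(self, rng):
        grid = np.array([500.0, 600.0])
        mat = make_matrix(rng, n=2, wavenumbers=grid)
        with pytest.raises(ValueError, match="retained"):
            truncate_and_remove_silent(mat, PreprocessConfig())

    def test_retention_depends_only_on_wavenumbers(self, rng):
        grid = default_grid()
        cfg = PreprocessConfig()
        m1 = make_matrix(rng, n=4, wavenumbers=grid)
        m2 = make_matrix(rng, n=7, wavenumbers=grid, loc=3.0)
        np.testing.assert_array_equal(
            retained_mask(m1.wavenumbers, cfg), retained_mask(m2.wavenumbers, cfg)
        )


class TestNormalize:
    def test_three_four_five_triangle(self):
        mat = SpectraMatrix(["A"], np.array([1000.0, 1004.0]), np.array([[3.0, 4.0]]))
        out = l2_normalize(mat)
        np.testing.assert_allclose(out.absorbance, [[0.6, 0.8]])

    def test_idempotent(self, rng):
        mat = l2_normalize(make_matrix(rng, n=5))
        again = l2_normalize(mat)
        np.testing.assert_allclose(again.absorbance, mat.absorbance, atol=1e-14)

    def test_zero_row_error_names_subject(self):
        mat = SpectraMatrix(
            ["ok", "zero"], np.array([1000.0, 1004.0]), np.array([[1.0, 2.0], [0.0, 0.0]])
        )
        with pytest.raises(ValueError, match="zero"):
            l2_normalize(mat)


class TestFullChain:
    def test_output_unit_norms_and_263_points(self, rng):
        mat = make_matrix(rng, n=6, wavenumbers=default_grid())
        cfg = PreprocessConfig(
            water_reference=rng.random(526), water_scale=0.1
        )
        out = preprocess(mat, cfg)
        assert out.n_wavenumbers == 263
        np.testing.assert_allclose(
            np.linalg.norm(out.absorbance, axis=1), 1.0, atol=1e-12
        )

    def test_normalize_before_truncate_differs(self, rng):
        # the composition order is load-bearing
        mat = make_matrix(rng, n=3, wavenumbers=default_grid())
        cfg = PreprocessConfig()
        correct = preprocess(mat, cfg)
        swapped = truncate_and_remove_silent(l2_normalize(mat), cfg)
        # normalizing first leaves non-unit rows after truncation
        assert not np.allclose(np.linalg.norm(swapped.absorbance, axis=1), 1.0)
        assert not np.allclose(correct.absorbance, swapped.absorbance)

    @settings(max_examples=20, deadline=None)
    @given(perm_seed=st.integers(0, 10**6))
    def test_permutation_equivariance(self, perm_seed):
        """Row order never affects any subject's preprocessed spectrum."""
        rng = np.random.default_rng(99)
        mat = make_matrix(rng, n=8, wavenumbers=default_grid())
        cfg = PreprocessConfig()
        perm = np.random.default_rng(perm_seed).permutation(8)
        permuted = SpectraMatrix(
            [mat.subject_ids[i] for i in perm], mat.wavenumbers, mat.absorbance[perm]
        )
        out = preprocess(mat, cfg)
        out_perm = preprocess(permuted, cfg)
        for sid in mat.subject_ids:
            i = out.subject_ids.index(sid)
            j = out_perm.subject_ids.index(sid)
            np.testing.assert_allclose(
                out.absorbance[i], out_perm.absorbance[j], atol=1e-14
            )
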