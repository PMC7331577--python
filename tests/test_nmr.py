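"""Spectral axis, normalization, Pareto scaling and the Welch bin screen."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import metabosurv as ms
from metabosurv.nmr import (
    AnnotationLibrary,
    SpectralMatrix,
    bin_axis,
    bin_index,
    welch_t,
)


class TestBinAxis:
    def test_full_axis_has_900_bins(self):
        axis = bin_axis(exclude_water=False)
        assert len(axis) == 900
        assert axis[0] == pytest.approx(0.505)
        assert axis[-1] == pytest.approx(9.495)

    def test_water_exclusion_drops_50_bins(self):
        axis = bin_axis(exclude_water=True)
        assert len(axis) == 850
        assert axis[0] == pytest.approx(0.505)
        assert axis[-1] == pytest.approx(9.495)
        assert not np.any((axis >= 4.50) & (axis < 5.00))

    def test_bin_index_half_open_membership(self):
        axis = bin_axis()
        assert axis[bin_index(axis, 7.395)] == pytest.approx(7.395)
        # 7.400 is the lower edge of the 7.405 bin under [c-0.005, c+0.005)
        assert axis[bin_index(axis, 7.400)] == pytest.approx(7.405)
        with pytest.raises(ValueError):
            bin_index(axis, 0.3)


def _tiny_matrix(values, centers=None):
    values = np.asarray(values, dtype=float)
    if centers is None:
        centers = bin_axis()[: values.shape[1]]
    ids = [f"P{i}" for i in range(values.shape[0])]
    return SpectralMatrix(ids, centers, values)


class TestNormalization:
    def test_reference_division_hand_example(self):
        m = _tiny_matrix([[2.0, 4.0, 8.0]])
        out = ms.normalize_to_reference(m, m.bin_centers[0])
        assert np.allclose(out.intensities, [[1.0, 2.0, 4.0]])

    def test_identity_when_reference_is_one(self):
        m = _tiny_matrix([[1.0, 3.0, 5.0]])
        out = ms.normalize_to_reference(m, m.bin_centers[0])
        assert np.allclose(out.intensities, m.intensities)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(1, 10, size=(4, 6))
        m = _tiny_matrix(raw)
        scaled = _tiny_matrix(raw * np.array([[1.0], [7.3], [0.2], [100.0]]))
        a = ms.normalize_to_reference(m, m.bin_centers[2])
        b = ms.normalize_to_reference(scaled, m.bin_centers[2])
        assert np.allclose(a.intensities, b.intensities)

    def test_nonpositive_reference_names_patient(self):
        m = _tiny_matrix([[1.0, 2.0], [0.0, 3.0]])
        with pytest.raises(ValueError, match="P1"):
            ms.normalize_to_reference(m, m.bin_centers[0])

    def test_total_area_option(self):
        m = _tiny_matrix([[1.0, 3.0]])
        out = ms.normalize_total_area(m)
        assert np.allclose(out.intensities.sum(axis=1), 1.0)


class TestParetoScaling:
    def test_hand_example(self):
        m = _tiny_matrix([[1.0], [2.0], [3.0]])
        out = ms.pareto_scale(m)
        assert np.allclose(out.intensities.ravel(), [-1.0, 0.0, 1.0])

    def test_constant_column_zeroed_with_warning(self, caplog):
        m = _tiny_matrix([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        with caplog.at_level(logging.WARNING):
            out = ms.pareto_scale(m)
        assert np.allclose(out.intensities[:, 0], 0.0)
        assert any("constant" in r.message for r in caplog.records)

    def test_columns_centered_and_variance_equals_sd(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(0, 5, size=(50, 8))
        out = ms.pareto_scale(_tiny_matrix(raw))
        assert np.all(np.abs(out.intensities.mean(axis=0)) < 1e-12)
        # Pareto property: variance of the scaled column equals the sd
        assert np.allclose(out.intensities.var(axis=0, ddof=1), raw.std(axis=0, ddof=1))

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            ms.pareto_scale(_tiny_matrix([[1.0, 2.0]]))


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_example(self):
        t, df, p = welch_t([1, 2, 3, 4], [2, 4, 6, 8])
        assert t == pytest.approx(-1.732, abs=5e-4)

    def test_equal_variance_equal_n_matches_pooled_t(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        t_w, _, _ = welch_t(a, b)
        t_p = stats.ttest_ind(a, b, equal_var=True).statistic
        assert t_w == pytest.approx(t_p, abs=1e-12)

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=12),
        st.lists(st.floats(-50, 50), min_size=3, max_size=12),
    )
    @settings(max_examples=50, derandomize=True)
    def test_antisymmetry_under_group_swap(self, a, b):
        if np.var(a) == 0 and np.var(b) == 0:
            return
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1, 2, 3])
        with pytest.raises(ValueError):
            welch_t([2.0, 2.0], [3.0, 3.0])


class TestScreen:
    def _matrix(self, n=60, bins=30, seed=0):
        rng = np.random.default_rng(seed)
        centers = bin_axis()[:bins]
        return SpectralMatrix(
            [f"P{i}" for i in range(n)], centers, rng.normal(10, 1, size=(n, bins))
        ), rng

    def test_alpha_zero_flags_nothing(self):
        m, rng = self._matrix()
        labels = np.r_[np.ones(20, int), np.zeros(40, int)]
        out = ms.screen_bins(m, labels, alpha=0.0)
        assert not out["significant"].any()

    def test_planted_effect_detected_with_positive_direction(self):
        m, rng = self._matrix(n=200)
        labels = np.r_[np.ones(40, int), np.zeros(160, int)]
        planted = m.intensities.copy()
        planted[labels == 1, 3] += 1.5  # Cohen's d = 1.5 at unit noise
        m2 = SpectralMatrix(m.patient_ids, m.bin_centers, planted)
        out = ms.screen_bins(m2, labels, alpha=0.01)
        row = out.iloc[3]
        assert row["significant"]
        assert row["direction"] == "positive"

    def test_water_bins_absent_from_output(self):
        rng = np.random.default_rng(3)
        full = SpectralMatrix(
            [f"P{i}" for i in range(20)], bin_axis(), rng.normal(10, 1, (20, 900))
        )
        labels = np.r_[np.ones(8, int), np.zeros(12, int)]
        out = ms.screen_bins(full, labels)
        assert len(out) == 850
        assert not np.any((out["bin_center"] >= 4.50) & (out["bin_center"] < 5.00))

    def test_scale_invariance_through_normalization(self):
        m, rng = self._matrix(n=40)
        labels = np.r_[np.ones(15, int), np.zeros(25, int)]
        scaled = SpectralMatrix(
            m.patient_ids, m.bin_centers, m.intensities * rng.uniform(0.5, 2, (40, 1))
        )
        out1 = ms.screen_bins(ms.pareto_scale(ms.normalize_total_area(m)), labels)
        out2 = ms.screen_bins(ms.pareto_scale(ms.normalize_total_area(scaled)), labels)
        # identical because per-spectrum scaling divides out
        m_equal = SpectralMatrix(m.patient_ids, m.bin_centers, m.intensities * 3.0)
        out3 = ms.screen_bins(ms.pareto_scale(ms.normalize_total_area(m_equal)), labels)
        pd.testing.assert_frame_equal(out1, out3)

    def test_single_class_labels_rejected(self):
        m, _ = self._matrix()
        with pytest.raises(ValueError):
            ms.screen_bins(m, np.ones(60, int))

    def test_degenerate_bin_reported_nan_not_raised(self, caplog):
        m, _ = self._matrix(n=30)
        vals = m.intensities.copy()
        vals[:, 0] = 1.0  # constant bin, e.g. a normalization reference
        m2 = SpectralMatrix(m.patient_ids, m.bin_centers, vals)
        labels = np.r_[np.ones(10, int), np.zeros(20, int)]
        with caplog.at_level(logging.WARNING):
            out = ms.screen_bins(m2, labels)
        assert np.isnan(out.iloc[0]["p_value"])
        assert not out.iloc[0]["significant"]


class TestAnnotation:
    def test_empty_library_annotates_nothing(self):
        rows = pd.DataFrame(
            {"bin_center": [7.395], "significant": [True], "annotation": [""]}
        )
        out = ms.annotate_bins(rows, AnnotationLibrary({}))
        assert (out["annotation"] == "").all()

    def test_interval_membership(self):
        rows = pd.DataFrame(
            {"bin_center": [7.395, 2.0], "significant": [True, True], "annotation": ["", ""]}
        )
        lib = AnnotationLibrary({"Phe": [(7.30, 7.45)]})
        out = ms.annotate_bins(rows, lib)
        assert out.loc[0, "annotation"] == "Phe"
        assert out.loc[1, "annotation"] == ""

    def test_overlapping_intervals_joined_sorted(self):
        rows = pd.DataFrame(
            {"bin_center": [7.40], "significant": [True], "annotation": [""]}
        )
        lib = AnnotationLibrary({"Zeta": [(7.3, 7.5)], "Alpha": [(7.35, 7.45)]})
        out = ms.annotate_bins(rows, lib)
        assert out.loc[0, "annotation"] == "Alpha;Zeta"

    def test_library_interval_outside_axis_rejected(self):
        with pytest.raises(ValueError):
            AnnotationLibrary({"X": [(9.8, 10.0)]})

    def test_end_to_end_screen_recovers_planted_metabolites(self):
        """Planted positive-Phe / negative-Gln hazards must surface as
        annotated bins with the matching directions."""
        score = ms.PolynomialScore((("phe_um", 1, 0.08), ("gln_um", 1, -0.012)))
        cfg = ms.GeneratorConfig(n_patients=800, seed=21, true_score=score, hr_per_unit=1.0)
        cohort, _ = ms.generate_cohort(cfg)
        lib = ms.default_annotation_library()
        spectra = ms.generate_spectra(cohort, lib, noise_sd=3.0, seed=22)
        screened = ms.screen_bins(
            ms.pareto_scale(ms.normalize_total_area(spectra)), cohort["event"].to_numpy()
        )
        annotated = ms.annotate_bins(screened, lib)
        phe = annotated[annotated["annotation"] == "Phe"]
        gln = annotated[annotated["annotation"] == "Gln"]
        assert len(phe) and (phe["direction"] == "positive").all()
        assert len(gln) and (gln["direction"] == "negative").all()
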