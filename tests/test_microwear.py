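"""Microwear counting, LSR bands and reference-ellipse membership."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from paleowear.data_model import DietMain, DietQualifier
from paleowear.microwear import (
    MicrowearObservation,
    classify_diet_bivariate,
    classify_diet_lsr,
    compute_lsr,
    gaussian_ellipse,
    summarize_microwear,
    tooth_microwear_counts,
)


def field(sid, idx, ns, np_, **kw):
    defaults = dict(
        texture_score=1, large_pits=False, gouges=False, cross_scratches=False, coarse_scratches=False
    )
    defaults.update(kw)
    return MicrowearObservation(sid, idx, ns, np_, **defaults)


class TestToothCounts:
    def test_mean_over_replicate_fields(self):
        t = tooth_microwear_counts([field("S1", 1, 16, 27), field("S1", 2, 18, 25)])
        assert (t.ns, t.np_) == (17.0, 26.0)

    def test_single_field_is_identity(self):
        t = tooth_microwear_counts([field("S1", 1, 20, 10)])
        assert (t.ns, t.np_) == (20.0, 10.0)

    def test_all_zero_fields(self):
        t = tooth_microwear_counts([field("S1", 1, 0, 0), field("S1", 2, 0, 0)])
        assert (t.ns, t.np_) == (0.0, 0.0)

    def test_zero_fields_rejected(self):
        with pytest.raises(ValueError):
            tooth_microwear_counts([])


class TestSummary:
    def test_means_sds_and_feature_rates(self):
        teeth = [
            tooth_microwear_counts([field(f"S{i}", 1, ns, 20, cross_scratches=xs)])
            for i, (ns, xs) in enumerate([(16, True), (18, True), (17, True), (19, False)])
        ]
        s = summarize_microwear(teeth)
        assert s.ns_mean == pytest.approx(17.5)
        assert s.pct_xs == 75.0
        assert s.ns_cv == pytest.approx(s.ns_sd / s.ns_mean)
        assert s.ns_cv_star >= s.ns_cv

    def test_single_tooth_summary_has_no_dispersion_fields(self):
        s = summarize_microwear([tooth_microwear_counts([field("S1", 1, 16, 27)])])
        assert s.ns_sd is None and s.ns_cv_star is None and s.n == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_microwear([])


class TestLSR:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([10, 12, 20, 25], 50.0),
            ([18, 19, 22], 0.0),
            ([17.0, 17.5, 16.0, 20.0], 50.0),  # inclusive <= 17 on fractional means
        ],
    )
    def test_low_scratch_range_percentage(self, values, expected):
        assert compute_lsr(values) == expected

    @given(st.lists(st.floats(min_value=0, max_value=40), min_size=1, max_size=30))
    def test_order_invariant_and_duplication_invariant(self, values):
        lsr = compute_lsr(values)
        assert compute_lsr(values[::-1]) == lsr
        assert compute_lsr(values * 2) == pytest.approx(lsr)

    @pytest.mark.parametrize(
        "lsr,main,qualifier,boundary",
        [
            (0.0, DietMain.grazer, DietQualifier.none, False),
            (6.67, DietMain.grazer, DietQualifier.none, False),
            (20.0, DietMain.grazer, DietQualifier.none, False),
            (21.0, DietMain.mixed, DietQualifier.grass_dominated, True),  # band overlap
            (28.57, DietMain.mixed, DietQualifier.grass_dominated, False),
            (47.05, DietMain.mixed, DietQualifier.browse_dominated, False),
            (54.83, DietMain.mixed, DietQualifier.browse_dominated, False),
            (62.5, DietMain.mixed, DietQualifier.browse_dominated, False),
            (72.41, DietMain.browser, DietQualifier.browse_dominated, True),  # band gap
            (73.33, DietMain.browser, DietQualifier.none, False),
            (100.0, DietMain.browser, DietQualifier.none, False),
        ],
    )
    def test_diet_bands_including_gap_and_overlap(self, lsr, main, qualifier, boundary):
        diet = classify_diet_lsr(lsr)
        assert (diet.main, diet.qualifier, diet.boundary_flag) == (main, qualifier, boundary)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_diet_lsr(101.0)


class TestEllipse:
    def test_isotropic_boundary_radius_is_chi2_quantile(self):
        ell = gaussian_ellipse(centroid=[0, 0], covariance=np.eye(2), p=0.95)
        r = np.sqrt(ell.q)
        assert r == pytest.approx(np.sqrt(5.9915), abs=1e-3)
        assert ell.contains([r - 1e-6, 0]) and not ell.contains([r + 1e-6, 0])

    def test_centroid_always_inside_and_10sd_outside(self, reference_populations):
        for pop in reference_populations.values():
            c = pop.ellipse.centroid
            assert pop.ellipse.contains(c)
            sd = np.sqrt(np.diag(pop.ellipse.covariance))
            assert not pop.ellipse.contains([c[0] + 10 * sd[0], c[1]])
            assert not pop.ellipse.contains([c[0], c[1] + 10 * sd[1]])

    def test_monte_carlo_coverage_matches_p(self):
        rng = np.random.default_rng(7)
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        ell = gaussian_ellipse(centroid=[1, 2], covariance=cov, p=0.95)
        pts = rng.multivariate_normal([1, 2], cov, size=20000)
        inside = np.mean([ell.contains(p) for p in pts])
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_degenerate_covariance_rejected(self):
        with pytest.raises(ValueError):
            gaussian_ellipse(centroid=[0, 0], covariance=[[1, 1], [1, 1]])

    def test_fit_requires_three_points(self):
        with pytest.raises(ValueError):
            gaussian_ellipse(points=[[0, 0], [1, 1]])


class TestBivariateMembership:
    def test_browser_centroid_is_inside_browser(self, reference_populations):
        c = reference_populations["browser"].ellipse.centroid
        m = classify_diet_bivariate(c[0], c[1], reference_populations)
        assert m.inside_browser and not m.outside_all

    def test_fossil_deer_centroid_falls_in_browser_ellipse(self, reference_populations):
        m = classify_diet_bivariate(16.93, 26.17, reference_populations)
        assert m.inside_browser

    def test_pit_excess_keeps_grazer_scratches_outside_all(self, reference_populations):
        """High NP at grazer-typical NS: outside every ellipse, flagged."""
        m = classify_diet_bivariate(21.8, 27.45, reference_populations)
        assert m.outside_all and m.excess_pits_flag

    def test_missing_reference_class_rejected(self, reference_populations):
        with pytest.raises(ValueError):
            classify_diet_bivariate(15, 20, {"browser": reference_populations["browser"]})
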