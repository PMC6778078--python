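"""Corrected CV, zone boundary fitting/classification, discrepancy flag."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from paleowear.data_model import DietClass, DietMain, DietQualifier
from paleowear.pipeline import round_half_up
from paleowear.wear_seasonality import (
    BoundaryModel,
    Zone,
    ZoneBoundarySimulator,
    corrected_cv,
    detect_wear_discrepancy,
    fit_zone_boundaries,
)


class TestCorrectedCV:
    @pytest.mark.parametrize(
        "mean,sd,n,printed",
        [
            (21.8, 3.77, 10, 0.18),
            (21.28, 2.27, 30, 0.11),
            (16.93, 1.66, 29, 0.10),
            (17.18, 2.06, 31, 0.12),
            (20.38, 3.04, 21, 0.15),
        ],
    )
    def test_reproduces_published_rows_at_print_precision(self, mean, sd, n, printed):
        assert round_half_up(corrected_cv(mean, sd, n), 2) == printed

    def test_zero_sd_gives_zero(self):
        assert corrected_cv(12.3, 0.0, 5) == 0.0

    @given(
        st.floats(min_value=0.1, max_value=100),
        st.floats(min_value=0, max_value=50),
        st.integers(min_value=2, max_value=500),
    )
    def test_exceeds_raw_cv_by_exactly_the_small_sample_factor(self, mean, sd, n):
        assert corrected_cv(mean, sd, n) == pytest.approx((sd / mean) * (1 + 1 / (4 * n)))

    @pytest.mark.parametrize("mean,sd,n", [(0, 1, 5), (-1, 1, 5), (10, 1, 1), (10, -1, 5)])
    def test_invalid_inputs_rejected(self, mean, sd, n):
        with pytest.raises(ValueError):
            corrected_cv(mean, sd, n)


class TestSimulator:
    def test_same_seed_gives_identical_model(self):
        a = fit_zone_boundaries(20, 2.4, 5.8, 12, 1000, seed=5)
        b = fit_zone_boundaries(20, 2.4, 5.8, 12, 1000, seed=5)
        assert np.array_equal(a.probabilities, b.probabilities)
        assert np.array_equal(a.cv_grid, b.cv_grid)

    def test_json_round_trip_is_bit_identical(self, tmp_path):
        model = fit_zone_boundaries(20, 2.4, 5.8, 12, 1000, seed=5)
        path = tmp_path / "model.json"
        model.to_json(path)
        again = BoundaryModel.from_json(path)
        assert np.array_equal(model.probabilities, again.probabilities)
        assert np.array_equal(model.sd_grid, again.sd_grid)
        assert again.params == model.params and again.seed == model.seed

    def test_multi_season_mixtures_inflate_both_coordinates(self):
        """Non-consecutive-season mixtures shift mean (CV*, SD) strictly up."""
        sim = ZoneBoundarySimulator(20, 2.4, 5.8, 15, 1000)
        rng = np.random.default_rng(11)
        single = sim.simulate_case("single", rng).mean(axis=0)
        rng = np.random.default_rng(11)
        non = sim.simulate_case("two_nonconsecutive", rng).mean(axis=0)
        assert non[0] > single[0] and non[1] > single[1]

    def test_delta_zero_degenerates_to_equiprobable_surface(self):
        with pytest.warns(UserWarning, match="indistinguishable"):
            model = fit_zone_boundaries(20, 2.4, 0.0, 12, 1000, seed=3)
        assert np.allclose(model.probabilities, 1 / 3)

    def test_boundary_monotonicity_along_sd(self, boundary_model):
        """p(single event) never increases with SD at fixed CV*."""
        p_single = boundary_model.probabilities[0]
        diffs = np.diff(p_single, axis=1)
        assert (diffs <= 1e-9).all()

    def test_probabilities_sum_to_one_everywhere(self, boundary_model):
        assert np.allclose(boundary_model.probabilities.sum(axis=0), 1.0)

    def test_few_replicates_warns(self):
        with pytest.warns(UserWarning, match="replicates"):
            ZoneBoundarySimulator(20, 2.4, 5.8, 12, replicates=50)


class TestClassifyZone:
    @pytest.mark.parametrize(
        "cv,sd,zone",
        [
            (0.10, 1.66, Zone.A),
            (0.18, 3.77, Zone.B),
            (0.15, 3.04, Zone.boundary_AB),
        ],
    )
    def test_published_placements_under_default_model(self, boundary_model, cv, sd, zone):
        assert boundary_model.classify(cv, sd).zone is zone

    def test_far_point_reaches_zone_c(self, boundary_model):
        assert boundary_model.classify(0.34, 6.8).zone is Zone.C

    def test_call_probabilities_are_coherent(self, boundary_model):
        call = boundary_model.classify(0.12, 2.2)
        assert sum(call.probabilities) == pytest.approx(1.0)
        assert call.error_probability == pytest.approx(1 - max(call.probabilities))

    def test_single_event_recovery_consistent_with_model_error(self, boundary_model):
        """Self-consistency: simulated single events recover zone A at least
        as often as the surface's own confidence predicts."""
        sim = ZoneBoundarySimulator(**boundary_model.params)
        rng = np.random.default_rng(99)
        pts = sim.simulate_case("single", rng, replicates=2000)
        calls = [boundary_model.classify(cv, sd, tau=0.0) for cv, sd in pts]
        rate_a = np.mean([c.zone is Zone.A for c in calls])
        predicted = np.mean([c.p_single for c in calls])
        assert rate_a >= predicted - 0.03


class TestDiscrepancy:
    def test_boundary_browse_call_vs_mixed_is_a_discrepancy(self):
        meso = DietClass(DietMain.mixed, DietQualifier.grass_dominated)
        micro = DietClass(DietMain.browser, DietQualifier.browse_dominated, boundary_flag=True)
        assert detect_wear_discrepancy(meso, micro).flag

    def test_identical_mixed_classifications_are_consistent(self):
        d = DietClass(DietMain.mixed, DietQualifier.grass_dominated)
        assert not detect_wear_discrepancy(d, d).flag

    def test_two_grazers_are_consistent(self):
        g = DietClass(DietMain.grazer)
        assert not detect_wear_discrepancy(g, g).flag

    def test_dominance_shift_within_mixed_flags(self):
        a = DietClass(DietMain.mixed, DietQualifier.grass_dominated)
        b = DietClass(DietMain.mixed, DietQualifier.browse_dominated)
        assert detect_wear_discrepancy(a, b).flag
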