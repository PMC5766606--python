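"""ROI filtering, coherence correlations, permutation test, circular
correlation, parameter consistency and gaze MAD."""

import numpy as np
import pandas as pd
import pytest

from carpetprf import (ROIBand, circular_correlation, fisher_z_mean,
                       gaze_mad, parameter_correlations, permutation_test,
                       prediction_correlation, responsive_fraction,
                       roi_filter)


def fits_frame(points):
    return pd.DataFrame([dict(x0=x, y0=y) for x, y in points])


class TestROIFilter:
    @pytest.mark.parametrize("x0, y0, keep", [
        (1.0, 1.0, True),     # interior of the band
        (0.5, 2.0, False),    # too close to the vertical meridian
        (3.2, 1.0, False),    # beyond the outer bound
        (0.75, 0.75, True),   # inner bound inclusive
        (3.0, -3.0, True),    # outer bound inclusive, any quadrant
        (-2.0, 0.74, False),
    ])
    def test_band_membership(self, x0, y0, keep):
        mask = roi_filter(fits_frame([(x0, y0)]))
        assert mask[0] == keep

    def test_missing_columns(self):
        with pytest.raises(KeyError):
            roi_filter(pd.DataFrame({"x0": [1.0]}))

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            ROIBand(inner_deg=3.0, outer_deg=0.75)


class TestResponsiveFraction:
    def test_all_above(self):
        fits = pd.DataFrame({"r_squared": [0.2, 0.2, 0.2]})
        assert responsive_fraction(fits) == 1.0

    def test_strict_boundary(self):
        fits = pd.DataFrame({"r_squared": [0.05, 0.05 + 1e-9, 0.04]})
        assert responsive_fraction(fits) == pytest.approx(1 / 3)

    def test_empty_selection(self):
        fits = pd.DataFrame({"r_squared": [0.2]})
        with pytest.raises(ValueError):
            responsive_fraction(fits, mask=np.array([False]))


class TestFisherZMean:
    def test_antisymmetry(self):
        assert fisher_z_mean(np.array([0.5, -0.5])) == pytest.approx(0.0)

    def test_perfect_correlations_clipped(self):
        assert fisher_z_mean(np.array([1.0, 1.0])) == pytest.approx(1.0)


class TestPredictionCorrelation:
    def test_exact_match(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(size=(20, 180))
        r, zbar, skipped = prediction_correlation(pred, pred)
        assert r == pytest.approx(np.ones(20))
        assert zbar == pytest.approx(1.0)
        assert skipped == 0

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(size=(500, 180))
        pred = rng.normal(size=(500, 180))
        _, zbar, _ = prediction_correlation(obs, pred)
        assert abs(zbar) < 0.02

    def test_zero_variance_vertices_skipped(self):
        rng = np.random.default_rng(2)
        obs = rng.normal(size=(3, 50))
        obs[1] = 5.0
        pred = rng.normal(size=(3, 50))
        _, _, skipped = prediction_correlation(obs, pred)
        assert skipped == 1


class TestPermutationTest:
    def test_two_vertices_one_perm(self):
        rng = np.random.default_rng(3)
        obs = rng.normal(size=(2, 60))
        res = permutation_test(obs, obs, n_perm=1, seed=0)
        assert res.p_value in (0.5, 1.0)

    def test_matched_data_attains_minimum_p(self):
        rng = np.random.default_rng(4)
        pred = rng.normal(size=(40, 180))
        obs = pred + rng.normal(0, 0.2, pred.shape)
        res = permutation_test(obs, pred, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1.0 / 1000.0)
        assert res.observed_zbar > res.null_zbars.max()

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        obs = rng.normal(size=(10, 80))
        pred = rng.normal(size=(10, 80))
        a = permutation_test(obs, pred, n_perm=200, seed=7)
        b = permutation_test(obs, pred, n_perm=200, seed=7)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_zbars, b.null_zbars)

    def test_p_value_invariant_formula(self):
        rng = np.random.default_rng(6)
        obs = rng.normal(size=(8, 80))
        res = permutation_test(obs, rng.normal(size=(8, 80)), n_perm=99,
                               seed=2)
        k = int((res.null_zbars >= res.observed_zbar).sum())
        assert res.p_value == (k + 1) / 100

    def test_parameter_errors(self):
        rng = np.random.default_rng(7)
        obs = rng.normal(size=(4, 30))
        with pytest.raises(ValueError):
            permutation_test(obs, obs, n_perm=0)
        with pytest.raises(ValueError):
            permutation_test(obs[:1], obs[:1], n_perm=10)


class TestCircularCorrelation:
    def test_identity_and_rotation_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(-np.pi, np.pi, 50)
        assert circular_correlation(a, a) == pytest.approx(1.0)
        assert circular_correlation(a, a + 1.3) == pytest.approx(1.0)
        assert circular_correlation(a + 0.4, a + 2.9) == pytest.approx(1.0)

    def test_joint_negation_invariance(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(-np.pi, np.pi, 40)
        b = a + rng.normal(0, 0.5, 40)
        assert circular_correlation(-a, -b) == pytest.approx(
            circular_correlation(a, b))

    def test_independent_angles_near_zero(self):
        rng = np.random.default_rng(10)
        a = rng.uniform(-np.pi, np.pi, 1000)
        b = rng.uniform(-np.pi, np.pi, 1000)
        assert abs(circular_correlation(a, b)) < 0.08

    def test_against_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 2 * np.pi, 60)
        b = np.mod(a + rng.normal(0, 0.8, 60), 2 * np.pi)
        ours = circular_correlation(a, b)
        theirs = pingouin.circ_corrcc(a, b)[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            circular_correlation(np.zeros(5), np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            circular_correlation(np.array([0.1, 0.2]), np.array([0.3, 0.4]))


class TestParameterCorrelations:
    @staticmethod
    def two_condition_fits(seed=0, n=40):
        rng = np.random.default_rng(seed)
        base = pd.DataFrame({
            "vertex_id": np.arange(n),
            "area": ["V1"] * n,
            "polar_rad": rng.uniform(-np.pi, np.pi, n),
            "ecc_deg": rng.uniform(0.5, 3.5, n),
            "sigma": rng.uniform(0.3, 1.5, n),
            "beta": rng.normal(1, 0.2, n),
            "r_squared": rng.uniform(0, 1, n),
        })
        a = base.assign(condition="A")
        b = base.assign(condition="B")
        return a, b, rng

    def test_identical_conditions_give_unit_cells(self):
        a, b, _ = self.two_condition_fits()
        out = parameter_correlations(pd.concat([a, b], ignore_index=True))
        assert np.allclose(out["r"], 1.0)

    def test_noise_parameter_decorrelates_only_that_cell(self):
        a, b, rng = self.two_condition_fits(seed=1, n=200)
        b["sigma"] = rng.uniform(0.3, 1.5, len(b))
        out = parameter_correlations(pd.concat([a, b], ignore_index=True))
        sig = out[out["parameter"] == "sigma"]["r"].iloc[0]
        others = out[out["parameter"] != "sigma"]["r"]
        assert abs(sig) < 0.2
        assert (others > 0.99).all()

    def test_insufficient_vertices_marked_missing(self):
        a, b, _ = self.two_condition_fits(n=2)
        out = parameter_correlations(pd.concat([a, b], ignore_index=True))
        assert out["r"].isna().all()
        assert (out["n"] == 2).all()


class TestGazeMad:
    def test_constant_trace(self):
        g = pd.DataFrame({"x_deg": np.zeros(10), "y_deg": np.zeros(10)})
        assert gaze_mad(g) == (0.0, 0.0)

    def test_two_point_trace_exact(self):
        x = np.tile([0.3, -0.3], 50)
        g = pd.DataFrame({"x_deg": x, "y_deg": np.zeros(100)})
        assert gaze_mad(g)[0] == pytest.approx(0.3)

    def test_empty_trace(self):
        with pytest.raises(ValueError):
            gaze_mad(pd.DataFrame({"x_deg": [], "y_deg": []}))
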