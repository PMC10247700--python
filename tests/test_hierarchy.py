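import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from voxenc.coords import pixel_to_percent
from voxenc.hierarchy import (LayerPartition, alpha_index, default_partition,
                              fit_rf_ellipse, layer_contribution_fractions,
                              size_eccentricity_fit)
from voxenc.readout import GaussianPoolingField


def entailment_matrix(a=4, slope=-0.1):
    """Zero diagonal and train-anterior/test-posterior triangle; the opposite
    triangle falls off linearly with taxicab distance."""
    m = np.zeros((a, a))
    for r in range(a):
        for c in range(a):
            if r < c:
                m[r, c] = slope * (c - r)
    return m


class TestAlphaIndex:
    def test_strict_entailment_gives_alpha_one(self):
        res = alpha_index(entailment_matrix())
        assert res.alpha == pytest.approx(1.0, abs=1e-12)
        assert res.a_plus == pytest.approx(0.0, abs=1e-12)
        assert res.a_minus == pytest.approx(-0.1, abs=1e-12)

    def test_symmetric_matrix_gives_alpha_zero(self):
        m = np.array([[-0.05 * abs(i - j) for j in range(4)]
                      for i in range(4)])
        assert alpha_index(m).alpha == pytest.approx(0.0, abs=1e-12)

    def test_reverse_entailment_gives_minus_one(self):
        assert alpha_index(entailment_matrix().T).alpha \
            == pytest.approx(-1.0, abs=1e-12)

    def test_transposition_negates_alpha(self, rng):
        m = rng.normal(scale=0.1, size=(4, 4))
        assert alpha_index(m.T).alpha == pytest.approx(-alpha_index(m).alpha,
                                                       abs=1e-12)

    def test_degenerate_slopes_flagged_undefined(self):
        res = alpha_index(np.zeros((4, 4)))
        assert res.undefined

    def test_requires_three_areas(self):
        with pytest.raises(ValueError):
            alpha_index(np.zeros((2, 2)))

    @given(st.integers(0, 10_000))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_alpha_bounded_for_random_matrices(self, seed):
        m = np.random.default_rng(seed).normal(scale=0.1, size=(4, 4))
        res = alpha_index(m)
        if not res.undefined:
            assert -1.0 - 1e-12 <= res.alpha <= 1.0 + 1e-12


class TestLayerPartition:
    def test_partition_halves_must_be_nonempty_and_disjoint(self):
        with pytest.raises(ValueError):
            LayerPartition((), ("a",))
        with pytest.raises(ValueError):
            LayerPartition(("a",), ("a", "b"))

    def test_partition_must_cover_exposed_layers(self):
        p = LayerPartition(("a",), ("b",))
        with pytest.raises(ValueError):
            p.validate(["a", "b", "c"])

    def test_default_partition_splits_at_midpoint_ties_to_bottom(self):
        p = default_partition(["l1", "l2", "l3"])
        assert p.bottom == ("l1", "l2") and p.top == ("l3",)


class TestLayerContributionFractions:
    @staticmethod
    def _masked(rho, rho_b, rho_t):
        return pd.DataFrame({"voxel": np.arange(len(rho)), "rho": rho,
                             "rho_bottom": rho_b, "rho_top": rho_t})

    def test_hand_computed_fractions(self):
        masked = self._masked([0.5], [0.4], [0.3])
        out = layer_contribution_fractions(masked, np.array([1]),
                                           threshold=0.055, n_bootstrap=0)
        assert out["f_bottom_specific"].iloc[0] == pytest.approx(0.64)
        assert out["f_bottom_unique"].iloc[0] \
            == pytest.approx((0.25 - 0.09) / 0.25)

    def test_zero_top_weights_give_unit_bottom_fractions(self):
        masked = self._masked([0.5], [0.5], [0.0])
        out = layer_contribution_fractions(masked, np.array([1]),
                                           n_bootstrap=0)
        assert out["f_bottom_specific"].iloc[0] == pytest.approx(1.0)
        assert out["f_bottom_unique"].iloc[0] == pytest.approx(1.0)

    def test_subthreshold_voxels_excluded_with_count(self):
        masked = self._masked([0.5, 0.01], [0.4, 0.0], [0.3, 0.0])
        out = layer_contribution_fractions(masked, np.array([1, 1]),
                                           threshold=0.055, n_bootstrap=0)
        assert out.attrs["n_excluded"] == 1

    def test_partition_identity(self, rng):
        """f_unique - f_specific = (rho^2 - rho_b^2 - rho_t^2)/rho^2, exactly."""
        rho = rng.uniform(0.2, 0.9, 20)
        rho_b = rho * rng.uniform(0, 1, 20)
        rho_t = rho * rng.uniform(0, 1, 20)
        masked = self._masked(rho, rho_b, rho_t)
        out = layer_contribution_fractions(masked, np.ones(20, dtype=int),
                                           threshold=0.0, n_bootstrap=0)
        # recompute per-voxel identity from the same inputs
        lhs = (rho ** 2 - rho_t ** 2) / rho ** 2 - rho_b ** 2 / rho ** 2
        rhs = (rho ** 2 - rho_b ** 2 - rho_t ** 2) / rho ** 2
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)
        assert {"f_bottom_specific", "f_bottom_unique"} <= set(out.columns)


class TestRFEllipse:
    def test_isotropic_gaussian_recovered_within_two_percent(self):
        for sigma in (5.0, 10.0, 20.0):
            grid = GaussianPoolingField((8.0, -4.0), sigma).raster(64)
            e = fit_rf_ellipse(grid)
            assert e.a == pytest.approx(sigma, rel=0.02)
            assert e.b == pytest.approx(sigma, rel=0.02)
            assert e.size == pytest.approx(sigma * np.sqrt(np.pi), rel=0.02)

    def test_translation_equivariance(self):
        res, shift_px = 64, 6
        grid = GaussianPoolingField((0.0, 0.0), 8.0).raster(res)
        shifted = np.roll(grid, shift_px, axis=1)  # shift right by k pixels
        e0 = fit_rf_ellipse(grid)
        e1 = fit_rf_ellipse(shifted)
        dx_expected = shift_px * 100.0 / res
        assert e1.center[0] - e0.center[0] == pytest.approx(dx_expected,
                                                            abs=0.05)
        assert e1.center[1] == pytest.approx(e0.center[1], abs=0.05)

    def test_anisotropic_axis_ratio(self):
        res = 64
        from voxenc.coords import pixel_centers
        x, y = pixel_centers(res)
        sx, sy = 16.0, 8.0
        grid = np.exp(-0.5 * ((x / sx) ** 2 + (y / sy) ** 2))
        grid /= grid.sum()
        e = fit_rf_ellipse(grid)
        assert e.a / e.b == pytest.approx(2.0, rel=0.05)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            fit_rf_ellipse(np.full((8, 8), -1.0))
        with pytest.raises(ValueError):
            fit_rf_ellipse(np.zeros((8, 8)))

    def test_diffuse_grid_falls_back_to_moments(self, rng):
        grid = np.full((16, 16), 1 / 256) + rng.random((16, 16)) * 1e-4
        grid /= grid.sum()
        e = fit_rf_ellipse(grid)
        assert e.size < 200  # sane even for a near-uniform field


class TestSizeEccentricityFit:
    @staticmethod
    def _rf_table(slope, intercept, areas, n=30, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for area in areas:
            ecc = rng.uniform(0, 40, n)
            rows.append(pd.DataFrame({
                "voxel": np.arange(n), "eccentricity": ecc,
                "size": slope[area - 1] * ecc + intercept[area - 1],
                "area": area}))
        return pd.concat(rows, ignore_index=True)

    def test_recovers_constructed_line(self):
        rf = self._rf_table([0.1], [2.0], [1])
        out = size_eccentricity_fit(rf)
        assert out["slope"].iloc[0] == pytest.approx(0.1, abs=0.01)
        assert out["intercept"].iloc[0] == pytest.approx(2.0, abs=0.2)

    def test_ordering_preserved_at_matched_eccentricity(self):
        rf = self._rf_table([0.1, 0.15, 0.22, 0.3], [2, 3.5, 5.5, 8],
                            [1, 2, 3, 4])
        out = size_eccentricity_fit(rf).sort_values("area")
        sizes = out["size_at_ref"].to_numpy()
        assert (np.diff(sizes) > 0).all()

    def test_single_area_fits_one_line(self):
        out = size_eccentricity_fit(self._rf_table([0.2], [3.0], [1]))
        assert len(out) == 1

    def test_sparse_area_skipped_with_report(self):
        rf = self._rf_table([0.1], [2.0], [1], n=4)
        out = size_eccentricity_fit(rf, min_voxels=10)
        assert out["skipped"].iloc[0]
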