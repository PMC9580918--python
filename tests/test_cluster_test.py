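"""Unit and property tests for the toroidal-shift nanoclustering test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clasta.cluster_test import (StepCDF, cdf_integral, clasta_p_value,
                                 cross_nn_distances, rank_p_value,
                                 toroidal_shift)
from clasta.smlm import LocalizationMap, SmlmConfig, simulate_two_color_map


def torus_pairwise_distances(points, roi):
    """Brute-force multiset of pairwise distances on the torus."""
    w, h = roi
    out = []
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            dx = abs(points[i, 0] - points[j, 0])
            dy = abs(points[i, 1] - points[j, 1])
            dx = min(dx, w - dx)
            dy = min(dy, h - dy)
            out.append(np.hypot(dx, dy))
    return np.sort(out)


class TestToroidalShift:
    def test_zero_vector_is_identity(self, rng):
        pts = rng.uniform(0, 1000, size=(10, 2))
        np.testing.assert_array_equal(toroidal_shift(pts, (1000, 1000), (0, 0)), pts)

    def test_wraps_modularly(self):
        out = toroidal_shift(np.array([[900.0, 500.0]]), (1000, 1000), (200, 0))
        np.testing.assert_allclose(out, [[100.0, 500.0]])

    def test_point_outside_roi_rejected(self):
        with pytest.raises(ValueError, match="outside ROI"):
            toroidal_shift(np.array([[1500.0, 0.0]]), (1000, 1000), (1, 1))

    @given(st.integers(0, 2**31 - 1))
    def test_preserves_within_channel_torus_distances(self, seed):
        rng = np.random.default_rng(seed)
        roi = (800.0, 600.0)
        pts = rng.uniform((0, 0), roi, size=(20, 2))
        v = rng.uniform((0, 0), roi)
        shifted = toroidal_shift(pts, roi, v)
        np.testing.assert_allclose(torus_pairwise_distances(shifted, roi),
                                   torus_pairwise_distances(pts, roi),
                                   atol=1e-9)


class TestCrossNNDistances:
    def test_three_four_five_triangle(self):
        d = cross_nn_distances(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]))
        np.testing.assert_allclose(d, [5.0])

    def test_colocated_points_have_zero_distance(self):
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(cross_nn_distances(pts, pts), [0.0, 0.0])

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="no reference localizations"):
            cross_nn_distances(np.array([[0.0, 0.0]]), np.zeros((0, 2)))

    def test_matches_brute_force_minima(self, rng):
        q = rng.uniform(0, 100, size=(50, 2))
        r = rng.uniform(0, 100, size=(50, 2))
        brute = np.sqrt(((q[:, None, :] - r[None, :, :]) ** 2).sum(-1)).min(axis=1)
        np.testing.assert_allclose(cross_nn_distances(q, r), brute)


class TestCdfIntegral:
    def test_all_distances_zero_gives_full_width(self):
        cdf = StepCDF.from_values(np.zeros(5))
        assert cdf_integral(cdf, 0.0, 200.0) == pytest.approx(200.0)

    def test_all_distances_beyond_upper_bound_give_zero(self):
        cdf = StepCDF.from_values(np.array([300.0, 400.0]))
        assert cdf_integral(cdf, 0.0, 200.0) == pytest.approx(0.0)

    def test_equal_weight_distances(self):
        cdf = StepCDF.from_values(np.array([50.0, 100.0, 150.0, 200.0]))
        assert cdf_integral(cdf, 0.0, 200.0) == pytest.approx(75.0)

    def test_invalid_bounds_rejected(self):
        cdf = StepCDF.from_values(np.array([1.0]))
        with pytest.raises(ValueError):
            cdf_integral(cdf, 200.0, 100.0)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_fine_grid_riemann_sum(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 300, size=rng.integers(1, 40))
        cdf = StepCDF.from_values(values)
        grid = np.arange(0.0, 200.0, 0.01)
        riemann = float(np.sum(cdf(grid) * 0.01))
        assert cdf_integral(cdf, 0.0, 200.0) == pytest.approx(riemann, abs=0.02)


class TestRankPValue:
    def test_strictly_largest_gives_minimal_p(self, rng):
        controls = rng.normal(size=99)
        assert rank_p_value(controls.max() + 1, controls) == pytest.approx(0.01)

    def test_strictly_smallest_right_sided_gives_one(self, rng):
        controls = rng.normal(size=99)
        assert rank_p_value(controls.min() - 1, controls, "right") == pytest.approx(1.0)

    def test_third_largest_of_five(self):
        # S = {s0} U controls has 5 elements; s0 ranked third -> p = 3/5
        assert rank_p_value(3.0, [5.0, 4.0, 2.0, 1.0]) == pytest.approx(0.6)

    def test_ties_count_as_extreme(self):
        assert rank_p_value(1.0, [1.0, 1.0, 0.0, 0.0]) == pytest.approx(0.6)

    def test_left_and_two_sided(self):
        controls = [1.0, 2.0, 3.0, 4.0]
        assert rank_p_value(0.0, controls, "left") == pytest.approx(0.2)
        assert rank_p_value(0.0, controls, "two") == pytest.approx(0.4)
        assert rank_p_value(2.5, controls, "two") == pytest.approx(1.0)

    def test_non_finite_statistic_rejected(self):
        with pytest.raises(ValueError):
            rank_p_value(float("nan"), [1.0, 2.0])

    @given(st.integers(0, 2**31 - 1), st.integers(1, 50))
    def test_p_lies_on_discrete_grid(self, seed, n):
        rng = np.random.default_rng(seed)
        controls = rng.normal(size=n)
        p = rank_p_value(rng.normal(), controls)
        assert (p * (n + 1)) == pytest.approx(round(p * (n + 1)))
        assert 1 / (n + 1) <= p <= 1


def tiny_map(rng, n_blue=15, n_red=15, roi=(1000.0, 1000.0)):
    coords = np.concatenate([rng.uniform((0, 0), roi, size=(n_red, 2)),
                             rng.uniform((0, 0), roi, size=(n_blue, 2))])
    channels = np.array(["red"] * n_red + ["blue"] * n_blue, dtype=object)
    return LocalizationMap(coords=coords, channels=channels, roi=roi)


class TestClastaPValue:
    def test_p_on_grid_and_deterministic(self, rng):
        loc_map = tiny_map(rng)
        r1 = clasta_p_value(loc_map, n_shifts=99, rng=7)
        r2 = clasta_p_value(loc_map, n_shifts=99, rng=7)
        assert r1.p == r2.p
        assert round(r1.p * 100) == pytest.approx(r1.p * 100)
        np.testing.assert_array_equal(r1.shift_vectors, r2.shift_vectors)

    def test_empty_channel_rejected(self, rng):
        loc_map = tiny_map(rng, n_blue=0)
        with pytest.raises(ValueError, match="no localizations"):
            clasta_p_value(loc_map, rng=rng)

    def test_matches_monolithic_brute_force(self, rng):
        """The KD-tree/step-CDF path equals a from-scratch recomputation."""
        loc_map = tiny_map(rng, n_blue=30, n_red=30)
        result = clasta_p_value(loc_map, n_shifts=25, rng=11)

        def brute_statistic(blue, red, lo=0.0, hi=200.0):
            d = np.sqrt(((blue[:, None, :] - red[None, :, :]) ** 2).sum(-1)).min(1)
            return np.mean(np.maximum(hi - np.maximum(d, lo), 0.0))

        blue, red = loc_map.points("blue"), loc_map.points("red")
        s0 = brute_statistic(blue, red)
        controls = np.array([
            brute_statistic(np.mod(blue + v, loc_map.roi), red)
            for v in result.shift_vectors
        ])
        assert result.s0 == pytest.approx(s0, rel=1e-12)
        np.testing.assert_allclose(result.controls, controls, rtol=1e-12)
        expected_p = (1 + np.count_nonzero(controls >= s0)) / 26
        assert result.p == pytest.approx(expected_p)

    def test_null_rejection_rate_small_scale(self):
        # monomer null on a tiny ROI: rate at alpha=0.05 within 3 binomial s.e.
        config = SmlmConfig(roi_width=1500.0, roi_height=1500.0)
        master = np.random.default_rng(2024)
        n_runs, n_shifts, alpha = 200, 19, 0.05
        rejections = 0
        for child in master.spawn(n_runs):
            loc_map = simulate_two_color_map(config, child)
            p = clasta_p_value(loc_map, n_shifts=n_shifts, rng=child).p
            rejections += p <= alpha
        se = np.sqrt(alpha * (1 - alpha) / n_runs)
        assert abs(rejections / n_runs - alpha) < 3 * se

    def test_power_increases_with_molecule_count(self):
        # dimer sensitivity grows with ROI size (hence molecule count)
        master = np.random.default_rng(77)
        rates = []
        for side_nm in (2600.0, 6400.0):
            config = SmlmConfig(roi_width=side_nm, roi_height=side_nm,
                                oligomer_size=2)
            hits = 0
            for child in master.spawn(40):
                loc_map = simulate_two_color_map(config, child)
                hits += clasta_p_value(loc_map, n_shifts=39, rng=child).p <= 0.05
            rates.append(hits / 40)
        assert rates[1] >= rates[0]
        assert rates[1] >= 0.8
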