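"""Estimator correctness: brute-force oracles, symmetry, invariances, edge weights.

The independent reference for both statistics is a naive double loop over
ordered inter-type pairs, written here without any of the implementation's
vectorised machinery.  The edge weight it uses is the analytic
circle-in-rectangle fraction, which is itself checked against a numeric
arc-sampling oracle in this module.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treeassoc import DistanceGrid, MarkedPattern, Window, cross_pair_weights, kmm_hat, lrs_hat
from treeassoc.spatial_stats import circle_in_rectangle_fraction

from conftest import random_pattern

COARSE = DistanceGrid([2.0, 5.0, 10.0, 20.0, 35.0, 50.0])


def edge_weight(point, r, window):
    frac = float(circle_in_rectangle_fraction(np.asarray(point), np.asarray(r), window))
    return 1.0 / frac


def brute_lrs(a, b, lags, corr):
    lam = a.n / a.window.area + b.n / b.window.area
    out = []
    for d in lags:
        s_ab = s_ba = 0.0
        for i in range(a.n):
            for j in range(b.n):
                dij = math.hypot(*(a.points[i] - b.points[j]))
                if dij <= d:
                    w_ab = 1.0 if corr == "none" else edge_weight(a.points[i], dij, a.window)
                    w_ba = 1.0 if corr == "none" else edge_weight(b.points[j], dij, b.window)
                    s_ab += w_ab
                    s_ba += w_ba
        out.append((s_ab / a.n + s_ba / b.n) / (lam * (a.n + b.n) * math.pi))
    return np.array(out)


def brute_kmm(a, b, lags, corr):
    z_a = (a.marks - a.marks.mean()) / a.marks.std(ddof=1)
    z_b = (b.marks - b.marks.mean()) / b.marks.std(ddof=1)
    out = []
    for d in lags:
        num = den = 0.0
        for i in range(a.n):
            for j in range(b.n):
                dij = math.hypot(*(a.points[i] - b.points[j]))
                if dij <= d:
                    w_ab = 1.0 if corr == "none" else edge_weight(a.points[i], dij, a.window)
                    w_ba = 1.0 if corr == "none" else edge_weight(b.points[j], dij, b.window)
                    num += (w_ab + w_ba) * z_a[i] * z_b[j]
                    den += w_ab + w_ba
        out.append(num / den if den > 0 else np.nan)
    return np.array(out)


class TestEdgeWeight:
    def test_interior_circle_fully_inside(self, window):
        frac = circle_in_rectangle_fraction(np.array([50.0, 50.0]), np.array(10.0), window)
        assert frac == pytest.approx(1.0)

    def test_numeric_arc_oracle(self, window, rng):
        theta = np.linspace(0, 2 * np.pi, 100_001)[:-1]
        for _ in range(25):
            c = rng.uniform(0, 100, 2)
            r = rng.uniform(0.5, 50.0)
            inside = (
                (c[0] + r * np.cos(theta) >= 0) & (c[0] + r * np.cos(theta) <= 100)
                & (c[1] + r * np.sin(theta) >= 0) & (c[1] + r * np.sin(theta) <= 100)
            )
            analytic = float(circle_in_rectangle_fraction(c, np.array(r), window))
            assert analytic == pytest.approx(inside.mean(), abs=1e-4)


class TestCrossPairWeights:
    def test_no_pair_within_distance(self, window):
        a = MarkedPattern([[40.0, 50.0]], [10.0], window, "A")
        b = MarkedPattern([[50.0, 50.0]], [10.0], window, "B")
        assert cross_pair_weights(a, b, 5.0, "none") == (0.0, 0.0)

    def test_single_pair_counted_both_directions(self, window):
        a = MarkedPattern([[40.0, 50.0]], [10.0], window, "A")
        b = MarkedPattern([[50.0, 50.0]], [10.0], window, "B")
        assert cross_pair_weights(a, b, 15.0, "none") == (1.0, 1.0)

    def test_ripley_weights_match_geometric_oracle(self, window):
        # 3+3 stems, some near edges so the correction actually bites
        a = MarkedPattern([[1.0, 1.0], [50.0, 2.0], [99.0, 50.0]], [1, 2, 3], window, "A")
        b = MarkedPattern([[5.0, 10.0], [45.0, 1.0], [90.0, 55.0]], [1, 2, 3], window, "B")
        d = 20.0
        exp_ab = exp_ba = 0.0
        for p in a.points:
            for q in b.points:
                dij = math.hypot(*(p - q))
                if dij <= d:
                    exp_ab += edge_weight(p, dij, window)
                    exp_ba += edge_weight(q, dij, window)
        got_ab, got_ba = cross_pair_weights(a, b, d, "ripley_isotropic")
        assert got_ab == pytest.approx(exp_ab, rel=1e-10)
        assert got_ba == pytest.approx(exp_ba, rel=1e-10)

    def test_mismatched_windows_rejected(self, window):
        a = MarkedPattern([[1.0, 1.0]], [1.0], window, "A")
        b = MarkedPattern([[2.0, 2.0]], [1.0], Window(50, 50), "B")
        with pytest.raises(ValueError, match="window"):
            cross_pair_weights(a, b, 5.0)


@pytest.mark.parametrize("corr", ["none", "ripley_isotropic"])
class TestOracleEquivalence:
    def test_lrs_matches_double_loop(self, rng, window, corr):
        for _ in range(10):
            a = random_pattern(rng, window, int(rng.integers(2, 21)), "A")
            b = random_pattern(rng, window, int(rng.integers(2, 21)), "B")
            got = lrs_hat(a, b, COARSE, corr).values
            np.testing.assert_allclose(got, brute_lrs(a, b, COARSE.lags, corr), atol=1e-10)

    def test_kmm_matches_double_loop(self, rng, window, corr):
        for _ in range(10):
            a = random_pattern(rng, window, int(rng.integers(3, 21)), "A")
            b = random_pattern(rng, window, int(rng.integers(3, 21)), "B")
            got = kmm_hat(a, b, COARSE, corr).values
            np.testing.assert_allclose(got, brute_kmm(a, b, COARSE.lags, corr), atol=1e-10)


class TestLrs:
    def test_all_zero_when_no_intertype_pair_in_range(self, window):
        a = MarkedPattern([[0.0, 0.0]], [5.0], window, "A")
        b = MarkedPattern([[99.0, 99.0]], [5.0], window, "B")
        assert np.all(lrs_hat(a, b, DistanceGrid(), "none").values == 0.0)

    def test_symmetric_in_arguments(self, pattern_pair, grid):
        a, b = pattern_pair
        for corr in ("none", "ripley_isotropic"):
            np.testing.assert_array_equal(
                lrs_hat(a, b, grid, corr).values, lrs_hat(b, a, grid, corr).values
            )

    def test_monotone_without_correction(self, pattern_pair, grid):
        vals = lrs_hat(*pattern_pair, grid, "none").values
        assert np.all(np.diff(vals) >= 0)

    def test_empty_pattern_names_species(self, window):
        a = MarkedPattern(np.empty((0, 2)), [], window, "Ghost")
        b = MarkedPattern([[1.0, 1.0]], [5.0], window, "B")
        with pytest.raises(ValueError, match="Ghost"):
            lrs_hat(a, b)

    def test_csr_expectation(self, window):
        """Mean over independent CSR pairs: d^2/(n_r+n_s) with edge correction at
        all lags; without correction only as a small-d limit (counts near the
        boundary are deflated)."""
        g = DistanceGrid([2.5, 5.0, 20.0, 50.0])
        none_curves, ripley_curves = [], []
        for s in range(300):
            r = np.random.default_rng(s)
            a = MarkedPattern(r.uniform(0, 100, (100, 2)), np.ones(100), window)
            b = MarkedPattern(r.uniform(0, 100, (100, 2)), np.ones(100), window)
            none_curves.append(lrs_hat(a, b, g, "none").values)
            ripley_curves.append(lrs_hat(a, b, g, "ripley_isotropic").values)
        expect = g.lags**2 / 200.0
        ratio_none = np.mean(none_curves, axis=0) / expect
        ratio_ripley = np.mean(ripley_curves, axis=0) / expect
        assert ratio_none[0] == pytest.approx(1.0, abs=0.06)  # d = 2.5 m
        np.testing.assert_allclose(ratio_ripley, 1.0, atol=0.03)


class TestKmm:
    def test_undefined_lags_are_nan_not_zero(self, window):
        a = MarkedPattern([[0.0, 0.0], [1.0, 0.0]], [5.0, 10.0], window, "A")
        b = MarkedPattern([[40.0, 0.0], [41.0, 0.0]], [5.0, 10.0], window, "B")
        vals = kmm_hat(a, b, DistanceGrid([1.0, 30.0, 45.0]), "none").values
        assert np.isnan(vals[0]) and np.isnan(vals[1]) and not np.isnan(vals[2])

    def test_symmetric_in_arguments(self, pattern_pair, grid):
        a, b = pattern_pair
        np.testing.assert_array_equal(kmm_hat(a, b, grid).values, kmm_hat(b, a, grid).values)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), shift=st.floats(-100.0, 100.0))
    def test_affine_invariance_of_marks(self, scale, shift):
        rng = np.random.default_rng(7)
        w = Window(100, 100)
        a = random_pattern(rng, w, 12, "A")
        b = random_pattern(rng, w, 12, "B")
        base = kmm_hat(a, b, COARSE).values
        a2 = MarkedPattern(a.points, scale * a.marks + shift, w, "A")
        np.testing.assert_allclose(kmm_hat(a2, b, COARSE).values, base, atol=1e-9)

    def test_sign_flips_when_one_species_negated(self, pattern_pair, grid):
        a, b = pattern_pair
        base = kmm_hat(a, b, grid).values
        neg = MarkedPattern(a.points, -a.marks, a.window, "A")
        np.testing.assert_allclose(kmm_hat(neg, b, grid).values, -base, atol=1e-9)

    def test_constant_marks_rejected(self, window):
        a = MarkedPattern([[0.0, 0.0], [1.0, 0.0]], [5.0, 5.0], window, "Flat")
        b = MarkedPattern([[2.0, 0.0], [3.0, 0.0]], [5.0, 10.0], window, "B")
        with pytest.raises(ValueError, match="Flat"):
            kmm_hat(a, b)

    def test_permuted_marks_average_to_zero(self, rng, window):
        a = random_pattern(rng, window, 40, "A")
        b = random_pattern(rng, window, 40, "B")
        g = DistanceGrid([10.0, 25.0, 50.0])
        curves = []
        for _ in range(500):
            aa = MarkedPattern(a.points, rng.permutation(a.marks), window, "A")
            bb = MarkedPattern(b.points, rng.permutation(b.marks), window, "B")
            curves.append(kmm_hat(aa, bb, g, "none").values)
        np.testing.assert_allclose(np.mean(curves, axis=0), 0.0, atol=0.05)
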