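"""Density filtering, multiplex richness, rich-core decomposition, coreness
sweep, and the coreness disruption index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plexcore import (
    DensityGrid,
    LayerCoefficients,
    coreness,
    group_kappa,
    kappa,
    multiplex_richness,
    planted_core_multiplex,
    rich_core,
    threshold_layer,
)


def _sym(rng, n, scale=1.0):
    w = rng.random((n, n)) * scale
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    return w


def brute_force_mu_plus(layers, coeffs, order):
    """Independent oracle: mu_plus by explicit double loop over ranked nodes."""
    n = layers[0].shape[0]
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if pos[j] < pos[i]:
                out[i] += sum(c * w[i, j] for c, w in zip(coeffs, layers))
    return out


class TestThresholdLayer:
    def test_density_one_is_identity(self, rng):
        w = _sym(rng, 8)
        np.testing.assert_array_equal(threshold_layer(w, 1.0), w)

    def test_four_nodes_half_density_keeps_three_largest(self):
        w = np.zeros((4, 4))
        vals = {(0, 1): 6, (0, 2): 5, (0, 3): 4, (1, 2): 3, (1, 3): 2, (2, 3): 1}
        for (i, j), v in vals.items():
            w[i, j] = w[j, i] = v
        out = threshold_layer(w, 0.5)
        kept = {(i, j) for i, j in zip(*np.triu_indices(4, 1)) if out[i, j] > 0}
        assert kept == {(0, 1), (0, 2), (0, 3)}
        assert out[0, 1] == 6  # weights retained, not binarized

    def test_tie_break_lexicographic(self):
        w = np.ones((4, 4)) - np.eye(4)
        out = threshold_layer(w, 0.5)
        kept = [(i, j) for i, j in zip(*np.triu_indices(4, 1)) if out[i, j] > 0]
        assert kept == [(0, 1), (0, 2), (0, 3)]

    @pytest.mark.parametrize("density", [0.0, -0.1, 1.5])
    def test_bad_density_raises(self, density, rng):
        with pytest.raises(ValueError, match="density"):
            threshold_layer(_sym(rng, 4), density)


class TestRichness:
    def test_linear_combination_of_strengths(self):
        # one node with strengths (2, 4, 6) across layers, c = 0.5 each
        layers = [np.array([[0.0, s], [s, 0.0]]) for s in (2.0, 4.0, 6.0)]
        rv = multiplex_richness(layers, [0.5, 0.5, 0.5])
        assert rv.mu[0] == pytest.approx(6.0)

    def test_isolated_node_zero(self, rng):
        w = _sym(rng, 5)
        w[4, :] = w[:, 4] = 0
        rv = multiplex_richness([w], [1.0])
        assert rv.mu[4] == 0 and rv.mu_plus[4] == 0

    def test_linearity_in_coefficients(self, rng):
        layers = [_sym(rng, 6) for _ in range(3)]
        rv1 = multiplex_richness(layers, [0.5, 0.5, 0.5])
        order = np.lexsort((np.arange(6), -rv1.mu))
        rv2 = multiplex_richness(layers, [1.0, 1.0, 1.0], ranking=order)
        np.testing.assert_allclose(2 * rv1.mu, rv2.mu, atol=1e-12)
        np.testing.assert_allclose(2 * rv1.mu_plus, rv2.mu_plus, atol=1e-12)

    def test_mu_plus_bounded_by_mu(self, rng):
        layers = [_sym(rng, 10) for _ in range(3)]
        rv = multiplex_richness(layers, [0.5, 0.5, 0.5])
        assert np.all(rv.mu_plus <= rv.mu + 1e-12)

    def test_coefficient_count_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="coefficients"):
            multiplex_richness([_sym(rng, 4)], [0.5, 0.5])


class TestRichCore:
    def test_star_hand_trace(self):
        # star A-B=3, A-C=2, A-D=1: strengths (6,3,2,1), mu_plus (0,3,2,1),
        # boundary at B -> core {A, B}
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 3.0
        w[0, 2] = w[2, 0] = 2.0
        w[0, 3] = w[3, 0] = 1.0
        np.testing.assert_array_equal(rich_core(w, [1.0]), [0, 1])

    def test_all_zero_gives_empty_core(self):
        assert rich_core(np.zeros((5, 5)), [1.0]).size == 0

    def test_two_nodes_one_edge_full_core(self):
        w = np.array([[0.0, 0.7], [0.7, 0.0]])
        np.testing.assert_array_equal(rich_core(w, [1.0]), [0, 1])

    def test_boundary_maximizes_mu_plus_exhaustive(self):
        # oracle check on random small weighted multiplexes
        rng = np.random.default_rng(2024)
        coeffs = [0.5, 0.5, 0.5]
        for _ in range(100):
            n = int(rng.integers(2, 7))
            layers = [_sym(rng, n, scale=rng.uniform(0.5, 3)) for _ in range(3)]
            core = rich_core(layers, coeffs)
            rv = multiplex_richness(layers, coeffs)
            order = np.lexsort((np.arange(n), -rv.mu))
            oracle = brute_force_mu_plus(layers, coeffs, order)[order]
            if core.size == 0:
                assert oracle.max(initial=0) == 0
            else:
                r_star = core.size - 1
                assert oracle[r_star] == pytest.approx(oracle.max())
                # smallest-rank tie rule
                assert not np.any(oracle[:r_star] >= oracle[r_star] - 1e-12)


class TestCoreness:
    def test_planted_noiseless_core_recovered_everywhere(self):
        mx, core = planted_core_multiplex(6, [0, 1, 2], (1.0, 0.5, 0.1), 0.0, seed=0)
        np.testing.assert_array_equal(rich_core(mx), core)

    def test_hand_traceable_fraction(self):
        # B joins the core only once the A-B edge enters the sweep: coreness
        # values are exact counts over the 4-density grid.
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 3.0
        w[0, 2] = w[2, 0] = 2.0
        w[1, 2] = w[2, 1] = 1.0
        grid = DensityGrid(np.array([0.25, 0.5, 0.75, 1.0]))
        prof = coreness(w, grid, [1.0])
        assert np.all(prof.coreness * 4 == np.round(prof.coreness * 4))
        assert prof.coreness[3] == 0.0  # isolated node never in core
        assert prof.coreness[0] == 1.0  # strongest hub always in core

    def test_values_are_grid_multiples_and_in_unit_interval(self, rng):
        layers = [_sym(rng, 12) for _ in range(3)]
        grid = DensityGrid.from_range(0.1, 1.0, 0.1)
        prof = coreness(layers, grid, [0.5, 0.5, 0.5])
        assert np.all((prof.coreness >= 0) & (prof.coreness <= 1))
        np.testing.assert_allclose(
            prof.coreness * len(grid), np.round(prof.coreness * len(grid)), atol=1e-12
        )

    def test_matches_per_density_filtering(self, rng):
        # incremental sweep must equal explicit threshold_layer + rich_core
        layers = [_sym(rng, 9) for _ in range(3)]
        grid = DensityGrid(np.array([0.2, 0.5, 0.9]))
        prof = coreness(layers, grid, [0.5, 0.5, 0.5])
        counts = np.zeros(9)
        for d in grid.densities:
            filtered = [threshold_layer(w, float(d)) for w in layers]
            counts[rich_core(filtered, [0.5, 0.5, 0.5])] += 1
        np.testing.assert_allclose(prof.coreness, counts / 3, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        layers = [_sym(rng, 10) for _ in range(3)]
        grid = DensityGrid.from_range(0.1, 1.0, 0.1)
        base = coreness(layers, grid, [0.5, 0.5, 0.5]).coreness
        perm = rng.permutation(10)
        permuted = [w[np.ix_(perm, perm)] for w in layers]
        prof_p = coreness(permuted, grid, [0.5, 0.5, 0.5]).coreness
        np.testing.assert_allclose(prof_p, base[perm], atol=1e-12)

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError, match="empty"):
            DensityGrid(np.array([]))


class TestKappa:
    def test_subject_equals_reference(self):
        ref = np.array([0.8, 0.5, 0.2])
        res = kappa(ref, ref)
        assert res.kappa == pytest.approx(0.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_zero_subject_gives_minus_one(self):
        ref = np.array([0.8, 0.5, 0.2])
        res = kappa(np.zeros(3), ref)
        assert res.kappa == pytest.approx(-1.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_slope(self):
        # exact least squares: cov(-0.12) / var(0.18) = -2/3
        res = kappa([0.4, 0.35, 0.2], [0.8, 0.5, 0.2])
        assert res.kappa == pytest.approx(-2.0 / 3.0, abs=1e-9)

    def test_recomputable_from_stored_vectors(self, rng):
        ref = rng.random(30)
        subj = rng.random(30)
        res = kappa(subj, ref)
        slope = np.polyfit(res.reference, res.delta, 1)[0]
        assert res.kappa == pytest.approx(slope, abs=1e-12)

    def test_constant_reference_raises(self):
        with pytest.raises(ValueError, match="constant reference"):
            kappa([0.1, 0.2, 0.3], [0.5, 0.5, 0.5])

    def test_group_of_identical_subjects_equals_individual(self, rng):
        ref = rng.random(20)
        subj = rng.random(20)
        gk = group_kappa(np.tile(subj, (5, 1)), ref)
        assert gk.kappa == pytest.approx(kappa(subj, ref).kappa, abs=1e-12)

    def test_group_equal_to_reference_sample_gives_zero(self, rng):
        mat = rng.random((8, 15))
        gk = group_kappa(mat, mat.mean(axis=0))
        assert gk.kappa == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_kappa_affine_response_property(self, seed):
        # subject = a*reference + b  =>  delta = (a-1)*ref + b, slope a-1
        r = np.random.default_rng(seed)
        ref = r.random(12)
        if np.ptp(ref) == 0:
            ref[0] += 0.5
        a, b = r.uniform(-2, 2), r.uniform(-1, 1)
        res = kappa(a * ref + b, ref)
        assert res.kappa == pytest.approx(a - 1, abs=1e-9)
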