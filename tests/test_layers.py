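"""Layer construction: HC-anchored z-scoring, the MC edge formula, the SC/FC
transforms, and spectral-norm normalization."""

import numpy as np
import pytest

from plexcore import (
    ConnectivityLayer,
    NuisanceZScorer,
    assemble_multiplex,
    build_mc_layer,
    svd_normalize,
    transform_fc,
    transform_sc,
    zscore_volumes,
)


class TestZScoreVolumes:
    def test_hand_worked_identical_covariates(self):
        # Three HC at identical covariates: model collapses to the mean (12),
        # residuals (-2, 0, 2), SD (ddof=1) = 2, so z = (-1, 0, +1).
        vols = np.array([[10.0], [12.0], [14.0]])
        covs = np.tile([50.0, 0.0, 1400.0], (3, 1))
        with pytest.warns(UserWarning, match="constant covariate"):
            vz = zscore_volumes(vols, covs, [True, True, True], min_hc=3)
        np.testing.assert_allclose(vz.z.ravel(), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_patient_on_hc_prediction_gets_zero(self, rng):
        # A patient whose volume sits exactly on the HC-fitted model at its
        # covariates must get z = 0.  The patient is outside the fitting
        # sample, so placing it on the fitted plane does not move the fit.
        n = 40
        covs = np.column_stack(
            [rng.uniform(20, 70, n), rng.integers(0, 2, n), rng.normal(1450, 100, n)]
        )
        vols = rng.normal(8, 1, (n, 1)) - 0.02 * covs[:, [0]]
        hc = np.zeros(n, dtype=bool)
        hc[:30] = True
        vz = zscore_volumes(vols, covs, hc)
        design = np.column_stack([np.ones(n), covs])
        vols[-1, 0] = design[-1] @ vz.coef[:, 0]  # last subject is a patient
        vz2 = zscore_volumes(vols, covs, hc)
        assert abs(vz2.z[-1, 0]) < 1e-10

    def test_hc_z_mean_zero_sd_one(self, rng):
        n, p = 60, 5
        covs = np.column_stack(
            [rng.uniform(20, 70, n), rng.integers(0, 2, n), rng.normal(1450, 100, n)]
        )
        vols = rng.normal(8, 1, (n, p)) - 0.02 * covs[:, [0]]
        hc = np.zeros(n, dtype=bool)
        hc[:40] = True
        vz = zscore_volumes(vols, covs, hc)
        np.testing.assert_allclose(vz.z[hc].mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(vz.z[hc].std(axis=0, ddof=1), 1, atol=1e-8)

    def test_age_effect_removed(self):
        rng = np.random.default_rng(42)
        n = 200
        age = rng.uniform(20, 70, n)
        covs = np.column_stack([age, rng.integers(0, 2, n), rng.normal(1450, 100, n)])
        vols = (10 + 0.5 * age + rng.normal(0, 1, n))[:, None]  # planted age slope
        vz = zscore_volumes(vols, covs, np.ones(n, dtype=bool))
        r = np.corrcoef(vz.z[:, 0], age)[0, 1]
        assert abs(r) < 0.05

    def test_too_few_hc_raises(self, rng):
        vols = rng.normal(size=(12, 2))
        covs = rng.normal(size=(12, 3))
        with pytest.raises(ValueError, match="at least 10 HC"):
            zscore_volumes(vols, covs, np.arange(12) < 5)

    def test_collinear_design_raises(self, rng):
        n = 20
        age = rng.uniform(20, 70, n)
        covs = np.column_stack([age, 2 * age])  # genuinely collinear
        with pytest.raises(ValueError, match="singular"):
            NuisanceZScorer().fit(rng.normal(size=(n, 1)), covariates=covs)


class TestMCLayer:
    @pytest.mark.parametrize(
        "zdiff, expected",
        [(0.0, 1.0), (1.0, 0.36787944), (2.0, 0.01831564)],
    )
    def test_edge_formula(self, zdiff, expected):
        layer = build_mc_layer([0.0, zdiff])
        assert layer.weights[0, 1] == pytest.approx(expected, abs=1e-8)

    def test_weight_one_iff_equal_z(self):
        layer = build_mc_layer([0.3, 0.3, -0.5])
        assert layer.weights[0, 1] == 1.0
        assert layer.weights[0, 2] < 1.0

    def test_diagonal_zero_and_range(self, rng):
        layer = build_mc_layer(rng.normal(size=20))
        assert np.all(np.diag(layer.weights) == 0)
        off = layer.weights[~np.eye(20, dtype=bool)]
        assert np.all((off > 0) & (off <= 1))

    def test_shift_invariance(self, rng):
        z = rng.normal(size=10)
        a = build_mc_layer(z).weights
        b = build_mc_layer(z + 3.7).weights
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_nonfinite_z_names_node(self):
        with pytest.raises(ValueError, match="thalamus"):
            build_mc_layer([0.0, np.nan], node_labels=["cortex", "thalamus"])


class TestSCTransform:
    @pytest.mark.parametrize("raw, expected", [(0.0, 0.0), (9.0, 1.0), (99.0, 2.0)])
    def test_log_anchor_values(self, raw, expected):
        m = np.array([[0.0, raw], [raw, 0.0]])
        assert transform_sc(m).weights[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_monotone(self, rng):
        w = rng.gamma(2, 10, size=(6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        t = transform_sc(w).weights
        iu = np.triu_indices(6, 1)
        order_raw = np.argsort(w[iu])
        order_t = np.argsort(t[iu])
        np.testing.assert_array_equal(order_raw, order_t)

    def test_negative_raises(self):
        m = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="negative"):
            transform_sc(m)


class TestFCTransform:
    @pytest.mark.parametrize(
        "r, expected", [(0.0, 0.0), (-0.5, 0.54930614), (0.76159416, 1.0)]
    )
    def test_fisher_z_anchor_values(self, r, expected):
        m = np.array([[1.0, r], [r, 1.0]])
        assert transform_fc(m).weights[0, 1] == pytest.approx(expected, abs=1e-7)

    def test_out_of_range_raises(self):
        m = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match=r"\|r\| >= 1"):
            transform_fc(m)

    def test_absolutization_symmetric_in_sign(self):
        plus = np.array([[1.0, 0.6], [0.6, 1.0]])
        minus = np.array([[1.0, -0.6], [-0.6, 1.0]])
        assert transform_fc(plus).weights[0, 1] == transform_fc(minus).weights[0, 1]


class TestSVDNormalize:
    def test_two_node_example(self):
        out = svd_normalize(np.array([[0.0, 2.0], [2.0, 0.0]]))
        np.testing.assert_allclose(out, [[0.0, 1.0], [1.0, 0.0]], atol=1e-12)

    def test_idempotent_on_normalized(self, rng):
        w = rng.random((8, 8))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        once = svd_normalize(w)
        twice = svd_normalize(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_top_singular_value_is_one(self, rng):
        w = rng.gamma(2, 5, size=(15, 15))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        out = svd_normalize(w)
        assert np.linalg.norm(out, 2) == pytest.approx(1.0, abs=1e-9)

    def test_preserves_rank_order(self, rng):
        w = rng.random((10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        out = svd_normalize(w)
        iu = np.triu_indices(10, 1)
        np.testing.assert_array_equal(np.argsort(w[iu]), np.argsort(out[iu]))

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            svd_normalize(np.zeros((4, 4)))


class TestAssemble:
    def _layer(self, kind, labels, rng):
        w = rng.random((len(labels), len(labels)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        return svd_normalize(ConnectivityLayer(kind, w, labels))

    def test_three_layers_shared_order(self, rng):
        labels = ["a", "b", "c"]
        mx = assemble_multiplex(
            self._layer("MC", labels, rng),
            self._layer("SC", labels, rng),
            self._layer("FC", labels, rng),
        )
        assert len(mx.layers) == 3
        assert mx.node_labels == labels

    def test_permuted_labels_raise(self, rng):
        mx_args = [
            self._layer("MC", ["a", "b", "c"], rng),
            self._layer("SC", ["a", "c", "b"], rng),
            self._layer("FC", ["a", "b", "c"], rng),
        ]
        with pytest.raises(ValueError, match="mismatch"):
            assemble_multiplex(*mx_args)

    def test_unnormalized_layer_raises(self, rng):
        labels = ["a", "b", "c"]
        w = np.array([[0, 2.0, 0], [2.0, 0, 0], [0, 0, 0]])
        bad = ConnectivityLayer("SC", w, labels)
        with pytest.raises(ValueError, match="not SVD-normalized"):
            assemble_multiplex(
                self._layer("MC", labels, rng), bad, self._layer("FC", labels, rng)
            )
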