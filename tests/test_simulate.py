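"""Synthetic cohort generator: planted structure, targeted attack, ground
truth, and calibration of the null (delta = 0) case."""

import numpy as np
import pytest

from plexcore import (
    DensityGrid,
    apply_targeted_attack,
    coreness,
    planted_core_multiplex,
    simulate_cohort,
)
from plexcore.stats import permutation_ttest


class TestPlantedCoreMultiplex:
    def test_noiseless_block_weights_exact(self):
        mx, core = planted_core_multiplex(6, [0, 1, 2], (1.0, 0.5, 0.1), 0.0, seed=0)
        w = mx.layers[0].weights
        # block structure survives normalization up to a common scale
        scale = w[0, 1]  # core-core weight
        assert w[0, 3] / scale == pytest.approx(0.5)
        assert w[3, 4] / scale == pytest.approx(0.1)

    def test_two_nodes_core_orders_coreness(self):
        mx, _ = planted_core_multiplex(3, [0], (1.0, 0.5, 0.1), 0.0, seed=0)
        prof = coreness(mx, DensityGrid(np.array([0.5, 1.0])))
        assert prof.coreness[0] >= prof.coreness[1]

    def test_permutation_equivariant_generation(self):
        mx, core = planted_core_multiplex(8, [0, 1, 2], (1.0, 0.5, 0.1), 0.0, seed=5)
        base = coreness(mx, DensityGrid.from_range(0.1, 1.0, 0.1)).coreness
        perm = np.random.default_rng(1).permutation(8)
        permuted_layers = [w[np.ix_(perm, perm)] for w in mx.weight_arrays()]
        prof = coreness(permuted_layers, DensityGrid.from_range(0.1, 1.0, 0.1)).coreness
        np.testing.assert_allclose(prof, base[perm], atol=1e-12)

    def test_empty_core_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            planted_core_multiplex(6, [], (1.0, 0.5, 0.1), 0.0)

    def test_core_not_proper_subset_raises(self):
        with pytest.raises(ValueError, match="proper subset"):
            planted_core_multiplex(4, [0, 1, 2, 3], (1.0, 0.5, 0.1), 0.0)


class TestTargetedAttack:
    def test_delta_zero_is_identity(self, rng):
        w = rng.random((6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        np.testing.assert_array_equal(apply_targeted_attack(w, np.ones(6), 0.0), w)

    def test_full_attack_annihilates(self, rng):
        w = rng.random((6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        assert np.all(apply_targeted_attack(w, np.ones(6), 1.0) == 0)

    def test_half_attack_on_single_node(self):
        w = np.ones((4, 4)) - np.eye(4)
        aff = np.array([1.0, 0.0, 0.0, 0.0])
        out = apply_targeted_attack(w, aff, 0.5)
        assert np.all(out[0, 1:] == 0.5)      # edges at the attacked node halved
        assert out[1, 2] == 1.0               # others untouched
        np.testing.assert_array_equal(out, out.T)

    @pytest.mark.parametrize("delta", [-0.1, 1.5])
    def test_delta_out_of_range_raises(self, delta):
        with pytest.raises(ValueError, match="delta"):
            apply_targeted_attack(np.zeros((3, 3)), np.ones(3), delta)


class TestSimulateCohort:
    def test_same_seed_identical(self):
        a, _ = simulate_cohort(n_hc=8, n_ms=8, n_nodes=20, n_core=5, seed=77)
        b, _ = simulate_cohort(n_hc=8, n_ms=8, n_nodes=20, n_core=5, seed=77)
        assert a.cohort.equals(b.cohort)
        np.testing.assert_array_equal(a.volumes.to_numpy(), b.volumes.to_numpy())
        for sid in a.subject_ids:
            np.testing.assert_array_equal(a.sc[sid], b.sc[sid])
            np.testing.assert_array_equal(a.fc[sid], b.fc[sid])

    def test_value_ranges(self, small_cohort):
        data, truth = small_cohort
        for sid in data.subject_ids:
            assert np.all(data.sc[sid] >= 0)
            off = ~np.eye(data.parcellation.n_nodes, dtype=bool)
            assert np.all(np.abs(data.fc[sid][off]) < 1)
        assert np.all(data.volumes.to_numpy() > 0)

    def test_hc_have_no_disease_fields(self, small_cohort):
        data, truth = small_cohort
        hc = data.cohort[data.cohort["group"] == "HC"]
        assert (hc["phenotype"] == "NA").all()
        assert hc["edss"].isna().all() and hc["tlv"].isna().all()
        assert all(truth.attack_strength[s] == 0 for s in hc["subject_id"])

    def test_strong_signal_core_block_dominates(self):
        data, truth = simulate_cohort(
            n_hc=3, n_ms=3, n_nodes=30, n_core=6, seed=5,
            params={"sc_weight_means": (40.0, 10.0, 4.0)},
        )
        core = truth.core_indices
        periph = np.setdiff1d(np.arange(30), core)
        for sid in data.subject_ids:
            m = data.sc[sid]
            cc = m[np.ix_(core, core)]
            pp = m[np.ix_(periph, periph)]
            assert cc[np.triu_indices_from(cc, 1)].mean() > \
                pp[np.triu_indices_from(pp, 1)].mean()

    def test_clinical_scores_monotone_in_delta(self):
        balanced = {p: 0.25 for p in ("CIS", "RRMS", "SPMS", "PPMS")}
        data, truth = simulate_cohort(n_hc=5, n_ms=120, n_nodes=16, n_core=4,
                                      phenotype_mix=balanced, seed=9)
        ms = data.cohort[data.cohort["group"] == "MS"]
        delta = np.array([truth.attack_strength[s] for s in ms["subject_id"]])
        assert np.corrcoef(delta, ms["edss"])[0, 1] > 0.3
        assert np.corrcoef(delta, ms["sdmt_z"])[0, 1] < -0.3
        assert np.corrcoef(delta, ms["bpf"])[0, 1] < -0.1
        assert np.corrcoef(delta, ms["tlv"])[0, 1] > 0.1

    def test_null_cohort_groups_indistinguishable(self):
        # delta = 0 everywhere, single site: pooled MS and HC edge weights come
        # from the same distribution; a permutation test should stay calibrated
        zero = {"delta_by_phenotype": {p: 0.0 for p in ("CIS", "RRMS", "SPMS", "PPMS")},
                "delta_sd": 0.0}
        ok = 0
        for seed in range(50):
            data, _ = simulate_cohort(n_hc=6, n_ms=6, n_nodes=16, n_core=4,
                                      params=zero, seed=seed)
            hc_ids = list(data.cohort.loc[data.cohort["group"] == "HC", "subject_id"])
            ms_ids = list(data.cohort.loc[data.cohort["group"] == "MS", "subject_id"])
            iu = np.triu_indices(16, 1)
            rng = np.random.default_rng(seed)
            pick = rng.choice(iu[0].size, 40, replace=False)
            x = np.concatenate([data.sc[s][iu][pick] for s in hc_ids])
            y = np.concatenate([data.sc[s][iu][pick] for s in ms_ids])
            sub = np.random.default_rng(seed + 1).choice(x.size, 60, replace=False)
            _, p = permutation_ttest(x[sub], y[sub], n_perm=1000, seed=seed)
            ok += p > 0.05
        assert ok >= 45  # >= 90% of runs

    def test_bad_phenotype_mix_raises(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_cohort(5, 5, 16, 4, phenotype_mix={"RRMS": 0.5}, seed=0)

    def test_core_too_large_raises(self):
        with pytest.raises(ValueError, match="n_core"):
            simulate_cohort(5, 5, n_nodes=10, n_core=10, seed=0)

    def test_unknown_param_raises(self):
        with pytest.raises(ValueError, match="unknown simulation parameter"):
            simulate_cohort(5, 5, 16, 4, params={"bogus": 1}, seed=0)
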