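"""Binomial test, BH-FDR, cluster filtering and their composition."""

import numpy as np
import pytest
from scipy.stats import binom

from slmvpa import (
    accuracy_to_counts,
    binomial_two_tailed_p,
    cluster_filter,
    fdr_bh,
    infer_subject,
)
from slmvpa.decoding import CentreMap


from _oracles import exact_two_tailed_by_pmf_summation, grow_blob, quadratic_reference_bh


class TestBinomial:
    def test_exhaustive_agreement_with_pmf_summation(self):
        for n in range(1, 51):
            for k in range(n + 1):
                for p0 in (0.25, 0.5, 0.23):
                    assert binomial_two_tailed_p(k, n, p0) == pytest.approx(
                        exact_two_tailed_by_pmf_summation(k, n, p0), abs=1e-12
                    )

    def test_reference_values(self):
        assert binomial_two_tailed_p(0, 10, 0.25) == pytest.approx(2 * 0.75**10)
        assert binomial_two_tailed_p(10, 10, 0.25) == pytest.approx(2 * 0.25**10)
        assert binomial_two_tailed_p(5, 20, 0.25) == 1.0  # central value capped

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_two_tailed_p(0, 0, 0.25)
        with pytest.raises(ValueError):
            binomial_two_tailed_p(5, 4, 0.25)
        with pytest.raises(ValueError):
            binomial_two_tailed_p(1, 4, 0.0)


class TestAccuracyToCounts:
    @pytest.mark.parametrize(
        "acc,n,expected", [(0.25, 400, 100), (1.0, 17, 17), (0.333, 300, 100), (0.0, 5, 0)]
    )
    def test_rounding_rule(self, acc, n, expected):
        assert accuracy_to_counts(acc, n) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            accuracy_to_counts(1.2, 10)


class TestFDR:
    def test_hand_checkable_example(self):
        assert fdr_bh([0.001, 0.2, 0.9], 0.01).tolist() == [True, False, False]

    def test_all_half_rejects_nothing(self):
        assert not fdr_bh([0.5] * 20, 0.01).any()

    def test_boundary_of_step_up_rule(self):
        m = 7
        assert fdr_bh([0.01 / m] * m, 0.01).all()

    def test_thousand_random_lists_match_quadratic_reference(self, rng):
        for _ in range(1000):
            m = rng.integers(1, 60)
            p = rng.uniform(1e-6, 1.0, size=m)
            if rng.random() < 0.3:  # plant some strong signals
                p[: max(1, m // 4)] *= 1e-4
            q = rng.uniform(0.005, 0.2)
            assert np.array_equal(fdr_bh(p, q), quadratic_reference_bh(p, q))

    def test_empty_input(self):
        assert fdr_bh([], 0.01).size == 0


class TestClusterFilter:
    def _blob(self, size, shape=(16, 16, 16)):
        return grow_blob(size, shape=shape)

    def test_isolated_voxel_removed(self):
        vol = np.zeros((8, 8, 8), dtype=bool)
        vol[4, 4, 4] = True
        assert not cluster_filter(vol, min_size=20).any()

    def test_twenty_removed_twentyone_retained(self):
        assert not cluster_filter(self._blob(20), min_size=20).any()
        out = cluster_filter(self._blob(21), min_size=20)
        assert out.sum() == 21

    def test_idempotent_and_monotone(self):
        vol = self._blob(25)
        once = cluster_filter(vol, min_size=20)
        assert np.array_equal(once, cluster_filter(once, min_size=20))
        bigger = vol | self._blob(30)
        assert (cluster_filter(bigger, min_size=20) & once == once).all()

    def test_diagonal_voxels_connected_under_26_but_not_6(self):
        vol = np.zeros((6, 6, 6), dtype=bool)
        vol[2, 2, 2] = vol[3, 3, 3] = True
        assert cluster_filter(vol, min_size=1, connectivity=26).sum() == 2
        assert not cluster_filter(vol, min_size=1, connectivity=6).any()


def _centre_maps(shape, centres, acc_values, chance_values, n_total=160,
                 n_repeats=20, n_pool=40):
    acc = CentreMap(shape=shape, centres=centres, values=np.asarray(acc_values),
                    n_test_total=np.full(len(centres), n_total, dtype=np.int64),
                    n_repeats=n_repeats, n_pool=n_pool)
    ch = CentreMap(shape=shape, centres=centres, values=np.asarray(chance_values),
                   n_test_total=np.full(len(centres), n_total, dtype=np.int64),
                   n_repeats=n_repeats, n_pool=n_pool)
    return acc, ch


class TestInferSubject:
    def test_all_chance_accuracy_gives_empty_map(self):
        shape = (10, 10, 10)
        centres = np.arange(0, 1000, 7, dtype=np.int64)
        acc, ch = _centre_maps(shape, centres, np.full(len(centres), 0.25),
                               np.full(len(centres), 0.25))
        res = infer_subject(acc, ch)
        assert not res.sig_fdr.any() and not res.sig_final.any()
        assert ((res.pvals > 0) & (res.pvals <= 1)).all()

    def test_strong_cluster_survives_and_singleton_does_not(self):
        shape = (12, 12, 12)
        strong = np.zeros(shape, dtype=bool)
        strong[3:7, 3:7, 3:7] = True  # 64-voxel block
        lone = np.ravel_multi_index((10, 10, 10), shape)
        centres = np.sort(np.concatenate([np.flatnonzero(strong), [lone]])).astype(np.int64)
        accv = np.where(np.isin(centres, np.flatnonzero(strong)), 0.6, 0.6)
        # background centres to form the FDR family
        bg = np.setdiff1d(np.arange(0, 1728, 3, dtype=np.int64), centres)
        centres_all = np.sort(np.concatenate([centres, bg]))
        acc_values = np.where(np.isin(centres_all, centres), 0.6, 0.25)
        acc, ch = _centre_maps(shape, centres_all, acc_values,
                               np.full(len(centres_all), 0.25))
        res = infer_subject(acc, ch, q=0.01, min_cluster=20)
        assert res.sig_fdr.flat[lone]          # significant pre-clustering
        assert not res.sig_final.flat[lone]    # removed by extent rule
        assert res.sig_final[3:7, 3:7, 3:7].all()

    def test_below_chance_kept_only_in_signed_layer(self):
        shape = (10, 10, 10)
        centres = np.arange(0, 1000, 5, dtype=np.int64)
        acc_values = np.full(len(centres), 0.25)
        acc_values[:10] = 0.02  # strongly below chance
        acc, ch = _centre_maps(shape, centres, acc_values, np.full(len(centres), 0.25))
        res = infer_subject(acc, ch, q=0.01, min_cluster=0)
        assert not res.sig_fdr.flat[centres[:10]].any()
        assert (res.sig_signed.flat[centres[:10]] == -1).all()

    def test_grid_mismatch_rejected(self):
        shape = (10, 10, 10)
        centres = np.arange(0, 1000, 5, dtype=np.int64)
        acc, _ = _centre_maps(shape, centres, np.full(len(centres), 0.25),
                              np.full(len(centres), 0.25))
        _, ch = _centre_maps(shape, centres[:-1], np.full(len(centres) - 1, 0.25),
                             np.full(len(centres) - 1, 0.25))
        with pytest.raises(ValueError, match="same centres"):
            infer_subject(acc, ch)

    def test_per_repeat_mode_is_more_conservative(self):
        shape = (10, 10, 10)
        centres = np.arange(0, 1000, 5, dtype=np.int64)
        acc_values = np.full(len(centres), 0.25)
        acc_values[:40] = 0.40
        acc, ch = _centre_maps(shape, centres, acc_values, np.full(len(centres), 0.25))
        res_total = infer_subject(acc, ch, q=0.01, min_cluster=0, n_mode="total")
        res_rep = infer_subject(acc, ch, q=0.01, min_cluster=0, n_mode="per_repeat")
        assert res_rep.sig_fdr.sum() <= res_total.sig_fdr.sum()
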