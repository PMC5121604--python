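"""Sphere-level decoding: schemes, splits, chance estimation, determinism."""

import numpy as np
import pytest

from slmvpa import (
    GridSpec,
    RegionSpec,
    SplitPlan,
    empirical_chance_map,
    enumerate_spheres,
    evaluate_sphere,
    generate_beta_dataset,
    make_ground_truth,
    run_searchlight,
)
from slmvpa._svm import fit_predict
from slmvpa.decoding import SCHEMES, get_scheme


class TestFastSVM:
    def test_matches_public_svc_exactly(self, rng):
        """The gram-based libsvm path must reproduce SVC(kernel='linear')."""
        from sklearn.svm import SVC

        for _ in range(25):
            X = rng.normal(size=(40, 20))
            y = rng.permutation(np.repeat([1, 2, 3, 4], 10))
            X[:, :4] += 0.7 * np.eye(4)[y - 1]
            pred = fit_predict(X[:30], y[:30], X[30:])
            ref = SVC(kernel="linear", C=1.0).fit(X[:30], y[:30]).predict(X[30:])
            assert np.array_equal(pred, ref)


class TestSchemes:
    def test_registry_covers_four_schemes(self):
        assert set(SCHEMES) == {"face", "voice", "face_to_voice", "voice_to_face"}
        assert not SCHEMES["face"].is_cross
        assert SCHEMES["voice_to_face"].is_cross
        assert SCHEMES["face_to_voice"].train_modality == "face"
        assert SCHEMES["face_to_voice"].test_modality == "voice"

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            get_scheme("face_to_face")


class TestEvaluateSphere:
    def test_separable_patterns_decode_perfectly(self):
        ident = np.repeat([1, 2, 3, 4], 10)
        X = 5.0 * np.eye(4)[ident - 1]
        acc, n_total = evaluate_sphere(X, ident, plan=SplitPlan(n_repeats=10, seed=0))
        assert acc == 1.0
        assert n_total == 80  # 10 repeats x 8 held-out samples

    def test_pure_noise_decodes_at_chance(self, rng):
        ident = np.repeat([1, 2, 3, 4], 10)
        accs = [
            evaluate_sphere(rng.normal(size=(40, 25)), ident,
                            plan=SplitPlan(n_repeats=20, seed=s))[0]
            for s in range(12)
        ]
        assert abs(np.mean(accs) - 0.25) < 0.04

    def test_amodal_region_cross_decodes_noiselessly(self, amodal_gt):
        betas = generate_beta_dataset(amodal_gt, 10, noise_sd=0.0, seed=0)
        vox = amodal_gt.region_voxels(0)
        ids = betas.labels["identity"].to_numpy()
        mods = betas.labels["modality"].to_numpy()
        for scheme in ("face_to_voice", "voice_to_face"):
            acc, _ = evaluate_sphere(betas.data[:, vox], ids, mods, scheme,
                                     SplitPlan(n_repeats=5, seed=1))
            assert acc == 1.0

    def test_too_few_samples_per_identity_rejected(self):
        ident = np.array([1, 1, 2, 2, 3, 3, 4])
        with pytest.raises(ValueError, match="2 samples per identity"):
            evaluate_sphere(np.zeros((7, 3)), ident, plan=SplitPlan(seed=0))


@pytest.fixture(scope="module")
def face_only_setup():
    grid = GridSpec((14, 14, 14))
    gt = make_ground_truth(
        grid, [RegionSpec("face_only", (7, 7, 7), 2, 2.0)], fill_fraction=0.5, seed=3
    )
    betas = generate_beta_dataset(gt, 10, noise_sd=1.0, seed=3)
    sl = enumerate_spheres(gt.gm_mask, 2, 0.5)
    return gt, betas, sl


class TestSearchlightMaps:
    def test_single_centre_consistent_with_direct_call(self, face_only_setup):
        gt, betas, sl = face_only_setup
        from slmvpa.searchlight import SearchlightMap

        k = len(sl) // 2
        single = SearchlightMap(
            shape=sl.shape, centres=sl.centres[k : k + 1],
            features=[sl.features[k]], radius_voxels=sl.radius_voxels,
            min_inmask_fraction=sl.min_inmask_fraction,
        )
        plan = SplitPlan(n_repeats=5, seed=4)
        amap = run_searchlight(betas, single, "face", plan)
        full = run_searchlight(betas, sl, "face", plan)
        assert amap.values[0] == full.values[k]

    def test_runs_are_deterministic(self, face_only_setup):
        _, betas, sl = face_only_setup
        plan = SplitPlan(n_repeats=4, seed=9)
        a = run_searchlight(betas, sl, "voice", plan)
        b = run_searchlight(betas, sl, "voice", plan)
        assert np.array_equal(a.values, b.values)

    def test_values_in_unit_interval_on_centres_only(self, face_only_setup):
        _, betas, sl = face_only_setup
        amap = run_searchlight(betas, sl, "face", SplitPlan(n_repeats=4, seed=2))
        assert ((amap.values >= 0) & (amap.values <= 1)).all()
        vol = amap.volume(fill=-1.0)
        off_centres = np.ones(vol.shape, dtype=bool)
        off_centres.flat[amap.centres] = False
        assert (vol[off_centres] == -1.0).all()

    def test_face_only_region_invisible_to_voice_decoder(self, face_only_setup):
        gt, betas, sl = face_only_setup
        vmap = run_searchlight(betas, sl, "voice", SplitPlan(n_repeats=15, seed=5))
        region = gt.any_region_mask()
        in_region = region.ravel()[vmap.centres]
        # in-region centres behave like background: compare against the
        # empirical null spread of the out-of-region centres (the analytic
        # binomial SD understates the Monte-Carlo spread because the split
        # repeats reuse samples)
        out_vals = vmap.values[~in_region]
        in_vals = vmap.values[in_region]
        # the few in-region centres share voxels and samples, so they are one
        # correlated observation, not n independent ones: allow the full
        # per-centre null spread on their mean
        assert in_vals.mean() <= out_vals.mean() + 2 * out_vals.std()
        assert in_vals.max() <= max(out_vals.max(), out_vals.mean() + 4 * out_vals.std())

    def test_empty_searchlight_rejected(self, face_only_setup):
        _, betas, _ = face_only_setup
        from slmvpa.searchlight import SearchlightMap

        empty = SearchlightMap(shape=betas.grid.shape, centres=np.array([], dtype=np.int64),
                               features=[], radius_voxels=2, min_inmask_fraction=0.5)
        with pytest.raises(ValueError, match="empty"):
            run_searchlight(betas, empty, "face", SplitPlan(seed=0))


class TestEmpiricalChance:
    def test_chance_near_quarter_with_and_without_signal(self, face_only_setup):
        gt, betas, sl = face_only_setup
        ch = empirical_chance_map(betas, sl, "face", n_shuffles=10,
                                  plan=SplitPlan(seed=6))
        assert abs(ch.values.mean() - 0.25) < 0.01
        # planted signal does not bias shuffled-training accuracy
        region = gt.any_region_mask().ravel()[ch.centres]
        assert abs(ch.values[region].mean() - 0.25) < 0.05

    def test_zero_shuffles_rejected(self, face_only_setup):
        _, betas, sl = face_only_setup
        with pytest.raises(ValueError, match="n_shuffles"):
            empirical_chance_map(betas, sl, "face", n_shuffles=0, plan=SplitPlan(seed=0))

    def test_fixed_split_variant_also_calibrated(self, face_only_setup):
        _, betas, sl = face_only_setup
        plan = SplitPlan(seed=6, redraw_split_per_shuffle=False)
        ch = empirical_chance_map(betas, sl, "face", n_shuffles=10, plan=plan)
        assert abs(ch.values.mean() - 0.25) < 0.015


class TestAccuracyMonotonicity:
    def test_in_region_accuracy_rises_with_amplitude(self):
        """More planted signal never lowers expected in-region accuracy."""
        grid = GridSpec((12, 12, 12))
        means = []
        for amp in (0.2, 0.6, 1.8):
            gt = make_ground_truth(
                grid, [RegionSpec("amodal", (6, 6, 6), 2, amp)],
                fill_fraction=0.6, seed=8,
            )
            betas = generate_beta_dataset(gt, 10, noise_sd=1.0, seed=8)
            vox = gt.region_voxels(0)
            acc, n = evaluate_sphere(
                betas.data[:, vox], betas.labels["identity"].to_numpy(),
                betas.labels["modality"].to_numpy(), "face",
                SplitPlan(n_repeats=30, seed=8),
            )
            means.append((acc, n))
        mc_sd = np.sqrt(0.25 * 0.75 / means[0][1])
        assert means[1][0] >= means[0][0] - 2 * mc_sd
        assert means[2][0] >= means[1][0] - 2 * mc_sd
        assert means[2][0] > 0.5  # strong amplitude actually decodes
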