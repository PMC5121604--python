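"""GLM stage: HRF shape, design construction, OLS recovery."""

import numpy as np
import pytest

from slmvpa import (
    GridSpec,
    HRFParams,
    RegionSpec,
    build_design,
    fit_glm,
    generate_beta_dataset,
    generate_bold,
    hrf_kernel,
    make_event_schedule,
    make_ground_truth,
)


class TestHRF:
    def test_peak_near_five_seconds(self):
        # fine sampling: the canonical double-gamma peaks at (shape-1)*scale = 5 s
        k = hrf_kernel(HRFParams(), tr=3.6, dt=0.01)
        assert abs(np.argmax(k) * 0.01 - 5.0) <= 3.6

    def test_kernel_integral_positive(self):
        k = hrf_kernel(HRFParams(), tr=3.6, dt=0.1)
        assert k.sum() * 0.1 > 0

    def test_matches_independent_spm_implementation(self):
        nilearn = pytest.importorskip("nilearn.glm.first_level")
        ours = hrf_kernel(HRFParams(), tr=1.0, dt=1.0 / 50)
        ref = nilearn.spm_hrf(1.0, oversampling=50, time_length=32.0)
        ours, ref = ours[: len(ref)] / np.max(ours), ref / np.max(ref)
        assert np.corrcoef(ours, ref[: len(ours)])[0, 1] > 0.999

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HRFParams(peak_dispersion=0.0)
        with pytest.raises(ValueError):
            HRFParams(length_s=0.0)


class TestDesign:
    def test_twelve_columns_per_block(self):
        es = make_event_schedule(1, seed=0)
        assert build_design(es).n_regressors == 12
        es29 = make_event_schedule(29, seed=0)
        assert build_design(es29).n_regressors == 348

    def test_regressor_support_near_own_trials(self):
        es = make_event_schedule(2, seed=3)
        design = build_design(es)
        for j, (b, i, m) in enumerate(design.regressors()):
            sel = (es.block == b) & (es.identity == i) & (es.modality == m)
            onsets = es.onset_s[sel]
            col = design.matrix[:, j]
            t = np.arange(len(col)) * design.tr
            active = np.abs(col) > 1e-3 * np.abs(col).max()
            # every active scan lies within the HRF span of one of the trials
            spans = [(t >= o - 1e-9) & (t <= o + 32.5) for o in onsets]
            assert (~active | np.logical_or.reduce(spans)).all()

    def test_empty_schedule_rejected(self):
        es = make_event_schedule(1, seed=0)
        empty = type(es)(block=es.block[:0], identity=es.identity[:0],
                         modality=es.modality[:0], onset_s=es.onset_s[:0], tr=es.tr)
        with pytest.raises(ValueError):
            build_design(empty)


@pytest.fixture(scope="module")
def noiseless_case():
    grid = GridSpec((8, 8, 8))
    gt = make_ground_truth(
        grid, [RegionSpec("amodal", (4, 4, 4), 2, 1.2)], fill_fraction=0.6, seed=2
    )
    schedule = make_event_schedule(2, seed=2)
    bold = generate_bold(gt, schedule, noise_sd=0.0, seed=2)
    return gt, schedule, bold


class TestFitGLM:
    def test_noiseless_recovery_exact(self, noiseless_case):
        gt, schedule, bold = noiseless_case
        design = build_design(schedule, n_scans=bold.shape[0])
        betas = fit_glm(bold, design, gt.gm_mask)
        truth = generate_beta_dataset(gt, 2, noise_sd=0.0, seed=0)
        scale = np.abs(truth.data).max()
        assert np.abs(betas.data - truth.data).max() / scale < 1e-6
        assert betas.n_samples == 24

    def test_residuals_orthogonal_to_design(self, noiseless_case, rng):
        gt, schedule, _ = noiseless_case
        bold = generate_bold(gt, schedule, noise_sd=0.5, seed=3)
        design = build_design(schedule, n_scans=bold.shape[0])
        betas = fit_glm(bold, design, gt.gm_mask)
        Y = bold.reshape(bold.shape[0], -1)[:, gt.gm_mask.ravel()]
        coef = betas.data[:, gt.gm_mask.ravel()]
        resid = Y - design.matrix @ coef
        assert np.abs(design.matrix.T @ resid).max() < 1e-8 * np.abs(Y).max()

    def test_background_voxel_flat_and_region_voxel_hrf_shaped(self, noiseless_case):
        gt, schedule, bold = noiseless_case
        background = ~gt.any_region_mask() & gt.gm_mask
        bg_series = bold.reshape(bold.shape[0], -1)[:, background.ravel()]
        assert np.abs(bg_series).max() == 0.0
        region_series = bold.reshape(bold.shape[0], -1)[:, gt.region_voxels(0)]
        assert np.abs(region_series).max() > 0

    def test_rank_deficient_design_names_columns(self, noiseless_case):
        gt, schedule, bold = noiseless_case
        design = build_design(schedule, n_scans=bold.shape[0])
        design.matrix[:, 5] = design.matrix[:, 3]
        with pytest.raises(np.linalg.LinAlgError, match="block="):
            fit_glm(bold, design, gt.gm_mask)

    def test_time_dimension_mismatch_rejected(self, noiseless_case):
        gt, schedule, bold = noiseless_case
        design = build_design(schedule, n_scans=bold.shape[0])
        with pytest.raises(ValueError):
            fit_glm(bold[:-3], design, gt.gm_mask)
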