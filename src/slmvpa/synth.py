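"""Synthetic multi-subject fMRI datasets with planted multivoxel patterns.

This module is the forward model for the whole analysis: it generates
grey-matter masks, slow event-related schedules, condition-per-block beta
images and (optionally) raw BOLD time-series in which local identity
information has been planted in regions of known location and kind. Every
generator is a pure function of its arguments including the seed, so any
downstream result can be traced back to a reproducible ground truth.

Experimental structure emulated
-------------------------------
Four familiar identities are presented in three modalities (face, voice,
audiovisual face-voice), i.e. 12 conditions. Each condition occurs twice
per block and the two trials are combined into one regressor, so a subject
with ``n_blocks`` blocks yields ``12 * n_blocks`` beta samples. Trial
onsets are locked to the volume acquisition (TR = 3.6 s) with
inter-stimulus intervals drawn uniformly from 10-18 s.

Region kinds
------------
face_only / voice_only
    identity patterns exist in one modality only; the other modality sees
    pure noise inside the region.
bimodal_overlap
    independent identity patterns per modality: both within-modality
    decoders can succeed, but nothing transfers across modalities.
amodal
    one shared identity pattern used for both face and voice samples: the
    signature of a modality-abstracted identity code, detectable by
    cross-modal decoding.

Face-voice (audiovisual) samples carry the sum of the face and the voice
pattern; they exist so sample counts match the experimental design but are
not used by any decoding scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "IDENTITIES",
    "MODALITIES",
    "REGION_KINDS",
    "TR_DEFAULT",
    "GridSpec",
    "RegionSpec",
    "GroundTruth",
    "EventSchedule",
    "BetaImageSet",
    "SubjectDataset",
    "make_grey_matter_mask",
    "make_ground_truth",
    "make_event_schedule",
    "generate_beta_dataset",
    "generate_bold",
    "generate_subject",
    "calibrate_effect_amplitude",
]

IDENTITIES = (1, 2, 3, 4)
MODALITIES = ("face", "voice", "face_voice")
REGION_KINDS = ("face_only", "voice_only", "bimodal_overlap", "amodal")

#: repetition time of the emulated acquisition, seconds
TR_DEFAULT = 3.6

#: ISI bounds, seconds
ISI_MIN, ISI_MAX = 10.0, 18.0

N_CONDITIONS = len(IDENTITIES) * len(MODALITIES)  # 12
TRIALS_PER_CONDITION_PER_BLOCK = 2


@dataclass(frozen=True)
class GridSpec:
    """Subject voxel grid: shape in voxels and voxel size in mm."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 2 for s in self.shape):
            raise ValueError(f"grid shape must be 3 dims of >= 2 voxels, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def affine(self) -> np.ndarray:
        """NIfTI affine: diag(voxel sizes, 1), origin at voxel (0,0,0)."""
        return np.diag(list(self.voxel_size_mm) + [1.0])


@dataclass(frozen=True)
class RegionSpec:
    """A planted informative region: a ball of voxels with one kind of code."""

    kind: str
    centre: tuple[int, int, int]
    radius_voxels: int
    effect_amplitude: float

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}; expected one of {REGION_KINDS}")
        if self.radius_voxels < 1:
            raise ValueError("region radius must be a positive integer")
        object.__setattr__(self, "centre", tuple(int(c) for c in self.centre))

    def voxel_indices(self, grid: GridSpec) -> np.ndarray:
        """Flat (C-order) indices of the region's voxels; errors if the ball
        sticks out of the grid."""
        r = self.radius_voxels
        lo = np.array(self.centre) - r
        hi = np.array(self.centre) + r
        if (lo < 0).any() or (hi >= np.array(grid.shape)).any():
            raise ValueError(f"region at {self.centre} radius {r} extends outside grid {grid.shape}")
        ax = np.arange(-r, r + 1)
        dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
        inside = dx**2 + dy**2 + dz**2 <= r**2
        coords = np.stack([dx[inside] + self.centre[0],
                           dy[inside] + self.centre[1],
                           dz[inside] + self.centre[2]])
        return np.ravel_multi_index(coords, grid.shape)


@dataclass
class GroundTruth:
    """Everything needed to score recovery: grid, mask, regions and the
    pattern vector planted for each (region, identity, modality)."""

    grid: GridSpec
    gm_mask: np.ndarray  # bool, grid.shape
    regions: list[RegionSpec]
    #: pattern_table[(region_index, identity, modality)] -> vector over the
    #: region's voxels (same order as RegionSpec.voxel_indices)
    pattern_table: dict[tuple[int, int, str], np.ndarray]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.gm_mask.shape != self.grid.shape:
            raise ValueError("gm_mask shape does not match grid")
        self.gm_mask = self.gm_mask.astype(bool)

    def region_voxels(self, region_index: int) -> np.ndarray:
        return self.regions[region_index].voxel_indices(self.grid)

    def any_region_mask(self) -> np.ndarray:
        """Boolean volume marking voxels belonging to any planted region."""
        vol = np.zeros(self.grid.shape, dtype=bool)
        for i in range(len(self.regions)):
            vol.flat[self.region_voxels(i)] = True
        return vol

    def signal_row(self, identity: int, modality: str) -> np.ndarray:
        """Noise-free beta image (flat, full grid) for one condition."""
        row = np.zeros(self.grid.n_voxels)
        for i in range(len(self.regions)):
            vox = self.region_voxels(i)
            if modality == "face_voice":
                pat = (self.pattern_table[(i, identity, "face")]
                       + self.pattern_table[(i, identity, "voice")])
            else:
                pat = self.pattern_table[(i, identity, modality)]
            row[vox] += pat
        return row


@dataclass
class EventSchedule:
    """Trial-level schedule: block, identity, modality and TR-locked onset."""

    block: np.ndarray      # int, per trial
    identity: np.ndarray   # int in IDENTITIES
    modality: np.ndarray   # str in MODALITIES
    onset_s: np.ndarray    # float, multiples of tr
    tr: float = TR_DEFAULT

    def __len__(self) -> int:
        return len(self.onset_s)

    @property
    def n_blocks(self) -> int:
        return int(self.block.max()) + 1 if len(self) else 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"block": self.block, "identity": self.identity,
             "modality": self.modality, "onset_s": self.onset_s}
        )


@dataclass
class BetaImageSet:
    """Sample-by-voxel beta matrix plus labels and grid geometry.

    ``data`` covers the full grid (flat C-order columns); voxels outside the
    grey-matter mask may be zero or noise depending on provenance. ``labels``
    has columns sample_id, block, identity, modality.
    """

    data: np.ndarray  # (n_samples, grid.n_voxels) float
    labels: "object"  # pandas.DataFrame
    grid: GridSpec
    gm_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != self.grid.n_voxels:
            raise ValueError("beta data must be (n_samples, n_grid_voxels)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label rows must match beta samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def modality_rows(self, modality: str) -> np.ndarray:
        return np.flatnonzero((self.labels["modality"] == modality).to_numpy())


@dataclass
class SubjectDataset:
    betas: BetaImageSet
    ground_truth: GroundTruth
    seed: int
    bold: np.ndarray | None = None
    schedule: EventSchedule | None = None


def _largest_component(binary: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(binary)
    if n == 0:
        return binary
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def make_grey_matter_mask(grid: GridSpec, fill_fraction: float, seed: int) -> np.ndarray:
    """Connected binary mask covering ~fill_fraction of the grid.

    A smoothed Gaussian random field is thresholded at the requested
    quantile; the mask is then grown greedily by field value from its
    largest connected component until the target voxel count is reached.
    This yields irregular, realistic borders (exercising the >50 %
    in-mask sphere rule) while guaranteeing connectivity and an exact
    fill fraction.
    """
    if any(s < 3 for s in grid.shape):
        raise ValueError(f"grid too small for a mask: {grid.shape}")
    if not 0.0 < fill_fraction <= 1.0:
        raise ValueError("fill_fraction must be in (0, 1]")
    if fill_fraction == 1.0:
        return np.ones(grid.shape, dtype=bool)

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x6D61736B)))
    field = ndimage.gaussian_filter(rng.normal(size=grid.shape), sigma=max(2.0, min(grid.shape) / 8.0))
    target = int(round(fill_fraction * grid.n_voxels))
    target = max(target, 1)

    thr = np.quantile(field, 1.0 - fill_fraction)
    mask = _largest_component(field >= thr)

    # greedy region growing on field value until exact target count
    struct = ndimage.generate_binary_structure(3, 1)
    while mask.sum() < target:
        frontier = ndimage.binary_dilation(mask, structure=struct) & ~mask
        if not frontier.any():  # pragma: no cover - cannot happen before full grid
            break
        need = target - int(mask.sum())
        cand = np.flatnonzero(frontier.ravel())
        order = np.argsort(field.ravel()[cand])[::-1]
        mask.ravel()[cand[order[:need]]] = True
    if mask.sum() > target:
        # trim lowest-value boundary voxels that do not disconnect the mask
        inner = ndimage.binary_erosion(mask, structure=struct)
        boundary = np.flatnonzero((mask & ~inner).ravel())
        order = np.argsort(field.ravel()[boundary])
        for idx in order:
            if mask.sum() <= target:
                break
            mask.ravel()[boundary[idx]] = False
    return mask


def make_ground_truth(
    grid: GridSpec,
    regions: Sequence[RegionSpec],
    fill_fraction: float = 0.4,
    seed: int = 0,
    ensure_regions_in_mask: bool = True,
) -> GroundTruth:
    """Build a subject's ground truth: mask + per-region identity patterns.

    Pattern vectors are drawn once per (region, identity) from a standard
    Gaussian over the region's voxels, scaled by ``effect_amplitude`` --
    a distributed local pattern with no imposed geometry. Kind rules:
    amodal shares one vector between face and voice; bimodal_overlap draws
    independent vectors; face_only / voice_only zero the silent modality.
    """
    regions = list(regions)
    mask = make_grey_matter_mask(grid, fill_fraction, seed)
    if ensure_regions_in_mask:
        for r in regions:
            mask.flat[r.voxel_indices(grid)] = True

    table: dict[tuple[int, int, str], np.ndarray] = {}
    for ri, region in enumerate(regions):
        n_vox = len(region.voxel_indices(grid))
        for identity in IDENTITIES:
            rng = np.random.default_rng(
                np.random.SeedSequence((int(seed), 0x706174, ri, identity))
            )
            g1 = rng.standard_normal(n_vox) * region.effect_amplitude
            g2 = rng.standard_normal(n_vox) * region.effect_amplitude
            if region.kind == "face_only":
                face, voice = g1, np.zeros(n_vox)
            elif region.kind == "voice_only":
                face, voice = np.zeros(n_vox), g1
            elif region.kind == "bimodal_overlap":
                face, voice = g1, g2
            else:  # amodal
                face = voice = g1
            table[(ri, identity, "face")] = face
            table[(ri, identity, "voice")] = voice
    return GroundTruth(grid=grid, gm_mask=mask, regions=regions,
                       pattern_table=table, seed=int(seed))


def _snap_isi_to_tr(isi: float, tr: float) -> int:
    """Nearest whole number of TRs whose duration stays inside the ISI bounds."""
    k = round(isi / tr)
    tol = 1e-9
    if k * tr < ISI_MIN - tol:
        k += 1
    elif k * tr > ISI_MAX + tol:
        k -= 1
    if not ISI_MIN - tol <= k * tr <= ISI_MAX + tol:  # pragma: no cover - tr too coarse
        raise ValueError(f"TR {tr} admits no multiple inside [{ISI_MIN}, {ISI_MAX}] s")
    return k


def make_event_schedule(n_blocks: int, seed: int, tr: float = TR_DEFAULT) -> EventSchedule:
    """Slow event-related schedule: 24 trials per block (12 conditions x 2),
    ISI uniform on [10, 18] s snapped to the TR grid, onsets locked to
    volume acquisition. Blocks run on one continuous timeline."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x65766E74)))
    conditions = [(i, m) for m in MODALITIES for i in IDENTITIES]

    blocks, idents, mods, onset_trs = [], [], [], []
    t_tr = int(round(ISI_MIN / tr + 0.5))  # lead-in before the first trial
    for b in range(int(n_blocks)):
        trials = conditions * TRIALS_PER_CONDITION_PER_BLOCK
        order = rng.permutation(len(trials))
        for k in order:
            identity, modality = trials[k]
            blocks.append(b)
            idents.append(identity)
            mods.append(modality)
            onset_trs.append(t_tr)
            t_tr += _snap_isi_to_tr(rng.uniform(ISI_MIN, ISI_MAX), tr)
    return EventSchedule(
        block=np.array(blocks), identity=np.array(idents),
        modality=np.array(mods, dtype=object),
        onset_s=np.array(onset_trs, dtype=float) * tr, tr=tr,
    )


def _beta_labels(n_blocks: int):
    import pandas as pd

    rows = []
    for b in range(n_blocks):
        for m in MODALITIES:
            for i in IDENTITIES:
                rows.append((len(rows), b, i, m))
    return pd.DataFrame(rows, columns=["sample_id", "block", "identity", "modality"])


def generate_beta_dataset(
    gt: GroundTruth, n_blocks: int, noise_sd: float, seed: int,
    smooth_noise_fwhm_mm: float = 0.0,
) -> BetaImageSet:
    """Simulate the GLM's outputs directly: one beta sample per condition per
    block = planted pattern (per region-kind rules) + iid Gaussian voxel
    noise; background grey matter is pure noise, non-GM voxels are zero.

    ``smooth_noise_fwhm_mm`` > 0 optionally smooths each sample's noise
    field (spatially autocorrelated noise); the default is iid noise,
    the simplest model satisfying the exchangeability the null analyses
    rely on.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    labels = _beta_labels(int(n_blocks))
    n_samples = len(labels)

    signal = np.zeros((N_CONDITIONS, gt.grid.n_voxels))
    cond_index = {}
    k = 0
    for m in MODALITIES:
        for i in IDENTITIES:
            signal[k] = gt.signal_row(i, m)
            cond_index[(i, m)] = k
            k += 1

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x62657461)))
    gm_flat = gt.gm_mask.ravel()
    data = np.zeros((n_samples, gt.grid.n_voxels))
    if noise_sd > 0:
        if smooth_noise_fwhm_mm > 0:
            sigma_vox = (smooth_noise_fwhm_mm / 2.3548) / np.asarray(gt.grid.voxel_size_mm)
            for s in range(n_samples):
                f = ndimage.gaussian_filter(
                    rng.normal(size=gt.grid.shape), sigma=sigma_vox
                )
                f *= noise_sd / f.std()
                data[s, gm_flat] = f.ravel()[gm_flat]
        else:
            data[:, gm_flat] = rng.normal(0.0, noise_sd, size=(n_samples, int(gm_flat.sum())))
    rows = zip(labels["identity"].to_numpy(), labels["modality"].to_numpy())
    for s, (i, m) in enumerate(rows):
        data[s] += signal[cond_index[(int(i), m)]]
    data[:, ~gm_flat] = 0.0
    return BetaImageSet(data=data, labels=labels, grid=gt.grid, gm_mask=gt.gm_mask)


def generate_bold(
    gt: GroundTruth,
    schedule: EventSchedule,
    hrf_params=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_scans: int | None = None,
    stim_duration_s: float = 0.5,
) -> np.ndarray:
    """Linear forward model: BOLD = design @ planted amplitudes + noise.

    The design matrix is built by :func:`slmvpa.glm.build_design` with the
    same HRF the fitting stage uses, so at ``noise_sd=0`` GLM estimation
    recovers the planted amplitudes exactly (up to numerical conditioning).
    Returns a (n_scans, nx, ny, nz) array.
    """
    from .glm import HRFParams, build_design  # local import to avoid cycle

    hrf_params = hrf_params or HRFParams()
    tr = schedule.tr
    needed = int(np.ceil((schedule.onset_s.max() + hrf_params.length_s + stim_duration_s) / tr)) + 1
    if n_scans is None:
        n_scans = needed
    elif schedule.onset_s.max() + stim_duration_s > n_scans * tr:
        raise ValueError("schedule extends beyond the requested scan length")

    design = build_design(schedule, hrf_params, n_scans=n_scans, tr=tr,
                          stim_duration_s=stim_duration_s)
    # planted amplitude per regressor (block, identity, modality) per voxel
    amp = np.zeros((design.matrix.shape[1], gt.grid.n_voxels))
    for j, (_b, i, m) in enumerate(design.regressors()):
        amp[j] = gt.signal_row(i, m)
    bold = design.matrix @ amp
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x626F6C64)))
        bold = bold + rng.normal(0.0, noise_sd, size=bold.shape)
    return bold.reshape(n_scans, *gt.grid.shape)


def generate_subject(
    grid: GridSpec,
    regions: Sequence[RegionSpec],
    n_blocks: int,
    noise_sd: float,
    seed: int,
    fill_fraction: float = 0.4,
    with_bold: bool = False,
    smooth_noise_fwhm_mm: float = 0.0,
) -> SubjectDataset:
    """One subject end to end: ground truth, betas and (optionally) BOLD."""
    gt = make_ground_truth(grid, regions, fill_fraction=fill_fraction, seed=seed)
    betas = generate_beta_dataset(gt, n_blocks, noise_sd, seed,
                                  smooth_noise_fwhm_mm=smooth_noise_fwhm_mm)
    bold = schedule = None
    if with_bold:
        schedule = make_event_schedule(n_blocks, seed)
        bold = generate_bold(gt, schedule, noise_sd=noise_sd, seed=seed)
    return SubjectDataset(betas=betas, ground_truth=gt, seed=int(seed),
                          bold=bold, schedule=schedule)


def calibrate_effect_amplitude(
    noise_sd: float,
    n_voxels: int,
    n_blocks: int,
    target_accuracy: float = 0.6,
    seed: int = 0,
    n_repeats: int = 30,
    tol: float = 0.02,
    max_iter: int = 20,
) -> float:
    """Amplitude at which a single sphere of ``n_voxels`` voxels decodes the
    four identities within-modality at ~``target_accuracy``.

    Bisection on simulated sphere data: per identity, a fixed Gaussian
    pattern scaled by the amplitude plus iid noise per sample, evaluated
    with the same 80/20 repeated-split classifier the searchlight uses.
    The effect size is a free simulation parameter (no empirical unit is
    available for it), so it is tied down by the operating point of the
    decoder instead.
    """
    from .decoding import SplitPlan, evaluate_sphere

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x63616C69)))
    patterns = rng.standard_normal((len(IDENTITIES), n_voxels))
    identities = np.repeat(IDENTITIES, n_blocks)

    def acc_at(amplitude: float) -> float:
        noise_rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x63616C32)))
        X = (amplitude * patterns[np.repeat(np.arange(len(IDENTITIES)), n_blocks)]
             + noise_rng.normal(0.0, noise_sd, size=(len(identities), n_voxels)))
        plan = SplitPlan(n_repeats=n_repeats, seed=int(seed))
        acc, _ = evaluate_sphere(X, identities, plan=plan)
        return acc

    lo, hi = 0.0, max(4.0 * noise_sd, 1e-3)
    while acc_at(hi) < target_accuracy and hi < 1e3:
        hi *= 2.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        a = acc_at(mid)
        if abs(a - target_accuracy) <= tol:
            return mid
        if a < target_accuracy:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
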