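"""Condition-per-block GLM: design construction and OLS beta estimation.

One regressor per condition per block (the two trials of a condition within
a block share a regressor), HRF-convolved, fit by ordinary least squares
within an explicit grey-matter mask. No drift terms or autocorrelation
model by default: the synthetic time-series this stage is exercised on are
white and drift-free; optional polynomial drift columns are available for
externally supplied data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .synth import (
    IDENTITIES,
    MODALITIES,
    N_CONDITIONS,
    TR_DEFAULT,
    BetaImageSet,
    EventSchedule,
    GridSpec,
    _beta_labels,
)

__all__ = ["HRFParams", "DesignMatrix", "hrf_kernel", "build_design", "fit_glm"]


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response parameters.

    Defaults: response peak 6 s, undershoot peak 16 s, unit dispersions,
    peak:undershoot ratio 6, 32 s kernel -- the standard canonical shape.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    length_s: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("HRF dispersions must be positive")
        if self.length_s < 24.0:
            raise ValueError("HRF kernel length must be >= 24 s")
        if self.peak_delay_s <= 0 or self.undershoot_delay_s <= 0:
            raise ValueError("HRF delays must be positive")
        if self.peak_undershoot_ratio <= 0:
            raise ValueError("peak:undershoot ratio must be positive")


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    """Gamma density, zero for t <= 0 (avoids scipy.stats overhead on hot path)."""
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp / scale - gammaln(shape) - shape * np.log(scale)
    )
    return out


def hrf_kernel(params: HRFParams = HRFParams(), tr: float = TR_DEFAULT,
               dt: float | None = None) -> np.ndarray:
    """Sample the double-gamma HRF at spacing ``dt`` (default: the TR).

    h(t) = gamma(t; peak_delay/disp, disp) - gamma(t; u_delay/u_disp, u_disp) / ratio

    With the default parameters the peak sits near 5 s (mode of a gamma
    with shape 6, scale 1), inside one TR of the nominal 6 s peak delay.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    step = dt if dt is not None else tr
    if step <= 0:
        raise ValueError("sampling step must be positive")
    t = np.arange(0.0, params.length_s + step / 2, step)
    peak = _gamma_pdf(t, params.peak_delay_s / params.peak_dispersion, params.peak_dispersion)
    under = _gamma_pdf(
        t, params.undershoot_delay_s / params.undershoot_dispersion, params.undershoot_dispersion
    )
    return peak - under / params.peak_undershoot_ratio


@dataclass
class DesignMatrix:
    """Time-points x regressors matrix with (block, identity, modality) labels."""

    matrix: np.ndarray
    blocks: np.ndarray      # int per column
    identities: np.ndarray  # int per column
    modalities: np.ndarray  # str per column
    tr: float

    def __post_init__(self) -> None:
        n = self.matrix.shape[1]
        if not (len(self.blocks) == len(self.identities) == len(self.modalities) == n):
            raise ValueError("column labels must match design columns")

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def regressors(self):
        """Iterate (block, identity, modality) per column."""
        return zip(self.blocks.tolist(), self.identities.tolist(), self.modalities.tolist())


def build_design(
    schedule: EventSchedule,
    hrf: HRFParams = HRFParams(),
    n_scans: int | None = None,
    tr: float | None = None,
    stim_duration_s: float = 0.5,
    oversampling: int = 16,
) -> DesignMatrix:
    """One HRF-convolved regressor per (block, condition); 12 per block.

    Stimulus indicators are unit-height boxcars of ``stim_duration_s``
    built on a grid oversampled ``oversampling``-fold relative to the TR,
    convolved with the HRF and resampled at scan times.
    """
    if len(schedule) == 0:
        raise ValueError("empty event schedule")
    tr = schedule.tr if tr is None else tr
    if n_scans is None:
        n_scans = int(np.ceil((schedule.onset_s.max() + hrf.length_s + stim_duration_s) / tr)) + 1
    if schedule.onset_s.max() + stim_duration_s > n_scans * tr:
        raise ValueError("a trial falls outside the scan window")

    dt = tr / oversampling
    n_fine = n_scans * oversampling
    kernel = hrf_kernel(hrf, tr, dt=dt)

    n_blocks = schedule.n_blocks
    cols, blocks, idents, mods = [], [], [], []
    dur_bins = max(1, int(round(stim_duration_s / dt)))
    scan_idx = (np.arange(n_scans) * oversampling).astype(int)
    for b in range(n_blocks):
        for m in MODALITIES:
            for i in IDENTITIES:
                sel = (schedule.block == b) & (schedule.identity == i) & (schedule.modality == m)
                onsets = schedule.onset_s[sel]
                if len(onsets) == 0:
                    raise ValueError(f"no trials for block {b}, identity {i}, modality {m}")
                box = np.zeros(n_fine)
                for onset in onsets:
                    j = int(round(onset / dt))
                    box[j : j + dur_bins] = 1.0
                col = np.convolve(box, kernel)[:n_fine][scan_idx]
                cols.append(col)
                blocks.append(b)
                idents.append(i)
                mods.append(m)
    return DesignMatrix(
        matrix=np.column_stack(cols), blocks=np.array(blocks),
        identities=np.array(idents), modalities=np.array(mods, dtype=object), tr=tr,
    )


def _check_full_rank(X: np.ndarray, design: DesignMatrix) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = np.flatnonzero(diag < max(X.shape) * np.finfo(float).eps * diag.max())
    if bad.size:
        names = [
            f"(block={design.blocks[j]}, identity={design.identities[j]}, "
            f"modality={design.modalities[j]})"
            for j in bad
        ]
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; collinear columns: " + ", ".join(names)
        )


def fit_glm(
    bold: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray,
    grid: GridSpec | None = None,
    drift_order: int = 0,
) -> BetaImageSet:
    """OLS betas per masked voxel, reshaped to one beta sample per regressor.

    ``bold`` is (n_scans, nx, ny, nz); analysis is restricted to ``mask``
    (out-of-mask betas are zero). ``drift_order`` > 0 appends Legendre
    drift columns whose betas are estimated then discarded.
    """
    n_scans = bold.shape[0]
    if n_scans != design.matrix.shape[0]:
        raise ValueError("bold time dimension does not match design rows")
    if bold.shape[1:] != mask.shape:
        raise ValueError("mask shape does not match bold spatial dimensions")
    grid = grid or GridSpec(shape=bold.shape[1:])

    X = design.matrix
    if drift_order > 0:
        t = np.linspace(-1, 1, n_scans)
        drift = np.polynomial.legendre.legvander(t, drift_order)  # includes constant
        X = np.hstack([X, drift])
    _check_full_rank(X, design)

    mask = mask.astype(bool)
    Y = bold.reshape(n_scans, -1)[:, mask.ravel()]
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    coef = coef[: design.n_regressors]

    n_blocks = int(design.blocks.max()) + 1
    if design.n_regressors != N_CONDITIONS * n_blocks:
        raise ValueError("design does not have 12 regressors per block")

    # reorder columns to the canonical beta layout: block-major, then
    # modality, then identity (matches synthetic beta datasets)
    order_key = {
        (b, m, i): j
        for j, (b, i, m) in enumerate(design.regressors())
    }
    order = [
        order_key[(b, m, i)]
        for b in range(n_blocks)
        for m in MODALITIES
        for i in IDENTITIES
    ]
    data = np.zeros((design.n_regressors, grid.n_voxels))
    data[:, mask.ravel()] = coef[order]
    return BetaImageSet(data=data, labels=_beta_labels(n_blocks), grid=grid,
                        gm_mask=mask)
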