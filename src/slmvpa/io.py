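"""NIfTI-1 and table I/O for beta bundles, masks and statistical maps.

A "beta bundle" is a 4-D NIfTI of beta volumes plus a TSV label table
(sample_id, block, identity, modality, volume_index) on one grid -- the
layout both the simulator and the GLM stage emit, so the decoding stage is
agnostic to provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synth import MODALITIES, BetaImageSet, GridSpec, GroundTruth, RegionSpec

__all__ = [
    "write_map",
    "read_map",
    "write_mask",
    "write_beta_bundle",
    "read_beta_bundle",
    "write_ground_truth",
    "read_ground_truth",
]

LABEL_COLUMNS = ["sample_id", "block", "identity", "modality", "volume_index"]


def write_map(volume: np.ndarray, path, grid: GridSpec | None = None,
              affine: np.ndarray | None = None) -> Path:
    """Write a 3-D (or 4-D) volume as NIfTI-1 with the grid's affine."""
    if affine is None:
        affine = grid.affine if grid is not None else np.eye(4)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_map(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_mask(mask: np.ndarray, path, grid: GridSpec) -> Path:
    return write_map(mask.astype(np.uint8), path, grid=grid)


def write_beta_bundle(betas: BetaImageSet, nifti_path, labels_path) -> None:
    """4-D NIfTI (one volume per sample) + TSV label table."""
    vols = betas.data.reshape(betas.n_samples, *betas.grid.shape)
    write_map(np.moveaxis(vols, 0, -1), nifti_path, grid=betas.grid)
    table = betas.labels.copy()
    table["volume_index"] = np.arange(len(table))
    Path(labels_path).parent.mkdir(parents=True, exist_ok=True)
    table[LABEL_COLUMNS].to_csv(labels_path, sep="\t", index=False)


def read_beta_bundle(nifti_paths, labels_path, mask_path=None) -> BetaImageSet:
    """Load beta volumes + labels, checking grid/affine consistency.

    ``nifti_paths`` is one 4-D file or a list of 3-D files (one per
    sample, in volume_index order).
    """
    if isinstance(nifti_paths, (str, Path)):
        nifti_paths = [nifti_paths]
    imgs = [nib.load(str(p)) for p in nifti_paths]

    affine0, shape0 = imgs[0].affine, imgs[0].shape[:3]
    offenders = [str(p) for p, im in zip(nifti_paths, imgs)
                 if im.shape[:3] != shape0 or not np.allclose(im.affine, affine0)]
    if offenders:
        raise ValueError("volumes disagree on grid/affine: " + ", ".join(offenders))

    stacks = []
    for im in imgs:
        arr = np.asarray(im.get_fdata())
        if arr.ndim == 3:
            arr = arr[..., None]
        stacks.append(arr)
    data4d = np.concatenate(stacks, axis=-1)
    n_samples = data4d.shape[-1]

    labels = pd.read_csv(labels_path, sep="\t")
    missing = [c for c in LABEL_COLUMNS if c not in labels.columns]
    if missing:
        raise ValueError(f"label table lacks columns: {missing}")
    if len(labels) != n_samples:
        extra = set(range(n_samples)) - set(labels["volume_index"])
        raise ValueError(
            f"label rows ({len(labels)}) do not match volumes ({n_samples});"
            + (f" volumes without labels: {sorted(extra)}" if extra else "")
        )
    bad_mod = set(labels["modality"]) - set(MODALITIES)
    if bad_mod:
        raise ValueError(f"unknown modalities in label table: {sorted(bad_mod)}")

    labels = labels.sort_values("volume_index").reset_index(drop=True)
    order = labels["volume_index"].to_numpy()
    grid = GridSpec(shape=shape0, voxel_size_mm=tuple(np.abs(np.diag(affine0)[:3])))
    data = data4d.reshape(-1, n_samples).T[order]

    gm_mask = None
    if mask_path is not None:
        mvol, maff = read_map(mask_path)
        if mvol.shape != shape0 or not np.allclose(maff, affine0):
            raise ValueError(f"mask grid/affine mismatch: {mask_path}")
        gm_mask = mvol > 0.5
    return BetaImageSet(data=data, labels=labels.drop(columns=["volume_index"]),
                        grid=grid, gm_mask=gm_mask)


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Structured JSON sidecar: grid, regions and planted patterns."""
    payload = {
        "grid": {"shape": list(gt.grid.shape), "voxel_size_mm": list(gt.grid.voxel_size_mm)},
        "seed": gt.seed,
        "regions": [
            {"kind": r.kind, "centre": list(r.centre),
             "radius_voxels": r.radius_voxels, "effect_amplitude": r.effect_amplitude}
            for r in gt.regions
        ],
        "patterns": {
            f"{ri}|{identity}|{modality}": vec.tolist()
            for (ri, identity, modality), vec in gt.pattern_table.items()
        },
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload))


def read_ground_truth(path, gm_mask: np.ndarray) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    grid = GridSpec(shape=tuple(payload["grid"]["shape"]),
                    voxel_size_mm=tuple(payload["grid"]["voxel_size_mm"]))
    regions = [RegionSpec(**r | {"centre": tuple(r["centre"])}) for r in payload["regions"]]
    table = {}
    for key, vec in payload["patterns"].items():
        ri, identity, modality = key.split("|")
        table[(int(ri), int(identity), modality)] = np.asarray(vec)
    return GroundTruth(grid=grid, gm_mask=gm_mask, regions=regions,
                       pattern_table=table, seed=payload.get("seed"))
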