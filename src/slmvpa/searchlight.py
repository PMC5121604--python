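"""Spherical searchlight construction over a grey-matter mask.

A searchlight of radius r (voxels) around a centre is the set of lattice
points within Euclidean distance r. A centre enters the analysis only if
it is itself in the mask and *more than* ``min_inmask_fraction`` of its
sphere's voxels (the sphere clipped at the grid border) are in the mask;
the classifier then sees only the in-mask voxels of the sphere as
features. At the 2 mm isotropic resolution emulated here the standard
8 mm searchlight is exactly 4 voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["SearchlightMap", "sphere_offsets", "enumerate_spheres"]


def sphere_offsets(radius_voxels: int) -> np.ndarray:
    """All integer offsets (dx, dy, dz) with dx²+dy²+dz² <= r², incl. (0,0,0).

    Returns an (n_offsets, 3) int array in lexicographic order.
    """
    r = int(radius_voxels)
    if r < 0:
        raise ValueError("radius must be >= 0")
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


@dataclass
class SearchlightMap:
    """Admissible sphere centres and their in-mask feature voxels.

    ``centres`` are flat C-order voxel indices into the grid;
    ``features[k]`` is the flat-index array of in-mask voxels of sphere k.
    """

    shape: tuple[int, int, int]
    centres: np.ndarray          # (n_centres,) int64 flat indices
    features: list[np.ndarray]   # per centre, flat indices
    radius_voxels: int
    min_inmask_fraction: float

    def __len__(self) -> int:
        return len(self.centres)

    @property
    def centre_mask(self) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=bool)
        vol.flat[self.centres] = True
        return vol

    def feature_counts(self) -> np.ndarray:
        return np.array([len(f) for f in self.features])

    def save(self, path) -> None:
        lengths = self.feature_counts()
        np.savez_compressed(
            path,
            shape=np.array(self.shape),
            centres=self.centres,
            feature_lengths=lengths,
            features_flat=np.concatenate(self.features) if len(self) else np.array([], dtype=np.int64),
            radius_voxels=self.radius_voxels,
            min_inmask_fraction=self.min_inmask_fraction,
        )

    @classmethod
    def load(cls, path) -> "SearchlightMap":
        with np.load(path) as z:
            lengths = z["feature_lengths"]
            splits = np.cumsum(lengths)[:-1]
            feats = np.split(z["features_flat"], splits) if len(lengths) else []
            return cls(
                shape=tuple(int(s) for s in z["shape"]),
                centres=z["centres"],
                features=[np.asarray(f) for f in feats],
                radius_voxels=int(z["radius_voxels"]),
                min_inmask_fraction=float(z["min_inmask_fraction"]),
            )


def enumerate_spheres(
    mask: np.ndarray, radius_voxels: int, min_inmask_fraction: float = 0.5
) -> SearchlightMap:
    """Build the searchlight map for a mask.

    Admission rule (strict): in-mask voxels of the border-clipped sphere
    divided by the clipped sphere size must *exceed* ``min_inmask_fraction``.
    Centres are additionally required to lie in the mask, since each
    sphere's accuracy is assigned to -- and inference is run on -- its
    centre voxel within grey matter.
    """
    mask = np.asarray(mask).astype(bool)
    if not 0.0 <= min_inmask_fraction <= 1.0:
        raise ValueError("min_inmask_fraction must be in [0, 1]")
    if radius_voxels >= max(mask.shape):
        raise ValueError(
            f"radius {radius_voxels} does not fit in grid {mask.shape}"
        )
    offs = sphere_offsets(radius_voxels)
    shape = mask.shape

    # in-mask and clipped-sphere counts per voxel via ball-kernel correlation
    r = int(radius_voxels)
    kernel = np.zeros((2 * r + 1,) * 3)
    kernel[tuple((offs + r).T)] = 1.0
    inmask_count = ndimage.correlate(mask.astype(float), kernel, mode="constant", cval=0.0)
    clipped_count = ndimage.correlate(np.ones(shape), kernel, mode="constant", cval=0.0)
    frac = inmask_count / clipped_count

    admissible = mask & (frac > min_inmask_fraction)
    centres_xyz = np.argwhere(admissible)
    centres = np.ravel_multi_index(centres_xyz.T, shape).astype(np.int64)

    features: list[np.ndarray] = []
    if len(centres):
        # (n_centres, n_offsets, 3) neighbour coordinates, clipped + mask-filtered
        neigh = centres_xyz[:, None, :] + offs[None, :, :]
        valid = ((neigh >= 0) & (neigh < np.array(shape))).all(axis=2)
        flat_all = np.empty(neigh.shape[:2], dtype=np.int64)
        nv = neigh[valid]
        flat_all[valid] = np.ravel_multi_index((nv[:, 0], nv[:, 1], nv[:, 2]), shape)
        mask_flat = mask.ravel()
        for k in range(len(centres)):
            idx = flat_all[k][valid[k]]
            features.append(np.sort(idx[mask_flat[idx]]))
    return SearchlightMap(
        shape=tuple(shape), centres=centres, features=features,
        radius_voxels=int(radius_voxels), min_inmask_fraction=float(min_inmask_fraction),
    )
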