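"""Cross-subject coincidence maps and ground-truth recovery scoring.

With few subjects and many samples per subject, a random-effects group
analysis would be underpowered; instead a voxel enters the group map when
it is significant in at least ``min_subjects`` of the individual maps
(default 4 of 5). Per the procedure this coincides on the FDR-thresholded
but *not* cluster-filtered subject maps. All synthetic subjects share one
grid, so no spatial normalization step is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import cluster_filter
from .synth import GroundTruth

__all__ = ["CoincidenceMap", "RecoveryReport", "coincidence", "scheme_overlap", "score_recovery"]


@dataclass
class CoincidenceMap:
    counts: np.ndarray   # int volume: subjects significant per voxel
    binary: np.ndarray   # counts >= min_subjects
    min_subjects: int
    n_subjects: int

    def cluster_filtered(self, min_size: int = 20, connectivity: int = 26) -> np.ndarray:
        """Optional post-hoc cluster filter on the thresholded group map."""
        return cluster_filter(self.binary, min_size=min_size, connectivity=connectivity)


def coincidence(subject_maps, min_subjects: int = 4) -> CoincidenceMap:
    """Voxelwise count of subjects significant, thresholded at min_subjects.

    ``subject_maps`` are the per-subject binary significance volumes
    (FDR-thresholded, non-cluster-filtered) on one shared grid.
    """
    maps = [np.asarray(m).astype(bool) for m in subject_maps]
    if len(maps) == 0:
        raise ValueError("no subject maps given")
    if len(maps) < min_subjects:
        raise ValueError(f"{len(maps)} maps cannot reach min_subjects={min_subjects}")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("subject maps are not on one grid")
    counts = np.sum(maps, axis=0).astype(np.int32)
    return CoincidenceMap(counts=counts, binary=counts >= min_subjects,
                          min_subjects=int(min_subjects), n_subjects=len(maps))


def scheme_overlap(map_a: CoincidenceMap, map_b: CoincidenceMap):
    """Voxelwise conjunction of two thresholded group maps.

    Returns (overlap volume, overlap voxel count). Overlap between the two
    within-modality maps marks candidate multimodal regions; overlap of the
    two cross-classification directions marks candidate amodal regions.
    """
    if map_a.binary.shape != map_b.binary.shape:
        raise ValueError("coincidence maps are not on one grid")
    overlap = map_a.binary & map_b.binary
    return overlap, int(overlap.sum())


@dataclass
class RecoveryReport:
    """How well the final maps recover the planted ground truth.

    sensitivity[(region_idx, scheme)] = fraction of the region's
    (in-mask) voxels present in that scheme's map;
    false_positive_rate[scheme] = fraction of non-region grey-matter
    voxels marked significant. overlap_counts[(scheme_a, scheme_b)] =
    conjunction voxel count.
    """

    region_kinds: list[str]
    sensitivity: dict[tuple[int, str], float]
    false_positive_rate: dict[str, float]
    overlap_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "region_kinds": self.region_kinds,
            "sensitivity": {f"region{ri}_{self.region_kinds[ri]}|{s}": v
                            for (ri, s), v in self.sensitivity.items()},
            "false_positive_rate": dict(self.false_positive_rate),
            "overlap_counts": {f"{a}&{b}": c for (a, b), c in self.overlap_counts.items()},
        }

    def to_text(self) -> str:
        lines = ["region recovery (sensitivity = planted voxels recovered):"]
        for (ri, s), v in sorted(self.sensitivity.items()):
            lines.append(f"  region {ri} ({self.region_kinds[ri]:15s}) {s:14s} {v:6.3f}")
        lines.append("false-positive rate outside planted regions:")
        for s, v in sorted(self.false_positive_rate.items()):
            lines.append(f"  {s:14s} {v:8.5f}")
        if self.overlap_counts:
            lines.append("scheme-pair overlap (voxels):")
            for (a, b), c in sorted(self.overlap_counts.items()):
                lines.append(f"  {a} & {b}: {c}")
        return "\n".join(lines)


def score_recovery(final_maps: dict, gt: GroundTruth) -> RecoveryReport:
    """Score per-scheme binary maps against the planted regions.

    ``final_maps`` maps scheme name -> binary volume (subject-level final
    maps or group maps). Only meaningful for synthetic data: raises if no
    ground truth is supplied.
    """
    if gt is None or not isinstance(gt, GroundTruth):
        raise ValueError("recovery scoring requires synthetic ground truth")
    gm = gt.gm_mask
    any_region = gt.any_region_mask()
    background = gm & ~any_region

    sensitivity: dict[tuple[int, str], float] = {}
    fpr: dict[str, float] = {}
    for scheme, vol in final_maps.items():
        vol = np.asarray(vol).astype(bool)
        if vol.shape != gt.grid.shape:
            raise ValueError(f"map for scheme {scheme!r} is not on the ground-truth grid")
        for ri in range(len(gt.regions)):
            region = np.zeros(gt.grid.shape, dtype=bool)
            region.flat[gt.region_voxels(ri)] = True
            region &= gm
            denom = int(region.sum())
            sensitivity[(ri, scheme)] = float((vol & region).sum() / denom) if denom else 0.0
        fpr[scheme] = float((vol & background).sum() / background.sum()) if background.any() else 0.0

    report = RecoveryReport(
        region_kinds=[r.kind for r in gt.regions],
        sensitivity=sensitivity, false_positive_rate=fpr,
    )
    names = list(final_maps)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            report.overlap_counts[(a, b)] = int(
                (np.asarray(final_maps[a]).astype(bool)
                 & np.asarray(final_maps[b]).astype(bool)).sum()
            )
    return report
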