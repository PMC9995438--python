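"""Dual-threshold lesion labeling.

The perfusion lesion is defined as brain tissue with delay time DT >= 3 s;
the ischemic core as the subset of those voxels with CBF below 30% of a
reference (normally perfused) CBF.  After thresholding, the candidate mask
is reduced to its single largest connected component ("single-lesion
cleanup"), which removes small artifactual islands such as skull-rim delay
elevations.  The result is a four-class label volume: 0 background,
1 non-ischemic brain, 2 penumbra, 3 core.

The CBF threshold is relative, so a reference region is needed.  By default
the reference is the non-candidate brain tissue of the hemisphere
contralateral to the lesion (midline = central sagittal plane, axis 0);
when laterality cannot be established the whole-brain non-candidate mean is
used instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .study import PerfusionStudy

LABEL_BACKGROUND = 0
LABEL_NONISCHEMIC = 1
LABEL_PENUMBRA = 2
LABEL_CORE = 3

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class ThresholdConfig:
    """Dual-threshold configuration.

    dt_threshold_s
        Delay-time cutoff (inclusive) defining the perfusion lesion; 3 s.
    cbf_relative_threshold
        Core is candidate tissue with CBF strictly below this fraction of
        the reference CBF; 0.30.
    """

    dt_threshold_s: float = 3.0
    cbf_relative_threshold: float = 0.30
    reference_region: str = "contralateral_brain"  # or "whole_brain_nonlesion"
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.dt_threshold_s <= 0:
            raise ValueError("dt_threshold_s must be positive")
        if not 0 < self.cbf_relative_threshold < 1:
            raise ValueError("cbf_relative_threshold must be a fraction in (0, 1)")
        if self.reference_region not in ("contralateral_brain", "whole_brain_nonlesion"):
            raise ValueError(f"unknown reference region {self.reference_region!r}")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class LesionMap:
    """Four-class 3D label volume over {0, 1, 2, 3}."""

    labels: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    study_id: str = "study"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, (0, 1, 2, 3)).all():
            raise ValueError("labels must be in {0, 1, 2, 3}")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def class_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def lesion_mask(self) -> np.ndarray:
        return self.labels >= LABEL_PENUMBRA

    def class_counts(self) -> dict[int, int]:
        return {k: int(np.count_nonzero(self.labels == k)) for k in range(4)}

    def save(self, path: str | Path) -> None:
        aff = np.diag(list(self.voxel_spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.uint8), aff), path)

    @classmethod
    def load(cls, path: str | Path, study_id: str = "study") -> "LesionMap":
        img = nib.load(path)
        labels = np.asarray(img.dataobj).astype(np.int8)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(labels=labels, voxel_spacing_mm=spacing, study_id=study_id)


def single_lesion_cleanup(candidate_mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Keep only the largest connected component of the candidate mask.

    Ties are broken toward the component with the lowest scan-order label.
    An empty mask maps to an empty mask.
    """
    candidate_mask = np.asarray(candidate_mask, dtype=bool)
    labeled, n = ndimage.label(candidate_mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return np.zeros_like(candidate_mask)
    counts = np.bincount(labeled.ravel())[1:]  # component sizes, label order
    keep = int(np.argmax(counts)) + 1
    return labeled == keep


def reference_cbf(
    study: PerfusionStudy, candidate_mask: np.ndarray, cfg: ThresholdConfig
) -> float:
    """Mean CBF over the configured reference region, excluding candidates.

    For ``contralateral_brain`` the lesion side is the side of the candidate
    center of mass along axis 0; the reference is non-candidate brain on the
    other side of the central sagittal plane.  Falls back to the whole-brain
    non-candidate mean when laterality is unknown (empty candidate) or the
    contralateral region is empty.
    """
    candidate_mask = np.asarray(candidate_mask, dtype=bool)
    noncand = study.brain_mask & ~candidate_mask
    region = np.zeros_like(noncand)
    if cfg.reference_region == "contralateral_brain" and candidate_mask.any():
        com_x = ndimage.center_of_mass(candidate_mask)[0]
        mid = (study.shape[0] - 1) / 2.0
        x_index = np.arange(study.shape[0])[:, None, None]
        opposite = x_index > mid if com_x < mid else x_index < mid
        region = noncand & np.broadcast_to(opposite, study.shape)
    if not region.any():
        region = noncand
    if not region.any():
        raise ValueError("empty reference region: all brain tissue is hypoperfused")
    return float(study.cbf[region].mean())


def build_lesion_map(study: PerfusionStudy, cfg: ThresholdConfig = ThresholdConfig()) -> LesionMap:
    """Apply the dual-threshold rule with single-lesion cleanup to a study."""
    brain = study.brain_mask
    candidate = brain & (study.dt >= cfg.dt_threshold_s)
    ref = reference_cbf(study, candidate, cfg) if candidate.any() else None
    lesion = single_lesion_cleanup(candidate, cfg.connectivity)
    labels = np.zeros(study.shape, dtype=np.int8)
    labels[brain] = LABEL_NONISCHEMIC
    if lesion.any():
        core = lesion & (study.cbf < cfg.cbf_relative_threshold * ref)
        labels[lesion & ~core] = LABEL_PENUMBRA
        labels[core] = LABEL_CORE
    return LesionMap(labels=labels, voxel_spacing_mm=study.voxel_spacing_mm, study_id=study.study_id)
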