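"""Core container for a CT-perfusion study.

A study is the unit of input to the whole pipeline: four co-registered 3D
hemodynamic parameter maps — delay time (DT, seconds), cerebral blood flow
(CBF, relative units), mean transit time (MTT, seconds) and cerebral blood
volume (CBV, relative units) — plus a brain mask and the voxel spacing.
Axis 0 is treated as the left-right (sagittal) axis throughout the package;
the midline is the central sagittal plane of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np

#: canonical channel order, matching the presentation order of the maps
MAP_NAMES: tuple[str, ...] = ("dt", "cbf", "mtt", "cbv")


@dataclass
class PerfusionStudy:
    """Four aligned parameter volumes, a brain mask and the voxel spacing."""

    dt: np.ndarray
    cbf: np.ndarray
    mtt: np.ndarray
    cbv: np.ndarray
    brain_mask: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    study_id: str = "study"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        shape = self.brain_mask.shape
        if len(shape) != 3:
            raise ValueError("volumes must be 3-D")
        for name in MAP_NAMES:
            vol = np.asarray(self.map(name), dtype=np.float64)
            if vol.shape != shape:
                raise ValueError(
                    f"map {name!r} shape {vol.shape} != mask shape {shape}"
                )
            setattr(self, name, vol)
        spacing = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("voxel spacing must be three positive reals")
        self.voxel_spacing_mm = spacing

    def map(self, name: str) -> np.ndarray:
        if name not in MAP_NAMES:
            raise KeyError(f"unknown parameter map {name!r}")
        return getattr(self, name)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.brain_mask.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing_mm))

    def validate_mask_closure(self, atol: float = 0.0) -> None:
        """Raise if any parameter value is nonzero outside the brain mask."""
        outside = ~self.brain_mask
        for name in MAP_NAMES:
            if not np.all(np.abs(self.map(name)[outside]) <= atol):
                raise ValueError(f"map {name!r} has nonzero values outside the brain mask")

    # ------------------------------------------------------------------ I/O

    def _affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_spacing_mm) + [1.0])
        return aff

    def save(self, out_dir: str | Path) -> list[Path]:
        """Write ``<id>_dt.nii.gz`` .. ``<id>_cbv.nii.gz`` and ``<id>_mask.nii.gz``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        aff = self._affine()
        written = []
        for name in MAP_NAMES:
            p = out_dir / f"{self.study_id}_{name}.nii.gz"
            nib.save(nib.Nifti1Image(self.map(name).astype(np.float32), aff), p)
            written.append(p)
        p = out_dir / f"{self.study_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(self.brain_mask.astype(np.uint8), aff), p)
        written.append(p)
        return written

    @classmethod
    def load(cls, in_dir: str | Path, study_id: str) -> "PerfusionStudy":
        in_dir = Path(in_dir)
        vols = {}
        for name in MAP_NAMES:
            img = nib.load(in_dir / f"{study_id}_{name}.nii.gz")
            vols[name] = np.asarray(img.dataobj, dtype=np.float64)
        mask_img = nib.load(in_dir / f"{study_id}_mask.nii.gz")
        mask = np.asarray(mask_img.dataobj) > 0
        spacing = tuple(float(z) for z in mask_img.header.get_zooms()[:3])
        return cls(brain_mask=mask, voxel_spacing_mm=spacing, study_id=study_id, **vols)
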