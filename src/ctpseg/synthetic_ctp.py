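"""Synthetic whole-brain CTP phantom generator.

Generates studies with a known, exactly recorded lesion geometry so every
downstream stage (thresholding, sampling, training, whole-volume inference,
evaluation) can be tested without patient data.  The phantom is deliberately
simple: an ellipsoidal brain with homogeneous tissue classes, a spherical
hypoperfused penumbra with a nested spherical core, Gaussian within-region
variation plus additive per-map noise, and an optional skull-rim artifact
patch with elevated delay time mimicking beam-hardening / partial-volume
effects near the skull.

Default tissue distributions respect the clinical dual-threshold structure:
penumbra delay time well above the 3 s perfusion-lesion threshold, core CBF
well below 30% of the healthy mean (healthy CBF is normalized to 100, so only
ratios matter).  The standard deviations are small relative to each voxel's
distance from the thresholds, so the class structure of a generated study is
stable across seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .study import MAP_NAMES, PerfusionStudy


@dataclass(frozen=True)
class TissueParams:
    """Per-map (mean, SD) of parameter values inside one tissue class."""

    dt: tuple[float, float]
    cbf: tuple[float, float]
    mtt: tuple[float, float]
    cbv: tuple[float, float]

    def get(self, name: str) -> tuple[float, float]:
        return getattr(self, name)


HEALTHY_DEFAULT = TissueParams(dt=(1.0, 0.15), cbf=(100.0, 6.0), mtt=(4.0, 0.4), cbv=(4.0, 0.3))
PENUMBRA_DEFAULT = TissueParams(dt=(6.0, 0.5), cbf=(60.0, 4.0), mtt=(9.0, 0.8), cbv=(3.2, 0.3))
CORE_DEFAULT = TissueParams(dt=(9.0, 0.8), cbf=(10.0, 3.0), mtt=(13.0, 1.2), cbv=(1.2, 0.25))
NOISE_DEFAULT: Mapping[str, float] = {"dt": 0.15, "cbf": 3.0, "mtt": 0.3, "cbv": 0.2}


@dataclass(frozen=True)
class SkullArtifact:
    """Skull-rim artifact: a patch of brain-edge voxels with elevated DT.

    The patch is the set of brain voxels within ``thickness_mm`` of the brain
    boundary whose axial angle (around the brain center, in the x-y plane)
    falls within ``arc_deg`` of ``center_deg``.  Beam-hardening artifacts in
    CT appear as localized patches along the skull, not full rings, and a
    localized patch is what exercises the single-lesion cleanup.
    """

    thickness_mm: float = 5.0
    dt_elevation_s: float = 4.0
    arc_deg: float = 60.0
    center_deg: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness_mm < 0 or self.dt_elevation_s < 0:
            raise ValueError("artifact thickness and DT elevation must be non-negative")
        if not 0 < self.arc_deg <= 360:
            raise ValueError("arc_deg must be in (0, 360]")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic study.

    ``lesion_center_mm`` is expressed in millimeters relative to the brain
    center (grid center); axis 0 is left-right.  ``core_radius_mm = 0``
    produces a penumbra with no core.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 4.0)
    brain_axes_mm: tuple[float, float, float] = (55.0, 55.0, 40.0)
    lesion_center_mm: tuple[float, float, float] = (-25.0, 0.0, 0.0)
    penumbra_radius_mm: float = 20.0
    core_radius_mm: float = 12.0
    healthy_params: TissueParams = HEALTHY_DEFAULT
    penumbra_params: TissueParams = PENUMBRA_DEFAULT
    core_params: TissueParams = CORE_DEFAULT
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(NOISE_DEFAULT))
    artifact: Optional[SkullArtifact] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if any(a <= 0 for a in self.brain_axes_mm):
            raise ValueError("brain semi-axes must be positive")
        if self.penumbra_radius_mm <= 0:
            raise ValueError("penumbra_radius_mm must be positive")
        if self.core_radius_mm < 0:
            raise ValueError("core_radius_mm must be non-negative")
        if self.core_radius_mm > self.penumbra_radius_mm:
            raise ValueError("core must be nested inside the penumbra")
        if self.penumbra_params.dt[0] < 3.0:
            raise ValueError("penumbra mean DT must be >= 3 s (perfusion-lesion threshold)")
        if self.core_radius_mm > 0 and not (
            self.core_params.cbf[0] < 0.30 * self.healthy_params.cbf[0]
        ):
            raise ValueError("core mean CBF must be < 30% of healthy mean CBF")
        # lesion center must lie inside the brain ellipsoid
        r2 = sum(
            (c / a) ** 2 for c, a in zip(self.lesion_center_mm, self.brain_axes_mm)
        )
        if r2 >= 1.0:
            raise ValueError("lesion center lies outside the brain ellipsoid")
        if self.artifact is not None and self.artifact.thickness_mm >= min(self.brain_axes_mm):
            raise ValueError("artifact thickness must be smaller than the smallest brain semi-axis")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["noise_sd"] = dict(self.noise_sd)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())
        for key in ("healthy_params", "penumbra_params", "core_params"):
            d[key] = TissueParams(**{k: tuple(v) for k, v in d[key].items()})
        if d.get("artifact") is not None:
            d["artifact"] = SkullArtifact(**d["artifact"])
        for key in ("grid_shape", "voxel_spacing_mm", "brain_axes_mm", "lesion_center_mm"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthGeometry:
    """Exact voxel sets used to generate the lesion (the simulation truth).

    ``penumbra`` is the shell only: penumbra and core are disjoint, core is
    nested inside the full perfusion lesion (core | penumbra).
    """

    core: np.ndarray
    penumbra: np.ndarray
    lesion_center_mm: tuple[float, float, float]
    penumbra_radius_mm: float
    core_radius_mm: float

    @property
    def perfusion_lesion(self) -> np.ndarray:
        return self.core | self.penumbra

    def label_volume(self, brain_mask: np.ndarray) -> np.ndarray:
        """0 background, 1 non-ischemic brain, 2 penumbra, 3 core."""
        labels = np.zeros(brain_mask.shape, dtype=np.int8)
        labels[brain_mask] = 1
        labels[self.penumbra] = 2
        labels[self.core] = 3
        return labels

    def save(self, path: str | Path, voxel_spacing_mm, brain_mask: np.ndarray) -> None:
        aff = np.diag(list(voxel_spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.label_volume(brain_mask).astype(np.uint8), aff), path)


def _physical_grid(shape, spacing):
    """Voxel-center coordinates (mm) relative to the grid center, per axis."""
    axes = [
        (np.arange(n, dtype=np.float64) - (n - 1) / 2.0) * s
        for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def generate_study(spec: PhantomSpec) -> tuple[PerfusionStudy, TruthGeometry]:
    """Generate one phantom study; a pure function of ``spec`` (incl. seed)."""
    shape = tuple(int(n) for n in spec.grid_shape)
    xx, yy, zz = _physical_grid(shape, spec.voxel_spacing_mm)
    ax, ay, az = spec.brain_axes_mm
    brain = (xx / ax) ** 2 + (yy / ay) ** 2 + (zz / az) ** 2 <= 1.0

    cx, cy, cz = spec.lesion_center_mm
    dist2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
    penumbra_ball = (dist2 <= spec.penumbra_radius_mm**2) & brain
    if spec.core_radius_mm > 0:
        core = (dist2 <= spec.core_radius_mm**2) & brain
    else:
        core = np.zeros(shape, dtype=bool)
    penumbra = penumbra_ball & ~core

    rng = np.random.default_rng(spec.seed)
    vols = {}
    for name in MAP_NAMES:
        mean = np.zeros(shape)
        sd = np.zeros(shape)
        for region, params in (
            (brain, spec.healthy_params),
            (penumbra, spec.penumbra_params),
            (core, spec.core_params),
        ):
            m, s = params.get(name)
            mean[region] = m
            sd[region] = s
        vol = mean + sd * rng.standard_normal(shape)
        vol += float(spec.noise_sd.get(name, 0.0)) * rng.standard_normal(shape)
        np.clip(vol, 0.0, None, out=vol)  # physical non-negativity
        vol[~brain] = 0.0
        vols[name] = vol

    study = PerfusionStudy(
        brain_mask=brain,
        voxel_spacing_mm=spec.voxel_spacing_mm,
        study_id=f"phantom_{spec.seed}",
        **vols,
    )
    truth = TruthGeometry(
        core=core,
        penumbra=penumbra,
        lesion_center_mm=spec.lesion_center_mm,
        penumbra_radius_mm=spec.penumbra_radius_mm,
        core_radius_mm=spec.core_radius_mm,
    )
    if spec.artifact is not None:
        study = add_skull_artifact(study, spec.artifact, seed=spec.seed + 7919)
    return study, truth


def rim_mask(
    brain_mask: np.ndarray,
    voxel_spacing_mm,
    thickness_mm: float,
    arc_deg: float = 360.0,
    center_deg: float = 0.0,
) -> np.ndarray:
    """Brain voxels within ``thickness_mm`` of the brain boundary, restricted
    to an axial angular sector of width ``arc_deg`` centered at ``center_deg``."""
    depth = ndimage.distance_transform_edt(brain_mask, sampling=voxel_spacing_mm)
    rim = brain_mask & (depth <= thickness_mm)
    if arc_deg < 360.0:
        xx, yy, _ = _physical_grid(brain_mask.shape, voxel_spacing_mm)
        theta = np.degrees(np.arctan2(yy, xx))
        delta = (theta - center_deg + 180.0) % 360.0 - 180.0
        rim &= np.abs(delta) <= arc_deg / 2.0
    return rim


def add_skull_artifact(
    study: PerfusionStudy, artifact: SkullArtifact, seed: int
) -> PerfusionStudy:
    """Return a copy of ``study`` with DT elevated in a skull-rim patch.

    The affected voxel set is recorded in ``metadata["artifact_rim"]`` so
    downstream robustness checks can measure false positives there.
    """
    if artifact.dt_elevation_s < 0 or artifact.thickness_mm < 0:
        raise ValueError("artifact elevation and thickness must be non-negative")
    brain_axes_proxy = [
        n * s / 2.0 for n, s in zip(study.shape, study.voxel_spacing_mm)
    ]
    if artifact.thickness_mm >= min(brain_axes_proxy):
        raise ValueError("artifact thickness exceeds the brain extent")

    rim = rim_mask(
        study.brain_mask,
        study.voxel_spacing_mm,
        artifact.thickness_mm,
        arc_deg=artifact.arc_deg,
        center_deg=artifact.center_deg,
    )
    rng = np.random.default_rng(seed)
    dt = study.dt.copy()
    bump = artifact.dt_elevation_s + artifact.noise_sd * rng.standard_normal(
        int(rim.sum())
    )
    dt[rim] = np.clip(dt[rim] + bump, 0.0, None)
    meta = dict(study.metadata)
    meta["artifact_rim"] = rim
    return PerfusionStudy(
        dt=dt,
        cbf=study.cbf.copy(),
        mtt=study.mtt.copy(),
        cbv=study.cbv.copy(),
        brain_mask=study.brain_mask.copy(),
        voxel_spacing_mm=study.voxel_spacing_mm,
        study_id=study.study_id,
        metadata=meta,
    )


def generate_cohort(
    n_images: int,
    n_no_core: int,
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    center_jitter_mm: Sequence[float] = (6.0, 6.0, 4.0),
    radius_jitter: float = 0.08,
    flip_sides: bool = True,
) -> list[tuple[PerfusionStudy, TruthGeometry]]:
    """Generate a cohort of phantoms with jittered lesion size and location.

    Exactly ``n_no_core`` studies get ``core_radius_mm = 0`` (penumbra but no
    core).  Per-study generation seeds are ``seed + index``; all jitters and
    the choice of no-core studies are drawn once from a cohort-level RNG, so
    two calls with the same arguments produce bit-identical cohorts.
    """
    if n_images <= 0:
        raise ValueError("n_images must be positive")
    if n_no_core > n_images:
        raise ValueError("n_no_core cannot exceed n_images")
    rng = np.random.default_rng(seed)
    no_core = set(rng.choice(n_images, size=n_no_core, replace=False).tolist())
    cohort = []
    for i in range(n_images):
        offset = rng.uniform(-1.0, 1.0, size=3) * np.asarray(center_jitter_mm)
        side = rng.choice((-1.0, 1.0)) if flip_sides else 1.0
        pr = base_spec.penumbra_radius_mm * (1.0 + radius_jitter * rng.uniform(-1, 1))
        cr = base_spec.core_radius_mm * (1.0 + radius_jitter * rng.uniform(-1, 1))
        cx, cy, cz = base_spec.lesion_center_mm
        center = (side * cx + offset[0], cy + offset[1], cz + offset[2])
        spec_i = dataclasses.replace(
            base_spec,
            lesion_center_mm=center,
            penumbra_radius_mm=float(pr),
            core_radius_mm=0.0 if i in no_core else float(min(cr, pr)),
            seed=int((seed + i) % 2**31),
        )
        study, truth = generate_study(spec_i)
        study.study_id = f"study_{i:03d}"
        cohort.append((study, truth))
    return cohort
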