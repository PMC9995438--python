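"""Class-balanced voxel sampling and 27-voxel patch extraction.

For each study, an equal number of voxels is sampled uniformly without
replacement from every class of its lesion map (under-sampling sidesteps the
severe class imbalance of whole images).  A study whose map has a penumbra
but no core instead contributes twice the per-class quota of non-ischemic
voxels, so every study yields 4 x n_per_class rows.

Each sampled voxel becomes one row: for every selected parameter map, the
values of the voxel and its 26 face/edge/corner neighbors (zero-padded at
the volume border) are laid out in a fixed raster order over the offsets
(-1,-1,-1) ... (1,1,1), and the per-map blocks of 27 values are concatenated
in channel order (default DT, CBF, MTT, CBV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from .ground_truth import LesionMap
from .study import MAP_NAMES, PerfusionStudy

#: fixed neighborhood offset order; the center voxel sits at index 13
NEIGHBOR_OFFSETS: np.ndarray = np.array(list(product((-1, 0, 1), repeat=3)), dtype=np.int64)
PATCH_SIZE = len(NEIGHBOR_OFFSETS)  # 27


@dataclass(frozen=True)
class SamplingConfig:
    n_per_class: int = 300
    seed: int = 0
    feature_maps: tuple[str, ...] = MAP_NAMES
    train_fraction: float = 0.60
    standardize_method: str = "zscore"  # or "minmax" (to [-1, 1])

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        maps = tuple(self.feature_maps)
        if not maps or len(set(maps)) != len(maps):
            raise ValueError("feature_maps must be non-empty without duplicates")
        unknown = set(maps) - set(MAP_NAMES)
        if unknown:
            raise ValueError(f"unknown feature maps: {sorted(unknown)}")
        object.__setattr__(self, "feature_maps", maps)
        if self.standardize_method not in ("zscore", "minmax"):
            raise ValueError("standardize_method must be 'zscore' or 'minmax'")


@dataclass
class PatchMatrix:
    """2-D training table: one row per sampled voxel.

    ``features`` has ``27 * len(feature_maps)`` columns; ``provenance`` keeps
    per-row (study_id, x, y, z) so rows can be traced back to voxels.
    """

    features: np.ndarray
    labels: np.ndarray
    provenance: pd.DataFrame
    feature_maps: tuple[str, ...]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.feature_maps = tuple(self.feature_maps)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.features.shape[1] != PATCH_SIZE * len(self.feature_maps):
            raise ValueError("column count must be 27 x number of feature maps")
        if len(self.labels) != len(self.features) or len(self.provenance) != len(self.features):
            raise ValueError("features, labels and provenance must align row-wise")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def column_names(self) -> list[str]:
        return [f"{m}_{k}" for m in self.feature_maps for k in range(PATCH_SIZE)]

    def select_maps(self, maps: Sequence[str]) -> "PatchMatrix":
        """Column-block subset (never re-sampled): e.g. four-map -> two-map."""
        maps = tuple(maps)
        missing = set(maps) - set(self.feature_maps)
        if missing:
            raise KeyError(f"maps not in matrix: {sorted(missing)}")
        blocks = []
        for m in maps:
            j = self.feature_maps.index(m)
            blocks.append(self.features[:, j * PATCH_SIZE : (j + 1) * PATCH_SIZE])
        return PatchMatrix(
            features=np.hstack(blocks),
            labels=self.labels.copy(),
            provenance=self.provenance.reset_index(drop=True),
            feature_maps=maps,
        )

    def subset(self, rows: np.ndarray) -> "PatchMatrix":
        return PatchMatrix(
            features=self.features[rows],
            labels=self.labels[rows],
            provenance=self.provenance.iloc[rows].reset_index(drop=True),
            feature_maps=self.feature_maps,
        )

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.features, columns=self.column_names)
        df["label"] = self.labels
        df = pd.concat([df, self.provenance.reset_index(drop=True)], axis=1)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PatchMatrix":
        df = pd.read_csv(path)
        feat_cols = [c for c in df.columns if c not in ("label", "study_id", "x", "y", "z")]
        maps = tuple(dict.fromkeys(c.rsplit("_", 1)[0] for c in feat_cols))
        return cls(
            features=df[feat_cols].to_numpy(dtype=np.float64),
            labels=df["label"].to_numpy(dtype=np.int64),
            provenance=df[["study_id", "x", "y", "z"]].copy(),
            feature_maps=maps,
        )


def sample_voxels(
    lesion_map: LesionMap, cfg: SamplingConfig, rng: np.random.Generator | None = None
) -> list[tuple[tuple[int, int, int], int]]:
    """Sample ``n_per_class`` voxels uniformly without replacement per class.

    If the core class (3) is absent, its quota is re-allocated to extra
    non-ischemic (class 1) voxels, so the total is always 4 x n_per_class.
    A present class with fewer than ``n_per_class`` voxels is an error.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_per_class
    labels = lesion_map.labels
    quotas = {0: n, 1: n, 2: n, 3: n}
    if not (labels == 3).any():
        quotas[1] += quotas.pop(3)  # no-core fallback: extra healthy samples
    out: list[tuple[tuple[int, int, int], int]] = []
    for cls in sorted(quotas):
        coords = np.argwhere(labels == cls)
        if len(coords) < quotas[cls]:
            raise ValueError(
                f"study {lesion_map.study_id!r}: class {cls} has {len(coords)} voxels, "
                f"fewer than the {quotas[cls]} requested"
            )
        pick = rng.choice(len(coords), size=quotas[cls], replace=False)
        out.extend((tuple(int(v) for v in coords[i]), cls) for i in pick)
    return out


def extract_patches(
    study: PerfusionStudy,
    coordinates: Iterable[tuple[int, int, int]],
    feature_maps: Sequence[str] = MAP_NAMES,
) -> np.ndarray:
    """Vectorized patch extraction: rows of 27 x len(feature_maps) values.

    Out-of-volume neighbors contribute 0 (zero padding); the coordinate
    itself must lie inside the volume.
    """
    coords = np.atleast_2d(np.asarray(list(coordinates), dtype=np.int64))
    if coords.size == 0:
        return np.zeros((0, PATCH_SIZE * len(feature_maps)))
    shape = np.asarray(study.shape)
    if (coords < 0).any() or (coords >= shape).any():
        raise IndexError("patch center coordinate outside the volume")
    neigh = coords[:, None, :] + NEIGHBOR_OFFSETS[None, :, :] + 1  # into padded frame
    blocks = []
    for name in feature_maps:
        padded = np.pad(study.map(name), 1, mode="constant")
        blocks.append(padded[neigh[..., 0], neigh[..., 1], neigh[..., 2]])
    return np.concatenate(blocks, axis=1)


def extract_patch(
    study: PerfusionStudy,
    coordinate: tuple[int, int, int],
    feature_maps: Sequence[str] = MAP_NAMES,
) -> np.ndarray:
    """Single-voxel convenience wrapper around :func:`extract_patches`."""
    return extract_patches(study, [coordinate], feature_maps)[0]


def build_matrix(
    studies: Sequence[PerfusionStudy],
    lesion_maps: Sequence[LesionMap],
    cfg: SamplingConfig = SamplingConfig(),
) -> PatchMatrix:
    """Sample every study and stack the patch rows into one training matrix.

    Per-study sampling seeds are ``cfg.seed + study_index`` so cohorts are
    reproducible piecewise.
    """
    if len(studies) != len(lesion_maps):
        raise ValueError("studies and lesion maps must align one-to-one")
    feats, labs, prov = [], [], []
    for i, (study, lmap) in enumerate(zip(studies, lesion_maps)):
        if study.shape != lmap.shape:
            raise ValueError(f"study {study.study_id!r}: lesion map shape mismatch")
        rng = np.random.default_rng((cfg.seed + i) % 2**31)
        samples = sample_voxels(lmap, cfg, rng=rng)
        coords = [c for c, _ in samples]
        feats.append(extract_patches(study, coords, cfg.feature_maps))
        labs.extend(lab for _, lab in samples)
        prov.extend((study.study_id, *c) for c in coords)
    return PatchMatrix(
        features=np.vstack(feats),
        labels=np.asarray(labs),
        provenance=pd.DataFrame(prov, columns=["study_id", "x", "y", "z"]),
        feature_maps=tuple(cfg.feature_maps),
    )


def split_train_validation(
    matrix: PatchMatrix, cfg: SamplingConfig
) -> tuple[PatchMatrix, PatchMatrix]:
    """Random row-level split into train/validation at ``train_fraction``."""
    n = len(matrix)
    if n == 0:
        raise ValueError("cannot split an empty matrix")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_train = int(round(cfg.train_fraction * n))
    train_rows = np.sort(perm[:n_train])
    val_rows = np.sort(perm[n_train:])
    return matrix.subset(train_rows), matrix.subset(val_rows)


@dataclass
class Standardizer:
    """Per-column affine rescaling fitted on the training split only.

    ``zscore`` centers to mean 0 / SD 1 (zero-variance columns pass through
    centered, scale 1); ``minmax`` maps the training range to [-1, 1].
    """

    method: str = "zscore"
    _scaler: object = field(default=None, repr=False)

    def fit(self, features: np.ndarray) -> "Standardizer":
        if self.method == "zscore":
            self._scaler = StandardScaler()
        else:
            self._scaler = MinMaxScaler(feature_range=(-1.0, 1.0))
        self._scaler.fit(np.asarray(features, dtype=np.float64))
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        if self._scaler is None:
            raise RuntimeError("standardizer is not fitted")
        return self._scaler.transform(np.asarray(features, dtype=np.float64))

    @property
    def n_features(self) -> int:
        return int(self._scaler.n_features_in_)


def fit_standardizer(train: PatchMatrix, method: str = "zscore") -> Standardizer:
    return Standardizer(method=method).fit(train.features)


def apply_standardizer(standardizer: Standardizer, matrix: PatchMatrix) -> PatchMatrix:
    return PatchMatrix(
        features=standardizer.transform(matrix.features),
        labels=matrix.labels.copy(),
        provenance=matrix.provenance.reset_index(drop=True),
        feature_maps=matrix.feature_maps,
    )
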