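"""Whole-volume prediction: apply a trained bundle voxel-by-voxel.

Every brain-mask voxel (or, optionally, every voxel of the grid) gets the
class of the model applied to its standardized 27xC neighborhood patch; the
predictions are written back at their spatial locations, reconstructing a
predicted lesion map in the study's space.  Batching is a memory knob only
and never changes the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ground_truth import LABEL_NONISCHEMIC, LesionMap, single_lesion_cleanup
from .modeling import ModelBundle, predict_scores
from .patch_sampling import extract_patches
from .study import PerfusionStudy

N_CLASSES = 4


@dataclass
class PredictionResult:
    """Predicted lesion map plus optional per-voxel class-score channels."""

    predicted: LesionMap
    scores: Optional[np.ndarray]  # (*grid_shape, 4) or None
    study_id: str
    bundle_manifest: dict

    def __post_init__(self) -> None:
        if self.scores is not None:
            if self.scores.shape[:3] != self.predicted.shape:
                raise ValueError("score volume shape mismatch")


def predict_study(
    study: PerfusionStudy,
    bundle: ModelBundle,
    batch_size: int = 20000,
    mask_only: bool = True,
    return_scores: bool = False,
) -> PredictionResult:
    """Classify every voxel of a study and reconstruct the label volume.

    With ``mask_only`` (default) only brain-mask voxels are classified and
    everything outside the mask is forced to background (class 0); with
    ``mask_only=False`` every voxel of the grid is pushed through the model.
    """
    missing = set(bundle.feature_maps) - {"dt", "cbf", "mtt", "cbv"}
    if missing:
        raise ValueError(f"bundle expects unknown maps {sorted(missing)}")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")

    if mask_only:
        coords = np.argwhere(study.brain_mask)
    else:
        coords = np.argwhere(np.ones(study.shape, dtype=bool))

    labels = np.zeros(study.shape, dtype=np.int8)
    scores = None
    if return_scores:
        scores = np.zeros(study.shape + (N_CLASSES,), dtype=np.float32)
        scores[..., 0] = 1.0  # default: background with certainty
    classes = np.asarray(bundle.model.classes_, dtype=int)

    for start in range(0, len(coords), batch_size):
        chunk = coords[start : start + batch_size]
        X = extract_patches(study, chunk, bundle.feature_maps)
        if X.shape[1] != bundle.standardizer.n_features:
            raise ValueError("study patches do not match the bundle's feature dimensionality")
        Xs = bundle.standardizer.transform(X)
        proba = predict_scores(bundle, Xs)
        pred = classes[np.argmax(proba, axis=1)]
        ii, jj, kk = chunk[:, 0], chunk[:, 1], chunk[:, 2]
        labels[ii, jj, kk] = pred
        if return_scores:
            block = np.zeros((len(chunk), N_CLASSES), dtype=np.float32)
            block[:, classes] = proba
            scores[ii, jj, kk] = block

    predicted = LesionMap(
        labels=labels, voxel_spacing_mm=study.voxel_spacing_mm, study_id=study.study_id
    )
    return PredictionResult(
        predicted=predicted,
        scores=scores,
        study_id=study.study_id,
        bundle_manifest=bundle.manifest(),
    )


def postprocess(predicted: LesionMap, policy: str = "none", connectivity: int = 26) -> LesionMap:
    """Optional single-lesion cleanup of a predicted map.

    ``largest_component`` keeps the largest connected lesion (labels 2/3)
    component and relabels removed lesion voxels to non-ischemic brain (1);
    ``none`` is the identity (raw reconstructions are reported by default).
    """
    if policy not in ("none", "largest_component"):
        raise ValueError("policy must be 'none' or 'largest_component'")
    if policy == "none":
        return predicted
    lesion = predicted.lesion_mask
    keep = single_lesion_cleanup(lesion, connectivity)
    labels = predicted.labels.copy()
    labels[lesion & ~keep] = LABEL_NONISCHEMIC
    return LesionMap(
        labels=labels,
        voxel_spacing_mm=predicted.voxel_spacing_mm,
        study_id=predicted.study_id,
    )
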