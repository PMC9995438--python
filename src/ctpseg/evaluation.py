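"""Segmentation evaluation: overlap metrics, volumes and cohort statistics.

Dice similarity coefficient DSC(A,B) = 2|A∩B| / (|A|+|B|) and Jaccard index
JI(A,B) = |A∩B| / |A∪B| are computed for core and penumbra as binary masks,
separately.  The two are related by JI = DSC / (2 - DSC).  Convention for
degenerate inputs: two empty masks agree perfectly (1.0); exactly one empty
mask scores 0.0 — needed for images with a penumbra but no core.

DSC values are banded into six agreement categories (half-open intervals,
exact 0 is its own category, 1.0 belongs to the top band).  Cohort-level
summaries add per-class mean/SD, paired t-tests of DSC vs JI, and Pearson
correlations of the metrics against ground-truth lesion volume and of the
predicted core volume against follow-up infarct volumes when supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
from scipy import stats

AGREEMENT_BANDS = [
    (0.0, 0.2, "Slight agreement"),
    (0.2, 0.4, "Fair agreement"),
    (0.4, 0.6, "Moderate agreement"),
    (0.6, 0.8, "Substantial agreement"),
    (0.8, 1.0, "Almost perfect agreement"),
]
NO_AGREEMENT = "No Agreement"


def _as_masks(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def dsc(a, b) -> float:
    """Dice similarity coefficient of two binary masks."""
    a, b = _as_masks(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int((a & b).sum())
    return 2.0 * inter / (na + nb)


def jaccard(a, b) -> float:
    """Jaccard index (intersection over union) of two binary masks."""
    a, b = _as_masks(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def agreement_category(dsc_value: float) -> str:
    """Map a DSC value onto the six-band agreement scale."""
    if not 0.0 <= dsc_value <= 1.0:
        raise ValueError("DSC must lie in [0, 1]")
    if dsc_value == 0.0:
        return NO_AGREEMENT
    for lo, hi, label in AGREEMENT_BANDS:
        if lo <= dsc_value < hi:
            return label
    return AGREEMENT_BANDS[-1][2]  # dsc_value == 1.0


def region_volume_ml(mask, voxel_spacing_mm) -> float:
    """|mask| x voxel volume, in milliliters."""
    spacing = tuple(float(s) for s in voxel_spacing_mm)
    if any(s <= 0 for s in spacing):
        raise ValueError("voxel spacing must be positive")
    return float(np.count_nonzero(np.asarray(mask, dtype=bool)) * np.prod(spacing) / 1000.0)


@dataclass
class RegionMetrics:
    """Overlap and volume metrics for one region (core or penumbra) of one image."""

    dsc: float
    ji: float
    gt_volume_ml: float
    pred_volume_ml: float
    agreement: str

    @classmethod
    def from_masks(cls, gt_mask, pred_mask, voxel_spacing_mm) -> "RegionMetrics":
        d = dsc(gt_mask, pred_mask)
        return cls(
            dsc=d,
            ji=jaccard(gt_mask, pred_mask),
            gt_volume_ml=region_volume_ml(gt_mask, voxel_spacing_mm),
            pred_volume_ml=region_volume_ml(pred_mask, voxel_spacing_mm),
            agreement=agreement_category(d),
        )

    def to_dict(self) -> dict[str, Any]:
        return dict(self.__dict__)


def evaluate_prediction(gt_map, pred_map) -> dict[str, RegionMetrics]:
    """Core-vs-core and penumbra-vs-penumbra metrics for one image pair."""
    from .ground_truth import LABEL_CORE, LABEL_PENUMBRA

    if gt_map.shape != pred_map.shape:
        raise ValueError("label volumes must share one shape")
    spacing = gt_map.voxel_spacing_mm
    return {
        "core": RegionMetrics.from_masks(
            gt_map.class_mask(LABEL_CORE), pred_map.class_mask(LABEL_CORE), spacing
        ),
        "penumbra": RegionMetrics.from_masks(
            gt_map.class_mask(LABEL_PENUMBRA), pred_map.class_mask(LABEL_PENUMBRA), spacing
        ),
    }


def _paired_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-tailed paired t-test; identical samples give (0, 1) rather than NaN."""
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    if np.std(diff) == 0.0:  # constant nonzero difference: degenerate t
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def _pearson(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CohortReport:
    """Cohort-level summary recomputable from the per-image table."""

    per_image: list[dict[str, RegionMetrics]]
    summary: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "summary": self.summary,
            "per_image": [
                {region: m.to_dict() for region, m in row.items()} for row in self.per_image
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def cohort_summary(
    per_image: Sequence[dict[str, RegionMetrics]],
    followup_volumes_ml: Optional[Sequence[float]] = None,
    artifact_flags: Optional[Sequence[bool]] = None,
) -> CohortReport:
    """Aggregate per-image core/penumbra metrics into the cohort report.

    Requires at least 3 images for the tests and correlations.  When
    ``followup_volumes_ml`` is given, predicted core volume is correlated
    against it, both over all images and excluding artifact-flagged ones.
    """
    if len(per_image) < 3:
        raise ValueError("cohort summary needs at least 3 images")
    summary: dict[str, Any] = {"n_images": len(per_image)}
    for region in ("core", "penumbra"):
        d = np.array([row[region].dsc for row in per_image])
        j = np.array([row[region].ji for row in per_image])
        gt_vol = np.array([row[region].gt_volume_ml for row in per_image])
        t, p = _paired_ttest(d, j)
        r_dsc, p_dsc = _pearson(d, gt_vol)
        r_ji, p_ji = _pearson(j, gt_vol)
        summary[region] = {
            "dsc_mean": float(d.mean()),
            "dsc_sd": float(d.std(ddof=1)),
            "ji_mean": float(j.mean()),
            "ji_sd": float(j.std(ddof=1)),
            "dsc_vs_ji_t": t,
            "dsc_vs_ji_p": p,
            "dsc_vs_gt_volume_r": r_dsc,
            "dsc_vs_gt_volume_p": p_dsc,
            "ji_vs_gt_volume_r": r_ji,
            "ji_vs_gt_volume_p": p_ji,
        }
    if followup_volumes_ml is not None:
        if len(followup_volumes_ml) != len(per_image):
            raise ValueError("follow-up volume list must align with the cohort")
        pred_core = np.array([row["core"].pred_volume_ml for row in per_image])
        fu = np.asarray(followup_volumes_ml, dtype=float)
        r, p = _pearson(pred_core, fu)
        summary["core_vs_followup"] = {"r": r, "p": p}
        if artifact_flags is not None:
            keep = ~np.asarray(artifact_flags, dtype=bool)
            if keep.sum() >= 3:
                r2, p2 = _pearson(pred_core[keep], fu[keep])
                summary["core_vs_followup_no_artifact"] = {"r": r2, "p": p2}
    return CohortReport(per_image=list(per_image), summary=summary)
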