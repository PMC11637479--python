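"""Exam-level quality control and aggregation of per-image measurements.

Exams with fewer than eight images, exams acquired without calibration, and
exams in which the software counted no capillaries at all are excluded before
classification. Surviving exams are collapsed into a single feature vector:
pooled density (total capillaries over total millimetres) and pooled
percentages sharing the exam-wide capillary denominator. Pooling weights each
image by the width of nailfold it actually covers and avoids the instability
of averaging per-image ratios with small denominators.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ContractError
from .model import FeatureVector, NvcExam

DEFAULT_MIN_IMAGES = 8


class QcReason(enum.StrEnum):
    OK = "OK"
    TOO_FEW_IMAGES = "TOO_FEW_IMAGES"
    NOT_CALIBRATED = "NOT_CALIBRATED"
    NO_CAPILLARIES = "NO_CAPILLARIES"


@dataclass(frozen=True)
class QcResult:
    exam_id: str
    passed: bool
    reason: QcReason

    def __post_init__(self) -> None:
        assert self.passed == (self.reason is QcReason.OK)


def qc_filter(exam: NvcExam, min_images: int = DEFAULT_MIN_IMAGES) -> QcResult:
    """Apply the exclusion rules to one exam; first failure is reported.

    Checks run in a fixed order: image count, then calibration, then the
    degenerate zero-capillary case.
    """
    if exam.n_images < min_images:
        return QcResult(exam.exam_id, False, QcReason.TOO_FEW_IMAGES)
    if not exam.calibrated:
        return QcResult(exam.exam_id, False, QcReason.NOT_CALIBRATED)
    if exam.total_capillaries == 0:
        return QcResult(exam.exam_id, False, QcReason.NO_CAPILLARIES)
    return QcResult(exam.exam_id, True, QcReason.OK)


def aggregate(exam: NvcExam) -> FeatureVector:
    """Pool an exam's image measurements into its feature vector.

    Requires at least one counted capillary and positive total width
    (guaranteed for exams that passed QC).
    """
    total_caps = exam.total_capillaries
    total_width = exam.total_width_mm
    if total_caps == 0 or not total_width > 0:
        raise ContractError(
            f"exam '{exam.exam_id}' cannot be aggregated: "
            f"{total_caps} capillaries over {total_width} mm"
        )
    n_giant = sum(img.n_giant for img in exam.images)
    n_abnormal = sum(img.n_abnormal for img in exam.images)
    n_tortuous = sum(img.n_tortuous for img in exam.images)
    n_haem = sum(img.n_haemorrhages for img in exam.images)
    return FeatureVector(
        density=total_caps / total_width,
        pct_giant=100.0 * n_giant / total_caps,
        pct_abnormal=100.0 * n_abnormal / total_caps,
        pct_tortuous=100.0 * n_tortuous / total_caps,
        haemorrhages_present=n_haem >= 1,
        total_capillaries=total_caps,
        total_width_mm=total_width,
    )


def per_image_mean_density(exam: NvcExam) -> float:
    """Unweighted mean of per-image densities (diagnostic alternative).

    The pooled density used for classification weights images by measured
    width; this companion statistic treats every image equally and is exposed
    for sensitivity analyses only — it never feeds the rules.
    """
    if exam.n_images == 0:
        raise ContractError(f"exam '{exam.exam_id}' has no images")
    return sum(img.n_capillaries / img.width_mm for img in exam.images) / exam.n_images
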