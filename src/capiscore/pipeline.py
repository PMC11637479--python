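"""End-to-end convenience: QC -> aggregation -> classification for many exams."""

from __future__ import annotations

from typing import Iterable, Sequence

from .model import NvcExam
from .patterns import Pattern
from .qc import DEFAULT_MIN_IMAGES, QcResult, aggregate, qc_filter
from .rules import DEFAULT_THRESHOLDS, ClassificationResult, Thresholds, classify_features


def classify_exams(
    exams: Iterable[NvcExam],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    min_images: int = DEFAULT_MIN_IMAGES,
) -> tuple[list[ClassificationResult], list[QcResult]]:
    """Classify every exam that passes QC; report QC outcomes for all.

    Returns classification results (QC-passing exams only, input order) and
    the complete QC report.
    """
    results: list[ClassificationResult] = []
    qc_results: list[QcResult] = []
    for exam in exams:
        qc = qc_filter(exam, min_images=min_images)
        qc_results.append(qc)
        if not qc.passed:
            continue
        results.append(classify_features(exam.exam_id, aggregate(exam), thresholds))
    return results, qc_results


def predictions(results: Sequence[ClassificationResult]) -> dict[str, Pattern]:
    """Map exam_id -> predicted pattern, for evaluation against a gold standard."""
    return {res.exam_id: res.pattern for res in results}
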