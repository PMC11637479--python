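"""Delimited-text readers and writers for every table the pipeline exchanges.

One dialect everywhere: comma-separated, ``.`` decimal mark, UTF-8, header
row required. Floats are serialized with Python's shortest round-tripping
representation, so write -> read -> write is byte-identical. A missing
haemorrhage count is rejected rather than treated as zero: the
normal/non-specific split depends on haemorrhage presence, and silent
missingness would change classifications.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from .errors import TableFormatError, ValidationError
from .model import FeatureVector, ImageMeasurement, NvcExam
from .patterns import Pattern, Verdict, group
from .qc import QcResult
from .rules import ClassificationResult

IMAGE_COLUMNS = (
    "exam_id",
    "image_id",
    "calibrated",
    "n_capillaries",
    "width_mm",
    "n_giant",
    "n_abnormal",
    "n_tortuous",
    "n_haemorrhages",
)

FEATURE_COLUMNS = (
    "exam_id",
    "density",
    "pct_giant",
    "pct_abnormal",
    "pct_tortuous",
    "haemorrhages_present",
    "total_capillaries",
    "total_width_mm",
)

CLASSIFICATION_COLUMNS = (
    "exam_id",
    "density",
    "pct_giant",
    "pct_abnormal",
    "pct_tortuous",
    "haemorrhages_present",
    "rule1",
    "rule_stage_or_rule4",
    "pattern",
    "trace",
)

VERDICT_COLUMNS = ("exam_id", "rater_1", "rater_2", "rater_3")
GOLD_COLUMNS = ("exam_id", "pattern")
QC_COLUMNS = ("exam_id", "passed", "reason")


def _open_reader(path: str | Path, expected: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TableFormatError(f"{path}: empty file, header row required")
        if tuple(reader.fieldnames) != tuple(expected):
            raise TableFormatError(
                f"{path}: header {reader.fieldnames} does not match "
                f"expected {list(expected)}"
            )
        return list(reader)


def _parse_int(raw: str, field: str, row: int) -> int:
    try:
        return int(raw)
    except (TypeError, ValueError):
        raise TableFormatError(f"expected an integer, got {raw!r}", row=row, field=field)


def _parse_float(raw: str, field: str, row: int) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise TableFormatError(f"expected a number, got {raw!r}", row=row, field=field)


def _parse_bool(raw: str, field: str, row: int) -> bool:
    if raw in ("0", "1"):
        return raw == "1"
    raise TableFormatError(f"expected 0 or 1, got {raw!r}", row=row, field=field)


def _writer(path: str | Path, columns: Sequence[str]):
    path = Path(path)
    fh = path.open("w", encoding="utf-8", newline="")
    writer = csv.writer(fh, lineterminator="\n")
    writer.writerow(columns)
    return fh, writer


def read_image_table(path: str | Path) -> list[NvcExam]:
    """Read per-image measurements grouped into exams, in file order.

    Every image-level invariant is validated; errors carry the 1-based data
    row number and offending field.
    """
    rows = _open_reader(path, IMAGE_COLUMNS)
    order: list[str] = []
    images: dict[str, list[ImageMeasurement]] = {}
    calibrated: dict[str, bool] = {}
    for i, raw in enumerate(rows, start=1):
        exam_id = raw["exam_id"]
        if exam_id is None or exam_id == "":
            raise TableFormatError("missing exam_id", row=i, field="exam_id")
        cal = _parse_bool(raw["calibrated"], "calibrated", i)
        try:
            img = ImageMeasurement(
                image_id=raw["image_id"],
                n_capillaries=_parse_int(raw["n_capillaries"], "n_capillaries", i),
                width_mm=_parse_float(raw["width_mm"], "width_mm", i),
                n_giant=_parse_int(raw["n_giant"], "n_giant", i),
                n_abnormal=_parse_int(raw["n_abnormal"], "n_abnormal", i),
                n_tortuous=_parse_int(raw["n_tortuous"], "n_tortuous", i),
                n_haemorrhages=_parse_int(raw["n_haemorrhages"], "n_haemorrhages", i),
            )
        except TableFormatError:
            raise
        except ValidationError as exc:
            raise TableFormatError(str(exc), row=i) from exc
        if exam_id not in images:
            order.append(exam_id)
            images[exam_id] = []
            calibrated[exam_id] = cal
        elif calibrated[exam_id] != cal:
            raise TableFormatError(
                f"calibrated flag inconsistent within exam '{exam_id}'",
                row=i,
                field="calibrated",
            )
        images[exam_id].append(img)
    exams = []
    for exam_id in order:
        try:
            exams.append(NvcExam(exam_id, calibrated[exam_id], tuple(images[exam_id])))
        except ValidationError as exc:
            raise TableFormatError(str(exc)) from exc
    return exams


def write_image_table(exams: Iterable[NvcExam], path: str | Path) -> None:
    fh, writer = _writer(path, IMAGE_COLUMNS)
    with fh:
        for exam in exams:
            for img in exam.images:
                writer.writerow(
                    [
                        exam.exam_id,
                        img.image_id,
                        int(exam.calibrated),
                        img.n_capillaries,
                        repr(img.width_mm),
                        img.n_giant,
                        img.n_abnormal,
                        img.n_tortuous,
                        img.n_haemorrhages,
                    ]
                )


def write_feature_table(
    features: Iterable[tuple[str, FeatureVector]], path: str | Path
) -> None:
    fh, writer = _writer(path, FEATURE_COLUMNS)
    with fh:
        for exam_id, fv in features:
            writer.writerow(
                [
                    exam_id,
                    repr(fv.density),
                    repr(fv.pct_giant),
                    repr(fv.pct_abnormal),
                    repr(fv.pct_tortuous),
                    int(fv.haemorrhages_present),
                    fv.total_capillaries,
                    repr(fv.total_width_mm),
                ]
            )


def read_feature_table(path: str | Path) -> list[tuple[str, FeatureVector]]:
    rows = _open_reader(path, FEATURE_COLUMNS)
    out = []
    for i, raw in enumerate(rows, start=1):
        try:
            fv = FeatureVector(
                density=_parse_float(raw["density"], "density", i),
                pct_giant=_parse_float(raw["pct_giant"], "pct_giant", i),
                pct_abnormal=_parse_float(raw["pct_abnormal"], "pct_abnormal", i),
                pct_tortuous=_parse_float(raw["pct_tortuous"], "pct_tortuous", i),
                haemorrhages_present=_parse_bool(
                    raw["haemorrhages_present"], "haemorrhages_present", i
                ),
                total_capillaries=_parse_int(
                    raw["total_capillaries"], "total_capillaries", i
                ),
                total_width_mm=_parse_float(raw["total_width_mm"], "total_width_mm", i),
            )
        except TableFormatError:
            raise
        except ValidationError as exc:
            raise TableFormatError(str(exc), row=i) from exc
        out.append((raw["exam_id"], fv))
    return out


def write_classification_table(
    results: Iterable[ClassificationResult], path: str | Path
) -> None:
    """One row per exam with features, both decision stages, and the trace."""
    fh, writer = _writer(path, CLASSIFICATION_COLUMNS)
    with fh:
        for res in results:
            fv = res.features
            writer.writerow(
                [
                    res.exam_id,
                    repr(fv.density),
                    repr(fv.pct_giant),
                    repr(fv.pct_abnormal),
                    repr(fv.pct_tortuous),
                    int(fv.haemorrhages_present),
                    res.group.value,
                    res.pattern.value,
                    res.pattern.value,
                    ";".join(res.trace),
                ]
            )


def read_classification_table(path: str | Path) -> list[dict]:
    """Read a classification table back as plain records (typed fields)."""
    rows = _open_reader(path, CLASSIFICATION_COLUMNS)
    out = []
    for i, raw in enumerate(rows, start=1):
        pattern = _parse_pattern(raw["pattern"], i)
        record = {
            "exam_id": raw["exam_id"],
            "density": _parse_float(raw["density"], "density", i),
            "pct_giant": _parse_float(raw["pct_giant"], "pct_giant", i),
            "pct_abnormal": _parse_float(raw["pct_abnormal"], "pct_abnormal", i),
            "pct_tortuous": _parse_float(raw["pct_tortuous"], "pct_tortuous", i),
            "haemorrhages_present": _parse_bool(
                raw["haemorrhages_present"], "haemorrhages_present", i
            ),
            "rule1": raw["rule1"],
            "rule_stage_or_rule4": raw["rule_stage_or_rule4"],
            "pattern": pattern,
            "trace": tuple(raw["trace"].split(";")) if raw["trace"] else (),
        }
        if record["rule1"] != group(pattern).value:
            raise TableFormatError(
                f"rule1 column {record['rule1']!r} inconsistent with pattern "
                f"{pattern.value!r}",
                row=i,
                field="rule1",
            )
        out.append(record)
    return out


def _parse_pattern(raw: str, row: int) -> Pattern:
    try:
        return Pattern(raw)
    except ValueError:
        raise TableFormatError(f"unknown pattern {raw!r}", row=row, field="pattern")


def _parse_verdict(raw: str, field: str, row: int) -> Verdict:
    try:
        return Verdict(raw)
    except ValueError:
        raise TableFormatError(f"unknown verdict {raw!r}", row=row, field=field)


def read_verdict_table(path: str | Path) -> list[tuple[str, tuple[Verdict, Verdict, Verdict]]]:
    rows = _open_reader(path, VERDICT_COLUMNS)
    out = []
    for i, raw in enumerate(rows, start=1):
        verdicts = tuple(
            _parse_verdict(raw[col], col, i) for col in ("rater_1", "rater_2", "rater_3")
        )
        out.append((raw["exam_id"], verdicts))
    return out


def write_verdict_table(
    verdicts: Iterable[tuple[str, Sequence[Verdict]]], path: str | Path
) -> None:
    fh, writer = _writer(path, VERDICT_COLUMNS)
    with fh:
        for exam_id, triple in verdicts:
            writer.writerow([exam_id] + [Verdict(v).value for v in triple])


def read_gold_table(path: str | Path) -> dict[str, Pattern]:
    rows = _open_reader(path, GOLD_COLUMNS)
    out: dict[str, Pattern] = {}
    for i, raw in enumerate(rows, start=1):
        exam_id = raw["exam_id"]
        if exam_id in out:
            raise TableFormatError(f"duplicate exam_id '{exam_id}'", row=i, field="exam_id")
        out[exam_id] = _parse_pattern(raw["pattern"], i)
    return out


def write_gold_table(gold: dict[str, Pattern] | Iterable[tuple[str, Pattern]], path) -> None:
    items = gold.items() if isinstance(gold, dict) else gold
    fh, writer = _writer(path, GOLD_COLUMNS)
    with fh:
        for exam_id, pattern in items:
            writer.writerow([exam_id, Pattern(pattern).value])


def write_qc_report(results: Iterable[QcResult], path: str | Path) -> None:
    fh, writer = _writer(path, QC_COLUMNS)
    with fh:
        for res in results:
            writer.writerow([res.exam_id, int(res.passed), res.reason.value])
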