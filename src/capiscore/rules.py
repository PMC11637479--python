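"""The CAPI-score decision tree over exam-level capillary features.

Four quantitative rules, applied in a fixed order, assign one of the five
disease patterns to every exam:

* **Rule 1** (SSc vs non-SSc): the exam shows an SSc pattern when density is
  at most 6 capillaries/mm, or any giant capillary is present, or abnormal
  capillaries exceed 10%.
* **Rule 2** (SSc, density >= 5/mm): SSc-early, unless giants reach 10% or
  abnormal capillaries reach 5%, which indicates SSc-active.
* **Rule 3** (SSc, density < 5/mm): SSc-late by default; giants >= 33% or
  abnormal <= 7% re-stage to SSc-active — yet, regardless of those
  conditions, giants <= 7% or abnormal >= 15% keeps the pattern SSc-late.
  The late clause is evaluated last and takes absolute precedence.
* **Rule 4** (non-SSc): non-specific when tortuosities reach 20%, any
  haemorrhage is present, or abnormal capillaries reach 2%; otherwise normal.

The engine is table-driven: every comparison is a (feature, operator,
threshold) triple drawn from one explicit :class:`Thresholds` configuration,
and each classification carries a trace of exactly which conditions fired, in
evaluation order, so any assignment can be audited. Comparisons use the exact
computed feature values — no rounding is applied before threshold tests,
since rounding would move boundary cases.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, fields
from typing import Callable, Mapping

from .errors import ContractError, ValidationError
from .model import FeatureVector
from .patterns import Group, Pattern, group


@dataclass(frozen=True)
class Thresholds:
    """The eleven cut-offs of the decision tree, in printed units.

    Densities are capillaries per mm; every other threshold is a percentage
    of the exam's capillaries. The defaults are the published cut-offs; the
    suffix of each field name records which side of the comparison is
    inclusive (``_max``/``_le``/``_ge`` inclusive, ``_gt`` strict).
    """

    r1_density_max: float = 6.0
    r1_abnormal_gt: float = 10.0
    r23_density_split: float = 5.0
    r2_giant_ge: float = 10.0
    r2_abnormal_ge: float = 5.0
    r3_giant_active_ge: float = 33.0
    r3_abnormal_active_le: float = 7.0
    r3_giant_late_le: float = 7.0
    r3_abnormal_late_ge: float = 15.0
    r4_tortuous_ge: float = 20.0
    r4_abnormal_ge: float = 2.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value < 0:
                raise ValidationError(f"threshold {f.name} must be non-negative")
            if "density" not in f.name and value > 100:
                raise ValidationError(f"percentage threshold {f.name} must be <= 100")

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "Thresholds":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class Condition:
    """One threshold comparison: feature <op> threshold, with a trace label."""

    feature: str
    op: Callable[[float, float], bool]
    label: str
    threshold_field: str | None = None  # None -> compare against `literal`
    literal: float = 0.0

    def cutoff(self, th: Thresholds) -> float:
        if self.threshold_field is None:
            return self.literal
        return getattr(th, self.threshold_field)

    def fires(self, fv: FeatureVector, th: Thresholds) -> bool:
        return self.op(getattr(fv, self.feature), self.cutoff(th))


# Trace vocabulary: labels appear in evaluation order in every trace.
R1_DENSITY_LE_6 = "R1_DENSITY_LE_6"
R1_GIANTS_DETECTED = "R1_GIANTS_DETECTED"
R1_ABNORMAL_GT_10 = "R1_ABNORMAL_GT_10"
R2_EARLY_DEFAULT = "R2_EARLY_DEFAULT"
R2_ACTIVE_GIANT_GE_10 = "R2_ACTIVE_GIANT_GE_10"
R2_ACTIVE_ABN_GE_5 = "R2_ACTIVE_ABN_GE_5"
R3_LATE_DEFAULT = "R3_LATE_DEFAULT"
R3_ACTIVE_OVERRIDE = "R3_ACTIVE_OVERRIDE"
R3_LATE_FINAL_OVERRIDE = "R3_LATE_FINAL_OVERRIDE"
R4_TORTUOUS_GE_20 = "R4_TORTUOUS_GE_20"
R4_HAEMORRHAGES = "R4_HAEMORRHAGES"
R4_ABNORMAL_GE_2 = "R4_ABNORMAL_GE_2"
R4_NORMAL_DEFAULT = "R4_NORMAL_DEFAULT"

_R1_DISJUNCTS = (
    Condition("density", operator.le, R1_DENSITY_LE_6, "r1_density_max"),
    Condition("pct_giant", operator.gt, R1_GIANTS_DETECTED, None, 0.0),
    Condition("pct_abnormal", operator.gt, R1_ABNORMAL_GT_10, "r1_abnormal_gt"),
)

_R2_ACTIVE = (
    Condition("pct_giant", operator.ge, R2_ACTIVE_GIANT_GE_10, "r2_giant_ge"),
    Condition("pct_abnormal", operator.ge, R2_ACTIVE_ABN_GE_5, "r2_abnormal_ge"),
)

_R3_ACTIVE_OVERRIDE = (
    Condition("pct_giant", operator.ge, R3_ACTIVE_OVERRIDE, "r3_giant_active_ge"),
    Condition("pct_abnormal", operator.le, R3_ACTIVE_OVERRIDE, "r3_abnormal_active_le"),
)

_R3_LATE_FINAL = (
    Condition("pct_giant", operator.le, R3_LATE_FINAL_OVERRIDE, "r3_giant_late_le"),
    Condition("pct_abnormal", operator.ge, R3_LATE_FINAL_OVERRIDE, "r3_abnormal_late_ge"),
)

_R4_DISJUNCTS = (
    Condition("pct_tortuous", operator.ge, R4_TORTUOUS_GE_20, "r4_tortuous_ge"),
    Condition("haemorrhages_present", operator.eq, R4_HAEMORRHAGES, None, True),
    Condition("pct_abnormal", operator.ge, R4_ABNORMAL_GE_2, "r4_abnormal_ge"),
)

DEFAULT_THRESHOLDS = Thresholds()


def _fired(conditions, fv: FeatureVector, th: Thresholds) -> list[str]:
    return [c.label for c in conditions if c.fires(fv, th)]


def rule1_ssc_vs_nonssc(
    fv: FeatureVector, th: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[Group, list[str]]:
    """First step: SSc whenever any of the three disjuncts fires."""
    trace = _fired(_R1_DISJUNCTS, fv, th)
    return (Group.SSC if trace else Group.NON_SSC), trace


def stage_ssc(
    fv: FeatureVector, th: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[Pattern, list[str]]:
    """Second step for SSc exams: early / active / late staging.

    Above the density split, Rule 2 applies (early unless giants or abnormal
    shapes are prominent). Below it, Rule 3 applies: late by default, an
    active override, then the unconditional late clause last.
    """
    grp, _ = rule1_ssc_vs_nonssc(fv, th)
    if grp is not Group.SSC:
        raise ContractError("stage_ssc requires a feature vector classified SSc by rule 1")

    if fv.density >= th.r23_density_split:
        fired = _fired(_R2_ACTIVE, fv, th)
        if fired:
            return Pattern.SSC_ACTIVE, fired
        return Pattern.SSC_EARLY, [R2_EARLY_DEFAULT]

    trace = [R3_LATE_DEFAULT]
    pattern = Pattern.SSC_LATE
    if any(c.fires(fv, th) for c in _R3_ACTIVE_OVERRIDE):
        trace.append(R3_ACTIVE_OVERRIDE)
        pattern = Pattern.SSC_ACTIVE
    # "regardless of these conditions": evaluated last, takes precedence.
    if any(c.fires(fv, th) for c in _R3_LATE_FINAL):
        trace.append(R3_LATE_FINAL_OVERRIDE)
        pattern = Pattern.SSC_LATE
    return pattern, trace


def rule4_normal_vs_nonspecific(
    fv: FeatureVector, th: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[Pattern, list[str]]:
    """Second step for non-SSc exams: normal vs non-specific."""
    grp, _ = rule1_ssc_vs_nonssc(fv, th)
    if grp is not Group.NON_SSC:
        raise ContractError(
            "rule4_normal_vs_nonspecific requires a feature vector classified "
            "non-SSc by rule 1"
        )
    fired = _fired(_R4_DISJUNCTS, fv, th)
    if fired:
        return Pattern.NON_SPECIFIC, fired
    return Pattern.NORMAL, [R4_NORMAL_DEFAULT]


def capi_score(
    fv: FeatureVector, th: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[Pattern, list[str]]:
    """Full decision tree: exactly one of the five patterns, with its trace."""
    grp, trace = rule1_ssc_vs_nonssc(fv, th)
    if grp is Group.SSC:
        pattern, sub = stage_ssc(fv, th)
    else:
        pattern, sub = rule4_normal_vs_nonspecific(fv, th)
    return pattern, trace + sub


@dataclass(frozen=True)
class ClassificationResult:
    """One exam's classification with its audit trail."""

    exam_id: str
    features: FeatureVector
    pattern: Pattern
    trace: tuple[str, ...]

    @property
    def group(self) -> Group:
        return group(self.pattern)


def classify_features(
    exam_id: str, fv: FeatureVector, th: Thresholds = DEFAULT_THRESHOLDS
) -> ClassificationResult:
    pattern, trace = capi_score(fv, th)
    return ClassificationResult(exam_id, fv, pattern, tuple(trace))
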