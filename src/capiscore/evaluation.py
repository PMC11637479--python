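"""Diagnostic-accuracy evaluation: confusion matrices, precision/recall, accuracy.

Performance of the classifier against the gold standard is assessed per
algorithm step, mirroring how the decision tree stratifies the cohort:

* ``RULE1_BINARY`` — SSc vs non-SSc, both sides mapped through the group.
* ``SSC_STAGING`` — early/active/late, restricted to exams whose *gold*
  pattern is SSc (a prediction routed to the wrong side of Rule 1 is excluded
  from staging metrics rather than counted as a staging error).
* ``NONSSC_SPLIT`` — normal vs non-specific, restricted to gold non-SSc exams.
* ``OVERALL_5CLASS`` — all five patterns on all paired exams.

Matrices are oriented rows = true, columns = predicted. A precision with an
empty predicted column, or a recall with an empty true row, is reported as
NaN — never silently zero — and excluded from any averaging.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .patterns import Group, Pattern, group

FIVE_CLASS_LABELS: tuple[str, ...] = tuple(p.value for p in Pattern)
BINARY_LABELS: tuple[str, ...] = (Group.SSC.value, Group.NON_SSC.value)
STAGING_LABELS: tuple[str, ...] = (
    Pattern.SSC_EARLY.value,
    Pattern.SSC_ACTIVE.value,
    Pattern.SSC_LATE.value,
)
SPLIT_LABELS: tuple[str, ...] = (Pattern.NORMAL.value, Pattern.NON_SPECIFIC.value)


class Step(enum.StrEnum):
    RULE1_BINARY = "rule1"
    SSC_STAGING = "staging"
    NONSSC_SPLIT = "nonssc"
    OVERALL_5CLASS = "overall"


_STEP_LABELS: dict[Step, tuple[str, ...]] = {
    Step.RULE1_BINARY: BINARY_LABELS,
    Step.SSC_STAGING: STAGING_LABELS,
    Step.NONSSC_SPLIT: SPLIT_LABELS,
    Step.OVERALL_5CLASS: FIVE_CLASS_LABELS,
}


def confusion_matrix(
    truth: Sequence, predicted: Sequence, labels: Sequence[str]
) -> np.ndarray:
    """Count matrix with rows = true label, columns = predicted label."""
    if len(truth) != len(predicted):
        raise ContractError(
            f"truth ({len(truth)}) and predicted ({len(predicted)}) differ in length"
        )
    index = {str(lab): i for i, lab in enumerate(labels)}
    matrix = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        t, p = str(t), str(p)
        if t not in index or p not in index:
            raise ContractError(f"label outside vocabulary {list(labels)}: ({t!r}, {p!r})")
        matrix[index[t], index[p]] += 1
    return matrix


@dataclass(frozen=True)
class EvaluationReport:
    step: Step
    labels: tuple[str, ...]
    matrix: np.ndarray
    precision: dict[str, float]
    recall: dict[str, float]
    accuracy: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format metrics table (one row per step x class, plus accuracy)."""
        rows = [
            {
                "step": self.step.value,
                "class": lab,
                "metric": metric,
                "value": values[lab],
            }
            for metric, values in (("precision", self.precision), ("recall", self.recall))
            for lab in self.labels
        ]
        rows.append(
            {"step": self.step.value, "class": "", "metric": "accuracy", "value": self.accuracy}
        )
        rows.append({"step": self.step.value, "class": "", "metric": "n", "value": self.n})
        return pd.DataFrame(rows, columns=["step", "class", "metric", "value"])

    def format_text(self) -> str:
        lines = [f"step: {self.step.value}  (n = {self.n})"]
        header = "true \\ pred".ljust(14) + "".join(lab.rjust(14) for lab in self.labels)
        lines.append(header)
        for i, lab in enumerate(self.labels):
            lines.append(
                lab.ljust(14) + "".join(str(int(v)).rjust(14) for v in self.matrix[i])
            )
        for lab in self.labels:
            lines.append(
                f"  {lab}: precision={_fmt(self.precision[lab])} recall={_fmt(self.recall[lab])}"
            )
        lines.append(f"  accuracy = {_fmt(self.accuracy)}")
        return "\n".join(lines)


def _fmt(x: float) -> str:
    return "NA" if math.isnan(x) else f"{x:.4f}"


def report_from_labels(
    truth: Sequence, predicted: Sequence, labels: Sequence[str], step: Step
) -> EvaluationReport:
    matrix = confusion_matrix(truth, predicted, labels)
    n = int(matrix.sum())
    diag = np.diag(matrix)
    col_sums = matrix.sum(axis=0)
    row_sums = matrix.sum(axis=1)
    precision = {
        lab: (diag[i] / col_sums[i] if col_sums[i] > 0 else math.nan)
        for i, lab in enumerate(labels)
    }
    recall = {
        lab: (diag[i] / row_sums[i] if row_sums[i] > 0 else math.nan)
        for i, lab in enumerate(labels)
    }
    accuracy = diag.sum() / n if n > 0 else math.nan
    return EvaluationReport(
        step=step,
        labels=tuple(labels),
        matrix=matrix,
        precision=precision,
        recall=recall,
        accuracy=float(accuracy),
        n=n,
    )


def step_evaluation(
    gold: Mapping[str, Pattern], pred: Mapping[str, Pattern], step: Step
) -> EvaluationReport:
    """Evaluate predictions against the gold standard for one algorithm step.

    Only exams present on both sides are compared; the staging and
    normal/non-specific steps restrict further by the gold label.
    """
    step = Step(step)
    shared = sorted(set(gold) & set(pred))
    pairs = [(Pattern(gold[e]), Pattern(pred[e])) for e in shared]

    if step is Step.RULE1_BINARY:
        truth = [group(t).value for t, _ in pairs]
        predicted = [group(p).value for _, p in pairs]
    elif step is Step.SSC_STAGING:
        pairs = [(t, p) for t, p in pairs if group(t) is Group.SSC]
        truth = [t.value for t, _ in pairs]
        predicted = [p.value for _, p in pairs]
    elif step is Step.NONSSC_SPLIT:
        pairs = [(t, p) for t, p in pairs if group(t) is Group.NON_SSC]
        truth = [t.value for t, _ in pairs]
        predicted = [p.value for _, p in pairs]
    else:
        truth = [t.value for t, _ in pairs]
        predicted = [p.value for _, p in pairs]

    labels = _STEP_LABELS[step]
    if step in (Step.SSC_STAGING, Step.NONSSC_SPLIT):
        # Predictions from the wrong side of rule 1 still need a column.
        extra = sorted({p for p in predicted if p not in labels})
        labels = labels + tuple(extra)
    return report_from_labels(truth, predicted, labels, step)
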