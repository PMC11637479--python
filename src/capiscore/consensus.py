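"""Gold-standard derivation from three blinded rater verdicts.

Each exam is graded independently by three blinded experts; the gold-standard
pattern is the verdict shared by at least two of them ("majority"), with
unanimity reported separately ("full consensus"). An ungradable majority is a
valid consensus outcome — such exams are counted, then excluded from pattern
analysis — and a triple with three distinct verdicts yields no consensus.
Exactly three raters are required; the rule is not generalized to n raters.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ContractError
from .patterns import Pattern, Verdict, verdict_to_pattern


class ConsensusLevel(enum.StrEnum):
    FULL = "FULL"
    MAJORITY = "MAJORITY"
    NONE = "NONE"


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of the majority vote for one exam.

    ``outcome`` is ``None`` exactly when no two raters agreed.
    """

    exam_id: str
    outcome: Verdict | None
    level: ConsensusLevel

    def __post_init__(self) -> None:
        assert (self.outcome is None) == (self.level is ConsensusLevel.NONE)

    @property
    def reached(self) -> bool:
        return self.outcome is not None


def derive_consensus(exam_id: str, verdicts: Sequence[Verdict]) -> ConsensusResult:
    """Majority vote over exactly three verdicts.

    At least two identical verdicts define the consensus (three identical is
    full consensus); three distinct verdicts define no consensus. With three
    voters at most one label can reach two votes, so the majority is unique.
    """
    if len(verdicts) != 3:
        raise ContractError(f"exactly three verdicts required, got {len(verdicts)}")
    verdicts = [Verdict(v) for v in verdicts]
    label, count = Counter(verdicts).most_common(1)[0]
    if count == 3:
        return ConsensusResult(exam_id, label, ConsensusLevel.FULL)
    if count == 2:
        return ConsensusResult(exam_id, label, ConsensusLevel.MAJORITY)
    return ConsensusResult(exam_id, None, ConsensusLevel.NONE)


def gold_standard_cohort(
    results: Iterable[ConsensusResult] | Mapping[str, ConsensusResult],
    include_full_only: bool = False,
) -> dict[str, Pattern]:
    """Exams entering pattern analysis: consensual and gradable.

    Exams without consensus and exams whose consensus verdict is ungradable
    are excluded. With ``include_full_only`` the cohort is further restricted
    to unanimous verdicts.
    """
    if isinstance(results, Mapping):
        results = results.values()
    cohort: dict[str, Pattern] = {}
    for res in results:
        if not res.reached or res.outcome is Verdict.UNGRADABLE:
            continue
        if include_full_only and res.level is not ConsensusLevel.FULL:
            continue
        cohort[res.exam_id] = verdict_to_pattern(res.outcome)
    return cohort
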