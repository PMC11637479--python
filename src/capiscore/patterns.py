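"""Disease-pattern labels, rater verdicts, and the SSc / non-SSc grouping.

Nailfold videocapillaroscopy exams are staged into five patterns: a normal
microvascular bed, a non-specific pattern (abnormalities short of scleroderma
criteria), and the three progressive stages of systemic-sclerosis
microangiopathy (early, active, late). Raters may additionally return an
"ungradable" verdict when image quality precludes assignment; the rule engine
never outputs it.
"""

from __future__ import annotations

import enum

from .errors import ContractError


class Pattern(enum.StrEnum):
    """The five gradable disease patterns."""

    NORMAL = "normal"
    NON_SPECIFIC = "non_specific"
    SSC_EARLY = "ssc_early"
    SSC_ACTIVE = "ssc_active"
    SSC_LATE = "ssc_late"


class Verdict(enum.StrEnum):
    """A rater's verdict: one of the five patterns, or ungradable."""

    NORMAL = "normal"
    NON_SPECIFIC = "non_specific"
    SSC_EARLY = "ssc_early"
    SSC_ACTIVE = "ssc_active"
    SSC_LATE = "ssc_late"
    UNGRADABLE = "ungradable"


class Group(enum.StrEnum):
    """Binary grouping used by the first classification step."""

    SSC = "ssc"
    NON_SSC = "non_ssc"


SSC_PATTERNS = frozenset({Pattern.SSC_EARLY, Pattern.SSC_ACTIVE, Pattern.SSC_LATE})
NON_SSC_PATTERNS = frozenset({Pattern.NORMAL, Pattern.NON_SPECIFIC})

#: Severity ordering of the five patterns; consecutive entries are
#: "adjacent" stages (used by the simulated-rater error model).
PATTERN_ORDER: tuple[Pattern, ...] = (
    Pattern.NORMAL,
    Pattern.NON_SPECIFIC,
    Pattern.SSC_EARLY,
    Pattern.SSC_ACTIVE,
    Pattern.SSC_LATE,
)


def group(pattern: Pattern) -> Group:
    """Map a pattern to its SSc / non-SSc group. Total on the five labels."""
    return Group.SSC if pattern in SSC_PATTERNS else Group.NON_SSC


def verdict_to_pattern(verdict: Verdict) -> Pattern:
    """Narrow a gradable verdict to its pattern; ungradable is rejected."""
    if verdict is Verdict.UNGRADABLE:
        raise ContractError("an ungradable verdict has no disease pattern")
    return Pattern(verdict.value)


def pattern_to_verdict(pattern: Pattern) -> Verdict:
    return Verdict(pattern.value)
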