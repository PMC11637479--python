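"""Independent reference implementations used only as test oracles.

Deliberately naive: the rule transcription below is a direct nested-
conditional reading of the published rule sentences, written separately from
the package's table-driven engine; the metric helpers count with plain loops
instead of matrices; the consensus tally is a frequency count. None of these
share code with the implementation under test.
"""

from collections import Counter

from capiscore.patterns import Pattern


def naive_capi(density, pct_giant, pct_abnormal, pct_tortuous, haemorrhages_present):
    """Direct transcription of the four rule sentences."""
    if density <= 6 or pct_giant > 0 or pct_abnormal > 10:  # rule 1: SSc
        if density >= 5:  # rule 2
            if pct_giant >= 10 or pct_abnormal >= 5:
                return Pattern.SSC_ACTIVE
            return Pattern.SSC_EARLY
        # rule 3: late by default
        pattern = Pattern.SSC_LATE
        if pct_giant >= 33 or pct_abnormal <= 7:
            pattern = Pattern.SSC_ACTIVE
        # "regardless of these conditions"
        if pct_giant <= 7 or pct_abnormal >= 15:
            pattern = Pattern.SSC_LATE
        return pattern
    # rule 4: non-SSc
    if pct_tortuous >= 20 or haemorrhages_present or pct_abnormal >= 2:
        return Pattern.NON_SPECIFIC
    return Pattern.NORMAL


def tally_consensus(verdicts):
    """(outcome, count-of-winner) by brute-force frequency count."""
    label, count = Counter(verdicts).most_common(1)[0]
    if count >= 2:
        return label, count
    return None, 1


def loop_confusion(truth, predicted, labels):
    """Confusion counts via nested loops, rows = true / cols = predicted."""
    return [
        [sum(1 for t, p in zip(truth, predicted) if t == lt and p == lp) for lp in labels]
        for lt in labels
    ]


def loop_metrics(truth, predicted, labels):
    """Per-class precision/recall and accuracy by direct counting."""
    precision, recall = {}, {}
    for lab in labels:
        pred_lab = [t for t, p in zip(truth, predicted) if p == lab]
        true_lab = [p for t, p in zip(truth, predicted) if t == lab]
        precision[lab] = (
            sum(1 for t in pred_lab if t == lab) / len(pred_lab) if pred_lab else None
        )
        recall[lab] = (
            sum(1 for p in true_lab if p == lab) / len(true_lab) if true_lab else None
        )
    n = len(truth)
    accuracy = sum(1 for t, p in zip(truth, predicted) if t == p) / n if n else None
    return precision, recall, accuracy


def boundary_grid(step=1.0):
    """Feature grids spanning the rule space with refinement at every cut-off.

    Returns (densities, percentages): densities cover 0..12, percentages
    0..100, each including every threshold value exactly and straddled by
    +/- 1e-9.
    """
    eps = 1e-9

    def refine(base, cutoffs):
        values = set(base)
        for c in cutoffs:
            values.update((c - eps, c, c + eps))
        return sorted(v for v in values if v >= 0)

    densities = refine(
        [x * step for x in range(int(12 / step) + 1)], [5.0, 6.0]
    )
    percentages = refine(
        [x * 4.0 for x in range(26)], [2.0, 5.0, 7.0, 10.0, 15.0, 20.0, 33.0]
    )
    return densities, percentages
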