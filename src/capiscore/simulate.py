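"""Seedable synthetic-cohort generator with known ground-truth patterns.

Real measurement tables from clinical capillaroscopy cohorts are rarely
shareable, so the pipeline ships its own generator. Each simulated exam draws
an image count (mean 24.8, s.d. 9.9, truncated at the 8-image quality floor)
and per-image nailfold widths (mean 1.76 mm, giving ~43.7 mm per exam); an
exam-level true density is drawn from its pattern's profile and per-image
capillary counts are Poisson with mean density x width. Giant, abnormal and
tortuous counts are binomial per capillary; haemorrhage counts are Poisson
per image. The default pattern mix follows the relative frequencies of a
consensus-graded referral cohort (normal : non-specific : early : active :
late = 231 : 326 : 162 : 122 : 40).

Two presets ship with the package. ``separable`` concentrates each pattern's
feature distributions well inside that pattern's rule region, so the
classifier should recover the generating pattern almost always — the preset
for closed-loop correctness testing. ``overlapping`` pulls the means toward
the decision thresholds to produce non-trivial confusion matrices for
exercising the evaluation pipeline. Both are synthetic constructions, not
estimates of any clinical cohort's feature distributions.

Simulated raters report the true pattern, or with a configurable error
probability a uniformly chosen *adjacent* stage (normal <-> non-specific <->
early <-> active <-> late), matching the qualitative observation that expert
disagreement concentrates between neighbouring patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.stats import truncnorm

from . import io
from .errors import ValidationError
from .model import ImageMeasurement, NvcExam
from .patterns import PATTERN_ORDER, Pattern, Verdict, pattern_to_verdict

#: Consensus-cohort pattern frequencies used as the default mix
#: (normal, non_specific, ssc_early, ssc_active, ssc_late).
DEFAULT_PATTERN_COUNTS = (231, 326, 162, 122, 40)


@dataclass(frozen=True)
class PatternProfile:
    """Generating distributions for one disease pattern.

    ``density_mean``/``density_sd`` parameterize a truncated-at-zero normal
    for the exam's true capillary density (caps/mm). The three rates are
    marginal per-capillary probabilities; ``haemorrhage_rate`` is the expected
    haemorrhage count per image.
    """

    pattern: Pattern
    density_mean: float
    density_sd: float
    giant_rate: float
    abnormal_rate: float
    tortuous_rate: float
    haemorrhage_rate: float

    def __post_init__(self) -> None:
        if self.density_mean <= 0 or self.density_sd <= 0:
            raise ValidationError("density_mean and density_sd must be positive")
        for name in ("giant_rate", "abnormal_rate", "tortuous_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.haemorrhage_rate < 0:
            raise ValidationError("haemorrhage_rate must be non-negative")


def _profiles(rows) -> dict[Pattern, PatternProfile]:
    return {
        p: PatternProfile(p, dm, ds, g, a, t, h)
        for p, dm, ds, g, a, t, h in rows
    }


# Distributions concentrated inside each pattern's rule region.
SEPARABLE_PROFILES = _profiles(
    [
        # pattern,            d_mean, d_sd, giant, abnormal, tortuous, haem/img
        (Pattern.NORMAL,        9.0,  0.7,  0.00,  0.000,    0.03,     0.0),
        (Pattern.NON_SPECIFIC,  9.0,  0.7,  0.00,  0.050,    0.06,     1.0),
        (Pattern.SSC_EARLY,     8.0,  0.7,  0.03,  0.010,    0.05,     0.5),
        (Pattern.SSC_ACTIVE,    6.5,  0.5,  0.20,  0.080,    0.06,     1.0),
        (Pattern.SSC_LATE,      3.0,  0.6,  0.03,  0.250,    0.08,     0.8),
    ]
)

# Means pulled toward the thresholds: deliberate confusion between neighbours.
OVERLAPPING_PROFILES = _profiles(
    [
        (Pattern.NORMAL,        7.0,  1.0,  0.00,  0.015,    0.15,     0.05),
        (Pattern.NON_SPECIFIC,  7.5,  1.0,  0.002, 0.030,    0.18,     0.30),
        (Pattern.SSC_EARLY,     6.0,  1.0,  0.06,  0.040,    0.08,     0.40),
        (Pattern.SSC_ACTIVE,    5.2,  0.8,  0.12,  0.070,    0.08,     0.80),
        (Pattern.SSC_LATE,      4.0,  1.0,  0.05,  0.120,    0.10,     0.80),
    ]
)

PRESETS: dict[str, Mapping[Pattern, PatternProfile]] = {
    "separable": SEPARABLE_PROFILES,
    "overlapping": OVERLAPPING_PROFILES,
}


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to reproduce a simulated cohort."""

    n_exams: int
    profiles: Mapping[Pattern, PatternProfile] = field(
        default_factory=lambda: dict(SEPARABLE_PROFILES)
    )
    pattern_mix: tuple[float, float, float, float, float] = DEFAULT_PATTERN_COUNTS
    images_per_exam_mean: float = 24.8
    images_per_exam_sd: float = 9.9
    min_images: int = 8
    width_mm_mean: float = 1.76
    width_mm_sd: float = 0.3
    width_mm_min: float = 0.2
    rater_error_rate: float = 0.0
    ungradable_rate: float = 0.0
    qc_violation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exams < 1:
            raise ValidationError("n_exams must be >= 1")
        mix = tuple(float(w) for w in self.pattern_mix)
        if len(mix) != 5 or any(w < 0 for w in mix) or sum(mix) <= 0:
            raise ValidationError("pattern_mix must be five non-negative weights")
        object.__setattr__(self, "pattern_mix", mix)
        for name in ("rater_error_rate", "ungradable_rate", "qc_violation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        missing = set(PATTERN_ORDER) - set(self.profiles)
        if missing:
            raise ValidationError(f"profiles missing for {sorted(p.value for p in missing)}")

    @property
    def mix_probabilities(self) -> np.ndarray:
        weights = np.asarray(self.pattern_mix, dtype=float)
        return weights / weights.sum()

    def describe(self) -> dict:
        """Plain-data summary for provenance manifests."""
        return {
            "n_exams": self.n_exams,
            "pattern_mix": list(self.mix_probabilities),
            "images_per_exam": [self.images_per_exam_mean, self.images_per_exam_sd],
            "min_images": self.min_images,
            "width_mm": [self.width_mm_mean, self.width_mm_sd, self.width_mm_min],
            "rater_error_rate": self.rater_error_rate,
            "ungradable_rate": self.ungradable_rate,
            "qc_violation_rate": self.qc_violation_rate,
            "seed": self.seed,
            "profiles": {
                p.value: {
                    "density_mean": prof.density_mean,
                    "density_sd": prof.density_sd,
                    "giant_rate": prof.giant_rate,
                    "abnormal_rate": prof.abnormal_rate,
                    "tortuous_rate": prof.tortuous_rate,
                    "haemorrhage_rate": prof.haemorrhage_rate,
                }
                for p, prof in self.profiles.items()
            },
        }


def make_config(preset: str = "separable", **overrides) -> CohortConfig:
    """Build a cohort configuration from a named preset."""
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    overrides.setdefault("n_exams", 1000)
    return CohortConfig(profiles=dict(PRESETS[preset]), **overrides)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lower: float, size=None):
    a = (lower - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_exam(
    profile: PatternProfile,
    config: CohortConfig,
    rng: np.random.Generator,
    exam_id: str = "EX1",
    calibrated: bool = True,
    n_images: int | None = None,
) -> NvcExam:
    """Draw one exam from a pattern profile."""
    if n_images is None:
        n_images = int(
            round(
                _trunc_normal(
                    rng,
                    config.images_per_exam_mean,
                    config.images_per_exam_sd,
                    config.min_images,
                )
            )
        )
        n_images = max(n_images, config.min_images)
    density = float(_trunc_normal(rng, profile.density_mean, profile.density_sd, 0.0))
    widths = _trunc_normal(
        rng, config.width_mm_mean, config.width_mm_sd, config.width_mm_min, size=n_images
    )
    n_caps = rng.poisson(density * widths)
    images = []
    for j in range(n_images):
        n = int(n_caps[j])
        images.append(
            ImageMeasurement(
                image_id=f"{exam_id}_I{j + 1:02d}",
                n_capillaries=n,
                width_mm=float(widths[j]),
                n_giant=int(rng.binomial(n, profile.giant_rate)) if n else 0,
                n_abnormal=int(rng.binomial(n, profile.abnormal_rate)) if n else 0,
                n_tortuous=int(rng.binomial(n, profile.tortuous_rate)) if n else 0,
                n_haemorrhages=int(rng.poisson(profile.haemorrhage_rate)),
            )
        )
    return NvcExam(exam_id, calibrated, tuple(images))


def adjacent_patterns(pattern: Pattern) -> tuple[Pattern, ...]:
    """Neighbouring stages in the severity ordering."""
    i = PATTERN_ORDER.index(pattern)
    neighbours = []
    if i > 0:
        neighbours.append(PATTERN_ORDER[i - 1])
    if i < len(PATTERN_ORDER) - 1:
        neighbours.append(PATTERN_ORDER[i + 1])
    return tuple(neighbours)


def generate_verdicts(
    true_pattern: Pattern,
    rater_error_rate: float,
    rng: np.random.Generator,
    ungradable_rate: float = 0.0,
) -> tuple[Verdict, Verdict, Verdict]:
    """Three independent simulated rater verdicts for one exam.

    Each rater returns ungradable with probability ``ungradable_rate``;
    otherwise the true pattern with probability ``1 - rater_error_rate``, or
    a uniformly chosen adjacent stage.
    """
    verdicts = []
    neighbours = adjacent_patterns(true_pattern)
    for _ in range(3):
        if ungradable_rate > 0 and rng.random() < ungradable_rate:
            verdicts.append(Verdict.UNGRADABLE)
        elif rater_error_rate > 0 and rng.random() < rater_error_rate:
            verdicts.append(pattern_to_verdict(neighbours[rng.integers(len(neighbours))]))
        else:
            verdicts.append(pattern_to_verdict(true_pattern))
    return tuple(verdicts)


@dataclass(frozen=True)
class Cohort:
    """A simulated cohort: exams, rater verdicts, and the generating truth."""

    config: CohortConfig
    exams: tuple[NvcExam, ...]
    verdicts: tuple[tuple[str, tuple[Verdict, Verdict, Verdict]], ...]
    truth: dict[str, Pattern]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the three tables (images, verdicts, ground truth) as CSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "images": out_dir / "images.csv",
            "verdicts": out_dir / "verdicts.csv",
            "truth": out_dir / "truth.csv",
        }
        io.write_image_table(self.exams, paths["images"])
        io.write_verdict_table(self.verdicts, paths["verdicts"])
        io.write_gold_table(self.truth, paths["truth"])
        return paths


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    probs = config.mix_probabilities
    pattern_idx = rng.choice(len(PATTERN_ORDER), size=config.n_exams, p=probs)
    width = len(str(config.n_exams))
    exams: list[NvcExam] = []
    verdicts = []
    truth: dict[str, Pattern] = {}
    for k in range(config.n_exams):
        exam_id = f"EX{k + 1:0{width}d}"
        pattern = PATTERN_ORDER[int(pattern_idx[k])]
        calibrated = True
        n_images = None
        if config.qc_violation_rate > 0 and rng.random() < config.qc_violation_rate:
            # Alternate between the two planted violation kinds.
            if rng.random() < 0.5:
                n_images = int(rng.integers(1, config.min_images))
            else:
                calibrated = False
        exam = generate_exam(
            config.profiles[pattern], config, rng, exam_id, calibrated, n_images
        )
        exams.append(exam)
        truth[exam_id] = pattern
        verdicts.append(
            (
                exam_id,
                generate_verdicts(
                    pattern, config.rater_error_rate, rng, config.ungradable_rate
                ),
            )
        )
    return Cohort(config, tuple(exams), tuple(verdicts), truth)


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    return replace(config, seed=seed)
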