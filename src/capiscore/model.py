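"""Core measurement containers: per-image counts, exams, and exam-level features.

The pipeline starts from software-measured tables, one row per NVC image:
how many capillaries were counted, over how many millimetres of nailfold,
and how many of those capillaries were giant, abnormal (branching/bushy/
coiled) or tortuous, plus a pericapillary haemorrhage count. Counts — not
percentages — are the canonical image-level representation; percentages only
exist at exam level, after pooling, so denominators are never ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError

#: Relative tolerance for the density = total capillaries / total width identity.
DENSITY_RTOL = 1e-9


@dataclass(frozen=True)
class ImageMeasurement:
    """Software measurements for a single NVC image."""

    image_id: str
    n_capillaries: int
    width_mm: float
    n_giant: int
    n_abnormal: int
    n_tortuous: int
    n_haemorrhages: int

    def __post_init__(self) -> None:
        for name in ("n_capillaries", "n_giant", "n_abnormal", "n_tortuous", "n_haemorrhages"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool) or value < 0:
                raise ValidationError(
                    f"image '{self.image_id}': {name} must be a non-negative integer, got {value!r}"
                )
        if not self.width_mm > 0:
            raise ValidationError(
                f"image '{self.image_id}': width_mm must be positive, got {self.width_mm!r}"
            )
        for name in ("n_giant", "n_abnormal", "n_tortuous"):
            value = getattr(self, name)
            if value > self.n_capillaries:
                raise ValidationError(
                    f"image '{self.image_id}': {name}={value} exceeds "
                    f"n_capillaries={self.n_capillaries}"
                )


@dataclass(frozen=True)
class NvcExam:
    """One capillaroscopy exam: an ordered collection of image measurements."""

    exam_id: str
    calibrated: bool
    images: tuple[ImageMeasurement, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "images", tuple(self.images))
        seen: set[str] = set()
        for img in self.images:
            if img.image_id in seen:
                raise ValidationError(
                    f"exam '{self.exam_id}': duplicate image_id '{img.image_id}'"
                )
            seen.add(img.image_id)

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def total_capillaries(self) -> int:
        return sum(img.n_capillaries for img in self.images)

    @property
    def total_width_mm(self) -> float:
        # exactly-rounded sum: aggregation stays invariant under image order
        return math.fsum(img.width_mm for img in self.images)


@dataclass(frozen=True)
class FeatureVector:
    """Exam-level features consumed by the classification rules.

    ``density`` is capillaries per millimetre of imaged nailfold, pooled over
    the whole exam; the percentages share the exam-wide capillary denominator.
    """

    density: float
    pct_giant: float
    pct_abnormal: float
    pct_tortuous: float
    haemorrhages_present: bool
    total_capillaries: int
    total_width_mm: float

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValidationError(f"density must be non-negative, got {self.density!r}")
        for name in ("pct_giant", "pct_abnormal", "pct_tortuous"):
            value = getattr(self, name)
            if not (0.0 <= value <= 100.0):
                raise ValidationError(f"{name} must lie in [0, 100], got {value!r}")
        if not self.total_width_mm > 0:
            raise ValidationError(
                f"total_width_mm must be positive, got {self.total_width_mm!r}"
            )
        if self.total_capillaries < 0:
            raise ValidationError(
                f"total_capillaries must be non-negative, got {self.total_capillaries!r}"
            )
        pooled = self.total_capillaries / self.total_width_mm
        if not math.isclose(self.density, pooled, rel_tol=DENSITY_RTOL, abs_tol=1e-12):
            raise ValidationError(
                f"density {self.density!r} is inconsistent with "
                f"{self.total_capillaries}/{self.total_width_mm!r} = {pooled!r}"
            )

    @classmethod
    def from_features(
        cls,
        density: float,
        pct_giant: float = 0.0,
        pct_abnormal: float = 0.0,
        pct_tortuous: float = 0.0,
        haemorrhages_present: bool = False,
        total_capillaries: int = 1000,
    ) -> "FeatureVector":
        """Build a consistent vector from target feature values.

        Convenience constructor for sensitivity grids and tests: the totals
        are back-solved so the pooled-density identity holds exactly.
        """
        if density > 0:
            width = total_capillaries / density
        else:
            total_capillaries = 0
            width = 1.0
        return cls(
            density=density,
            pct_giant=pct_giant,
            pct_abnormal=pct_abnormal,
            pct_tortuous=pct_tortuous,
            haemorrhages_present=haemorrhages_present,
            total_capillaries=total_capillaries,
            total_width_mm=width,
        )
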