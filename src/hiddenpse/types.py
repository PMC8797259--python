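"""Domain types for multi-method population size estimation.

The containers here mirror the tabular inputs of a hotspot-based size
estimation study of a hidden population: key-informant hotspot records,
individual survey responses, capture-history cell counts, program benchmark
counts, monthly service series, and city denominators. All invariants are
enforced at construction time so that downstream estimators can assume
valid data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class InsufficientDataError(ValueError):
    """Too few usable records for the requested estimator."""


class Method(str, Enum):
    """Provenance tag of a size estimate."""

    PRIOR = "prior"
    RTM = "rtm"
    UOM = "uom"
    SM = "sm"
    CRC_LOGLINEAR = "crc_loglinear"
    CRC_DGA = "crc_dga"
    WOTC = "wotc"
    ANCHORED = "anchored"
    ANCHORED_VA = "anchored_va"
    ADJUSTED = "adjusted"
    EXTRAPOLATED = "extrapolated"


class Subgroup(str, Enum):
    MALE = "male"
    FEMALE = "female"
    TOTAL = "total"


@dataclass(frozen=True)
class HotspotRecord:
    """One congregation site: key-informant reported count and optional
    enumeration.

    ``ki_count`` is the number of people key informants report at the
    hotspot (M_i); ``enum_count`` the number actually counted on a field
    visit (N_i), present only for visited hotspots.
    """

    hotspot_id: str
    city: str
    ki_count: int
    district: str = ""
    enum_count: Optional[int] = None
    visited: bool = False
    peak_label: str = ""

    def __post_init__(self) -> None:
        if self.ki_count < 1:
            raise ValidationError(
                f"hotspot {self.hotspot_id!r}: ki_count must be >= 1, "
                f"got {self.ki_count}"
            )
        if self.enum_count is not None:
            if self.enum_count < 0:
                raise ValidationError(
                    f"hotspot {self.hotspot_id!r}: enum_count must be >= 0"
                )
            if not self.visited:
                raise ValidationError(
                    f"hotspot {self.hotspot_id!r}: enum_count present but "
                    "visited is false"
                )


@dataclass(frozen=True)
class SurveyResponse:
    """One respondent interviewed at a hotspot (the sampling cluster)."""

    city: str
    hotspot_id: str
    received_object: Optional[bool] = None
    received_service: Mapping[str, bool] = field(default_factory=dict)
    in_first_survey: Optional[bool] = None
    wotc_min: Optional[float] = None
    wotc_max: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if self.wotc_min is not None and self.wotc_min < 0:
            raise ValidationError("wotc_min must be non-negative")
        if self.wotc_max is not None and self.wotc_max < 0:
            raise ValidationError("wotc_max must be non-negative")
        if (
            self.wotc_min is not None
            and self.wotc_max is not None
            and self.wotc_min > self.wotc_max
        ):
            raise ValidationError(
                f"wotc_min ({self.wotc_min}) exceeds wotc_max ({self.wotc_max})"
            )
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")


# order used throughout: (occ1, occ2, occ3) bit patterns, occ1 most significant
VENN_PATTERNS = ("100", "010", "001", "110", "101", "011", "111")


@dataclass(frozen=True)
class VennCounts:
    """The seven observable cells of a three-occasion capture study.

    ``n100`` counts people seen on occasion 1 only, ``n110`` on occasions
    1 and 2 but not 3, and so on. The all-zero pattern is unobservable by
    construction and is what capture-recapture estimates.
    """

    n100: int
    n010: int
    n001: int
    n110: int
    n101: int
    n011: int
    n111: int

    def __post_init__(self) -> None:
        for pat in VENN_PATTERNS:
            if getattr(self, "n" + pat) < 0:
                raise ValidationError(f"cell n{pat} is negative")

    @property
    def observed_total(self) -> int:
        return sum(getattr(self, "n" + pat) for pat in VENN_PATTERNS)

    def as_dict(self) -> dict[str, int]:
        return {pat: getattr(self, "n" + pat) for pat in VENN_PATTERNS}

    def margin(self, occasion: int) -> int:
        """Total caught on one occasion (1-based)."""
        return sum(
            getattr(self, "n" + pat)
            for pat in VENN_PATTERNS
            if pat[occasion - 1] == "1"
        )

    def relabel(self, perm: Sequence[int]) -> "VennCounts":
        """Return the table with occasions permuted; ``perm`` maps new
        occasion position -> old occasion (1-based)."""
        cells = {}
        for pat in VENN_PATTERNS:
            newpat = "".join(pat[p - 1] for p in perm)
            cells["n" + newpat] = getattr(self, "n" + pat)
        return VennCounts(**cells)


@dataclass(frozen=True)
class SizeEstimate:
    """A point estimate with 95% bounds for one method, city, subgroup."""

    method: Method
    city: str
    point: float
    lower: float
    upper: float
    subgroup: Subgroup = Subgroup.MALE
    denominator: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("point", "lower", "upper"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")
        if not (self.lower <= self.point + 1e-9 and self.point <= self.upper + 1e-9):
            raise ValidationError(
                f"bounds not ordered: lower={self.lower}, point={self.point}, "
                f"upper={self.upper}"
            )
        if self.denominator is not None:
            if self.denominator <= 0:
                raise ValidationError("denominator must be positive")
            if self.point / self.denominator > 1:
                raise ValidationError(
                    "prevalence point/denominator exceeds 1"
                )

    @property
    def prevalence(self) -> Optional[float]:
        """Point prevalence as a fraction, if a denominator is known."""
        if self.denominator is None:
            return None
        return self.point / self.denominator

    def prevalence_pct(self) -> Optional[tuple[float, float, float]]:
        """(point, lower, upper) prevalence in percent, unrounded."""
        if self.denominator is None:
            return None
        d = self.denominator
        return (100 * self.point / d, 100 * self.lower / d, 100 * self.upper / d)

    def scaled(self, factor: float, method: Optional[Method] = None) -> "SizeEstimate":
        """Multiply point and bounds by a positive factor."""
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        return SizeEstimate(
            method=method or self.method,
            city=self.city,
            subgroup=self.subgroup,
            point=self.point * factor,
            lower=self.lower * factor,
            upper=self.upper * factor,
            denominator=self.denominator,
            label=self.label,
        )


@dataclass(frozen=True)
class BetaSummary:
    """Beta(alpha, beta) representation of an estimate on the prevalence
    scale; alpha+beta is the effective sample size (certainty)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValidationError("alpha and beta must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


@dataclass(frozen=True)
class CityContext:
    """Adult population denominators and extrapolation proxies for a city."""

    city: str
    adult_male_pop: int
    adult_female_pop: int
    proxies: Mapping[str, float] = field(default_factory=dict)
    is_study_city: bool = True

    def __post_init__(self) -> None:
        if self.adult_male_pop <= 0 or self.adult_female_pop <= 0:
            raise ValidationError(f"city {self.city!r}: populations must be > 0")

    @property
    def adult_total_pop(self) -> int:
        return self.adult_male_pop + self.adult_female_pop


@dataclass(frozen=True)
class MonthlySeries:
    """Monthly drop-in-center client counts with data-collection flags."""

    city: str
    counts: Sequence[float]
    collected: Sequence[bool]

    def __post_init__(self) -> None:
        if len(self.counts) != 12 or len(self.collected) != 12:
            raise ValidationError("monthly series needs exactly 12 entries")
        if any(c < 0 for c in self.counts):
            raise ValidationError("monthly counts must be non-negative")
        if not any(self.collected) or all(self.collected):
            raise ValidationError(
                "need at least one collected and one non-collected month"
            )


@dataclass(frozen=True)
class ServiceBenchmark:
    """Fixed program tally used as a multiplier numerator: unduplicated
    clients of a service, or unique objects distributed."""

    city: str
    program_id: str
    benchmark_count: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.benchmark_count < 1:
            raise ValidationError(
                f"benchmark_count must be >= 1 for {self.program_id!r}"
            )


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (presentation only)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
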