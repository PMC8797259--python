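"""Post-estimation adjustments: winter seasonality, sex-ratio splitting,
and prevalence computation.

Size estimation fieldwork conducted in winter undercounts a population
that congregates outdoors, so estimates are inflated by the ratio of
average monthly service attendance outside the collection window to the
average during it, pooled across sentinel cities. Because women were
nearly absent from hotspots, only the male population is estimated
directly; a male-to-total ratio (from key informants and
wisdom-of-the-crowds counts) converts male estimates into total and
female estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .types import (
    CityContext,
    Method,
    MonthlySeries,
    SizeEstimate,
    Subgroup,
    ValidationError,
    round_half_up,
)


@dataclass(frozen=True)
class SeasonalityFactor:
    """Per-city and pooled non-collection/collection attendance ratios."""

    per_city: dict[str, float]
    pooled: float
    applied: float

    def summary(self) -> str:
        rows = [f"  {c}: {r:.2f}" for c, r in self.per_city.items()]
        return "\n".join(
            ["Seasonality adjustment"]
            + rows
            + [f"  pooled: {self.pooled:.2f}", f"  applied: {self.applied:.2f}"]
        )


def seasonality_factor(
    series: Sequence[MonthlySeries],
    applied: Optional[float] = None,
) -> SeasonalityFactor:
    """Ratio of mean monthly attendance outside vs. during collection.

    The pooled ratio is built from counts summed across the sentinel
    cities (not the mean of city ratios) and rounded to 2 decimals for
    application; pass ``applied`` to override the factor actually
    multiplied through (e.g. a published fixed adjustment).
    """
    if not series:
        raise ValidationError("no monthly series")
    per_city = {}
    for s in series:
        coll = [c for c, f in zip(s.counts, s.collected) if f]
        non = [c for c, f in zip(s.counts, s.collected) if not f]
        if sum(coll) == 0:
            raise ZeroDivisionError(
                f"{s.city}: zero attendance during collection months"
            )
        per_city[s.city] = (sum(non) / len(non)) / (sum(coll) / len(coll))
    coll_avg, non_avg = pooled_averages(series)
    pooled = non_avg / coll_avg
    applied_factor = round(pooled, 2) if applied is None else float(applied)
    if applied_factor <= 0:
        raise ValidationError("seasonality factor must be positive")
    return SeasonalityFactor(per_city=per_city, pooled=pooled, applied=applied_factor)


def pooled_averages(series: Sequence[MonthlySeries]) -> tuple[float, float]:
    """Pooled (collected, non-collected) monthly averages: the sentinel
    cities' series are summed month by month and averaged over calendar
    months, so all series must share a collection window."""
    flags = tuple(series[0].collected)
    for s in series[1:]:
        if tuple(s.collected) != flags:
            raise ValidationError(
                "pooled averages need a common collection window"
            )
    month_totals = [sum(s.counts[i] for s in series) for i in range(12)]
    coll = [t for t, f in zip(month_totals, flags) if f]
    non = [t for t, f in zip(month_totals, flags) if not f]
    if sum(coll) == 0:
        raise ZeroDivisionError("zero pooled attendance during collection")
    return sum(coll) / len(coll), sum(non) / len(non)


def collection_averages(series: MonthlySeries) -> tuple[float, float]:
    """(collected-month mean, non-collected-month mean) for one city."""
    coll = [c for c, f in zip(series.counts, series.collected) if f]
    non = [c for c, f in zip(series.counts, series.collected) if not f]
    return sum(coll) / len(coll), sum(non) / len(non)


def apply_seasonality(
    estimate: SizeEstimate, factor: SeasonalityFactor | float
) -> SizeEstimate:
    """Scale point and both bounds by the applied factor."""
    f = factor.applied if isinstance(factor, SeasonalityFactor) else float(factor)
    if f <= 0:
        raise ValidationError("factor must be positive")
    return estimate.scaled(f, method=Method.ADJUSTED)


def split_by_sex(
    male_estimate: SizeEstimate,
    male_to_total: float,
    adult_female_pop: Optional[int] = None,
    adult_male_pop: Optional[int] = None,
) -> tuple[SizeEstimate, SizeEstimate]:
    """Derive (total, female) estimates from a male estimate.

    Dividing the male estimate by the male-to-total ratio gives the
    total; the female estimate is the componentwise difference. All
    arithmetic is unrounded; presentation-time rounding reports female
    counts as the difference of the rounded total and rounded male
    counts so that printed tables stay additive.
    """
    if not 0 < male_to_total <= 1:
        raise ValidationError("male_to_total must be in (0, 1]")
    male_pop = adult_male_pop or male_estimate.denominator
    total_denom = None
    if male_pop is not None and adult_female_pop is not None:
        total_denom = male_pop + adult_female_pop
    total = SizeEstimate(
        method=male_estimate.method,
        city=male_estimate.city,
        subgroup=Subgroup.TOTAL,
        point=male_estimate.point / male_to_total,
        lower=male_estimate.lower / male_to_total,
        upper=male_estimate.upper / male_to_total,
        denominator=total_denom,
        label=male_estimate.label,
    )
    female = SizeEstimate(
        method=male_estimate.method,
        city=male_estimate.city,
        subgroup=Subgroup.FEMALE,
        point=total.point - male_estimate.point,
        lower=total.lower - male_estimate.lower,
        upper=total.upper - male_estimate.upper,
        denominator=adult_female_pop,
        label=male_estimate.label,
    )
    return total, female


@dataclass(frozen=True)
class SexRatioRow:
    """Averaged male/female counts and the resulting ratio for a city."""

    city: str
    avg_male: int
    avg_female: int
    ratio_pct: int

    @property
    def ratio(self) -> float:
        return self.ratio_pct / 100.0


def ratio_from_methods(
    ki_counts: Mapping[str, tuple[float, float]],
    wotc_counts: Mapping[str, tuple[float, float]],
) -> tuple[list[SexRatioRow], SexRatioRow]:
    """Male-to-total ratios from two methods' (male, female) counts.

    For each city the two methods' male counts are averaged (rounded
    half up), likewise female; the ratio male/(male+female) is reported
    as a whole percent. The overall row averages the two methods'
    column totals (not the rounded city rows).
    """
    cities = list(ki_counts)
    if set(cities) != set(wotc_counts):
        raise ValidationError("both methods must cover the same cities")
    rows = []
    for city in cities:
        m = round_half_up((ki_counts[city][0] + wotc_counts[city][0]) / 2)
        f = round_half_up((ki_counts[city][1] + wotc_counts[city][1]) / 2)
        if m + f == 0:
            raise ValidationError(f"{city}: zero total count, ratio undefined")
        rows.append(
            SexRatioRow(
                city=city,
                avg_male=m,
                avg_female=f,
                ratio_pct=round_half_up(100 * m / (m + f)),
            )
        )
    tot_m = round_half_up(
        (sum(v[0] for v in ki_counts.values()) + sum(v[0] for v in wotc_counts.values())) / 2
    )
    tot_f = round_half_up(
        (sum(v[1] for v in ki_counts.values()) + sum(v[1] for v in wotc_counts.values())) / 2
    )
    if tot_m + tot_f == 0:
        raise ValidationError("zero overall count, ratio undefined")
    overall = SexRatioRow(
        city="Total",
        avg_male=tot_m,
        avg_female=tot_f,
        ratio_pct=round_half_up(100 * tot_m / (tot_m + tot_f)),
    )
    return rows, overall


def prevalence(estimate: SizeEstimate) -> tuple[float, float, float]:
    """(point, lower, upper) prevalence in percent, unrounded."""
    pct = estimate.prevalence_pct()
    if pct is None:
        raise ValidationError("estimate has no denominator")
    return pct


def prevalence_rounded(estimate: SizeEstimate) -> tuple[float, float, float]:
    """Prevalence in percent to 2 decimals (presentation)."""
    return tuple(round(v, 2) for v in prevalence(estimate))  # type: ignore[return-value]


def report_row(estimate: SizeEstimate) -> dict:
    """Presentation-time row: person counts rounded half up, prevalence
    to 2 decimals."""
    row = {
        "method": estimate.method.value,
        "city": estimate.city,
        "subgroup": estimate.subgroup.value,
        "label": estimate.label,
        "point": round_half_up(estimate.point),
        "lower": round_half_up(estimate.lower),
        "upper": round_half_up(estimate.upper),
    }
    if estimate.denominator is not None:
        pct = prevalence_rounded(estimate)
        row.update(
            denominator=estimate.denominator,
            prev_point=pct[0],
            prev_lower=pct[1],
            prev_upper=pct[2],
        )
    return row


def report_table(estimates: Sequence[SizeEstimate]) -> pd.DataFrame:
    return pd.DataFrame([report_row(e) for e in estimates])
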