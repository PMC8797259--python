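"""Wisdom-of-the-crowds size estimate.

Survey respondents guess the minimum and maximum number of population
members in their city. Each respondent's average (min+max)/2 is formed,
and the medians of the minima, averages, and maxima give the lower
bound, point estimate, and upper bound. Medians across respondents need
not be ordered, so the final triple is sorted ascending before
reporting.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .types import (
    InsufficientDataError,
    Method,
    SizeEstimate,
    SurveyResponse,
    ValidationError,
)


@dataclass(frozen=True)
class WisdomOfCrowdsResults:
    estimate: SizeEstimate
    n_respondents: int

    def summary(self) -> str:
        e = self.estimate
        return "\n".join(
            [
                "Wisdom of the crowds",
                "=" * 44,
                f"Respondents with both guesses: {self.n_respondents}",
                f"Median of averages (point):    {e.point:.0f}",
                f"Median minimum (lower):        {e.lower:.0f}",
                f"Median maximum (upper):        {e.upper:.0f}",
            ]
        )


class WisdomOfCrowds:
    """Model over respondents' (min, max) city-size guesses.

    Accepts either ``SurveyResponse`` objects or raw (min, max) pairs.
    Responses missing either bound are dropped, not imputed.
    """

    def __init__(
        self,
        responses: Iterable[SurveyResponse] | Iterable[tuple[float, float]],
        city: str = "",
    ):
        pairs: list[tuple[float, float]] = []
        for r in responses:
            if isinstance(r, SurveyResponse):
                if r.wotc_min is None or r.wotc_max is None:
                    continue
                lo, hi = r.wotc_min, r.wotc_max
            else:
                lo, hi = float(r[0]), float(r[1])
                if lo > hi:
                    raise ValidationError(f"guess min {lo} exceeds max {hi}")
            pairs.append((lo, hi))
        self.pairs = pairs
        self.city = city

    def fit(self, denominator: Optional[int] = None) -> WisdomOfCrowdsResults:
        if not self.pairs:
            raise InsufficientDataError("no responses with both guesses")
        med_min = statistics.median(p[0] for p in self.pairs)
        med_avg = statistics.median((p[0] + p[1]) / 2 for p in self.pairs)
        med_max = statistics.median(p[1] for p in self.pairs)
        lower, point, upper = sorted((med_min, med_avg, med_max))
        est = SizeEstimate(
            method=Method.WOTC,
            city=self.city,
            point=point,
            lower=lower,
            upper=upper,
            denominator=denominator,
        )
        return WisdomOfCrowdsResults(estimate=est, n_respondents=len(self.pairs))


def wotc_estimate(
    responses: Sequence[SurveyResponse] | Sequence[tuple[float, float]],
    city: str = "",
    denominator: Optional[int] = None,
) -> SizeEstimate:
    return WisdomOfCrowds(responses, city=city).fit(denominator=denominator).estimate
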