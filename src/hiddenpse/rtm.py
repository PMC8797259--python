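"""Reverse tracking method (RTM).

Key informants report an approximate head count M_i at every mapped
hotspot; a field team then visits all (or a random sample of) hotspots
and enumerates N_i people actually present. Each visited hotspot yields
a size term

    S_i = (N_i / M_i) * M,      M = sum of M_i over ALL hotspots,

i.e. the enumerated count divided by the hotspot's selection probability
M_i / M. The city estimate is the unweighted mean S = (1/n) sum S_i over
the n visited hotspots, with

    Var(S) = sum_i (S_i - S)^2 / (n (n - 1)),

the variance of a mean of n exchangeable terms. A normal 95% interval
S -/+ 1.96 sqrt(Var(S)) is floored below at the total actually counted.
Dividing S (and its bounds) by M gives correction factors that convert
every key-informant count - visited or not - into a per-hotspot size
estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .types import (
    HotspotRecord,
    InsufficientDataError,
    Method,
    SizeEstimate,
    ValidationError,
)

Z95 = 1.959963984540054


def selection_probability(ki_count: int, total_ki: int) -> float:
    """Probability that a hotspot is 'selected', M_i / M."""
    if total_ki <= 0:
        raise ValidationError("total key-informant count must be positive")
    return ki_count / total_ki


@dataclass(frozen=True)
class ReverseTrackingResults:
    """Fitted RTM quantities; ``per_hotspot`` maps every hotspot (visited
    or not) to its corrected (point, lower, upper) size."""

    S: float
    var_S: float
    lower: float
    upper: float
    M: int
    n_visited: int
    enumerated_total: int
    per_hotspot: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    city: str = ""

    @property
    def se(self) -> float:
        return math.sqrt(self.var_S)

    def correction_factors(self) -> tuple[float, float, float]:
        """(point, lower, upper) factors that scale a key-informant count
        into a size estimate."""
        return (self.S / self.M, self.lower / self.M, self.upper / self.M)

    def as_estimate(self, denominator: Optional[int] = None) -> SizeEstimate:
        return SizeEstimate(
            method=Method.RTM,
            city=self.city,
            point=self.S,
            lower=self.lower,
            upper=self.upper,
            denominator=denominator,
        )

    def summary(self) -> str:
        lines = [
            "Reverse Tracking Method",
            "=" * 44,
            f"City:                {self.city or '-'}",
            f"Hotspots visited:    {self.n_visited}",
            f"KI total (M):        {self.M}",
            f"Enumerated total:    {self.enumerated_total}",
            f"Estimate S:          {self.S:.1f}",
            f"Var(S):              {self.var_S:.1f}",
            f"95% interval:        ({self.lower:.1f}, {self.upper:.1f})",
        ]
        return "\n".join(lines)

    def per_hotspot_frame(self) -> pd.DataFrame:
        rows = [
            {"hotspot_id": hid, "point": p, "lower": lo, "upper": hi}
            for hid, (p, lo, hi) in self.per_hotspot.items()
        ]
        return pd.DataFrame(rows, columns=["hotspot_id", "point", "lower", "upper"])


class ReverseTracking:
    """RTM model over one city's hotspot records.

    Parameters
    ----------
    hotspots
        All hotspot records of the city. Unvisited hotspots contribute to
        M (the key-informant total) and receive corrected per-hotspot
        sizes, but only visited hotspots with an enumerated count enter
        the ratio terms.
    """

    def __init__(self, hotspots: Sequence[HotspotRecord], city: str = ""):
        if not hotspots:
            raise InsufficientDataError("no hotspot records")
        self.hotspots = list(hotspots)
        self.city = city or self.hotspots[0].city
        self.usable = [
            h for h in self.hotspots if h.visited and h.enum_count is not None
        ]
        for h in self.usable:
            if h.ki_count <= 0:
                raise ValidationError(
                    f"hotspot {h.hotspot_id!r}: ki_count must be positive"
                )

    def fit(self) -> ReverseTrackingResults:
        if len(self.usable) < 2:
            raise InsufficientDataError(
                f"RTM needs >= 2 visited hotspots with enumeration, "
                f"got {len(self.usable)} (variance undefined)"
            )
        M = sum(h.ki_count for h in self.hotspots)
        n = len(self.usable)
        terms = [h.enum_count / h.ki_count * M for h in self.usable]
        S = sum(terms) / n
        var_S = sum((t - S) ** 2 for t in terms) / (n * (n - 1))
        se = math.sqrt(var_S)
        enumerated = sum(h.enum_count for h in self.usable)
        lower = max(S - Z95 * se, float(enumerated))
        upper = S + Z95 * se
        # degenerate noiseless case: S may sit below the floor already
        lower = min(lower, S)
        c_pt, c_lo, c_hi = S / M, lower / M, upper / M
        per_hotspot = {
            h.hotspot_id: (c_pt * h.ki_count, c_lo * h.ki_count, c_hi * h.ki_count)
            for h in self.hotspots
        }
        return ReverseTrackingResults(
            S=S,
            var_S=var_S,
            lower=lower,
            upper=upper,
            M=M,
            n_visited=n,
            enumerated_total=enumerated,
            per_hotspot=per_hotspot,
            city=self.city,
        )


def rtm_estimate(hotspots: Sequence[HotspotRecord], city: str = "") -> ReverseTrackingResults:
    """Functional wrapper around :class:`ReverseTracking`."""
    return ReverseTracking(hotspots, city=city).fit()
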