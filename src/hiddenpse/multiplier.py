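"""Unique-object and service multiplier estimators.

A fixed benchmark count n (objects distributed, or unduplicated program
clients) is divided by the survey proportion p reporting receipt:
e = n / p. Respondents are recruited at hotspots, so p's confidence
interval accounts for cluster sampling via one-stage ratio-estimator
(Taylor linearization) variance over cluster totals. Because n is fixed,
the bounds of e are the benchmark divided by the opposite bounds of p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .types import (
    InsufficientDataError,
    Method,
    SizeEstimate,
    ValidationError,
)

Z95 = 1.959963984540054


@dataclass(frozen=True)
class ClusteredProportion:
    """A survey proportion with a design-based 95% interval."""

    p: float
    lower: float
    upper: float
    n_responses: int
    n_clusters: int
    variance: float
    degenerate: bool = False  # single cluster: no between-cluster variance


def clustered_proportion(
    responses: Iterable[tuple[str, bool]],
) -> ClusteredProportion:
    """Estimate a proportion from (cluster_id, indicator) pairs.

    Uses the ratio-estimator linearization: with cluster totals y_c
    (affirmatives) and sizes n_c, p = sum y_c / sum n_c and

        Var(p) = m/(m-1) * sum_c (y_c - p n_c)^2 / (sum_c n_c)^2

    for m clusters. Bounds are truncated to [1/N, 1] so that the
    multiplier e = n/p stays finite.
    """
    by_cluster: dict[str, list[bool]] = {}
    total = 0
    affirmative = 0
    for cid, flag in responses:
        by_cluster.setdefault(cid, []).append(bool(flag))
        total += 1
        affirmative += bool(flag)
    if total == 0:
        raise InsufficientDataError("no responses")
    p = affirmative / total
    if p == 0:
        raise ValidationError("proportion is zero; multiplier undefined")
    m = len(by_cluster)
    if m < 2:
        return ClusteredProportion(
            p=p, lower=p, upper=p, n_responses=total, n_clusters=m,
            variance=0.0, degenerate=True,
        )
    resid_sq = 0.0
    for flags in by_cluster.values():
        y_c = sum(flags)
        n_c = len(flags)
        resid_sq += (y_c - p * n_c) ** 2
    variance = m / (m - 1) * resid_sq / total**2
    se = math.sqrt(variance)
    lower = max(p - Z95 * se, 1.0 / total)
    upper = min(p + Z95 * se, 1.0)
    lower = min(lower, p)
    upper = max(upper, p)
    return ClusteredProportion(
        p=p, lower=lower, upper=upper, n_responses=total, n_clusters=m,
        variance=variance,
    )


@dataclass(frozen=True)
class MultiplierResults:
    """Fitted multiplier estimate e = benchmark / p with inverted bounds."""

    estimate: SizeEstimate
    proportion: ClusteredProportion
    benchmark_n: int
    label: str = ""
    upper_unbounded: bool = False

    def summary(self) -> str:
        pr = self.proportion
        e = self.estimate
        kind = "unique object" if e.method is Method.UOM else "service"
        upper = "unbounded" if self.upper_unbounded else f"{e.upper:.1f}"
        return "\n".join(
            [
                f"Multiplier method ({kind})",
                "=" * 44,
                f"Benchmark n:        {self.benchmark_n}",
                f"Multiplier p:       {pr.p:.4f} "
                f"(95% CI {pr.lower:.4f}-{pr.upper:.4f})",
                f"Clusters:           {pr.n_clusters} "
                f"({pr.n_responses} responses)",
                f"Size estimate e:    {e.point:.1f} "
                f"(95% CI {e.lower:.1f}-{upper})",
            ]
        )


class Multiplier:
    """Multiplier model from a fixed benchmark and clustered indicators.

    Parameters
    ----------
    benchmark_n
        The fixed external tally (no sampling variation assumed).
    responses
        (cluster_id, indicator) pairs from the hotspot survey.
    kind
        ``"uom"`` for the unique-object benchmark, ``"sm"`` for a
        service benchmark.
    """

    def __init__(
        self,
        benchmark_n: int,
        responses: Sequence[tuple[str, bool]],
        kind: str = "sm",
        city: str = "",
        label: str = "",
    ):
        if benchmark_n < 1:
            raise ValidationError("benchmark_n must be >= 1")
        if not responses:
            raise InsufficientDataError("no survey responses")
        if kind not in ("uom", "sm"):
            raise ValidationError("kind must be 'uom' or 'sm'")
        for cid, _flag in responses:
            if cid is None or cid == "":
                raise ValidationError("every response needs a cluster id")
        self.benchmark_n = int(benchmark_n)
        self.responses = list(responses)
        self.kind = kind
        self.city = city
        self.label = label

    def fit(self, denominator: Optional[int] = None) -> MultiplierResults:
        prop = clustered_proportion(self.responses)
        point = self.benchmark_n / prop.p
        lower = self.benchmark_n / prop.upper
        upper_unbounded = prop.lower <= 0
        upper = point if upper_unbounded else self.benchmark_n / prop.lower
        if denominator is not None:
            # a benchmark can exceed the admissible prevalence range only on
            # inconsistent inputs; surface it as a validation failure
            upper = min(upper, float(denominator))
            point = min(point, float(denominator))
        est = SizeEstimate(
            method=Method.UOM if self.kind == "uom" else Method.SM,
            city=self.city,
            point=point,
            lower=min(lower, point),
            upper=max(upper, point),
            denominator=denominator,
            label=self.label,
        )
        return MultiplierResults(
            estimate=est,
            proportion=prop,
            benchmark_n=self.benchmark_n,
            label=self.label,
            upper_unbounded=upper_unbounded,
        )


def multiplier_estimate(
    benchmark_n: int,
    responses: Sequence[tuple[str, bool]],
    kind: str = "sm",
    city: str = "",
    label: str = "",
    denominator: Optional[int] = None,
) -> SizeEstimate:
    """Functional wrapper: fit and return only the :class:`SizeEstimate`."""
    return Multiplier(
        benchmark_n, responses, kind=kind, city=city, label=label
    ).fit(denominator=denominator).estimate
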