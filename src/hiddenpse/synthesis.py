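"""Anchored-multiplier Bayesian synthesis of size estimates.

Every size estimate for a city is expressed as a proportion of the
denominator population and matched to a beta distribution whose mean
equals the point prevalence and whose 2.5%/97.5% quantiles come as close
as possible to the interval bounds. Narrow intervals therefore turn into
large effective sample sizes alpha+beta, and wide intervals into small
ones. Treating each source as conjugate pseudo-data, the synthesis adds
pseudo-counts onto the prior:

    alpha_post = alpha_prior + sum_i alpha_i
    beta_post  = beta_prior  + sum_i beta_i

so sources with narrower intervals pull the consensus harder. The
variance-adjusted (VA) variant first estimates between-source
heterogeneity tau^2 by the DerSimonian-Laird moment estimator on the
prevalence scale, inflates every source's variance by tau^2, refits the
betas at the wider spread, and then pools. With disagreeing sources the
VA interval is wider - the more conservative consensus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import optimize, stats

from .types import (
    BetaSummary,
    InsufficientDataError,
    Method,
    SizeEstimate,
    ValidationError,
)

log = logging.getLogger(__name__)

LOG_ESS_LO = math.log(2.0)
LOG_ESS_HI = math.log(1e9)


@dataclass(frozen=True)
class BetaFit:
    """A quantile-matched beta plus goodness of the match."""

    summary: BetaSummary
    residual: float  # sum of squared quantile errors (proportion scale)
    flagged: bool


def _quantile_residual(ess: float, mean: float, lo: float, hi: float) -> float:
    a = mean * ess
    b = (1.0 - mean) * ess
    q_lo, q_hi = stats.beta.ppf([0.025, 0.975], a, b)
    return (q_lo - lo) ** 2 + (q_hi - hi) ** 2


def fit_beta(
    point: float,
    lower: float,
    upper: float,
    denominator: int,
) -> BetaFit:
    """Match a beta distribution to (point, lower, upper) person counts.

    The mean is constrained to point/denominator; the effective sample
    size alpha+beta is found by a bounded deterministic search on the
    log scale so that the 2.5% and 97.5% quantiles best reproduce
    (lower, upper)/denominator in least squares. A one-parameter search
    cannot match two quantiles exactly when the interval's asymmetry
    differs from a beta's, so small residuals are expected; fits whose
    quantile error exceeds a quarter of the interval width are flagged
    as genuinely inconsistent.
    """
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    mean = point / denominator
    lo = lower / denominator
    hi = upper / denominator
    if not (0 < lo <= mean <= hi < 1):
        raise ValidationError(
            f"need 0 < lower <= point <= upper < denominator on the "
            f"prevalence scale, got ({lo}, {mean}, {hi})"
        )
    res = optimize.minimize_scalar(
        lambda log_ess: _quantile_residual(math.exp(log_ess), mean, lo, hi),
        bounds=(LOG_ESS_LO, LOG_ESS_HI),
        method="bounded",
        options={"xatol": 1e-10},
    )
    ess = math.exp(res.x)
    residual = float(res.fun)
    width = max(hi - lo, 1e-12)
    flagged = math.sqrt(residual / 2.0) > 0.25 * width + 1e-9
    if flagged:
        log.warning(
            "beta fit residual %.3g inconsistent with interval (%.4g, %.4g) "
            "at mean %.4g",
            residual, lo, hi, mean,
        )
    return BetaFit(
        summary=BetaSummary(alpha=mean * ess, beta=(1.0 - mean) * ess),
        residual=residual,
        flagged=flagged,
    )


def beta_from_moments(mean: float, variance: float) -> BetaSummary:
    """Beta with the requested mean and variance (effective sample size
    floored at 2 when the variance is infeasibly large)."""
    if not 0 < mean < 1:
        raise ValidationError("mean must be in (0, 1)")
    if variance <= 0:
        raise ValidationError("variance must be positive")
    ess = mean * (1.0 - mean) / variance - 1.0
    ess = max(ess, 2.0)
    return BetaSummary(alpha=mean * ess, beta=(1.0 - mean) * ess)


def dersimonian_laird_tau2(
    means: Sequence[float], variances: Sequence[float]
) -> float:
    """Method-of-moments between-source variance on the proportion scale."""
    k = len(means)
    if k != len(variances):
        raise ValidationError("means and variances must align")
    if k < 2:
        return 0.0
    w = [1.0 / v for v in variances]
    sw = sum(w)
    mu_w = sum(wi * mi for wi, mi in zip(w, means)) / sw
    q = sum(wi * (mi - mu_w) ** 2 for wi, mi in zip(w, means))
    denom = sw - sum(wi * wi for wi in w) / sw
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / denom)


def _estimate_from_beta(
    summary: BetaSummary,
    method: Method,
    city: str,
    denominator: int,
    label: str = "",
) -> SizeEstimate:
    q_lo, q_hi = stats.beta.ppf([0.025, 0.975], summary.alpha, summary.beta)
    return SizeEstimate(
        method=method,
        city=city,
        point=summary.mean * denominator,
        lower=float(q_lo) * denominator,
        upper=float(q_hi) * denominator,
        denominator=denominator,
        label=label,
    )


@dataclass(frozen=True)
class AnchoredResults:
    """Plain and variance-adjusted consensus estimates for one city."""

    anchored: SizeEstimate
    anchored_va: Optional[SizeEstimate]
    prior_beta: BetaSummary
    source_betas: tuple[BetaFit, ...]
    tau2: float
    posterior_beta: BetaSummary
    posterior_beta_va: Optional[BetaSummary]
    city: str
    denominator: int

    def summary(self) -> str:
        rows = [
            "Anchored multiplier synthesis",
            "=" * 52,
            f"City: {self.city}   denominator: {self.denominator:,}",
            f"Sources combined: {len(self.source_betas)}   tau^2: {self.tau2:.3g}",
        ]
        for tag, est in (("Anchored", self.anchored), ("Anchored-VA", self.anchored_va)):
            if est is None:
                continue
            prev = est.prevalence_pct()
            rows.append(
                f"{tag:<12} {est.point:>9,.0f} "
                f"({est.lower:,.0f}-{est.upper:,.0f})   "
                f"{prev[0]:.2f}% ({prev[1]:.2f}-{prev[2]:.2f})"
            )
        return "\n".join(rows)


class AnchoredMultiplier:
    """Synthesis model for one city and subgroup.

    Parameters
    ----------
    prior
        The anchoring estimate (e.g. an earlier survey or expert
        opinion), sharing the city and denominator of the data sources.
    estimates
        Empirical size estimates from the individual methods.
    denominator
        The adult population the proportions refer to; defaults to the
        prior's denominator.
    """

    def __init__(
        self,
        prior: SizeEstimate,
        estimates: Sequence[SizeEstimate],
        denominator: Optional[int] = None,
    ):
        denom = denominator or prior.denominator
        if denom is None:
            raise ValidationError("a denominator population is required")
        for e in list(estimates) + [prior]:
            if e.denominator is not None and e.denominator != denom:
                raise ValidationError(
                    f"estimate {e.method.value!r} has denominator "
                    f"{e.denominator}, expected {denom}"
                )
        self.prior = prior
        self.estimates = list(estimates)
        self.denominator = int(denom)
        self.city = prior.city

    def _fit_sources(self) -> tuple[BetaFit, list[BetaFit]]:
        prior_fit = fit_beta(
            self.prior.point, self.prior.lower, self.prior.upper, self.denominator
        )
        fits = [
            fit_beta(e.point, e.lower, e.upper, self.denominator)
            for e in self.estimates
        ]
        return prior_fit, fits

    def fit(self, variance_adjusted: bool = True) -> AnchoredResults:
        prior_fit, fits = self._fit_sources()
        if not fits:
            log.warning("no data estimates; returning the prior unchanged")
            prior_as_anchored = SizeEstimate(
                method=Method.ANCHORED,
                city=self.city,
                point=self.prior.point,
                lower=self.prior.lower,
                upper=self.prior.upper,
                denominator=self.denominator,
            )
            return AnchoredResults(
                anchored=prior_as_anchored,
                anchored_va=None,
                prior_beta=prior_fit.summary,
                source_betas=(),
                tau2=0.0,
                posterior_beta=prior_fit.summary,
                posterior_beta_va=None,
                city=self.city,
                denominator=self.denominator,
            )

        def pool(source_summaries: Sequence[BetaSummary]) -> BetaSummary:
            return BetaSummary(
                alpha=prior_fit.summary.alpha + sum(s.alpha for s in source_summaries),
                beta=prior_fit.summary.beta + sum(s.beta for s in source_summaries),
            )

        post = pool([f.summary for f in fits])
        anchored = _estimate_from_beta(
            post, Method.ANCHORED, self.city, self.denominator
        )

        anchored_va = None
        post_va = None
        tau2 = 0.0
        if variance_adjusted and len(fits) >= 2:
            means = [f.summary.mean for f in fits]
            variances = [f.summary.variance for f in fits]
            tau2 = dersimonian_laird_tau2(means, variances)
            if tau2 > 0:
                inflated = [
                    beta_from_moments(m, v + tau2)
                    for m, v in zip(means, variances)
                ]
                post_va = pool(inflated)
            else:
                log.info("tau^2 = 0: variance-adjusted equals unadjusted")
                post_va = post
            anchored_va = _estimate_from_beta(
                post_va, Method.ANCHORED_VA, self.city, self.denominator
            )
        return AnchoredResults(
            anchored=anchored,
            anchored_va=anchored_va,
            prior_beta=prior_fit.summary,
            source_betas=tuple(fits),
            tau2=tau2,
            posterior_beta=post,
            posterior_beta_va=post_va,
            city=self.city,
            denominator=self.denominator,
        )


def combine(
    prior: SizeEstimate,
    estimates: Sequence[SizeEstimate],
    denominator: Optional[int] = None,
) -> SizeEstimate:
    """Unadjusted anchored-multiplier consensus."""
    return AnchoredMultiplier(prior, estimates, denominator).fit(
        variance_adjusted=False
    ).anchored


def combine_variance_adjusted(
    prior: SizeEstimate,
    estimates: Sequence[SizeEstimate],
    denominator: Optional[int] = None,
) -> SizeEstimate:
    """Variance-adjusted consensus; needs at least two data estimates."""
    if len(estimates) < 2:
        raise InsufficientDataError(
            "variance adjustment needs >= 2 data estimates"
        )
    res = AnchoredMultiplier(prior, estimates, denominator).fit(
        variance_adjusted=True
    )
    assert res.anchored_va is not None
    return res.anchored_va
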