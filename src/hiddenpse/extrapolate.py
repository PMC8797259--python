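"""Small-area extrapolation of city prevalences by proxy indicators.

Male size estimates from the study cities are regressed on candidate
proxy indicators in a Poisson model with the log adult male population
as an offset, so coefficients act on the prevalence scale. An
L1-penalized (lasso) fit with the penalty chosen by leave-one-out
deviance selects the proxies; any selected proxy whose distribution in
the unobserved cities does not overlap the study cities (mean +/- 2 SD
disjoint) is dropped. Three unpenalized Poisson fits - one each for the
point, lower, and upper estimates - then predict the unobserved cities,
and totals aggregate up to a national figure by applying the urban
prevalence to the national adult population.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import (
    CityContext,
    InsufficientDataError,
    Method,
    SizeEstimate,
    Subgroup,
    ValidationError,
)

log = logging.getLogger(__name__)


def _proxy_matrix(
    cities: Sequence[CityContext], names: Sequence[str]
) -> np.ndarray:
    rows = []
    for c in cities:
        missing = [n for n in names if n not in c.proxies]
        if missing:
            raise ValidationError(f"city {c.city!r} missing proxies {missing}")
        rows.append([c.proxies[n] for n in names])
    return np.asarray(rows, dtype=float)


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def overlap_filter(
    names: Sequence[str],
    study: Sequence[CityContext],
    targets: Sequence[CityContext],
) -> list[str]:
    """Keep proxies whose mean +/- 2 SD ranges overlap between study and
    target cities; log each exclusion."""
    kept = []
    for name in names:
        s = np.array([c.proxies[name] for c in study if name in c.proxies])
        t = np.array([c.proxies[name] for c in targets if name in c.proxies])
        if len(t) == 0:
            log.warning("proxy %r absent from target cities; dropped", name)
            continue
        s_lo, s_hi = s.mean() - 2 * s.std(), s.mean() + 2 * s.std()
        t_lo, t_hi = t.mean() - 2 * t.std(), t.mean() + 2 * t.std()
        if s_hi < t_lo or t_hi < s_lo:
            log.warning(
                "proxy %r: study range (%.3g, %.3g) disjoint from target "
                "range (%.3g, %.3g); dropped",
                name, s_lo, s_hi, t_lo, t_hi,
            )
            continue
        kept.append(name)
    return kept


def select_predictors(
    study: Sequence[CityContext],
    estimates: Sequence[SizeEstimate],
    candidates: Sequence[str],
    targets: Sequence[CityContext] = (),
    alphas: Optional[Sequence[float]] = None,
) -> list[str]:
    """Lasso-Poisson predictor selection with a log-population offset.

    Candidates are standardized over the study cities; the L1 penalty is
    chosen by leave-one-out deviance over a log-spaced grid (the
    procedure is deterministic). Returns the candidates with nonzero
    coefficients at the chosen penalty, after the study/target overlap
    filter.
    """
    if len(study) < 4:
        raise InsufficientDataError("predictor selection needs >= 4 study cities")
    if len(study) != len(estimates):
        raise ValidationError("one estimate per study city required")
    X_raw = _proxy_matrix(study, candidates)
    mean, sd = X_raw.mean(axis=0), X_raw.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    X = (X_raw - mean) / sd
    y = np.array([e.point for e in estimates], dtype=float)
    offset = np.log([c.adult_male_pop for c in study])
    Xd = sm.add_constant(X, has_constant="add")
    if alphas is None:
        alphas = np.logspace(-1.5, 1.5, 7)
    # per-parameter penalty: intercept unpenalized
    best_alpha, best_dev = None, np.inf
    n = len(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a in alphas:
            pen = np.r_[0.0, np.full(X.shape[1], a)]
            dev = 0.0
            ok = True
            for i in range(n):
                mask = np.arange(n) != i
                try:
                    fit = sm.GLM(
                        y[mask], Xd[mask], family=sm.families.Poisson(),
                        offset=offset[mask],
                    ).fit_regularized(alpha=pen, L1_wt=1.0, maxiter=50)
                except Exception:
                    ok = False
                    break
                mu = np.exp(Xd[i] @ fit.params + offset[i])
                dev += _poisson_deviance(np.array([y[i]]), np.array([mu]))
            if ok and dev < best_dev:
                best_dev, best_alpha = dev, a
        if best_alpha is None:
            raise InsufficientDataError("no lasso penalty produced a usable fit")
        pen = np.r_[0.0, np.full(X.shape[1], best_alpha)]
        fit = sm.GLM(
            y, Xd, family=sm.families.Poisson(), offset=offset
        ).fit_regularized(alpha=pen, L1_wt=1.0, maxiter=100)
    coefs = np.asarray(fit.params)[1:]
    selected = [c for c, b in zip(candidates, coefs) if abs(b) > 1e-8]
    if not selected:
        log.warning("lasso shrank every candidate to zero; intercept-only model")
        return []
    if targets:
        selected = overlap_filter(selected, study, targets)
    return selected


@dataclass(frozen=True)
class ExtrapolationModel:
    """Three fitted Poisson coefficient vectors (point, lower, upper)."""

    predictor_names: tuple[str, ...]
    coef_point: np.ndarray
    coef_lower: np.ndarray
    coef_upper: np.ndarray
    offset_name: str = "log adult male population"
    standardize_mean: Optional[np.ndarray] = None
    standardize_sd: Optional[np.ndarray] = None


@dataclass(frozen=True)
class ExtrapolationResults:
    """Predictions for target cities plus aggregation helpers."""

    model: ExtrapolationModel
    predictions: tuple[SizeEstimate, ...]
    study_estimates: tuple[SizeEstimate, ...]
    excluded_targets: tuple[str, ...]

    def subtotal(self, which: str = "predictions") -> tuple[float, float, float]:
        group = self.predictions if which == "predictions" else self.study_estimates
        return (
            sum(e.point for e in group),
            sum(e.lower for e in group),
            sum(e.upper for e in group),
        )

    def combined_total(self) -> tuple[float, float, float]:
        p = self.subtotal("predictions")
        s = self.subtotal("study")
        return tuple(a + b for a, b in zip(p, s))  # type: ignore[return-value]

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "city": e.city,
                "point": e.point,
                "lower": e.lower,
                "upper": e.upper,
                "denominator": e.denominator,
            }
            for e in self.predictions
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        pt, lo, hi = self.combined_total()
        return "\n".join(
            [
                "Poisson-offset extrapolation",
                "=" * 44,
                f"Predictors: {list(self.model.predictor_names) or '(intercept only)'}",
                f"Target cities: {len(self.predictions)}",
                f"Combined urban total: {pt:,.0f} ({lo:,.0f}-{hi:,.0f})",
            ]
        )


class PoissonOffsetExtrapolator:
    """Fit point/lower/upper Poisson models on study cities and predict
    unobserved cities.

    Parameters
    ----------
    study
        (CityContext, SizeEstimate) pairs for the directly estimated
        cities; estimates must be male counts.
    predictors
        Proxy names to use (typically from :func:`select_predictors`).
    """

    def __init__(
        self,
        study: Sequence[tuple[CityContext, SizeEstimate]],
        predictors: Sequence[str] = (),
    ):
        if len(study) < 2:
            raise InsufficientDataError("need >= 2 study cities")
        self.study_cities = [c for c, _e in study]
        self.study_estimates = [e for _c, e in study]
        self.predictors = tuple(predictors)

    def _design(self, cities: Sequence[CityContext], mean, sd) -> np.ndarray:
        if not self.predictors:
            return np.ones((len(cities), 1))
        X = _proxy_matrix(cities, self.predictors)
        X = (X - mean) / sd
        return sm.add_constant(X, has_constant="add")

    def fit(self) -> ExtrapolationModel:
        if self.predictors:
            X_raw = _proxy_matrix(self.study_cities, self.predictors)
            mean, sd = X_raw.mean(axis=0), X_raw.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            mean = sd = None
        Xd = self._design(self.study_cities, mean, sd)
        offset = np.log([c.adult_male_pop for c in self.study_cities])
        coefs = {}
        for key, getter in (
            ("point", lambda e: e.point),
            ("lower", lambda e: e.lower),
            ("upper", lambda e: e.upper),
        ):
            y = np.array([getter(e) for e in self.study_estimates], dtype=float)
            res = sm.GLM(
                y, Xd, family=sm.families.Poisson(), offset=offset
            ).fit(maxiter=200)
            coefs[key] = np.asarray(res.params)
        return ExtrapolationModel(
            predictor_names=self.predictors,
            coef_point=coefs["point"],
            coef_lower=coefs["lower"],
            coef_upper=coefs["upper"],
            standardize_mean=mean,
            standardize_sd=sd,
        )

    def predict(
        self, model: ExtrapolationModel, targets: Sequence[CityContext]
    ) -> ExtrapolationResults:
        usable, excluded = [], []
        for c in targets:
            if any(p not in c.proxies for p in self.predictors):
                log.warning("target %r missing predictors; excluded", c.city)
                excluded.append(c.city)
            else:
                usable.append(c)
        preds = []
        if usable:
            Xd = self._design(usable, model.standardize_mean, model.standardize_sd)
            offset = np.log([c.adult_male_pop for c in usable])
            mu_pt = np.exp(Xd @ model.coef_point + offset)
            mu_lo = np.exp(Xd @ model.coef_lower + offset)
            mu_hi = np.exp(Xd @ model.coef_upper + offset)
            for c, pt, lo, hi in zip(usable, mu_pt, mu_lo, mu_hi):
                lo, hi = min(lo, pt), max(hi, pt)
                preds.append(
                    SizeEstimate(
                        method=Method.EXTRAPOLATED,
                        city=c.city,
                        subgroup=Subgroup.MALE,
                        point=float(pt),
                        lower=float(lo),
                        upper=float(hi),
                        denominator=c.adult_male_pop,
                    )
                )
        return ExtrapolationResults(
            model=model,
            predictions=tuple(preds),
            study_estimates=tuple(self.study_estimates),
            excluded_targets=tuple(excluded),
        )


def extrapolate(
    study: Sequence[tuple[CityContext, SizeEstimate]],
    targets: Sequence[CityContext],
    predictors: Sequence[str] = (),
) -> ExtrapolationResults:
    ex = PoissonOffsetExtrapolator(study, predictors)
    return ex.predict(ex.fit(), targets)


def national_total(
    urban_triple: tuple[float, float, float],
    urban_population: float,
    national_population: float,
) -> tuple[float, float, float]:
    """Scale an urban (point, lower, upper) total to the nation by
    applying the urban prevalence to the national adult population."""
    if urban_population <= 0 or national_population <= 0:
        raise ValidationError("populations must be positive")
    f = national_population / urban_population
    return tuple(v * f for v in urban_triple)  # type: ignore[return-value]
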