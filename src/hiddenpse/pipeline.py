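"""End-to-end orchestration: all estimators per city, Bayesian
synthesis, seasonality and sex adjustments, and the reproduction and
simulation-study profiles."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import adjust, synthesis
from .crc import DecomposableGraphCRC, LogLinearCRC, fit_loglinear
from .datasets import afghanistan2019 as ref
from .io import Dataset
from .multiplier import Multiplier
from .rtm import ReverseTracking
from .synthetic import TruthConfig, generate_city
from .types import (
    InsufficientDataError,
    Method,
    SizeEstimate,
    Subgroup,
    ValidationError,
    VennCounts,
    round_half_up,
)
from .wotc import WisdomOfCrowds

log = logging.getLogger(__name__)


def venn_from_survey(ds: Dataset, object_benchmark: int) -> VennCounts:
    """Reconstruct the three-occasion cell counts from survey tables.

    Occasion 1 is object receipt (total = the benchmark count),
    occasion 2 the first survey (rows with ``in_first_survey`` unset),
    occasion 3 the second survey (rows carrying the recapture answer).
    """
    first = [s for s in ds.surveys if s.in_first_survey is None]
    second = [s for s in ds.surveys if s.in_first_survey is not None]
    n2 = len(first)
    n3 = len(second)
    o12 = sum(1 for s in first if s.received_object)
    o13 = sum(1 for s in second if s.received_object)
    o23 = sum(1 for s in second if s.in_first_survey)
    o123 = sum(1 for s in second if s.received_object and s.in_first_survey)
    return VennCounts(
        n111=o123,
        n110=o12 - o123,
        n101=o13 - o123,
        n011=o23 - o123,
        n100=object_benchmark - o12 - o13 + o123,
        n010=n2 - o12 - o23 + o123,
        n001=n3 - o13 - o23 + o123,
    )


@dataclass
class CityRun:
    """All method estimates for one city plus skip log."""

    city: str
    estimates: list[SizeEstimate]
    skipped: dict[str, str]

    def by_method(self, method: Method) -> list[SizeEstimate]:
        return [e for e in self.estimates if e.method is method]

    def table(self) -> pd.DataFrame:
        return adjust.report_table(self.estimates)


def run_city(
    ds: Dataset,
    city: str,
    prior: Optional[SizeEstimate] = None,
    denominator: Optional[int] = None,
) -> CityRun:
    """Run every applicable estimator for one city and synthesize.

    Methods with insufficient data are skipped with a logged reason;
    synthesis requires a prior and at least two data estimates.
    """
    cds = ds.for_city(city)
    if denominator is None and cds.cities:
        denominator = cds.cities[0].adult_male_pop
    estimates: list[SizeEstimate] = []
    skipped: dict[str, str] = {}
    if prior is not None:
        estimates.append(prior)

    try:
        res = ReverseTracking(cds.hotspots, city=city).fit()
        estimates.append(res.as_estimate(denominator))
        log.info("%s rtm: n=%d S=%.1f", city, res.n_visited, res.S)
    except (InsufficientDataError, ValidationError) as exc:
        skipped["rtm"] = str(exc)

    first = [s for s in cds.surveys if s.in_first_survey is None]
    benchmarks = {s.program_id: s.benchmark_count for s in cds.services}
    obj_responses = [
        (s.hotspot_id, bool(s.received_object))
        for s in first
        if s.received_object is not None
    ]
    if "object" in benchmarks and obj_responses:
        try:
            est = Multiplier(
                benchmarks["object"], obj_responses, kind="uom", city=city,
                label="unique object",
            ).fit(denominator=denominator).estimate
            estimates.append(est)
        except (InsufficientDataError, ValidationError) as exc:
            skipped["uom"] = str(exc)
    else:
        skipped["uom"] = "no object benchmark or responses"

    for prog, n_bench in sorted(benchmarks.items()):
        if prog == "object":
            continue
        responses = [
            (s.hotspot_id, s.received_service[prog])
            for s in first
            if prog in s.received_service
        ]
        if not responses:
            skipped[f"sm:{prog}"] = "no survey responses for program"
            continue
        try:
            est = Multiplier(
                n_bench, responses, kind="sm", city=city, label=prog
            ).fit(denominator=denominator).estimate
            estimates.append(est)
        except (InsufficientDataError, ValidationError) as exc:
            skipped[f"sm:{prog}"] = str(exc)

    try:
        venn = venn_from_survey(cds, benchmarks.get("object", 0))
        suite = LogLinearCRC(venn).fit()
        best = suite.best("aic")
        estimates.append(
            SizeEstimate(
                method=Method.CRC_LOGLINEAR, city=city, point=best.N_hat,
                lower=best.ci_lower, upper=best.ci_upper,
                denominator=denominator, label=best.name,
            )
        )
        dga = DecomposableGraphCRC(venn, city=city).fit()
        estimates.append(dga.as_estimate(denominator))
        log.info("%s crc: observed=%d dga=%.0f", city, venn.observed_total, dga.mean_N)
    except (InsufficientDataError, ValidationError) as exc:
        skipped["crc"] = str(exc)

    try:
        est = WisdomOfCrowds(cds.surveys, city=city).fit(denominator=denominator).estimate
        estimates.append(est)
    except InsufficientDataError as exc:
        skipped["wotc"] = str(exc)

    data_estimates = [
        e for e in estimates
        if e.method not in (Method.PRIOR, Method.CRC_LOGLINEAR)
    ]
    if prior is not None and len(data_estimates) >= 2 and denominator is not None:
        try:
            res = synthesis.AnchoredMultiplier(
                prior, data_estimates, denominator
            ).fit(variance_adjusted=True)
            estimates.append(res.anchored)
            if res.anchored_va is not None:
                estimates.append(res.anchored_va)
        except (InsufficientDataError, ValidationError) as exc:
            skipped["anchored"] = str(exc)
    else:
        skipped["anchored"] = "prior or >= 2 data estimates missing"
    for method, reason in skipped.items():
        log.warning("%s: skipped %s (%s)", city, method, reason)
    return CityRun(city=city, estimates=estimates, skipped=skipped)


# ---------------------------------------------------------------------------
# simulation study
# ---------------------------------------------------------------------------


def _sim_estimates(cfg: TruthConfig, seed: int) -> dict[str, tuple[float, float, float]]:
    ds, truth = generate_city(replace(cfg, seed=seed))
    out: dict[str, tuple[float, float, float]] = {}
    try:
        r = ReverseTracking(ds.hotspots).fit()
        out["rtm"] = (r.S, r.lower, r.upper)
    except (InsufficientDataError, ValidationError):
        pass
    first = [s for s in ds.surveys if s.in_first_survey is None]
    try:
        m = Multiplier(
            truth.object_benchmark,
            [(s.hotspot_id, bool(s.received_object)) for s in first],
            kind="uom",
        ).fit().estimate
        out["uom"] = (m.point, m.lower, m.upper)
    except (InsufficientDataError, ValidationError):
        pass
    try:
        m = Multiplier(
            truth.service_benchmark,
            [(s.hotspot_id, s.received_service["prog1"]) for s in first],
            kind="sm",
        ).fit().estimate
        out["sm"] = (m.point, m.lower, m.upper)
    except (InsufficientDataError, ValidationError):
        pass
    try:
        f = fit_loglinear(truth.venn, ())
        if f.converged:
            out["crc_independence"] = (f.N_hat, f.ci_lower, f.ci_upper)
    except (InsufficientDataError, ValidationError):
        pass
    return out


def run_simulation_study(
    scenarios: dict[str, TruthConfig],
    n_replicates: int = 200,
    seed: int = 0,
    include_dga: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo bias/RMSE/coverage table per estimator per scenario.

    Deterministic given ``seed``: replicate r of every scenario uses
    child seed ``seed * 100_000 + r``.
    """
    rows = []
    for name, cfg in scenarios.items():
        acc: dict[str, list[tuple[float, float, float]]] = {}
        for r in range(n_replicates):
            child = (seed * 100_000 + r) % (2**31 - 1)
            ests = _sim_estimates(cfg, child)
            if include_dga:
                _, truth = generate_city(replace(cfg, seed=child))
                dga = DecomposableGraphCRC(truth.venn).fit()
                ests["crc_dga"] = (dga.mean_N, dga.ci_lower, dga.ci_upper)
            for k, v in ests.items():
                acc.setdefault(k, []).append(v)
        for est_name, triples in acc.items():
            pts = np.array([t[0] for t in triples])
            lo = np.array([t[1] for t in triples])
            hi = np.array([t[2] for t in triples])
            rel = (pts - cfg.true_N) / cfg.true_N
            rows.append(
                {
                    "scenario": name,
                    "estimator": est_name,
                    "n_replicates": len(triples),
                    "mean_rel_bias": float(rel.mean()),
                    "rmse": float(np.sqrt(((pts - cfg.true_N) ** 2).mean())),
                    "coverage": float(
                        np.mean((lo <= cfg.true_N) & (cfg.true_N <= hi))
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reproduction profile
# ---------------------------------------------------------------------------


def _va_estimate_from_published(city: str) -> SizeEstimate:
    """The published variance-adjusted consensus for a city, carried
    unrounded on the prevalence scale."""
    male_pop = ref.ADULT_POP[city][0]
    pt, lo, hi = ref.PUBLISHED_ANCHORED_VA[city]
    return SizeEstimate(
        method=Method.ANCHORED_VA,
        city=city,
        point=pt / 100 * male_pop,
        lower=lo / 100 * male_pop,
        upper=hi / 100 * male_pop,
        denominator=male_pop,
    )


def synthesize_city_from_published(city: str) -> synthesis.AnchoredResults:
    """Re-run the anchored synthesis from the published per-method rows."""
    male_pop = ref.ADULT_POP[city][0]
    rows = ref.SYNTHESIS_INPUTS[city]

    def est(label: str, triple, method: Method) -> SizeEstimate:
        pt, lo, hi = triple
        return SizeEstimate(
            method=method, city=city, label=label,
            point=pt / 100 * male_pop,
            lower=lo / 100 * male_pop,
            upper=hi / 100 * male_pop,
            denominator=male_pop,
        )

    prior = est("prior", rows["prior"], Method.PRIOR)
    method_map = {
        "rtm": Method.RTM, "uom": Method.UOM, "crc_dga": Method.CRC_DGA,
        "sm1": Method.SM, "sm2": Method.SM, "wotc": Method.WOTC,
    }
    data = [
        est(label, triple, method_map[label])
        for label, triple in rows.items()
        if label != "prior"
    ]
    return synthesis.AnchoredMultiplier(prior, data, male_pop).fit(
        variance_adjusted=True
    )


def reproduce_study() -> dict:
    """Recompute every quantity of the published analysis that the
    printed tables determine.

    Returns a nested dict: the reverse-tracking worked example, the
    seasonality averages and factors, the sex-ratio table, the pooled
    prior prevalence, the per-city adjust-and-split chains, our own
    anchored synthesis of the published method rows, and the study-city
    and national aggregates.
    """
    report: dict = {}

    ex = ref.RTM_EXAMPLE
    sel_p = ex["ki_count"] / ex["ki_total"]
    report["rtm_example"] = {
        "selection_probability": sel_p,
        "hotspot_size": ex["enum_count"] / round(sel_p, 4),
    }

    series = ref.monthly_series()
    factor = adjust.seasonality_factor(series, applied=ref.APPLIED_SEASONALITY)
    averages = {s.city: adjust.collection_averages(s) for s in series}
    coll_avg, non_avg = adjust.pooled_averages(series)
    report["seasonality"] = {
        "per_city_averages": averages,
        "pooled_collected_avg": coll_avg,
        "pooled_noncollected_avg": non_avg,
        "pooled_ratio": factor.pooled,
        "applied_factor": factor.applied,
    }

    rows, overall = adjust.ratio_from_methods(ref.KI_SEX_COUNTS, ref.WOTC_SEX_COUNTS)
    report["sex_ratio"] = {
        "per_city": {r.city: (r.avg_male, r.avg_female, r.ratio_pct) for r in rows},
        "overall": (overall.avg_male, overall.avg_female, overall.ratio_pct),
    }

    pooled = SizeEstimate(
        method=Method.PRIOR, city="Pooled",
        point=ref.PRIORS_2012_POOLED[0],
        lower=ref.PRIORS_2012_POOLED[1],
        upper=ref.PRIORS_2012_POOLED[2],
        denominator=ref.PRIORS_2012_POOLED_MALE_POP,
    )
    report["pooled_prior_prevalence_pct"] = adjust.prevalence_rounded(pooled)

    chains = {}
    male_sum = np.zeros(3)
    female_sum = np.zeros(3)
    total_sum = np.zeros(3)
    ratio = ref.GLOBAL_MALE_TO_TOTAL
    for city in ref.CITIES:
        va = _va_estimate_from_published(city)
        adjusted = adjust.apply_seasonality(va, factor)
        total, female = adjust.split_by_sex(
            adjusted, ratio,
            adult_female_pop=ref.ADULT_POP[city][1],
            adult_male_pop=ref.ADULT_POP[city][0],
        )
        male_r = round_half_up(adjusted.point)
        total_r = round_half_up(total.point)
        chains[city] = {
            "male": (male_r, round_half_up(adjusted.lower), round_half_up(adjusted.upper)),
            "total": (total_r, round_half_up(total.lower), round_half_up(total.upper)),
            # printed tables keep female = total - male after rounding
            "female": (
                total_r - male_r,
                round_half_up(total.lower) - round_half_up(adjusted.lower),
                round_half_up(total.upper) - round_half_up(adjusted.upper),
            ),
        }
        male_sum += (adjusted.point, adjusted.lower, adjusted.upper)
        total_sum += (total.point, total.lower, total.upper)
        female_sum += (
            total.point - adjusted.point,
            total.lower - adjusted.lower,
            total.upper - adjusted.upper,
        )
    report["study_city_chains"] = chains
    report["study_subtotal_male"] = tuple(male_sum)
    report["study_subtotal_female"] = tuple(female_sum)
    report["study_subtotal_total"] = tuple(total_sum)

    synth = {}
    for city in ref.CITIES:
        res = synthesize_city_from_published(city)
        row = {
            "anchored_pct": tuple(res.anchored.prevalence_pct()),
            "tau2": res.tau2,
        }
        if res.anchored_va is not None:
            row["anchored_va_pct"] = tuple(res.anchored_va.prevalence_pct())
        synth[city] = row
    report["anchored_synthesis"] = synth

    # national aggregation: published extrapolated subtotals are fixed
    # inputs (their proxy table was never published)
    from .extrapolate import national_total

    ex_m = np.array(ref.EXTRAPOLATED_MALE_SUBTOTAL, dtype=float)
    ex_f = np.array(ref.EXTRAPOLATED_FEMALE_SUBTOTAL, dtype=float)
    ex_t = np.array(ref.EXTRAPOLATED_TOTAL_SUBTOTAL, dtype=float)
    urban_m = male_sum + ex_m
    urban_f = female_sum + ex_f
    urban_t = total_sum + ex_t
    report["urban31_male"] = tuple(urban_m)
    report["national_male"] = national_total(
        tuple(urban_m), ref.URBAN_31_MALE_POP, ref.NATIONAL_ADULT_POP[0]
    )
    report["national_female"] = national_total(
        tuple(urban_f), ref.URBAN_31_FEMALE_POP, ref.NATIONAL_ADULT_POP[1]
    )
    report["national_total"] = national_total(
        tuple(urban_t),
        ref.URBAN_31_MALE_POP + ref.URBAN_31_FEMALE_POP,
        sum(ref.NATIONAL_ADULT_POP),
    )
    return report
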