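"""Seasonality, sex-ratio splitting, and prevalence arithmetic,
anchored on the published sentinel-city and ratio tables."""

import pytest

from hiddenpse import adjust
from hiddenpse.datasets import afghanistan2019 as ref
from hiddenpse.types import (
    Method,
    MonthlySeries,
    SizeEstimate,
    Subgroup,
    ValidationError,
)


def flat_series(city="c", value=100.0):
    return MonthlySeries(
        city=city,
        counts=[value] * 12,
        collected=[m < 3 for m in range(12)],
    )


def test_flat_series_factor_one():
    f = adjust.seasonality_factor([flat_series()])
    assert f.per_city["c"] == pytest.approx(1.0)
    assert f.pooled == pytest.approx(1.0)
    assert f.applied == 1.0


def test_published_sentinel_averages():
    """Monthly drop-in-center tables: Kunduz averages 477.7 collected /
    527.9 non-collected; pooled collected average 532.0."""
    series = ref.monthly_series()
    kunduz = next(s for s in series if s.city == "Kunduz")
    coll, non = adjust.collection_averages(kunduz)
    assert round(coll, 1) == 477.7
    assert round(non, 1) == 527.9
    pooled_coll, pooled_non = adjust.pooled_averages(series)
    assert round(pooled_coll, 1) == 532.0
    assert round(pooled_non, 1) == 599.1
    f = adjust.seasonality_factor(series)
    assert round(f.per_city["Kunduz"], 1) == 1.1
    assert round(f.per_city["Faizabad"], 1) == 1.3


def test_apply_seasonality_scales_linearly():
    est = SizeEstimate(Method.ANCHORED_VA, "c", point=1000, lower=700, upper=1500)
    out = adjust.apply_seasonality(est, 1.1)
    assert out.method is Method.ADJUSTED
    assert (out.point, out.lower, out.upper) == pytest.approx((1100, 770, 1650))
    same = adjust.apply_seasonality(est, 1.0)
    assert same.point == est.point


def test_split_by_sex_ratio_one():
    est = SizeEstimate(Method.ADJUSTED, "c", point=500, lower=400, upper=600,
                       denominator=10_000)
    total, female = adjust.split_by_sex(est, 1.0, adult_female_pop=9_000)
    assert total.point == 500
    assert female.point == 0
    assert total.denominator == 19_000


def test_split_by_sex_invalid_ratio():
    est = SizeEstimate(Method.ADJUSTED, "c", point=500, lower=400, upper=600)
    with pytest.raises(ValidationError):
        adjust.split_by_sex(est, 1.2)
    with pytest.raises(ValidationError):
        adjust.split_by_sex(est, 0.0)


def test_seasonality_and_split_commute():
    est = SizeEstimate(Method.ANCHORED_VA, "c", point=987.3, lower=650.1,
                       upper=1402.9, denominator=100_000)
    a_total, a_female = adjust.split_by_sex(
        adjust.apply_seasonality(est, 1.1), 0.96, adult_female_pop=90_000
    )
    b_total_pre, b_female_pre = adjust.split_by_sex(
        est, 0.96, adult_female_pop=90_000
    )
    b_total = adjust.apply_seasonality(b_total_pre, 1.1)
    b_female = adjust.apply_seasonality(b_female_pre, 1.1)
    assert a_total.point == pytest.approx(b_total.point)
    assert a_female.point == pytest.approx(b_female.point)
    assert a_female.upper == pytest.approx(b_female.upper)


def test_published_sex_ratio_rows():
    """Averaging key-informant and crowd counts: 2,900 males for the
    largest city; 96% male overall."""
    rows, overall = adjust.ratio_from_methods(ref.KI_SEX_COUNTS, ref.WOTC_SEX_COUNTS)
    by_city = {r.city: r for r in rows}
    assert by_city["Kabul"].avg_male == 2_900
    assert by_city["Kabul"].avg_female == 119
    assert by_city["Kabul"].ratio_pct == 96
    assert by_city["Herat"].avg_male == 353
    assert overall.avg_male == 4_648
    assert overall.ratio_pct == 96


def test_equal_counts_give_fifty_percent():
    rows, overall = adjust.ratio_from_methods(
        {"c": (50, 50)}, {"c": (30, 30)}
    )
    assert rows[0].ratio_pct == 50


def test_prevalence_published_pooled_row():
    """16,719 of 1,471,210 adults is 1.14%."""
    est = SizeEstimate(
        Method.PRIOR, "Pooled", point=16_719, lower=9_919, upper=32_870,
        denominator=1_471_210,
    )
    assert adjust.prevalence_rounded(est) == (1.14, 0.67, 2.23)


def test_prevalence_arithmetic(rng):
    pt = float(rng.integers(1, 5000))
    denom = int(rng.integers(10_000, 1_000_000))
    est = SizeEstimate(Method.RTM, "c", point=pt, lower=pt, upper=pt,
                       denominator=denom)
    assert adjust.prevalence(est)[0] == pytest.approx(100 * pt / denom)


def test_prevalence_requires_denominator():
    est = SizeEstimate(Method.RTM, "c", point=10, lower=5, upper=20)
    with pytest.raises(ValidationError):
        adjust.prevalence(est)


def test_split_total_prevalence_weighted_combination():
    """Total prevalence is the population-weighted mix of male and
    female prevalences."""
    est = SizeEstimate(Method.ADJUSTED, "c", point=960, lower=800, upper=1150,
                       denominator=100_000)
    total, female = adjust.split_by_sex(
        est, 0.96, adult_female_pop=80_000, adult_male_pop=100_000
    )
    p_m = est.point / 100_000
    p_f = female.point / 80_000
    weighted = (p_m * 100_000 + p_f * 80_000) / 180_000
    assert total.point / total.denominator == pytest.approx(weighted)


def test_zero_collected_average_errors():
    s = MonthlySeries("c", counts=[0, 0, 0] + [5.0] * 9,
                      collected=[True] * 3 + [False] * 9)
    with pytest.raises(ZeroDivisionError):
        adjust.seasonality_factor([s])
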