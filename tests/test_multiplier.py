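"""Multiplier estimators: clustered proportion and benchmark division."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hiddenpse.multiplier import Multiplier, clustered_proportion, multiplier_estimate
from hiddenpse.types import InsufficientDataError, ValidationError


def jackknife_variance(responses):
    """Delete-one-cluster jackknife for the overall proportion."""
    clusters = {}
    for cid, flag in responses:
        clusters.setdefault(cid, []).append(flag)
    m = len(clusters)
    reps = []
    for left_out in clusters:
        flags = [f for cid, fl in clusters.items() if cid != left_out for f in fl]
        reps.append(sum(flags) / len(flags))
    pbar = sum(reps) / m
    return (m - 1) / m * sum((r - pbar) ** 2 for r in reps)


def test_identical_clusters_zero_variance():
    responses = [(c, i < 3) for c in "abcd" for i in range(10)]
    prop = clustered_proportion(responses)
    assert prop.p == pytest.approx(0.3)
    assert prop.variance == pytest.approx(0.0)
    assert prop.lower == prop.upper == prop.p


def test_all_affirmative_boundary():
    responses = [(c, True) for c in "abc" for _ in range(5)]
    prop = clustered_proportion(responses)
    assert prop.p == 1.0
    assert prop.upper == 1.0


def test_zero_proportion_rejected():
    with pytest.raises(ValidationError):
        clustered_proportion([("a", False), ("b", False)])


def test_single_cluster_degenerate_flag():
    prop = clustered_proportion([("a", True), ("a", False)])
    assert prop.degenerate
    assert prop.lower == prop.p == prop.upper


def test_variance_close_to_jackknife(rng):
    """Linearization variance agrees with the delete-one-cluster
    jackknife within 10% on unequal clusters."""
    for trial in range(5):
        responses = []
        for c in range(10):
            size = int(rng.integers(8, 30))
            pc = rng.uniform(0.2, 0.7)
            responses += [(f"c{c}", bool(rng.random() < pc)) for _ in range(size)]
        prop = clustered_proportion(responses)
        jk = jackknife_variance(responses)
        assert prop.variance == pytest.approx(jk, rel=0.10)


def test_kabul_service_multiplier_division():
    """898 clients at a 38.3% survey proportion give about 2,345 people."""
    assert 898 / 0.383 == pytest.approx(2344.6, abs=0.1)
    # through the estimator with a single homogeneous proportion
    rng = np.random.default_rng(0)
    flags = np.zeros(1000, dtype=bool)
    flags[:383] = True
    rng.shuffle(flags)
    responses = [(f"c{i % 25}", bool(f)) for i, f in enumerate(flags)]
    est = multiplier_estimate(898, responses, kind="sm", city="Kabul")
    assert est.point == pytest.approx(2344.6, abs=0.1)


def test_full_coverage_gives_benchmark():
    responses = [(c, True) for c in "ab" for _ in range(4)]
    est = multiplier_estimate(50, responses, kind="uom")
    assert est.point == est.lower == est.upper == 50


def test_bounds_inverted():
    rng = np.random.default_rng(3)
    responses = [
        (f"c{i % 6}", bool(rng.random() < 0.4)) for i in range(120)
    ]
    res = Multiplier(100, responses, kind="sm").fit()
    prop = res.proportion
    assert res.estimate.point == pytest.approx(100 / prop.p)
    assert res.estimate.lower == pytest.approx(100 / prop.upper)
    assert res.estimate.upper == pytest.approx(100 / prop.lower)


def test_monotone_decreasing_in_p():
    base = [(f"c{i % 5}", i % 3 == 0) for i in range(90)]  # p = 1/3
    higher = [(f"c{i % 5}", i % 3 != 2) for i in range(90)]  # p = 2/3
    e1 = multiplier_estimate(60, base, kind="sm").point
    e2 = multiplier_estimate(60, higher, kind="sm").point
    assert e2 < e1


@given(seed=st.integers(0, 100))
def test_invariant_to_order_and_relabeling(seed):
    rng = np.random.default_rng(seed)
    responses = [
        (f"c{i % 4}", bool(rng.random() < 0.5)) for i in range(40)
    ]
    if not any(f for _c, f in responses):
        responses[0] = (responses[0][0], True)
    shuffled = list(responses)
    rng.shuffle(shuffled)
    relabeled = [(f"x-{cid}", f) for cid, f in shuffled]
    p1 = clustered_proportion(responses)
    p2 = clustered_proportion(relabeled)
    assert p1.p == pytest.approx(p2.p)
    assert p1.variance == pytest.approx(p2.variance)


def test_simulation_recovery_mean():
    """With service probability q and a fixed benchmark of exactly
    q x N, the estimator centres on the true size (simulation oracle)."""
    from hiddenpse.synthetic import TruthConfig, generate_city

    true_N = 1000
    cfg = TruthConfig(true_N=true_N)
    benchmark = int(cfg.service_prob * true_N)
    pts = []
    for seed in range(200):
        ds, _truth = generate_city(TruthConfig(true_N=true_N, seed=seed))
        first = [s for s in ds.surveys if s.in_first_survey is None]
        responses = [(s.hotspot_id, s.received_service["prog1"]) for s in first]
        est = multiplier_estimate(benchmark, responses, kind="sm")
        pts.append(est.point)
    mean = np.mean(pts)
    mc_se = np.std(pts, ddof=1) / np.sqrt(len(pts))
    # a ratio estimator carries O(1/n) bias ~ var(p)/p^2, here ~0.7%
    assert abs(mean - true_N) < 3 * mc_se + 0.01 * true_N


def test_empty_responses_rejected():
    with pytest.raises(InsufficientDataError):
        Multiplier(10, [], kind="sm")
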