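"""Capture-recapture: cell construction, log-linear fits vs an IPF
oracle, Lincoln-Petersen collapse, and the model-averaged posterior vs
brute-force enumeration."""

import math

import numpy as np
import pytest
from scipy.stats import dirichlet_multinomial

from hiddenpse.crc import (
    ALL_MODELS,
    DECOMPOSABLE_GRAPHS,
    DecomposableGraphCRC,
    GridTooSmallError,
    LogLinearCRC,
    fit_loglinear,
    lincoln_petersen,
    venn_from_histories,
)
from hiddenpse.types import ValidationError, VennCounts, VENN_PATTERNS

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def ipf_fitted_cells(cells: dict, pairs, tol=1e-13, max_iter=50_000) -> dict:
    """Iterative proportional fitting on the seven observed cells: an
    independently coded route to the same Poisson MLE."""
    patterns = list(cells)
    gens: list[tuple[int, ...]] = []
    covered: set[int] = set()
    for pr in sorted(pairs):
        a, b = divmod(pr, 10)
        gens.append((a - 1, b - 1))
        covered |= {a - 1, b - 1}
    for i in range(len(patterns[0])):
        if i not in covered:
            gens.append((i,))
    fitted = {p: 1.0 for p in patterns}
    for _ in range(max_iter):
        delta = 0.0
        for g in gens:
            groups: dict[tuple, list] = {}
            for p in patterns:
                groups.setdefault(tuple(p[i] for i in g), []).append(p)
            for members in groups.values():
                obs = sum(cells[p] for p in members)
                cur = sum(fitted[p] for p in members)
                if cur <= 0:
                    continue
                r = obs / cur
                for p in members:
                    new = fitted[p] * r
                    delta = max(delta, abs(new - fitted[p]))
                    fitted[p] = new
        if delta < tol:
            break
    return fitted


def brute_force_dga(venn: VennCounts, delta: float, n_max: int):
    """Posterior over N by direct summation of the same hyper-Dirichlet
    integrals, with clique terms via scipy's compound
    dirichlet-multinomial distribution."""
    cells = venn.as_dict()
    n_obs = venn.observed_total

    def log_T(lists, full, N):
        d_cell = delta * 2 ** (3 - len(lists))
        margins: dict[str, float] = {}
        for p, v in full.items():
            key = "".join(p[i - 1] for i in lists)
            margins[key] = margins.get(key, 0) + v
        x = np.array(list(margins.values()))
        alpha = np.full(len(x), d_cell)
        logpmf = dirichlet_multinomial.logpmf(x, alpha, N)
        log_mult = math.lgamma(N + 1) - sum(math.lgamma(v + 1) for v in x)
        return logpmf - log_mult

    grid = list(range(n_obs, n_max + 1))
    log_joint = np.empty((len(DECOMPOSABLE_GRAPHS), len(grid)))
    for gi, (cliques, seps) in enumerate(DECOMPOSABLE_GRAPHS.values()):
        for ni, N in enumerate(grid):
            full = dict(cells)
            full["000"] = N - n_obs
            logp = math.lgamma(N + 1) - sum(
                math.lgamma(v + 1) for v in full.values()
            )
            for cl in cliques:
                logp += log_T(cl, full, N)
            for sp in seps:
                logp -= log_T(sp, full, N)
            log_joint[gi, ni] = logp - math.log(N)
    joint = np.exp(log_joint - log_joint.max())
    post = joint.sum(axis=0)
    return np.array(grid), post / post.sum()


# ---------------------------------------------------------------------------
# cell construction
# ---------------------------------------------------------------------------


def test_venn_from_histories_counts():
    v = venn_from_histories(["111", "111", "100"])
    assert v.n111 == 2 and v.n100 == 1
    assert v.observed_total == 3
    assert venn_from_histories([]).observed_total == 0


def test_venn_rejects_unobservable_pattern():
    with pytest.raises(ValidationError):
        venn_from_histories(["111", "000"])


def test_venn_matches_generator_bookkeeping(default_city):
    _, truth = default_city
    pats = ["".join(map(str, row)) for row in truth.capture_histories]
    v = venn_from_histories([p for p in pats if p != "000"])
    assert v == truth.venn


# ---------------------------------------------------------------------------
# log-linear fits
# ---------------------------------------------------------------------------


def random_table(rng) -> VennCounts:
    cells = {f"n{p}": int(rng.integers(3, 120)) for p in VENN_PATTERNS}
    return VennCounts(**cells)


def test_fitted_cells_match_ipf_oracle(rng):
    """GLM fitted cell means equal iterative proportional fitting to
    1e-6 over random tables and all eight models."""
    models = list(ALL_MODELS)
    for trial in range(20):
        venn = random_table(rng)
        model = models[trial % len(models)]
        import statsmodels.api as sm

        from hiddenpse.crc import _design

        cells = venn.as_dict()
        patterns = list(cells)
        counts = np.array([cells[p] for p in patterns], dtype=float)
        X = _design(patterns, model)
        res = sm.GLM(counts, X, family=sm.families.Poisson()).fit(
            maxiter=500, tol=1e-12
        )
        ipf = ipf_fitted_cells(cells, model)
        fitted = dict(zip(patterns, res.fittedvalues))
        for p in patterns:
            assert abs(fitted[p] - ipf[p]) < 1e-6, (trial, model, p)


def test_independence_collapse_equals_lincoln_petersen(rng):
    """Summing out occasion 3 and fitting independence reproduces the
    closed-form two-list estimate n1 n2 / m."""
    for _ in range(5):
        v = random_table(rng)
        cells2 = {
            "10": v.n100 + v.n101,
            "01": v.n010 + v.n011,
            "11": v.n110 + v.n111,
        }
        fit = fit_loglinear(cells2, ())
        n1 = cells2["10"] + cells2["11"]
        n2 = cells2["01"] + cells2["11"]
        lp = lincoln_petersen(n1, n2, cells2["11"])
        assert fit.N_hat == pytest.approx(lp, rel=1e-8)


def test_complete_overlap_no_unobserved():
    """When everyone is caught on all three occasions there is no
    evidence of unobserved individuals: the posterior mode and median
    sit at the observed total, and near-complete overlap drives the
    log-linear prediction of the unobserved cell towards zero."""
    v = VennCounts(n100=0, n010=0, n001=0, n110=0, n101=0, n011=0, n111=50)
    dga = DecomposableGraphCRC(v).fit()
    assert dga.n_grid[int(np.argmax(dga.posterior))] == 50
    assert dga.quantile(0.5) == 50
    # the degenerate table itself is inestimable (zero margins flagged)
    assert not any(f.converged for f in LogLinearCRC(v).fit().fits)
    near = VennCounts(n100=1, n010=1, n001=1, n110=1, n101=1, n011=1, n111=50)
    f = fit_loglinear(near, ())
    assert f.converged
    assert f.unobserved < 0.2
    assert f.N_hat == pytest.approx(near.observed_total, abs=1.0)


def test_nhat_at_least_observed(rng):
    for _ in range(5):
        v = random_table(rng)
        for model in ALL_MODELS:
            f = fit_loglinear(v, model)
            if f.converged:
                assert f.N_hat >= v.observed_total - 1e-9
                assert f.ci_lower <= f.N_hat <= f.ci_upper


def test_loglinear_relabeling_invariance():
    v = VennCounts(n100=40, n010=25, n001=30, n110=12, n101=9, n011=7, n111=5)
    perm = (2, 3, 1)
    w = v.relabel(perm)
    f_v = fit_loglinear(v, ())
    f_w = fit_loglinear(w, ())
    assert f_v.N_hat == pytest.approx(f_w.N_hat, rel=1e-9)
    # a pairwise model follows the permutation: [12] on v is [13] on w
    # (occasions 1,2 of v sit at positions 3,1 of w)
    f12 = fit_loglinear(v, {12})
    f13 = fit_loglinear(w, {13})
    assert f12.N_hat == pytest.approx(f13.N_hat, rel=1e-9)


def test_aic_bic_finite_and_selection(rng):
    v = random_table(rng)
    suite = LogLinearCRC(v).fit()
    assert len(suite.fits) == 8
    best = suite.best("aic")
    assert best.converged and math.isfinite(best.aic)
    assert math.isfinite(suite.best("bic").bic)
    assert suite.table().shape[0] == 8


# ---------------------------------------------------------------------------
# decomposable-graph model average
# ---------------------------------------------------------------------------


def test_dga_matches_brute_force_enumeration():
    """Model-averaged posterior equals direct summation of the same
    integrals on a tiny table."""
    v = VennCounts(n100=4, n010=3, n001=3, n110=2, n101=1, n011=1, n111=2)
    assert v.observed_total == 16
    res = DecomposableGraphCRC(v, n_max=60).fit(auto_extend=False)
    grid, post = brute_force_dga(v, delta=2.0**-3, n_max=60)
    assert np.array_equal(res.n_grid, grid)
    assert np.max(np.abs(res.posterior - post)) < 1e-8
    assert res.mean_N == pytest.approx(float(np.sum(grid * post)), abs=1e-6)


def test_dga_posterior_properties(default_city):
    _, truth = default_city
    res = DecomposableGraphCRC(truth.venn).fit()
    assert res.posterior.sum() == pytest.approx(1.0, abs=1e-9)
    assert res.n_grid[0] == truth.venn.observed_total
    assert res.mean_N >= truth.venn.observed_total
    assert res.ci_lower <= res.mean_N <= res.ci_upper
    assert sum(res.by_model_weight.values()) == pytest.approx(1.0, abs=1e-9)


def test_dga_relabeling_invariance():
    v = VennCounts(n100=30, n010=22, n001=18, n110=10, n101=8, n011=6, n111=4)
    r1 = DecomposableGraphCRC(v, n_max=2000).fit(auto_extend=False)
    r2 = DecomposableGraphCRC(v.relabel((3, 1, 2)), n_max=2000).fit(auto_extend=False)
    assert np.max(np.abs(r1.posterior - r2.posterior)) < 1e-10
    assert r1.mean_N == pytest.approx(r2.mean_N, rel=1e-12)


def test_dga_grid_too_small_raises_and_autoextends():
    # heavy unobserved mass: tiny overlaps
    v = VennCounts(n100=40, n010=40, n001=40, n110=1, n101=1, n011=1, n111=0)
    with pytest.raises(GridTooSmallError):
        DecomposableGraphCRC(v, n_max=130).fit(auto_extend=False)
    res = DecomposableGraphCRC(v, n_max=130).fit(auto_extend=True)
    assert res.posterior[-1] <= 0.01


def test_dga_tracks_independence_loglinear():
    """Under independent lists the model-averaged mean stays within 10%
    of the independence log-linear estimate on average."""
    from hiddenpse.synthetic import TruthConfig, generate_city

    rel = []
    for seed in range(40):
        _, truth = generate_city(TruthConfig(true_N=1000, seed=seed))
        f = fit_loglinear(truth.venn, ())
        if not f.converged:
            continue
        d = DecomposableGraphCRC(truth.venn).fit()
        rel.append((d.mean_N - f.N_hat) / f.N_hat)
    assert abs(np.mean(rel)) < 0.10


def test_positive_dependence_biases_independence_downward():
    """Lists that positively depend on each other make the independence
    model under-estimate (sign test over seeds)."""
    from hiddenpse.synthetic import TruthConfig, generate_city

    below = total = 0
    for seed in range(60):
        _, truth = generate_city(
            TruthConfig(true_N=1000, pair_dependence={12: 3.0}, seed=seed)
        )
        f = fit_loglinear(truth.venn, ())
        if f.converged:
            total += 1
            below += f.N_hat < 1000
    assert below / total > 0.9
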