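"""Three-occasion capture-recapture estimation.

Two routes to the size of a closed population from three overlapping
"sightings" (lists):

* **Log-linear models.** A Poisson regression on the seven observable
  cells of the 2x2x2 capture table, with main effects for the three
  occasions and any subset of the three pairwise interaction terms
  (eight hierarchical models). The unobserved all-zero cell is predicted
  as exp(intercept) and added to the observed total. Positive dependence
  between two lists inflates their overlap and, if ignored, biases the
  estimate downward.

* **Decomposable-graph Bayesian model averaging.** Every decomposable
  graphical model on three lists (the empty graph, three single-edge,
  three two-edge, and the triangle - eight in all) receives a
  hyper-Dirichlet prior over its clique marginals; the marginal
  likelihood of the completed table is computed for every candidate
  population size N on a grid, and the models are averaged into a single
  posterior over N under a prior proportional to 1/N. The posterior mean
  is the headline estimate, with a central 95% credible interval.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln, logsumexp

from .types import (
    InsufficientDataError,
    Method,
    SizeEstimate,
    ValidationError,
    VennCounts,
    VENN_PATTERNS,
)

Z95 = 1.959963984540054

PAIRS = (12, 13, 23)
#: the eight hierarchical models: every subset of the pairwise terms
ALL_MODELS: tuple[frozenset, ...] = tuple(
    frozenset(c) for r in range(4) for c in itertools.combinations(PAIRS, r)
)


def venn_from_histories(histories: Iterable[str]) -> VennCounts:
    """Tally 3-bit capture patterns ('100' ... '111') into cell counts.

    The all-zero pattern denotes someone never observed and cannot occur
    in data; its presence raises a validation error.
    """
    cells = {pat: 0 for pat in VENN_PATTERNS}
    for h in histories:
        h = str(h)
        if h == "000":
            raise ValidationError("pattern '000' is unobservable by definition")
        if h not in cells:
            raise ValidationError(f"invalid capture pattern {h!r}")
        cells[h] += 1
    return VennCounts(**{"n" + pat: v for pat, v in cells.items()})


@dataclass(frozen=True)
class LoglinearFit:
    """One fitted log-linear capture-recapture model."""

    model_id: frozenset
    N_hat: float
    ci_lower: float
    ci_upper: float
    aic: float
    bic: float
    converged: bool
    n_observed: int
    unobserved: float = float("nan")

    @property
    def name(self) -> str:
        if not self.model_id:
            return "independence"
        return "+".join(f"[{p}]" for p in sorted(self.model_id))


def _design(patterns: Sequence[str], model_id: frozenset) -> np.ndarray:
    """Design matrix: intercept, one main effect per occasion, requested
    pairwise interactions. Works for 2- or 3-occasion patterns."""
    k = len(patterns[0])
    cols = [np.ones(len(patterns))]
    bits = np.array([[int(b) for b in pat] for pat in patterns], dtype=float)
    for j in range(k):
        cols.append(bits[:, j])
    for pair in sorted(model_id):
        a, b = divmod(pair, 10)
        cols.append(bits[:, a - 1] * bits[:, b - 1])
    return np.column_stack(cols)


def fit_loglinear(
    venn: VennCounts | Mapping[str, int],
    model_id: Iterable[int] = (),
) -> LoglinearFit:
    """Fit one Poisson log-linear model to the observed capture cells.

    ``model_id`` is a subset of {12, 13, 23} naming the pairwise
    dependence terms to include. The table may be the full 3-occasion
    Venn or any 2-occasion collapse (pattern keys of length 2), in which
    case the independence fit reduces to Lincoln-Petersen.
    """
    model_id = frozenset(model_id)
    if not model_id <= set(PAIRS):
        raise ValidationError(f"model_id must be a subset of {PAIRS}")
    if isinstance(venn, VennCounts):
        cells = venn.as_dict()
    else:
        cells = dict(venn)
    patterns = list(cells)
    counts = np.array([cells[p] for p in patterns], dtype=float)
    if counts.sum() <= 0:
        raise InsufficientDataError("all capture cells are zero")
    k = len(patterns[0])
    valid_pairs = {12, 13, 23} if k == 3 else {12}
    if not model_id <= valid_pairs:
        raise ValidationError(
            f"model {sorted(model_id)} not estimable on a {k}-occasion table"
        )
    X = _design(patterns, model_id)
    n_obs = int(counts.sum())
    converged = True
    try:
        res = sm.GLM(counts, X, family=sm.families.Poisson()).fit(maxiter=200)
        params = res.params
        cov = res.cov_params()
        if not (np.all(np.isfinite(params)) and np.all(np.isfinite(cov))):
            converged = False
    except Exception:
        converged = False
    if converged:
        # implausibly large intercept variance signals an inestimable margin
        if cov[0, 0] > 1e4 or abs(params[0]) > 30:
            converged = False
    if not converged:
        return LoglinearFit(
            model_id=model_id,
            N_hat=float("nan"),
            ci_lower=float("nan"),
            ci_upper=float("nan"),
            aic=float("nan"),
            bic=float("nan"),
            converged=False,
            n_observed=n_obs,
        )
    b0 = params[0]
    se_b0 = math.sqrt(cov[0, 0])
    n000 = math.exp(b0)  # predicted unobserved cell
    # lognormal interval on the unobserved cell (delta method on log scale)
    lo000 = math.exp(b0 - Z95 * se_b0)
    hi000 = math.exp(b0 + Z95 * se_b0)
    kparams = X.shape[1]
    llf = res.llf
    aic = -2 * llf + 2 * kparams
    bic = -2 * llf + kparams * math.log(n_obs)
    return LoglinearFit(
        model_id=model_id,
        N_hat=n_obs + n000,
        ci_lower=n_obs + lo000,
        ci_upper=n_obs + hi000,
        aic=aic,
        bic=bic,
        converged=True,
        n_observed=n_obs,
        unobserved=n000,
    )


@dataclass(frozen=True)
class LoglinearSuiteResults:
    """All eight hierarchical log-linear fits plus selections."""

    fits: tuple[LoglinearFit, ...]
    venn: VennCounts

    @property
    def independence(self) -> LoglinearFit:
        return next(f for f in self.fits if not f.model_id)

    def best(self, criterion: str = "aic") -> LoglinearFit:
        usable = [f for f in self.fits if f.converged]
        if not usable:
            raise InsufficientDataError("no log-linear model converged")
        return min(usable, key=lambda f: getattr(f, criterion))

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "model": f.name,
                "N_hat": f.N_hat,
                "ci_lower": f.ci_lower,
                "ci_upper": f.ci_upper,
                "aic": f.aic,
                "bic": f.bic,
                "converged": f.converged,
            }
            for f in self.fits
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Log-linear capture-recapture (3 occasions)",
            "=" * 50,
            f"Observed: {self.venn.observed_total}",
            self.table().to_string(index=False, float_format=lambda v: f"{v:.1f}"),
        ]
        return "\n".join(lines)


class LogLinearCRC:
    """Fit the eight hierarchical log-linear models to one Venn table."""

    def __init__(self, venn: VennCounts):
        self.venn = venn

    def fit(self) -> LoglinearSuiteResults:
        fits = tuple(fit_loglinear(self.venn, mid) for mid in ALL_MODELS)
        return LoglinearSuiteResults(fits=fits, venn=self.venn)


# ---------------------------------------------------------------------------
# Decomposable-graph Bayesian model averaging
# ---------------------------------------------------------------------------

#: the eight decomposable graphs on three vertices, as (cliques, separators)
DECOMPOSABLE_GRAPHS: dict[str, tuple[tuple[tuple[int, ...], ...], tuple[tuple[int, ...], ...]]] = {
    "empty": (((1,), (2,), (3,)), ()),
    "[12]": (((1, 2), (3,)), ()),
    "[13]": (((1, 3), (2,)), ()),
    "[23]": (((2, 3), (1,)), ()),
    "[12][13]": (((1, 2), (1, 3)), ((1,),)),
    "[12][23]": (((1, 2), (2, 3)), ((2,),)),
    "[13][23]": (((1, 3), (2, 3)), ((3,),)),
    "saturated": (((1, 2, 3),), ()),
}


def _marginal_cells(lists: tuple[int, ...]) -> list[tuple[str, tuple[str, ...]]]:
    """For a clique/separator, map each marginal cell (a bit pattern over
    its lists) to the full-table patterns that collapse onto it,
    excluding the all-zero full pattern (handled separately)."""
    out = []
    for bits in itertools.product("01", repeat=len(lists)):
        key = "".join(bits)
        members = tuple(
            pat
            for pat in VENN_PATTERNS
            if all(pat[l - 1] == b for l, b in zip(lists, bits))
        )
        out.append((key, members))
    return out


def _log_marginal_terms(
    lists: tuple[int, ...],
    cells: Mapping[str, int],
    x000: np.ndarray,
    n_grid: np.ndarray,
    delta: float,
) -> np.ndarray:
    """log T(A) over the grid for one clique or separator A:

        T(A) = Gamma(D_A)/Gamma(D_A + N) * prod_j Gamma(d_j + x_j)/Gamma(d_j)

    with per-marginal-cell prior weight d_j = delta * 2^(3-|A|) and
    D_A = sum d_j = 8 * delta. The all-zero marginal cell absorbs the
    unobserved count x000 = N - observed."""
    d_cell = delta * 2 ** (3 - len(lists))
    D = delta * 8.0
    out = gammaln(D) - gammaln(D + n_grid)
    for key, members in _marginal_cells(lists):
        base = sum(cells[p] for p in members)
        if key == "0" * len(lists):
            out = out + gammaln(d_cell + base + x000) - gammaln(d_cell)
        else:
            out = out + gammaln(d_cell + base) - gammaln(d_cell)
    return out


class GridTooSmallError(ValueError):
    """More than 1% posterior mass at the top of the N grid."""


@dataclass(frozen=True)
class DgaPosterior:
    """Model-averaged posterior over the population size N."""

    n_grid: np.ndarray
    posterior: np.ndarray
    by_model_weight: dict[str, float]
    mean_N: float
    ci_lower: float
    ci_upper: float
    observed_total: int
    city: str = ""

    def quantile(self, q: float) -> float:
        cdf = np.cumsum(self.posterior)
        return float(self.n_grid[int(np.searchsorted(cdf, q))])

    def as_estimate(self, denominator: Optional[int] = None) -> SizeEstimate:
        return SizeEstimate(
            method=Method.CRC_DGA,
            city=self.city,
            point=self.mean_N,
            lower=self.ci_lower,
            upper=self.ci_upper,
            denominator=denominator,
        )

    def summary(self) -> str:
        weights = ", ".join(
            f"{k}: {v:.3f}" for k, v in sorted(
                self.by_model_weight.items(), key=lambda kv: -kv[1]
            )[:3]
        )
        return "\n".join(
            [
                "Capture-recapture: decomposable-graph model average",
                "=" * 52,
                f"Observed:         {self.observed_total}",
                f"Posterior mean N: {self.mean_N:.1f}",
                f"95% CrI:          ({self.ci_lower:.0f}, {self.ci_upper:.0f})",
                f"Top models:       {weights}",
            ]
        )


class DecomposableGraphCRC:
    """Bayesian model averaging over decomposable list-dependence graphs.

    Parameters
    ----------
    venn
        The observed three-occasion cell counts.
    prior_delta
        Hyper-Dirichlet prior weight per full-table cell (default 1/8).
    n_max
        Upper end of the N grid; defaults to 20x the observed total and
        is doubled automatically while >1% of posterior mass sits at the
        top of the grid.
    """

    def __init__(
        self,
        venn: VennCounts,
        prior_delta: float = 2.0**-3,
        n_max: Optional[int] = None,
        city: str = "",
    ):
        if prior_delta <= 0:
            raise ValidationError("prior_delta must be positive")
        if venn.observed_total < 1:
            raise InsufficientDataError("empty capture table")
        self.venn = venn
        self.prior_delta = prior_delta
        self.n_max = n_max
        self.city = city

    def _posterior_once(self, n_max: int):
        n_obs = self.venn.observed_total
        if n_max < n_obs:
            raise ValidationError("n_max below the observed total")
        cells = self.venn.as_dict()
        n_grid = np.arange(n_obs, n_max + 1, dtype=float)
        x000 = n_grid - n_obs
        # multinomial coefficient of the completed table
        log_coef = (
            gammaln(n_grid + 1)
            - sum(gammaln(c + 1) for c in cells.values())
            - gammaln(x000 + 1)
        )
        log_prior_n = -np.log(np.maximum(n_grid, 1.0))  # p(N) propto 1/N
        per_model = {}
        for name, (cliques, seps) in DECOMPOSABLE_GRAPHS.items():
            lm = log_coef.copy()
            for cl in cliques:
                lm += _log_marginal_terms(cl, cells, x000, n_grid, self.prior_delta)
            for sp in seps:
                lm -= _log_marginal_terms(sp, cells, x000, n_grid, self.prior_delta)
            per_model[name] = lm
        stacked = np.vstack([per_model[name] for name in DECOMPOSABLE_GRAPHS])
        # uniform prior over the eight graphs
        log_joint = stacked + log_prior_n[None, :]
        log_norm = logsumexp(log_joint)
        posterior = np.exp(logsumexp(log_joint, axis=0) - log_norm)
        model_weights = {
            name: float(np.exp(logsumexp(log_joint[i]) - log_norm))
            for i, name in enumerate(DECOMPOSABLE_GRAPHS)
        }
        return n_grid, posterior, model_weights

    def fit(self, auto_extend: bool = True, max_doublings: int = 8) -> DgaPosterior:
        n_obs = self.venn.observed_total
        n_max = self.n_max if self.n_max is not None else max(20 * n_obs, n_obs + 10)
        for _ in range(max_doublings + 1):
            n_grid, posterior, weights = self._posterior_once(n_max)
            if posterior[-1] <= 0.01:
                break
            if not auto_extend:
                raise GridTooSmallError(
                    f"posterior mass {posterior[-1]:.3f} at n_max={n_max}; "
                    "increase n_max"
                )
            n_max *= 2
        else:
            raise GridTooSmallError(f"posterior never contained below n_max={n_max}")
        posterior = posterior / posterior.sum()
        mean_N = float(np.sum(n_grid * posterior))
        cdf = np.cumsum(posterior)
        ci_lower = float(n_grid[int(np.searchsorted(cdf, 0.025))])
        ci_upper = float(n_grid[int(np.searchsorted(cdf, 0.975))])
        return DgaPosterior(
            n_grid=n_grid,
            posterior=posterior,
            by_model_weight=weights,
            mean_N=mean_N,
            ci_lower=ci_lower,
            ci_upper=ci_upper,
            observed_total=n_obs,
            city=self.city,
        )


def dga_average(
    venn: VennCounts,
    prior_delta: float = 2.0**-3,
    n_max: Optional[int] = None,
    auto_extend: bool = True,
) -> DgaPosterior:
    """Functional wrapper around :class:`DecomposableGraphCRC`."""
    return DecomposableGraphCRC(venn, prior_delta=prior_delta, n_max=n_max).fit(
        auto_extend=auto_extend
    )


def lincoln_petersen(n1: int, n2: int, m: int) -> float:
    """Closed-form two-list estimate N = n1 n2 / m (m = overlap)."""
    if m <= 0:
        raise InsufficientDataError("no overlap between the two lists")
    return n1 * n2 / m
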