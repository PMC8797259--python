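"""Synthetic cities with known truth for estimator validation.

The generator emulates the data a hotspot-based size-estimation study
collects, with every latent quantity recorded so that recovery and
coverage can be checked exactly:

* a true population of ``true_N`` people allocated to hotspots by a
  symmetric Dirichlet-multinomial (small concentration = a few dominant
  hotspots);
* key-informant counts: the hotspot size perturbed by lognormal noise,
  floored at 1;
* field enumeration: a binomial thinning of the hotspot size by the
  attendance probability, for visited hotspots;
* three capture occasions (object receipt, first survey, second survey)
  drawn from an 8-cell joint distribution with the requested marginals,
  optionally tilted by pairwise odds multipliers to inject list
  dependence;
* service receipt and object receipt kept consistent between program
  benchmark counts and survey answers;
* wisdom-of-the-crowds guesses lognormal around ``wotc_bias * true_N``;
* a seasonal monthly attendance series peaking in July.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import Dataset
from .types import (
    CityContext,
    HotspotRecord,
    MonthlySeries,
    ServiceBenchmark,
    SurveyResponse,
    ValidationError,
    VennCounts,
    VENN_PATTERNS,
)

_PAIR_KEYS = {12: (0, 1), 13: (0, 2), 23: (1, 2)}


@dataclass(frozen=True)
class TruthConfig:
    """Study conditions for one synthetic city.

    Defaults describe a mid-sized city under the assumptions the
    estimators make: noisy but unbiased-on-the-log-scale key-informant
    counts, full peak-time attendance, independent capture occasions,
    and unbiased crowd guesses.
    """

    true_N: int = 1000
    n_hotspots: int = 15
    hotspot_concentration: float = 2.0
    ki_noise_sd: float = 0.15
    attendance_prob: float = 1.0
    visit_fraction: float = 1.0
    capture_probs: tuple[float, float, float] = (0.3, 0.3, 0.3)
    pair_dependence: Mapping[int, float] = field(default_factory=dict)
    service_prob: float = 0.35
    object_coverage: Optional[float] = None  # None: alias capture occasion 1
    wotc_bias: float = 1.0
    wotc_sd: float = 0.4
    wotc_spread: float = 0.25
    seasonal_amplitude: float = 0.1
    seasonal_peak_month: int = 7
    monthly_base: Optional[float] = None  # None: 0.5 * true_N
    collection_months: tuple[int, ...] = (1, 2, 3)
    male_to_total: float = 0.96
    adult_male_pop: Optional[int] = None  # None: 100 * true_N
    adult_female_pop: Optional[int] = None
    city: str = "simtown"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = list(self.capture_probs) + [
            self.attendance_prob,
            self.visit_fraction,
            self.service_prob,
            self.male_to_total,
        ]
        if self.object_coverage is not None:
            probs.append(self.object_coverage)
        for p in probs:
            if not 0 <= p <= 1:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.true_N < self.n_hotspots:
            raise ValidationError("true_N must be >= n_hotspots")
        if not 0 <= self.seasonal_amplitude < 1:
            raise ValidationError("seasonal_amplitude must be in [0, 1)")
        if any(t <= 0 for t in dict(self.pair_dependence).values()):
            raise ValidationError("odds multipliers must be positive")
        if self.ki_noise_sd < 0 or self.wotc_sd < 0 or self.wotc_bias <= 0:
            raise ValidationError("invalid noise configuration")


@dataclass
class Truth:
    """Latent state of a generated city, for oracle checks."""

    config: TruthConfig
    hotspot_sizes: np.ndarray
    capture_histories: np.ndarray  # (true_N, 3) 0/1
    venn: VennCounts
    object_benchmark: int
    service_benchmark: int
    n_male: int
    n_female: int

    def as_dict(self) -> dict:
        return {
            "true_N": self.config.true_N,
            "hotspot_sizes": self.hotspot_sizes.tolist(),
            "venn": self.venn.as_dict(),
            "object_benchmark": self.object_benchmark,
            "service_benchmark": self.service_benchmark,
            "n_male": self.n_male,
            "n_female": self.n_female,
        }


def capture_cell_probs(
    marginals: Sequence[float], dependence: Mapping[int, float]
) -> np.ndarray:
    """Joint probabilities of the 8 capture patterns (order: 000 then
    :data:`~hiddenpse.types.VENN_PATTERNS`), built from independent
    marginals and tilted by per-pair odds multipliers, renormalized."""
    pats = ["000"] + list(VENN_PATTERNS)
    probs = np.empty(8)
    for i, pat in enumerate(pats):
        p = 1.0
        for j, b in enumerate(pat):
            p *= marginals[j] if b == "1" else 1 - marginals[j]
        for pair, theta in dict(dependence).items():
            a, b = _PAIR_KEYS[int(pair)]
            if pat[a] == "1" and pat[b] == "1":
                p *= float(theta)
        probs[i] = p
    total = probs.sum()
    if total <= 0:
        raise ValidationError("degenerate capture configuration")
    return probs / total


def generate_city(cfg: TruthConfig) -> tuple[Dataset, Truth]:
    """Draw one fully reproducible synthetic city."""
    rng = np.random.default_rng(cfg.seed)
    N = cfg.true_N
    k = cfg.n_hotspots

    weights = rng.dirichlet(np.full(k, cfg.hotspot_concentration))
    sizes = rng.multinomial(N, weights)
    # guarantee every hotspot is non-empty (ki_count >= 1 required)
    for i in np.flatnonzero(sizes == 0):
        donor = int(np.argmax(sizes))
        sizes[i] += 1
        sizes[donor] -= 1
    hotspot_of = np.repeat(np.arange(k), sizes)

    noise = rng.normal(0.0, cfg.ki_noise_sd, size=k) if cfg.ki_noise_sd > 0 else np.zeros(k)
    ki_counts = np.maximum(1, np.rint(sizes * np.exp(noise)).astype(int))

    n_visited = max(2, int(round(cfg.visit_fraction * k)))
    visited_idx = np.sort(rng.choice(k, size=min(n_visited, k), replace=False))
    visited = np.zeros(k, dtype=bool)
    visited[visited_idx] = True
    enum_counts = np.where(
        visited, rng.binomial(sizes, cfg.attendance_prob), -1
    )

    marginals = list(cfg.capture_probs)
    if cfg.object_coverage is not None:
        marginals[0] = cfg.object_coverage
    cell_p = capture_cell_probs(marginals, cfg.pair_dependence)
    pats = ["000"] + list(VENN_PATTERNS)
    cells = rng.choice(8, size=N, p=cell_p)
    bits = np.array([[int(b) for b in pat] for pat in pats])
    histories = bits[cells]  # (N, 3)

    observed = cells > 0
    venn_counts = {
        "n" + pat: int(np.sum(cells == i + 1)) for i, pat in enumerate(VENN_PATTERNS)
    }
    venn = VennCounts(**venn_counts)

    service = rng.random(N) < cfg.service_prob
    male = rng.random(N) < cfg.male_to_total
    object_benchmark = int(histories[:, 0].sum())
    service_benchmark = int(service.sum())

    hotspots = [
        HotspotRecord(
            hotspot_id=f"h{i:03d}",
            city=cfg.city,
            district=f"d{i % 5}",
            ki_count=int(ki_counts[i]),
            enum_count=int(enum_counts[i]) if visited[i] else None,
            visited=bool(visited[i]),
        )
        for i in range(k)
    ]

    surveys: list[SurveyResponse] = []
    first = np.flatnonzero(histories[:, 1] == 1)
    centers = cfg.wotc_bias * N * np.exp(rng.normal(0.0, cfg.wotc_sd, size=first.size))
    for j, idx in enumerate(first):
        c = centers[j]
        surveys.append(
            SurveyResponse(
                city=cfg.city,
                hotspot_id=f"h{hotspot_of[idx]:03d}",
                received_object=bool(histories[idx, 0]),
                received_service={"prog1": bool(service[idx])},
                wotc_min=float(c * math.exp(-cfg.wotc_spread)),
                wotc_max=float(c * math.exp(cfg.wotc_spread)),
                sex="male" if male[idx] else "female",
            )
        )
    second = np.flatnonzero(histories[:, 2] == 1)
    for idx in second:
        surveys.append(
            SurveyResponse(
                city=cfg.city,
                hotspot_id=f"h{hotspot_of[idx]:03d}",
                received_object=bool(histories[idx, 0]),
                in_first_survey=bool(histories[idx, 1]),
                sex="male" if male[idx] else "female",
            )
        )

    services = [
        ServiceBenchmark(
            city=cfg.city, program_id="object",
            benchmark_count=max(object_benchmark, 1),
            description="unique objects distributed",
        ),
        ServiceBenchmark(
            city=cfg.city, program_id="prog1",
            benchmark_count=max(service_benchmark, 1),
            description="program clients",
        ),
    ]

    base = cfg.monthly_base if cfg.monthly_base is not None else 0.5 * N
    months = np.arange(1, 13)
    series = base * (
        1.0
        + cfg.seasonal_amplitude
        * np.cos(2 * np.pi * (months - cfg.seasonal_peak_month) / 12.0)
    )
    monthly = [
        MonthlySeries(
            city=cfg.city,
            counts=[float(v) for v in np.round(series, 1)],
            collected=[m in cfg.collection_months for m in months],
        )
    ]

    male_pop = cfg.adult_male_pop or 100 * N
    female_pop = cfg.adult_female_pop or int(0.95 * male_pop)
    cities = [
        CityContext(
            city=cfg.city,
            adult_male_pop=male_pop,
            adult_female_pop=female_pop,
            is_study_city=True,
        )
    ]

    ds = Dataset(
        hotspots=hotspots, surveys=surveys, services=services,
        monthly=monthly, cities=cities,
    )
    truth = Truth(
        config=cfg,
        hotspot_sizes=sizes,
        capture_histories=histories,
        venn=venn,
        object_benchmark=object_benchmark,
        service_benchmark=service_benchmark,
        n_male=int(male.sum()),
        n_female=int(N - male.sum()),
    )
    return ds, truth


def generate_extrapolation_scenario(
    n_study: int = 8,
    n_targets: int = 10,
    true_coef: float = 0.4,
    n_noise_proxies: int = 5,
    base_prevalence: float = 0.008,
    seed: int = 0,
) -> tuple[list[CityContext], list, list[CityContext]]:
    """City contexts plus male size estimates generated from one true
    proxy ('signal') among standard-normal noise proxies, for testing
    predictor selection and extrapolation recovery.

    Returns (study_cities, study_estimates, target_cities); the true
    expected count in every city is
    ``base_prevalence * exp(true_coef * signal) * male_pop``.
    """
    from .types import Method, SizeEstimate, Subgroup

    rng = np.random.default_rng(seed)
    names = ["signal"] + [f"noise{i}" for i in range(n_noise_proxies)]

    def make_city(tag: str, i: int, is_study: bool) -> CityContext:
        proxies = {n: float(rng.normal()) for n in names}
        pop = int(rng.integers(30_000, 300_000))
        return CityContext(
            city=f"{tag}{i}",
            adult_male_pop=pop,
            adult_female_pop=int(0.95 * pop),
            proxies=proxies,
            is_study_city=is_study,
        )

    study = [make_city("study", i, True) for i in range(n_study)]
    targets = [make_city("target", i, False) for i in range(n_targets)]
    estimates = []
    for c in study:
        mu = base_prevalence * math.exp(true_coef * c.proxies["signal"]) * c.adult_male_pop
        y = rng.poisson(mu)
        y = max(y, 1)
        se = math.sqrt(y)
        estimates.append(
            SizeEstimate(
                method=Method.RTM,
                city=c.city,
                subgroup=Subgroup.MALE,
                point=float(y),
                lower=float(max(y - 1.96 * se, 1.0)),
                upper=float(y + 1.96 * se),
                denominator=c.adult_male_pop,
            )
        )
    return study, estimates, targets


def replicate(cfg: TruthConfig, seed: int) -> tuple[Dataset, Truth]:
    """The same study conditions under a different random seed."""
    return generate_city(replace(cfg, seed=seed))
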