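"""Readers and writers for the study's tabular formats.

All files are comma-separated UTF-8 with a header row; booleans are
written as ``true``/``false`` and absent values as empty fields. Reading
enforces every domain invariant and names the offending row on failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import (
    CityContext,
    HotspotRecord,
    Method,
    MonthlySeries,
    ServiceBenchmark,
    SizeEstimate,
    Subgroup,
    SurveyResponse,
    ValidationError,
)

log = logging.getLogger(__name__)

HOTSPOT_COLUMNS = ["hotspot_id", "city", "district", "ki_count", "enum_count", "visited"]
SURVEY_BASE_COLUMNS = [
    "city",
    "hotspot_id",
    "received_object",
    "in_first_survey",
    "wotc_min",
    "wotc_max",
    "sex",
]
SERVICE_COLUMNS = ["city", "program_id", "benchmark_count", "description"]
CITY_BASE_COLUMNS = ["city", "adult_male_pop", "adult_female_pop", "is_study_city"]
ESTIMATE_COLUMNS = [
    "method",
    "city",
    "subgroup",
    "label",
    "point",
    "lower",
    "upper",
    "denominator",
    "prevalence_pct",
]


class SchemaError(ValueError):
    """A required column is missing from an input file."""


@dataclass
class Dataset:
    """Everything one city-level analysis needs, already validated."""

    hotspots: list[HotspotRecord] = field(default_factory=list)
    surveys: list[SurveyResponse] = field(default_factory=list)
    services: list[ServiceBenchmark] = field(default_factory=list)
    monthly: list[MonthlySeries] = field(default_factory=list)
    cities: list[CityContext] = field(default_factory=list)

    def for_city(self, city: str) -> "Dataset":
        return Dataset(
            hotspots=[h for h in self.hotspots if h.city == city],
            surveys=[s for s in self.surveys if s.city == city],
            services=[s for s in self.services if s.city == city],
            monthly=[m for m in self.monthly if m.city == city],
            cities=[c for c in self.cities if c.city == city],
        )


def _require(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _as_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot parse boolean from {value!r}")


def _as_opt_float(value) -> Optional[float]:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def _as_opt_int(value) -> Optional[int]:
    f = _as_opt_float(value)
    return None if f is None else int(round(f))


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])


def read_hotspots(path) -> list[HotspotRecord]:
    df = _read_csv(path)
    _require(df, HOTSPOT_COLUMNS[:4] + ["visited"], path)
    records = []
    seen: dict[tuple[str, str], int] = {}
    for idx, row in df.iterrows():
        try:
            rec = HotspotRecord(
                hotspot_id=str(row["hotspot_id"]),
                city=str(row["city"]),
                district=str(row.get("district") or ""),
                ki_count=int(float(row["ki_count"])),
                enum_count=_as_opt_int(row.get("enum_count")),
                visited=bool(_as_bool(row.get("visited"))),
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"{path} row {idx + 2}: {exc}") from exc
        key = (rec.city, rec.hotspot_id)
        if key in seen:
            raise ValidationError(
                f"{path} row {idx + 2}: duplicate hotspot_id {rec.hotspot_id!r} "
                f"within city {rec.city!r}"
            )
        seen[key] = idx
        records.append(rec)
    if not records:
        log.warning("%s: no hotspot rows", path)
    return records


def read_surveys(path) -> list[SurveyResponse]:
    df = _read_csv(path)
    _require(df, ["city", "hotspot_id"], path)
    service_cols = [c for c in df.columns if c.startswith("service_")]
    records = []
    for idx, row in df.iterrows():
        try:
            services = {}
            for col in service_cols:
                v = _as_bool(row.get(col))
                if v is not None:
                    services[col[len("service_"):]] = v
            sex = row.get("sex")
            rec = SurveyResponse(
                city=str(row["city"]),
                hotspot_id=str(row["hotspot_id"]),
                received_object=_as_bool(row.get("received_object")),
                received_service=services,
                in_first_survey=_as_bool(row.get("in_first_survey")),
                wotc_min=_as_opt_float(row.get("wotc_min")),
                wotc_max=_as_opt_float(row.get("wotc_max")),
                sex=None if (sex is None or pd.isna(sex) or sex == "") else str(sex),
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"{path} row {idx + 2}: {exc}") from exc
        records.append(rec)
    return records


def read_services(path) -> list[ServiceBenchmark]:
    df = _read_csv(path)
    _require(df, SERVICE_COLUMNS[:3], path)
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                ServiceBenchmark(
                    city=str(row["city"]),
                    program_id=str(row["program_id"]),
                    benchmark_count=int(float(row["benchmark_count"])),
                    description=str(row.get("description") or ""),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {idx + 2}: {exc}") from exc
    return out


def read_monthly(path) -> list[MonthlySeries]:
    df = _read_csv(path)
    month_cols = [f"month_{i}" for i in range(1, 13)]
    flag_cols = [f"collected_{i}" for i in range(1, 13)]
    _require(df, ["city"] + month_cols + flag_cols, path)
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                MonthlySeries(
                    city=str(row["city"]),
                    counts=[float(row[c]) for c in month_cols],
                    collected=[bool(_as_bool(row[c])) for c in flag_cols],
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"{path} row {idx + 2}: {exc}") from exc
    return out


def read_cities(path) -> list[CityContext]:
    df = _read_csv(path)
    _require(df, CITY_BASE_COLUMNS, path)
    proxy_cols = [c for c in df.columns if c not in CITY_BASE_COLUMNS]
    out = []
    for idx, row in df.iterrows():
        try:
            proxies = {}
            for col in proxy_cols:
                v = _as_opt_float(row.get(col))
                if v is not None:
                    proxies[col] = v
            out.append(
                CityContext(
                    city=str(row["city"]),
                    adult_male_pop=int(float(row["adult_male_pop"])),
                    adult_female_pop=int(float(row["adult_female_pop"])),
                    proxies=proxies,
                    is_study_city=bool(_as_bool(row["is_study_city"])),
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"{path} row {idx + 2}: {exc}") from exc
    return out


def read_tables(
    hotspots=None, surveys=None, services=None, monthly=None, cities=None
) -> Dataset:
    """Read any subset of the study tables into a validated :class:`Dataset`."""
    ds = Dataset()
    if hotspots is not None:
        ds.hotspots = read_hotspots(hotspots)
    if surveys is not None:
        ds.surveys = read_surveys(surveys)
    if services is not None:
        ds.services = read_services(services)
    if monthly is not None:
        ds.monthly = read_monthly(monthly)
    if cities is not None:
        ds.cities = read_cities(cities)
    for name in ("hotspots", "surveys", "services", "monthly", "cities"):
        log.info("read %d %s rows", len(getattr(ds, name)), name)
    return ds


def _bool_str(v: Optional[bool]) -> str:
    return "" if v is None else ("true" if v else "false")


def write_dataset(ds: Dataset, outdir) -> dict[str, Path]:
    """Write every table of a dataset as CSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = [
        {
            "hotspot_id": h.hotspot_id,
            "city": h.city,
            "district": h.district,
            "ki_count": h.ki_count,
            "enum_count": "" if h.enum_count is None else h.enum_count,
            "visited": _bool_str(h.visited),
        }
        for h in ds.hotspots
    ]
    paths["hotspots"] = outdir / "hotspots.csv"
    pd.DataFrame(rows, columns=HOTSPOT_COLUMNS).to_csv(paths["hotspots"], index=False)

    service_ids = sorted({k for s in ds.surveys for k in s.received_service})
    rows = []
    for s in ds.surveys:
        row = {
            "city": s.city,
            "hotspot_id": s.hotspot_id,
            "received_object": _bool_str(s.received_object),
            "in_first_survey": _bool_str(s.in_first_survey),
            "wotc_min": "" if s.wotc_min is None else s.wotc_min,
            "wotc_max": "" if s.wotc_max is None else s.wotc_max,
            "sex": s.sex or "",
        }
        for sid in service_ids:
            row[f"service_{sid}"] = _bool_str(s.received_service.get(sid))
        rows.append(row)
    cols = SURVEY_BASE_COLUMNS[:3] + [f"service_{sid}" for sid in service_ids] + SURVEY_BASE_COLUMNS[3:]
    paths["surveys"] = outdir / "survey.csv"
    pd.DataFrame(rows, columns=cols).to_csv(paths["surveys"], index=False)

    rows = [
        {
            "city": s.city,
            "program_id": s.program_id,
            "benchmark_count": s.benchmark_count,
            "description": s.description,
        }
        for s in ds.services
    ]
    paths["services"] = outdir / "services.csv"
    pd.DataFrame(rows, columns=SERVICE_COLUMNS).to_csv(paths["services"], index=False)

    rows = []
    for m in ds.monthly:
        row = {"city": m.city}
        for i in range(12):
            row[f"month_{i + 1}"] = m.counts[i]
            row[f"collected_{i + 1}"] = _bool_str(m.collected[i])
        rows.append(row)
    cols = ["city"] + [f"month_{i}" for i in range(1, 13)] + [f"collected_{i}" for i in range(1, 13)]
    paths["monthly"] = outdir / "monthly.csv"
    pd.DataFrame(rows, columns=cols).to_csv(paths["monthly"], index=False)

    proxy_cols = sorted({k for c in ds.cities for k in c.proxies})
    rows = []
    for c in ds.cities:
        row = {
            "city": c.city,
            "adult_male_pop": c.adult_male_pop,
            "adult_female_pop": c.adult_female_pop,
            "is_study_city": _bool_str(c.is_study_city),
        }
        for p in proxy_cols:
            row[p] = c.proxies.get(p, "")
        rows.append(row)
    paths["cities"] = outdir / "cities.csv"
    pd.DataFrame(rows, columns=CITY_BASE_COLUMNS + proxy_cols).to_csv(
        paths["cities"], index=False
    )
    return paths


def read_dataset(indir) -> Dataset:
    """Inverse of :func:`write_dataset`."""
    indir = Path(indir)
    return read_tables(
        hotspots=indir / "hotspots.csv",
        surveys=indir / "survey.csv",
        services=indir / "services.csv",
        monthly=indir / "monthly.csv",
        cities=indir / "cities.csv",
    )


def estimates_frame(estimates: Sequence[SizeEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        prev = e.prevalence_pct()
        rows.append(
            {
                "method": e.method.value,
                "city": e.city,
                "subgroup": e.subgroup.value,
                "label": e.label,
                "point": e.point,
                "lower": e.lower,
                "upper": e.upper,
                "denominator": "" if e.denominator is None else e.denominator,
                "prevalence_pct": "" if prev is None else round(prev[0], 2),
            }
        )
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def write_estimates(estimates: Sequence[SizeEstimate], path) -> Path:
    """One CSV row per method x city x subgroup, re-readable losslessly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    estimates_frame(estimates).to_csv(path, index=False)
    return path


def read_estimates(path) -> list[SizeEstimate]:
    df = _read_csv(path)
    _require(df, [c for c in ESTIMATE_COLUMNS if c != "prevalence_pct"], path)
    out = []
    for idx, row in df.iterrows():
        label = row.get("label")
        if label is None or (isinstance(label, float) and pd.isna(label)):
            label = ""
        try:
            out.append(
                SizeEstimate(
                    method=Method(row["method"]),
                    city=str(row["city"]),
                    subgroup=Subgroup(row["subgroup"]),
                    label=str(label),
                    point=float(row["point"]),
                    lower=float(row["lower"]),
                    upper=float(row["upper"]),
                    denominator=_as_opt_int(row.get("denominator")),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {idx + 2}: {exc}") from exc
    return out
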