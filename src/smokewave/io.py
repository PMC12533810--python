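"""CSV / YAML readers and writers for the pipeline's tabular interfaces.

Schemas (all plain text, ISO-8601 dates, missing values empty):

* monitors:   site_id, x, y (or lon, lat), date, pm25
* counties:   county_id, region_id, population, baseline_rate  (per person-day)
* crosswalk:  county_id, row, col, weight                      (sums to 1/county)
* endpoints:  YAML list of {name, beta, beta_se, reference}
* visits:     region_id, date, count
* burdens:    county_id, delta_x, delta_events, variance, baseline_events,
              irr, ci_low, ci_high                             (fixed order)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .health import BURDEN_COLUMNS, CountyCrosswalk, CountyProfile, HealthImpactFunction
from .validation import VisitSeries

__all__ = [
    "read_monitors",
    "read_counties",
    "read_crosswalk",
    "read_endpoints",
    "read_visits",
    "write_burdens",
]


def read_monitors(path) -> pd.DataFrame:
    from .evaluation import normalize_monitors

    return normalize_monitors(pd.read_csv(path))


def write_monitors(monitors: pd.DataFrame, path) -> None:
    df = monitors.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_counties(path) -> list[CountyProfile]:
    df = pd.read_csv(path, dtype={"county_id": str, "region_id": str})
    required = {"county_id", "population", "baseline_rate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"county table missing columns: {sorted(missing)}")
    return [
        CountyProfile(
            county_id=str(r.county_id),
            population=float(r.population),
            baseline_rate=float(r.baseline_rate),
            region_id=str(r.region_id) if "region_id" in df.columns else None,
        )
        for r in df.itertuples(index=False)
    ]


def write_counties(profiles: list[CountyProfile], path) -> None:
    pd.DataFrame(
        [
            {
                "county_id": p.county_id,
                "region_id": p.region_id,
                "population": p.population,
                "baseline_rate": p.baseline_rate,
            }
            for p in profiles
        ]
    ).to_csv(path, index=False)


def read_crosswalk(path) -> CountyCrosswalk:
    df = pd.read_csv(path, dtype={"county_id": str})
    return CountyCrosswalk(df)


def write_crosswalk(xwalk: CountyCrosswalk, path) -> None:
    xwalk.entries.to_csv(path, index=False)


def read_endpoints(path) -> list[HealthImpactFunction]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{path}: expected a non-empty YAML list of endpoints")
    return [
        HealthImpactFunction(
            endpoint=str(e["name"]),
            beta=float(e["beta"]),
            beta_se=float(e["beta_se"]),
            reference=str(e.get("reference", "")),
        )
        for e in raw
    ]


def write_endpoints(hifs: list[HealthImpactFunction], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            [
                {
                    "name": h.endpoint,
                    "beta": h.beta,
                    "beta_se": h.beta_se,
                    "reference": h.reference,
                }
                for h in hifs
            ],
            fh,
            sort_keys=False,
        )


def read_visits(path) -> dict[str, VisitSeries]:
    df = pd.read_csv(path, dtype={"region_id": str})
    required = {"region_id", "date", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"visits table missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    return VisitSeries.from_frame(df)


def write_visits(series: dict[str, VisitSeries], path) -> None:
    rows = []
    for region_id, vs in series.items():
        for day, count in vs.counts.items():
            rows.append((region_id, day.strftime("%Y-%m-%d"), int(count)))
    pd.DataFrame(rows, columns=["region_id", "date", "count"]).to_csv(path, index=False)


def write_burdens(burdens: pd.DataFrame, path) -> None:
    burdens[BURDEN_COLUMNS].to_csv(path, index=False)


def read_burdens(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"county_id": str})
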