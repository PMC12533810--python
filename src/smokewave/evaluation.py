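"""Monitor-based evaluation of gridded PM2.5 fields.

Monitor-day observations are joined to the value of the grid cell whose
center is nearest the monitor (no interpolation), and the pooled pairs are
summarized with the standard air-quality model-performance battery: mean bias
(MB), normalized mean error (NME), normalized mean bias (NMB), root mean
square error (RMSE), and an ordinary least-squares regression of model on
observation (slope, intercept, R²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import ConcentrationField

__all__ = ["EvalStats", "pair", "evaluate", "evaluate_by_site"]

log = logging.getLogger(__name__)

MONITOR_COLUMNS = ("site_id", "x", "y", "date", "pm25")
#: accepted aliases for the monitor coordinate columns
_COORD_ALIASES = {"lon": "x", "lat": "y"}


@dataclass(frozen=True)
class EvalStats:
    """Pooled model-performance statistics over paired site-days."""

    slope: float
    intercept: float  # µg m⁻³
    r2: float
    mb: float  # µg m⁻³
    nme: float  # %
    nmb: float  # %
    rmse: float  # µg m⁻³
    n_pairs: int

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "slope": self.slope,
                "r2": self.r2,
                "mb": self.mb,
                "nme": self.nme,
                "nmb": self.nmb,
                "rmse": self.rmse,
                "intercept": self.intercept,
                "n_pairs": self.n_pairs,
            }
        )


def normalize_monitors(monitors: pd.DataFrame) -> pd.DataFrame:
    """Validate a monitor table and normalize coordinate column names."""
    df = monitors.rename(columns=_COORD_ALIASES).copy()
    missing = [c for c in MONITOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"monitor table missing columns: {missing}")
    df["date"] = pd.to_datetime(df["date"])
    if (df["pm25"].dropna() < 0).any():
        raise ValueError("monitor pm25 values must be non-negative or missing")
    return df


def pair(field: ConcentrationField, monitors: pd.DataFrame) -> pd.DataFrame:
    """Join monitor-days to nearest-cell-center model values.

    Returns a frame with columns site_id, date, obs, model, row, col.
    Out-of-domain monitors are skipped (logged); monitor-days with a missing
    observation or a date outside the field are dropped (counts logged).
    Raises if no site-day overlaps.
    """
    df = normalize_monitors(monitors)
    grid = field.grid

    site_cells: dict[str, tuple[int, int] | None] = {}
    skipped_sites = []
    for site_id, g in df.groupby("site_id", sort=False):
        x, y = float(g["x"].iloc[0]), float(g["y"].iloc[0])
        cell = grid.nearest_cell(x, y)
        site_cells[site_id] = cell
        if cell is None:
            skipped_sites.append(site_id)
    if skipped_sites:
        log.warning(
            "skipped %d out-of-domain monitors: %s",
            len(skipped_sites),
            ", ".join(map(str, skipped_sites)),
        )

    day_index = {d: i for i, d in enumerate(field.days)}
    rows = []
    n_missing_obs = 0
    n_missing_day = 0
    for rec in df.itertuples(index=False):
        cell = site_cells[rec.site_id]
        if cell is None:
            continue
        if pd.isna(rec.pm25):
            n_missing_obs += 1
            continue
        di = day_index.get(pd.Timestamp(rec.date))
        if di is None:
            n_missing_day += 1
            continue
        r, c = cell
        rows.append((rec.site_id, pd.Timestamp(rec.date), float(rec.pm25),
                     float(field.values[di, r, c]), r, c))
    if n_missing_obs or n_missing_day:
        log.info(
            "dropped %d monitor-days with missing obs and %d outside the field's days",
            n_missing_obs,
            n_missing_day,
        )
    if not rows:
        raise ValueError("no overlapping site-days between monitors and field")
    return pd.DataFrame(rows, columns=["site_id", "date", "obs", "model", "row", "col"])


def evaluate(pairs: pd.DataFrame) -> EvalStats:
    """Pooled statistics over paired obs/model values.

    MB   = mean(model − obs)
    NME  = 100 · Σ|model − obs| / Σobs
    NMB  = 100 · Σ(model − obs) / Σobs
    RMSE = sqrt(mean((model − obs)²))
    slope/intercept/R² from OLS of model (ordinate) on obs (abscissa).
    """
    obs = np.asarray(pairs["obs"], dtype=float)
    model = np.asarray(pairs["model"], dtype=float)
    n = obs.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs to evaluate, got {n}")
    diff = model - obs
    mb = float(diff.mean())
    rmse = float(np.sqrt(np.mean(diff**2)))
    obs_sum = float(obs.sum())
    if obs_sum <= 0:
        raise ValueError("normalized metrics undefined: observation sum is zero")
    nme = float(100.0 * np.abs(diff).sum() / obs_sum)
    nmb = float(100.0 * diff.sum() / obs_sum)
    if np.ptp(obs) == 0 or np.ptp(model) == 0:
        # degenerate cloud: the regression is undefined, not zero
        slope = intercept = r2 = float("nan")
    else:
        reg = stats.linregress(obs, model)
        slope, intercept, r2 = float(reg.slope), float(reg.intercept), float(reg.rvalue**2)
    return EvalStats(
        slope=slope,
        intercept=intercept,
        r2=r2,
        mb=mb,
        nme=nme,
        nmb=nmb,
        rmse=rmse,
        n_pairs=int(n),
    )


def evaluate_by_site(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-site statistics (sites with < 3 pairs are omitted)."""
    out = {}
    for site_id, g in pairs.groupby("site_id", sort=False):
        if len(g) < 3:
            continue
        out[site_id] = evaluate(g).to_series()
    return pd.DataFrame(out).T.rename_axis("site_id")
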