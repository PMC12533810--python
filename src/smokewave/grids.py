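"""Gridded daily-mean PM2.5 scenario fields and factorial-ensemble algebra.

The pipeline's currency is a daily-mean surface PM2.5 concentration field on a
uniform rectangular grid, one field per model scenario.  Scenarios form a 2x2
factorial ensemble over wildfire-emissions inventory (CAMS vs QFED) and
meteorological driver (FNL vs NAM), plus no-wildfire controls.  This module
implements the ensemble average ("CMAQ-Average" in the source runs' naming),
the signed half-sum decomposition that isolates the emissions and meteorology
contributions to ensemble spread, and the relative-change reporting used for
city/day uncertainty tables.

Sign convention (fixed, not configurable): emissions differences are taken as
QFED minus CAMS, meteorology differences as FNL minus NAM.  Reversing either
order would flip the sign of the corresponding uncertainty field.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field as _dc_field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "Emissions",
    "Meteorology",
    "ScenarioLabel",
    "Grid",
    "ConcentrationField",
    "ScenarioEnsemble",
    "UncertaintyField",
    "FieldLoadError",
    "read_field",
    "write_field",
    "ensemble_average",
    "factor_uncertainty",
    "relative_change",
    "episode_mean",
    "round_half_up",
    "AVERAGE_SCENARIO",
    "CONTROL_AVERAGE_SCENARIO",
]

#: µg m⁻³ floor below which relative changes are masked rather than reported.
DEFAULT_RELATIVE_FLOOR = 1.0

AVERAGE_SCENARIO = "CMAQ-Average"
CONTROL_AVERAGE_SCENARIO = "noWildfire-Average"


class Emissions(str, enum.Enum):
    """Wildfire emissions inventory; NONE marks a no-wildfire control run."""

    CAMS = "CAMS"
    QFED = "QFED"
    NONE = "NONE"


class Meteorology(str, enum.Enum):
    """Meteorological driver of the transport simulation."""

    FNL = "FNL"
    NAM = "NAM"


class Factor(str, enum.Enum):
    """The two varied inputs of the factorial ensemble."""

    EMISSIONS = "emissions"
    METEOROLOGY = "meteorology"


@dataclass(frozen=True)
class ScenarioLabel:
    emissions: Emissions
    meteorology: Meteorology

    def __post_init__(self) -> None:
        object.__setattr__(self, "emissions", Emissions(self.emissions))
        object.__setattr__(self, "meteorology", Meteorology(self.meteorology))

    @property
    def is_control(self) -> bool:
        return self.emissions is Emissions.NONE

    @property
    def name(self) -> str:
        if self.is_control:
            return f"noWildfire-{self.meteorology.value}"
        return f"{self.emissions.value}-{self.meteorology.value}"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


#: The four wildfire-inclusive members of a complete factorial.
FACTORIAL_LABELS = tuple(
    ScenarioLabel(e, m)
    for e in (Emissions.CAMS, Emissions.QFED)
    for m in (Meteorology.FNL, Meteorology.NAM)
)

CONTROL_LABELS = tuple(
    ScenarioLabel(Emissions.NONE, m) for m in (Meteorology.FNL, Meteorology.NAM)
)


@dataclass(frozen=True)
class Grid:
    """Uniform rectangular grid described by its cell centers.

    Coordinates are abstract projected x/y (or lon/lat) in whatever unit the
    inputs use; no map-projection math is performed anywhere in the package.
    """

    nrows: int
    ncols: int
    dx: float
    dy: float
    x0: float = 0.0  # x coordinate of the center of column 0
    y0: float = 0.0  # y coordinate of the center of row 0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("grid spacing must be positive")

    @property
    def row_centers(self) -> np.ndarray:
        return self.y0 + self.dy * np.arange(self.nrows)

    @property
    def col_centers(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.ncols)

    def nearest_cell(self, x: float, y: float) -> tuple[int, int] | None:
        """Index of the cell whose center is nearest (x, y).

        Returns None when the point lies outside the grid's outer cell edges.
        """
        col = (x - self.x0) / self.dx
        row = (y - self.y0) / self.dy
        if not (-0.5 <= col <= self.ncols - 0.5 and -0.5 <= row <= self.nrows - 0.5):
            return None
        return int(np.clip(round(row), 0, self.nrows - 1)), int(
            np.clip(round(col), 0, self.ncols - 1)
        )


def _coerce_days(days) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(pd.to_datetime(list(days)))
    if len(idx) < 1:
        raise ValueError("a field needs at least one day")
    if not idx.is_monotonic_increasing or idx.has_duplicates:
        raise ValueError("days must be strictly increasing calendar dates")
    return idx


@dataclass
class ConcentrationField:
    """Daily-mean PM2.5 (µg m⁻³) for one scenario, indexed (day, row, col)."""

    values: np.ndarray
    days: pd.DatetimeIndex
    grid: Grid
    scenario: ScenarioLabel | str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.days = _coerce_days(self.days)
        if self.values.ndim != 3:
            raise ValueError("values must be a (day, row, col) array")
        expected = (len(self.days), self.grid.nrows, self.grid.ncols)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"days x grid {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("concentration values must be finite")
        if np.any(self.values < 0):
            raise ValueError("concentration values must be non-negative")

    @property
    def scenario_name(self) -> str:
        return self.scenario.name if isinstance(self.scenario, ScenarioLabel) else str(self.scenario)

    def same_axes(self, other: "ConcentrationField") -> bool:
        return self.grid == other.grid and self.days.equals(other.days)

    def select_days(self, days: Iterable) -> "ConcentrationField":
        wanted = _coerce_days(days)
        missing = wanted.difference(self.days)
        if len(missing):
            raise KeyError(f"days not in field: {list(missing.strftime('%Y-%m-%d'))}")
        locs = self.days.get_indexer(wanted)
        return ConcentrationField(self.values[locs], wanted, self.grid, self.scenario)

    def to_dataset(self) -> xr.Dataset:
        da = xr.DataArray(
            self.values,
            dims=("day", "row", "col"),
            coords={
                "day": self.days,
                "row": ("row", self.grid.row_centers),
                "col": ("col", self.grid.col_centers),
            },
            name="pm25",
            attrs={
                "units": "ug m-3",
                "long_name": "daily mean surface PM2.5 concentration",
            },
        )
        ds = da.to_dataset()
        label = self.scenario
        if isinstance(label, ScenarioLabel):
            ds.attrs["emissions"] = label.emissions.value
            ds.attrs["meteorology"] = label.meteorology.value
        ds.attrs["scenario"] = self.scenario_name
        ds.attrs["dx"] = self.grid.dx
        ds.attrs["dy"] = self.grid.dy
        return ds


class FieldLoadError(ValueError):
    """Raised when a scenario file violates the field contract."""


_UNIT_ALIASES = {
    "ug m-3", "ug/m3", "ug/m^3", "ug m^-3", "µg m-3", "µg/m3",
    "micrograms per cubic meter", "ug.m-3",
}


def write_field(field: ConcentrationField, path) -> None:
    """Write a scenario field as CF-style NetCDF (classic format)."""
    ds = field.to_dataset()
    ds.to_netcdf(path, engine="scipy")


def read_field(path, scenario: ScenarioLabel | str | None = None) -> ConcentrationField:
    """Read and validate a scenario field written by :func:`write_field`.

    The file must contain a ``pm25(day, row, col)`` variable with a recognized
    µg m⁻³ units attribute and uniformly spaced coordinate axes.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if "pm25" not in ds:
        raise FieldLoadError(f"{path}: missing variable 'pm25'")
    da = ds["pm25"]
    units = str(da.attrs.get("units", "")).strip()
    if units.lower() not in _UNIT_ALIASES:
        raise FieldLoadError(
            f"{path}: attribute 'units' is {units!r}, expected µg m⁻³ ('ug m-3')"
        )
    if da.dims != ("day", "row", "col"):
        raise FieldLoadError(f"{path}: pm25 dims {da.dims} != ('day','row','col')")
    rows = np.asarray(ds["row"].values, dtype=float)
    cols = np.asarray(ds["col"].values, dtype=float)
    grid = Grid(
        nrows=rows.size,
        ncols=cols.size,
        dx=_uniform_spacing(cols, "col", path),
        dy=_uniform_spacing(rows, "row", path),
        x0=float(cols[0]),
        y0=float(rows[0]),
    )
    if scenario is None:
        emis = ds.attrs.get("emissions")
        met = ds.attrs.get("meteorology")
        if emis is not None and met is not None:
            scenario = ScenarioLabel(Emissions(emis), Meteorology(met))
        else:
            scenario = str(ds.attrs.get("scenario", "unknown"))
    values = np.asarray(da.values, dtype=float)
    if np.any(values < 0):
        raise FieldLoadError(f"{path}: variable 'pm25' contains negative values")
    if not np.all(np.isfinite(values)):
        raise FieldLoadError(f"{path}: variable 'pm25' contains non-finite values")
    return ConcentrationField(values, pd.DatetimeIndex(ds["day"].values), grid, scenario)


def _uniform_spacing(centers: np.ndarray, axis: str, path) -> float:
    if centers.size == 1:
        return 1.0
    steps = np.diff(centers)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9) or steps[0] <= 0:
        raise FieldLoadError(f"{path}: coordinate '{axis}' is not uniformly spaced")
    return float(steps[0])


@dataclass
class ScenarioEnsemble:
    """The 2x2 factorial members (and optional controls) on a shared grid."""

    members: dict[ScenarioLabel, ConcentrationField] = _dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        fields = list(self.members.values())
        for f in fields[1:]:
            if not f.same_axes(fields[0]):
                raise ValueError("all ensemble members must share grid and day axis")

    @property
    def complete_factorial(self) -> bool:
        return all(lab in self.members for lab in FACTORIAL_LABELS)

    @property
    def missing_members(self) -> list[ScenarioLabel]:
        return [lab for lab in FACTORIAL_LABELS if lab not in self.members]

    def require_complete(self) -> None:
        if not self.complete_factorial:
            missing = ", ".join(lab.name for lab in self.missing_members)
            raise ValueError(f"incomplete factorial ensemble; missing members: {missing}")

    def member(self, emissions: Emissions, meteorology: Meteorology) -> ConcentrationField:
        return self.members[ScenarioLabel(emissions, meteorology)]


def ensemble_average(ens: ScenarioEnsemble) -> ConcentrationField:
    """Cell-wise arithmetic mean of the four wildfire-inclusive members."""
    ens.require_complete()
    stack = np.stack([ens.members[lab].values for lab in FACTORIAL_LABELS])
    ref = ens.members[FACTORIAL_LABELS[0]]
    return ConcentrationField(stack.mean(axis=0), ref.days, ref.grid, AVERAGE_SCENARIO)


@dataclass
class UncertaintyField:
    """Signed factor contribution to ensemble spread, absolute and relative.

    ``relative`` is 100 × absolute / baseline where the baseline (ensemble
    average) exceeds ``floor`` µg m⁻³; cells below the floor are NaN with
    ``undefined`` set, never silently zeroed.
    """

    absolute: np.ndarray  # signed µg m⁻³, shape (day, row, col)
    relative: np.ndarray  # signed %, NaN where undefined
    undefined: np.ndarray  # bool mask of cells where relative is not reportable
    factor: Factor
    baseline: ConcentrationField
    days: pd.DatetimeIndex
    grid: Grid

    def __post_init__(self) -> None:
        if not (self.absolute.shape == self.relative.shape == self.undefined.shape):
            raise ValueError("absolute/relative/undefined shapes differ")


def factor_uncertainty(
    ens: ScenarioEnsemble,
    factor: Factor | str,
    floor: float = DEFAULT_RELATIVE_FLOOR,
) -> UncertaintyField:
    """Signed half-sum decomposition of the 2x2 ensemble for one factor.

    emissions:    ½ × [(QFED_FNL − CAMS_FNL) + (QFED_NAM − CAMS_NAM)]
    meteorology:  ½ × [(CAMS_FNL − CAMS_NAM) + (QFED_FNL − QFED_NAM)]

    The relative field is computed against the four-member ensemble average.
    """
    ens.require_complete()
    factor = Factor(factor)
    cams_fnl = ens.member(Emissions.CAMS, Meteorology.FNL).values
    cams_nam = ens.member(Emissions.CAMS, Meteorology.NAM).values
    qfed_fnl = ens.member(Emissions.QFED, Meteorology.FNL).values
    qfed_nam = ens.member(Emissions.QFED, Meteorology.NAM).values
    if factor is Factor.EMISSIONS:
        absolute = 0.5 * ((qfed_fnl - cams_fnl) + (qfed_nam - cams_nam))
    else:
        absolute = 0.5 * ((cams_fnl - cams_nam) + (qfed_fnl - qfed_nam))
    baseline = ensemble_average(ens)
    relative, undefined = relative_change(absolute, baseline.values, floor=floor)
    ref = ens.members[FACTORIAL_LABELS[0]]
    return UncertaintyField(
        absolute=absolute,
        relative=relative,
        undefined=undefined,
        factor=factor,
        baseline=baseline,
        days=ref.days,
        grid=ref.grid,
    )


def relative_change(
    absolute, average, floor: float = DEFAULT_RELATIVE_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """Signed percent change, 100 × absolute / average, with a validity mask.

    Cells where the average is at or below ``floor`` (µg m⁻³) are undefined:
    the percent value is NaN and the mask is True there.  Works on scalars and
    arrays alike; always returns arrays.
    """
    absolute = np.asarray(absolute, dtype=float)
    average = np.asarray(average, dtype=float)
    undefined = ~(average > floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(undefined, np.nan, 100.0 * absolute / average)
    return rel, undefined


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at the given decimal, for tabular reports.

    Internal arithmetic everywhere is full precision; this is presentation
    only (e.g. one-decimal percent columns in uncertainty tables).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def episode_mean(field: ConcentrationField, days: Iterable) -> ConcentrationField:
    """Per-cell mean over the selected days, returned as a single-day field.

    The result's day axis is the first selected day; the number of averaged
    days is the caller's episode-length convention to carry forward.
    """
    sel = field.select_days(days)
    mean = sel.values.mean(axis=0, keepdims=True)
    return ConcentrationField(mean, sel.days[:1], field.grid, field.scenario)


def episode_days(start, end) -> pd.DatetimeIndex:
    """Inclusive daily date range helper (ISO date strings or datetimes)."""
    rng = pd.date_range(pd.to_datetime(start), pd.to_datetime(end), freq="D")
    if len(rng) == 0:
        raise ValueError("empty day range")
    return rng
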