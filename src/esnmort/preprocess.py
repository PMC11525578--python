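"""Preprocessing of gridded temperature fields and mortality tables.

Turns raw inputs — sub-monthly 2 m temperature stacks and deaths/population
tables — into what the network consumes: monthly per-cell maxima, the
European spatial subset, the affine [-13 °C, 47 °C] -> [0, 1] normalization,
monthly population by linear interpolation of annual values anchored to
mid-year, mortality rates per 100,000 inhabitants, and flattened input
vectors in a fixed cell order.

Temperature stacks are handled as :class:`TemperatureFieldSeries`, a thin
validated wrapper around an ``xarray.DataArray`` with dimensions
``(time, lat, lon)``; mortality as :class:`MortalitySeries`, a wrapper around
a ``pandas.DataFrame`` with columns ``year, month, deaths, population,
rate_per_100k``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

Month = tuple[int, int]

#: netCDF variable name used for monthly-maximum 2 m temperature.
DEFAULT_TEMP_VAR = "t2m_monthlymax"

#: Columns of the tidy mortality CSV schema.
MORTALITY_COLUMNS = ("year", "month", "deaths", "population", "rate_per_100k")


# ---------------------------------------------------------------------------
# Month bookkeeping
# ---------------------------------------------------------------------------

def month_index(month: Month) -> int:
    """Absolute month index on a linear axis (Jan of year y -> 12*y)."""
    y, m = month
    if not 1 <= m <= 12:
        raise ValueError(f"month out of range: {month!r}")
    return 12 * y + (m - 1)


def month_from_index(idx: int) -> Month:
    return idx // 12, idx % 12 + 1


def month_range(start: Month, end: Month) -> list[Month]:
    """Inclusive list of consecutive (year, month) pairs."""
    i0, i1 = month_index(start), month_index(end)
    if i1 < i0:
        raise ValueError(f"month range ends before it starts: {start!r}..{end!r}")
    return [month_from_index(i) for i in range(i0, i1 + 1)]


def months_are_consecutive(months: Sequence[Month]) -> bool:
    idx = [month_index(m) for m in months]
    return all(b - a == 1 for a, b in zip(idx, idx[1:]))


def format_month(month: Month) -> str:
    return f"{month[0]:04d}-{month[1]:02d}"


def months_to_datetimes(months: Sequence[Month]) -> np.ndarray:
    """First-of-month datetime64 stamps for a list of (year, month) pairs."""
    return np.array([np.datetime64(f"{y:04d}-{m:02d}-01") for y, m in months],
                    dtype="datetime64[ns]")


def datetimes_to_months(times: Iterable) -> list[Month]:
    out = []
    for t in pd.DatetimeIndex(times):
        out.append((int(t.year), int(t.month)))
    return out


# ---------------------------------------------------------------------------
# Temperature field series
# ---------------------------------------------------------------------------

@dataclass
class TemperatureFieldSeries:
    """A time-ordered stack of 2-D gridded temperature maps.

    Parameters
    ----------
    data
        ``xarray.DataArray`` with dimensions ``(time, lat, lon)``; monthly
        stacks carry first-of-month timestamps.  Latitudes ascend, longitudes
        ascend, both on a regular grid.
    scenario
        Label of the climate storyline the stack belongs to
        (``reference``, ``plus2K`` or ``plus4K`` in the default pipeline).
    """

    data: xr.DataArray
    scenario: str = "reference"

    def __post_init__(self) -> None:
        if tuple(self.data.dims) != ("time", "lat", "lon"):
            raise ValueError(
                f"expected dims (time, lat, lon), got {tuple(self.data.dims)}")
        for axis in ("lat", "lon"):
            coord = np.asarray(self.data[axis].values, dtype=float)
            if coord.size > 1:
                steps = np.diff(coord)
                if not np.all(steps > 0):
                    raise ValueError(f"{axis} coordinates must ascend")
                if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
                    raise ValueError(f"{axis} grid is not regular")
        if not np.all(np.isfinite(self.data.values)):
            raise ValueError("temperature values must be finite")
        months = self.months
        if len(months) == 0:
            raise ValueError("temperature series has no months")
        if not months_are_consecutive(months):
            raise ValueError("temperature series has missing months inside its span")

    # -- accessors ----------------------------------------------------------

    @property
    def months(self) -> list[Month]:
        return datetimes_to_months(self.data["time"].values)

    @property
    def lats(self) -> np.ndarray:
        return np.asarray(self.data["lat"].values, dtype=float)

    @property
    def lons(self) -> np.ndarray:
        return np.asarray(self.data["lon"].values, dtype=float)

    @property
    def values(self) -> np.ndarray:
        """Array of shape (time, lat, lon)."""
        return np.asarray(self.data.values, dtype=float)

    @property
    def units(self) -> str:
        return str(self.data.attrs.get("units", "degC"))

    # -- construction -------------------------------------------------------

    @classmethod
    def from_arrays(cls, months: Sequence[Month], lats: np.ndarray,
                    lons: np.ndarray, values: np.ndarray,
                    scenario: str = "reference",
                    units: str = "degC") -> "TemperatureFieldSeries":
        da = xr.DataArray(
            np.asarray(values, dtype=float),
            dims=("time", "lat", "lon"),
            coords={"time": months_to_datetimes(months),
                    "lat": np.asarray(lats, dtype=float),
                    "lon": np.asarray(lons, dtype=float)},
            attrs={"units": units},
        )
        return cls(data=da, scenario=scenario)

    def select_months(self, months: Sequence[Month]) -> "TemperatureFieldSeries":
        """Restrict to a consecutive subset of months (preserving order)."""
        have = {m: i for i, m in enumerate(self.months)}
        missing = [m for m in months if m not in have]
        if missing:
            raise ValueError(
                f"months not covered by series: {[format_month(m) for m in missing]}")
        idx = [have[m] for m in months]
        return TemperatureFieldSeries(self.data.isel(time=idx), scenario=self.scenario)

    # -- netCDF I/O ---------------------------------------------------------

    def to_netcdf(self, path, var_name: str = DEFAULT_TEMP_VAR) -> None:
        """Write as netCDF (dimensions time, lat, lon)."""
        da = self.data.copy()
        da.attrs.setdefault("units", "degC")
        ds = da.to_dataset(name=var_name)
        ds.attrs["scenario"] = self.scenario
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path, var_name: str = DEFAULT_TEMP_VAR,
                    scenario: str | None = None) -> "TemperatureFieldSeries":
        with xr.open_dataset(path, engine="scipy") as ds:
            if var_name not in ds:
                raise ValueError(
                    f"variable {var_name!r} not found in {path}; "
                    f"present: {list(ds.data_vars)}")
            da = ds[var_name].load()
            label = scenario or str(ds.attrs.get("scenario", "reference"))
        return cls(data=da, scenario=label)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationSpec:
    """Affine map sending [t_min, t_max] °C to [0, 1] (no clipping)."""

    t_min: float = -13.0
    t_max: float = 47.0

    def __post_init__(self) -> None:
        if not self.t_max > self.t_min:
            raise ValueError(
                f"t_max ({self.t_max}) must exceed t_min ({self.t_min})")

    def normalize(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.t_min) / (self.t_max - self.t_min)

    def denormalize(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * (self.t_max - self.t_min) + self.t_min


def normalize_temperature(fields: TemperatureFieldSeries,
                          spec: NormalizationSpec = NormalizationSpec(),
                          ) -> TemperatureFieldSeries:
    """Map temperatures affinely so [t_min, t_max] becomes [0, 1].

    Values outside the reference interval are mapped linearly outside
    [0, 1] — deliberately not clipped, since warmer-scenario fields may
    locally exceed the upper anchor — and a warning is logged.
    """
    norm = spec.normalize(fields.values)
    n_out = int(np.sum((norm < 0) | (norm > 1)))
    if n_out:
        logger.warning(
            "%d of %d normalized values fall outside [0, 1] "
            "(temperatures beyond [%g, %g] degC); values are not clipped",
            n_out, norm.size, spec.t_min, spec.t_max)
    da = xr.DataArray(norm, dims=fields.data.dims, coords=fields.data.coords,
                      attrs={"units": "1"})
    return TemperatureFieldSeries(data=da, scenario=fields.scenario)


def denormalize_temperature(fields: TemperatureFieldSeries,
                            spec: NormalizationSpec = NormalizationSpec(),
                            ) -> TemperatureFieldSeries:
    """Inverse of :func:`normalize_temperature`."""
    da = xr.DataArray(spec.denormalize(fields.values), dims=fields.data.dims,
                      coords=fields.data.coords, attrs={"units": "degC"})
    return TemperatureFieldSeries(data=da, scenario=fields.scenario)


# ---------------------------------------------------------------------------
# Temporal and spatial reduction
# ---------------------------------------------------------------------------

def monthly_max(fields: xr.DataArray) -> TemperatureFieldSeries:
    """Per-cell maximum over each calendar month of a sub-monthly stack.

    ``fields`` must be a DataArray with dims ``(time, lat, lon)`` and a
    datetime ``time`` coordinate (hourly, daily, ...).  Calendar months are
    taken in the timestamps' own clock (climate-model output is UTC);
    every month between the first and last timestamp must contain at least
    one sample.
    """
    if tuple(fields.dims) != ("time", "lat", "lon"):
        raise ValueError(f"expected dims (time, lat, lon), got {tuple(fields.dims)}")
    fields = fields.sortby("time")
    times = pd.DatetimeIndex(fields["time"].values)
    if len(times) == 0:
        raise ValueError("empty time axis")
    stamps = [(int(t.year), int(t.month)) for t in times]
    span = month_range(min(stamps, key=month_index), max(stamps, key=month_index))
    present = set(stamps)
    for m in span:
        if m not in present:
            raise ValueError(f"month {format_month(m)} has no timestamps")
    reduced = fields.resample(time="MS").max("time")
    da = reduced.assign_coords(time=months_to_datetimes(span))
    da.attrs.update(fields.attrs)
    return TemperatureFieldSeries(
        data=da, scenario=str(fields.attrs.get("scenario", "reference")))


def subset_domain(fields: TemperatureFieldSeries,
                  lon_range: tuple[float, float],
                  lat_range: tuple[float, float]) -> TemperatureFieldSeries:
    """Select grid cells whose centers lie inside the closed box (inclusive)."""
    lon0, lon1 = sorted(map(float, lon_range))
    lat0, lat1 = sorted(map(float, lat_range))
    lat_ok = (fields.lats >= lat0) & (fields.lats <= lat1)
    lon_ok = (fields.lons >= lon0) & (fields.lons <= lon1)
    if not lat_ok.any() or not lon_ok.any():
        raise ValueError(
            f"requested box lon [{lon0}, {lon1}], lat [{lat0}, {lat1}] "
            "does not intersect the grid")
    da = fields.data.isel(lat=np.where(lat_ok)[0], lon=np.where(lon_ok)[0])
    return TemperatureFieldSeries(data=da, scenario=fields.scenario)


def domain_mean_series(fields: TemperatureFieldSeries,
                       lon_range: tuple[float, float] | None = None,
                       lat_range: tuple[float, float] | None = None,
                       ) -> np.ndarray:
    """Unweighted spatial mean per month, optionally over a sub-box."""
    sub = fields
    if lon_range is not None or lat_range is not None:
        sub = subset_domain(
            fields,
            lon_range if lon_range is not None else (fields.lons[0], fields.lons[-1]),
            lat_range if lat_range is not None else (fields.lats[0], fields.lats[-1]))
    return sub.values.mean(axis=(1, 2))


# ---------------------------------------------------------------------------
# Mortality
# ---------------------------------------------------------------------------

def compute_rate(deaths, population):
    """Deaths per 100,000 inhabitants: ``deaths / population * 1e5``."""
    deaths = np.asarray(deaths, dtype=float)
    population = np.asarray(population, dtype=float)
    if np.any(population <= 0):
        raise ValueError("population must be positive")
    return deaths / population * 1e5


def interpolate_population(annual: Mapping[int, float] | pd.Series,
                           months: Sequence[Month]) -> np.ndarray:
    """Monthly population by linear interpolation of annual values.

    Each annual value is anchored at July of its year on a month-index
    axis; interpolation is linear between anchors and constant beyond the
    first and last anchor.
    """
    if isinstance(annual, pd.Series):
        annual = annual.to_dict()
    if len(annual) == 0:
        raise ValueError("need at least one annual population value")
    years = sorted(int(y) for y in annual)
    values = np.array([float(annual[y]) for y in years])
    if np.any(values <= 0):
        raise ValueError("population must be positive")
    anchors = np.array([month_index((y, 7)) for y in years], dtype=float)
    query = np.array([month_index(m) for m in months], dtype=float)
    # np.interp extrapolates by holding the edge values constant
    return np.interp(query, anchors, values)


@dataclass
class MortalitySeries:
    """Monthly deaths, interpolated population, and rate per 100,000.

    Wraps a DataFrame with columns ``year, month, deaths, population,
    rate_per_100k`` over consecutive months.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MORTALITY_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"mortality table misses columns {missing}")
        self.frame = self.frame.reset_index(drop=True)
        if len(self.frame) == 0:
            raise ValueError("empty mortality series")
        if not months_are_consecutive(self.months):
            raise ValueError("mortality series months are not consecutive")
        if np.any(self.frame["population"].to_numpy(dtype=float) <= 0):
            raise ValueError("population must be positive")
        expected = compute_rate(self.frame["deaths"], self.frame["population"])
        if not np.allclose(self.frame["rate_per_100k"], expected, rtol=1e-9, atol=1e-9):
            raise ValueError("rate_per_100k inconsistent with deaths and population")

    @property
    def months(self) -> list[Month]:
        return [(int(y), int(m)) for y, m in
                zip(self.frame["year"], self.frame["month"])]

    @property
    def rate(self) -> np.ndarray:
        return self.frame["rate_per_100k"].to_numpy(dtype=float)

    @property
    def deaths(self) -> np.ndarray:
        return self.frame["deaths"].to_numpy(dtype=float)

    @property
    def population(self) -> np.ndarray:
        return self.frame["population"].to_numpy(dtype=float)

    @classmethod
    def from_components(cls, months: Sequence[Month], deaths: np.ndarray,
                        population: np.ndarray) -> "MortalitySeries":
        deaths = np.asarray(deaths, dtype=float)
        population = np.asarray(population, dtype=float)
        frame = pd.DataFrame({
            "year": [y for y, _ in months],
            "month": [m for _, m in months],
            "deaths": deaths,
            "population": population,
            "rate_per_100k": compute_rate(deaths, population),
        })
        return cls(frame)

    def restrict(self, span: tuple[Month, Month]) -> "MortalitySeries":
        """Sub-series over an inclusive (start, end) month span."""
        wanted = set(month_range(*span))
        mask = [m in wanted for m in self.months]
        if not any(mask):
            raise ValueError(
                f"span {format_month(span[0])}..{format_month(span[1])} "
                "not covered by mortality series")
        return MortalitySeries(self.frame.loc[mask].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False,
                          columns=list(MORTALITY_COLUMNS), float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "MortalitySeries":
        return cls(pd.read_csv(path))


def load_mortality(deaths_csv, population_csv,
                   months: Sequence[Month] | None = None) -> MortalitySeries:
    """Assemble a national mortality series from two raw tables.

    ``deaths_csv`` columns: ``year, month, deaths`` and optionally
    ``region`` (per-state rows are summed per month); ``population_csv``
    columns: ``year, population`` and optionally ``region`` (summed per
    year).  This mirrors the national aggregation of the federal-state
    tables published by the German Federal Statistical Office (codes
    12613-03-01-4-B for deaths, 12411-05-01-4-B for population).  Annual
    population is interpolated to months via
    :func:`interpolate_population`.
    """
    deaths = pd.read_csv(deaths_csv)
    pop = pd.read_csv(population_csv)
    for col in ("year", "month", "deaths"):
        if col not in deaths.columns:
            raise ValueError(f"deaths table misses column {col!r}")
    for col in ("year", "population"):
        if col not in pop.columns:
            raise ValueError(f"population table misses column {col!r}")
    monthly_deaths = (deaths.groupby(["year", "month"], as_index=False)["deaths"]
                      .sum().sort_values(["year", "month"]))
    annual_pop = pop.groupby("year")["population"].sum()
    series_months = [(int(y), int(m)) for y, m in
                     zip(monthly_deaths["year"], monthly_deaths["month"])]
    if months is not None:
        keep = set(months)
        sel = [m in keep for m in series_months]
        monthly_deaths = monthly_deaths.loc[sel]
        series_months = [m for m in series_months if m in keep]
    population_monthly = interpolate_population(annual_pop, series_months)
    return MortalitySeries.from_components(
        series_months, monthly_deaths["deaths"].to_numpy(dtype=float),
        population_monthly)


# ---------------------------------------------------------------------------
# Flattening to input vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridOrder:
    """Fixed flattening order of the grid: latitude-major, north to south,
    west to east within each latitude row."""

    lats: tuple[float, ...] = field(default=())  # descending (north first)
    lons: tuple[float, ...] = field(default=())  # ascending

    @classmethod
    def of(cls, fields: TemperatureFieldSeries) -> "GridOrder":
        return cls(lats=tuple(fields.lats[::-1]), lons=tuple(fields.lons))

    @property
    def n_cells(self) -> int:
        return len(self.lats) * len(self.lons)


def flatten_inputs(fields: TemperatureFieldSeries,
                   order: GridOrder | None = None,
                   ) -> tuple[np.ndarray, GridOrder]:
    """Flatten each monthly field into one input vector.

    Cell order is latitude-major: northernmost row first, west-to-east
    within each row.  If ``order`` is given, the grid must match it exactly
    (training and scenario inputs must share one flattening).

    Returns an array of shape ``(n_months, n_cells)`` and the order used.
    """
    this = GridOrder.of(fields)
    if order is not None and this != order:
        raise ValueError(
            "grid mismatch with the reference flattening order "
            f"({len(this.lats)}x{len(this.lons)} vs "
            f"{len(order.lats)}x{len(order.lons)} cells or shifted coordinates)")
    # values are stored south-to-north; flip lat axis to get north first
    vals = fields.values[:, ::-1, :]
    flat = vals.reshape(vals.shape[0], -1)
    return np.ascontiguousarray(flat), this


def unflatten_inputs(vectors: np.ndarray, order: GridOrder,
                     months: Sequence[Month],
                     scenario: str = "reference") -> TemperatureFieldSeries:
    """Inverse of :func:`flatten_inputs`."""
    vectors = np.asarray(vectors, dtype=float)
    n_lat, n_lon = len(order.lats), len(order.lons)
    if vectors.shape[1] != n_lat * n_lon:
        raise ValueError(
            f"vector length {vectors.shape[1]} does not match grid "
            f"{n_lat}x{n_lon}")
    grids = vectors.reshape(len(months), n_lat, n_lon)[:, ::-1, :]
    return TemperatureFieldSeries.from_arrays(
        months, np.array(order.lats)[::-1], np.array(order.lons), grids,
        scenario=scenario, units="1")
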