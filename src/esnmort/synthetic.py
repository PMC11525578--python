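"""Synthetic storyline temperature fields and matching mortality series.

The generator emulates the statistical features of monthly-maximum 2 m
temperature fields from nudged climate storylines over Europe, and a
mortality series produced by a known ground-truth temperature->mortality
response, so the whole training/prediction pipeline can be exercised
offline with recoverable structure:

* a seasonal cycle with Northern-Hemisphere phase (warmest in July) on top
  of a north-south climatological gradient,
* a domain-coherent monthly anomaly (synoptic-scale hot/cool months, the
  interannual variability that makes the temperature->mortality response
  identifiable from a few years of data),
* spatially correlated weather noise (Gaussian-smoothed white noise at a
  configurable correlation length),
* occasional summer heat waves as localized additive bumps,
* scenario warming as a uniform offset whose heat-wave extremes are
  additionally amplified, so local exceedances can be much larger than the
  mean offset,
* mortality with a seasonal baseline peaking in winter, a heat-excess term
  driven by summer maxima over a Germany-covering sub-box, a cold/winter
  respiratory term, and observation noise.

All randomness flows through one seeded generator per spec; identical specs
give bit-identical outputs.  Because the same draws are consumed regardless
of the warming offset, the fields for offset ``w`` equal the reference
fields plus ``w`` whenever ``extreme_amplification`` is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocess import (
    Month,
    MortalitySeries,
    TemperatureFieldSeries,
    interpolate_population,
    month_range,
    months_are_consecutive,
    subset_domain,
)

#: Scenario labels keyed by global-mean warming offset in K.
SCENARIO_LABELS = {0.0: "reference", 2.0: "plus2K", 4.0: "plus4K"}

_SUMMER = (6, 7, 8)


def _default_months() -> list[Month]:
    return month_range((2015, 1), (2019, 12))


@dataclass(frozen=True)
class SyntheticClimateSpec:
    """Parameters of the synthetic monthly-maximum temperature generator.

    Defaults reproduce the real pipeline's geometry: an inclusive 1-degree
    grid over 10W-40E, 30N-65N (51 x 36 cells) covering Jan 2015-Dec 2019.

    Parameters
    ----------
    lon_range, lat_range
        Closed coordinate ranges in degrees east / north.
    resolution
        Grid spacing in degrees.
    months
        Ordered, consecutive (year, month) pairs.
    seasonal_amplitude
        Half peak-to-trough amplitude of the seasonal cycle, K.
    anomaly_sd
        Standard deviation of the domain-coherent monthly temperature
        anomaly, K.  Monthly anomalies over a continental-scale box are
        spatially coherent; this term carries the hot-summer/mild-winter
        interannual variability.
    spatial_corr_length
        Gaussian correlation length of the cell-scale weather noise, degrees.
    heatwave_rate
        Expected number of heat-wave events per summer (Jun-Aug), Poisson.
    heatwave_magnitude
        Typical central amplitude of a heat-wave bump, K.
    warming_offset
        Global-mean warming added uniformly, K; one of {0, 2, 4}.
    extreme_amplification
        Factor (>= 1) by which heat-wave amplitudes grow in the fully
        warmed (+4 K) world; intermediate offsets interpolate linearly.
    noise_sd
        Per-cell standard deviation of the correlated weather noise, K.
    seed
        Seed for the generator's single random stream.
    """

    lon_range: tuple[float, float] = (-10.0, 40.0)
    lat_range: tuple[float, float] = (30.0, 65.0)
    resolution: float = 1.0
    months: tuple[Month, ...] = field(
        default_factory=lambda: tuple(_default_months()))
    seasonal_amplitude: float = 12.0
    anomaly_sd: float = 1.8
    spatial_corr_length: float = 4.0
    heatwave_rate: float = 2.0
    heatwave_magnitude: float = 6.0
    warming_offset: float = 0.0
    extreme_amplification: float = 1.5
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if len(self.months) == 0:
            raise ValueError("months must be non-empty")
        if not months_are_consecutive(list(self.months)):
            raise ValueError("months must be consecutive")
        if float(self.warming_offset) not in SCENARIO_LABELS:
            raise ValueError(
                f"warming_offset must be one of {sorted(SCENARIO_LABELS)}, "
                f"got {self.warming_offset}")
        if self.extreme_amplification < 1:
            raise ValueError("extreme_amplification must be >= 1")
        if self.noise_sd < 0 or self.heatwave_rate < 0 or self.anomaly_sd < 0:
            raise ValueError(
                "noise_sd, anomaly_sd and heatwave_rate must be >= 0")

    @property
    def lats(self) -> np.ndarray:
        lo, hi = sorted(self.lat_range)
        n = int(round((hi - lo) / self.resolution)) + 1
        return lo + self.resolution * np.arange(n)

    @property
    def lons(self) -> np.ndarray:
        lo, hi = sorted(self.lon_range)
        n = int(round((hi - lo) / self.resolution)) + 1
        return lo + self.resolution * np.arange(n)

    @property
    def scenario(self) -> str:
        return SCENARIO_LABELS[float(self.warming_offset)]

    def replace(self, **kwargs) -> "SyntheticClimateSpec":
        from dataclasses import replace as _replace
        return _replace(self, **kwargs)


def _climatology(lats: np.ndarray, lons: np.ndarray, month: int,
                 amplitude: float) -> np.ndarray:
    """Latitude gradient plus NH seasonal cycle (peak in July), in °C."""
    base = 38.0 - 0.6 * (lats - 30.0)          # warm south, cool north
    seasonal = -amplitude * np.cos(2.0 * np.pi * (month - 1) / 12.0)
    return np.broadcast_to((base + seasonal)[:, None],
                           (lats.size, lons.size)).copy()


def _correlated_noise(rng: np.random.Generator, shape: tuple[int, int],
                      corr_cells: float, sd: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to per-cell SD ``sd``.

    The white field is always drawn so the random stream does not depend
    on ``sd`` (keeps scenario runs draw-aligned when only sd differs).
    """
    white = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    smooth = gaussian_filter(white, sigma=corr_cells, mode="nearest")
    scale = smooth.std()
    if scale == 0:  # degenerate 1x1 grid
        return np.zeros(shape)
    return smooth * (sd / scale)


def generate_temperature_series(spec: SyntheticClimateSpec) -> TemperatureFieldSeries:
    """Generate one monthly-maximum 2-D temperature field per month.

    Deterministic given ``spec.seed``; the warming offset is added uniformly
    after all stochastic draws, and heat-wave amplitudes are scaled by
    ``1 + (extreme_amplification - 1) * warming_offset / 4``.
    """
    rng = np.random.default_rng(spec.seed)
    lats, lons = spec.lats, spec.lons
    shape = (lats.size, lons.size)
    corr_cells = spec.spatial_corr_length / spec.resolution
    months = list(spec.months)

    fields = np.empty((len(months), *shape))
    for t, (_, m) in enumerate(months):
        fields[t] = _climatology(lats, lons, m, spec.seasonal_amplitude)
        # domain-coherent monthly anomaly (drawn unconditionally to keep
        # the stream aligned across scenario offsets)
        fields[t] += rng.standard_normal() * spec.anomaly_sd
        fields[t] += _correlated_noise(rng, shape, corr_cells, spec.noise_sd)

    # summer heat waves: Poisson count per calendar year, localized bumps
    amp_scale = 1.0 + (spec.extreme_amplification - 1.0) * spec.warming_offset / 4.0
    lat_grid = lats[:, None]
    lon_grid = lons[None, :]
    by_year: dict[int, list[int]] = {}
    for t, (y, m) in enumerate(months):
        if m in _SUMMER:
            by_year.setdefault(y, []).append(t)
    for year in sorted(by_year):
        n_events = rng.poisson(spec.heatwave_rate)
        for _ in range(n_events):
            t = by_year[year][rng.integers(len(by_year[year]))]
            c_lat = rng.uniform(lats[0], lats[-1])
            c_lon = rng.uniform(lons[0], lons[-1])
            sigma = rng.uniform(1.5, 3.0)  # footprint scale, degrees (localized)
            amp = spec.heatwave_magnitude * rng.uniform(0.5, 1.5)
            bump = np.exp(-((lat_grid - c_lat) ** 2 + (lon_grid - c_lon) ** 2)
                          / (2.0 * sigma ** 2))
            fields[t] += amp * amp_scale * bump

    fields += spec.warming_offset
    return TemperatureFieldSeries.from_arrays(
        months, lats, lons, fields, scenario=spec.scenario)


# ---------------------------------------------------------------------------
# Ground-truth mortality response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticResponseSpec:
    """Ground-truth temperature->mortality response.

    The monthly rate (deaths per 100,000 inhabitants) is

    ``baseline + seasonal * cos(2*pi*(month-1)/12)
    + heat_coefficient * max(0, T_m - heat_threshold)
    + winter_coefficient * max(0, cold_threshold - T_m) + noise``

    where ``T_m`` is the unweighted mean of the monthly-maximum field over
    a Germany-covering sub-box.  The cosine peaks in January, encoding the
    usual winter mortality maximum; the two hinge terms encode summer heat
    excess and cold-season (respiratory) excess.

    ``population`` may be a single value or a mapping year -> inhabitants;
    annual values are interpolated to months with the same mid-year
    anchoring used for the real tables.
    """

    baseline_rate: float = 90.0
    seasonal_rate_amplitude: float = 8.0
    heat_coefficient: float = 1.2
    heat_threshold: float = 34.0
    winter_coefficient: float = 1.0
    cold_threshold: float = 16.0
    noise_sd: float = 1.0
    population: float | Mapping[int, float] = 80_000_000.0
    seed: int = 0
    response_lon_range: tuple[float, float] = (5.0, 15.0)
    response_lat_range: tuple[float, float] = (47.0, 55.0)

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "seasonal_rate_amplitude",
                     "heat_coefficient", "heat_threshold",
                     "winter_coefficient", "cold_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        pops = (self.population.values() if isinstance(self.population, Mapping)
                else [self.population])
        if any(p <= 0 for p in pops):
            raise ValueError("population must be positive")

    def annual_population(self, years: Sequence[int]) -> dict[int, float]:
        if isinstance(self.population, Mapping):
            missing = [y for y in years if y not in self.population]
            if missing:
                raise ValueError(f"population mapping misses years {missing}")
            return {int(y): float(self.population[y]) for y in years}
        return {int(y): float(self.population) for y in years}

    def replace(self, **kwargs) -> "SyntheticResponseSpec":
        from dataclasses import replace as _replace
        return _replace(self, **kwargs)


def response_box_mean(temps: TemperatureFieldSeries,
                      resp: SyntheticResponseSpec) -> np.ndarray:
    """Domain-mean monthly maximum over the response sub-box (clipped to
    the grid; the whole grid if the box does not intersect it)."""
    lon0 = max(min(resp.response_lon_range), float(temps.lons[0]))
    lon1 = min(max(resp.response_lon_range), float(temps.lons[-1]))
    lat0 = max(min(resp.response_lat_range), float(temps.lats[0]))
    lat1 = min(max(resp.response_lat_range), float(temps.lats[-1]))
    if lon0 > lon1 or lat0 > lat1:
        raise ValueError(
            "response box does not intersect the temperature grid")
    sub = subset_domain(temps, (lon0, lon1), (lat0, lat1))
    return sub.values.mean(axis=(1, 2))


def expected_rate(temps: TemperatureFieldSeries,
                  resp: SyntheticResponseSpec) -> np.ndarray:
    """Noise-free ground-truth rate for each month of ``temps``."""
    t_mean = response_box_mean(temps, resp)
    months = np.array([m for _, m in temps.months])
    seasonal = resp.seasonal_rate_amplitude * np.cos(
        2.0 * np.pi * (months - 1) / 12.0)
    heat = resp.heat_coefficient * np.maximum(0.0, t_mean - resp.heat_threshold)
    cold = resp.winter_coefficient * np.maximum(0.0, resp.cold_threshold - t_mean)
    return resp.baseline_rate + seasonal + heat + cold


def generate_mortality_series(temps: TemperatureFieldSeries,
                              resp: SyntheticResponseSpec) -> MortalitySeries:
    """Mortality series implied by the ground-truth response plus noise.

    Deaths are the expected counts ``rate * population / 1e5`` (kept as
    real numbers so the rate/deaths/population identity is exact);
    deterministic given ``resp.seed``.
    """
    months = temps.months
    if len(months) < 24:
        raise ValueError(
            f"need at least 24 months of temperatures, got {len(months)}")
    rng = np.random.default_rng(resp.seed)
    noise = rng.standard_normal(len(months)) * resp.noise_sd
    rate = expected_rate(temps, resp) + noise
    years = sorted({y for y, _ in months})
    population = interpolate_population(resp.annual_population(years), months)
    deaths = rate * population / 1e5
    return MortalitySeries.from_components(months, deaths, population)


def generate_scenario_suite(spec: SyntheticClimateSpec,
                            resp: SyntheticResponseSpec,
                            offsets: Sequence[float] = (0.0, 2.0, 4.0),
                            ) -> tuple[dict[str, TemperatureFieldSeries],
                                       MortalitySeries]:
    """All scenario temperature stacks (shared weather seed) plus the
    mortality implied by the reference stack."""
    temps = {}
    for w in offsets:
        s = spec.replace(warming_offset=float(w))
        temps[s.scenario] = generate_temperature_series(s)
    mortality = generate_mortality_series(temps["reference"], resp)
    return temps, mortality
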