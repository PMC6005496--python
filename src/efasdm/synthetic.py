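"""Virtual landscapes and virtual species with known truth.

This module emulates the statistical structure of the real inputs of a
multi-scale SDM study — elevation-driven monthly climate, a patchy
categorical land cover, and three seasonal satellite time series (an
EVI-like vegetation index, an LST-like surface temperature and an
albedo-like reflectance) — entirely synthetically, so that every later
stage of the pipeline can be exercised offline against a species whose
true suitability surface is known exactly.

Scientific shape of the generator
---------------------------------
* Elevation is a smoothed Gaussian random field scaled to 0–2500 m.
* Monthly temperature follows a seasonal harmonic at sea level minus a
  lapse of 6.5 °C per km of elevation; precipitation follows a
  winter-peaked harmonic plus 50 mm per 100 m of elevation (an
  Atlantic-Iberian orographic gradient).
* Land cover (agric / forest / scrubs / bs) is a smoothed random field
  thresholded into four classes; the smoothing length controls
  patchiness.
* Each satellite dimension is a per-cell seasonal harmonic whose
  baseline, amplitude and peak day depend on the land-cover class and on
  climate (so the satellite dynamics are *climate-driven*, which is what
  makes functional attributes informative proxies), plus observation
  noise, clipped to the physical range of the dimension
  (EVI ∈ [−1, 1], LST ∈ [−25, 45] °C, albedo ∈ [0, 1]).
* The virtual species' true suitability is a logistic function of a
  chosen subset of predictors; presences are sampled without
  replacement with probability proportional to the truth map.  No true
  absences are ever emitted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grids import RasterGrid, SatelliteSeries

__all__ = [
    "LandscapeConfig",
    "LandscapeBundle",
    "VirtualSpecies",
    "OccurrenceTable",
    "generate_landscape",
    "define_virtual_species",
    "sample_occurrences",
]

# physical ranges of the three satellite dimensions
EVI_RANGE = (-1.0, 1.0)
LST_RANGE = (-25.0, 45.0)
ALB_RANGE = (0.0, 1.0)

DEFAULT_CLASSES = ("agric", "forest", "scrubs", "bs")

# per-class harmonic parameters (baseline, amplitude, peak day of year)
_EVI_CLASS = {
    "agric": (0.35, 0.25, 113),   # spring crop peak
    "forest": (0.55, 0.12, 193),  # midsummer canopy peak
    "scrubs": (0.40, 0.15, 161),
    "bs": (0.10, 0.03, 177),
}
_ALB_CLASS = {"agric": 0.18, "forest": 0.10, "scrubs": 0.15, "bs": 0.30}
_LST_CLASS_OFFSET = {"agric": 1.0, "forest": -1.5, "scrubs": 0.5, "bs": 4.0}
# vegetation damps the seasonal surface-temperature swing; bare soil amplifies it
_LST_CLASS_AMP = {"agric": 1.05, "forest": 0.70, "scrubs": 1.0, "bs": 1.35}


@dataclass(frozen=True)
class LandscapeConfig:
    """Knobs of the virtual landscape.

    The defaults produce a NW-Iberia-like setting: mean annual
    temperatures of roughly 5–15 °C and annual precipitation of roughly
    600–3000 mm along the elevation gradient.
    """

    nrows: int = 60
    ncols: int = 60
    fine_cell_km: float = 1.0
    n_years: int = 2
    composite_interval_days: int = 16
    seed: int = 0
    climate_noise: float = 0.5          # sd of monthly temperature noise, °C
    satellite_noise: float = 0.02       # sd of per-composite EVI noise
    landcover_classes: tuple[str, ...] = DEFAULT_CLASSES
    landcover_smoothing: float = 4.0    # cells; patchiness of the LC field
    landcover_subfactor: int = 4        # LC cells per fine-cell edge (LC is finer)
    elevation_smoothing: float = 8.0    # cells
    elevation_max_m: float = 2500.0
    lapse_rate_c_per_km: float = -6.5
    precip_gradient_mm_per_km: float = 500.0   # +50 mm / 100 m
    sea_level_tmean_c: float = 15.0
    tmean_seasonal_amp_c: float = 8.0
    annual_precip_base_mm: float = 800.0
    precip_seasonal_rel_amp: float = 0.8       # winter-wet harmonic
    diurnal_half_range_c: float = 5.0
    satellite_landcover_effect: float = 1.0    # 0 = class-independent harmonics
    satellite_climate_effect: float = 1.0      # 0 = climate-decoupled satellites
    evi_base: float = 0.35
    evi_amp: float = 0.20
    evi_peak_day: int = 129

    def __post_init__(self) -> None:
        if self.nrows < 10 or self.ncols < 10:
            raise ValueError("landscape must be at least 10x10 cells")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.composite_interval_days < 1 or 365 // self.composite_interval_days < 12:
            raise ValueError("composite interval must yield >= 12 composites per year")
        if self.climate_noise < 0 or self.satellite_noise < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.fine_cell_km <= 0:
            raise ValueError("cell size must be positive")
        if self.landcover_subfactor < 1:
            raise ValueError("landcover_subfactor must be >= 1")

    @property
    def composite_days(self) -> np.ndarray:
        """Day-of-year of each composite (fixed calendar, starting day 1)."""
        return np.arange(1, 366, self.composite_interval_days)


@dataclass
class LandscapeBundle:
    """Everything the generator produces for one landscape."""

    config: LandscapeConfig
    elevation: RasterGrid                       # m
    monthly_tmean: list[RasterGrid]             # 12 x °C
    monthly_tmax: list[RasterGrid]
    monthly_tmin: list[RasterGrid]
    monthly_precip: list[RasterGrid]            # 12 x mm
    landcover: RasterGrid                       # class codes 0..k-1, sub-fine grid
    landcover_modal: RasterGrid                 # modal class per fine cell
    landcover_classes: tuple[str, ...]
    satellite: dict[str, SatelliteSeries]       # keys EVI, LST, ALB

    def validate(self) -> None:
        """Assert the physical-range invariants of the bundle."""
        for name, (lo, hi) in (("EVI", EVI_RANGE), ("LST", LST_RANGE), ("ALB", ALB_RANGE)):
            for _, _, g in self.satellite[name].composites:
                v = g.data[np.isfinite(g.data)]
                if v.size and (v.min() < lo - 1e-9 or v.max() > hi + 1e-9):
                    raise AssertionError(f"{name} outside [{lo}, {hi}]")
        for m in range(12):
            a, b, c = (self.monthly_tmax[m].data, self.monthly_tmean[m].data,
                       self.monthly_tmin[m].data)
            if not (np.all(a >= b - 1e-9) and np.all(b >= c - 1e-9)):
                raise AssertionError("tmax >= tmean >= tmin violated")
            if np.nanmin(self.monthly_precip[m].data) < 0:
                raise AssertionError("negative precipitation")


@dataclass
class VirtualSpecies:
    """A species whose true suitability surface is known.

    ``coefficients`` are on the logistic scale and apply to the
    *standardized* driver predictors; ``drivers`` are exactly the
    predictors with nonzero coefficients.
    """

    driver_names: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    truth_map: RasterGrid
    prevalence: float

    def __post_init__(self) -> None:
        v = self.truth_map.data[np.isfinite(self.truth_map.data)]
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("truth map must lie in [0, 1]")


@dataclass
class OccurrenceTable:
    """Presence-only records on a grid: point records plus occupied cells."""

    species: str
    grid: RasterGrid
    records: pd.DataFrame          # columns: species, x, y, grid_id, year
    cells: list[tuple[int, int]]   # unique occupied (row, col)
    n_dropped: int = 0             # records outside the grid extent

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def presence_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid.shape, dtype=bool)
        for r, c in self.cells:
            mask[r, c] = True
        return mask

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean unit-variance smoothed Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_landscape(config: LandscapeConfig) -> LandscapeBundle:
    """Generate a full virtual landscape; bit-identical for identical config."""
    rng = np.random.default_rng(config.seed)
    shape = (config.nrows, config.ncols)
    cell = config.fine_cell_km

    # --- terrain ---
    relief = _smooth_field(rng, shape, config.elevation_smoothing)
    relief = (relief - relief.min()) / (relief.max() - relief.min())
    elev_m = relief * config.elevation_max_m
    elevation = RasterGrid(elev_m, cell_size=cell)
    elev_km = elev_m / 1000.0

    # --- monthly climate ---
    months = np.arange(12)
    # temperature peaks mid-July (month index 6.5), precipitation mid-January
    t_season = config.tmean_seasonal_amp_c * np.cos(2 * np.pi * (months - 6.5) / 12.0)
    p_season = 1.0 + config.precip_seasonal_rel_amp * np.cos(2 * np.pi * (months - 0.5) / 12.0)

    monthly_tmean, monthly_tmax, monthly_tmin, monthly_precip = [], [], [], []
    annual_precip = (config.annual_precip_base_mm
                     + config.precip_gradient_mm_per_km * elev_km)
    for m in months:
        noise_t = config.climate_noise * _smooth_field(rng, shape, 2.0) if config.climate_noise else 0.0
        tmean = (config.sea_level_tmean_c + t_season[m]
                 + config.lapse_rate_c_per_km * elev_km + noise_t)
        half = config.diurnal_half_range_c
        monthly_tmean.append(RasterGrid(tmean, cell_size=cell))
        monthly_tmax.append(RasterGrid(tmean + half, cell_size=cell))
        monthly_tmin.append(RasterGrid(tmean - half, cell_size=cell))
        noise_p = 10.0 * config.climate_noise * _smooth_field(rng, shape, 2.0) if config.climate_noise else 0.0
        precip = np.clip(annual_precip / 12.0 * p_season[m] + noise_p, 0.0, None)
        monthly_precip.append(RasterGrid(precip, cell_size=cell))

    # --- land cover: threshold a smooth field into k classes by quantile ---
    # generated `subfactor` x finer than the climate grid (as a 100 m land
    # cover is finer than a 1 km analysis grid); the modal class per fine
    # cell drives the satellite harmonics
    k = len(config.landcover_classes)
    s = config.landcover_subfactor
    sub_shape = (config.nrows * s, config.ncols * s)
    lc_field = _smooth_field(rng, sub_shape, config.landcover_smoothing * s)
    # elevation pulls the field so that bare soil ends up on the tops
    lc_field = lc_field + 0.8 * (np.kron(relief, np.ones((s, s))) - 0.5)
    edges = np.quantile(lc_field, np.linspace(0, 1, k + 1)[1:-1])
    lc_sub = np.digitize(lc_field, edges).astype(float)
    landcover = RasterGrid(lc_sub, cell_size=cell / s)
    if s == 1:
        lc_codes = lc_sub
    else:
        blocks = lc_sub.reshape(config.nrows, s, config.ncols, s).swapaxes(1, 2)
        counts = np.stack([(blocks == code).sum(axis=(2, 3)) for code in range(k)])
        lc_codes = np.argmax(counts, axis=0).astype(float)

    # --- satellite series ---
    tmean_annual = np.mean([g.data for g in monthly_tmean], axis=0)
    z_precip = (annual_precip - annual_precip.mean()) / (annual_precip.std() or 1.0)
    z_temp = (tmean_annual - tmean_annual.mean()) / (tmean_annual.std() or 1.0)

    lce = config.satellite_landcover_effect
    cce = config.satellite_climate_effect

    if lce == 0.0:
        evi_base = np.full(shape, config.evi_base)
        evi_amp = np.full(shape, config.evi_amp)
        evi_peak = np.full(shape, float(config.evi_peak_day))
        alb_base = np.full(shape, 0.18)
        lst_offset = np.zeros(shape)
        lst_amp = np.ones(shape)
    else:
        evi_base = np.zeros(shape)
        evi_amp = np.zeros(shape)
        evi_peak = np.zeros(shape)
        alb_base = np.zeros(shape)
        lst_offset = np.zeros(shape)
        lst_amp = np.ones(shape)
        for code, name in enumerate(config.landcover_classes):
            sel = lc_codes == code
            b, a, p = _EVI_CLASS.get(name, (0.3, 0.1, 180))
            evi_base[sel] = b
            evi_amp[sel] = a
            evi_peak[sel] = p
            alb_base[sel] = _ALB_CLASS.get(name, 0.15)
            lst_offset[sel] = _LST_CLASS_OFFSET.get(name, 0.0)
            lst_amp[sel] = _LST_CLASS_AMP.get(name, 1.0)

    # climate coupling: wetter cells are greener; seasonality follows temperature
    evi_base = evi_base + cce * 0.12 * z_precip
    evi_amp = np.clip(evi_amp + cce * 0.04 * z_temp, 0.0, None)
    alb_base = alb_base + cce * (-0.02) * z_precip

    days = config.composite_days
    # monthly tmean interpolated to composite days (month centers at day 15+30m)
    month_centers = 15 + 30.4 * months
    tmean_stack = np.stack([g.data for g in monthly_tmean])  # (12, r, c)

    comps: dict[str, list[tuple[int, int, RasterGrid]]] = {"EVI": [], "LST": [], "ALB": []}
    sd_evi = config.satellite_noise
    sd_lst = 50.0 * config.satellite_noise
    sd_alb = 0.5 * config.satellite_noise
    for year in range(config.n_years):
        for doy in days:
            season = np.cos(2 * np.pi * (doy - evi_peak) / 365.0)
            evi = evi_base + evi_amp * season
            if sd_evi:
                evi = evi + rng.normal(0.0, sd_evi, shape)
            evi = np.clip(evi, *EVI_RANGE)
            comps["EVI"].append((year, int(doy), RasterGrid(evi, cell_size=cell)))

            # LST follows air temperature interpolated across month centers
            w = np.interp(doy, month_centers, np.arange(12.0), period=365)
            lo, hi = int(np.floor(w)) % 12, (int(np.floor(w)) + 1) % 12
            frac = w - np.floor(w)
            t_air = (1 - frac) * tmean_stack[lo] + frac * tmean_stack[hi]
            # class-dependent amplitude applies to the seasonal departure only
            lst = tmean_annual + lst_amp * (t_air - tmean_annual) + 3.0 + lce * lst_offset
            if sd_lst:
                lst = lst + rng.normal(0.0, sd_lst, shape)
            lst = np.clip(lst, *LST_RANGE)
            comps["LST"].append((year, int(doy), RasterGrid(lst, cell_size=cell)))

            alb = alb_base + 0.02 * np.cos(2 * np.pi * (doy - 15) / 365.0)
            if sd_alb:
                alb = alb + rng.normal(0.0, sd_alb, shape)
            alb = np.clip(alb, *ALB_RANGE)
            comps["ALB"].append((year, int(doy), RasterGrid(alb, cell_size=cell)))

    satellite = {dim: SatelliteSeries(dim, comps[dim]) for dim in ("EVI", "LST", "ALB")}
    return LandscapeBundle(
        config=config,
        elevation=elevation,
        monthly_tmean=monthly_tmean,
        monthly_tmax=monthly_tmax,
        monthly_tmin=monthly_tmin,
        monthly_precip=monthly_precip,
        landcover=landcover,
        landcover_modal=RasterGrid(lc_codes, cell_size=cell),
        landcover_classes=config.landcover_classes,
        satellite=satellite,
    )


# ---------------------------------------------------------------------------
# virtual species
# ---------------------------------------------------------------------------

def define_virtual_species(
    predictors,
    driver_names: Sequence[str],
    coefficients: Sequence[float],
    intercept: float = 0.0,
    prevalence_target: float | None = None,
) -> VirtualSpecies:
    """True suitability = logistic(intercept + Σ βᵢ · zᵢ) on standardized drivers.

    Parameters
    ----------
    predictors
        A :class:`~efasdm.predictors.PredictorStack` holding the drivers.
    driver_names, coefficients
        Parallel sequences; a zero coefficient disqualifies a name from
        being a driver (drivers are exactly the nonzero-coefficient
        predictors).
    prevalence_target
        If given, the intercept is re-solved (bisection) so that the mean
        of the truth map equals this fraction.
    """
    if len(driver_names) != len(coefficients):
        raise ValueError("driver_names and coefficients must have equal length")
    for name in driver_names:
        if name not in predictors.names:
            raise KeyError(f"unknown driver predictor {name!r}")

    grid = predictors.grid()
    z_layers = []
    for name in driver_names:
        d = predictors[name].data
        mu, sd = np.nanmean(d), np.nanstd(d)
        if sd == 0:
            raise ValueError(f"driver {name!r} is constant; cannot standardize")
        z_layers.append((d - mu) / sd)

    linear = np.zeros(grid.shape)
    for z, beta in zip(z_layers, coefficients):
        linear = linear + beta * z

    if prevalence_target is not None:
        if not 0 < prevalence_target < 1:
            raise ValueError("prevalence_target must be in (0, 1)")
        lo, hi = -50.0, 50.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if np.nanmean(expit(linear + mid)) < prevalence_target:
                lo = mid
            else:
                hi = mid
        intercept = 0.5 * (lo + hi)

    truth = expit(linear + intercept)
    drivers = tuple(n for n, b in zip(driver_names, coefficients) if b != 0.0)
    return VirtualSpecies(
        driver_names=drivers,
        coefficients={n: float(b) for n, b in zip(driver_names, coefficients) if b != 0.0},
        intercept=float(intercept),
        truth_map=grid.with_data(truth),
        prevalence=float(np.nanmean(truth)),
    )


def sample_occurrences(
    species: VirtualSpecies,
    n_records: int,
    seed: int,
    species_name: str = "virtual",
    bias: RasterGrid | None = None,
    year: int = 2007,
) -> OccurrenceTable:
    """Draw presence cells ∝ truth (optionally × a sampling-bias layer).

    Cells are drawn *without replacement*; each drawn cell yields one
    point record jittered uniformly within the cell so the same records
    can later be re-binned at a coarser grain.  The table is
    presence-only: cells never drawn carry no information.
    """
    grid = species.truth_map
    w = np.array(grid.data, dtype=float)
    if bias is not None:
        grid.require_same_grid(bias)
        w = w * bias.data
    valid = np.isfinite(w) & (w > 0)
    flat_idx = np.flatnonzero(valid.ravel())
    if n_records > flat_idx.size:
        raise ValueError(
            f"n_records={n_records} exceeds the {flat_idx.size} cells with positive suitability"
        )
    weights = w.ravel()[flat_idx]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat_idx, size=n_records, replace=False,
                        p=weights / weights.sum(), shuffle=False)
    ncols = grid.shape[1]
    cells = sorted((int(i // ncols), int(i % ncols)) for i in chosen)

    rows = []
    for gid, (r, c) in enumerate(cells):
        cx, cy = grid.cell_center(r, c)
        jx, jy = rng.uniform(-0.49, 0.49, 2) * grid.cell_size
        rows.append({"species": species_name, "x": cx + jx, "y": cy + jy,
                     "grid_id": gid, "year": year})
    records = pd.DataFrame(rows, columns=["species", "x", "y", "grid_id", "year"])
    return OccurrenceTable(species=species_name, grid=grid, records=records, cells=cells)
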