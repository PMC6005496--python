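"""Ecosystem Functional Attributes (EFAs) from satellite time series.

For each of the three satellite dimensions (EVI, LST, ALB) eight summary
metrics of the seasonal dynamics are computed per year and cell, then
averaged across years:

* annual mean (surrogate of the annual total amount),
* annual maximum and minimum (annual extremes),
* seasonal standard deviation (seasonality),
* sine and cosine of the dates of the maximum and of the minimum
  (phenology), with θ = 2π · day_of_year / 365.

The phenology convention anchors sin ≈ +1 to late March/early April and
cos ≈ +1 to late December/early January.  Interannual averaging is done
on the sine/cosine *components* of each year (vector averaging), never on
the dates themselves, so two years peaking in spring and autumn average
to a near-zero phenology signal rather than to a fictitious summer date.

Raster codes follow the ``{DIM}{metric}`` pattern: ``EVImx`` (annual
maximum), ``EVImn`` (minimum), ``EVIav`` (mean), ``EVIsd`` (seasonal sd),
``EVIdmxs``/``EVIdmxc`` (sin/cos of the date of maximum), ``EVIdmns``/
``EVIdmnc`` (date of minimum) — 8 metrics × 3 dimensions = 24 rasters.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .grids import RasterGrid, SatelliteSeries, write_ascii_grid

__all__ = ["annual_metrics", "compute_efa_stack", "METRIC_SUFFIXES", "efa_names"]

#: suffix -> long name, in canonical order
METRIC_SUFFIXES = {
    "av": "annual_mean",
    "mx": "annual_max",
    "mn": "annual_min",
    "sd": "seasonal_sd",
    "dmxs": "sin_date_of_max",
    "dmxc": "cos_date_of_max",
    "dmns": "sin_date_of_min",
    "dmnc": "cos_date_of_min",
}

_TWO_PI = 2.0 * np.pi


def efa_names(dimensions: Sequence[str] = ("EVI", "LST", "ALB")) -> list[str]:
    """The 24 canonical EFA raster codes."""
    return [f"{dim}{suf}" for dim in dimensions for suf in METRIC_SUFFIXES]


def _phase(day: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    theta = _TWO_PI * np.asarray(day, dtype=float) / 365.0
    return np.sin(theta), np.cos(theta)


def annual_metrics(cell_series: Sequence[tuple[int, float]]) -> dict[str, float]:
    """Eight summary metrics of one cell-year of dated composite values.

    Parameters
    ----------
    cell_series
        (day_of_year, value) pairs, at least 12 of them, within one year.

    Returns
    -------
    dict with keys ``mean, max, min, sd, sin_dmax, cos_dmax, sin_dmin,
    cos_dmin``.  The date of the maximum (minimum) is the earliest day
    attaining it.  NaN anywhere in the series propagates NaN everywhere
    (masking is the caller's job).
    """
    if len(cell_series) < 12:
        raise ValueError(f"need >= 12 composites in a year, got {len(cell_series)}")
    days = np.array([d for d, _ in cell_series], dtype=float)
    vals = np.array([v for _, v in cell_series], dtype=float)
    order = np.argsort(days, kind="stable")
    days, vals = days[order], vals[order]
    if np.any(~np.isfinite(vals)):
        nan = float("nan")
        return dict.fromkeys(
            ("mean", "max", "min", "sd", "sin_dmax", "cos_dmax", "sin_dmin", "cos_dmin"), nan
        )
    i_max = int(np.argmax(vals))   # argmax returns the first (earliest) tie
    i_min = int(np.argmin(vals))
    s_mx, c_mx = _phase(days[i_max])
    s_mn, c_mn = _phase(days[i_min])
    return {
        "mean": float(vals.mean()),
        "max": float(vals.max()),
        "min": float(vals.min()),
        "sd": float(vals.std()),
        "sin_dmax": float(s_mx),
        "cos_dmax": float(c_mx),
        "sin_dmin": float(s_mn),
        "cos_dmin": float(c_mn),
    }


def _annual_metric_cubes(days: np.ndarray, cube: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised annual metrics for a (n_composites, rows, cols) cube."""
    order = np.argsort(days, kind="stable")
    days, cube = days[order], cube[order]
    i_max = np.argmax(cube, axis=0)
    i_min = np.argmin(cube, axis=0)
    s_mx, c_mx = _phase(days[i_max])
    s_mn, c_mn = _phase(days[i_min])
    return {
        "av": cube.mean(axis=0),
        "mx": cube.max(axis=0),
        "mn": cube.min(axis=0),
        "sd": cube.std(axis=0),
        "dmxs": s_mx,
        "dmxc": c_mx,
        "dmns": s_mn,
        "dmnc": c_mn,
    }


def compute_efa_stack(
    series: Mapping[str, SatelliteSeries],
    years: Sequence[int] | None = None,
) -> dict[str, RasterGrid]:
    """Interannual-mean EFA rasters for all dimensions present in ``series``.

    For every dimension and metric, each year's metric raster is computed
    independently and the result is the arithmetic mean over years.

    Returns a name → raster mapping with 8 × n_dimensions entries.
    """
    out: dict[str, RasterGrid] = {}
    ref_grid: RasterGrid | None = None
    for dim, s in series.items():
        grid = s.grid()
        if ref_grid is None:
            ref_grid = grid
        else:
            ref_grid.require_same_grid(grid)
        use_years = list(years) if years is not None else s.years
        missing = set(use_years) - set(s.years)
        if missing:
            raise ValueError(f"{dim}: requested years missing from series: {sorted(missing)}")
        acc: dict[str, np.ndarray] = {}
        for y in use_years:
            d, cube = s.as_array(y)
            cubes = _annual_metric_cubes(d, cube)
            for suf, arr in cubes.items():
                acc[suf] = acc.get(suf, 0.0) + arr
        for suf in METRIC_SUFFIXES:
            out[f"{dim}{suf}"] = grid.with_data(acc[suf] / len(use_years))
    return out


def write_efa_stack(stack: Mapping[str, RasterGrid], outdir: str | Path) -> list[Path]:
    """One ASCII raster per metric, named by its EFA code."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return [write_ascii_grid(g, outdir / f"{name}.asc") for name, g in stack.items()]
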