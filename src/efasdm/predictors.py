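"""Climate (CLI) and land-cover (LC) predictors, and grain aggregation.

The CLI set is a compact bioclim-style family derived from monthly
climate rasters: mean temperature of the wettest and driest quarters
(TmWQ, TmDQ), temperature annual range as the mean monthly diurnal range
(TAR), precipitation of the wettest and driest months (PpWM, PpDM) and
precipitation seasonality as a coefficient of variation in percent (PS).
Quarters are the 12 wrap-around windows of three consecutive months
(Dec–Jan–Feb allowed), matching the standard bioclim construction; ties
are broken toward the earliest starting month.

The LC set consists of per-analysis-cell composition fractions of the
four land-cover classes, Shannon's diversity index (SHDI) of the class
proportions, and the mean patch area (AREAmean, km²) of 8-connected
patches clipped at the analysis-cell boundary.

``aggregate_to_grid`` block-averages continuous rasters (or expands a
categorical raster to per-class fractions) from the fine grain to an
analysis grain that is an integer multiple of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .grids import RasterGrid, write_ascii_grid

__all__ = [
    "BioclimSet",
    "PredictorStack",
    "derive_bioclim",
    "landscape_metrics",
    "aggregate_to_grid",
]

CLI_NAMES = ("TmWQ", "TmDQ", "TAR", "PpWM", "PpDM", "PS")


@dataclass
class BioclimSet:
    """The six CLI rasters of the final predictor set."""

    TmWQ: RasterGrid
    TmDQ: RasterGrid
    TAR: RasterGrid
    PpWM: RasterGrid
    PpDM: RasterGrid
    PS: RasterGrid

    def as_dict(self) -> dict[str, RasterGrid]:
        return {n: getattr(self, n) for n in CLI_NAMES}


@dataclass
class PredictorStack:
    """Named predictor rasters on one grid, each tagged with its group.

    Groups are ``CLI``, ``LC`` or ``EFAs``; names are unique across
    groups.  The stack is the single container every downstream stage
    (screening, model fitting, projection) consumes.
    """

    rasters: dict[str, RasterGrid] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)

    VALID_GROUPS = ("CLI", "LC", "EFAs")

    def add(self, name: str, raster: RasterGrid, group: str) -> None:
        if group not in self.VALID_GROUPS:
            raise ValueError(f"unknown predictor group {group!r}")
        if name in self.rasters:
            raise ValueError(f"duplicate predictor name {name!r}")
        if self.rasters:
            self.grid().require_same_grid(raster)
        self.rasters[name] = raster
        self.groups[name] = group

    def update(self, items: Mapping[str, RasterGrid], group: str) -> None:
        for name, r in items.items():
            self.add(name, r, group)

    def __getitem__(self, name: str) -> RasterGrid:
        return self.rasters[name]

    def __contains__(self, name: str) -> bool:
        return name in self.rasters

    @property
    def names(self) -> list[str]:
        return list(self.rasters)

    def names_in_groups(self, groups: Sequence[str]) -> list[str]:
        return [n for n in self.rasters if self.groups[n] in groups]

    def grid(self) -> RasterGrid:
        return next(iter(self.rasters.values()))

    def subset(self, names: Sequence[str]) -> "PredictorStack":
        sub = PredictorStack()
        for n in names:
            sub.add(n, self.rasters[n], self.groups[n])
        return sub

    def features_at(self, cells: Sequence[tuple[int, int]],
                    names: Sequence[str] | None = None) -> np.ndarray:
        """(n_cells, n_predictors) matrix of predictor values at grid cells."""
        names = list(names) if names is not None else self.names
        rows = np.array([rc[0] for rc in cells])
        cols = np.array([rc[1] for rc in cells])
        return np.column_stack([self.rasters[n].data[rows, cols] for n in names])

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        return [write_ascii_grid(g, outdir / f"{n}.asc") for n, g in self.rasters.items()]


# ---------------------------------------------------------------------------
# CLI: bioclim derivation
# ---------------------------------------------------------------------------

def derive_bioclim(
    monthly_tmean: Sequence[RasterGrid],
    monthly_tmax: Sequence[RasterGrid],
    monthly_tmin: Sequence[RasterGrid],
    monthly_precip: Sequence[RasterGrid],
) -> BioclimSet:
    """Derive the six CLI predictors from 12 monthly rasters per variable."""
    for name, seq in (("tmean", monthly_tmean), ("tmax", monthly_tmax),
                      ("tmin", monthly_tmin), ("precip", monthly_precip)):
        if len(seq) != 12:
            raise ValueError(f"{name}: need 12 monthly rasters, got {len(seq)}")
    grid = monthly_tmean[0]
    for seq in (monthly_tmean, monthly_tmax, monthly_tmin, monthly_precip):
        for g in seq:
            grid.require_same_grid(g)

    tmean = np.stack([g.data for g in monthly_tmean])   # (12, r, c)
    tmax = np.stack([g.data for g in monthly_tmax])
    tmin = np.stack([g.data for g in monthly_tmin])
    prcp = np.stack([g.data for g in monthly_precip])
    if np.nanmin(prcp) < 0:
        raise ValueError("negative precipitation")

    # 12 wrap-around quarters: q[w] = months (w, w+1, w+2) mod 12
    q_prcp = np.stack([prcp[[w, (w + 1) % 12, (w + 2) % 12]].sum(axis=0) for w in range(12)])
    q_tmean = np.stack([tmean[[w, (w + 1) % 12, (w + 2) % 12]].mean(axis=0) for w in range(12)])
    wet_q = np.argmax(q_prcp, axis=0)   # earliest window on ties
    dry_q = np.argmin(q_prcp, axis=0)
    ij = np.indices(wet_q.shape)
    tm_wq = q_tmean[wet_q, ij[0], ij[1]]
    tm_dq = q_tmean[dry_q, ij[0], ij[1]]

    tar = (tmax - tmin).mean(axis=0)
    pp_wm = prcp.max(axis=0)
    pp_dm = prcp.min(axis=0)
    p_mean = prcp.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ps = np.where(p_mean > 0, 100.0 * prcp.std(axis=0) / p_mean, 0.0)

    g = grid.with_data
    return BioclimSet(TmWQ=g(tm_wq), TmDQ=g(tm_dq), TAR=g(tar),
                      PpWM=g(pp_wm), PpDM=g(pp_dm), PS=g(ps))


# ---------------------------------------------------------------------------
# LC: landscape metrics
# ---------------------------------------------------------------------------

_EIGHT = np.ones((3, 3), dtype=int)


def landscape_metrics(
    landcover: RasterGrid,
    classes: Sequence[str],
    factor: int,
) -> dict[str, RasterGrid]:
    """Composition and configuration metrics per analysis cell.

    ``factor`` is the integer number of fine cells per analysis-cell edge
    and must be > 1 (the land-cover raster must be strictly finer than
    the analysis grain).  Returns per-class fraction rasters plus SHDI
    and AREAmean on the analysis grid.
    """
    if factor <= 1:
        raise ValueError("land cover must be strictly finer than the analysis grain")
    codes = landcover.data
    k = len(classes)
    present = np.unique(codes[np.isfinite(codes)])
    if present.size and (present.min() < 0 or present.max() > k - 1):
        raise ValueError(f"land-cover codes outside 0..{k - 1}: {present}")

    nr, nc = landcover.shape
    ar, ac = nr // factor, nc // factor
    if ar == 0 or ac == 0:
        raise ValueError("analysis grain larger than the landscape")
    coarse_cell = landcover.cell_size * factor
    fine_area = landcover.cell_area_km2

    frac = {name: np.full((ar, ac), np.nan) for name in classes}
    shdi = np.full((ar, ac), np.nan)
    area_mean = np.full((ar, ac), np.nan)

    for i in range(ar):
        for j in range(ac):
            block = codes[i * factor:(i + 1) * factor, j * factor:(j + 1) * factor]
            valid = np.isfinite(block)
            n_valid = valid.sum()
            if n_valid == 0:
                continue
            n_total = block.size
            props = []
            for code, name in enumerate(classes):
                sel = valid & (block == code)
                frac[name][i, j] = sel.sum() / n_total   # nodata lowers the sum below 1
                p = sel.sum() / n_valid
                if p > 0:
                    props.append(p)
            shdi[i, j] = -sum(p * np.log(p) for p in props)
            # mean area of 8-connected patches clipped to this block
            sizes = []
            for code in range(k):
                lab, n = ndimage.label(valid & (block == code), structure=_EIGHT)
                if n:
                    sizes.extend(np.bincount(lab.ravel())[1:])
            area_mean[i, j] = float(np.mean(sizes)) * fine_area if sizes else np.nan

    y0 = landcover.y0 + (nr - ar * factor) * landcover.cell_size
    def mk(a: np.ndarray) -> RasterGrid:
        return RasterGrid(a, cell_size=coarse_cell, x0=landcover.x0, y0=y0)

    out = {name: mk(frac[name]) for name in classes}
    out["SHDI"] = mk(shdi)
    out["AREAmean"] = mk(area_mean)
    return out


# ---------------------------------------------------------------------------
# aggregation to the analysis grain
# ---------------------------------------------------------------------------

def aggregate_to_grid(
    raster: RasterGrid,
    factor: int,
    method: str = "mean",
    classes: Sequence[str] | None = None,
) -> RasterGrid | dict[str, RasterGrid]:
    """Aggregate a fine raster to a grain ``factor`` × coarser.

    ``method="mean"`` block-averages, excluding nodata cells from each
    block's average.  ``method="fraction_by_class"`` expands a
    categorical raster into one fraction raster per class (fractions of
    *all* fine cells in the block, so nodata lowers the sum below 1).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("aggregation factor must be a positive integer")
    factor = int(factor)
    nr, nc = raster.shape
    if nr % factor or nc % factor:
        raise ValueError(f"raster shape {raster.shape} not divisible by factor {factor}")
    ar, ac = nr // factor, nc // factor
    coarse = raster.cell_size * factor

    blocks = raster.data.reshape(ar, factor, ac, factor).swapaxes(1, 2)  # (ar, ac, f, f)
    if method == "mean":
        with np.errstate(invalid="ignore"):
            out = np.nanmean(blocks.reshape(ar, ac, -1), axis=2)
        return RasterGrid(out, cell_size=coarse, x0=raster.x0, y0=raster.y0)
    if method == "fraction_by_class":
        if classes is None:
            raise ValueError("fraction_by_class requires the class list")
        flat = blocks.reshape(ar, ac, -1)
        out: dict[str, RasterGrid] = {}
        for code, name in enumerate(classes):
            f = (flat == code).sum(axis=2) / (factor * factor)
            out[name] = RasterGrid(f.astype(float), cell_size=coarse,
                                   x0=raster.x0, y0=raster.y0)
        return out
    raise ValueError(f"unknown aggregation method {method!r}")
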