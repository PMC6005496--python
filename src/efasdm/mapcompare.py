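"""Agreement between habitat-suitability projections.

Four complementary views of agreement between two maps:

* **fuzzy kappa** for categorical (e.g. suitable/unsuitable) maps —
  chance-corrected cell agreement that tolerates near-miss locations via
  distance-decayed category membership (decay 2^(−d/halving_distance)
  within a neighbourhood radius; radius 0 reduces exactly to Cohen's
  kappa).  Expected agreement uses the category-proportion product form
  under random relocation of the cells of both maps.
* **Spearman ρ** between continuous suitability maps over jointly valid
  cells, with a large-sample p-value.
* **global Moran's I** of a single map under queen contiguity with
  row-standardised weights — the spatial-autocorrelation context for
  interpreting the other indices.
* **overlay areas**: A-only / B-only / overlaid / union areas of binary
  suitability maps in km², with percentages of the union total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .grids import RasterGrid

__all__ = [
    "MapAgreementReport",
    "OverlayStats",
    "fuzzy_kappa",
    "morans_i",
    "spearman_maps",
    "overlay_stats",
    "compare_maps",
]


@dataclass
class OverlayStats:
    """Binary-map overlay accounting (areas in km²)."""

    area_a_only: float
    area_b_only: float
    area_overlaid: float

    @property
    def area_total_union(self) -> float:
        return self.area_a_only + self.area_b_only + self.area_overlaid

    def percentages(self, ndigits: int = 2) -> dict[str, float]:
        """Shares of the union total, round-half-even to ``ndigits``."""
        total = self.area_total_union
        if total == 0:
            return {"a_only": 0.0, "b_only": 0.0, "overlaid": 0.0}
        return {
            "a_only": round(100.0 * self.area_a_only / total, ndigits),
            "b_only": round(100.0 * self.area_b_only / total, ndigits),
            "overlaid": round(100.0 * self.area_overlaid / total, ndigits),
        }


@dataclass
class MapAgreementReport:
    fuzzy_kappa: float
    spearman_rho: float
    spearman_p: float
    morans_i_a: float
    morans_i_b: float
    overlay: OverlayStats


# ---------------------------------------------------------------------------
# fuzzy kappa
# ---------------------------------------------------------------------------

def _decay_offsets(halving_distance: float, radius: int
                   ) -> list[tuple[int, int, float]]:
    """Neighbourhood offsets and their membership weights 2^(−d/h)."""
    out = []
    r = int(radius)
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            d = float(np.hypot(dr, dc))
            if d <= radius + 1e-9:
                w = 2.0 ** (-d / halving_distance) if halving_distance > 0 else (1.0 if d == 0 else 0.0)
                out.append((dr, dc, w))
    return out


def _fuzzy_membership(codes: np.ndarray, categories: np.ndarray,
                      offsets: Sequence[tuple[int, int, float]]) -> np.ndarray:
    """(k, rows, cols) fuzzy membership of each cell in each category."""
    nr, nc = codes.shape
    k = categories.size
    fuzz = np.zeros((k, nr, nc))
    for ci, cat in enumerate(categories):
        ind = (codes == cat).astype(float)
        acc = np.zeros((nr, nc))
        for dr, dc, w in offsets:
            shifted = np.zeros((nr, nc))
            src_r = slice(max(0, dr), min(nr, nr + dr))
            dst_r = slice(max(0, -dr), min(nr, nr - dr))
            src_c = slice(max(0, dc), min(nc, nc + dc))
            dst_c = slice(max(0, -dc), min(nc, nc - dc))
            shifted[dst_r, dst_c] = ind[src_r, src_c]
            np.maximum(acc, w * shifted, out=acc)
        fuzz[ci] = acc
    return fuzz


def fuzzy_kappa(
    map_a: RasterGrid,
    map_b: RasterGrid,
    halving_distance: float = 2.0,
    radius: int = 4,
) -> float:
    """Fuzzy kappa agreement between two categorical maps.

    Per cell, each map contributes a fuzzy category-membership vector
    built by exponential distance decay within ``radius``; the one-way
    similarity of map A at a cell is B's fuzzy membership in A's crisp
    category there, and the cell similarity is the minimum of the two
    one-way similarities.  κ = (P_obs − P_exp) / (1 − P_exp) with P_exp
    from the product of the two maps' category proportions.  Identical
    maps give κ = 1; at radius 0 the statistic is Cohen's kappa.
    """
    map_a.require_same_grid(map_b)
    a, b = map_a.data, map_b.data
    valid = np.isfinite(a) & np.isfinite(b)
    if not valid.any():
        raise ValueError("no jointly valid cells")
    cats_a = np.unique(a[valid])
    cats_b = np.unique(b[valid])
    cats = np.unique(np.concatenate([cats_a, cats_b]))
    offsets = _decay_offsets(halving_distance, radius)

    fa = _fuzzy_membership(np.where(valid, a, np.nan), cats, offsets)
    fb = _fuzzy_membership(np.where(valid, b, np.nan), cats, offsets)

    ia = np.searchsorted(cats, a[valid]).astype(int)
    ib = np.searchsorted(cats, b[valid]).astype(int)
    rr, cc = np.nonzero(valid)
    sim_ab = fb[ia, rr, cc]   # A's crisp category against B's fuzzy vector
    sim_ba = fa[ib, rr, cc]
    p_obs = float(np.minimum(sim_ab, sim_ba).mean())

    pa = np.array([(a[valid] == c).mean() for c in cats])
    pb = np.array([(b[valid] == c).mean() for c in cats])
    p_exp = float((pa * pb).sum())
    if p_exp >= 1.0 - 1e-12:
        return 1.0 if p_obs >= 1.0 - 1e-12 else 0.0
    return (p_obs - p_exp) / (1.0 - p_exp)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def morans_i(grid: RasterGrid) -> float:
    """Global Moran's I with queen contiguity and row-standardised weights."""
    x = grid.data
    valid = np.isfinite(x)
    n = int(valid.sum())
    vals = x[valid]
    if np.unique(vals).size < 2:
        raise ValueError("Moran's I undefined for a constant map")
    z = np.where(valid, x - vals.mean(), 0.0)

    nr, nc = x.shape
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    # neighbour count per cell (queen, valid neighbours only)
    deg = np.zeros((nr, nc))
    num = np.zeros((nr, nc))
    for dr, dc in offsets:
        nb_valid = np.zeros((nr, nc), dtype=bool)
        nb_z = np.zeros((nr, nc))
        src_r = slice(max(0, dr), min(nr, nr + dr))
        dst_r = slice(max(0, -dr), min(nr, nr - dr))
        src_c = slice(max(0, dc), min(nc, nc + dc))
        dst_c = slice(max(0, -dc), min(nc, nc - dc))
        nb_valid[dst_r, dst_c] = valid[src_r, src_c]
        nb_z[dst_r, dst_c] = z[src_r, src_c]
        deg += nb_valid
        num += np.where(nb_valid, nb_z, 0.0)
    # row-standardised: each neighbour weight is 1/deg(i); total weight sum = n_with_nb
    has_nb = valid & (deg > 0)
    w_sum = float(has_nb.sum())
    numerator = float((z[has_nb] * num[has_nb] / deg[has_nb]).sum())
    denominator = float((z[valid] ** 2).sum())
    return (n / w_sum) * numerator / denominator


# ---------------------------------------------------------------------------
# continuous-map correlation and overlays
# ---------------------------------------------------------------------------

def spearman_maps(map_a: RasterGrid, map_b: RasterGrid) -> tuple[float, float]:
    """Spearman ρ and p-value over jointly valid cells of two continuous maps."""
    map_a.require_same_grid(map_b)
    valid = np.isfinite(map_a.data) & np.isfinite(map_b.data)
    if valid.sum() < 10:
        raise ValueError("need at least 10 jointly valid cells")
    a = map_a.data[valid]
    b = map_b.data[valid]
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError("Spearman correlation undefined for a constant map")
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def overlay_stats(bin_a: RasterGrid, bin_b: RasterGrid,
                  cell_area_km2: float | None = None) -> OverlayStats:
    """A-only / B-only / overlaid / union areas of two binary maps."""
    bin_a.require_same_grid(bin_b)
    if cell_area_km2 is None:
        cell_area_km2 = bin_a.cell_area_km2
    a = bin_a.data
    b = bin_b.data
    valid = np.isfinite(a) & np.isfinite(b)
    a1 = valid & (a > 0.5)
    b1 = valid & (b > 0.5)
    return OverlayStats(
        area_a_only=float((a1 & ~b1).sum()) * cell_area_km2,
        area_b_only=float((b1 & ~a1).sum()) * cell_area_km2,
        area_overlaid=float((a1 & b1).sum()) * cell_area_km2,
    )


def compare_maps(
    cont_a: RasterGrid, cont_b: RasterGrid,
    bin_a: RasterGrid, bin_b: RasterGrid,
    halving_distance: float = 2.0, radius: int = 4,
) -> MapAgreementReport:
    """Full agreement report between two projections (continuous + binary)."""
    rho, p = spearman_maps(cont_a, cont_b)
    return MapAgreementReport(
        fuzzy_kappa=fuzzy_kappa(bin_a, bin_b, halving_distance, radius),
        spearman_rho=rho,
        spearman_p=p,
        morans_i_a=morans_i(cont_a),
        morans_i_b=morans_i(cont_b),
        overlay=overlay_stats(bin_a, bin_b),
    )
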