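import math

import numpy as np
import pytest

from efasdm import RasterGrid, aggregate_to_grid, derive_bioclim, landscape_metrics
from efasdm.predictors import CLI_NAMES


def grids(values, shape=(1, 1)):
    """12 monthly single-value rasters."""
    return [RasterGrid(np.full(shape, float(v))) for v in values]


def bioclim_cell_oracle(tmean, tmax, tmin, precip):
    """Exhaustive 12-window scan for one cell (independent of the module)."""
    totals = [sum(precip[(w + k) % 12] for k in range(3)) for w in range(12)]
    wet = totals.index(max(totals))
    dry = totals.index(min(totals))
    q_mean = lambda w: sum(tmean[(w + k) % 12] for k in range(3)) / 3.0
    mean_p = sum(precip) / 12.0
    sd_p = math.sqrt(sum((p - mean_p) ** 2 for p in precip) / 12.0)
    return {
        "TmWQ": q_mean(wet),
        "TmDQ": q_mean(dry),
        "TAR": sum(a - b for a, b in zip(tmax, tmin)) / 12.0,
        "PpWM": max(precip),
        "PpDM": min(precip),
        "PS": 100.0 * sd_p / mean_p if mean_p > 0 else 0.0,
    }


class TestBioclim:
    def test_uniform_climate_degenerates_cleanly(self):
        bio = derive_bioclim(grids([10] * 12), grids([15] * 12), grids([5] * 12),
                             grids([50] * 12))
        assert bio.TmWQ.data[0, 0] == pytest.approx(10.0)
        assert bio.TmDQ.data[0, 0] == pytest.approx(10.0)
        assert bio.PS.data[0, 0] == pytest.approx(0.0)
        assert bio.TAR.data[0, 0] == pytest.approx(10.0)

    def test_toy_cell_wettest_quarter_wraps_the_year_boundary(self):
        precip = [100, 90, 80, 10, 10, 10, 10, 10, 20, 60, 110, 120]
        tmean = list(range(1, 13))
        bio = derive_bioclim(grids(tmean), grids([t + 5 for t in tmean]),
                             grids([t - 5 for t in tmean]), grids(precip))
        # wettest 3-month window is Nov-Dec-Jan (110+120+100 = 330)
        oracle = bioclim_cell_oracle(tmean, [t + 5 for t in tmean],
                                     [t - 5 for t in tmean], precip)
        assert oracle["TmWQ"] == pytest.approx(8.0)  # mean(11, 12, 1)
        assert bio.TmWQ.data[0, 0] == pytest.approx(8.0)
        assert bio.PpWM.data[0, 0] == pytest.approx(120.0)
        assert bio.PpDM.data[0, 0] == pytest.approx(10.0)

    def test_matches_exhaustive_window_oracle_on_random_cells(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            tmean = rng.uniform(-5, 25, 12)
            trange = rng.uniform(2, 12, 12)
            precip = rng.uniform(0, 250, 12)
            bio = derive_bioclim(grids(tmean), grids(tmean + trange / 2),
                                 grids(tmean - trange / 2), grids(precip))
            want = bioclim_cell_oracle(tmean.tolist(),
                                       (tmean + trange / 2).tolist(),
                                       (tmean - trange / 2).tolist(),
                                       precip.tolist())
            for name in CLI_NAMES:
                got = getattr(bio, name).data[0, 0]
                assert got == pytest.approx(want[name], rel=1e-9), name

    def test_input_validation(self):
        with pytest.raises(ValueError):
            derive_bioclim(grids([10] * 11), grids([15] * 12), grids([5] * 12),
                           grids([50] * 12))
        with pytest.raises(ValueError):
            derive_bioclim(grids([10] * 12), grids([15] * 12), grids([5] * 12),
                           grids([-1] * 12))


def flood_fill_patch_sizes(block, code):
    """BFS connected components (8-neighbour) — independent labelling oracle."""
    nr, nc = block.shape
    seen = np.zeros_like(block, dtype=bool)
    sizes = []
    for r in range(nr):
        for c in range(nc):
            if seen[r, c] or block[r, c] != code:
                continue
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                i, j = stack.pop()
                size += 1
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if (0 <= ni < nr and 0 <= nj < nc and not seen[ni, nj]
                                and block[ni, nj] == code):
                            seen[ni, nj] = True
                            stack.append((ni, nj))
            sizes.append(size)
    return sizes


class TestLandscapeMetrics:
    CLASSES = ("agric", "forest", "scrubs", "bs")

    def test_single_class_cell(self):
        lc = RasterGrid(np.ones((4, 4)), cell_size=0.25)  # all "forest"
        out = landscape_metrics(lc, self.CLASSES, factor=4)
        assert out["forest"].data[0, 0] == pytest.approx(1.0)
        assert out["SHDI"].data[0, 0] == pytest.approx(0.0)
        assert out["AREAmean"].data[0, 0] == pytest.approx(1.0)  # = cell area km2

    def test_even_two_class_split_gives_ln2(self):
        block = np.zeros((4, 4))
        block[:, 2:] = 1.0
        out = landscape_metrics(RasterGrid(block, cell_size=0.25), self.CLASSES, 4)
        assert out["SHDI"].data[0, 0] == pytest.approx(math.log(2))
        assert out["agric"].data[0, 0] == pytest.approx(0.5)
        assert out["forest"].data[0, 0] == pytest.approx(0.5)

    def test_mean_patch_area_matches_flood_fill_oracle(self, rng):
        codes = rng.integers(0, 4, size=(20, 20)).astype(float)
        lc = RasterGrid(codes, cell_size=0.1)
        out = landscape_metrics(lc, self.CLASSES, factor=20)
        sizes = []
        for code in range(4):
            sizes.extend(flood_fill_patch_sizes(codes, code))
        expected = np.mean(sizes) * 0.1 ** 2
        assert out["AREAmean"].data[0, 0] == pytest.approx(expected, rel=1e-9)

    def test_requires_strictly_finer_landcover(self):
        with pytest.raises(ValueError):
            landscape_metrics(RasterGrid(np.zeros((4, 4))), self.CLASSES, factor=1)

    def test_unknown_class_code_rejected(self):
        with pytest.raises(ValueError):
            landscape_metrics(RasterGrid(np.full((4, 4), 9.0)), self.CLASSES, factor=2)


class TestAggregation:
    def test_constant_raster_invariant(self):
        g = RasterGrid(np.full((8, 8), 3.7))
        out = aggregate_to_grid(g, 4)
        np.testing.assert_allclose(out.data, 3.7)
        assert out.cell_size == pytest.approx(4.0)

    def test_block_mean_arithmetic(self):
        g = RasterGrid(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert aggregate_to_grid(g, 2).data[0, 0] == pytest.approx(2.5)

    def test_class_fractions_sum_to_one_without_nodata(self, rng):
        codes = rng.integers(0, 3, size=(10, 10)).astype(float)
        out = aggregate_to_grid(RasterGrid(codes), 5, method="fraction_by_class",
                                classes=("a", "b", "c"))
        total = sum(out[k].data for k in out)
        np.testing.assert_allclose(total, 1.0)
        # counting oracle on the first 5x5 block
        frac_a = (codes[:5, :5] == 0).sum() / 25.0
        assert out["a"].data[0, 0] == pytest.approx(frac_a)

    def test_mean_aggregation_preserves_grand_mean(self, rng):
        g = RasterGrid(rng.normal(size=(12, 12)))
        out = aggregate_to_grid(g, 3)
        assert out.data.mean() == pytest.approx(g.data.mean(), rel=1e-12)

    def test_nodata_excluded_from_block_average(self):
        data = np.array([[1.0, np.nan], [3.0, 5.0]])
        out = aggregate_to_grid(RasterGrid(data), 2)
        assert out.data[0, 0] == pytest.approx(3.0)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            aggregate_to_grid(RasterGrid(np.zeros((9, 9))), 2)
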