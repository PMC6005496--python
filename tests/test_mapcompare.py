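import numpy as np
import pytest
from scipy import stats

from efasdm import (
    RasterGrid,
    fuzzy_kappa,
    morans_i,
    overlay_stats,
    spearman_maps,
)
from efasdm.mapcompare import OverlayStats


def cohen_kappa_2x2_oracle(a, b):
    """Cohen's kappa from the explicit contingency table of two binary maps."""
    n = a.size
    n11 = np.sum((a == 1) & (b == 1))
    n00 = np.sum((a == 0) & (b == 0))
    p_obs = (n11 + n00) / n
    pa1, pb1 = a.mean(), b.mean()
    p_exp = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    return (p_obs - p_exp) / (1 - p_exp)


def morans_double_sum_oracle(x):
    """Direct double-sum Moran's I with row-standardised queen weights."""
    nr, nc = x.shape
    z = x - x.mean()
    num = 0.0
    w_total = 0
    for r in range(nr):
        for c in range(nc):
            nbs = [(r + dr, c + dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0) and 0 <= r + dr < nr and 0 <= c + dc < nc]
            w = 1.0 / len(nbs)
            for (rr, cc) in nbs:
                num += w * z[r, c] * z[rr, cc]
            w_total += 1
    n = x.size
    return (n / w_total) * num / (z ** 2).sum()


class TestFuzzyKappa:
    def test_identical_maps_give_one(self, rng):
        m = RasterGrid(rng.integers(0, 2, size=(15, 15)).astype(float))
        assert fuzzy_kappa(m, m) == pytest.approx(1.0)

    @pytest.mark.parametrize("case", range(25))
    def test_radius_zero_reduces_to_cohens_kappa(self, case):
        rng = np.random.default_rng(2100 + case)
        a = rng.integers(0, 2, size=(12, 12)).astype(float)
        b = rng.integers(0, 2, size=(12, 12)).astype(float)
        got = fuzzy_kappa(RasterGrid(a), RasterGrid(b), radius=0)
        assert got == pytest.approx(cohen_kappa_2x2_oracle(a, b), abs=1e-12)

    def test_distance_tolerance_rewards_near_misses(self):
        checker = np.indices((12, 12)).sum(axis=0) % 2
        shifted = np.roll(checker, 1, axis=1)
        a, b = RasterGrid(checker.astype(float)), RasterGrid(shifted.astype(float))
        crisp = fuzzy_kappa(a, b, radius=0)
        fuzzy = fuzzy_kappa(a, b, halving_distance=2.0, radius=4)
        assert fuzzy > crisp

    def test_symmetry(self, rng):
        a = RasterGrid(rng.integers(0, 3, size=(10, 10)).astype(float))
        b = RasterGrid(rng.integers(0, 3, size=(10, 10)).astype(float))
        assert fuzzy_kappa(a, b) == pytest.approx(fuzzy_kappa(b, a))

    def test_bounded_above_by_one(self, rng):
        for _ in range(10):
            a = RasterGrid(rng.integers(0, 2, size=(10, 10)).astype(float))
            b = RasterGrid(rng.integers(0, 2, size=(10, 10)).astype(float))
            assert fuzzy_kappa(a, b) <= 1.0 + 1e-12

    def test_agreement_decreases_with_label_noise(self):
        base = (np.indices((20, 20)).sum(axis=0) > 19).astype(float)
        noise_levels = np.linspace(0.0, 0.5, 20)
        means = []
        for q in noise_levels:
            vals = []
            for seed in range(10):
                rng = np.random.default_rng(3000 + seed)
                noisy = base.copy()
                flip = rng.uniform(size=base.shape) < q
                noisy[flip] = 1 - noisy[flip]
                vals.append(fuzzy_kappa(RasterGrid(base), RasterGrid(noisy)))
            means.append(np.mean(vals))
        rho = stats.spearmanr(noise_levels, means).statistic
        assert rho < -0.95  # monotone decrease in expectation
        assert means[0] == pytest.approx(1.0)

    def test_nodata_only_overlap_rejected(self):
        a = RasterGrid(np.full((5, 5), np.nan))
        with pytest.raises(ValueError):
            fuzzy_kappa(a, a)


class TestMoransI:
    def test_smooth_gradient_is_positively_autocorrelated(self):
        g = RasterGrid(np.add.outer(np.arange(10.0), np.arange(10.0)))
        assert morans_i(g) > 0.5

    def test_checkerboard_matches_double_sum_oracle_and_is_negative(self):
        checker = (np.indices((8, 8)).sum(axis=0) % 2).astype(float)
        got = morans_i(RasterGrid(checker))
        want = morans_double_sum_oracle(checker)
        assert got == pytest.approx(want, abs=1e-12)
        assert got < 0

    def test_random_permutation_destroys_autocorrelation(self, rng):
        base = np.add.outer(np.arange(12.0), np.arange(12.0))
        perm = rng.permutation(base.ravel()).reshape(base.shape)
        envelope = [morans_i(RasterGrid(
            np.random.default_rng(s).permutation(base.ravel()).reshape(base.shape)))
            for s in range(50)]
        i_perm = morans_i(RasterGrid(perm))
        lo, hi = np.percentile(envelope, [1, 99])
        assert lo - 0.05 <= i_perm <= hi + 0.05

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            morans_i(RasterGrid(np.ones((5, 5))))


class TestSpearmanMaps:
    def test_self_correlation_is_one(self, rng):
        m = RasterGrid(rng.uniform(size=(8, 8)))
        rho, p = spearman_maps(m, m)
        assert rho == pytest.approx(1.0)

    def test_negation_is_minus_one(self, rng):
        m = RasterGrid(rng.uniform(size=(8, 8)))
        rho, _ = spearman_maps(m, m.with_data(-m.data))
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        a = rng.uniform(size=(9, 9))
        b = rng.uniform(size=(9, 9))
        rho, _ = spearman_maps(RasterGrid(a), RasterGrid(b))
        want = np.corrcoef(stats.rankdata(a.ravel()), stats.rankdata(b.ravel()))[0, 1]
        assert rho == pytest.approx(want, abs=1e-12)

    def test_too_few_joint_cells_rejected(self):
        a = RasterGrid(np.full((2, 2), 1.0))
        with pytest.raises(ValueError):
            spearman_maps(a, a)


class TestOverlay:
    def test_identical_maps_fully_overlaid(self, rng):
        m = RasterGrid(rng.integers(0, 2, size=(10, 10)).astype(float))
        ov = overlay_stats(m, m)
        assert ov.area_a_only == 0 and ov.area_b_only == 0
        assert ov.area_overlaid == ov.area_total_union

    def test_counting_oracle_on_random_maps(self, rng):
        a = rng.integers(0, 2, size=(30, 30)).astype(float)
        b = rng.integers(0, 2, size=(30, 30)).astype(float)
        ov = overlay_stats(RasterGrid(a, cell_size=5.0), RasterGrid(b, cell_size=5.0))
        assert ov.area_a_only == ((a == 1) & (b == 0)).sum() * 25.0
        assert ov.area_b_only == ((a == 0) & (b == 1)).sum() * 25.0
        assert ov.area_overlaid == ((a == 1) & (b == 1)).sum() * 25.0

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_identity_holds_exactly(self, seed):
        rng = np.random.default_rng(4000 + seed)
        a = rng.integers(0, 2, size=(13, 17)).astype(float)
        b = rng.integers(0, 2, size=(13, 17)).astype(float)
        ov = overlay_stats(RasterGrid(a), RasterGrid(b))
        assert (ov.area_a_only + ov.area_b_only + ov.area_overlaid
                == ov.area_total_union)

    def test_percentages_recomputable_from_areas(self):
        ov = OverlayStats(area_a_only=30.0, area_b_only=50.0, area_overlaid=20.0)
        pct = ov.percentages()
        assert pct == {"a_only": 30.0, "b_only": 50.0, "overlaid": 20.0}
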