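import numpy as np
import pytest
from scipy.special import expit

from efasdm import (
    EnsembleEmptyError,
    ModelRun,
    RasterGrid,
    auc_score,
    build_ensemble,
    fit_and_evaluate,
    generate_pseudo_absences,
    project_model,
    response_curve,
    threshold_roc_corner,
    tss_score,
    variable_importance,
)
from efasdm.ensemble import LEARNER_REGISTRY, SurfaceRangeEnvelope


def auc_pair_counting_oracle(scores, labels):
    """All-pairs Mann–Whitney count, ties at half weight."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def corner_threshold_oracle(scores, labels):
    """Exhaustive search over all unique-score midpoints."""
    uniq = sorted(set(scores))
    best = (np.inf, None)
    for a, b in zip(uniq[:-1], uniq[1:]):
        tau = (a + b) / 2
        sens = np.mean([s >= tau for s, l in zip(scores, labels) if l == 1])
        spec = np.mean([s < tau for s, l in zip(scores, labels) if l == 0])
        d = np.hypot(1 - sens, 1 - spec)
        if d < best[0] - 1e-15:
            best = (d, tau)
    return best[1]


class TestPseudoAbsences:
    def _grid(self, n=20):
        return RasterGrid(np.zeros((n, n)), cell_size=1.0)

    def test_same_count_as_presences_and_no_overlap(self):
        presences = [(0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (5, 5), (6, 6),
                     (7, 7), (8, 8), (9, 9)]
        sets = generate_pseudo_absences(self._grid(), presences, n_sets=5, seed=3)
        assert len(sets) == 5
        for pa in sets:
            assert len(pa.cells) == 10
            assert not set(pa.cells) & set(presences)

    def test_sets_are_seeded_and_reproducible(self):
        presences = [(i, i) for i in range(8)]
        a = generate_pseudo_absences(self._grid(), presences, n_sets=3, seed=9)
        b = generate_pseudo_absences(self._grid(), presences, n_sets=3, seed=9)
        assert [s.cells for s in a] == [s.cells for s in b]
        assert a[0].cells != a[1].cells

    def test_min_distance_verified_by_all_pairs_oracle(self):
        grid = self._grid(20)
        presences = [(0, c) for c in range(5)]
        sets = generate_pseudo_absences(grid, presences, n_sets=3, seed=1,
                                        min_distance=3.0)
        for pa in sets:
            for i, (r1, c1) in enumerate(pa.cells):
                for r2, c2 in pa.cells[i + 1:]:
                    assert np.hypot(r1 - r2, c1 - c2) >= 3.0 - 1e-9

    def test_infeasible_constraint_names_the_binding_one(self):
        # two pseudo-absences cannot be 100 km apart on a 5 km-wide grid
        grid = self._grid(5)
        with pytest.raises(RuntimeError, match="minimum pairwise distance"):
            generate_pseudo_absences(grid, [(0, 0), (1, 1)], n_sets=1, seed=0,
                                     min_distance=100.0, max_rounds=3)

    def test_not_enough_unoccupied_cells(self):
        grid = RasterGrid(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            generate_pseudo_absences(grid, [(0, 0), (0, 1), (1, 0)], n_sets=1, seed=0)


class TestScores:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert auc_score(scores, labels) == 1.0
        tau = threshold_roc_corner(scores, labels)
        assert tau == pytest.approx(0.5)  # the lowest zero-distance midpoint
        assert tss_score(scores, labels, tau) == 1.0

    @pytest.mark.parametrize("case", range(30))
    def test_auc_matches_all_pairs_oracle(self, case):
        rng = np.random.default_rng(900 + case)
        scores = rng.integers(0, 10, size=20) / 10.0  # ties guaranteed
        labels = rng.integers(0, 2, size=20)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        assert auc_score(scores, labels) == pytest.approx(
            auc_pair_counting_oracle(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("case", range(30))
    def test_corner_threshold_matches_exhaustive_oracle(self, case):
        rng = np.random.default_rng(1300 + case)
        scores = rng.uniform(size=15).round(2)
        labels = rng.integers(0, 2, size=15)
        if labels.sum() in (0, 15) or len(set(scores)) < 2:
            pytest.skip("degenerate draw")
        assert threshold_roc_corner(scores, labels) == pytest.approx(
            corner_threshold_oracle(scores, labels))

    def test_random_scores_give_null_auc(self, rng):
        scores = rng.uniform(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert auc_score(scores, labels) == pytest.approx(0.5, abs=0.04)

    def test_all_equal_scores_rejected(self):
        with pytest.raises(ValueError, match="no discriminating threshold"):
            threshold_roc_corner(np.full(10, 0.3), np.array([0, 1] * 5))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score(np.array([0.1, 0.2]), np.array([1, 1]))


class TestFitAndEvaluate:
    def test_separable_predictor_reaches_perfect_scores(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.uniform(0, 0.3, 40), rng.uniform(0.7, 1.0, 40)])
        y = np.array([0] * 40 + [1] * 40)
        run = fit_and_evaluate(x.reshape(-1, 1), y, "glm", split_seed=2,
                               feature_names=("x",))
        assert run.auc == 1.0
        assert run.tss == 1.0
        assert len(run.eval_idx) == pytest.approx(0.2 * 80, abs=1)

    def test_unknown_learner_rejected(self):
        with pytest.raises(KeyError):
            fit_and_evaluate(np.zeros((10, 1)), np.array([0, 1] * 5), "nope", 0)

    @pytest.mark.parametrize("name", sorted(LEARNER_REGISTRY))
    def test_every_registered_learner_fits_and_scores(self, name):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] + 0.3 * rng.normal(size=60) > 0).astype(int)
        run = fit_and_evaluate(X, y, name, split_seed=4, feature_names=("a", "b"))
        p = run.predict(X)
        assert np.all((p >= 0) & (p <= 1))
        assert run.auc > 0.5  # the signal is strong; any sane learner beats chance

    def test_surface_range_envelope_brackets_presence_quantiles(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(200, 2))
        y = (np.abs(X[:, 0]) < 1).astype(int)
        sre = SurfaceRangeEnvelope().fit(X, y)
        inside = np.array([[0.0, 0.0]])
        outside = np.array([[5.0, 0.0]])
        assert sre.predict_proba(inside)[0, 1] == 1.0
        assert sre.predict_proba(outside)[0, 1] < 1.0


def _fake_run(auc, data, names=("x",)):
    class _Const:
        def __init__(self, m):
            self.m = m
        def predict_proba(self, X):
            p = np.full(len(X), self.m)
            return np.column_stack([1 - p, p])
    return ModelRun(learner="fake", pa_set_id=0, run_id=0, auc=auc, tss=auc,
                    threshold=0.5, calib_idx=np.arange(1), eval_idx=np.arange(1),
                    model=_Const(float(np.nanmean(data))), feature_names=names)


class TestBuildEnsemble:
    def _maps(self, values):
        return [RasterGrid(np.full((3, 3), v)) for v in values]

    def _pooled(self):
        X = np.linspace(0, 1, 20).reshape(-1, 1)
        y = np.array([0] * 10 + [1] * 10)
        return X, y

    def test_single_member_identity(self, rng):
        data = rng.uniform(size=(3, 3))
        run = fit_and_evaluate(*_separable(rng), "glm", split_seed=0)
        member_map = RasterGrid(data)
        X, y = self._pooled()
        ens = build_ensemble([run], [member_map], X, y)
        np.testing.assert_array_equal(ens.continuous.data, data)

    def test_cellwise_median_of_three(self):
        runs = [_fake_run(0.9, v) for v in (0.2, 0.5, 0.9)]
        X, y = self._pooled()
        ens = build_ensemble(runs, self._maps([0.2, 0.5, 0.9]), X, y)
        np.testing.assert_allclose(ens.continuous.data, 0.5)

    def test_median_and_iqr_match_sorting_oracle(self, rng):
        aucs = rng.uniform(0.7, 1.0, 12)
        runs = [_fake_run(a, a) for a in aucs]
        maps = self._maps(aucs)
        X, y = self._pooled()
        ens = build_ensemble(runs, maps, X, y)
        srt = np.sort(aucs)
        assert ens.auc_median == pytest.approx(float(np.median(srt)))
        q1, q3 = np.percentile(srt, [25, 75])
        assert ens.auc_iqr == pytest.approx(q3 - q1)
        np.testing.assert_allclose(ens.continuous.data,
                                   float(np.median(aucs)), rtol=1e-12)

    def test_auc_filter_excludes_weak_members(self):
        runs = [_fake_run(a, a) for a in (0.95, 0.65, 0.72)]
        X, y = self._pooled()
        ens = build_ensemble(runs, self._maps([0.95, 0.65, 0.72]), X, y)
        assert len(ens.members) == 2
        assert all(r.auc >= 0.7 for r in ens.members)

    def test_no_passing_member_is_an_explicit_outcome(self):
        runs = [_fake_run(0.6, 0.6)]
        X, y = self._pooled()
        with pytest.raises(EnsembleEmptyError):
            build_ensemble(runs, self._maps([0.6]), X, y)


def _separable(rng):
    x = np.concatenate([rng.uniform(0, 0.3, 40), rng.uniform(0.7, 1.0, 40)])
    return x.reshape(-1, 1), np.array([0] * 40 + [1] * 40)


class TestImportanceAndCurves:
    def test_unused_predictor_has_zero_importance(self, rng):
        X = rng.normal(size=(300, 2))
        predict = lambda Z: expit(Z[:, 0])  # ignores column 1
        imps, contribs = variable_importance(predict, X, n_permutations=3, seed=0)
        assert imps[1] == pytest.approx(0.0, abs=1e-12)
        assert imps[0] > 0.5
        assert contribs.sum() == pytest.approx(1.0)

    def test_identity_model_importance_close_to_one(self, rng):
        X = rng.normal(size=(1000, 1))
        imps, _ = variable_importance(lambda Z: Z[:, 0], X, n_permutations=5, seed=1)
        assert imps[0] == pytest.approx(1.0, abs=0.1)

    def test_constant_prediction_warns_and_reports_zero(self, rng):
        X = rng.normal(size=(50, 2))
        with pytest.warns(UserWarning, match="constant"):
            imps, _ = variable_importance(lambda Z: np.full(len(Z), 0.4), X)
        assert np.all(imps == 0)

    def test_response_curve_of_logistic_model_matches_closed_form(self, rng):
        X = rng.normal(size=(200, 2))
        predict = lambda Z: expit(1.7 * Z[:, 0] + 0.5 * Z[:, 1])
        curve = response_curve(predict, X, ("a", "b"), "a", n_points=40)
        med_b = np.median(X[:, 1])
        expected = expit(1.7 * curve[:, 0] + 0.5 * med_b)
        np.testing.assert_allclose(curve[:, 1], expected, rtol=1e-10)
        assert np.all(np.diff(curve[:, 1]) > 0)  # monotone increasing
        assert np.all((curve[:, 1] >= 0) & (curve[:, 1] <= 1))

    def test_flat_curve_for_constant_model(self, rng):
        X = rng.normal(size=(50, 2))
        curve = response_curve(lambda Z: np.full(len(Z), 0.3), X, ("a", "b"), "b")
        np.testing.assert_allclose(curve[:, 1], 0.3)

    def test_unknown_focal_predictor_rejected(self, rng):
        with pytest.raises(KeyError):
            response_curve(lambda Z: Z[:, 0], rng.normal(size=(10, 2)),
                           ("a", "b"), "zzz")


def test_projection_fills_valid_cells_only(small_efa_stack):
    names = ["EVIav", "LSTav"]
    proj = project_model(lambda X: np.clip(X[:, 0], 0, 1), small_efa_stack, names)
    assert proj.shape == small_efa_stack.grid().shape
    assert np.isfinite(proj.data).all()
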