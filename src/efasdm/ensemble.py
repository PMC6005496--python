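"""Presence/pseudo-absence ensemble models: fitting, evaluation, projection.

The modelling protocol follows the standard ensemble-forecasting recipe
for presence-only data:

* pseudo-absences are random unoccupied cells, as many as there are
  presences, with a minimum pairwise center distance of one grain;
* each (pseudo-absence set × run × learner) combination is fitted on a
  random 80% of the records and evaluated on the held-out 20%;
* discrimination is the rank-based AUC (Mann–Whitney formulation) and
  the True Skill Statistic (sensitivity + specificity − 1) at the
  threshold that minimises the straight-line distance from the ROC curve
  to the (0, 1) corner of the unit square;
* members with AUC ≥ 0.7 form the ensemble; the ensemble suitability map
  is the cellwise median of member probability maps, binarised at the
  ROC-corner threshold of the ensemble scores;
* predictor importance is permutation-based: 1 − |Pearson r| between
  reference predictions and predictions with the focal column shuffled,
  averaged over permutations and normalised to contributions summing
  to 1.

The learner registry mirrors the families of the usual ensemble SDM
toolkits (GLM with quadratic terms, penalised GLM, spline GAM, CART,
random forest, boosted trees, small neural network, discriminant
analysis on a basis expansion, piecewise-linear adaptive splines, and a
rectilinear surface range envelope implemented from scratch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .grids import RasterGrid

__all__ = [
    "PseudoAbsenceSet",
    "ModelRun",
    "EnsembleResult",
    "EnsembleEmptyError",
    "LEARNER_REGISTRY",
    "DEFAULT_LEARNERS",
    "FULL_LEARNERS",
    "generate_pseudo_absences",
    "auc_score",
    "threshold_roc_corner",
    "tss_score",
    "fit_and_evaluate",
    "build_ensemble",
    "variable_importance",
    "response_curve",
    "project_model",
]


class EnsembleEmptyError(RuntimeError):
    """No member model passed the AUC filter: no ensemble can be built."""


# ---------------------------------------------------------------------------
# pseudo-absences
# ---------------------------------------------------------------------------

@dataclass
class PseudoAbsenceSet:
    set_id: int
    cells: list[tuple[int, int]]
    seed: int


def generate_pseudo_absences(
    grid: RasterGrid,
    presence_cells: Sequence[tuple[int, int]],
    n_sets: int = 30,
    seed: int = 0,
    min_distance: float | None = None,
    max_rounds: int = 200,
) -> list[PseudoAbsenceSet]:
    """Seeded random pseudo-absence sets on unoccupied valid cells.

    Each set has exactly as many cells as there are presences, never
    overlaps the presences, and keeps all pairwise center distances
    ≥ ``min_distance`` (default: one grain, i.e. the grid cell size).
    """
    if min_distance is None:
        min_distance = grid.cell_size
    presences = set(map(tuple, presence_cells))
    n_needed = len(presences)
    valid = grid.valid_mask
    pool = [(r, c) for r in range(grid.shape[0]) for c in range(grid.shape[1])
            if valid[r, c] and (r, c) not in presences]
    if len(pool) < n_needed:
        raise ValueError(
            f"only {len(pool)} unoccupied cells for {n_needed} pseudo-absences"
        )
    pool_arr = np.array(pool)
    min_d2 = (min_distance / grid.cell_size) ** 2  # distances in cell units
    rng = np.random.default_rng(seed)
    sets: list[PseudoAbsenceSet] = []
    for set_id in range(n_sets):
        set_seed = int(rng.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(set_seed)
        chosen: list[tuple[int, int]] | None = None
        for _ in range(max_rounds):
            order = sub_rng.permutation(len(pool_arr))
            picked: list[np.ndarray] = []
            for idx in order:
                cand = pool_arr[idx]
                if min_d2 > 1.0 and any(
                    ((cand - p) ** 2).sum() < min_d2 - 1e-9 for p in picked
                ):
                    continue
                picked.append(cand)
                if len(picked) == n_needed:
                    break
            if len(picked) == n_needed:
                chosen = [(int(r), int(c)) for r, c in picked]
                break
        if chosen is None:
            raise RuntimeError(
                f"could not place {n_needed} pseudo-absences at min distance "
                f"{min_distance} km after {max_rounds} rounds (binding constraint: "
                "minimum pairwise distance)"
            )
        sets.append(PseudoAbsenceSet(set_id=set_id, cells=sorted(chosen), seed=set_seed))
    return sets


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank (Mann–Whitney U) formulation, tie-corrected."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def threshold_roc_corner(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold minimising the distance from the ROC curve to (0, 1).

    Candidate thresholds are the midpoints of consecutive sorted unique
    scores; ties in the distance are broken toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to choose a threshold")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("all scores equal: no discriminating threshold exists")
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best_tau, best_d = None, np.inf
    for tau in cands:  # ascending: first strict improvement keeps the lowest tie
        sens = float((pos >= tau).mean())
        spec = float((neg < tau).mean())
        d = np.hypot(1.0 - sens, 1.0 - spec)
        if d < best_d - 1e-15:
            best_d, best_tau = d, float(tau)
    return best_tau


def tss_score(scores: np.ndarray, labels: np.ndarray, tau: float) -> float:
    """True Skill Statistic = sensitivity + specificity − 1 at threshold τ."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("TSS needs both classes")
    return float((pos >= tau).mean() + (neg < tau).mean() - 1.0)


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------

class SurfaceRangeEnvelope:
    """Rectilinear presence envelope on per-predictor quantiles.

    A cell is fully suitable iff every predictor lies within the
    [q, 1−q] presence quantiles (default q = 0.025); the returned score
    is the fraction of predictors inside their interval, which grades the
    envelope so that ROC-based evaluation remains meaningful.
    """

    def __init__(self, quantile: float = 0.025):
        self.quantile = quantile
        self.lo_: np.ndarray | None = None
        self.hi_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SurfaceRangeEnvelope":
        X = np.asarray(X, dtype=float)
        pres = X[np.asarray(y) == 1]
        if len(pres) == 0:
            raise ValueError("surface range envelope needs presence records")
        self.lo_ = np.quantile(pres, self.quantile, axis=0)
        self.hi_ = np.quantile(pres, 1.0 - self.quantile, axis=0)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        inside = (X >= self.lo_) & (X <= self.hi_)
        p1 = inside.mean(axis=1)
        return np.column_stack([1.0 - p1, p1])


def _make_learner(name: str, seed: int):
    rs = seed % (2**31 - 1)
    if name == "glm":
        return make_pipeline(StandardScaler(), PolynomialFeatures(2, include_bias=False),
                             LogisticRegression(max_iter=500))
    if name == "glm_ridge":
        return make_pipeline(StandardScaler(), LogisticRegression(C=0.2, max_iter=500))
    if name == "gam":
        return make_pipeline(StandardScaler(),
                             SplineTransformer(n_knots=4, degree=3),
                             LogisticRegression(max_iter=500))
    if name == "mars":
        return make_pipeline(StandardScaler(),
                             SplineTransformer(n_knots=5, degree=1),
                             LogisticRegression(max_iter=500))
    if name == "cart":
        return DecisionTreeClassifier(min_samples_leaf=5, random_state=rs)
    if name == "rf":
        return RandomForestClassifier(n_estimators=50, min_samples_leaf=2, random_state=rs)
    if name == "gbm":
        return GradientBoostingClassifier(n_estimators=50, max_depth=2, random_state=rs)
    if name == "ann":
        return make_pipeline(StandardScaler(),
                             MLPClassifier(hidden_layer_sizes=(8,), max_iter=2000,
                                           random_state=rs))
    if name == "fda":
        return make_pipeline(StandardScaler(), PolynomialFeatures(2, include_bias=False),
                             LinearDiscriminantAnalysis())
    if name == "sre":
        return SurfaceRangeEnvelope()
    raise KeyError(f"unknown learner {name!r}")


LEARNER_REGISTRY: dict[str, Callable[[int], object]] = {
    name: (lambda seed, _n=name: _make_learner(_n, seed))
    for name in ("glm", "glm_ridge", "gam", "mars", "cart", "rf", "gbm", "ann", "fda", "sre")
}

FULL_LEARNERS = tuple(LEARNER_REGISTRY)          # the 10-technique registry
DEFAULT_LEARNERS = ("glm", "cart", "rf", "sre")  # desk-scale default


# ---------------------------------------------------------------------------
# fitting and evaluation
# ---------------------------------------------------------------------------

@dataclass
class ModelRun:
    learner: str
    pa_set_id: int
    run_id: int
    auc: float
    tss: float
    threshold: float
    calib_idx: np.ndarray
    eval_idx: np.ndarray
    model: object
    feature_names: tuple[str, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X, dtype=float))[:, 1]


def _stratified_split(y: np.ndarray, eval_fraction: float, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    eval_idx: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_eval = max(1, int(round(eval_fraction * idx.size)))
        eval_idx.extend(rng.choice(idx, size=n_eval, replace=False))
    eval_idx = np.sort(np.array(eval_idx))
    calib_idx = np.setdiff1d(np.arange(y.size), eval_idx)
    return calib_idx, eval_idx


def fit_and_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    learner: str,
    split_seed: int,
    feature_names: Sequence[str] = (),
    pa_set_id: int = 0,
    run_id: int = 0,
    eval_fraction: float = 0.2,
    max_retries: int = 20,
) -> ModelRun:
    """Fit one learner on an 80/20 split and score the held-out records."""
    if learner not in LEARNER_REGISTRY:
        raise KeyError(f"learner {learner!r} not registered")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(split_seed)
    for attempt in range(max_retries):
        calib_idx, eval_idx = _stratified_split(y, eval_fraction, rng)
        if len(np.unique(y[calib_idx])) == 2 and len(np.unique(y[eval_idx])) == 2:
            break
    else:
        raise RuntimeError("could not obtain a two-class 80/20 split")

    model = LEARNER_REGISTRY[learner](split_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X[calib_idx], y[calib_idx])
        scores = model.predict_proba(X[eval_idx])[:, 1]
    auc = auc_score(scores, y[eval_idx])
    if np.unique(scores).size < 2:
        tau, tss = 0.5, 0.0   # non-discriminating model
    else:
        tau = threshold_roc_corner(scores, y[eval_idx])
        tss = tss_score(scores, y[eval_idx], tau)
    return ModelRun(
        learner=learner, pa_set_id=pa_set_id, run_id=run_id,
        auc=auc, tss=tss, threshold=tau,
        calib_idx=calib_idx, eval_idx=eval_idx,
        model=model, feature_names=tuple(feature_names),
    )


def project_model(run_or_predict, stack, names: Sequence[str]) -> RasterGrid:
    """Project a fitted model over a predictor stack into a suitability map."""
    grid = stack.grid()
    valid = np.ones(grid.shape, dtype=bool)
    for n in names:
        valid &= np.isfinite(stack[n].data)
    cells = np.argwhere(valid)
    X = stack.features_at([tuple(rc) for rc in cells], names)
    predict = run_or_predict.predict if hasattr(run_or_predict, "predict") else run_or_predict
    p = predict(X)
    out = np.full(grid.shape, np.nan)
    out[cells[:, 0], cells[:, 1]] = p
    return grid.with_data(out)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    members: list[ModelRun]
    auc_median: float
    auc_iqr: float
    tss_median: float
    tss_iqr: float
    continuous: RasterGrid
    binary: RasterGrid
    threshold: float
    ensemble_auc: float                       # the median map's own held-out AUC
    importance: dict[str, float] = field(default_factory=dict)
    contributions: dict[str, float] = field(default_factory=dict)
    response_curves: dict[str, np.ndarray] = field(default_factory=dict)
    feature_names: tuple[str, ...] = ()

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Cellwise-median prediction over member models."""
        preds = np.stack([m.predict(X) for m in self.members])
        return np.median(preds, axis=0)

    def top_contributions(self, threshold: float = 0.1) -> dict[str, float]:
        """Predictors whose normalised contribution exceeds the report cut."""
        return {k: v for k, v in sorted(self.contributions.items(),
                                        key=lambda kv: -kv[1]) if v > threshold}


def build_ensemble(
    runs: Sequence[ModelRun],
    member_maps: Sequence[RasterGrid],
    X_pooled: np.ndarray,
    y_pooled: np.ndarray,
    auc_threshold: float = 0.7,
    stat: str = "median",
) -> EnsembleResult:
    """Combine member runs passing the AUC filter into an ensemble.

    ``X_pooled``/``y_pooled`` are the pooled presence + pseudo-absence
    records used to choose the ensemble binarisation threshold from the
    ensemble's own scores.
    """
    if len(runs) != len(member_maps):
        raise ValueError("one projection map per run required")
    keep = [(r, m) for r, m in zip(runs, member_maps) if r.auc >= auc_threshold]
    if not keep:
        raise EnsembleEmptyError(
            f"no model reached AUC >= {auc_threshold}; no ensemble built"
        )
    members = [r for r, _ in keep]
    maps = [m for _, m in keep]
    for m in maps[1:]:
        maps[0].require_same_grid(m)
    cube = np.stack([m.data for m in maps])
    if stat == "median":
        cont = np.median(cube, axis=0)
    elif stat == "mean":
        cont = np.mean(cube, axis=0)
    else:
        raise ValueError(f"unknown ensemble statistic {stat!r}")
    continuous = maps[0].with_data(cont)

    aucs = np.array([r.auc for r in members])
    tsss = np.array([r.tss for r in members])
    q1a, q3a = np.percentile(aucs, [25, 75])
    q1t, q3t = np.percentile(tsss, [25, 75])

    ens = EnsembleResult(
        members=members,
        auc_median=float(np.median(aucs)), auc_iqr=float(q3a - q1a),
        tss_median=float(np.median(tsss)), tss_iqr=float(q3t - q1t),
        continuous=continuous, binary=continuous,  # placeholder until thresholded
        threshold=0.5, ensemble_auc=float("nan"),
        feature_names=members[0].feature_names,
    )
    scores = ens.predict(np.asarray(X_pooled, dtype=float))
    ens.ensemble_auc = auc_score(scores, y_pooled)
    if np.unique(scores).size >= 2:
        ens.threshold = threshold_roc_corner(scores, y_pooled)
    ens.binary = continuous.with_data(
        np.where(np.isfinite(cont), (cont >= ens.threshold).astype(float), np.nan)
    )
    return ens


# ---------------------------------------------------------------------------
# importance and response curves
# ---------------------------------------------------------------------------

def variable_importance(
    predict: Callable[[np.ndarray], np.ndarray] | EnsembleResult | ModelRun,
    X: np.ndarray,
    n_permutations: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation importance in [0, 1] and contributions summing to 1.

    importanceⱼ = mean over permutations of 1 − |Pearson r| between the
    reference predictions and the predictions with column j shuffled.
    A constant reference prediction has undefined correlation; every
    importance is then reported as 0 with a warning.
    """
    if hasattr(predict, "predict"):
        predict = predict.predict  # ModelRun / EnsembleResult
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    ref = np.asarray(predict(X), dtype=float)
    p = X.shape[1]
    imps = np.zeros(p)
    if np.ptp(ref) == 0:
        warnings.warn("constant predictions: importance undefined, reported as 0")
        return imps, (np.full(p, 1.0 / p) if p else imps)
    for j in range(p):
        vals = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            pred = np.asarray(predict(Xp), dtype=float)
            if np.ptp(pred) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(ref, pred)[0, 1])
            vals.append(1.0 - abs(r))
        imps[j] = float(np.clip(np.mean(vals), 0.0, 1.0))
    total = imps.sum()
    contrib = imps / total if total > 0 else np.full(p, 1.0 / p)
    return imps, contrib


def response_curve(
    predict: Callable[[np.ndarray], np.ndarray] | EnsembleResult | ModelRun,
    X: np.ndarray,
    feature_names: Sequence[str],
    focal: str,
    n_points: int = 50,
) -> np.ndarray:
    """(n_points, 2) sweep of suitability along one predictor.

    The focal predictor spans its observed range; all other predictors
    are held at their median.
    """
    if hasattr(predict, "predict"):
        predict = predict.predict
    names = list(feature_names)
    if focal not in names:
        raise KeyError(f"unknown predictor {focal!r}")
    X = np.asarray(X, dtype=float)
    j = names.index(focal)
    sweep = np.linspace(X[:, j].min(), X[:, j].max(), n_points)
    base = np.median(X, axis=0)
    grid = np.tile(base, (n_points, 1))
    grid[:, j] = sweep
    return np.column_stack([sweep, np.asarray(predict(grid), dtype=float)])
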