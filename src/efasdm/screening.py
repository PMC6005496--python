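"""Predictor screening: collinearity filters and the sample-size cap.

Candidate predictors are reduced to a final per-model set with three
rules applied in order:

1. greedy de-correlation — candidates are visited in descending priority
   (by default the cross-validated AUC of a single-predictor logistic
   model) and a candidate is skipped if its Spearman |ρ| with any
   already-selected predictor is ≥ 0.8;
2. an iterative variance-inflation-factor (VIF) filter on the survivors,
   dropping the largest-VIF predictor until all VIF < 4;
3. truncation at the cap of ⌊m/5⌋ predictors, where m is the number of
   presence records (a rule of thumb limiting model complexity to the
   available sample).

An expert-override list may pin predictors that bypass the correlation
skip (they are still counted against the cap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .ensemble import auc_score

__all__ = [
    "ScreeningReport",
    "spearman_matrix",
    "vif",
    "iterative_vif_filter",
    "select_predictors",
    "single_predictor_auc",
    "predictor_cap",
]


def predictor_cap(m: int) -> int:
    """Maximum number of predictors for m presence records: ⌊m/5⌋."""
    return m // 5


@dataclass
class ScreeningReport:
    """Outcome of predictor screening, with per-candidate reasons."""

    spearman: pd.DataFrame            # candidates × candidates ρ matrix
    vif_values: dict[str, float]      # VIF of each *selected* predictor
    selected: list[str]
    cap: int
    m: int
    priorities: dict[str, float]
    exclusions: dict[str, str]        # name -> reason

    def validate(self) -> None:
        assert len(self.selected) <= self.cap, "cap exceeded"
        for i, a in enumerate(self.selected):
            for b in self.selected[:i]:
                rho = abs(self.spearman.loc[a, b])
                assert rho < 0.8 + 1e-12, f"|rho|({a},{b}) = {rho:.3f} >= 0.8"
        for name, v in self.vif_values.items():
            assert v < 4.0 + 1e-9, f"VIF({name}) = {v:.2f} >= 4"

    def to_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.spearman.to_csv(outdir / "spearman_matrix.csv")
        rows = []
        for name in self.spearman.index:
            rows.append({
                "predictor": name,
                "priority": self.priorities.get(name, np.nan),
                "selected": name in self.selected,
                "vif": self.vif_values.get(name, np.nan),
                "reason": self.exclusions.get(name, "selected" if name in self.selected else ""),
            })
        pd.DataFrame(rows).to_csv(outdir / "screening.csv", index=False)


def spearman_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman ρ (average ranks on ties), diagonal exactly 1.

    Constant columns make ρ undefined; they are flagged with an error
    rather than silently dropped.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 rows for rank correlation")
    const = [c for c in features.columns if features[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant columns have undefined rank correlation: {const}")
    if features.shape[1] == 1:
        rho = np.ones((1, 1))
    else:
        rho = stats.spearmanr(features.to_numpy(), axis=0).statistic
        if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=features.columns, columns=features.columns)


def vif(features: pd.DataFrame) -> dict[str, float]:
    """VIFⱼ = 1/(1−R²ⱼ) from regressing column j on all the others.

    Columns are standardized internally; an exactly collinear column
    reports ``inf``.
    """
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    if p == 1:
        return {features.columns[0]: 1.0}
    if n <= p:
        raise ValueError(f"need more rows ({n}) than columns ({p}) for VIF")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(features.columns, sd) if s == 0]
        raise ValueError(f"constant columns: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    out: dict[str, float] = {}
    for j, name in enumerate(features.columns):
        others = np.delete(Z, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, Z[:, j], rcond=None)
        resid = Z[:, j] - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(Z[:, j] @ Z[:, j])          # column is centered
        r2 = 1.0 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def iterative_vif_filter(features: pd.DataFrame, threshold: float = 4.0
                         ) -> tuple[list[str], dict[str, float]]:
    """Drop the largest-VIF column until every VIF < threshold.

    Returns (surviving names in original order, their final VIFs).
    """
    cols = list(features.columns)
    while len(cols) > 1:
        v = vif(features[cols])
        worst = max(cols, key=lambda c: v[c])
        if v[worst] < threshold:
            return cols, v
        cols.remove(worst)
    return cols, {c: 1.0 for c in cols}


def single_predictor_auc(
    x: np.ndarray, y: np.ndarray, n_splits: int = 4, seed: int = 0
) -> float:
    """Cross-validated AUC of a one-predictor logistic model (priority score)."""
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=int)
    sd = x.std()
    if sd == 0:
        return 0.5
    z = (x - x.mean()) / sd
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in cv.split(z, y):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            continue
        model = LogisticRegression(max_iter=200).fit(z[tr], y[tr])
        scores = model.predict_proba(z[te])[:, 1]
        aucs.append(auc_score(scores, y[te]))
    return float(np.mean(aucs)) if aucs else 0.5


def select_predictors(
    features: pd.DataFrame,
    m: int,
    priority_scores: Mapping[str, float],
    rho_threshold: float = 0.8,
    vif_threshold: float = 4.0,
    pinned: Sequence[str] = (),
    max_predictors: int | None = None,
) -> ScreeningReport:
    """Apply the correlation, VIF and sample-size rules to the candidates.

    Parameters
    ----------
    features
        Candidate predictor values at the cells the models will see
        (presences plus the first pseudo-absence set).
    m
        Number of presence records; the cap is ⌊m/5⌋.
    priority_scores
        Per-candidate priority (higher is better); must cover all
        candidates.
    pinned
        Expert-override names selected first, bypassing the correlation
        skip (still subject to the cap).
    max_predictors
        Optional hard ceiling on the number of selected predictors in
        addition to the ⌊m/5⌋ rule (final model sets are conventionally
        held to six predictors regardless of sample size).
    """
    candidates = list(features.columns)
    if not candidates:
        raise ValueError("no candidate predictors")
    cap = predictor_cap(m)
    if max_predictors is not None:
        cap = min(cap, max_predictors)
    if cap < 1:
        raise ValueError(
            f"m={m} presence records allow no predictors (cap {cap}); "
            "need at least 5 records"
        )
    missing = [c for c in candidates if c not in priority_scores]
    if missing:
        raise ValueError(f"priority scores missing for: {missing}")

    rho = spearman_matrix(features)
    exclusions: dict[str, str] = {}

    order = sorted(candidates, key=lambda c: (-priority_scores[c], c))
    selected: list[str] = [p for p in pinned if p in candidates]
    for name in order:
        if name in selected:
            continue
        clash = next(
            (s for s in selected if abs(rho.loc[name, s]) >= rho_threshold), None
        )
        if clash is not None:
            exclusions[name] = f"|rho| >= {rho_threshold} with {clash}"
            continue
        selected.append(name)

    # VIF filter, priority-aware: among the over-threshold columns the
    # lowest-priority one is dropped first (of highly collinear predictors,
    # the more relevant one is kept)
    while len(selected) > 1:
        v = vif(features[selected])
        flagged = [c for c in selected if v[c] >= vif_threshold]
        if not flagged:
            break
        drop = min(flagged, key=lambda c: (priority_scores[c], c))
        exclusions[drop] = f"VIF >= {vif_threshold}"
        selected.remove(drop)
    # re-rank pinned+survivors by priority before applying the cap
    selected = sorted(selected, key=lambda c: (-priority_scores[c], c))
    for name in selected[cap:]:
        exclusions[name] = f"over cap {cap} (m={m})"
    selected = selected[:cap]
    vif_final = vif(features[selected]) if len(selected) > 1 else {
        s: 1.0 for s in selected
    }

    report = ScreeningReport(
        spearman=rho,
        vif_values=vif_final,
        selected=selected,
        cap=cap,
        m=m,
        priorities=dict(priority_scores),
        exclusions=exclusions,
    )
    report.validate()
    return report
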