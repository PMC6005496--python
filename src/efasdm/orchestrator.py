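"""The multi-scale experiment driver.

``run_experiment`` executes the full matrix — nested extents × grains ×
predictor groups — over one synthetic landscape and one virtual species:

    generate landscape → EFA / bioclim / landscape-metric derivation →
    aggregation to each (extent, grain) analysis grid → per-group
    predictor screening → pseudo-absences → model runs → ensembles →
    pairwise map comparison

and emits a comparative report: a performance table (best ensemble per
group with AUC/TSS medians ± IQR and top contributing predictors) and a
map-agreement table (fuzzy kappa, Spearman ρ, Moran's I, overlay areas)
comparing the best traditional (CLI / LC / CLI+LC) projection against
the EFA-based one for every scale combination.

The nested extents mimic a sub-continental / regional / local design:
the full landscape plays the sub-continental window and the regional and
local windows are placed where the virtual species is densest (as a
protected area is placed around a species stronghold), preserving strict
nesting.  Every stage derives its random seed from the master seed by
stable hashing of the combination label, so a rerun with the same
configuration is byte-identical.

Two experiment harnesses used in validation live here as well:
``recovery_trial`` (can screening + ensembles recover the true drivers
of a virtual species from the 24 EFA candidates?) and ``h1_trial``
(does an EFA-based ensemble match a climate+land-cover ensemble when the
satellite dynamics are climate-driven?).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .efa import compute_efa_stack, efa_names
from .ensemble import (
    DEFAULT_LEARNERS,
    EnsembleEmptyError,
    EnsembleResult,
    build_ensemble,
    fit_and_evaluate,
    generate_pseudo_absences,
    project_model,
    response_curve,
    variable_importance,
)
from .grids import RasterGrid
from .mapcompare import compare_maps
from .predictors import (
    CLI_NAMES,
    PredictorStack,
    aggregate_to_grid,
    derive_bioclim,
    landscape_metrics,
)
from .screening import select_predictors, single_predictor_auc
from .synthetic import (
    LandscapeBundle,
    LandscapeConfig,
    OccurrenceTable,
    VirtualSpecies,
    define_virtual_species,
    generate_landscape,
    sample_occurrences,
)

__all__ = [
    "ExperimentConfig",
    "ComparativeReport",
    "derive_seed",
    "aggregate_occurrences",
    "build_predictor_stack",
    "fit_group_ensemble",
    "run_experiment",
    "recovery_trial",
    "h1_trial",
]

GROUPS = ("CLI", "LC", "CLI+LC", "EFAs")
_GROUP_MEMBERS = {"CLI": ("CLI",), "LC": ("LC",), "CLI+LC": ("CLI", "LC"), "EFAs": ("EFAs",)}


def derive_seed(master: int, *labels) -> int:
    """Stable per-stage seed below 2³¹, derived from the master seed."""
    h = zlib.crc32("|".join(map(str, labels)).encode())
    return int((h ^ (master * 2654435761)) % (2**31 - 1))


# ---------------------------------------------------------------------------
# occurrences on analysis grids
# ---------------------------------------------------------------------------

def aggregate_occurrences(records: pd.DataFrame, grid: RasterGrid,
                          species: str = "virtual") -> OccurrenceTable:
    """Bin point records into grid cells, one presence per occupied cell.

    Records outside the grid extent are dropped; the count of dropped
    records is available as ``table.n_dropped``.
    """
    cells: set[tuple[int, int]] = set()
    kept_rows = []
    n_dropped = 0
    for _, rec in records.iterrows():
        cell = grid.cell_of_point(float(rec["x"]), float(rec["y"]))
        if cell is None:
            n_dropped += 1
            continue
        cells.add(cell)
        kept_rows.append(rec)
    kept = pd.DataFrame(kept_rows, columns=records.columns).reset_index(drop=True)
    table = OccurrenceTable(species=species, grid=grid, records=kept, cells=sorted(cells))
    table.n_dropped = n_dropped
    return table


# ---------------------------------------------------------------------------
# predictor derivation per (extent, grain)
# ---------------------------------------------------------------------------

def build_predictor_stack(
    bundle: LandscapeBundle,
    window: tuple[int, int, int, int],
    grain_factor: int,
    efa_fine: Mapping[str, RasterGrid] | None = None,
) -> PredictorStack:
    """CLI + LC + EFA predictors on one analysis grid.

    ``window`` is (row0, col0, nrows, ncols) on the fine grid;
    ``grain_factor`` is the number of fine cells per analysis-cell edge.
    """
    r0, c0, nr, nc = window
    if nr % grain_factor or nc % grain_factor:
        raise ValueError("window not divisible by the grain factor")

    def win(g: RasterGrid) -> RasterGrid:
        return g.window(r0, c0, nr, nc)

    stack = PredictorStack()

    # CLI: derive at fine grain inside the window, then block-average
    bio = derive_bioclim(
        [win(g) for g in bundle.monthly_tmean],
        [win(g) for g in bundle.monthly_tmax],
        [win(g) for g in bundle.monthly_tmin],
        [win(g) for g in bundle.monthly_precip],
    )
    for name, g in bio.as_dict().items():
        stack.add(name, aggregate_to_grid(g, grain_factor), "CLI")

    # LC: from the sub-fine land cover at the analysis grain
    s = bundle.config.landcover_subfactor
    lc_win = bundle.landcover.window(r0 * s, c0 * s, nr * s, nc * s)
    lc = landscape_metrics(lc_win, bundle.landcover_classes, factor=grain_factor * s)
    for name, g in lc.items():
        stack.add(name, g, "LC")

    # EFAs: interannual metrics at fine grain, then block-average
    if efa_fine is None:
        efa_fine = compute_efa_stack(bundle.satellite)
    for name, g in efa_fine.items():
        stack.add(name, aggregate_to_grid(win(g), grain_factor), "EFAs")
    return stack


# ---------------------------------------------------------------------------
# one group x combination ensemble
# ---------------------------------------------------------------------------

@dataclass
class GroupResult:
    group: str
    selected: list[str]
    m: int
    ensemble: EnsembleResult
    n_runs_total: int


def fit_group_ensemble(
    stack: PredictorStack,
    occurrences: OccurrenceTable,
    group: str,
    n_pa_sets: int,
    n_runs: int,
    learners: Sequence[str],
    seed: int,
    compute_importance: bool = True,
    max_predictors: int | None = 6,
) -> GroupResult:
    """Screen predictors and fit the full run matrix for one group."""
    grid = stack.grid()
    presences = occurrences.cells
    m = len(presences)
    candidates = stack.names_in_groups(_GROUP_MEMBERS[group])

    pa_sets = generate_pseudo_absences(
        grid, presences, n_sets=n_pa_sets, seed=derive_seed(seed, group, "pa")
    )

    # screening on the cells the models see: presences + first PA set
    screen_cells = list(presences) + list(pa_sets[0].cells)
    y_screen = np.array([1] * m + [0] * len(pa_sets[0].cells))
    feats = pd.DataFrame(stack.features_at(screen_cells, candidates), columns=candidates)
    usable = [c for c in candidates if feats[c].nunique() > 1]
    feats = feats[usable]
    priorities = {
        c: single_predictor_auc(feats[c].to_numpy(), y_screen,
                                seed=derive_seed(seed, group, "prio", c))
        for c in usable
    }
    report = select_predictors(feats, m=m, priority_scores=priorities,
                               max_predictors=max_predictors)
    selected = report.selected

    runs, maps = [], []
    for pa in pa_sets:
        cells = list(presences) + list(pa.cells)
        y = np.array([1] * m + [0] * len(pa.cells))
        X = stack.features_at(cells, selected)
        for run_id in range(n_runs):
            for learner in learners:
                run = fit_and_evaluate(
                    X, y, learner,
                    split_seed=derive_seed(seed, group, pa.set_id, run_id, learner),
                    feature_names=selected, pa_set_id=pa.set_id, run_id=run_id,
                )
                runs.append(run)
                maps.append(project_model(run, stack, selected))

    X_pooled = stack.features_at(
        list(presences) + [c for pa in pa_sets for c in pa.cells], selected
    )
    y_pooled = np.array([1] * m + [0] * (len(pa_sets) * m))
    ens = build_ensemble(runs, maps, X_pooled, y_pooled)
    if compute_importance:
        imps, contribs = variable_importance(
            ens, stack.features_at(list(presences) + list(pa_sets[0].cells), selected),
            n_permutations=5, seed=derive_seed(seed, group, "imp"),
        )
        ens.importance = dict(zip(selected, map(float, imps)))
        ens.contributions = dict(zip(selected, map(float, contribs)))
        for name, contrib in ens.contributions.items():
            if contrib > 0.1:
                ens.response_curves[name] = response_curve(
                    ens, X_pooled, selected, name
                )
    return GroupResult(group=group, selected=selected, m=m, ensemble=ens,
                       n_runs_total=len(runs))


# ---------------------------------------------------------------------------
# experiment configuration and report
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """The full experiment matrix at desk scale.

    Extents are nested square windows on the fine grid (cells per edge);
    the regional and local windows are auto-placed over the species'
    densest area.  ``combos`` pairs extent names with grain factors
    (fine cells per analysis-cell edge), defaulting to the four
    sub-continental/regional/local × 5 km/1 km combinations.
    """

    landscape: LandscapeConfig = field(default_factory=lambda: LandscapeConfig(seed=1))
    species_name: str = "virtual"
    driver_names: tuple[str, ...] = ("TmWQ", "forest")
    driver_coefficients: tuple[float, ...] = (-2.0, 1.5)
    prevalence: float = 0.15
    n_records: int = 80
    extent_cells: Mapping[str, int] = field(
        default_factory=lambda: {"IP": 60, "NW": 40, "NP": 20})
    combos: tuple[tuple[str, int], ...] = (("IP", 5), ("NW", 5), ("NW", 1), ("NP", 1))
    groups: tuple[str, ...] = GROUPS
    n_pa_sets: int = 5
    n_runs: int = 5
    learners: tuple[str, ...] = DEFAULT_LEARNERS
    seed: int = 1
    outdir: str | None = None

    def __post_init__(self) -> None:
        sizes = list(self.extent_cells.values())
        if sizes != sorted(sizes, reverse=True):
            raise ValueError("extents must be ordered from largest to smallest")
        for name, grain in self.combos:
            if name not in self.extent_cells:
                raise ValueError(f"unknown extent {name!r}")
            if self.extent_cells[name] % grain:
                raise ValueError(f"extent {name} not divisible by grain {grain}")


@dataclass
class ComparativeReport:
    performance: pd.DataFrame      # per combination x group scores + top variables
    comparisons: pd.DataFrame      # pairwise map agreement per combination
    manifest: dict
    occurrences: dict[str, int]    # presence cells per combination
    failures: dict[str, str]

    def validate(self) -> None:
        for _, row in self.performance.iterrows():
            assert row["auc_median"] >= 0.7 or np.isnan(row["auc_median"])
        for col in ("top_var_contribution",):
            vals = self.performance[col].dropna()
            assert (vals > 0.1).all(), "reported contributions must exceed 0.1"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.6g"
        self.performance.to_csv(outdir / "performance.csv", index=False, float_format=fmt)
        self.comparisons.to_csv(outdir / "map_comparisons.csv", index=False, float_format=fmt)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))


def _nested_windows(config: ExperimentConfig, truth: RasterGrid
                    ) -> dict[str, tuple[int, int, int, int]]:
    """Place the nested extent windows, densest-truth-first, on a 5-cell lattice."""
    names = list(config.extent_cells)
    sizes = [config.extent_cells[n] for n in names]
    windows: dict[str, tuple[int, int, int, int]] = {}
    prev = (0, 0, truth.shape[0], truth.shape[1])
    for name, size in zip(names, sizes):
        pr, pc, pnr, pnc = prev
        if size >= pnr and size >= pnc:
            windows[name] = prev
            continue
        best, best_sum = None, -np.inf
        step = 5  # keeps 5 km alignment for every nested window
        for r0 in range(pr, pr + pnr - size + 1, step):
            for c0 in range(pc, pc + pnc - size + 1, step):
                s = np.nansum(truth.data[r0:r0 + size, c0:c0 + size])
                if s > best_sum:
                    best_sum, best = s, (r0, c0, size, size)
        windows[name] = best
        prev = best
    return windows


def run_experiment(config: ExperimentConfig) -> ComparativeReport:
    """Run the full experiment matrix and build the comparative report."""
    bundle = generate_landscape(config.landscape)
    efa_fine = compute_efa_stack(bundle.satellite)

    # species truth on the full fine grid (1 km grain)
    full = (0, 0, config.landscape.nrows, config.landscape.ncols)
    fine_stack = build_predictor_stack(bundle, full, 1, efa_fine=efa_fine)
    species = define_virtual_species(
        fine_stack, config.driver_names, config.driver_coefficients,
        prevalence_target=config.prevalence,
    )
    occurrences = sample_occurrences(
        species, config.n_records, seed=derive_seed(config.seed, "occ"),
        species_name=config.species_name,
    )
    windows = _nested_windows(config, species.truth_map)

    perf_rows, comp_rows = [], []
    occ_counts: dict[str, int] = {}
    failures: dict[str, str] = {}
    run_counts: dict[str, int] = {}

    for extent, grain in config.combos:
        combo = f"{extent}-{grain}km"
        window = windows[extent]
        stack = build_predictor_stack(bundle, window, grain, efa_fine=efa_fine)
        occ = aggregate_occurrences(occurrences.records, stack.grid(),
                                    species=config.species_name)
        occ_counts[combo] = occ.n_cells
        group_results: dict[str, GroupResult] = {}
        for group in config.groups:
            try:
                gr = fit_group_ensemble(
                    stack, occ, group,
                    n_pa_sets=config.n_pa_sets, n_runs=config.n_runs,
                    learners=config.learners,
                    seed=derive_seed(config.seed, combo, group),
                )
            except (ValueError, RuntimeError, EnsembleEmptyError) as exc:
                failures[f"{combo}/{group}"] = str(exc)
                continue
            group_results[group] = gr
            run_counts[f"{combo}/{group}"] = gr.n_runs_total
            ens = gr.ensemble
            top = ens.top_contributions(0.1)
            top_var = next(iter(top), None)
            perf_rows.append({
                "combination": combo, "extent": extent, "grain_km": grain,
                "group": group, "m": gr.m, "n_members": len(ens.members),
                "auc_median": ens.auc_median, "auc_iqr": ens.auc_iqr,
                "tss_median": ens.tss_median, "tss_iqr": ens.tss_iqr,
                "ensemble_auc": ens.ensemble_auc,
                "top_var": top_var,
                "top_var_contribution": top.get(top_var, np.nan),
                "top_vars_gt_0.1": ";".join(top),
                "selected": ";".join(gr.selected),
            })

        # map agreement: best traditional group vs the EFA-based projection
        if "EFAs" in group_results:
            trad = [g for g in ("CLI", "LC", "CLI+LC") if g in group_results]
            if trad:
                best = max(trad, key=lambda g: group_results[g].ensemble.auc_median)
                ea, eb = group_results[best].ensemble, group_results["EFAs"].ensemble
                rep = compare_maps(ea.continuous, eb.continuous, ea.binary, eb.binary)
                pct = rep.overlay.percentages()
                comp_rows.append({
                    "combination": combo, "model_a": best, "model_b": "EFAs",
                    "fuzzy_kappa": rep.fuzzy_kappa,
                    "spearman_rho": rep.spearman_rho, "spearman_p": rep.spearman_p,
                    "morans_i_a": rep.morans_i_a, "morans_i_b": rep.morans_i_b,
                    "area_a_only_km2": rep.overlay.area_a_only,
                    "area_b_only_km2": rep.overlay.area_b_only,
                    "area_overlaid_km2": rep.overlay.area_overlaid,
                    "area_total_km2": rep.overlay.area_total_union,
                    "pct_a_only": pct["a_only"], "pct_b_only": pct["b_only"],
                    "pct_overlaid": pct["overlaid"],
                })

    performance = pd.DataFrame(perf_rows)
    comparisons = pd.DataFrame(comp_rows)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "landscape_seed": config.landscape.seed,
        "n_records": config.n_records,
        "species_drivers": list(config.driver_names),
        "combos": [f"{e}-{g}km" for e, g in config.combos],
        "groups": list(config.groups),
        "run_design": {
            "n_pa_sets": config.n_pa_sets, "n_runs": config.n_runs,
            "learners": list(config.learners),
            "runs_per_group": config.n_pa_sets * config.n_runs * len(config.learners),
        },
        "run_counts": run_counts,
        "occurrence_cells": occ_counts,
        "failures": failures,
    }
    report = ComparativeReport(performance=performance, comparisons=comparisons,
                               manifest=manifest, occurrences=occ_counts,
                               failures=failures)
    if not performance.empty:
        report.validate()
    if config.outdir:
        report.write(config.outdir)
    return report


# ---------------------------------------------------------------------------
# validation harnesses
# ---------------------------------------------------------------------------

def recovery_trial(
    seed: int,
    nrows: int = 40,
    ncols: int = 40,
    driver_names: tuple[str, str] = ("EVIdmxs", "LSTmn"),
    coefficients: tuple[float, float] = (4.0, -4.0),
    n_records: int = 150,
    n_fresh: int = 60,
) -> dict:
    """One driver-recovery replicate on a virtual species with EFA drivers.

    The species' truth is a logistic function of two of the 24 EFA
    candidates (a spring-phenology axis and a thermal axis).  Returns
    whether screening kept both true drivers, whether they got the top-2
    normalised importance contributions, and the ensemble AUC on a fresh
    validation sample: new presences drawn ∝ truth and — since in the
    virtual world the truth is known — true absences drawn ∝ (1 − truth),
    neither seen during fitting.  Fitting itself remains presence-only.
    """
    cfg = LandscapeConfig(nrows=nrows, ncols=ncols, seed=derive_seed(seed, "land"),
                          landcover_subfactor=1)
    bundle = generate_landscape(cfg)
    efa = compute_efa_stack(bundle.satellite)
    stack = PredictorStack()
    stack.update(efa, "EFAs")

    species = define_virtual_species(stack, driver_names, coefficients,
                                     prevalence_target=0.2)
    occ_records = sample_occurrences(species, n_records,
                                     seed=derive_seed(seed, "occ")).records
    occ = aggregate_occurrences(occ_records, stack.grid())
    gr = fit_group_ensemble(
        stack, occ, "EFAs", n_pa_sets=2, n_runs=2, learners=("glm", "rf"),
        seed=derive_seed(seed, "fit"),
    )
    selected_ok = set(driver_names) <= set(gr.selected)
    top2 = sorted(gr.ensemble.contributions, key=gr.ensemble.contributions.get)[-2:]
    top2_ok = set(top2) == set(driver_names)

    # fresh validation: presences ∝ truth, true absences ∝ (1 − truth),
    # both excluding every cell used in fitting
    fresh = sample_occurrences(species, n_fresh, seed=derive_seed(seed, "fresh"))
    seen = set(occ.cells)
    fresh_cells = [c for c in fresh.cells if c not in seen]
    truth = species.truth_map.data
    rng = np.random.default_rng(derive_seed(seed, "freshabs"))
    excluded = seen | set(fresh_cells)
    pool = [(r, c) for r in range(truth.shape[0]) for c in range(truth.shape[1])
            if np.isfinite(truth[r, c]) and (r, c) not in excluded]
    w = np.array([1.0 - truth[r, c] for r, c in pool])
    idx = rng.choice(len(pool), size=len(fresh_cells), replace=False, p=w / w.sum())
    absent_cells = [pool[i] for i in idx]
    cells = fresh_cells + absent_cells
    y = np.array([1] * len(fresh_cells) + [0] * len(absent_cells))
    scores = gr.ensemble.predict(stack.features_at(cells, gr.selected))
    from .ensemble import auc_score
    fresh_auc = auc_score(scores, y)
    return {
        "selected_ok": bool(selected_ok),
        "top2_ok": bool(top2_ok),
        "fresh_auc": float(fresh_auc),
        "selected": gr.selected,
        "contributions": gr.ensemble.contributions,
    }


def h1_trial(
    seed: int,
    nrows: int = 40,
    ncols: int = 40,
    n_records: int = 80,
) -> dict:
    """One replicate of the EFA-vs-(CLI+LC) performance comparison.

    The landscape's satellite dynamics are climate- and land-cover-driven
    (the generator's defaults) and the species is driven by climate and
    forest cover, so functional attributes carry the same signal the
    traditional predictors do.  Returns the member-AUC medians of the
    EFA-based and the CLI+LC-based ensembles on one analysis grid.
    """
    cfg = LandscapeConfig(nrows=nrows, ncols=ncols, seed=derive_seed(seed, "land"))
    bundle = generate_landscape(cfg)
    stack = build_predictor_stack(bundle, (0, 0, nrows, ncols), 1)
    species = define_virtual_species(stack, ("TmWQ", "forest"), (-2.0, 1.5),
                                     prevalence_target=0.2)
    occ_records = sample_occurrences(species, n_records,
                                     seed=derive_seed(seed, "occ")).records
    occ = aggregate_occurrences(occ_records, stack.grid())
    out = {}
    for group in ("CLI+LC", "EFAs"):
        gr = fit_group_ensemble(
            stack, occ, group, n_pa_sets=2, n_runs=2, learners=("glm", "rf"),
            seed=derive_seed(seed, "fit", group), compute_importance=False,
        )
        out[group] = gr.ensemble.auc_median
    out["gap"] = out["CLI+LC"] - out["EFAs"]
    return out
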