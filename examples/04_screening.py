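"""Predictor screening: Spearman, VIF and the m/5 sample-size cap.

Candidates are ranked by single-predictor cross-validated AUC, then
de-correlated (|rho| < 0.8), VIF-filtered (< 4) and capped at m/5
predictors (at most six).
"""

import numpy as np
import pandas as pd

from efasdm import (
    LandscapeConfig,
    PredictorStack,
    compute_efa_stack,
    define_virtual_species,
    generate_landscape,
    generate_pseudo_absences,
    predictor_cap,
    sample_occurrences,
    select_predictors,
)
from efasdm.orchestrator import aggregate_occurrences
from efasdm.screening import single_predictor_auc

print(f"cap for 30 presence records: {predictor_cap(30)} predictors")

bundle = generate_landscape(LandscapeConfig(nrows=30, ncols=30, seed=21,
                                            landcover_subfactor=1))
stack = PredictorStack()
stack.update(compute_efa_stack(bundle.satellite), "EFAs")
species = define_virtual_species(stack, ("EVIdmxs", "LSTmn"), (4.0, -4.0),
                                 prevalence_target=0.2)
occ = aggregate_occurrences(sample_occurrences(species, 100, seed=3).records,
                            stack.grid())
pa = generate_pseudo_absences(stack.grid(), occ.cells, n_sets=1, seed=4)[0]

cells = list(occ.cells) + list(pa.cells)
y = np.array([1] * occ.n_cells + [0] * len(pa.cells))
feats = pd.DataFrame(stack.features_at(cells), columns=stack.names)
priorities = {c: single_predictor_auc(feats[c].to_numpy(), y) for c in feats}

report = select_predictors(feats, m=occ.n_cells, priority_scores=priorities,
                           max_predictors=6)
print(f"m={report.m} records -> cap {report.cap}; "
      f"selected {len(report.selected)} of {len(feats.columns)} candidates:")
for name in report.selected:
    print(f"  {name:8s} priority={priorities[name]:.3f} "
          f"VIF={report.vif_values[name]:.2f}")
ex = [f"{k} ({v})" for k, v in list(report.exclusions.items())[:3]]
print("example exclusions:", "; ".join(ex))
# the true drivers EVIdmxs and LSTmn should sit near the top of the list
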