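"""Generate a virtual landscape and a virtual species with known truth.

The landscape couples terrain, monthly climate, patchy land cover and
three satellite time series; the species' true suitability is a logistic
function of chosen predictors, so later recovery can be scored exactly.
"""

import numpy as np

from efasdm import (
    LandscapeConfig,
    build_predictor_stack,
    define_virtual_species,
    generate_landscape,
    sample_occurrences,
)

cfg = LandscapeConfig(nrows=40, ncols=40, seed=42)
bundle = generate_landscape(cfg)
bundle.validate()

print(f"elevation range: {bundle.elevation.data.min():.0f}-"
      f"{bundle.elevation.data.max():.0f} m")
jan, jul = bundle.monthly_tmean[0].data, bundle.monthly_tmean[6].data
print(f"mean temperature: January {jan.mean():.1f} degC, July {jul.mean():.1f} degC")
annual_precip = sum(g.data for g in bundle.monthly_precip)
print(f"annual precipitation: {annual_precip.min():.0f}-{annual_precip.max():.0f} mm")

days, evi = bundle.satellite["EVI"].as_array(0)
print(f"EVI composites in year 0: {len(days)} (16-day calendar), "
      f"values {evi.min():.2f}-{evi.max():.2f}")

# a cool-wet forest species: suitability falls with wet-quarter temperature
# and rises with forest cover
stack = build_predictor_stack(bundle, (0, 0, 40, 40), 1)
species = define_virtual_species(stack, ("TmWQ", "forest"), (-2.0, 1.5),
                                 prevalence_target=0.2)
print(f"virtual species prevalence: {species.prevalence:.3f} "
      f"(drivers: {', '.join(species.driver_names)})")

occ = sample_occurrences(species, 80, seed=7)
print(f"sampled {len(occ.records)} presence-only records "
      f"occupying {occ.n_cells} grid cells")
# the presences concentrate where the truth map is high; no absences exist
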