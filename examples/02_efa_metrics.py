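"""Ecosystem Functional Attributes from satellite time series.

Eight summary metrics (level, extremes, seasonality, phenology) per
satellite dimension, averaged across years: the 24 candidate predictors
of the EFA group.
"""

import numpy as np

from efasdm import LandscapeConfig, annual_metrics, compute_efa_stack, generate_landscape

bundle = generate_landscape(LandscapeConfig(nrows=30, ncols=30, seed=5, n_years=3))
stack = compute_efa_stack(bundle.satellite)
print(f"{len(stack)} EFA rasters: {', '.join(sorted(stack))}")

evi_av, evi_sd = stack["EVIav"].data, stack["EVIsd"].data
print(f"EVIav (productivity level) spans {evi_av.min():.2f}-{evi_av.max():.2f}; "
      f"EVIsd (seasonality) spans {evi_sd.min():.3f}-{evi_sd.max():.3f}")

# phenology: sine of the date of the annual EVI maximum; +1 means an
# early-April green-up peak, -1 an early-October one
dmxs = stack["EVIdmxs"].data
print(f"EVIdmxs (springiness axis) spans {dmxs.min():.2f}-{dmxs.max():.2f}")

# the same metrics for one hand-made series: a spring-peaking cell
days = list(range(1, 366, 16))
series = [(d, 0.3 + 0.25 * np.cos(2 * np.pi * (d - 113) / 365)) for d in days]
m = annual_metrics(series)
print(f"hand-made series peaking on day 113: mean={m['mean']:.2f}, "
      f"sin(date of max)={m['sin_dmax']:.2f} (near +1 -> spring green-up)")
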