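"""Bioclim-style climate predictors and per-cell landscape metrics.

Quarters are the 12 wrap-around 3-month windows; landscape metrics are
FRAGSTATS-style composition fractions, Shannon diversity and mean patch
area computed per analysis cell from a finer land-cover raster.
"""

import numpy as np

from efasdm import (
    LandscapeConfig,
    aggregate_to_grid,
    derive_bioclim,
    generate_landscape,
    landscape_metrics,
)

bundle = generate_landscape(LandscapeConfig(nrows=30, ncols=30, seed=9))

bio = derive_bioclim(bundle.monthly_tmean, bundle.monthly_tmax,
                     bundle.monthly_tmin, bundle.monthly_precip)
print(f"TmWQ (mean T of wettest quarter): {np.nanmean(bio.TmWQ.data):.1f} degC "
      f"-- winter-wet, so cooler than the annual mean")
print(f"PpWM/PpDM (wettest/driest month): {np.nanmean(bio.PpWM.data):.0f} / "
      f"{np.nanmean(bio.PpDM.data):.0f} mm")
print(f"PS (precipitation seasonality, CV%): {np.nanmean(bio.PS.data):.0f}")

lc = landscape_metrics(bundle.landcover, bundle.landcover_classes,
                       factor=bundle.config.landcover_subfactor)
shdi = lc["SHDI"].data
print(f"SHDI per 1 km cell: 0 (single class) to {np.nanmax(shdi):.2f} "
      f"(theoretical max ln 4 = {np.log(4):.2f})")
print(f"mean patch area: {np.nanmean(lc['AREAmean'].data):.2f} km2 per cell")

coarse = aggregate_to_grid(bio.TmWQ, 5)
print(f"TmWQ aggregated 1 km -> 5 km: grid {bio.TmWQ.shape} -> {coarse.shape}, "
      f"grand mean preserved ({np.nanmean(coarse.data):.2f} degC)")
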