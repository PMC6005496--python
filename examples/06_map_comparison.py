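"""Agreement between two habitat-suitability projections.

Fuzzy kappa tolerates near-miss locations (distance-decayed category
membership); Spearman rho compares the continuous maps; Moran's I gives
their spatial autocorrelation; overlay accounting splits the suitable
union into A-only / B-only / overlaid areas.
"""

import numpy as np

from efasdm import RasterGrid, compare_maps, fuzzy_kappa

rng = np.random.default_rng(31)
base = np.clip(np.add.outer(np.linspace(0, 1, 30), np.linspace(0, 1, 30)) / 2
               + rng.normal(0, 0.05, (30, 30)), 0, 1)
other = np.clip(base + rng.normal(0, 0.15, (30, 30)), 0, 1)
cont_a, cont_b = RasterGrid(base), RasterGrid(other)
bin_a = cont_a.with_data((base >= 0.5) * 1.0)
bin_b = cont_b.with_data((other >= 0.5) * 1.0)

rep = compare_maps(cont_a, cont_b, bin_a, bin_b)
print(f"fuzzy kappa {rep.fuzzy_kappa:.3f} (1 = identical, 0 = chance agreement)")
print(f"Spearman rho {rep.spearman_rho:.3f} (p = {rep.spearman_p:.1e})")
print(f"Moran's I: map A {rep.morans_i_a:.3f}, map B {rep.morans_i_b:.3f} "
      f"(both positive: smooth suitability surfaces)")
ov, pct = rep.overlay, rep.overlay.percentages()
print(f"overlay: A-only {ov.area_a_only:.0f} km2 ({pct['a_only']}%), "
      f"B-only {ov.area_b_only:.0f} km2 ({pct['b_only']}%), "
      f"overlaid {ov.area_overlaid:.0f} km2 ({pct['overlaid']}%), "
      f"union {ov.area_total_union:.0f} km2")

# a shifted map agrees poorly cell-by-cell but well within a tolerance
checker = (np.indices((20, 20)).sum(axis=0) % 2).astype(float)
shifted = np.roll(checker, 1, axis=1)
crisp = fuzzy_kappa(RasterGrid(checker), RasterGrid(shifted), radius=0)
fuzzy = fuzzy_kappa(RasterGrid(checker), RasterGrid(shifted), radius=4)
print(f"checkerboard vs its shift: Cohen's kappa {crisp:.2f}, "
      f"fuzzy kappa {fuzzy:.2f} -- distance tolerance rewards near-misses")
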