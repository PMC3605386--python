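"""Osmotic-stress series: kurtosis falls as buffer osmolarity rises.

Ten subjects are simulated at five buffer osmolarities (259-335
mosmol/kg).  Low osmolarity swells erythrocytes toward spheres (modes
merge, kurtosis near 0); high osmolarity restores the biconcave bimodal
shape (kurtosis falls).  The per-level means and the Friedman test with
adjusted pairwise comparisons are printed.
"""

import numpy as np

from fscshape import (
    OsmolarityScenario,
    excess_kurtosis,
    friedman_adjusted,
    simulate_osmolarity_series,
)

scenario = OsmolarityScenario(n_events=20_000, seed=42)
samples = simulate_osmolarity_series(scenario)
print(f"simulated {len(samples)} samples "
      f"({scenario.n_subjects} subjects x {len(scenario.osmolarities)} osmolarities)")

kurt = {}
for s in samples:
    kurt.setdefault(s.meta["subject"], {})[s.meta["osmolarity"]] = (
        excess_kurtosis(s.events))

osms = list(scenario.osmolarities)
print("\nosmolarity (mosmol/kg)   mean excess kurtosis")
for o in osms:
    vals = [kurt[subj][o] for subj in kurt]
    print(f"  {o:6.0f}                 {np.mean(vals):+.3f}")

matrix = np.array([[kurt[subj][o] for o in osms] for subj in sorted(kurt)])
res = friedman_adjusted(matrix, conditions=osms)
print(f"\nFriedman omnibus: chi2 = {res.chi2:.1f}, p = {res.p_value:.2e}")
print("adjusted pairwise comparisons (Bonferroni):")
for (a, b), p in res.pairwise:
    mark = "*" if p < 0.05 else " "
    print(f"  {a:.0f} vs {b:.0f}: p_adj = {p:.4f} {mark}")

print("\nMean kurtosis decreases monotonically with osmolarity — the")
print("direction expected if higher osmolarity dehydrates cells back")
print("toward the biconcave, bimodally scattering shape.")
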