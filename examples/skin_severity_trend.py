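"""Staged-severity skin phantom study (normal vs disordered dermis).

Simulates three-stratum skin phantoms whose dermal birefringence falls and
fast-axis disorder grows with a severity dial, runs the full
tomogram → maps → depth-profile → metrics chain for all four polarization
parameters, and compares the groups (one-way ANOVA + Welch t-tests against
the severity-0 group).
"""

import pandas as pd

from psoct import dm_trend_report

pd.set_option("display.width", 120)

table, comparisons = dm_trend_report(
    stages=[0.0, 0.5, 1.0], n_replicates=5, seed=7
)

print("Mean metrics per severity stage (retardation):")
sub = table[table.parameter == "retardation"]
print(
    sub.groupby("severity")[["num_peaks", "range_value", "avg_residual"]]
    .mean()
    .round(3)
)

print("\nGroup comparisons (p-values vs severity 0):")
cols = [c for c in comparisons.columns if not c.startswith("code|")]
print(comparisons[comparisons.parameter == "retardation"][cols].round(4))

print(
    "\nFalling peak counts and range with severity reproduce the loss of the\n"
    "layer-like dermal birefringence structure; DOPU is comparatively\n"
    "insensitive to this purely structural disorder."
)
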