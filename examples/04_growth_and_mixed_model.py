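"""Growth-curve AUC, gene-count association, and the CFU mixed model.

Simulates OD600 curves whose carrying capacity scales with the number
of sugar ABC transporters, computes trapezoidal AUCs, correlates them
with gene counts (Spearman), and fits the random-intercept linear
model of CFUs on gene presence/absence.
"""

import numpy as np
import pandas as pd

from sugartrait import (
    GrowthCurve,
    MixedModelDesign,
    curve_auc,
    fit_random_intercept_lmm,
    prevalence_gene_filter,
    spearman_assoc,
)

rng = np.random.default_rng(3)
t = np.arange(0, 72.5, 0.5)

abc_counts = rng.integers(0, 12, size=16)
aucs = []
for i, abc in enumerate(abc_counts):
    k = 0.3 + 0.1 * abc  # carrying capacity rises with ABC repertoire
    od = k / (1 + np.exp(-(t - 24) / 5)) + rng.normal(0, 0.01, len(t))
    aucs.append(curve_auc(GrowthCurve(f"s{i}", "GLU", t, np.clip(od, 0, None))))

rho, p = spearman_assoc(abc_counts, aucs)
print(f"Spearman rho between ABC gene counts and growth AUC: "
      f"{rho:.2f} (p={p:.2g})")

# mixed model: log10 CFU on gene presence with a repeat random intercept
n, reps = 24, 6
presence = pd.DataFrame(
    {
        "ABC": rng.integers(0, 2, n),
        "PTS": rng.integers(0, 2, n),
        "MFS": rng.integers(0, 2, n),
        "RPI": rng.integers(0, 2, n),
    }
)
print("genes passing the 25-75% prevalence filter:",
      prevalence_gene_filter(presence))

rows = pd.concat([presence] * reps, ignore_index=True)
group = np.repeat(np.arange(reps), n)
log_cfu = (
    5.0 + 2.0 * rows["ABC"] + 0.3 * rows["PTS"]
    + rng.normal(0, 0.4, reps)[group] + rng.normal(0, 0.5, len(rows))
)
design = MixedModelDesign(
    outcome=(10.0**log_cfu) - 1, predictors=rows, group=group
)
fit = fit_random_intercept_lmm(design)
print("\nfixed effects on log10(CFU+1):")
for name in fit.params.index:
    print(f"  {name:>5}: {fit.params[name]:+.2f} +- {fit.bse[name]:.2f} "
          f"(p={fit.pvalues[name]:.2g})")
print(f"variance components: group {fit.sigma_u2:.3f}, "
      f"residual {fit.sigma_e2:.3f}")
print()
print("The ABC coefficient should dominate: carrying a sugar ABC importer")
print("is the planted driver of CFU yield in this simulation.")
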