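"""Two-stage Bayesian association: genus responses to dietary sugar,
then transporter counts as a predictor of those responses.

Stage 1 fits, per genus, CLR abundance ~ Normal(alpha + beta * sugar,
sigma) with standard-normal priors and an Exponential(1) prior on
sigma (4 chains x 1000 draws).  Stage 2 regresses the per-genus beta
means on genus-mean ABC transporter counts normalized by their
maximum.  Here the generator plants a positive trait effect, so the
second stage should recover a positive slope whose 95% HPD excludes 0.
"""

import numpy as np
import pandas as pd

from sugartrait import (
    SyntheticConfig,
    clr_transform,
    fit_all_genera,
    gen_diet_abundance,
    gen_trait_beta_pair,
    trait_regression,
    trait_spearman,
)

config = SyntheticConfig(seed=19, n_genera=12, n_samples=250, n_patients=20)
# plant betas rising with an ABC-like gradient
gradient = np.linspace(0, 1, config.n_genera)
true_beta = gradient - gradient.mean()
study = gen_diet_abundance(config, true_beta=true_beta)

exposures = pd.DataFrame(
    {
        "sample_id": study.abundance.index,
        "sugar_exposure": study.true_exposure.to_numpy(),
    }
)
fits = fit_all_genera(clr_transform(study.abundance), exposures, seed=3)
print("per-genus sugar coefficients (stage 1):")
cols = ["genus", "beta_mean", "ci95_lo", "ci95_hi", "excludes_zero"]
print(fits[cols].round(2).to_string(index=False))

census = pd.DataFrame(
    {
        "genus": fits["genus"],
        "abc": np.round(46 * gradient, 0),
        "pts": 5.0,
        "mfs": 3.0,
    }
)
census["total"] = census[["abc", "pts", "mfs"]].sum(axis=1)

reg = trait_regression(fits, census, transporter_type="abc", seed=5)
rho, p = trait_spearman(fits, census, transporter_type="abc")
print(f"\nstage 2 (ABC): Spearman rho={rho:.2f} (p={p:.2g}); posterior "
      f"slope {reg.summary.beta_mean:.2f}, 95% HPD "
      f"[{reg.summary.hpd95[0]:.2f}, {reg.summary.hpd95[1]:.2f}]")
print()
print("Genera with more sugar ABC transporters respond more positively to")
print("dietary sugar; a positive slope with HPD excluding 0 recovers the")
print("planted trait effect.")
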