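"""Fit the null variance-component model and estimate heritability.

Simulates a quantitative trait with additive polygenic variance 1.1 and
environmental variance 0.9 (true h² = 0.55) over ten 16-person pedigrees,
fits the Gaussian model Σ = σa²·2Φ + σe²·I by maximum likelihood with Age
and Sex as fixed effects, and prints the estimates.
"""

import numpy as np

from pedscore.simkit import SimConfig, simulate_traits
from pedscore.vcfit import (
    StackedData,
    fit_null_ml,
    heritability,
    spec_from_pedigree,
)

cfg = SimConfig(seed=2026, n_pedigrees=10, n_visits=1,
                sigma_a2=1.1, sigma_e2=0.9)
ped = cfg.pedigree()
ph = simulate_traits(ped, cfg, rng=cfg.rng_for(0))

Y = ph.wide("Y").loc[ped.ids].to_numpy()
X = np.column_stack([ph.wide("Age").loc[ped.ids].to_numpy(),
                     ph.wide("Sex").loc[ped.ids].to_numpy()])
spec = spec_from_pedigree(ped, ("additive", "environment"))
fit = fit_null_ml(spec, StackedData.from_traits(Y, X))

print(f"converged in {fit.n_iter} iterations, loglik {fit.loglik:.4f}")
print(f"sigma_a2 = {fit.component('additive'):.4f}   (truth 1.1)")
print(f"sigma_e2 = {fit.component('environment'):.4f}   (truth 0.9)")
print(f"h2       = {heritability(fit)[0]:.3f}   (truth 0.55)")
# Single-replicate estimates scatter around the truth; the mean over many
# replicates lands within a few hundredths of 0.55.
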