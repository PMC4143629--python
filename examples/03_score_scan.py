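"""Score-test scan with LRT refinement of top hits.

Gene-drops 500 SNPs over ten pedigrees, plants an effect at one of them,
fits the null model once, scans every SNP with the efficient score test,
and refits the top 5 by likelihood ratio.  The planted SNP should surface
at the top with score and LRT p-values in close agreement.
"""

import numpy as np
import pandas as pd

from pedscore.assoc import scan
from pedscore.genio import GenotypeSource
from pedscore.simkit import SimConfig, gene_drop, simulate_traits
from pedscore.vcfit import StackedData, fit_null_ml, spec_from_pedigree

cfg = SimConfig(seed=7, n_pedigrees=10, n_visits=1, sigma_a2=1.0, sigma_e2=1.0)
ped = cfg.pedigree()
rng = cfg.rng_for(0)

m = 500
dosages = np.column_stack(
    [gene_drop(ped, float(rng.uniform(0.1, 0.5)), rng) for _ in range(m)]
).astype(float)
causal = 123
ph = simulate_traits(ped, cfg, causal=(dosages[:, [causal]], [1.3]), rng=rng)

Y = ph.wide("Y").loc[ped.ids].to_numpy()
X = np.column_stack([ph.wide("Age").loc[ped.ids].to_numpy(),
                     ph.wide("Sex").loc[ped.ids].to_numpy()])
fit = fit_null_ml(spec_from_pedigree(ped, ("additive", "environment")),
                  StackedData.from_traits(Y, X))

snps = pd.DataFrame({"snp_id": [f"rs{j}" for j in range(m)], "chrom": "1",
                     "bp": np.arange(1, m + 1) * 1000,
                     "allele_effect": "A", "allele_other": "G"})
res = scan(GenotypeSource(dosages, snps, ped.ids), fit, top_k=5)

top = res.table.nsmallest(5, "pvalue")
print(top[["snp_id", "pvalue", "lrt_pvalue", "effect_1"]].to_string(index=False))
print(f"\nplanted causal SNP: rs{causal} (true effect 1.3 per allele)")
# The causal SNP should rank first; score and LRT p-values agree to within
# a few percent on the -log10 scale, and effect_1 is its one-step estimate.
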