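"""Neutral-marker statistics on diploid microsatellites: hierarchical
AMOVA, pairwise Weir-Cockerham F_ST with locus-bootstrap CIs, and Evanno
delta-K post-processing of clustering log-likelihoods.
"""

import numpy as np
import pandas as pd

from spectraits.popgen import (amova, assign_membership, evanno_delta_k,
                               fst_bootstrap_ci, pairwise_fst)
from spectraits.simulate import SimConfig, simulate_dataset

data = simulate_dataset(SimConfig(n_species=3, pops_per_species=2,
                                  inds_per_pop=12, n_loci=11,
                                  fst_target=0.12, seed=4))
g = data["genotypes"]

res = amova(g)
print("AMOVA variance percentages:")
for level, pct in res.percentages.items():
    print(f"  {level:22s} {pct:6.1f} %")

pairs = pairwise_fst(g, level="species")
print("\npairwise species F_ST (with 95% locus-bootstrap CI):")
for f in pairs:
    ci = fst_bootstrap_ci(g, f.pair, level="species", n_boot=500, seed=1)
    print(f"  {f.pair[0]}/{f.pair[1]}: theta={ci.theta:.3f} "
          f"[{ci.ci_low:.3f}, {ci.ci_high:.3f}]")

# delta-K on synthetic clustering log-likelihoods peaking at K=3
loglik = pd.DataFrame({k: -500 - 40 * abs(k - 3) + np.random.default_rng(k)
                       .normal(0, 2, 5) for k in range(1, 7)})
k_star, curve = evanno_delta_k(loglik)
print(f"\nEvanno delta-K selects K = {k_star}")
# Percentages sum to 100; theta near the 0.12 simulation target confirms
# the estimator tracks the generating differentiation.
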