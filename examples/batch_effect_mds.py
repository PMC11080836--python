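"""Show a dimer-driven batch effect in expression space.

Simulates a 12-sample cohort whose adapter-dimer fractions span 5%-80% with
a composition bias coupled to contamination, computes log2-CPM, embeds the
samples by leading-log-fold-change classical MDS, and tests each coordinate
for association with the dimer percentage by seeded permutation.
"""

import numpy as np

from dimerqc import (
    SimConfig,
    dimer_batch_effect_test,
    leading_logfc_mds,
    log_cpm,
    simulate_cohort,
)

dimer_fractions = list(np.linspace(0.05, 0.8, 12))
base = SimConfig(
    n_reads=10_000, short_fraction=0.1, dimer_bias_coupling=1.5, seed=21
)
sim = simulate_cohort(12, dimer_fractions, base, make_reads=False)

mds = leading_logfc_mds(
    log_cpm(sim.counts), top_n=200, k=2, samples=sim.sample_ids
)
results = dimer_batch_effect_test(
    mds, 100 * np.array(dimer_fractions), n_perm=10_000, seed=1
)

for r in results:
    print(
        f"MDS dimension {r.dimension}: Spearman rho = {r.spearman_rho:+.3f}, "
        f"permutation p = {r.p_perm:.2e} ({r.n_perm} permutations)"
    )
lead = results[0]
print(
    f"\nDimension 1 tracks the dimer percentage (|rho| = "
    f"{abs(lead.spearman_rho):.2f}): samples separate by contamination "
    "level, not biology — a batch effect a naive clustering would "
    "misread as signal."
)
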