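"""Neutral island-model baseline: pi_w against the 4*d*N*mu expectation.

With selection switched off (V_S = 1e9) and ongoing migration, per-locus
within-patch diversity at mutation-drift-migration equilibrium approaches
4*d*N*mu; with m = 0 each deme drifts alone towards 4*N*mu.  A high
mutation rate is used here so that a short run at small N gives a readable
Monte-Carlo average.
"""

import numpy as np

import msdiv

N, mu = 50, 1e-3
gm = msdiv.unlinked_loci_map(1, n_neutral=60)

for m in (0.1, 0.0):
    pis = []
    for seed in range(3):
        params = msdiv.SimulationParams(
            N=N, m=m, V_S=1e9, mu_neutral=mu, mu_adaptive=0.0, seed=seed,
            sample_every=25 * N * 2,
        )
        res = msdiv.run(params, gm)
        fin = res.metrics[res.metrics.generation == res.metrics.generation.max()]
        pis.append(fin[fin.kind == "neutral"].pi_w_mean.mean())
    expect = msdiv.neutral_expectation(N, 2, mu, m)
    print(f"m = {m}: simulated mean pi_w = {np.mean(pis):.4f}, "
          f"island-model expectation {expect:.4f} "
          f"(small-theta approximation; the exact equilibrium is lower)")
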