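"""Troughs vs peaks in within-population diversity around a selected locus.

Runs the two-patch, single-continuum-locus model at a low and an
intermediate-high migration rate (small N so it finishes in about a minute)
and prints the diversity-distance slope: positive slope = trough (diversity
depleted near the selected site), negative slope = peak (migrant haplotypes
inflate diversity near the selected site).

The neutral mutation rate is set higher than the experiment-grid default (1e-4 vs
1e-5) so that this small, fast run carries readable diversity levels; the
regime structure is the same.
"""

import numpy as np

import msdiv

gm = msdiv.build_flanking_map()
N = 100

for m, label in [(10**-3.5, "low migration"), (10**-1.5, "high migration")]:
    slopes, nears, fars = [], [], []
    for seed in range(3):
        params = msdiv.SimulationParams(
            N=N, m=m, V_S=5.0, mu_neutral=1e-4, mu_adaptive=1e-2 / N,
            seed=seed, sample_every=25 * N * 2,  # final snapshot only
        )
        res = msdiv.run(params, gm)
        fin = res.metrics[res.metrics.generation == res.metrics.generation.max()]
        neu = fin[fin.kind == "neutral"]
        slope, p = msdiv.dd_slope(neu.pi_w_mean, neu.distance_cM)
        x = np.abs(neu.distance_cM.to_numpy())
        y = neu.pi_w_mean.to_numpy()
        slopes.append(slope)
        nears.append(y[x < 0.01].mean())   # binned: less noisy than 2 loci
        fars.append(y[x > 5.0].mean())
    print(f"{label} (m = {m:.4g}):")
    print(f"  mean dd-slope {np.mean(slopes):+.4f}  "
          f"mean pi_w within 0.01 cM {np.mean(nears):.4f}  beyond 5 cM "
          f"{np.mean(fars):.4f}")
    if np.mean(slopes) < 0:
        print("  -> negative slope: diversity peaks near the selected locus "
              "(peak regime)")
    else:
        print("  -> positive slope: diversity rises away from the selected "
              "locus (trough regime; at this demo scale the contrast is "
              "shallow and rare migrant lineages add noise near the locus)")
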