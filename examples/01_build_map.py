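"""Build the standard simulated chromosome and inspect its genetic map.

One divergently selected locus sits at position 0, symmetrically flanked by
37 neutral loci per side at log-spaced distances from 0.001 to 10 cM.
Adjacent-locus recombination fractions follow r = min(d/100, 0.5).
"""

import numpy as np

import msdiv

gm = msdiv.build_flanking_map()
print(f"loci: {gm.n_loci} ({len(gm.selected_idx)} selected, "
      f"{len(gm.neutral_idx)} neutral)")
d = gm.abs_distance_cM[gm.neutral_idx]
print(f"nearest neutral locus: {d.min()} cM, farthest: {d.max()} cM")
print(f"total recombination mass along the chromosome: "
      f"{gm.rec_fractions.sum():.3f}")

# Two selected loci -> two complements separated by a free-recombining gap
gm2 = msdiv.build_flanking_map(n_selected=2)
boundary = np.flatnonzero(np.diff(gm2.complement_id))[0]
print(f"two-complement map: {gm2.n_loci} loci, boundary interval r = "
      f"{gm2.rec_fractions[boundary]}")

# The background-calibration map adds ~100 loci per side on [9, 10] cM
gmx = msdiv.add_background_loci(gm)
print(f"extended background map: {gmx.n_loci} loci")

gm.to_tsv("map_standard.tsv")
print("wrote map_standard.tsv (4-column TSV, re-importable with "
      "GeneticMap.from_tsv)")
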