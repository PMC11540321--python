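# Methods

## The model

`msdiv` simulates a diploid Wright–Fisher metapopulation adapting to
spatially divergent phenotypic optima, to characterize how
migration–selection balance reshapes neutral variation linked to the
selected loci. Individuals carry a single chromosome; each divergently
selected locus is symmetrically flanked by 37 neutral diallelic loci per
side at log-spaced distances 10⁻³–10 cM, and each such 75-locus complement
is unlinked from every other (50 cM gaps, free recombination under the
linear map convention below).

Fitness is Gaussian stabilizing selection on an additive phenotype:

    W(z) = exp(−(z − θ_p)² / (2·V_S)),   z = Σ allele effects (both copies)

with patch-specific optima θ_p (two patches: −1/+1; ten-patch stepping
stone: linearly spaced from −1 to +1). There is no dominance and no
epistasis on the phenotype. Soft selection regulates density: every patch
produces exactly N offspring each generation.

The per-generation life cycle is

1. **backward migration** — each offspring slot draws a source patch
   (two-patch exchange at rate m; stepping stone: m/2 from each neighbour,
   so interior patches receive twice the immigrant influx of terminal
   patches);
2. **fitness-proportional parent sampling** within the source patch
   (with replacement; selfing allowed), fitness evaluated against the
   source patch's own optimum — viability selection in the natal patch.
   Scaling fitness by the patch mean is a no-op for proportional sampling
   and is applied only when fitness itself is reported;
3. **recombination** — each parent contributes one gamete: a random
   starting haplotype with independent switches at each interval
   (probability = the interval's recombination fraction; no interference);
4. **mutation** — neutral loci flip 0↔1 at μ_neutral = 10⁻⁵; selected loci
   either gain a Normal(0, 1) increment (continuum of alleles; mono-locus
   models) or flip to the opposite allele (house of cards; diallelic
   polygenic models) at μ_adaptive.

Backward (offspring-samples-source) migration is used rather than literal
forward dispersal so that patch sizes stay exactly N; for m ≪ 1 the two are
equivalent to first order. The event order (selection before dispersal of
offspring) is one of two defensible readings of the underlying
individual-based scheme; it was chosen because it preserves fixed patch
sizes exactly, and the package treats it as part of its model definition.

Initial state: every neutral allele copy is Bernoulli(0.5) — maximal
standing variation; continuum selected loci start monomorphic at effect 0,
so adaptive divergence is mutation-driven; diallelic selected loci start
Bernoulli(0.5) over {−a, +a}. Diallelic initialization at intermediate
frequency is a choice (only the neutral initialization is pinned down by
the bundled experiment designs); it matters little because selection sorts the standing
variation within a few hundred generations.

## Map convention

Distances are stored as signed cM offsets from the complement's selected
locus. Adjacent-interval recombination fractions use the linear rule
r = min(d/100, 0.5) with independent crossovers per interval. This is
deliberately not a map function with interference: it makes a 50 cM gap
*exactly* unlinked (r = 0.5), which Haldane's function would not, and at
the small distances that matter here (≤ 10 cM) it agrees with any map
function to first order. The flank positions are spaced
evenly on the log₁₀ scale — the natural reading of "log-spaced", adopted
as this package's convention — and the nearest/farthest flanks sit exactly
at 10⁻³ and 10 cM, the distances used by the near/far contrast.

The background-calibration map adds loci evenly spaced on the linear
[9, 10] cM band at each end (default 100 per side; positions that collide
exactly with an existing locus are dropped, so the default standard map
gains 99 per side).

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| N | — | diploids per patch (experiment grids: 500–10,000; desk runs 100–250) |
| d | 2 | number of patches (2 or a 10-patch linear stepping stone) |
| m | — | forward migration rate per generation; experiment grid 10⁻⁵–10⁻⁰·⁵, 4 steps/decade, plus 0 |
| V_S | 5 | variance of the Gaussian fitness function (2–100; 10⁹ ≈ neutral control) |
| θ | ±1 | patch optima (ten-patch: linspace(−1, 1, 10)) |
| μ_neutral | 10⁻⁵ | per-copy flip rate at neutral loci |
| μ_adaptive | 10⁻⁵ | per-copy rate at selected loci; the scaled alternative 10⁻²/N keeps mutational input constant across N |
| effect (nonredundant) | ±1/(2l) | all l loci must be homozygous-optimal to reach the optimum |
| effect (redundant) | ±0.25 | any two homozygous-optimal loci reach ±1 |
| generations | 25·N·d | quasi-equilibrium horizon |
| sample_every | ½·N·d | metric sampling interval |

All diversity statistics are census statistics over the full 2N haplotypes
per patch. π_w is the unbiased Nei estimator ((1 − Σxᵢ²)·n/(n−1));
d_xy carries no sample-size correction; F_ST is the Weir–Cockerham
variance-components estimator for haploid-sampled counts (negative values
retained; multi-locus reporting is ratio-of-sums); LD is the squared
Pearson correlation of haplotype indicators across the pooled
metapopulation, with continuum selected alleles dichotomized by effect
sign.

## Signatures

* **dd-slope**: OLS of per-locus π_w (or F_ST) on log₁₀|distance|, pooling
  both flanks. Positive slope = trough, negative = peak. Both-flank pooling
  (rather than averaging mirrored loci first) is the implemented default.
* **near/far contrast**: mean over the two loci at exactly 10⁻³ cM vs the
  two at 10 cM.
* **background level**: mean π_w over all loci 9–10 cM from the selected
  locus in neutral-control runs (V_S = 10⁹) on the extended map at
  matching N, d, m, μ.
* **peak detection**: slope significantly negative (t-test at α = 0.05,
  the package's fixed significance convention) AND ≥ 25% of neutral loci
  above 1.1× background.
* **peak width**: π_w of all loci above background regressed on *linear*
  |distance|; width = 2× the x-intercept. Linear cM is used (after the
  earlier log-scale regressions) because an intercept in log space cannot
  be half a width in cM without back-transformation; this reading is an
  interpretation and is flagged here.
* **critical migration**: the largest grid m at which a majority of
  replicates maintain local adaptation at the final sampling point.
  Maintenance is defined as between-patch difference in patch-mean
  phenotype exceeding half the optimum gap; an allele-frequency variant
  (|Δp| ≥ 0.5 for sign-classified alleles at the selected locus) is
  available as `criterion="allele_sign"` for sensitivity analysis, since no
  canonical maintenance criterion exists.
* **adaptive-allele summary**: continuum allele values are binned at a
  stated resolution (default 0.05) into effect classes per patch.

Replicate aggregation reports the arithmetic mean for headline curves and
also the median and 5/25/75/95% quantiles: at very low migration the mean
is dominated by rare recent-migrant replicates and the median is the more
representative summary.

## Numerical choices

* One `numpy` Generator per replicate, seeded from a `SeedSequence`;
  experiment grids spawn per-cell, per-replicate seeds deterministically
  from a base seed, so reruns are byte-identical.
* Crossovers are sampled sparsely: per-interval binomial counts placed on
  distinct gametes (intervals with r ≥ 0.03, e.g. complement boundaries,
  are drawn densely). This is an exact sampling of the independent-interval
  model, chosen because the expected number of crossovers per gamete on the
  standard map is only ≈ 0.2.
* Mutation counts are binomial per generation with uniform placement;
  flip-type duplicates collapse to a site set, continuum increments
  accumulate.
* Fitness underflow (all-zero weights in a patch) falls back to uniform
  parent sampling with a warning; unreachable for the bounded phenotypes of
  the bundled experiment designs.
* F_ST is reported as missing at loci monomorphic in the pooled census;
  constant-metric distance regressions return slope 0 with p = 1.

## Desk scales

The full experiment conditions (N = 1000, horizon 25·N·d = 50,000 generations,
hundreds of grid cells) are reproducible with this package but are
multi-hour runs. The bundled tests and the acceptance script use the
package's desk scales, chosen once and recorded here:

* two-patch single-locus regime runs: N = 250, horizon 12,500, 20–40
  replicates per migration rate, metrics read at the final sampling point;
* two-patch regime runs use the population-size-standardized rate
  μ_adaptive = 10⁻²/N so that the mutational supply per generation matches
  the full-size runs (at full scale the standardization has little effect; at desk scale it is essential — with the
  unscaled rate a 250-diploid patch receives too few adaptive mutations in
  25·N·d generations to reach the refined monomorphic state, lingers in
  heterozygote-advantage allele pairs at the continuum locus, and the
  balanced polymorphism inflates linked diversity enough to invert the
  low-migration trough);
* critical-migration scan: N = 500, 10 replicates per grid point,
  scaled μ_adaptive = 10⁻²/N, on a flankless single-locus map (maintenance
  is a phenotype-only readout and neutral flanks carry no fitness);
* redundant-architecture runs: N = 200, 20 unlinked adaptive loci, 10
  replicates. Neutral flanks are omitted there because they carry no
  fitness and cannot affect adaptive-locus allele-frequency dynamics;
* neutral calibration: N = 50, m = 0.1, μ = 10⁻³ at 60 unlinked neutral
  loci, compared against the exact two-deme single-locus Markov chain
  (μ = 10⁻³ rather than 10⁻⁵ so that enough loci segregate for an
  informative Monte-Carlo average at small N).

Smaller N at fixed m shifts drift-migration balance (N·m is not
preserved), so scaled runs reproduce the *regime structure* (sign pattern,
peak existence, differentiation fractions, grid-point thresholds) rather
than exact magnitudes; magnitude-sensitive quantities in the tests carry
correspondingly generous tolerances.

## What the generator does and does not emulate

The simulator *is* the data source: there is no empirical input. It
emulates equilibrium and quasi-equilibrium patterns of diversity around
loci under divergent selection with idealized demography: constant equal
patch sizes, non-overlapping generations, a single linkage group per
complement, diallelic neutral sites with symmetric mutation, and no
background selection, sweeps at unlinked sites, GC-biased gene conversion,
or variable recombination landscape. Passing tests therefore demonstrate
the internal consistency of the migration–selection mechanism, not that
any particular empirical peak or trough in π_w was caused by local
adaptation.

## Known limitations

* Quasi-equilibrium, not equilibrium: at m ≲ 10⁻⁴ true equilibrium lies
  far beyond 25·N·d generations; headline metrics are read at the horizon by design.
* The arithmetic mean across a finite replicate set misses the rare
  recent-migrant inflation of π_w at very low m (hence mean π_w trends
  toward the 4·N·μ single-deme value instead of the analytic 4·d·N·μ);
  this is a property of the measurement, reported deliberately.
* `critical_migration` depends on the (invented) maintenance criterion at
  scaled N; establishment from a monomorphic continuum locus is
  waiting-time limited, so under-scaled runs can report the threshold one
  grid step low.
* The VCF export uses pseudo-positions derived from cM offsets (there are
  no physical coordinates in the model) and covers diallelic loci only.
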