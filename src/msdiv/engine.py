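"""Forward-time, individual-based Wright-Fisher engine.

Life cycle per generation (soft selection, constant patch size N):

1. each of the N offspring slots of a patch draws a *source* patch from the
   backward migration matrix (two-patch exchange, or a linear stepping stone
   for d >= 3);
2. two parents are drawn (with replacement, selfing allowed) from the source
   patch with probability proportional to Gaussian stabilizing-selection
   fitness W(z) = exp(-(z - theta)^2 / (2 V_S)), evaluated against the source
   patch's own optimum (viability selection in the natal patch);
3. each parent contributes one gamete built by per-interval recombination
   (independent crossovers, no interference);
4. mutation: neutral diallelic loci flip 0<->1; selected loci either gain a
   Normal(0,1) increment (continuum of alleles) or flip to the opposite
   allele (house of cards), per allele copy per generation.

Phenotype is the additive sum of both allele effect values over all selected
loci (no dominance, no epistasis); neutral loci carry 0/1 states and do not
contribute.  Scaling fitness by the patch mean (as reported fitness) is a
no-op for fitness-proportional parent sampling and is therefore not applied
inside the sampling loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genmap import GeneticMap

__all__ = [
    "SimulationParams",
    "MetapopState",
    "SimulationResult",
    "fitness",
    "patch_scaled_fitness",
    "phenotype",
    "migration_matrix",
    "initialize",
    "dump_haplotypes",
    "recombine",
    "mutate",
    "step_generation",
    "run",
]

CONTINUUM = "continuum"
NONREDUNDANT = "nonredundant_diallelic"
REDUNDANT = "redundant_diallelic"
_EFFECT_MODELS = (CONTINUUM, NONREDUNDANT, REDUNDANT)


@dataclass
class SimulationParams:
    """Parameters of one simulation run.

    theta defaults to (-1, +1) for d=2 and to a linear gradient from -1 to +1
    for stepping stones.  adaptive_allele_effect defaults to 1/(2l) for the
    nonredundant diallelic model and 0.25 for the redundant one; generations
    defaults to 25*N*d and sample_every to N*d/2.
    """

    N: int
    m: float
    V_S: float = 5.0
    d: int = 2
    theta: Sequence[float] | None = None
    effect_model: str = CONTINUUM
    n_adaptive: int = 1
    adaptive_allele_effect: float | None = None
    mu_neutral: float = 1e-5
    mu_adaptive: float = 1e-5
    generations: int | None = None
    sample_every: int | None = None
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.d < 2:
            raise ValueError("d must be >= 2")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("m must lie in [0, 1]")
        if self.V_S <= 0:
            raise ValueError("V_S must be positive")
        if self.effect_model not in _EFFECT_MODELS:
            raise ValueError(f"effect_model must be one of {_EFFECT_MODELS}")
        if self.n_adaptive < 1:
            raise ValueError("n_adaptive must be >= 1")
        if self.theta is None:
            self.theta = (-1.0, 1.0) if self.d == 2 else tuple(
                np.linspace(-1.0, 1.0, self.d)
            )
        self.theta = tuple(float(t) for t in self.theta)
        if len(self.theta) != self.d:
            raise ValueError("theta must have one optimum per patch")
        if self.adaptive_allele_effect is None:
            if self.effect_model == NONREDUNDANT:
                self.adaptive_allele_effect = 1.0 / (2 * self.n_adaptive)
            elif self.effect_model == REDUNDANT:
                self.adaptive_allele_effect = 0.25
        if self.generations is None:
            self.generations = 25 * self.N * self.d
        if self.sample_every is None:
            self.sample_every = max(self.N * self.d // 2, 1)


@dataclass
class MetapopState:
    """Per-patch diploid genotypes: array (d, N, 2, L) of allele values.

    Selected loci hold real effect sizes; neutral loci hold 0/1 states.
    """

    genotypes: np.ndarray
    generation: int = 0

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.genotypes.shape


@dataclass
class SimulationResult:
    """Metric stream and final state of one run."""

    params: SimulationParams
    gmap: GeneticMap
    metrics: pd.DataFrame
    phenotypes: pd.DataFrame  # per sampling point: generation, patch, mean_z
    final_state: MetapopState = field(repr=False, default=None)


def dump_haplotypes(state: MetapopState, gmap: GeneticMap, path) -> None:
    """Write the snapshot as a tidy haplotype matrix TSV (gzipped if the
    path ends in .gz): one row per haplotype (patch, individual, haplotype,
    then one column per locus named by locus_id)."""
    d, N, _, L = state.genotypes.shape
    hap = state.genotypes.reshape(d * N * 2, L)
    idx = pd.MultiIndex.from_product(
        [range(d), range(N), range(2)], names=["patch", "individual", "haplotype"]
    )
    df = pd.DataFrame(hap, index=idx,
                      columns=[l.locus_id for l in gmap.loci])
    df.reset_index().to_csv(path, sep="\t", index=False)


def fitness(z, theta_p, V_S):
    """Gaussian stabilizing-selection fitness W(z) = exp(-(z-theta)^2/(2 V_S))."""
    z = np.asarray(z, dtype=float)
    return np.exp(-((z - theta_p) ** 2) / (2.0 * V_S))


def patch_scaled_fitness(w):
    """Fitness relative to the patch mean (the form in which fitness is reported)."""
    w = np.asarray(w, dtype=float)
    mean = w.mean()
    if mean == 0:
        return np.full_like(w, np.nan)
    return w / mean


def phenotype(genotypes: np.ndarray, gmap: GeneticMap) -> np.ndarray:
    """Additive phenotype: sum of both allele effects over selected loci.

    Accepts a single individual (2, L), a patch (N, 2, L) or the full
    metapopulation (d, N, 2, L); returns the array with the last two axes
    summed out.
    """
    g = np.asarray(genotypes, dtype=float)
    return g[..., gmap.selected_idx].sum(axis=(-1, -2))


def migration_matrix(params: SimulationParams) -> np.ndarray:
    """Backward migration matrix: row p = source-patch probabilities for patch p.

    d = 2: symmetric exchange at rate m.  d >= 3: linear stepping stone;
    an interior patch receives m/2 from each neighbour, a terminal patch m/2
    from its single neighbour (remainder from itself), so the interior
    immigrant influx is twice the terminal one.
    """
    d, m = params.d, params.m
    M = np.zeros((d, d))
    if d == 2:
        M[0, 0] = M[1, 1] = 1.0 - m
        M[0, 1] = M[1, 0] = m
    else:
        for p in range(d):
            if p > 0:
                M[p, p - 1] = m / 2.0
            if p < d - 1:
                M[p, p + 1] = m / 2.0
            M[p, p] = 1.0 - M[p].sum()
    if np.any(M < 0):
        raise ValueError(f"migration rate m={m} yields negative self-recruitment")
    assert np.allclose(M.sum(axis=1), 1.0)
    return M


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def initialize(
    params: SimulationParams, gmap: GeneticMap, rng=None
) -> MetapopState:
    """Initial metapopulation with maximal neutral standing variation.

    Every neutral allele copy is Bernoulli(0.5) over {0, 1}.  Continuum
    selected loci start monomorphic at effect 0 (divergence is
    mutation-driven); diallelic selected loci start Bernoulli(0.5) over
    {-a, +a}.
    """
    rng = _as_rng(rng if rng is not None else params.seed)
    d, N, L = params.d, params.N, gmap.n_loci
    g = np.zeros((d, N, 2, L))
    neu = gmap.neutral_idx
    if len(neu):
        g[:, :, :, neu] = rng.integers(0, 2, size=(d, N, 2, len(neu))).astype(float)
    sel = gmap.selected_idx
    if params.effect_model in (NONREDUNDANT, REDUNDANT) and len(sel):
        a = params.adaptive_allele_effect
        signs = rng.integers(0, 2, size=(d, N, 2, len(sel))) * 2 - 1
        g[:, :, :, sel] = a * signs
    return MetapopState(genotypes=g, generation=0)


def recombine(parent: np.ndarray, gmap: GeneticMap, rng) -> np.ndarray:
    """One gamete from a (2, L) parent genotype.

    Starts from a random haplotype and switches at interval i with
    probability rec_fractions[i], independently per interval.
    """
    rng = _as_rng(rng)
    return _recombine_batch(parent[None], gmap.rec_fractions, rng)[0]


def _haplotype_choice(
    n: int, L: int, rec: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n, L) matrix: which parental haplotype each gamete copies at
    each locus (random start, switch at interval i with probability rec[i])."""
    hap = np.empty((n, L), dtype=bool)
    hap[:, 0] = rng.integers(0, 2, size=n, dtype=np.int8).astype(bool)
    if L > 1:
        switches = rng.random((n, L - 1)) < rec
        np.logical_xor.accumulate(switches, axis=1, out=switches)
        hap[:, 1:] = hap[:, 0:1] ^ switches
    return hap


def _recombine_batch(
    parents: np.ndarray, rec: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gametes (n, L) from parent genotypes (n, 2, L)."""
    n, _, L = parents.shape
    hap = _haplotype_choice(n, L, rec, rng)
    return np.where(hap, parents[:, 1, :], parents[:, 0, :])


def _switch_events(
    n: int, rec: np.ndarray, rng: np.random.Generator,
    dense_threshold: float = 0.03,
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse sample of crossover events over an (n gametes x intervals)
    Bernoulli field.

    Most intervals of a log-spaced map have tiny recombination fractions, so
    the expected number of events is small; intervals with r >= the
    threshold (e.g. the free-recombining complement boundaries) are drawn
    densely, the rest via per-interval binomial counts placed on distinct
    gametes.  Returns (gamete_index, interval_index) pairs.
    """
    gs, its = [], []
    sparse = np.flatnonzero((rec > 0.0) & (rec < dense_threshold))
    dense = np.flatnonzero(rec >= dense_threshold)
    if sparse.size:
        ks = rng.binomial(n, rec[sparse])
        total = int(ks.sum())
        if total:
            want = np.zeros(rec.size, dtype=np.intp)
            want[sparse] = ks
            ev_i = np.repeat(sparse, ks)
            ev_g = rng.integers(0, n, size=total)
            key = np.unique(ev_g * rec.size + ev_i)
            while key.size < total:  # top up rare placement collisions
                have = np.bincount(key % rec.size, minlength=rec.size)
                short = np.repeat(
                    np.arange(rec.size), np.maximum(want - have, 0)
                )
                extra = rng.integers(0, n, size=short.size) * rec.size + short
                key = np.unique(np.concatenate([key, extra]))
            gs.append(key // rec.size)
            its.append(key % rec.size)
    if dense.size:
        hits = rng.random((n, dense.size)) < rec[dense]
        gg, jj = np.nonzero(hits)
        if gg.size:
            gs.append(gg)
            its.append(dense[jj])
    if gs:
        return np.concatenate(gs), np.concatenate(its)
    return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)


def mutate(
    state: MetapopState, params: SimulationParams, gmap: GeneticMap, rng
) -> MetapopState:
    """Apply one generation of mutation in place and return the state.

    The per-copy mutation count is drawn Binomial(copies, mu) and positions
    are placed uniformly; for flip-type mutations (neutral and house of
    cards) duplicate positions are collapsed, for continuum increments they
    accumulate.
    """
    rng = _as_rng(rng)
    g = state.genotypes
    d, N, _, L = g.shape
    flat = g.reshape(-1)
    n_copies = d * N * 2

    neu = gmap.neutral_idx
    if params.mu_neutral > 0 and len(neu):
        total = n_copies * len(neu)
        k = rng.binomial(total, params.mu_neutral)
        if k:
            pos = np.unique(rng.integers(0, total, size=k))
            body, which = np.divmod(pos, len(neu))
            idx = body * L + neu[which]
            flat[idx] = 1.0 - flat[idx]

    sel = gmap.selected_idx
    if params.mu_adaptive > 0 and len(sel):
        total = n_copies * len(sel)
        k = rng.binomial(total, params.mu_adaptive)
        if k:
            pos = rng.integers(0, total, size=k)
            if params.effect_model == CONTINUUM:
                body, which = np.divmod(pos, len(sel))
                idx = body * L + sel[which]
                np.add.at(flat, idx, rng.normal(size=k))
            else:
                pos = np.unique(pos)
                body, which = np.divmod(pos, len(sel))
                idx = body * L + sel[which]
                flat[idx] = -flat[idx]
    return state


def step_generation(
    state: MetapopState,
    params: SimulationParams,
    gmap: GeneticMap,
    rng,
    M: np.ndarray | None = None,
) -> MetapopState:
    """Advance the metapopulation by one full life cycle."""
    rng = _as_rng(rng)
    if M is None:
        M = migration_matrix(params)
    g = state.genotypes
    d, N, _, L = g.shape

    z = phenotype(g, gmap)  # (d, N)
    theta = np.asarray(params.theta)
    w = np.exp(-((z - theta[:, None]) ** 2) / (2.0 * params.V_S))

    cdf = np.cumsum(w, axis=1)  # per-patch fitness CDFs
    tot = cdf[:, -1]

    # choose, for every gamete of every offspring slot, a global parent row
    # (source patch chosen by backward migration, parent by fitness)
    row_parts = []
    for dest in range(d):
        counts = rng.multinomial(N, M[dest])
        for src in np.flatnonzero(counts):
            n_gam = 2 * int(counts[src])
            if tot[src] <= 0.0:
                warnings.warn(
                    "all-zero fitness in a patch; falling back to uniform "
                    "parent sampling",
                    RuntimeWarning,
                )
                pidx = rng.integers(0, N, size=n_gam)
            else:
                pidx = np.searchsorted(cdf[src], rng.random(n_gam) * tot[src])
                np.minimum(pidx, N - 1, out=pidx)  # fp guard
            row_parts.append(src * N + pidx)
    rows = row_parts[0] if len(row_parts) == 1 else np.concatenate(row_parts)

    # one recombination pass for all 2*N*d gametes: copy the starting
    # haplotype wholesale, then rebuild only the gametes with crossovers
    n_gam = rows.size
    start = rng.integers(0, 2, size=n_gam)
    flat2 = g.reshape(d * N * 2, L)
    gametes = np.take(flat2, rows * 2 + start, axis=0)
    ev_g, ev_i = _switch_events(n_gam, gmap.rec_fractions, rng)
    if ev_g.size:
        aff, inv = np.unique(ev_g, return_inverse=True)
        sub = np.zeros((aff.size, L - 1), dtype=bool)
        sub[inv, ev_i] = True
        np.logical_xor.accumulate(sub, axis=1, out=sub)
        s_aff = start[aff].astype(bool)
        hap = np.empty((aff.size, L), dtype=bool)
        hap[:, 0] = s_aff
        hap[:, 1:] = s_aff[:, None] ^ sub
        flat = g.reshape(d * N, 2, L)
        pa = flat[rows[aff]]
        gametes[aff] = np.where(hap, pa[:, 1, :], pa[:, 0, :])
    new = gametes.reshape(d, N, 2, L)

    out = MetapopState(genotypes=new, generation=state.generation + 1)
    return mutate(out, params, gmap, rng)


def run(
    params: SimulationParams,
    gmap: GeneticMap,
    rng=None,
    *,
    include_ld: bool = False,
    keep_final_state: bool = True,
) -> SimulationResult:
    """Run the configured horizon, sampling metrics every sample_every steps.

    Fully reproducible from params.seed (or an explicit rng).  Metrics are
    computed on the whole census (all 2N haplotypes per patch) by
    :func:`msdiv.diversity.locus_metrics`.
    """
    from .diversity import locus_metrics

    if params.generations < params.sample_every:
        raise ValueError("generations must be >= sample_every")
    rng = _as_rng(rng if rng is not None else params.seed)
    M = migration_matrix(params)
    state = initialize(params, gmap, rng)

    metric_frames = []
    phen_rows = []

    def _sample(st: MetapopState) -> None:
        df = locus_metrics(st.genotypes, gmap, generation=st.generation,
                           include_ld=include_ld)
        metric_frames.append(df)
        zbar = phenotype(st.genotypes, gmap).mean(axis=1)
        for p, v in enumerate(zbar):
            phen_rows.append((st.generation, p, float(v)))

    for _ in range(params.generations):
        state = step_generation(state, params, gmap, rng, M=M)
        if state.generation % params.sample_every == 0:
            _sample(state)
    if state.generation % params.sample_every != 0:
        _sample(state)  # always report the final point

    metrics = pd.concat(metric_frames, ignore_index=True)
    phen = pd.DataFrame(phen_rows, columns=["generation", "patch", "mean_z"])
    return SimulationResult(
        params=params,
        gmap=gmap,
        metrics=metrics,
        phenotypes=phen,
        final_state=state if keep_final_state else None,
    )
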