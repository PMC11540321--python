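"""Nucleotide-diversity and differentiation statistics from haplotype state.

Conventions (documented because the neutral-expectation checks depend on
them):

* pi (within-population diversity) uses the unbiased Nei estimator: the
  probability that two distinct sequences differ, times n/(n-1).  For a
  diallelic locus this is 2p(1-p) * n/(n-1).
* d_xy (between-population diversity) carries no sample-size correction:
  for a diallelic locus, p_A(1-p_B) + p_B(1-p_A).
* F_ST is the Weir-Cockerham variance-components estimator for
  haploid-sampled allele counts; slightly negative values are retained.
  Multi-locus averages use the ratio-of-sums form.
* LD between a selected and a neutral locus is the squared Pearson
  correlation of allele indicators across pooled metapopulation haplotypes;
  continuum selected alleles are dichotomized by effect sign (>= 0 vs < 0).

All statistics are census statistics over the full 2N haplotypes per patch
(no subsampling).  Multiallelic continuum alleles are treated as distinct
states by exact value identity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import GeneticMap

__all__ = [
    "pi",
    "dxy",
    "fst_wc",
    "fst_wc_components",
    "fst_wc_multilocus",
    "ld_r2",
    "locus_metrics",
    "write_vcf",
]


def _freqs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, counts = np.unique(np.asarray(values).ravel(), return_counts=True)
    return vals, counts / counts.sum()


def pi(values) -> float:
    """Unbiased Nei diversity of one locus from n >= 2 sampled sequences.

    pi = (1 - sum_i x_i^2) * n / (n - 1) with x_i the frequencies of the
    distinct allelic states (pairwise difference = 1 for distinct states at
    one site).  Returns NaN for n < 2.
    """
    v = np.asarray(values).ravel()
    n = v.size
    if n < 2:
        return float("nan")
    _, x = _freqs(v)
    return float((1.0 - np.sum(x**2)) * n / (n - 1))


def dxy(values_a, values_b) -> float:
    """Between-population diversity at one locus (no sample-size correction).

    Probability that one sequence from A and one from B differ:
    sum over states of x_i * y_j * [state_i != state_j].
    """
    a = np.asarray(values_a).ravel()
    b = np.asarray(values_b).ravel()
    if a.size == 0 or b.size == 0:
        return float("nan")
    states = np.union1d(a, b)
    xa = np.array([(a == s).mean() for s in states])
    xb = np.array([(b == s).mean() for s in states])
    return float(1.0 - np.sum(xa * xb))


def fst_wc_components(counts) -> tuple[float, float]:
    """Weir-Cockerham numerator and denominator for haploid allele counts.

    counts: array (d, n_alleles) of allele counts per population.  Returns
    (num, den) with theta = num / den, where per allele
    MSP = sum_i n_i (p_i - pbar)^2 / (r - 1),
    MSG = sum_i n_i p_i (1 - p_i) / sum_i (n_i - 1),
    num_allele = MSP - MSG, den_allele = MSP + (n_c - 1) MSG,
    summed over alleles.  Suitable for ratio-of-sums averaging.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2:
        raise ValueError("counts must be (d, n_alleles)")
    r, _ = c.shape
    if r < 2:
        raise ValueError("F_ST needs at least two populations")
    n_i = c.sum(axis=1)
    if np.any(n_i < 2):
        raise ValueError("each population needs >= 2 sampled haplotypes")
    n_tot = n_i.sum()
    n_c = (n_tot - np.sum(n_i**2) / n_tot) / (r - 1)
    p = c / n_i[:, None]
    pbar = c.sum(axis=0) / n_tot
    num = den = 0.0
    for a in range(c.shape[1]):
        msp = np.sum(n_i * (p[:, a] - pbar[a]) ** 2) / (r - 1)
        msg = np.sum(n_i * p[:, a] * (1.0 - p[:, a])) / np.sum(n_i - 1.0)
        num += msp - msg
        den += msp + (n_c - 1.0) * msg
    return float(num), float(den)


def fst_wc(counts) -> float:
    """Weir-Cockerham theta-hat at one locus; NaN if the pooled sample is
    monomorphic (may be slightly negative, retained untruncated)."""
    num, den = fst_wc_components(counts)
    if den == 0.0:
        return float("nan")
    return num / den


def fst_wc_multilocus(counts_per_locus) -> float:
    """Ratio-of-sums multi-locus Weir-Cockerham estimate."""
    nums, dens = zip(*(fst_wc_components(c) for c in counts_per_locus))
    den = float(np.sum(dens))
    if den == 0.0:
        return float("nan")
    return float(np.sum(nums)) / den


def ld_r2(selected_classes, neutral_alleles) -> float:
    """Squared Pearson correlation between two 0/1 haplotype indicators.

    NaN when either locus is monomorphic in the pooled sample.
    """
    x = np.asarray(selected_classes, dtype=float).ravel()
    y = np.asarray(neutral_alleles, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("haplotype vectors must be the same length")
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def _pairwise_dxy_mean(p: np.ndarray) -> np.ndarray:
    """Mean diallelic d_xy over all unordered patch pairs; p is (d, L)."""
    d = p.shape[0]
    if d < 2:
        raise ValueError("need >= 2 patches")
    sum_p = p.sum(axis=0)
    sum_p2 = (p**2).sum(axis=0)
    n_pairs = d * (d - 1) / 2.0
    # sum over pairs of (pa + pb - 2 pa pb)
    tot = (d - 1) * sum_p - (sum_p**2 - sum_p2)
    return tot / n_pairs


def locus_metrics(
    genotypes: np.ndarray,
    gmap: GeneticMap,
    generation: int = 0,
    include_ld: bool = False,
) -> pd.DataFrame:
    """Per-locus census metrics for a metapopulation snapshot.

    Returns one row per locus with columns: generation, locus_id, kind,
    complement_id, distance_cM, pi_w_0..pi_w_{d-1}, pi_w_mean, pi_total,
    dxy (mean over patch pairs; for d=2 the single pair), fst, and
    r2_with_selected when include_ld is set.

    Neutral and diallelic selected loci are computed vectorized from allele
    frequencies; continuum selected loci fall back to the generic
    multiallelic estimators.
    """
    g = np.asarray(genotypes, dtype=float)
    d, N, _, L = g.shape
    n = 2 * N  # haplotypes per patch

    hap = g.reshape(d, n, L)
    # indicator of the "high" allele: works for 0/1 neutrals and +/-a diallelics
    high = hap > 0.0
    p = high.mean(axis=1)  # (d, L)

    corr_w = n / (n - 1.0)
    pi_w = 2.0 * p * (1.0 - p) * corr_w
    pbar = p.mean(axis=0)
    nt = n * d
    pi_total = 2.0 * pbar * (1.0 - pbar) * nt / (nt - 1.0)
    dxy_mean = _pairwise_dxy_mean(p)

    counts_high = (p * n).round()
    fst = np.full(L, np.nan)
    poly = (pbar > 0.0) & (pbar < 1.0)
    if poly.any():
        for j in np.flatnonzero(poly):
            c = np.stack([counts_high[:, j], n - counts_high[:, j]], axis=1)
            fst[j] = fst_wc(c)

    # Selected loci whose states the >0 indicator cannot separate (continuum
    # alleles) are redone with exact multiallelic state identity.
    sel = gmap.selected_idx
    is_multiallelic = np.zeros(L, dtype=bool)
    for j in sel:
        states = np.unique(hap[:, :, j])
        if len(states) > 2 or (
            len(states) == 2 and not states[0] <= 0.0 < states[1]
        ):
            is_multiallelic[j] = True
    for j in np.flatnonzero(is_multiallelic):
        cols = [hap[q, :, j] for q in range(d)]
        pi_w[:, j] = [pi(c) for c in cols]
        pooled = hap[:, :, j].ravel()
        states, x = _freqs(pooled)
        pi_total[j] = (1.0 - np.sum(x**2)) * nt / (nt - 1.0)
        pair_vals = [
            dxy(cols[a], cols[b]) for a in range(d) for b in range(a + 1, d)
        ]
        dxy_mean[j] = float(np.mean(pair_vals))
        if len(states) > 1:
            cmat = np.stack(
                [[(cols[q] == s).sum() for s in states] for q in range(d)]
            )
            fst[j] = fst_wc(cmat)
        else:
            fst[j] = np.nan

    out = {
        "generation": np.full(L, generation),
        "locus_id": np.array([l.locus_id for l in gmap.loci]),
        "kind": np.array([l.kind for l in gmap.loci]),
        "complement_id": gmap.complement_id,
        "distance_cM": gmap.signed_distance_cM,
    }
    for q in range(d):
        out[f"pi_w_{q}"] = pi_w[q]
    out["pi_w_mean"] = pi_w.mean(axis=0)
    out["pi_total"] = pi_total
    out["dxy"] = dxy_mean
    out["fst"] = fst

    if include_ld:
        r2 = np.full(L, np.nan)
        pooled = hap.reshape(d * n, L)
        for j in sel:
            cls = (pooled[:, j] >= 0.0).astype(float) if is_multiallelic[j] else (
                pooled[:, j] > 0.0
            ).astype(float)
            mask = gmap.complement_id == gmap.complement_id[j]
            for k in np.flatnonzero(mask):
                if k == j:
                    continue
                r2[k] = ld_r2(cls, pooled[:, k])
        out["r2_with_selected"] = r2

    return pd.DataFrame(out)


def write_vcf(genotypes: np.ndarray, gmap: GeneticMap, path: str | Path,
              generation: int = 0) -> None:
    """Export a snapshot of the diallelic loci as an uncompressed VCF.

    Haploid-phased diploid GT records, one pseudo-contig per complement with
    positions 1e4 * (signed offset + max offset) + 1 to keep ordering; meant
    for cross-checking allele frequencies with external tooling, not as a
    physical-coordinate export.  Continuum (multiallelic real-valued) loci
    are skipped.
    """
    g = np.asarray(genotypes)
    d, N, _, L = g.shape
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=msdiv_snapshot_generation_{generation}",
    ]
    comps = sorted(set(gmap.complement_id.tolist()))
    for c in comps:
        lines.append(f"##contig=<ID=comp{c}>")
    samples = [f"p{q}_i{i}" for q in range(d) for i in range(N)]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    offmax = np.abs(gmap.signed_distance_cM).max()
    for j, loc in enumerate(gmap.loci):
        vals = np.unique(g[:, :, :, j])
        diallelic = np.all(np.isin(vals, [0.0, 1.0])) or (
            len(vals) <= 2 and np.allclose(vals, -vals[::-1]) and vals[-1] > 0
        )
        if not diallelic:
            continue
        high = g[:, :, :, j] > 0.0
        pos = int(round((loc.signed_distance_cM + offmax) * 1e4)) + 1
        gts = "\t".join(
            f"{int(high[q, i, 0])}|{int(high[q, i, 1])}"
            for q in range(d)
            for i in range(N)
        )
        lines.append(
            f"comp{loc.complement_id}\t{pos}\tL{loc.locus_id}\tA\tT\t.\tPASS\t"
            f"KIND={loc.kind}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
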