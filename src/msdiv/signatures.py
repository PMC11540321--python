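"""Summary signatures of local adaptation around a selected locus.

Positive diversity-distance slope (metric regressed on log10 map distance)
means a *trough*: diversity depleted near the selected site, as with
background selection or a sweep.  Negative slope means a *peak*: diversity
inflated near the selected site by migrant haplotypes held at
migration-selection balance — the signature this package exists to
characterize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SignatureReport",
    "dd_slope",
    "near_far_contrast",
    "background_level",
    "detect_peak",
    "peak_width",
    "adaptive_differentiation",
    "critical_migration",
    "maintains_local_adaptation",
    "summarize_adaptive_alleles",
    "signature_report",
]


@dataclass
class SignatureReport:
    dd_slope: float
    slope_p: float
    fst_slope: float | None
    near_pi: float
    far_pi: float
    background_pi: float | None
    peak_detected: bool
    peak_width_cM: float | None
    patch_id: int | None = None
    generation: int | None = None


def dd_slope(metric, distance_cM) -> tuple[float, float]:
    """OLS slope of a per-locus metric on log10(|distance in cM|).

    Pools both flanks (uses absolute distance).  Returns (slope, two-sided
    t-test p-value for slope = 0); a constant metric gives (0.0, 1.0).
    """
    y = np.asarray(metric, dtype=float)
    x = np.abs(np.asarray(distance_cM, dtype=float))
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValueError("need at least 3 loci for the distance regression")
    if np.any(x <= 0):
        raise ValueError("distances must be positive (exclude the selected locus)")
    if np.ptp(y) == 0.0:
        return 0.0, 1.0
    res = stats.linregress(np.log10(x), y)
    return float(res.slope), float(res.pvalue)


def near_far_contrast(
    metric, distance_cM, near_cM: float = 1e-3, far_cM: float = 10.0
) -> tuple[float, float]:
    """Mean metric over the flanking loci at exactly near_cM and far_cM."""
    y = np.asarray(metric, dtype=float)
    x = np.abs(np.asarray(distance_cM, dtype=float))
    near = np.isclose(x, near_cM, rtol=1e-9, atol=0.0)
    far = np.isclose(x, far_cM, rtol=1e-9, atol=0.0)
    if not near.any() or not far.any():
        raise ValueError(
            f"map has no loci at the contrast distances {near_cM} / {far_cM} cM"
        )
    return float(y[near].mean()), float(y[far].mean())


def background_level(
    pi_w, distance_cM, band: tuple[float, float] = (9.0, 10.0)
) -> float:
    """Genome-wide background diversity from neutral-control runs.

    Mean pi_w over all loci whose |distance| lies in the 9-10 cM band,
    pooled across whatever replicates are passed in.  Intended for runs with
    V_S = 1e9 (effectively neutral) on a map extended with background loci.
    """
    y = np.asarray(pi_w, dtype=float)
    x = np.abs(np.asarray(distance_cM, dtype=float))
    lo, hi = band
    mask = (x >= lo) & (x <= hi) & np.isfinite(y)
    if not mask.any():
        raise ValueError(f"no loci in the background band [{lo}, {hi}] cM")
    return float(y[mask].mean())


def detect_peak(
    pi_w, distance_cM, background: float, alpha: float = 0.05,
    min_fraction: float = 0.25, excess: float = 1.1,
) -> bool:
    """Peak call: significant negative diversity-distance slope AND at least
    25% of neutral loci with pi_w above 1.1x the background level."""
    if background <= 0:
        raise ValueError("background must be positive")
    slope, p = dd_slope(pi_w, distance_cM)
    y = np.asarray(pi_w, dtype=float)
    frac = np.mean(y > excess * background)
    return bool(slope < 0 and p < alpha and frac >= min_fraction)


def peak_width(pi_w, distance_cM, background: float) -> float | None:
    """Peak width: 2x the x-intercept of pi_w regressed on linear |distance|
    over the loci exceeding the background level.

    The linear-cM scale is used so the x-intercept is directly a distance;
    a nonnegative slope or nonpositive intercept yields None (with a
    warning), as does a degenerate regression (< 3 qualifying loci or all at
    one distance).
    """
    y = np.asarray(pi_w, dtype=float)
    x = np.abs(np.asarray(distance_cM, dtype=float))
    mask = np.isfinite(y) & (y > background)
    if mask.sum() < 3 or np.ptp(x[mask]) == 0.0:
        return None
    res = stats.linregress(x[mask], y[mask])
    if res.slope >= 0:
        warnings.warn("diversity does not decline with distance; no peak width")
        return None
    x0 = -res.intercept / res.slope
    if x0 <= 0:
        warnings.warn("nonpositive x-intercept; no peak width")
        return None
    return float(2.0 * x0)


def adaptive_differentiation(p_by_patch, threshold: float = 0.95) -> float:
    """Fraction of adaptive loci with |p_patch1 - p_patch2| >= threshold.

    p_by_patch: array (2, n_loci) of adaptive-allele frequencies.
    """
    p = np.asarray(p_by_patch, dtype=float)
    if p.ndim != 2 or p.shape[0] != 2:
        raise ValueError("expected frequencies for exactly two patches")
    return float(np.mean(np.abs(p[0] - p[1]) >= threshold))


def critical_migration(
    maintenance: Mapping[float, Sequence[bool]]
) -> float | None:
    """Largest grid migration rate at which local adaptation is maintained.

    maintenance maps each grid m to per-replicate booleans (True = the run
    maintained local adaptation at its final sampling point); a rate counts
    as maintained when a majority of replicates did.  Returns None when no
    rate qualifies.
    """
    maintained = [
        m for m, flags in maintenance.items()
        if len(flags) and np.mean(flags) > 0.5
    ]
    if not maintained:
        return None
    return float(max(maintained))


def maintains_local_adaptation(
    result, fraction: float = 0.5, criterion: str = "phenotype"
) -> bool:
    """Whether a finished run maintained local adaptation at its end point.

    criterion="phenotype": the difference in patch-mean phenotype between
    the two extreme patches exceeds ``fraction`` of their optimum gap.
    criterion="allele_sign": the frequency of positive-effect alleles at the
    selected loci differs by >= ``fraction`` between the extreme patches
    (sensitivity variant).
    """
    params = result.params
    theta = np.asarray(params.theta)
    lo, hi = int(np.argmin(theta)), int(np.argmax(theta))
    if criterion == "phenotype":
        final = result.phenotypes[
            result.phenotypes.generation == result.phenotypes.generation.max()
        ]
        zbar = final.set_index("patch").mean_z
        gap = theta[hi] - theta[lo]
        return bool(abs(zbar[hi] - zbar[lo]) > fraction * gap)
    if criterion == "allele_sign":
        g = result.final_state.genotypes
        sel = result.gmap.selected_idx
        p = (g[:, :, :, sel] > 0).mean(axis=(1, 2))  # (d, n_sel)
        return bool(np.mean(np.abs(p[hi] - p[lo])) >= fraction)
    raise ValueError(f"unknown criterion {criterion!r}")


def summarize_adaptive_alleles(
    allele_values_by_patch: Sequence[np.ndarray], resolution: float = 0.05
) -> pd.DataFrame:
    """Cluster continuum allele values into effect classes per patch.

    Allele values are rounded to ``resolution``; returns a tidy frame
    (patch, effect_class, frequency) plus the per-patch count of segregating
    classes in column n_classes.
    """
    rows = []
    for q, vals in enumerate(allele_values_by_patch):
        v = np.round(np.asarray(vals, dtype=float) / resolution) * resolution
        classes, counts = np.unique(v, return_counts=True)
        freqs = counts / counts.sum()
        for cls, f in zip(classes, freqs):
            rows.append((q, float(cls), float(f), len(classes)))
    return pd.DataFrame(
        rows, columns=["patch", "effect_class", "frequency", "n_classes"]
    )


def signature_report(
    locus_df: pd.DataFrame,
    background: float | None = None,
    patch: int | None = None,
    value_col: str = "pi_w_mean",
) -> SignatureReport:
    """Full SignatureReport from one snapshot's locus-metrics frame.

    Uses the neutral loci only; ``value_col`` selects which diversity column
    is regressed (patch-mean by default, or a single patch's pi_w_{p}).
    """
    neu = locus_df[locus_df.kind == "neutral"]
    col = value_col if patch is None else f"pi_w_{patch}"
    y = neu[col].to_numpy()
    x = neu.distance_cM.to_numpy()
    slope, p = dd_slope(y, x)
    fst_sl = None
    if neu.fst.notna().sum() >= 3:
        sub = neu[neu.fst.notna()]
        fst_sl, _ = dd_slope(sub.fst.to_numpy(), sub.distance_cM.to_numpy())
    near, far = near_far_contrast(y, x)
    peak = False
    width = None
    if background is not None and background > 0:
        peak = detect_peak(y, x, background)
        if peak:
            width = peak_width(y, x, background)
    gen = int(locus_df.generation.iloc[0]) if "generation" in locus_df else None
    return SignatureReport(
        dd_slope=slope, slope_p=p, fst_slope=fst_sl, near_pi=near, far_pi=far,
        background_pi=background, peak_detected=peak, peak_width_cM=width,
        patch_id=patch, generation=gen,
    )
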