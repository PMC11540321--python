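"""Genetic maps for a chromosome of selected loci with neutral flanks.

A map is an ordered list of loci grouped into *complements*: one divergently
selected locus symmetrically flanked by neutral loci at log-spaced map
distances (default 10^-3 to 10 cM, 37 per side).  Adjacent complements are
separated so that the interval spanning them recombines freely (r = 0.5),
i.e. each complement is unlinked from every other.

Distances are stored as signed cM offsets from the complement's selected
locus (negative = left flank).  Per-interval recombination fractions follow
the linear convention r = min(d/100, 0.5) with independent crossovers per
interval (no interference, no map function); this makes a 50 cM gap exactly
unlinked, which a map function such as Haldane's would not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LocusSpec",
    "GeneticMap",
    "build_flanking_map",
    "add_background_loci",
    "cm_to_recfrac",
    "unlinked_loci_map",
]

SELECTED = "selected"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class LocusSpec:
    """One locus on the map.

    signed_distance_cM is the offset from the complement's selected locus
    (0 for the selected locus itself, negative on the left flank).
    """

    locus_id: int
    kind: str
    complement_id: int
    signed_distance_cM: float


@dataclass
class GeneticMap:
    """Ordered loci plus per-adjacent-interval recombination fractions."""

    loci: list[LocusSpec]
    rec_fractions: np.ndarray
    n_complements: int

    # cached index arrays, filled in __post_init__
    selected_idx: np.ndarray = field(init=False, repr=False)
    neutral_idx: np.ndarray = field(init=False, repr=False)
    signed_distance_cM: np.ndarray = field(init=False, repr=False)
    complement_id: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.rec_fractions = np.asarray(self.rec_fractions, dtype=float)
        if len(self.rec_fractions) != len(self.loci) - 1:
            raise ValueError(
                f"need {len(self.loci) - 1} recombination fractions for "
                f"{len(self.loci)} loci, got {len(self.rec_fractions)}"
            )
        if np.any(self.rec_fractions < 0) or np.any(self.rec_fractions > 0.5):
            raise ValueError("recombination fractions must lie in [0, 0.5]")
        kinds = np.array([l.kind for l in self.loci])
        self.selected_idx = np.flatnonzero(kinds == SELECTED)
        self.neutral_idx = np.flatnonzero(kinds == NEUTRAL)
        self.signed_distance_cM = np.array(
            [l.signed_distance_cM for l in self.loci], dtype=float
        )
        self.complement_id = np.array([l.complement_id for l in self.loci])

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def abs_distance_cM(self) -> np.ndarray:
        return np.abs(self.signed_distance_cM)

    def to_tsv(self, path: str | Path) -> None:
        """Export the 4-column map table (header line included)."""
        df = pd.DataFrame(
            {
                "locus_id": [l.locus_id for l in self.loci],
                "kind": [l.kind for l in self.loci],
                "complement_id": [l.complement_id for l in self.loci],
                "signed_distance_cM": self.signed_distance_cM,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticMap":
        """Rebuild a map from its TSV export.

        Within-complement recombination fractions are recovered from the
        signed distances; the interval between complements is set to 0.5.
        """
        df = pd.read_csv(path, sep="\t")
        required = {"locus_id", "kind", "complement_id", "signed_distance_cM"}
        if not required.issubset(df.columns):
            raise ValueError(f"map TSV needs columns {sorted(required)}")
        loci = [
            LocusSpec(int(r.locus_id), str(r.kind), int(r.complement_id),
                      float(r.signed_distance_cM))
            for r in df.itertuples(index=False)
        ]
        return _with_recfracs(loci)


def cm_to_recfrac(d_cM):
    """Map distance (cM) -> recombination fraction, r = min(d/100, 0.5).

    Applied independently per adjacent-locus interval (no interference).
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = np.minimum(d / 100.0, 0.5)
    return float(r) if np.isscalar(d_cM) else r


def _with_recfracs(loci: list[LocusSpec]) -> GeneticMap:
    """Assemble a GeneticMap, deriving interval fractions from distances."""
    rec = np.empty(len(loci) - 1)
    for i in range(len(loci) - 1):
        a, b = loci[i], loci[i + 1]
        if a.complement_id != b.complement_id:
            rec[i] = 0.5
        else:
            gap = b.signed_distance_cM - a.signed_distance_cM
            if gap <= 0:
                raise ValueError(
                    "map positions must be strictly increasing within a complement"
                )
            rec[i] = cm_to_recfrac(gap)
    n_comp = len({l.complement_id for l in loci})
    return GeneticMap(loci=loci, rec_fractions=rec, n_complements=n_comp)


def build_flanking_map(
    n_selected: int = 1,
    n_flank_per_side: int = 37,
    min_cM: float = 1e-3,
    max_cM: float = 10.0,
    complement_gap_cM: float = 50.0,
) -> GeneticMap:
    """Build the standard chromosome: selected loci with log-spaced flanks.

    Each selected locus is symmetrically flanked by ``n_flank_per_side``
    neutral loci per side at distances 10^x for x evenly spaced on
    [log10(min_cM), log10(max_cM)].  Adjacent complements are separated by
    ``complement_gap_cM`` between their nearest loci, which under the linear
    r = d/100 convention makes the inter-complement interval r = 0.5
    (fully unlinked) for any gap >= 50 cM.
    """
    if n_selected < 1:
        raise ValueError("n_selected must be >= 1")
    if n_flank_per_side < 0:
        raise ValueError("n_flank_per_side must be >= 0")
    if min_cM <= 0:
        raise ValueError("min_cM must be positive (log spacing)")
    if max_cM < min_cM:
        raise ValueError("max_cM must be >= min_cM")
    if max_cM == min_cM and n_flank_per_side > 1:
        raise ValueError("min_cM == max_cM allows at most one flank per side")
    if complement_gap_cM < 50 and n_selected > 1:
        raise ValueError(
            "complement gap below 50 cM would leave complements linked"
        )

    if n_flank_per_side:
        exps = np.linspace(np.log10(min_cM), np.log10(max_cM), n_flank_per_side)
        flank = 10.0 ** exps
    else:
        flank = np.empty(0)

    loci: list[LocusSpec] = []
    lid = 0
    for c in range(n_selected):
        offsets = np.concatenate([-flank[::-1], [0.0], flank])
        for off in offsets:
            kind = SELECTED if off == 0.0 else NEUTRAL
            loci.append(LocusSpec(lid, kind, c, float(off)))
            lid += 1
    gm = _with_recfracs(loci)
    if n_selected > 1:
        # boundary intervals span complement_gap_cM >= 50 cM -> r = 0.5 already
        assert np.all(
            gm.rec_fractions[np.flatnonzero(np.diff(gm.complement_id))] == 0.5
        )
    return gm


def add_background_loci(gmap: GeneticMap, n_per_side: int = 100) -> GeneticMap:
    """Add evenly spaced neutral loci on the linear [9, 10] cM band, each side.

    Used for calibrating genome-wide background diversity: the extra loci sit
    9-10 cM from the selected locus where linkage effects are weakest.  Loci
    that would coincide exactly with an existing position are dropped
    (existing loci win), so the default map (which already has a locus at
    10 cM) gains 99 loci per side.
    """
    if gmap.n_complements != 1:
        raise ValueError("background loci are only added to single-complement maps")
    if n_per_side < 0:
        raise ValueError("n_per_side must be >= 0")
    if n_per_side == 0:
        return gmap
    existing = set(gmap.signed_distance_cM.tolist())
    extra = np.linspace(9.0, 10.0, n_per_side) if n_per_side > 1 else np.array([9.0])
    offsets = sorted(
        {float(o) for side in (-extra, extra) for o in side} - existing
    )
    comp = gmap.loci[0].complement_id
    merged = sorted(
        [(l.signed_distance_cM, l.kind) for l in gmap.loci]
        + [(o, NEUTRAL) for o in offsets]
    )
    loci = [
        LocusSpec(i, kind, comp, off) for i, (off, kind) in enumerate(merged)
    ]
    return _with_recfracs(loci)


def unlinked_loci_map(n_selected: int, n_neutral: int = 0) -> GeneticMap:
    """A map of mutually unlinked loci (r = 0.5 between every adjacent pair).

    Selected loci come first (each its own complement), then neutral loci in
    additional complements at offset 0 relative to a notional selected site.
    Handy for architectures where linkage is irrelevant (e.g. redundant
    polygenic traits whose adaptive loci are all on separate complements) and
    for neutral calibration runs.
    """
    loci = []
    lid = 0
    for c in range(n_selected):
        loci.append(LocusSpec(lid, SELECTED, c, 0.0))
        lid += 1
    for j in range(n_neutral):
        loci.append(LocusSpec(lid, NEUTRAL, n_selected + j, 0.0))
        lid += 1
    rec = np.full(max(len(loci) - 1, 0), 0.5)
    return GeneticMap(loci=loci, rec_fractions=rec, n_complements=len(loci))
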