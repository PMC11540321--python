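"""Parameter grids, replicate management and batch experiment orchestration.

The four experiment designs (two-patch single locus, two-patch polygenic with and
without genotypic redundancy, ten-patch stepping stone) each restrict which
grid dimensions are active; ``expand_grid`` enforces those restrictions and
derives deterministic per-cell, per-replicate seeds from a base seed.

A single ``scale_factor`` shrinks patch size N and the 25*N*d horizon
together, preserving the drift time scale for desk runs; continuum-model
cells can opt into the scaled adaptive mutation rate 1e-2/N so that the
per-generation mutational input matches the full-size runs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import engine
from .engine import CONTINUUM, NONREDUNDANT, REDUNDANT, SimulationParams
from .genmap import GeneticMap, build_flanking_map

__all__ = [
    "ExperimentGrid",
    "ExperimentCell",
    "migration_grid",
    "expand_grid",
    "neutral_expectation",
    "summarize_replicates",
    "run_experiment",
]

logger = logging.getLogger("msdiv")

MODELS = ("single2patch", "multi_nonredundant", "multi_redundant", "single10patch")

_DEFAULT_VS = {
    "single2patch": (2.0, 5.0, 10.0, 25.0, 100.0, 1e9),
    "multi_nonredundant": (5.0,),
    "multi_redundant": (5.0,),
    "single10patch": (5.0,),
}
_DEFAULT_N = {
    "single2patch": (500, 1000, 2000, 10000),
    "multi_nonredundant": (1000,),
    "multi_redundant": (1000,),
    "single10patch": (1000,),
}
_DEFAULT_L = {
    "single2patch": (1,),
    "multi_nonredundant": (1, 2, 4, 10, 20, 50, 100),
    "multi_redundant": (4, 10, 20, 50, 100),
    "single10patch": (1,),
}
# "scaled" marks the population-size-standardized continuum rate 1e-2/N
_DEFAULT_MU_A = {
    "single2patch": (1e-5, "scaled"),
    "multi_nonredundant": (1e-5,),
    "multi_redundant": (1e-5, 1e-4),
    "single10patch": (1e-5,),
}


def migration_grid(include_zero: bool = True) -> np.ndarray:
    """Forward migration rates 10^-5 ... 10^-0.5, four steps per decade,
    optionally with m = 0 prepended (20 values total by default)."""
    grid = 10.0 ** np.linspace(-5.0, -0.5, 19)
    if include_zero:
        grid = np.concatenate([[0.0], grid])
    return grid


@dataclass
class ExperimentGrid:
    model: str
    m_grid: Sequence[float] = field(default_factory=migration_grid)
    V_S_grid: Sequence[float] | None = None
    N_grid: Sequence[int] | None = None
    l_grid: Sequence[int] | None = None
    mu_adaptive_grid: Sequence | None = None
    theta_mode: str = "divergent"  # or "uniform" (redundant model only)
    replicates: int = 10
    base_seed: int = 0
    scale_factor: float = 1.0
    generations: int | None = None  # explicit override for smoke runs
    sample_every: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; one of {MODELS}")
        if self.V_S_grid is None:
            self.V_S_grid = _DEFAULT_VS[self.model]
        if self.N_grid is None:
            self.N_grid = _DEFAULT_N[self.model]
        if self.l_grid is None:
            self.l_grid = _DEFAULT_L[self.model]
        if self.mu_adaptive_grid is None:
            self.mu_adaptive_grid = _DEFAULT_MU_A[self.model]
        if self.theta_mode not in ("divergent", "uniform"):
            raise ValueError("theta_mode must be 'divergent' or 'uniform'")
        if self.theta_mode == "uniform" and self.model != "multi_redundant":
            raise ValueError(
                "uniform optima are defined only for the multi_redundant "
                "design row (MultiLocus, Redundant, Two-Patch)"
            )
        m = np.asarray(self.m_grid, dtype=float)
        if np.any((m != 0) & ((m < 0) | (m > 10**-0.5 + 1e-12))):
            raise ValueError("m_grid values must lie in {0} or [0, 10^-0.5]")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


@dataclass
class ExperimentCell:
    cell_id: str
    params: SimulationParams
    gmap: GeneticMap
    replicate: int
    model: str


def _validate_cell(grid: ExperimentGrid, V_S, N, l, mu_a) -> None:
    row = {
        "single2patch": "Single-Locus, Two-Patch",
        "multi_nonredundant": "MultiLocus, Nonredundant, Two-Patch",
        "multi_redundant": "MultiLocus, Redundant, Two-Patch",
        "single10patch": "Single-Locus, Ten-Patch",
    }[grid.model]
    if V_S not in _DEFAULT_VS[grid.model] and grid.model != "single2patch":
        raise ValueError(f"V_S={V_S} is not defined for the {row} design row")
    if l not in _DEFAULT_L[grid.model]:
        raise ValueError(
            f"l={l} adaptive loci is not defined for the {row} design row"
        )
    if grid.model != "single2patch" and N not in _DEFAULT_N[grid.model] and (
        grid.scale_factor == 1.0
    ):
        raise ValueError(f"N={N} is not defined for the {row} design row")


def expand_grid(grid: ExperimentGrid) -> list[ExperimentCell]:
    """Cartesian product over the grid's active dimensions x replicates.

    Per-cell seeds derive deterministically from base_seed via
    numpy SeedSequence spawn keys, so a rerun reproduces every replicate.
    """
    model = grid.model
    d = 10 if model == "single10patch" else 2
    effect_model = {
        "single2patch": CONTINUUM,
        "single10patch": CONTINUUM,
        "multi_nonredundant": NONREDUNDANT,
        "multi_redundant": REDUNDANT,
    }[model]

    maps: dict[int, GeneticMap] = {}
    cells: list[ExperimentCell] = []
    cell_idx = 0
    for l in grid.l_grid:
        if l not in maps:
            maps[l] = build_flanking_map(n_selected=l)
        for N_full in grid.N_grid:
            N = max(int(round(N_full * grid.scale_factor)), 2)
            for V_S in grid.V_S_grid:
                for mu_a in grid.mu_adaptive_grid:
                    _validate_cell(grid, V_S, N_full, l, mu_a)
                    mu_val = 1e-2 / N if mu_a == "scaled" else float(mu_a)
                    for m in grid.m_grid:
                        if grid.theta_mode == "uniform":
                            theta = (1.0, 1.0)
                        else:
                            theta = None  # engine default: divergent gradient
                        for rep in range(grid.replicates):
                            ss = np.random.SeedSequence(
                                entropy=grid.base_seed,
                                spawn_key=(cell_idx, rep),
                            )
                            params = SimulationParams(
                                N=N, m=float(m), V_S=float(V_S), d=d,
                                theta=theta, effect_model=effect_model,
                                n_adaptive=l, mu_adaptive=mu_val,
                                generations=grid.generations,
                                sample_every=grid.sample_every,
                                seed=ss,
                            )
                            cid = (
                                f"{model}_l{l}_N{N}_Vs{V_S:g}_mu{mu_val:g}"
                                f"_m{m:.5g}_{grid.theta_mode}"
                            )
                            cells.append(
                                ExperimentCell(cid, params, maps[l], rep, model)
                            )
                        cell_idx += 1
    return cells


def neutral_expectation(N: int, d: int, mu: float, m: float) -> float:
    """Island-model neutral per-locus diversity: 4*N*mu for an isolated deme
    (m = 0), 4*d*N*mu with any migration (small-theta approximation)."""
    if N <= 0 or d <= 0 or mu < 0 or m < 0:
        raise ValueError("arguments must be positive (mu, m non-negative)")
    return 4.0 * N * mu if m == 0 else 4.0 * d * N * mu


def summarize_replicates(
    df: pd.DataFrame,
    value_col: str,
    by: Iterable[str] = ("locus_id", "generation"),
    quantiles: Sequence[float] = (0.05, 0.25, 0.75, 0.95),
) -> pd.DataFrame:
    """Mean, median and quantile bands of a metric across replicates.

    The arithmetic mean and the median are both reported because they can
    disagree badly at low migration, where rare recent-migrant replicates
    inflate the mean far above the typical replicate.
    """
    g = df.groupby(list(by))[value_col]
    out = g.agg(mean="mean", median="median", n="count")
    for q in quantiles:
        out[f"q{int(q * 100):02d}"] = g.quantile(q)
    return out.reset_index()


# --------------------------------------------------------------------------
# batch driver

_CONFIG_KEYS = {
    "schema", "model", "m", "V_S", "N", "l", "mu_adaptive", "theta_mode",
    "replicates", "base_seed", "scale_factor", "generations", "sample_every",
    "include_ld",
}


def _load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if cfg.get("schema") != 1:
        raise ValueError("config must declare 'schema: 1'")
    return cfg


def _grid_from_config(cfg: dict) -> ExperimentGrid:
    kw = {}
    for src, dst in [
        ("m", "m_grid"), ("V_S", "V_S_grid"), ("N", "N_grid"),
        ("l", "l_grid"), ("mu_adaptive", "mu_adaptive_grid"),
        ("theta_mode", "theta_mode"), ("replicates", "replicates"),
        ("base_seed", "base_seed"), ("scale_factor", "scale_factor"),
        ("generations", "generations"), ("sample_every", "sample_every"),
    ]:
        if src in cfg:
            kw[dst] = cfg[src]
    return ExperimentGrid(model=cfg["model"], **kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(
    config_path: str | Path, out_dir: str | Path, resume: bool = True
) -> Path:
    """Run every cell/replicate of a config and write tidy TSV outputs.

    Per cell: ``metrics_<cell>.tsv`` (locus metrics of every replicate,
    stacked with a replicate column) and one ``signatures.tsv`` across all
    cells.  A ``manifest.tsv`` lists every emitted file with its sha256.
    Existing per-cell outputs are never overwritten: with resume=True they
    are skipped, otherwise an error is raised.
    """
    from .signatures import signature_report

    cfg = _load_config(config_path)
    grid = _grid_from_config(cfg)
    include_ld = bool(cfg.get("include_ld", False))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    cells = expand_grid(grid)
    by_cell: dict[str, list[ExperimentCell]] = {}
    for c in cells:
        by_cell.setdefault(c.cell_id, []).append(c)

    sig_rows = []
    written: list[Path] = []
    for cid, reps in by_cell.items():
        target = out / f"metrics_{cid}.tsv"
        if target.exists():
            if resume:
                logger.info("cell %s: output exists, skipping", cid)
                written.append(target)
                continue
            raise FileExistsError(f"{target} exists; use resume=True")
        frames = []
        for cell in reps:
            logger.info("cell %s replicate %d: running", cid, cell.replicate)
            res = engine.run(cell.params, cell.gmap, include_ld=include_ld,
                             keep_final_state=False)
            df = res.metrics.copy()
            df.insert(0, "replicate", cell.replicate)
            df.insert(0, "cell_id", cid)
            frames.append(df)
            final = df[df.generation == df.generation.max()]
            rep = signature_report(final)
            sig_rows.append(
                {
                    "cell_id": cid, "model": cell.model,
                    "m": cell.params.m, "V_S": cell.params.V_S,
                    "N": cell.params.N, "l": cell.params.n_adaptive,
                    "replicate": cell.replicate,
                    "generation": rep.generation,
                    "dd_slope": rep.dd_slope, "slope_p": rep.slope_p,
                    "fst_slope": rep.fst_slope,
                    "near_pi": rep.near_pi, "far_pi": rep.far_pi,
                }
            )
        pd.concat(frames, ignore_index=True).to_csv(target, sep="\t", index=False)
        written.append(target)

    if sig_rows:
        sig_path = out / "signatures.tsv"
        sig_df = pd.DataFrame(sig_rows)
        if sig_path.exists() and resume:
            old = pd.read_csv(sig_path, sep="\t")
            sig_df = pd.concat([old, sig_df], ignore_index=True)
        sig_df.to_csv(sig_path, sep="\t", index=False)
        written.append(sig_path)

    manifest = pd.DataFrame(
        {"path": [p.name for p in written], "sha256": [_sha256(p) for p in written]}
    )
    manifest_path = out / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return out
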