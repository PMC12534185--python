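"""Stochastic well-mixed simulator of competing seeded and bulk nucleation.

A fixed pool of tiles is consumed by three event classes, simulated exactly
with the Gillespie stochastic simulation algorithm (SSA):

* bulk (homogeneous) nucleation, at a propensity proportional to the CNT
  homogeneous rate times the free-tile fraction — creates an unseeded
  structure;
* per-seed (heterogeneous) nucleation, proportional to the CNT
  heterogeneous rate per seed site times the free-tile fraction — each seed
  nucleates at most once and creates a seeded structure;
* growth of an existing structure, proportional to its perimeter (√size for
  a 2D aggregate) times the free-tile fraction; an area-independent variant
  is selectable.

All rates are in reduced units: the simulator reproduces trends with seed
count and temperature (more seeds → more, smaller, more uniform lattices;
colder → more bulk nucleation → lower seeded fraction), not calendar hours
or molar concentrations.  Tile mass is conserved on every trajectory.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .nucleation import TileThermo, WettingSpec, nucleation_rates


@dataclass(frozen=True)
class SimConfig:
    seed_count: int
    tile_pool: int
    T_C: float
    thermo: TileThermo
    wetting: WettingSpec
    growth_rate_const: float
    duration: float
    rng_seed: int
    growth_law: str = "perimeter"  # 'perimeter' (∝ √size) or 'constant'
    method: str = "ssa"  # 'ssa' or 'tau'
    tau: float = 1e-3  # leap interval for method='tau'

    def __post_init__(self) -> None:
        if self.seed_count < 0 or self.tile_pool < 0:
            raise ValueError("counts must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.growth_law not in ("perimeter", "constant"):
            raise ValueError("growth_law must be 'perimeter' or 'constant'")
        if self.method not in ("ssa", "tau"):
            raise ValueError("method must be 'ssa' or 'tau'")
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory for reproducibility")


@dataclass
class SimResult:
    seeded: np.ndarray  # (n_structures,) bool
    sizes: np.ndarray  # (n_structures,) tiles
    free_tiles_final: int
    tile_pool: int
    t_final: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"seeded": self.seeded, "size": self.sizes})


@dataclass(frozen=True)
class GrowthSummary:
    seeded_fraction_pct: float
    mean_size: float
    sd_size: float
    n_structures: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "seeded_fraction_pct": self.seeded_fraction_pct,
                "mean_size": self.mean_size,
                "sd_size": self.sd_size,
                "n_structures": self.n_structures,
            }
        )


def _rates(config: SimConfig) -> tuple:
    curves = nucleation_rates([config.T_C], config.thermo, config.wetting)
    return float(curves.N_homo[0]), float(curves.N_hetero[0])


def simulate_growth(config: SimConfig) -> SimResult:
    """Run one trajectory; exact SSA by default, reproducible via rng_seed."""
    rng = np.random.default_rng(config.rng_seed)
    n_homo_rate, n_het_rate = _rates(config)
    pool = config.tile_pool

    sizes: list = []
    seeded: list = []
    free = pool
    unused_seeds = config.seed_count
    t = 0.0
    g = config.growth_rate_const
    perimeter = config.growth_law == "perimeter"

    if config.method == "tau":
        return _simulate_tau(config, rng, n_homo_rate, n_het_rate)

    while t < config.duration and free > 0:
        ff = free / pool if pool else 0.0
        sz = np.asarray(sizes, dtype=float)
        grow_w = g * (np.sqrt(sz) if perimeter else np.ones_like(sz)) * ff
        a_homo = n_homo_rate * ff
        a_het = n_het_rate * unused_seeds * ff
        a_grow = float(grow_w.sum())
        a_tot = a_homo + a_het + a_grow
        if a_tot <= 0:
            break
        t += rng.exponential(1.0 / a_tot)
        if t >= config.duration:
            break
        u = rng.uniform(0.0, a_tot)
        if u < a_homo:
            sizes.append(1)
            seeded.append(False)
            free -= 1
        elif u < a_homo + a_het:
            sizes.append(1)
            seeded.append(True)
            unused_seeds -= 1
            free -= 1
        else:
            idx = int(np.searchsorted(np.cumsum(grow_w), u - a_homo - a_het))
            idx = min(idx, len(sizes) - 1)
            sizes[idx] += 1
            free -= 1

    return SimResult(
        seeded=np.asarray(seeded, bool),
        sizes=np.asarray(sizes, int),
        free_tiles_final=free,
        tile_pool=pool,
        t_final=min(t, config.duration),
    )


def _simulate_tau(config: SimConfig, rng, n_homo_rate, n_het_rate) -> SimResult:
    """Tau-leaping variant for large pools: Poisson event counts per leap."""
    pool = config.tile_pool
    sizes: list = []
    seeded: list = []
    free = pool
    unused_seeds = config.seed_count
    g = config.growth_rate_const
    perimeter = config.growth_law == "perimeter"
    t = 0.0
    while t < config.duration and free > 0:
        ff = free / pool if pool else 0.0
        tau = min(config.tau, config.duration - t)
        n_new = rng.poisson(n_homo_rate * ff * tau)
        n_seed = min(rng.poisson(n_het_rate * unused_seeds * ff * tau), unused_seeds)
        sz = np.asarray(sizes, dtype=float)
        grow_w = g * (np.sqrt(sz) if perimeter else np.ones_like(sz)) * ff
        n_grow = rng.poisson(grow_w * tau) if len(sizes) else np.zeros(0, int)
        demand = n_new + n_seed + int(n_grow.sum())
        if demand > free:  # truncate the leap to the available tiles
            scale = free / demand
            n_new = int(n_new * scale)
            n_seed = int(n_seed * scale)
            n_grow = (n_grow * scale).astype(int)
        for _ in range(n_new):
            sizes.append(1)
            seeded.append(False)
        for _ in range(n_seed):
            sizes.append(1)
            seeded.append(True)
        unused_seeds -= n_seed
        for i, k in enumerate(n_grow):
            sizes[i] += int(k)
        free -= n_new + n_seed + int(n_grow.sum())
        t += tau
    return SimResult(
        seeded=np.asarray(seeded, bool),
        sizes=np.asarray(sizes, int),
        free_tiles_final=free,
        tile_pool=pool,
        t_final=min(t, config.duration),
    )


def summarize(result: SimResult, min_size: int = 1) -> GrowthSummary:
    """Seeded fraction (%) and size statistics over structures ≥ min_size.

    Returns NaN statistics when no structure reaches the size threshold.
    """
    mask = result.sizes >= min_size
    n = int(mask.sum())
    if n == 0:
        return GrowthSummary(math.nan, math.nan, math.nan, 0)
    sizes = result.sizes[mask].astype(float)
    frac = 100.0 * result.seeded[mask].mean()
    sd = float(sizes.std(ddof=1)) if n > 1 else 0.0
    return GrowthSummary(
        seeded_fraction_pct=float(frac),
        mean_size=float(sizes.mean()),
        sd_size=sd,
        n_structures=n,
    )


def mean_field_sizes(config: SimConfig, n_steps: int = 2000) -> float:
    """Deterministic mean-field expectation of the final mean structure size.

    Integrates the rate equations (nucleation counts and total growth flux)
    with explicit Euler; serves as an independent check of simulator trends.
    """
    n_homo_rate, n_het_rate = _rates(config)
    pool = config.tile_pool
    free = float(pool)
    n_structs = 0.0
    unused = float(config.seed_count)
    mass_in_structs = 0.0
    dt = config.duration / n_steps
    g = config.growth_rate_const
    for _ in range(n_steps):
        ff = max(free, 0.0) / pool if pool else 0.0
        mean_size = mass_in_structs / n_structs if n_structs > 0 else 0.0
        d_homo = n_homo_rate * ff * dt
        d_het = min(n_het_rate * unused * ff * dt, unused)
        per_struct = math.sqrt(mean_size) if config.growth_law == "perimeter" else 1.0
        d_grow = g * per_struct * n_structs * ff * dt
        total = d_homo + d_het + d_grow
        if total > free:
            f = free / total if total > 0 else 0.0
            d_homo, d_het, d_grow = d_homo * f, d_het * f, d_grow * f
        n_structs += d_homo + d_het
        unused -= d_het
        mass_in_structs += d_homo + d_het + d_grow
        free -= d_homo + d_het + d_grow
        if free <= 0:
            break
    return mass_in_structs / n_structs if n_structs > 0 else math.nan
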