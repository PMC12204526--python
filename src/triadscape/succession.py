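"""Cohort succession: growth, aging/mortality, establishment.

A deliberately simple 10-year-step stand-in for a full biomass-succession
model, keeping its two climate levers: maximum ANPP drives accrual (the
"escalator") and maximum cohort biomass caps it (the "hard ceiling").

Growth rule (documented reference): over one step each existing cohort of
species s in cell c gains

    timestep * max_ANPP[s, eco(c)] * (1 - crowding(c))

where crowding = total cell biomass / cell capacity (capacity = the largest
species maximum biomass attainable in that ecoregion).  If the cell's
summed cohort gains would push its total past capacity, all gains in that
cell are scaled down proportionally (the ceiling binds at the cell level,
not only per cohort); each cohort is additionally clipped at
max_biomass[s, eco(c)].

Establishment requires a seed source (a live cohort of the species within
the dispersal neighbourhood, or serotinous seed released on cells burned
this step), a shade gate (species shade tolerance >= site shade class,
derived from crowding), and a Bernoulli draw at the species' establishment
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .communities import Community
from .growth import GrowthTables
from .landscape import Landscape
from .species import SpeciesPool

__all__ = [
    "SuccessionConfig",
    "cell_capacity",
    "shade_class",
    "step_growth",
    "step_mortality_and_aging",
    "step_establishment",
]


@dataclass(frozen=True)
class SuccessionConfig:
    timestep: float = 10.0  # years
    initial_cohort_biomass: float = 50.0  # g/m^2 for new cohorts
    background_mortality: float = 0.05  # biomass fraction lost per step
    dispersal_radius: int = 2  # cells (uniform neighbourhood kernel)
    # crowding thresholds mapping relative stand biomass to shade class 1-5
    shade_thresholds: tuple[float, ...] = (0.15, 0.35, 0.55, 0.75)

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if not 0.0 <= self.background_mortality < 1.0:
            raise ValueError("background_mortality must lie in [0, 1)")
        if list(self.shade_thresholds) != sorted(self.shade_thresholds):
            raise ValueError("shade_thresholds must be non-decreasing")


def cell_capacity(landscape: Landscape, maxb: np.ndarray) -> np.ndarray:
    """Per-cell biomass capacity (g/m^2): the largest species ceiling in
    the cell's ecoregion."""
    cap_by_eco = maxb.max(axis=0)  # (n_eco,)
    return cap_by_eco[landscape.ecoregion_id.ravel()]


def _crowding(community: Community, cap: np.ndarray) -> np.ndarray:
    total = community.total_per_cell()
    return np.clip(
        np.divide(total, cap, out=np.zeros_like(total), where=cap > 0), 0.0, 1.0
    )


def shade_class(crowding: np.ndarray, config: SuccessionConfig) -> np.ndarray:
    """Site shade class 1 (open) .. 5 (closed) from relative biomass."""
    return 1 + np.digitize(
        np.clip(crowding, 0.0, 1.0), np.asarray(config.shade_thresholds)
    )


def step_growth(
    community: Community,
    landscape: Landscape,
    growth: GrowthTables,
    climate: str,
    year: float,
    config: SuccessionConfig = SuccessionConfig(),
) -> Community:
    """Advance cohort biomass by one step (returns a new Community)."""
    _, anpp, maxb = growth.lookup(climate, year)
    eco = landscape.ecoregion_id.ravel()
    cap = cell_capacity(landscape, maxb)
    total = community.total_per_cell()
    crowd = np.clip(
        np.divide(total, cap, out=np.zeros_like(total), where=cap > 0), 0.0, 1.0
    )

    gain = config.timestep * anpp[:, eco].T * (1.0 - crowd)[:, None]  # (cells, sp)
    b = community.biomass.copy()
    present = b > 0.0
    # scale gains so the cell total cannot exceed its capacity
    gain_sum = (gain * present.sum(axis=2)).sum(axis=1)
    headroom = np.maximum(cap - total, 0.0)
    scale = np.ones_like(gain_sum)
    over = gain_sum > headroom
    scale[over] = headroom[over] / gain_sum[over]
    b += (gain * scale[:, None])[:, :, None] * present
    np.minimum(b, maxb[:, eco].T[:, :, None], out=b)
    b[~present] = 0.0
    return Community(b, list(community.species_ids))


def step_mortality_and_aging(
    community: Community,
    species_pool: SpeciesPool,
    config: SuccessionConfig = SuccessionConfig(),
) -> Community:
    """Apply background mortality, advance ages one class, kill cohorts
    older than their species' longevity."""
    b = community.biomass * (1.0 - config.background_mortality)
    shifted = np.zeros_like(b)
    shifted[:, :, 1:] = b[:, :, :-1]
    # class k holds nominal age 10k+5; a cohort dies once that exceeds longevity
    dead = community.ages[None, :] > species_pool.array("longevity")[:, None]
    shifted[:, dead] = 0.0
    return Community(shifted, list(community.species_ids))


def step_establishment(
    landscape: Landscape,
    community: Community,
    species_pool: SpeciesPool,
    growth: GrowthTables,
    climate: str,
    year: float,
    rng: np.random.Generator,
    config: SuccessionConfig = SuccessionConfig(),
    serotiny_sources: np.ndarray | None = None,
) -> Community:
    """Recruit new age-class-0 cohorts (returns a new Community).

    ``serotiny_sources`` is an optional (n_cells, n_species) bool mask of
    cells where a serotinous seed bank was released by a background fire
    this step; those cells count as seed sources even though the parent
    cohorts burned.  The catastrophic large fire passes no such mask
    (serotinous regeneration suppressed).
    """
    estab, _, maxb = growth.lookup(climate, year)
    eco = landscape.ecoregion_id.ravel()
    n_rows, n_cols = landscape.shape

    site_shade = shade_class(
        _crowding(community, cell_capacity(landscape, maxb)), config
    )
    shade_tol = species_pool.array("shade_tolerance")

    presence = community.presence()  # (n_cells, n_sp)
    r = config.dispersal_radius
    structure = np.ones((2 * r + 1, 2 * r + 1), dtype=bool)

    b = community.biomass.copy()
    active = landscape.active_flat
    for s in range(community.n_species):
        src = presence[:, s].reshape(n_rows, n_cols)
        reach = binary_dilation(src, structure=structure).ravel()
        if serotiny_sources is not None:
            reach |= serotiny_sources[:, s]
        candidate = reach & (b[:, s, 0] == 0.0) & active
        if not candidate.any():
            continue
        idx = np.flatnonzero(candidate)
        ok = (shade_tol[s] >= site_shade[idx]) & (
            rng.random(len(idx)) < estab[s, eco[idx]]
        )
        b[idx[ok], s, 0] = config.initial_cohort_biomass
    return Community(b, list(community.species_ids))
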