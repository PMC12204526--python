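"""Recurrent background disturbances: wildfire and spruce budworm.

Background fires are stand-replacing crown fires: ignition counts are
Poisson per fire region, sizes uniform between the regime's bounds, and
burned cells lose all cohort biomass regardless of species tolerance.
Fire regimes intensify with climate forcing and period.

Spruce budworm (SBW) outbreaks recur with a fixed periodicity and last one
10-year step; host species lose a rank-dependent biomass fraction scaled
by the cell's host proportion, non-hosts are untouched.  Climate does not
alter the outbreak regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .communities import Community
from .growth import CLIMATES, period_of_year
from .landscape import Landscape, grow_patch
from .species import SpeciesPool

__all__ = [
    "FireRegimeSet",
    "SBWRegime",
    "default_fire_regimes",
    "default_sbw_regime",
    "background_fire_step",
    "sbw_outbreak_step",
    "sbw_active",
]


@dataclass(frozen=True)
class FireRegimeSet:
    """Annual burn fractions by (fire region, climate, period) plus size bounds.

    ``annual_burn_fraction[region][climate]`` is a 3-tuple over periods.
    Expected ignitions per step are derived at run time from the region's
    cell count: burn_target / mean fire size.
    """

    annual_burn_fraction: dict[int, dict[str, tuple[float, float, float]]]
    size_bounds: dict[int, tuple[int, int]]  # region -> (min_ha, max_ha)

    def __post_init__(self) -> None:
        for region, by_clim in self.annual_burn_fraction.items():
            lo, hi = self.size_bounds[region]
            if not 1 <= lo <= hi:
                raise ValueError("fire size bounds must satisfy 1 <= min <= max")
            for clim, fracs in by_clim.items():
                if clim not in CLIMATES:
                    raise ValueError(f"unknown climate scenario {clim!r}")
                if any(not 0.0 <= f < 1.0 for f in fracs):
                    raise ValueError("annual burn fractions must lie in [0, 1)")

    def burn_fraction(self, region: int, climate: str, year: float) -> float:
        if climate not in CLIMATES:
            raise ValueError(f"unknown climate scenario {climate!r}")
        return self.annual_burn_fraction[region][climate][period_of_year(year)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        from .growth import PERIODS

        for region, by_clim in self.annual_burn_fraction.items():
            lo, hi = self.size_bounds[region]
            for clim, fracs in by_clim.items():
                for pi, frac in enumerate(fracs):
                    rows.append(
                        dict(
                            fire_region_id=region,
                            climate_scenario=clim,
                            period=PERIODS[pi],
                            annual_burn_fraction=frac,
                            min_size_ha=lo,
                            max_size_ha=hi,
                        )
                    )
        return pd.DataFrame(rows)


def default_fire_regimes() -> FireRegimeSet:
    """Region 0 (north): larger, more frequent fires; region 1 (south):
    smaller, rarer.  Forcing multiplies activity, increasing with period,
    so that RCP 8.5 >= RCP 4.5 >= baseline everywhere."""

    def ladder(base: float) -> dict[str, tuple[float, float, float]]:
        return {
            "baseline": (base, base, base),
            "rcp45": (base * 1.2, base * 1.5, base * 1.8),
            "rcp85": (base * 1.4, base * 2.0, base * 3.0),
        }

    return FireRegimeSet(
        annual_burn_fraction={0: ladder(0.0025), 1: ladder(0.0010)},
        size_bounds={0: (5, 200), 1: (2, 50)},
    )


def background_fire_step(
    landscape: Landscape,
    community: Community,
    regime: FireRegimeSet,
    climate: str,
    year: float,
    rng: np.random.Generator,
    timestep: float = 10.0,
) -> tuple[Community, np.ndarray]:
    """Simulate one step of background fire; returns (community, burned mask).

    Per region: ignitions ~ Poisson(expected burn cells / mean size); each
    fire grows from a random active cell to a size uniform in the regime's
    bounds, clipped to the region.  Burned cells lose all biomass.
    """
    burned = np.zeros(landscape.n_cells, dtype=bool)
    region_flat = landscape.fire_region_id.ravel()
    active = landscape.active_flat
    b = community.biomass.copy()

    for region in sorted(regime.annual_burn_fraction):
        lo, hi = regime.size_bounds[region]
        in_region = active & (region_flat == region)
        n_region = int(in_region.sum())
        if n_region == 0:
            continue
        frac = regime.burn_fraction(region, climate, year)
        expected_cells = frac * timestep * n_region
        mean_size = 0.5 * (lo + hi)
        n_fires = rng.poisson(expected_cells / mean_size) if expected_cells > 0 else 0
        for _ in range(n_fires):
            size = int(rng.integers(lo, hi + 1))
            candidates = np.flatnonzero(in_region)
            start = int(rng.choice(candidates))
            cells = grow_patch(start, size, in_region, landscape.shape, rng)
            burned[cells] = True
            b[cells] = 0.0

    return Community(b, list(community.species_ids)), burned


@dataclass(frozen=True)
class SBWRegime:
    """Spruce budworm outbreak regime.

    ``severity_by_rank`` maps host vulnerability rank (1 = most vulnerable)
    to the biomass fraction lost in a fully host-dominated cell.
    """

    periodicity: float = 40.0  # years between outbreak onsets
    duration: float = 10.0  # years each outbreak lasts (one step)
    first_outbreak: float = 30.0  # year of the first outbreak window
    severity_by_rank: tuple[float, ...] = (0.6, 0.4, 0.3, 0.2)

    def __post_init__(self) -> None:
        if self.periodicity % 10 != 0:
            raise ValueError("periodicity must be a multiple of the 10-y timestep")
        if any(not 0.0 <= s <= 1.0 for s in self.severity_by_rank):
            raise ValueError("severity fractions must lie in [0, 1]")


def default_sbw_regime() -> SBWRegime:
    return SBWRegime()


def sbw_active(year: float, regime: SBWRegime) -> bool:
    """Whether ``year`` falls inside an outbreak window."""
    if year < regime.first_outbreak:
        return False
    return (year - regime.first_outbreak) % regime.periodicity < regime.duration


def sbw_outbreak_step(
    landscape: Landscape,
    community: Community,
    species_pool: SpeciesPool,
    regime: SBWRegime,
    year: float,
    rng: np.random.Generator | None = None,
) -> Community:
    """Apply one step of budworm defoliation mortality.

    Outside an outbreak window the community is returned unchanged.  During
    an outbreak, each host cohort loses severity(rank) * host proportion of
    its biomass, where host proportion is the cell's biomass share in host
    species; non-host species are never touched.
    """
    if not sbw_active(year, regime):
        return community

    ranks = np.asarray([s.sbw_rank for s in species_pool], dtype=int)
    hosts = np.flatnonzero(ranks > 0)
    if hosts.size == 0:
        return community

    sp_cell = community.species_per_cell()
    total = sp_cell.sum(axis=1)
    host_b = sp_cell[:, hosts].sum(axis=1)
    host_prop = np.divide(host_b, total, out=np.zeros_like(total), where=total > 0)

    b = community.biomass.copy()
    for s in hosts:
        sev = regime.severity_by_rank[ranks[s] - 1]
        b[:, s, :] *= (1.0 - sev * host_prop)[:, None]
    return Community(b, list(community.species_ids))
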