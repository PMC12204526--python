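"""Community state: per-cell age-cohort biomass.

The simulator's state is one dense array ``biomass[cell, species, age_class]``
(g/m^2) over 10-year age classes; a cohort exists where the entry is
positive, which enforces "at most one cohort per (species, age class) per
cell" by construction.  A cohort's nominal age is the midpoint of its age
class (class k spans [10k, 10k+10) years, nominal age 10k+5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import GrowthTables
from .landscape import Landscape
from .species import SpeciesPool

__all__ = ["Community", "cohort_ages", "generate_initial_communities"]


def cohort_ages(n_classes: int) -> np.ndarray:
    """Nominal (midpoint) age of each 10-year age class."""
    return np.arange(n_classes) * 10.0 + 5.0


@dataclass
class Community:
    """Dense cohort-biomass state for one landscape."""

    biomass: np.ndarray  # (n_cells, n_species, n_age_classes), g/m^2
    species_ids: list[str]

    @property
    def n_cells(self) -> int:
        return self.biomass.shape[0]

    @property
    def n_species(self) -> int:
        return self.biomass.shape[1]

    @property
    def n_age_classes(self) -> int:
        return self.biomass.shape[2]

    @property
    def ages(self) -> np.ndarray:
        return cohort_ages(self.n_age_classes)

    def copy(self) -> "Community":
        return Community(self.biomass.copy(), list(self.species_ids))

    def total_per_cell(self) -> np.ndarray:
        return self.biomass.sum(axis=(1, 2))

    def species_per_cell(self) -> np.ndarray:
        """(n_cells, n_species) total biomass by species."""
        return self.biomass.sum(axis=2)

    def presence(self) -> np.ndarray:
        """(n_cells, n_species) bool: species has at least one cohort."""
        return self.species_per_cell() > 0.0

    def mature_per_cell(self, maturity_age: float = 40.0) -> np.ndarray:
        """Per-cell biomass of cohorts aged >= maturity_age."""
        mature = self.ages >= maturity_age
        return self.biomass[:, :, mature].sum(axis=(1, 2))

    def to_frame(self) -> pd.DataFrame:
        """Long format (cell, species, age, biomass); cohorts only."""
        cells, sp, cls = np.nonzero(self.biomass > 0.0)
        return pd.DataFrame(
            {
                "cell": cells,
                "species_id": np.asarray(self.species_ids)[sp],
                "age": cohort_ages(self.n_age_classes)[cls],
                "biomass": self.biomass[cells, sp, cls],
            }
        )


def generate_initial_communities(
    landscape: Landscape,
    species_pool: SpeciesPool,
    growth: GrowthTables,
    rng_seed: int = 0,
    min_cohorts: int = 2,
    max_cohorts: int = 5,
) -> Community:
    """Populate every active cell with 1-6 age cohorts.

    Species are drawn (without replacement) with weights proportional to
    their baseline establishment probability in the cell's ecoregion, which
    encodes the compositional gradient: gymnosperm-rich boreal communities
    in the northern bands, hardwood-rich mixedwoods in the south.  Cohort
    age classes are uniform on [10, longevity); initial cohort biomass is a
    moderate fraction of the species' maximum, so every cell starts below
    its ceiling.
    """
    if not 1 <= min_cohorts <= max_cohorts <= 6:
        raise ValueError("cohort counts must satisfy 1 <= min <= max <= 6")
    rng = np.random.default_rng(rng_seed)
    n_sp = len(species_pool)
    n_classes = species_pool.n_age_classes
    biomass = np.zeros((landscape.n_cells, n_sp, n_classes))

    estab, _, maxb = growth.lookup("baseline", 0)
    longevity = species_pool.array("longevity")
    max_class = np.maximum((longevity // 10).astype(int) - 1, 1)

    eco_flat = landscape.ecoregion_id.ravel()
    active_cells = np.flatnonzero(landscape.active_flat)
    n_cohorts = rng.integers(min_cohorts, max_cohorts + 1, size=len(active_cells))

    for cell, k in zip(active_cells, n_cohorts):
        eco = eco_flat[cell]
        w = estab[:, eco]
        w = w / w.sum()
        sp_idx = rng.choice(n_sp, size=min(k, n_sp), replace=False, p=w)
        for s in sp_idx:
            cls = int(rng.integers(1, max_class[s] + 1))
            frac = rng.uniform(0.15, 0.55)
            biomass[cell, s, cls] = frac * maxb[s, eco]

    return Community(biomass, list(species_pool.ids))
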