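"""Per-(species, ecoregion, climate, period) growth parameter tables.

Three parameters govern cohort dynamics: probability of establishment,
maximum ANPP (the growth-rate "escalator") and maximum cohort biomass (the
"hard ceiling").  Under the baseline climate the tables are constant over
the three periods; under RCP 4.5 / 8.5 they drift at the period boundaries
(years 20 and 50 of the simulation) and are frozen afterwards, with
thermophilic hardwoods gaining and boreal conifers losing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .species import SpeciesPool

__all__ = [
    "CLIMATES",
    "PERIODS",
    "GrowthTables",
    "default_climate_profile",
    "generate_growth_tables",
    "period_of_year",
]

CLIMATES = ("baseline", "rcp45", "rcp85")
PERIODS = ("2020-2040", "2041-2070", "2070+")

# simulation year 0 = calendar 2020; period boundaries at years 20 and 50
_PERIOD_BOUNDS = (20, 50)


def period_of_year(year: float) -> int:
    """Index of the climate period containing simulation ``year``."""
    if year < _PERIOD_BOUNDS[0]:
        return 0
    if year < _PERIOD_BOUNDS[1]:
        return 1
    return 2


def default_climate_profile() -> dict:
    """Per-clade multiplicative ANPP trends by climate and period.

    Hardwoods (thermophilic) gain under warming; boreal conifers lose, the
    more so under RCP 8.5.  Establishment and maximum biomass drift with
    half the ANPP amplitude.
    """
    return {
        "gymnosperm": {
            "baseline": (1.00, 1.00, 1.00),
            "rcp45": (0.97, 0.92, 0.85),
            "rcp85": (0.93, 0.82, 0.68),
        },
        "angiosperm": {
            "baseline": (1.00, 1.00, 1.00),
            "rcp45": (1.03, 1.08, 1.12),
            "rcp85": (1.05, 1.15, 1.28),
        },
    }


@dataclass
class GrowthTables:
    """Dense lookup arrays indexed [climate, period, species, ecoregion]."""

    species_ids: list[str]
    n_ecoregions: int
    establishment_prob: np.ndarray  # (3, 3, n_sp, n_eco) in [0, 1]
    max_anpp: np.ndarray  # g m^-2 y^-1
    max_biomass: np.ndarray  # g m^-2
    climates: tuple[str, ...] = CLIMATES
    periods: tuple[str, ...] = PERIODS
    _climate_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._climate_index = {c: i for i, c in enumerate(self.climates)}

    def climate_index(self, climate: str) -> int:
        try:
            return self._climate_index[climate]
        except KeyError:
            raise ValueError(
                f"unknown climate scenario {climate!r}; expected one of {self.climates}"
            ) from None

    def lookup(self, climate: str, year: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(establishment_prob, max_anpp, max_biomass), each (n_sp, n_eco)."""
        ci = self.climate_index(climate)
        pi = period_of_year(year)
        return (
            self.establishment_prob[ci, pi],
            self.max_anpp[ci, pi],
            self.max_biomass[ci, pi],
        )

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (species, ecoregion, climate, period)."""
        rows = []
        for ci, climate in enumerate(self.climates):
            for pi, period in enumerate(self.periods):
                for si, sp in enumerate(self.species_ids):
                    for e in range(self.n_ecoregions):
                        rows.append(
                            dict(
                                species_id=sp,
                                ecoregion_id=e,
                                climate_scenario=climate,
                                period=period,
                                establishment_prob=self.establishment_prob[ci, pi, si, e],
                                max_ANPP=self.max_anpp[ci, pi, si, e],
                                max_biomass=self.max_biomass[ci, pi, si, e],
                            )
                        )
        return pd.DataFrame(rows)

    def with_species(
        self,
        species_id: str,
        establishment_prob: np.ndarray,
        max_anpp: np.ndarray,
        max_biomass: np.ndarray,
    ) -> "GrowthTables":
        """Return a new table set with one species row block appended."""
        return GrowthTables(
            species_ids=self.species_ids + [species_id],
            n_ecoregions=self.n_ecoregions,
            establishment_prob=np.concatenate(
                [self.establishment_prob, establishment_prob[:, :, None, :]], axis=2
            ),
            max_anpp=np.concatenate(
                [self.max_anpp, max_anpp[:, :, None, :]], axis=2
            ),
            max_biomass=np.concatenate(
                [self.max_biomass, max_biomass[:, :, None, :]], axis=2
            ),
            climates=self.climates,
            periods=self.periods,
        )


def _suitability(clade: str, n_eco: int) -> np.ndarray:
    """Latitudinal suitability across ecoregion bands (0 = north).

    Gymnosperms do best in the north, angiosperms in the south, producing
    the mixedwood-south / boreal-north compositional gradient.
    """
    grad = np.linspace(0.0, 1.0, n_eco)  # 0 north .. 1 south
    if clade == "gymnosperm":
        return 1.15 - 0.45 * grad
    return 0.70 + 0.45 * grad


def generate_growth_tables(
    species_pool: SpeciesPool,
    n_ecoregions: int = 4,
    climate_effect_profile: dict | None = None,
    rng_seed: int = 0,
) -> GrowthTables:
    """Build complete growth tables over the full cross-product.

    Species-level base values are drawn once (seeded) and shaped by the
    latitudinal suitability of the species' clade; climate multipliers from
    ``climate_effect_profile`` are applied per period on top, with half
    amplitude for establishment and maximum biomass.
    """
    profile = climate_effect_profile or default_climate_profile()
    for clade, by_climate in profile.items():
        for climate in by_climate:
            if climate not in CLIMATES:
                raise ValueError(
                    f"unknown climate scenario {climate!r} in profile for {clade}"
                )

    rng = np.random.default_rng(rng_seed)
    n_sp = len(species_pool)
    estab = np.zeros((3, 3, n_sp, n_ecoregions))
    anpp = np.zeros_like(estab)
    maxb = np.zeros_like(estab)

    for si, sp in enumerate(species_pool):
        suit = _suitability(sp.clade, n_ecoregions)
        base_anpp = rng.uniform(350.0, 750.0)
        base_maxb = rng.uniform(9000.0, 22000.0)
        base_estab = rng.uniform(0.15, 0.55)
        for ci, climate in enumerate(CLIMATES):
            mults = profile[sp.clade][climate]
            for pi in range(3):
                m = mults[pi]
                m_half = 1.0 + 0.5 * (m - 1.0)
                anpp[ci, pi, si] = base_anpp * suit * m
                maxb[ci, pi, si] = base_maxb * suit * m_half
                estab[ci, pi, si] = np.clip(base_estab * suit * m_half, 0.005, 1.0)

    return GrowthTables(
        species_ids=list(species_pool.ids),
        n_ecoregions=n_ecoregions,
        establishment_prob=estab,
        max_anpp=anpp,
        max_biomass=maxb,
    )
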