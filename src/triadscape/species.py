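"""Synthetic species pool.

Generates a pool of tree species whose nine functional response traits
(maximum height, seed dry mass, wood density, leaf nitrogen content, SLA,
bark thickness, fire tolerance, drought tolerance, shade tolerance) are
drawn around group archetypes, so that a trait clustering can recover a
known functional-group structure.  The default pool of 17 species in 5
groups (three gymnosperm groups, two angiosperm groups) mimics the mix of
boreal/temperate-transition species of eastern Canada: budworm-host
fir/spruces, beetle-host pines (one serotinous), dry-site conifers,
pioneer hardwoods, and late-succession hardwoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesTraits",
    "SpeciesPool",
    "CLUSTER_TRAITS",
    "generate_species_pool",
]

# Trait columns used by the functional clustering, in canonical order.
CLUSTER_TRAITS = [
    "max_height",
    "seed_dry_mass",
    "wood_density",
    "leaf_N",
    "SLA",
    "bark_thickness",
    "fire_tolerance",
    "drought_tolerance",
    "shade_tolerance",
]

# Physical traits are drawn multiplicatively (lognormal noise); the three
# tolerance scores are ordinal on [1, 5] and drawn additively, clipped.
_PHYSICAL = CLUSTER_TRAITS[:6]
_ORDINAL = CLUSTER_TRAITS[6:]


@dataclass(frozen=True)
class SpeciesTraits:
    """Response traits and demographic parameters of one species."""

    species_id: str
    clade: str  # "gymnosperm" | "angiosperm"
    longevity: float  # years
    maturity_age: float  # years
    max_height: float  # m
    seed_dry_mass: float  # mg
    wood_density: float  # g/cm^3
    leaf_N: float  # mg/g
    SLA: float  # mm^2/mg
    bark_thickness: float  # relative index
    fire_tolerance: float  # ordinal 1-5
    drought_tolerance: float  # ordinal 1-5
    shade_tolerance: float  # ordinal 1-5
    dispersal_distance: float  # m
    is_hybrid: bool = False
    is_serotinous: bool = False
    mpb_host: bool = False
    sbw_rank: int = 0  # 1 = most vulnerable budworm host .. 4; 0 = non-host
    true_group: int = 0  # generating archetype, ground truth for recovery tests

    def __post_init__(self) -> None:
        if not (self.longevity > self.maturity_age > 0):
            raise ValueError(
                f"{self.species_id}: longevity must exceed maturity_age > 0"
            )
        for name in _ORDINAL:
            v = getattr(self, name)
            if not 1.0 <= v <= 5.0:
                raise ValueError(f"{self.species_id}: {name}={v} outside [1, 5]")
        for name in _PHYSICAL + ["dispersal_distance"]:
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.species_id}: {name} must be positive")


@dataclass
class SpeciesPool:
    """An ordered collection of species; index in the list is the species'
    integer code used by array-based simulation state."""

    species: list[SpeciesTraits] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self):
        return iter(self.species)

    def __getitem__(self, i: int) -> SpeciesTraits:
        return self.species[i]

    @property
    def ids(self) -> list[str]:
        return [s.species_id for s in self.species]

    def index(self, species_id: str) -> int:
        return self.ids.index(species_id)

    def array(self, attr: str) -> np.ndarray:
        return np.asarray([getattr(s, attr) for s in self.species], dtype=float)

    def flags(self, attr: str) -> np.ndarray:
        return np.asarray([bool(getattr(s, attr)) for s in self.species])

    @property
    def true_groups(self) -> np.ndarray:
        return np.asarray([s.true_group for s in self.species], dtype=int)

    def trait_frame(self) -> pd.DataFrame:
        """Nine clustering traits, one row per species."""
        return pd.DataFrame(
            {t: self.array(t) for t in CLUSTER_TRAITS}, index=self.ids
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "species_id", "clade", "longevity", "maturity_age",
            *CLUSTER_TRAITS, "dispersal_distance",
            "is_hybrid", "is_serotinous", "mpb_host", "sbw_rank", "true_group",
        ]
        return pd.DataFrame(
            [{c: getattr(s, c) for c in cols} for s in self.species]
        )

    def with_species(self, extra: list[SpeciesTraits]) -> "SpeciesPool":
        return SpeciesPool(self.species + list(extra))

    @property
    def n_age_classes(self) -> int:
        """Number of 10-year age classes needed to hold the oldest cohort."""
        return int(max(s.longevity for s in self.species) // 10) + 2


# --------------------------------------------------------------------------
# Archetypes
#
# Group means for the default five groups.  Columns follow CLUSTER_TRAITS;
# the trailing triple is (longevity, maturity_age, dispersal_distance).
# Values are loosely calibrated to the boreal/temperate species they stand
# in for, on the 1-5 tolerance scale and in field-typical physical units.
_DEFAULT_ARCHETYPES = {
    # shade-tolerant boreal conifers (fir / spruces)
    1: dict(max_height=20.0, seed_dry_mass=3.0, wood_density=0.38, leaf_N=12.0,
            SLA=6.0, bark_thickness=1.5, fire_tolerance=1.5, drought_tolerance=2.0,
            shade_tolerance=4.5, longevity=200.0, maturity_age=30.0,
            dispersal_distance=100.0, clade="gymnosperm"),
    # fire-adapted pines
    2: dict(max_height=25.0, seed_dry_mass=8.0, wood_density=0.42, leaf_N=13.0,
            SLA=5.0, bark_thickness=3.5, fire_tolerance=4.2, drought_tolerance=4.0,
            shade_tolerance=1.8, longevity=180.0, maturity_age=20.0,
            dispersal_distance=150.0, clade="gymnosperm"),
    # dry-site, shade-intolerant conifers (larch / cedar analogues)
    3: dict(max_height=15.0, seed_dry_mass=2.0, wood_density=0.33, leaf_N=15.0,
            SLA=9.0, bark_thickness=2.0, fire_tolerance=2.5, drought_tolerance=4.5,
            shade_tolerance=2.2, longevity=150.0, maturity_age=25.0,
            dispersal_distance=120.0, clade="gymnosperm"),
    # pioneer hardwoods (aspen / birch / poplar)
    4: dict(max_height=22.0, seed_dry_mass=0.5, wood_density=0.45, leaf_N=22.0,
            SLA=16.0, bark_thickness=2.0, fire_tolerance=2.0, drought_tolerance=2.5,
            shade_tolerance=1.5, longevity=110.0, maturity_age=15.0,
            dispersal_distance=400.0, clade="angiosperm"),
    # mid/late-succession hardwoods (maples / oak / beech)
    5: dict(max_height=28.0, seed_dry_mass=150.0, wood_density=0.60, leaf_N=18.0,
            SLA=12.0, bark_thickness=3.0, fire_tolerance=2.8, drought_tolerance=3.2,
            shade_tolerance=4.2, longevity=250.0, maturity_age=40.0,
            dispersal_distance=80.0, clade="angiosperm"),
}

# Default roster: (name, group, serotinous, mpb_host, sbw_rank).
_DEFAULT_ROSTER = [
    ("balsam_fir", 1, False, False, 1),
    ("white_spruce", 1, False, False, 2),
    ("red_spruce", 1, False, False, 3),
    ("black_spruce", 1, False, False, 4),
    ("jack_pine", 2, True, True, 0),
    ("white_pine", 2, False, True, 0),
    ("red_pine", 2, False, True, 0),
    ("tamarack", 3, False, False, 0),
    ("eastern_cedar", 3, False, False, 0),
    ("trembling_aspen", 4, False, False, 0),
    ("white_birch", 4, False, False, 0),
    ("balsam_poplar", 4, False, False, 0),
    ("yellow_birch", 5, False, False, 0),
    ("sugar_maple", 5, False, False, 0),
    ("red_maple", 5, False, False, 0),
    ("red_oak", 5, False, False, 0),
    ("american_beech", 5, False, False, 0),
]

# Relative noise of physical traits (lognormal sigma) and additive noise of
# ordinal tolerances around the archetype mean.
_PHYS_SIGMA = 0.10
_ORD_SIGMA = 0.30


def _generic_archetypes(n_groups: int) -> dict[int, dict]:
    """Archetypes for non-default group counts: deterministic spread around
    the global centroid of the default archetypes, gymnosperm-majority."""
    base = pd.DataFrame(_DEFAULT_ARCHETYPES).T
    n_gym = int(np.ceil(0.6 * n_groups))
    rng = np.random.default_rng(n_groups * 7919 + 13)  # fixed per n_groups
    out = {}
    num_cols = [c for c in base.columns if c != "clade"]
    center = base[num_cols].astype(float).mean()
    for g in range(1, n_groups + 1):
        row = {}
        for c in num_cols:
            lo, hi = base[c].astype(float).min(), base[c].astype(float).max()
            row[c] = float(rng.uniform(lo, hi))
        # keep the centroid anchored so separation scaling behaves
        row = {c: 0.5 * (row[c] + float(center[c])) for c in num_cols}
        row["clade"] = "gymnosperm" if g <= n_gym else "angiosperm"
        out[g] = row
    return out


def _scaled_archetype(arch: dict, center: dict, separation: float) -> dict:
    """Move an archetype toward/away from the global centroid.

    separation 1 reproduces the archetype as defined; 0 collapses all groups
    onto the centroid (clustering recovery drops to chance).  Physical traits
    are interpolated on the log scale, ordinals on the natural scale.
    """
    out = dict(arch)
    for t in _PHYSICAL + ["longevity", "maturity_age", "dispersal_distance"]:
        out[t] = float(
            np.exp(np.log(center[t]) + separation * (np.log(arch[t]) - np.log(center[t])))
        )
    for t in _ORDINAL:
        out[t] = float(center[t] + separation * (arch[t] - center[t]))
    return out


def generate_species_pool(
    n_species: int = 17,
    n_groups: int = 5,
    archetype_separation: float = 1.0,
    rng_seed: int = 0,
) -> SpeciesPool:
    """Draw ``n_species`` species around ``n_groups`` trait archetypes.

    The generating group of each species is recorded in ``true_group`` as
    ground truth for clustering-recovery checks.  With the defaults
    (17 species, 5 groups) the roster, clade split (3 gymnosperm and 2
    angiosperm groups), beetle-host flags (3 pines, one serotinous) and
    budworm-host ranking (4 species) are fixed; only the quantitative trait
    values vary with the seed.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if n_species < n_groups:
        raise ValueError(
            f"n_species ({n_species}) must be >= n_groups ({n_groups})"
        )
    if archetype_separation < 0:
        raise ValueError("archetype_separation must be >= 0")

    rng = np.random.default_rng(rng_seed)

    if n_species == 17 and n_groups == 5:
        archetypes = _DEFAULT_ARCHETYPES
        roster = list(_DEFAULT_ROSTER)
    else:
        archetypes = (
            _DEFAULT_ARCHETYPES if n_groups == 5 else _generic_archetypes(n_groups)
        )
        # round-robin group assignment guarantees every group is populated
        roster = [
            (f"sp{i + 1:02d}", (i % n_groups) + 1, False, False, 0)
            for i in range(n_species)
        ]

    num_keys = CLUSTER_TRAITS + ["longevity", "maturity_age", "dispersal_distance"]
    center = {
        k: float(np.mean([a[k] for a in archetypes.values()])) for k in num_keys
    }

    species: list[SpeciesTraits] = []
    for name, group, serot, mpb, sbw in roster:
        arch = _scaled_archetype(archetypes[group], center, archetype_separation)
        vals: dict[str, float] = {}
        for t in _PHYSICAL:
            vals[t] = arch[t] * float(np.exp(rng.normal(0.0, _PHYS_SIGMA)))
        for t in _ORDINAL:
            vals[t] = float(np.clip(rng.normal(arch[t], _ORD_SIGMA), 1.0, 5.0))
        longevity = max(
            40.0, float(np.round(arch["longevity"] * np.exp(rng.normal(0, 0.08)), 0))
        )
        maturity = float(
            np.clip(np.round(arch["maturity_age"] * np.exp(rng.normal(0, 0.08))),
                    5.0, longevity - 10.0)
        )
        dispersal = arch["dispersal_distance"] * float(np.exp(rng.normal(0, 0.1)))
        species.append(
            SpeciesTraits(
                species_id=name,
                clade=archetypes[group]["clade"],
                longevity=longevity,
                maturity_age=maturity,
                dispersal_distance=dispersal,
                is_serotinous=serot,
                mpb_host=mpb,
                sbw_rank=sbw,
                true_group=group,
                **vals,
            )
        )
    return SpeciesPool(species)


def make_hybrid(base: SpeciesTraits, hybrid_id: str | None = None) -> SpeciesTraits:
    """Fast-growing planted hybrid of ``base``: longevity halved, traits kept.

    Growth-table changes (ANPP x2, max biomass x1.15) are applied separately
    where the growth tables are extended; see management.add_hybrid.
    """
    if base.is_hybrid:
        raise ValueError(f"{base.species_id} is already a hybrid")
    return replace(
        base,
        species_id=hybrid_id or f"hybrid_{base.species_id}",
        longevity=base.longevity / 2.0,
        maturity_age=min(base.maturity_age, base.longevity / 2.0 - 10.0),
        is_hybrid=True,
    )
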