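"""Forest management: TRIAD zoning, harvest prescriptions, planting.

Implements the four management strategies compared by the pipeline.  All
strategies harvest the same biomass target each 10-year step, split across
six stand-level prescriptions in fixed shares:

===============  ============== ============== ============== ============== ===== =====
scenario         CC-PlantIntens CC-PlantFunct  CC-NormalPlant CC-NoPlant     SC    CT
===============  ============== ============== ============== ============== ===== =====
TRIAD+           25 (I)         37.5 (E)                                     12.5(E) 25 (I)
TRIAD            25 (I)                                       37.5 (E)       12.5(E) 25 (I)
BAU-PlantFunct                  37.5 (A)       45 (A)                        12.5(A)  5 (A)
BAU-NoPlant                                    45 (A)         37.5 (A)       12.5(A)  5 (A)
===============  ============== ============== ============== ============== ===== =====

I = intensive zone only, E = extensive only, A = anywhere but protected.
Prescriptions select stands by descending harvestable biomass, except
CC-PlantFunct which targets the stands of lowest functional response
diversity.  Selection cutting (SC) re-enters its stands at +30 and +60
years and locks them for 90; commercial thinning (CT) in TRIAD intensive
zones re-enters at +20 and +50 and locks for 50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .communities import Community, cohort_ages
from .functional import FunctionalGrouping
from .growth import GrowthTables
from .landscape import (
    Landscape,
    ZONE_CONSERVATION,
    ZONE_EXTENSIVE,
    ZONE_INTENSIVE,
)
from .species import SpeciesPool, make_hybrid

__all__ = [
    "PRESCRIPTIONS",
    "SCENARIOS",
    "MANAGEMENT_SCENARIOS",
    "Prescription",
    "HarvestState",
    "allocate_zones",
    "add_hybrid",
    "removal_fraction",
    "apply_prescription",
    "select_planting_species",
    "schedule_harvest",
]

_G_TO_MG = 0.01  # g/m^2 on a 1-ha cell -> Mg


# --------------------------------------------------------------------------
# Zoning
# --------------------------------------------------------------------------

def allocate_zones(
    landscape: Landscape,
    growth: GrowthTables,
    intensive_frac: float = 0.16,
    conservation_frac: float = 0.24,
    buffer_radius_m: float = 5000.0,
) -> tuple[Landscape, dict]:
    """Assign TRIAD zones; returns (zoned landscape copy, report).

    Conservation = initial protected areas plus a distance-ordered buffer
    around the largest 10% of protected patches, grown (up to
    ``buffer_radius_m``) until ``conservation_frac`` of active cells is
    reached; a shortfall is reported, not raised.  Intensive = whole stands
    of highest potential productivity (ecoregion ANPP potential x stand
    site quality) outside conservation, accumulated until
    ``intensive_frac`` is reached (overshoot at most one stand).  Extensive
    = the remaining active cells.
    """
    from scipy.ndimage import distance_transform_edt

    if not 0.0 <= intensive_frac < 1.0:
        raise ValueError("intensive_frac must lie in [0, 1)")
    if not 0.0 < conservation_frac < 1.0:
        raise ValueError("conservation_frac must lie in (0, 1)")

    ls = landscape.copy()
    active = ls.active_flat
    n_active = int(active.sum())
    report: dict = {}

    # conservation: protected core + buffers around the largest patches
    conservation = ls.protected.ravel().copy()
    need = int(round(conservation_frac * n_active)) - int(conservation.sum())
    if need > 0:
        pid = ls.protected_patch_id.ravel()
        n_patches = pid.max() + 1
        if n_patches > 0:
            sizes = np.bincount(pid[pid >= 0], minlength=n_patches)
            n_big = max(1, int(np.ceil(0.10 * n_patches)))
            big_patches = np.argsort(sizes)[::-1][:n_big]
            big_mask = np.isin(pid, big_patches).reshape(ls.shape)
            dist = distance_transform_edt(~big_mask).ravel()
            radius_cells = buffer_radius_m / 100.0
            candidates = np.flatnonzero(
                active & ~conservation & (dist <= radius_cells)
            )
            order = candidates[np.argsort(dist[candidates], kind="stable")]
            take = order[:need]
            conservation[take] = True
            if len(take) < need:
                report["conservation_shortfall_cells"] = need - len(take)

    # intensive: top-productivity whole stands outside conservation
    _, anpp0, _ = growth.lookup("baseline", 0)
    potential = anpp0.max(axis=0)  # (n_eco,) best attainable ANPP per ecoregion
    cell_pot = potential[ls.ecoregion_id.ravel()]
    sid = ls.stand_id.ravel()
    ok = sid >= 0
    stand_pot = np.bincount(sid[ok], weights=cell_pot[ok], minlength=ls.n_stands)
    stand_n = np.bincount(sid[ok], minlength=ls.n_stands)
    with np.errstate(invalid="ignore"):
        stand_index = (stand_pot / np.maximum(stand_n, 1)) * ls.site_quality

    intensive = np.zeros_like(conservation)
    target_int = int(round(intensive_frac * n_active))
    if target_int > 0:
        free_by_stand = np.bincount(
            sid[ok & ~conservation], minlength=ls.n_stands
        )
        placed = 0
        for stand in np.argsort(stand_index)[::-1]:
            if placed >= target_int:
                break
            if free_by_stand[stand] == 0:
                continue
            # skip stands swallowed by conservation (> half their area)
            if free_by_stand[stand] < 0.5 * stand_n[stand]:
                continue
            cells = ls.stand_cells(stand)
            cells = cells[~conservation[cells]]
            intensive[cells] = True
            placed += len(cells)

    zone = np.zeros(ls.n_cells, dtype=np.int8)
    zone[active & conservation] = ZONE_CONSERVATION
    zone[active & intensive & ~conservation] = ZONE_INTENSIVE
    zone[active & ~conservation & ~intensive] = ZONE_EXTENSIVE
    ls.zone = zone.reshape(ls.shape)

    report["conservation_frac"] = float((zone == ZONE_CONSERVATION).sum() / n_active)
    report["intensive_frac"] = float((zone == ZONE_INTENSIVE).sum() / n_active)
    report["extensive_frac"] = float((zone == ZONE_EXTENSIVE).sum() / n_active)
    return ls, report


# --------------------------------------------------------------------------
# Hybrid species
# --------------------------------------------------------------------------

def add_hybrid(
    pool: SpeciesPool,
    growth: GrowthTables,
    base_species_id: str,
    hybrid_id: str | None = None,
) -> tuple[SpeciesPool, GrowthTables]:
    """Append a fast-growing hybrid of ``base_species_id``.

    Growth-parameter transform in every ecoregion, climate and period:
    maximum ANPP doubled, maximum biomass +15%; longevity halved and all
    other traits copied (see species.make_hybrid).  Re-hybridising a hybrid
    is rejected.
    """
    si = pool.index(base_species_id)
    hybrid = make_hybrid(pool[si], hybrid_id)
    new_pool = pool.with_species([hybrid])
    new_growth = growth.with_species(
        hybrid.species_id,
        establishment_prob=growth.establishment_prob[:, :, si, :].copy(),
        max_anpp=growth.max_anpp[:, :, si, :] * 2.0,
        max_biomass=growth.max_biomass[:, :, si, :] * 1.15,
    )
    return new_pool, new_growth


# --------------------------------------------------------------------------
# Prescriptions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Prescription:
    """One stand-level harvest prescription."""

    name: str
    plant_mode: str | None  # "intensive" | "functional" | "normal" | None
    lock_years: float = 0.0
    revisit_offsets: tuple[float, ...] = ()  # years after first entry
    revisit_in_intensive_only: bool = False  # CT repeats only in TRIAD zones


PRESCRIPTIONS: dict[str, Prescription] = {
    "CC-PlantIntens": Prescription("CC-PlantIntens", "intensive"),
    "CC-PlantFunct": Prescription("CC-PlantFunct", "functional"),
    "CC-NormalPlant": Prescription("CC-NormalPlant", "normal"),
    "CC-NoPlant": Prescription("CC-NoPlant", None),
    "SC": Prescription("SC", None, lock_years=90.0, revisit_offsets=(30.0, 60.0)),
    "CT": Prescription(
        "CT", None, lock_years=50.0, revisit_offsets=(20.0, 50.0),
        revisit_in_intensive_only=True,
    ),
}

# (prescription, share % of the biomass target, zone code) in fixed order.
SCENARIOS: dict[str, list[tuple[str, float, str]]] = {
    "TRIAD+": [
        ("CC-PlantIntens", 25.0, "I"),
        ("CC-PlantFunct", 37.5, "E"),
        ("SC", 12.5, "E"),
        ("CT", 25.0, "I"),
    ],
    "TRIAD": [
        ("CC-PlantIntens", 25.0, "I"),
        ("CC-NoPlant", 37.5, "E"),
        ("SC", 12.5, "E"),
        ("CT", 25.0, "I"),
    ],
    "BAU-PlantFunct": [
        ("CC-PlantFunct", 37.5, "A"),
        ("CC-NormalPlant", 45.0, "A"),
        ("SC", 12.5, "A"),
        ("CT", 5.0, "A"),
    ],
    "BAU-NoPlant": [
        ("CC-NormalPlant", 45.0, "A"),
        ("CC-NoPlant", 37.5, "A"),
        ("SC", 12.5, "A"),
        ("CT", 5.0, "A"),
    ],
}

MANAGEMENT_SCENARIOS = tuple(SCENARIOS)


def removal_fraction(name: str, ages: np.ndarray) -> np.ndarray:
    """Fraction of cohort biomass removed by prescription ``name`` per age.

    CC-PlantIntens clears everything; the other clearcuts take 90% of
    cohorts older than 10 years (advanced regeneration spared); SC takes
    30% of cohorts aged >= 30; CT follows a declining age-bin schedule
    (<=30: 80%, 31-50: 66%, 51-90: 60%, 91-100: 40%, older: 5%).
    """
    a = np.asarray(ages, dtype=float)
    if name == "CC-PlantIntens":
        return np.ones_like(a)
    if name in ("CC-PlantFunct", "CC-NormalPlant", "CC-NoPlant"):
        return np.where(a > 10.0, 0.9, 0.0)
    if name == "SC":
        return np.where(a >= 30.0, 0.3, 0.0)
    if name == "CT":
        out = np.full_like(a, 0.05)
        out[a <= 100.0] = 0.40
        out[a <= 90.0] = 0.60
        out[a <= 50.0] = 0.66
        out[a <= 30.0] = 0.80
        return out
    raise ValueError(f"unknown prescription {name!r}")


def apply_prescription(
    community: Community, cells: np.ndarray, name: str
) -> tuple[Community, float]:
    """Apply a prescription to ``cells``; returns (new community, removed Mg)."""
    frac = removal_fraction(name, community.ages)
    b = community.biomass.copy()
    removed = float((b[cells] * frac).sum() * _G_TO_MG)
    b[cells] *= 1.0 - frac
    return Community(b, list(community.species_ids)), removed


# --------------------------------------------------------------------------
# Planting
# --------------------------------------------------------------------------

def select_planting_species(
    stand_species_biomass: np.ndarray,
    group_labels: np.ndarray,
    establishment_probs: np.ndarray,
    mode: str,
    rng: np.random.Generator,
    intensive_pair: tuple[int, int] | None = None,
) -> list[int]:
    """Choose species (indices) to plant in one treated stand.

    functional: one species per functional group missing from the stand,
    each drawn among that group's members of highest establishment
    probability (ties broken uniformly at random); if no group is missing,
    one species from the group of smallest biomass abundance.  normal: the
    stand's biomass-dominant species.  intensive: the region-appropriate
    hybrid plus its companion crop species (``intensive_pair``).
    """
    b = np.asarray(stand_species_biomass, dtype=float)
    labels = np.asarray(group_labels, dtype=int)
    estab = np.asarray(establishment_probs, dtype=float)

    if mode == "normal":
        if b.sum() <= 0:
            return []
        return [int(b.argmax())]

    if mode == "intensive":
        if intensive_pair is None:
            raise ValueError("intensive planting requires an intensive_pair")
        return [int(i) for i in intensive_pair]

    if mode != "functional":
        raise ValueError(f"unknown planting mode {mode!r}")

    groups = np.unique(labels)
    group_biomass = {g: b[labels == g].sum() for g in groups}
    missing = [g for g in groups if group_biomass[g] == 0.0]

    def pick(group: int) -> int:
        members = np.flatnonzero(labels == group)
        p = estab[members]
        best = members[p >= p.max() - 1e-12]
        return int(rng.choice(best))

    if missing:
        return [pick(g) for g in missing]
    present = [g for g in groups if group_biomass[g] > 0.0]
    rarest = min(present, key=lambda g: group_biomass[g])
    return [pick(rarest)]


# --------------------------------------------------------------------------
# Scheduling
# --------------------------------------------------------------------------

@dataclass
class HarvestState:
    """Locks and pending revisit obligations carried across steps."""

    locked_until: dict[int, float] = field(default_factory=dict)  # stand -> year
    revisits: list[tuple[float, int, str, str]] = field(default_factory=list)
    # (due year, stand, prescription, zone code)


def _zone_mask(landscape: Landscape, code: str) -> np.ndarray:
    active = landscape.active_flat
    zone = landscape.zone.ravel()
    if code == "I":
        return active & (zone == ZONE_INTENSIVE)
    if code == "E":
        return active & (zone == ZONE_EXTENSIVE)
    if code == "A":
        return active & ~landscape.protected.ravel() & (zone != ZONE_CONSERVATION)
    raise ValueError(f"unknown zone code {code!r}")


def _stand_totals(
    landscape: Landscape, values: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    sid = landscape.stand_id.ravel()
    ok = mask & (sid >= 0)
    return np.bincount(sid[ok], weights=values[ok], minlength=landscape.n_stands)


def default_intensive_pair(pool: SpeciesPool, fire_region: int) -> tuple[int, int]:
    """(hybrid, companion) species indices for intensive plantations.

    Southern fire region (1) plants the angiosperm hybrid (poplar
    analogue), northern (0) the gymnosperm hybrid (larch analogue); the
    companion is the marketable spruce analogue.
    """
    hybrids = [i for i, s in enumerate(pool) if s.is_hybrid]
    if not hybrids:
        raise ValueError("species pool contains no hybrid; call add_hybrid first")
    want = "angiosperm" if fire_region == 1 else "gymnosperm"
    matches = [i for i in hybrids if pool[i].clade == want] or hybrids
    hybrid = matches[0]
    if "black_spruce" in pool.ids:
        companion = pool.index("black_spruce")
    else:
        ranked = [i for i, s in enumerate(pool) if s.sbw_rank > 0]
        gymno = [i for i, s in enumerate(pool) if s.clade == "gymnosperm" and not s.is_hybrid]
        companion = (ranked or gymno or [hybrid])[-1]
    return hybrid, companion


def schedule_harvest(
    landscape: Landscape,
    community: Community,
    pool: SpeciesPool,
    growth: GrowthTables,
    grouping: FunctionalGrouping,
    scenario: str,
    biomass_target: float,
    year: float,
    climate: str,
    state: HarvestState,
    rng: np.random.Generator,
    initial_cohort_biomass: float = 50.0,
) -> tuple[Community, dict[str, float], list[dict]]:
    """Run one 10-year harvest step for ``scenario``.

    Returns (community, removed Mg per prescription, ledger rows).  Pending
    SC/CT revisits are served first; they count toward (and are truncated
    at) their prescription's share, so that removal per prescription never
    exceeds share x target by more than the last partial stand.  New stands
    are then consumed in ranking order until each share of
    ``biomass_target`` (Mg) is met or eligible stands run out (recorded as
    a shortfall row, not an error).  Only the last stand needed for a share
    may be harvested partially.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown management scenario {scenario!r}")
    plan = SCENARIOS[scenario]
    share_sum = sum(share for _, share, _ in plan)
    if abs(share_sum - 100.0) > 1e-9:
        raise AssertionError("prescription shares must sum to 100%")

    b = community.biomass.copy()
    ages = cohort_ages(b.shape[2])
    labels = grouping.labels(community.species_ids)
    estab, _, _ = growth.lookup(climate, year)
    stand_eco = landscape.stand_majority(landscape.ecoregion_id)
    stand_fire = landscape.stand_majority(landscape.fire_region_id)
    sid_flat = landscape.stand_id.ravel()

    removed: dict[str, float] = {p: 0.0 for p, _, _ in plan}
    rows: list[dict] = []

    def plant(cells: np.ndarray, stand: int, mode: str | None) -> list[str]:
        if mode is None or len(cells) == 0:
            return []
        stand_cells = landscape.stand_cells(stand)
        stand_sp = b[stand_cells].sum(axis=(0, 2))
        if mode == "intensive":
            pair = default_intensive_pair(pool, int(stand_fire[stand]))
            chosen = select_planting_species(
                stand_sp, labels, estab[:, stand_eco[stand]], mode, rng,
                intensive_pair=pair,
            )
        else:
            chosen = select_planting_species(
                stand_sp, labels, estab[:, stand_eco[stand]], mode, rng
            )
        for s in chosen:
            b[cells, s, 0] = np.maximum(b[cells, s, 0], initial_cohort_biomass)
        return [community.species_ids[s] for s in chosen]

    def harvest_cells(cells: np.ndarray, pname: str) -> float:
        frac = removal_fraction(pname, ages)
        got = float((b[cells] * frac).sum() * _G_TO_MG)
        b[cells] *= 1.0 - frac
        return got

    need_by_presc = {p: share / 100.0 * biomass_target for p, share, _ in plan}

    def cut_to_need(
        cells: np.ndarray, pname: str, need: float
    ) -> tuple[float, bool, np.ndarray]:
        """Harvest cells, truncated (by random cell subset) at ``need``;
        returns (removed Mg, truncated?, cells actually cut)."""
        frac = removal_fraction(pname, ages)
        cell_removable = (b[cells] * frac).sum(axis=(1, 2)) * _G_TO_MG
        partial = cell_removable.sum() > need
        if partial:
            perm = rng.permutation(len(cells))
            cum = np.cumsum(cell_removable[perm])
            k = int(np.searchsorted(cum, need)) + 1
            cells = cells[perm[:k]]
        return harvest_cells(cells, pname), partial, cells

    # 1. revisit obligations due this step, served within the share
    still_pending: list[tuple[float, int, str, str]] = []
    for due, stand, pname, code in state.revisits:
        if due > year:
            still_pending.append((due, stand, pname, code))
            continue
        cells = landscape.stand_cells(stand)
        cells = cells[_zone_mask(landscape, code)[cells]]
        need = need_by_presc.get(pname, 0.0) - removed.get(pname, 0.0)
        if need > 0 and len(cells):
            got, partial, _ = cut_to_need(cells, pname, need)
        else:
            got, partial = 0.0, False
        removed[pname] = removed.get(pname, 0.0) + got
        rows.append(
            dict(year=year, prescription=pname, stand=int(stand), removed_Mg=got,
                 event="revisit", partial=partial, planted="")
        )
    state.revisits = still_pending

    # 2. new stand selections, in the fixed prescription order
    for pname, share, code in plan:
        need = need_by_presc[pname] - removed.get(pname, 0.0)
        if need <= 0.0 or biomass_target <= 0.0:
            continue
        presc = PRESCRIPTIONS[pname]
        mask = _zone_mask(landscape, code)
        frac = removal_fraction(pname, ages)
        cell_removable = (b * frac).sum(axis=(1, 2)) * _G_TO_MG  # Mg per cell
        stand_removable = _stand_totals(landscape, cell_removable, mask)

        unlocked = np.ones(landscape.n_stands, dtype=bool)
        for stand, until in state.locked_until.items():
            if year < until:
                unlocked[stand] = False
        eligible = np.flatnonzero((stand_removable > 0.0) & unlocked)
        if eligible.size == 0:
            rows.append(
                dict(year=year, prescription=pname, stand=-1, removed_Mg=0.0,
                     event="shortfall", partial=False, planted="")
            )
            continue

        if pname == "CC-PlantFunct":
            # target the least functionally diverse stands first
            stand_fd = _stand_fd_by_stand(landscape, b, labels, grouping.n_groups)
            order = eligible[np.argsort(stand_fd[eligible], kind="stable")]
        else:
            order = eligible[np.argsort(stand_removable[eligible], kind="stable")[::-1]]

        for stand in order:
            if need <= 0.0:
                break
            cells = landscape.stand_cells(stand)
            cells = cells[mask[cells]]
            if len(cells) == 0:
                continue
            got, partial, cells = cut_to_need(cells, pname, need)
            need -= got
            removed[pname] += got
            planted = plant(cells, int(stand), presc.plant_mode)
            if presc.lock_years > 0 and (
                not presc.revisit_in_intensive_only or code == "I"
            ):
                state.locked_until[int(stand)] = year + presc.lock_years
                for off in presc.revisit_offsets:
                    state.revisits.append((year + off, int(stand), pname, code))
            rows.append(
                dict(year=year, prescription=pname, stand=int(stand),
                     removed_Mg=got, event="harvest", partial=bool(partial),
                     planted=";".join(planted))
            )
        if need > 1e-9:
            # unmet share; removed_Mg records the missing amount
            rows.append(
                dict(year=year, prescription=pname, stand=-1, removed_Mg=need,
                     event="shortfall", partial=False, planted="")
            )

    return Community(b, list(community.species_ids)), removed, rows


def _stand_fd_by_stand(
    landscape: Landscape, biomass: np.ndarray, labels: np.ndarray, n_groups: int
) -> np.ndarray:
    """FD_S per stand from a raw biomass array (empty stands get +inf so
    they rank last for CC-PlantFunct)."""
    sid = landscape.stand_id.ravel()
    ok = sid >= 0
    sp_cell = biomass.sum(axis=2)
    stand_group = np.zeros((landscape.n_stands, n_groups))
    for g in range(1, n_groups + 1):
        v = sp_cell[:, labels == g].sum(axis=1)
        stand_group[:, g - 1] = np.bincount(
            sid[ok], weights=v[ok], minlength=landscape.n_stands
        )
    total = stand_group.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stand_group / total[:, None]
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        fd = np.exp(-plogp.sum(axis=1))
    fd[total == 0.0] = np.inf
    return fd


def ledger_frame(rows: list[dict]) -> pd.DataFrame:
    """Harvest ledger rows -> DataFrame (stable column order)."""
    cols = ["year", "prescription", "stand", "removed_Mg", "event", "partial", "planted"]
    return pd.DataFrame(rows, columns=cols)
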