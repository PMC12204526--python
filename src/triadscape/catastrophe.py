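"""Catastrophic pulse disturbances at mid-simulation.

Three events — a landscape-wide fire with unburned refugia, a severe
drought, and a mountain pine beetle (MPB) outbreak — each remove cohort
biomass as the product of a species-level loss and a stand-level
protection:

    loss = species_loss(trait or host status) x (1 - stand_reduction)

The lookup tables (binned, right-closed intervals (a, b], bottom bin
closed on the left) are:

large fire    species fire tolerance -> loss   100/90/80/70/60 % per unit bin
              stand CWM fire tolerance -> reduction 0/10/20/30/40 %
drought       species drought tolerance -> loss 70/60/50/40/30 %
              stand FD -> reduction 0/5/10/15/20 %
MPB           hosts lose 80 %, non-hosts 0 %
              stand host abundance (%, descending bins of 10 from 100)
              -> reduction 0, 8.6, 17.2, 25.8, 34.4, 43, 51.6, 60.2, 68.8, 77.4 %

The fire spares refugium cells entirely; drought affects the whole
landscape; MPB touches only host cohorts.  Stand modifiers are evaluated
on the pre-event state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .communities import Community
from .landscape import Landscape

__all__ = [
    "SEVERITY_TABLES",
    "RefugiaMap",
    "bin_lookup",
    "generate_refugia",
    "apply_large_fire",
    "apply_drought",
    "apply_mpb",
    "severity_frame",
]

# (lo, hi, fraction); intervals are (lo, hi], with the lowest bin closed at lo.
_FIRE_SPECIES = [(0, 1, 1.00), (1, 2, 0.90), (2, 3, 0.80), (3, 4, 0.70), (4, 5, 0.60)]
_FIRE_STAND = [(0, 1, 0.00), (1, 2, 0.10), (2, 3, 0.20), (3, 4, 0.30), (4, 5, 0.40)]
_DROUGHT_SPECIES = [(0, 1, 0.70), (1, 2, 0.60), (2, 3, 0.50), (3, 4, 0.40), (4, 5, 0.30)]
_DROUGHT_STAND = [(0, 1, 0.00), (1, 2, 0.05), (2, 3, 0.10), (3, 4, 0.15), (4, 5, 0.20)]
MPB_HOST_LOSS = 0.80
# host-abundance bins descend from 100%: [90,100] -> 0 ... [0,10) -> 0.774
_MPB_STAND = [
    (90, 100, 0.000), (80, 90, 0.086), (70, 80, 0.172), (60, 70, 0.258),
    (50, 60, 0.344), (40, 50, 0.430), (30, 40, 0.516), (20, 30, 0.602),
    (10, 20, 0.688), (0, 10, 0.774),
]

SEVERITY_TABLES = {
    "fire": {"species": _FIRE_SPECIES, "stand": _FIRE_STAND},
    "drought": {"species": _DROUGHT_SPECIES, "stand": _DROUGHT_STAND},
    "mpb": {"species": [(0, 100, MPB_HOST_LOSS)], "stand": _MPB_STAND},
}


def bin_lookup(value: float, rows: list[tuple[float, float, float]]) -> float:
    """Fraction of the bin containing ``value``.

    Bins are right-closed, (lo, hi], except the bin with the smallest lower
    edge, which is closed on both ends so the domain's minimum is covered.
    Values outside the table domain raise.
    """
    lo_min = min(r[0] for r in rows)
    for lo, hi, frac in rows:
        if (value > lo or (lo == lo_min and value >= lo)) and value <= hi:
            return float(frac)
    raise ValueError(f"value {value} outside table domain")


def _lookup_vec(values: np.ndarray, rows: list[tuple[float, float, float]]) -> np.ndarray:
    out = np.empty(len(values), dtype=float)
    for i, v in enumerate(values):
        out[i] = bin_lookup(float(v), rows)
    return out


def severity_frame() -> pd.DataFrame:
    """Severity tables in long CSV form (event, level, bin_lo, bin_hi, fraction)."""
    rows = []
    for event, tabs in SEVERITY_TABLES.items():
        for level, tab in tabs.items():
            for lo, hi, frac in tab:
                rows.append(
                    dict(event=event, level=level, bin_lo=lo, bin_hi=hi, fraction=frac)
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Refugia
# --------------------------------------------------------------------------

@dataclass
class RefugiaMap:
    """Unburned patches of the catastrophic fire."""

    mask: np.ndarray  # flat bool, True = refugium cell
    patch_sizes: list[int]  # realized size of each refugium, ha

    @property
    def coverage(self) -> float:
        return float(self.mask.mean())


def _powerlaw_sizes(
    rng: np.random.Generator, size_min: int, size_max: int, exponent: float, n: int
) -> np.ndarray:
    sizes = np.arange(size_min, size_max + 1)
    pmf = sizes.astype(float) ** -exponent
    pmf /= pmf.sum()
    return rng.choice(sizes, size=n, p=pmf)


def generate_refugia(
    landscape: Landscape,
    target_fraction: float = 0.30,
    size_min: int = 1,
    size_max: int = 100,
    powerlaw_exponent: float = 2.0,
    rng: np.random.Generator | None = None,
) -> RefugiaMap:
    """Place fire refugia until ``target_fraction`` of active cells is covered.

    Each refugium's size is drawn from a truncated discrete power law on
    [size_min, size_max] ha; the patch starts at a uniformly random stand
    not already inside a refugium and accretes neighbouring stands (cells
    of the final stand truncated so the sampled size is met exactly).
    Accumulation stops with the first refugium that reaches or exceeds the
    target.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie in (0, 1)")
    if landscape.n_active < 100:
        raise ValueError("landscape too small for refugia generation")
    rng = rng or np.random.default_rng()

    n_active = landscape.n_active
    target_cells = target_fraction * n_active
    mask = np.zeros(landscape.n_cells, dtype=bool)
    adjacency = landscape.stand_adjacency()
    # a stand can seed a refugium while any of its cells is still unburied
    free_cells = landscape.stand_sizes().astype(int)
    sizes: list[int] = []
    covered = 0

    # draw sizes in blocks to amortize the pmf sampling
    block = max(64, int(target_cells / ((size_min + size_max) / 8)))
    pending: list[int] = []
    while covered < target_cells:
        if not pending:
            pending = list(
                _powerlaw_sizes(rng, size_min, size_max, powerlaw_exponent, block)
            )
        size = int(pending.pop())
        candidates = np.flatnonzero(free_cells > 0)
        if candidates.size == 0:
            break
        start = int(rng.choice(candidates))
        # stand-by-stand accretion from the seed stand
        taken_cells: list[np.ndarray] = []
        n_taken = 0
        visited = {start}
        frontier = [start]
        while n_taken < size and frontier:
            i = rng.integers(len(frontier))
            frontier[i], frontier[-1] = frontier[-1], frontier[i]
            stand = frontier.pop()
            cells = landscape.stand_cells(stand)
            cells = cells[~mask[cells]]
            if len(cells) > 0:
                room = size - n_taken
                if len(cells) > room:
                    cells = cells[:room]  # truncate the last stand
                taken_cells.append(cells)
                n_taken += len(cells)
                free_cells[stand] -= len(cells)
            for nb in adjacency[stand]:
                if nb not in visited:
                    visited.add(nb)
                    frontier.append(nb)
        if n_taken == 0:
            continue
        patch = np.concatenate(taken_cells)
        mask[patch] = True
        sizes.append(n_taken)
        covered += n_taken

    return RefugiaMap(mask=mask, patch_sizes=sizes)


# --------------------------------------------------------------------------
# Events
# --------------------------------------------------------------------------

def _stand_reduction_per_cell(
    landscape: Landscape, stand_values: np.ndarray,
    rows: list[tuple[float, float, float]],
) -> np.ndarray:
    """Map per-stand modifier values through the stand-level table to a
    per-cell reduction factor.  NaN (empty) stands get the bottom bin;
    values beyond the table domain are clamped to its edges (e.g. FD above
    5 with a non-default group count)."""
    lo_min = float(min(r[0] for r in rows))
    hi_max = float(max(r[1] for r in rows))
    vals = np.clip(np.nan_to_num(stand_values, nan=lo_min), lo_min, hi_max)
    red_by_stand = _lookup_vec(vals, rows)
    sid = landscape.stand_id.ravel()
    out = np.zeros(landscape.n_cells)
    ok = sid >= 0
    out[ok] = red_by_stand[sid[ok]]
    return out


def apply_large_fire(
    landscape: Landscape,
    community: Community,
    refugia: RefugiaMap,
    stand_cwm_fire: np.ndarray,
    fire_tolerance: np.ndarray,
) -> Community:
    """Landscape-scale fire: refugium cells untouched; elsewhere each cohort
    loses species_loss(fire tolerance) x (1 - reduction(stand CWM))."""
    sp_loss = _lookup_vec(fire_tolerance, _FIRE_SPECIES)  # (n_sp,)
    red = _stand_reduction_per_cell(landscape, stand_cwm_fire, _FIRE_STAND)
    factor = sp_loss[None, :] * (1.0 - red)[:, None]  # (cells, sp)
    factor[refugia.mask] = 0.0
    b = community.biomass * (1.0 - factor)[:, :, None]
    return Community(b, list(community.species_ids))


def apply_drought(
    landscape: Landscape,
    community: Community,
    stand_fd: np.ndarray,
    drought_tolerance: np.ndarray,
) -> Community:
    """Severe drought over the whole landscape, no refugia; diverse stands
    (high FD) shelter all their species."""
    sp_loss = _lookup_vec(drought_tolerance, _DROUGHT_SPECIES)
    red = _stand_reduction_per_cell(landscape, stand_fd, _DROUGHT_STAND)
    factor = sp_loss[None, :] * (1.0 - red)[:, None]
    b = community.biomass * (1.0 - factor)[:, :, None]
    return Community(b, list(community.species_ids))


def apply_mpb(
    landscape: Landscape,
    community: Community,
    stand_host_pct: np.ndarray,
    mpb_host: np.ndarray,
) -> Community:
    """MPB outbreak: host cohorts lose 80% x (1 - dilution reduction from
    the stand's host abundance); non-hosts are untouched."""
    host = np.asarray(mpb_host, dtype=bool)
    red = _stand_reduction_per_cell(landscape, stand_host_pct, _MPB_STAND)
    factor = np.zeros((community.n_cells, community.n_species))
    factor[:, host] = (MPB_HOST_LOSS * (1.0 - red))[:, None]
    b = community.biomass * (1.0 - factor)[:, :, None]
    return Community(b, list(community.species_ids))
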