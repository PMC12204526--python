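"""Synthetic raster landscape.

A rectangular grid of 1-ha cells carrying the static spatial structure the
simulation needs: contiguous forest stands (Voronoi tiles around random
seed points), ecoregions as latitudinal bands, two fire regions splitting
the grid north/south, and an initial protected-area network made of a few
large and many small patches.  Management zones (intensive / extensive /
conservation) start unset and are assigned by the management module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["Landscape", "generate_landscape", "grow_patch", "ZONE_CODES"]

# zone codes stored in Landscape.zone
ZONE_NONE, ZONE_INTENSIVE, ZONE_EXTENSIVE, ZONE_CONSERVATION = 0, 1, 2, 3
ZONE_CODES = {
    "none": ZONE_NONE,
    "intensive": ZONE_INTENSIVE,
    "extensive": ZONE_EXTENSIVE,
    "conservation": ZONE_CONSERVATION,
}

CELL_AREA_HA = 1.0  # fixed: one cell = 1 ha (100 m grid)


@dataclass
class Landscape:
    """Static spatial layers; every array has shape (n_rows, n_cols)."""

    active: np.ndarray  # bool, forested cells
    stand_id: np.ndarray  # int, -1 on inactive cells
    ecoregion_id: np.ndarray  # int bands, 0 = northernmost
    fire_region_id: np.ndarray  # int, 0 = north, 1 = south
    protected: np.ndarray  # bool
    protected_patch_id: np.ndarray  # int, -1 outside patches
    zone: np.ndarray  # int8 ZONE_* codes
    site_quality: np.ndarray  # per-stand fertility multiplier, shape (n_stands,)
    n_ecoregions: int
    _stand_cells: list[np.ndarray] | None = field(default=None, repr=False)
    _stand_adjacency: list[set[int]] | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.active.shape

    @property
    def n_cells(self) -> int:
        return self.active.size

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def n_stands(self) -> int:
        return len(self.site_quality)

    @property
    def active_flat(self) -> np.ndarray:
        return self.active.ravel()

    def stand_cells(self, stand: int) -> np.ndarray:
        """Flat indices of the cells of one stand (cached)."""
        if self._stand_cells is None:
            flat = self.stand_id.ravel()
            order = np.argsort(flat, kind="stable")
            sorted_ids = flat[order]
            self._stand_cells = []
            for s in range(self.n_stands):
                lo = np.searchsorted(sorted_ids, s)
                hi = np.searchsorted(sorted_ids, s, side="right")
                self._stand_cells.append(order[lo:hi].copy())
        return self._stand_cells[stand]

    def stand_sizes(self) -> np.ndarray:
        flat = self.stand_id.ravel()
        return np.bincount(flat[flat >= 0], minlength=self.n_stands)

    def stand_adjacency(self) -> list[set[int]]:
        """Stand -> set of neighbouring stands (4-neighbourhood)."""
        if self._stand_adjacency is None:
            sid = self.stand_id
            adj: list[set[int]] = [set() for _ in range(self.n_stands)]
            for a, b in (
                (sid[:, :-1], sid[:, 1:]),
                (sid[:-1, :], sid[1:, :]),
            ):
                diff = (a != b) & (a >= 0) & (b >= 0)
                for u, v in zip(a[diff].ravel(), b[diff].ravel()):
                    adj[u].add(int(v))
                    adj[v].add(int(u))
            self._stand_adjacency = adj
        return self._stand_adjacency

    def stand_majority(self, layer: np.ndarray) -> np.ndarray:
        """Per-stand majority value of an integer cell layer."""
        flat_sid = self.stand_id.ravel()
        flat_val = layer.ravel()
        ok = flat_sid >= 0
        nv = int(flat_val[ok].max()) + 1
        counts = np.bincount(
            flat_sid[ok] * nv + flat_val[ok], minlength=self.n_stands * nv
        ).reshape(self.n_stands, nv)
        return counts.argmax(axis=1)

    def copy(self) -> "Landscape":
        return Landscape(
            active=self.active.copy(),
            stand_id=self.stand_id.copy(),
            ecoregion_id=self.ecoregion_id.copy(),
            fire_region_id=self.fire_region_id.copy(),
            protected=self.protected.copy(),
            protected_patch_id=self.protected_patch_id.copy(),
            zone=self.zone.copy(),
            site_quality=self.site_quality.copy(),
            n_ecoregions=self.n_ecoregions,
        )


def grow_patch(
    start: int,
    size: int,
    allowed: np.ndarray,
    shape: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow a connected patch of ``size`` cells from flat index ``start``.

    Randomised breadth-first accretion on the 4-neighbourhood, restricted to
    ``allowed`` (flat bool mask).  Returns the flat indices reached; may be
    shorter than ``size`` if the allowed component is exhausted.
    """
    n_rows, n_cols = shape
    taken = [start]
    in_patch = {start}
    frontier = [start]
    while len(taken) < size and frontier:
        # pop a random frontier cell
        i = rng.integers(len(frontier))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        cell = frontier.pop()
        r, c = divmod(cell, n_cols)
        nbrs = []
        if r > 0:
            nbrs.append(cell - n_cols)
        if r < n_rows - 1:
            nbrs.append(cell + n_cols)
        if c > 0:
            nbrs.append(cell - 1)
        if c < n_cols - 1:
            nbrs.append(cell + 1)
        rng.shuffle(nbrs)
        for nb in nbrs:
            if nb not in in_patch and allowed[nb]:
                in_patch.add(nb)
                taken.append(nb)
                frontier.append(nb)
                if len(taken) >= size:
                    break
    return np.asarray(taken, dtype=np.int64)


def _protected_patch_sizes(
    target_cells: int, rng: np.random.Generator
) -> list[int]:
    """Right-skewed patch-size sequence summing to ``target_cells``.

    A heavy-tailed (Lomax) draw gives many small patches and a few large
    ones, echoing a reserve network of numerous small refugia plus a handful
    of large parks; the median patch is much smaller than the mean.
    """
    sizes: list[int] = []
    placed = 0
    cap = max(8, int(0.35 * target_cells))
    while placed < target_cells:
        s = int(2 + rng.pareto(1.1) * 6)
        s = min(s, cap, target_cells - placed)
        s = max(s, 1)
        sizes.append(s)
        placed += s
    return sizes


def generate_landscape(
    n_rows: int = 200,
    n_cols: int = 250,
    n_ecoregions: int = 4,
    stand_mean_size: float = 25.0,
    protected_fraction: float = 0.09,
    rng_seed: int = 0,
) -> Landscape:
    """Generate the synthetic landscape.

    Stands are Voronoi tiles around uniformly random seed points (contiguous,
    size fluctuating around ``stand_mean_size`` ha).  Ecoregions are
    ``n_ecoregions`` latitudinal bands (band 0 northernmost); two fire
    regions split the grid at mid-latitude.  Protected patches are grown by
    randomised accretion to a size-skewed sequence until they cover
    ``protected_fraction`` of the active area (exactly, by construction).
    """
    if not 0.0 < protected_fraction < 0.5:
        raise ValueError("protected_fraction must lie in (0, 0.5)")
    n_cells = n_rows * n_cols
    n_stands_target = max(2, int(round(n_cells / stand_mean_size)))
    if n_cells < 100 or n_stands_target < 4:
        raise ValueError("grid too small to host the requested patch structure")

    rng = np.random.default_rng(rng_seed)
    active = np.ones((n_rows, n_cols), dtype=bool)

    # stands: nearest-seed (Voronoi) tiling
    pts = rng.uniform(0, 1, size=(n_stands_target, 2)) * [n_rows, n_cols]
    rr, cc = np.meshgrid(
        np.arange(n_rows) + 0.5, np.arange(n_cols) + 0.5, indexing="ij"
    )
    tree = cKDTree(pts)
    _, nearest = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    # relabel to contiguous ids (some seeds may own no cell)
    uniq, stand_flat = np.unique(nearest, return_inverse=True)
    stand_id = stand_flat.reshape(n_rows, n_cols).astype(np.int64)
    n_stands = len(uniq)

    # ecoregions: latitudinal bands, 0 = north
    band = np.minimum(
        (np.arange(n_rows) * n_ecoregions) // n_rows, n_ecoregions - 1
    )
    ecoregion_id = np.repeat(band[:, None], n_cols, axis=1).astype(np.int64)

    # two fire regions, split at mid-latitude
    fire_region_id = (np.arange(n_rows)[:, None] >= n_rows // 2).astype(np.int64)
    fire_region_id = np.broadcast_to(fire_region_id, (n_rows, n_cols)).copy()

    # protected patches
    target = int(round(protected_fraction * active.sum()))
    protected = np.zeros(n_cells, dtype=bool)
    patch_id = np.full(n_cells, -1, dtype=np.int64)
    sizes = _protected_patch_sizes(target, rng)
    free = active.ravel() & ~protected
    pid = 0
    for size in sorted(sizes, reverse=True):
        candidates = np.flatnonzero(free)
        if len(candidates) == 0:
            break
        start = int(rng.choice(candidates))
        cells = grow_patch(start, size, free, (n_rows, n_cols), rng)
        protected[cells] = True
        patch_id[cells] = pid
        free[cells] = False
        pid += 1

    site_quality = np.exp(rng.normal(0.0, 0.15, size=n_stands))

    return Landscape(
        active=active,
        stand_id=stand_id,
        ecoregion_id=ecoregion_id,
        fire_region_id=fire_region_id,
        protected=protected.reshape(n_rows, n_cols),
        protected_patch_id=patch_id.reshape(n_rows, n_cols),
        zone=np.zeros((n_rows, n_cols), dtype=np.int8),
        site_quality=site_quality,
        n_ecoregions=n_ecoregions,
    )
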