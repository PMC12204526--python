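"""Functional groups, functional response diversity, and stand summaries.

Functional groups come from Ward-linkage agglomerative clustering of the
nine z-scored response traits.  A stand's functional response diversity
FD_S is the exponential of the Shannon entropy of group biomass shares
(the Hill number of order 1): the effective number of functional groups,
ranging from 1 (monoculture) to the number of groups present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .communities import Community
from .landscape import Landscape
from .species import CLUSTER_TRAITS, SpeciesPool

__all__ = [
    "EMPTY_STAND",
    "FunctionalGrouping",
    "LandscapeSummary",
    "cluster_functional_groups",
    "stand_fd",
    "stand_cwm",
    "landscape_summaries",
]


class _EmptyStand:
    """Sentinel returned by stand_fd for an empty (all-zero) stand."""

    def __repr__(self) -> str:  # pragma: no cover
        return "EMPTY_STAND"


EMPTY_STAND = _EmptyStand()


@dataclass(frozen=True)
class FunctionalGrouping:
    """species_id -> functional group (1..n_groups)."""

    mapping: dict[str, int]
    n_groups: int

    def labels(self, species_ids: list[str]) -> np.ndarray:
        """Group label per species, aligned with ``species_ids``."""
        return np.asarray([self.mapping[s] for s in species_ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species_id": list(self.mapping), "group_id": list(self.mapping.values())}
        )


def cluster_functional_groups(
    trait_table: pd.DataFrame, n_groups: int
) -> FunctionalGrouping:
    """Cluster species on the nine response traits.

    Traits are standardised (z-scored) and clustered with Ward linkage on
    Euclidean distance, cut at ``n_groups`` — a deterministic procedure with
    no random initialisation.  Group ids are relabelled contiguously from 1
    in order of first appearance.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    missing_cols = [t for t in CLUSTER_TRAITS if t not in trait_table.columns]
    if missing_cols:
        raise ValueError(f"trait table lacks columns: {missing_cols}")
    X = trait_table[CLUSTER_TRAITS].astype(float)
    if X.isna().any().any():
        sp, tr = next(
            (i, c) for c in X.columns for i in X.index[X[c].isna()]
        )
        raise ValueError(f"missing trait value: species {sp!r}, trait {tr!r}")
    if n_groups > len(X):
        raise ValueError("n_groups exceeds the number of species")

    Z = X.to_numpy()
    sd = Z.std(axis=0)
    sd[sd == 0.0] = 1.0  # constant trait carries no distance information
    Z = (Z - Z.mean(axis=0)) / sd
    labels = fcluster(linkage(Z, method="ward"), t=n_groups, criterion="maxclust")

    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for sp, lab in zip(trait_table.index, labels):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[str(sp)] = relabel[lab]
    return FunctionalGrouping(mapping=out, n_groups=len(relabel))


def stand_fd(group_biomass: np.ndarray):
    """Effective number of functional groups in a stand.

    exp(-sum p_i ln p_i) over the groups with positive biomass share p_i
    (natural logarithm, matching the exponential).  Returns the
    ``EMPTY_STAND`` sentinel when all abundances are zero.
    """
    b = np.asarray(group_biomass, dtype=float)
    if np.any(b < 0):
        raise ValueError("group biomass must be non-negative")
    total = b.sum()
    if total == 0.0:
        return EMPTY_STAND
    p = b[b > 0] / total
    return float(np.exp(-(p * np.log(p)).sum()))


def stand_cwm(species_biomass: np.ndarray, trait_values: np.ndarray) -> float:
    """Community-weighted mean of a trait (biomass weights over species)."""
    b = np.asarray(species_biomass, dtype=float)
    t = np.asarray(trait_values, dtype=float)
    total = b.sum()
    if total <= 0.0:
        raise ValueError("community is empty: CWM undefined")
    return float((b * t).sum() / total)


@dataclass
class LandscapeSummary:
    """Per-stand and landscape-level biomass / diversity summaries.

    Biomass sums are in Mg (1-ha cells: g/m^2 x 1 ha = 10 kg); FD values
    are effective group counts.  ``B_L`` counts mature cohorts only;
    ``B_FG`` counts all ages.
    """

    B_L: float  # landscape mature biomass, Mg
    FD_mean: float  # stand-area-weighted mean FD_S over non-empty stands
    B_FG: np.ndarray  # (n_groups,) all-age biomass per functional group, Mg
    stands: pd.DataFrame  # one row per stand
    stand_fd_values: np.ndarray  # (n_stands,) FD_S, NaN for empty stands
    stand_cwm_fire: np.ndarray  # (n_stands,) CWM fire tolerance, NaN if empty
    stand_host_pct: np.ndarray  # (n_stands,) % of stand biomass in MPB hosts


_G_TO_MG = 0.01  # g/m^2 over one 1-ha cell -> Mg


def landscape_summaries(
    landscape: Landscape,
    community: Community,
    grouping: FunctionalGrouping,
    pool: SpeciesPool,
    maturity_age: float = 40.0,
) -> LandscapeSummary:
    """Aggregate the community into stand and landscape summaries.

    B_L sums the biomass of cohorts aged >= ``maturity_age`` over all
    stands; FD_S uses all-age group biomass shares; the area-weighted mean
    FD excludes empty stands (FD undefined there); B_FG includes all ages.
    """
    n_stands = landscape.n_stands
    sid = landscape.stand_id.ravel()
    ok = sid >= 0
    labels = grouping.labels(community.species_ids)  # 1..G
    n_groups = grouping.n_groups

    sp_cell = community.species_per_cell()  # (n_cells, n_sp)
    mature_cell = community.mature_per_cell(maturity_age)  # (n_cells,)

    # per-stand per-group biomass (all ages)
    group_by_cell = np.zeros((community.n_cells, n_groups))
    for g in range(1, n_groups + 1):
        group_by_cell[:, g - 1] = sp_cell[:, labels == g].sum(axis=1)
    stand_group = np.zeros((n_stands, n_groups))
    for g in range(n_groups):
        stand_group[:, g] = np.bincount(
            sid[ok], weights=group_by_cell[ok.nonzero()[0], g], minlength=n_stands
        )

    stand_total = stand_group.sum(axis=1)
    stand_mature = np.bincount(sid[ok], weights=mature_cell[ok], minlength=n_stands)
    area = np.bincount(sid[ok], minlength=n_stands).astype(float)  # ha

    # FD_S per stand (vectorised Shannon exponential)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stand_group / stand_total[:, None]
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        fd = np.exp(-plogp.sum(axis=1))
    fd[stand_total == 0.0] = np.nan

    # CWM fire tolerance and MPB host share per stand
    fire_tol = pool.array("fire_tolerance")
    host = pool.flags("mpb_host").astype(float)
    stand_sp = np.zeros((n_stands, community.n_species))
    for s in range(community.n_species):
        stand_sp[:, s] = np.bincount(sid[ok], weights=sp_cell[ok, s], minlength=n_stands)
    with np.errstate(divide="ignore", invalid="ignore"):
        cwm_fire = (stand_sp * fire_tol).sum(axis=1) / stand_total
        host_pct = 100.0 * (stand_sp * host).sum(axis=1) / stand_total
    cwm_fire[stand_total == 0.0] = np.nan
    host_pct[stand_total == 0.0] = 0.0

    nonempty = stand_total > 0.0
    fd_mean = (
        float((fd[nonempty] * area[nonempty]).sum() / area[nonempty].sum())
        if nonempty.any()
        else float("nan")
    )

    stands = pd.DataFrame(
        {
            "stand_id": np.arange(n_stands),
            "area_ha": area,
            "B_S": stand_mature * _G_TO_MG,
            "FD_S": fd,
            "CWM_fire_tolerance": cwm_fire,
            "host_abundance_pct": host_pct,
            **{
                f"B_group_{g + 1}": stand_group[:, g] * _G_TO_MG
                for g in range(n_groups)
            },
        }
    )

    return LandscapeSummary(
        B_L=float(stand_mature.sum() * _G_TO_MG),
        FD_mean=fd_mean,
        B_FG=stand_group.sum(axis=0) * _G_TO_MG,
        stands=stands,
        stand_fd_values=fd,
        stand_cwm_fire=cwm_fire,
        stand_host_pct=host_pct,
    )
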