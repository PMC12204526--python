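"""Scenario grid, run orchestration and aggregation.

The factorial design crosses 4 management strategies x 3 climate forcings
x 4 catastrophe arms (fire, drought, MPB, none), i.e. 48 scenarios, each
replicated; every run covers 200 years in 10-year steps with the pulse
event at year 100.  All scenarios of one master seed share the same
synthetic inputs (landscape, species pool, growth tables, initial
communities) and scenarios sharing a replicate index share their
random-number stream (common random numbers), so scenario contrasts are
paired.

Within-step operation order (fixed): growth -> mortality/aging ->
background fire -> budworm -> harvest -> catastrophe (event year only) ->
establishment -> summaries.  Catastrophe severity modifiers (stand CWM
fire tolerance, FD, host abundance) are evaluated on the year-90 state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catastrophe import (
    apply_drought,
    apply_large_fire,
    apply_mpb,
    generate_refugia,
)
from .communities import Community, generate_initial_communities
from .disturbance import (
    FireRegimeSet,
    SBWRegime,
    background_fire_step,
    default_fire_regimes,
    default_sbw_regime,
    sbw_outbreak_step,
)
from .functional import (
    FunctionalGrouping,
    LandscapeSummary,
    cluster_functional_groups,
    landscape_summaries,
)
from .growth import CLIMATES, GrowthTables, generate_growth_tables
from .landscape import Landscape, generate_landscape
from .management import (
    MANAGEMENT_SCENARIOS,
    HarvestState,
    add_hybrid,
    allocate_zones,
    ledger_frame,
    schedule_harvest,
)
from .resilience import ResilienceSummary, RunSeries, summarize_run
from .species import SpeciesPool, generate_species_pool
from .succession import (
    SuccessionConfig,
    step_establishment,
    step_growth,
    step_mortality_and_aging,
)

__all__ = [
    "CATASTROPHES",
    "ScenarioSpec",
    "ExperimentConfig",
    "SimulationInputs",
    "RunResult",
    "build_grid",
    "prepare_inputs",
    "run_scenario",
    "run_grid",
    "aggregate",
]

CATASTROPHES = ("fire", "drought", "mpb", "none")

_SEED_MOD = 2**31


@dataclass(frozen=True)
class ScenarioSpec:
    """One point of the management x climate x catastrophe grid."""

    management: str
    climate: str
    catastrophe: str
    replicate: int
    seed: int

    def __post_init__(self) -> None:
        if self.management not in MANAGEMENT_SCENARIOS:
            raise ValueError(f"unknown management scenario {self.management!r}")
        if self.climate not in CLIMATES:
            raise ValueError(f"unknown climate scenario {self.climate!r}")
        if self.catastrophe not in CATASTROPHES:
            raise ValueError(f"unknown catastrophe {self.catastrophe!r}")

    @property
    def label(self) -> str:
        return (
            f"{self.management}|{self.climate}|{self.catastrophe}|r{self.replicate}"
        )


def build_grid(replicates: int = 5, master_seed: int = 0) -> list[ScenarioSpec]:
    """Full factorial grid: 48 scenarios x ``replicates`` specs.

    Replicate seeds are derived deterministically from ``master_seed`` and
    shared by all scenarios with the same replicate index (common random
    numbers), so paired scenario contrasts are sharpened.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rep_seeds = (
        np.random.SeedSequence([master_seed, 7]).generate_state(replicates)
        % _SEED_MOD
    )
    specs = []
    for management in MANAGEMENT_SCENARIOS:
        for climate in CLIMATES:
            for catastrophe in CATASTROPHES:
                for rep in range(replicates):
                    specs.append(
                        ScenarioSpec(
                            management=management,
                            climate=climate,
                            catastrophe=catastrophe,
                            replicate=rep,
                            seed=int(rep_seeds[rep]),
                        )
                    )
    return specs


@dataclass(frozen=True)
class ExperimentConfig:
    """Problem sizes and shared physical settings of one experiment."""

    n_rows: int = 200
    n_cols: int = 250
    n_ecoregions: int = 4
    stand_mean_size: float = 25.0
    protected_fraction: float = 0.09
    horizon: float = 200.0
    event_time: float = 100.0
    harvest_fraction: float = 0.03  # of initial unprotected biomass, per step
    n_species: int = 17
    n_groups: int = 5
    succession: SuccessionConfig = field(default_factory=SuccessionConfig)


@dataclass
class SimulationInputs:
    """Inputs generated once per master seed and shared across the grid."""

    config: ExperimentConfig
    pool: SpeciesPool  # includes the two planted hybrids
    landscape: Landscape  # un-zoned base landscape
    growth: GrowthTables
    grouping: FunctionalGrouping
    initial_community: Community
    zoned: dict[str, Landscape]  # per management scenario
    zoning_reports: dict[str, dict]
    biomass_target: float  # Mg per 10-y step, common to all scenarios
    fire_regimes: FireRegimeSet
    sbw_regime: SBWRegime


def prepare_inputs(
    config: ExperimentConfig = ExperimentConfig(), master_seed: int = 0
) -> SimulationInputs:
    """Generate all shared synthetic inputs for one master seed."""
    sub = np.random.SeedSequence([master_seed, 11]).generate_state(4) % _SEED_MOD
    pool = generate_species_pool(
        config.n_species, config.n_groups, rng_seed=int(sub[0])
    )
    landscape = generate_landscape(
        config.n_rows,
        config.n_cols,
        config.n_ecoregions,
        config.stand_mean_size,
        config.protected_fraction,
        rng_seed=int(sub[1]),
    )
    growth = generate_growth_tables(
        pool, config.n_ecoregions, rng_seed=int(sub[2])
    )

    # functional groups from the base species; hybrids inherit their parent's
    grouping_base = cluster_functional_groups(pool.trait_frame(), config.n_groups)

    # the two intensive-plantation hybrids (poplar- and larch-analogue)
    angio = next(
        (s.species_id for s in pool if s.species_id == "trembling_aspen"),
        next(s.species_id for s in pool if s.clade == "angiosperm"),
    )
    gymno = next(
        (s.species_id for s in pool if s.species_id == "tamarack"),
        next(s.species_id for s in pool if s.clade == "gymnosperm"),
    )
    pool, growth = add_hybrid(pool, growth, angio, "hybrid_poplar")
    pool, growth = add_hybrid(pool, growth, gymno, "hybrid_larch")
    mapping = dict(grouping_base.mapping)
    mapping["hybrid_poplar"] = mapping[angio]
    mapping["hybrid_larch"] = mapping[gymno]
    grouping = FunctionalGrouping(mapping=mapping, n_groups=grouping_base.n_groups)

    community = generate_initial_communities(
        landscape, pool, growth, rng_seed=int(sub[3])
    )

    zoned: dict[str, Landscape] = {}
    reports: dict[str, dict] = {}
    for management in MANAGEMENT_SCENARIOS:
        if management in ("TRIAD+", "TRIAD"):
            ls, rep = allocate_zones(landscape, growth)
        else:  # BAU: protected areas only, no intensive zone
            ls, rep = allocate_zones(
                landscape,
                growth,
                intensive_frac=0.0,
                conservation_frac=config.protected_fraction,
            )
        zoned[management] = ls
        reports[management] = rep

    # equal harvest target for the four strategies: a fraction of the
    # initial biomass outside the (shared) initial protected network
    unprotected = landscape.active_flat & ~landscape.protected.ravel()
    initial_mg = float(community.total_per_cell()[unprotected].sum() * 0.01)
    target = config.harvest_fraction * initial_mg

    return SimulationInputs(
        config=config,
        pool=pool,
        landscape=landscape,
        growth=growth,
        grouping=grouping,
        initial_community=community,
        zoned=zoned,
        zoning_reports=reports,
        biomass_target=target,
        fire_regimes=default_fire_regimes(),
        sbw_regime=default_sbw_regime(),
    )


@dataclass
class RunResult:
    """Outputs of one simulated scenario."""

    spec: ScenarioSpec
    series: RunSeries
    summary: ResilienceSummary
    variables: pd.DataFrame  # long (time, variable, value)
    harvest: pd.DataFrame  # ledger rows
    removed_per_step: pd.DataFrame  # (year, removed_Mg)


def run_scenario(spec: ScenarioSpec, inputs: SimulationInputs) -> RunResult:
    """Simulate one scenario to the horizon and summarise it."""
    cfg = inputs.config
    pool = inputs.pool
    ls = inputs.zoned[spec.management]
    growth = inputs.growth
    grouping = inputs.grouping
    rng = np.random.default_rng(spec.seed)
    comm = inputs.initial_community.copy()
    state = HarvestState()
    scfg = cfg.succession
    serotinous = pool.flags("is_serotinous")

    times = [0.0]
    summ = landscape_summaries(ls, comm, grouping, pool)
    b_l = [summ.B_L]
    fd = [summ.FD_mean]
    b_fg = [summ.B_FG]
    ledger_rows: list[dict] = []
    removed_steps: list[dict] = []
    summ_pre_event: LandscapeSummary | None = None

    n_steps = int(round(cfg.horizon / scfg.timestep))
    try:
        for k in range(1, n_steps + 1):
            year = k * scfg.timestep
            comm = step_growth(comm, ls, growth, spec.climate, year, scfg)
            comm = step_mortality_and_aging(comm, pool, scfg)

            pre_fire_presence = comm.presence()
            comm, burned = background_fire_step(
                ls, comm, inputs.fire_regimes, spec.climate, year, rng,
                timestep=scfg.timestep,
            )
            sero_sources = (
                pre_fire_presence & burned[:, None] & serotinous[None, :]
            )
            comm = sbw_outbreak_step(ls, comm, pool, inputs.sbw_regime, year)

            comm, removed, rows = schedule_harvest(
                ls, comm, pool, growth, grouping, spec.management,
                inputs.biomass_target, year, spec.climate, state, rng,
                initial_cohort_biomass=scfg.initial_cohort_biomass,
            )
            ledger_rows.extend(rows)
            removed_steps.append(
                dict(year=year, removed_Mg=sum(removed.values()))
            )

            suppress_serotiny = False
            if year == cfg.event_time and spec.catastrophe != "none":
                if summ_pre_event is None:
                    raise RuntimeError("pre-event summaries missing")
                if spec.catastrophe == "fire":
                    refugia = generate_refugia(ls, rng=rng)
                    comm = apply_large_fire(
                        ls, comm, refugia, summ_pre_event.stand_cwm_fire,
                        pool.array("fire_tolerance"),
                    )
                    suppress_serotiny = True
                elif spec.catastrophe == "drought":
                    comm = apply_drought(
                        ls, comm, summ_pre_event.stand_fd_values,
                        pool.array("drought_tolerance"),
                    )
                elif spec.catastrophe == "mpb":
                    comm = apply_mpb(
                        ls, comm, summ_pre_event.stand_host_pct,
                        pool.flags("mpb_host"),
                    )

            comm = step_establishment(
                ls, comm, pool, growth, spec.climate, year, rng, scfg,
                serotiny_sources=None if suppress_serotiny else sero_sources,
            )

            summ = landscape_summaries(ls, comm, grouping, pool)
            times.append(year)
            b_l.append(summ.B_L)
            fd.append(summ.FD_mean)
            b_fg.append(summ.B_FG)
            if year == cfg.event_time - scfg.timestep:
                summ_pre_event = summ
    except Exception as exc:
        raise RuntimeError(f"scenario {spec.label} failed: {exc}") from exc

    series = RunSeries(
        times=np.asarray(times),
        B_L=np.asarray(b_l),
        FD_mean=np.asarray(fd),
        B_FG=np.vstack(b_fg),
    )
    summary, variables = summarize_run(series, event_time=cfg.event_time)
    for df in (variables,):
        df.insert(0, "management", spec.management)
        df.insert(1, "climate", spec.climate)
        df.insert(2, "catastrophe", spec.catastrophe)
        df.insert(3, "replicate", spec.replicate)
    return RunResult(
        spec=spec,
        series=series,
        summary=summary,
        variables=variables,
        harvest=ledger_frame(ledger_rows),
        removed_per_step=pd.DataFrame(removed_steps),
    )


def run_grid(
    specs: list[ScenarioSpec],
    inputs: SimulationInputs,
    progress: bool = False,
) -> list[RunResult]:
    results = []
    for i, spec in enumerate(specs):
        if progress:
            print(f"[{i + 1}/{len(specs)}] {spec.label}", flush=True)
        results.append(run_scenario(spec, inputs))
    return results


def metrics_frame(results: list[RunResult]) -> pd.DataFrame:
    """One row per run with the three resilience metrics."""
    return pd.DataFrame(
        [
            dict(
                management=r.spec.management,
                climate=r.spec.climate,
                catastrophe=r.spec.catastrophe,
                replicate=r.spec.replicate,
                seed=r.spec.seed,
                R=r.summary.R,
                NC=r.summary.NC,
                RR=r.summary.RR,
            )
            for r in results
        ]
    )


def aggregate(results: list[RunResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scenario means across replicates.

    Returns (variables, metrics): per-scenario mean/std/count of every
    output variable at every time, and of the resilience metrics.  Missing
    replicates simply lower the recorded count.
    """
    if not results:
        raise ValueError("no results to aggregate")
    keys = ["management", "climate", "catastrophe"]
    var = pd.concat([r.variables for r in results], ignore_index=True)
    var_agg = (
        var.groupby(keys + ["time", "variable"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    met = metrics_frame(results)
    met_long = met.melt(
        id_vars=keys + ["replicate"],
        value_vars=["R", "NC", "RR"],
        var_name="metric",
    )
    met_agg = (
        met_long.groupby(keys + ["metric"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return var_agg, met_agg
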