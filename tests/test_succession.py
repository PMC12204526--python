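"""Succession steps: growth ceiling, aging/longevity, establishment gates."""

import numpy as np
import pytest

from triadscape.communities import Community, generate_initial_communities
from triadscape.succession import (
    SuccessionConfig,
    cell_capacity,
    step_establishment,
    step_growth,
    step_mortality_and_aging,
)


def _empty_like(landscape, pool):
    return Community(
        np.zeros((landscape.n_cells, len(pool), pool.n_age_classes)), pool.ids
    )


class TestGrowth:
    def test_cohort_at_ceiling_stops(self, small_landscape, pool, growth):
        comm = _empty_like(small_landscape, pool)
        _, _, maxb = growth.lookup("baseline", 10)
        eco = small_landscape.ecoregion_id.ravel()
        comm.biomass[0, 0, 5] = maxb[0, eco[0]]
        out = step_growth(comm, small_landscape, growth, "baseline", 10)
        assert out.biomass[0, 0, 5] == pytest.approx(maxb[0, eco[0]])

    def test_empty_cell_unchanged(self, small_landscape, pool, growth):
        comm = _empty_like(small_landscape, pool)
        out = step_growth(comm, small_landscape, growth, "baseline", 10)
        assert not out.biomass.any()

    def test_single_cohort_gain_matches_rule(self, small_landscape, pool, growth):
        """gain = timestep * max_ANPP * (1 - crowding) for an uncrowded cohort."""
        comm = _empty_like(small_landscape, pool)
        comm.biomass[0, 3, 4] = 500.0
        _, anpp, maxb = growth.lookup("baseline", 10)
        eco = small_landscape.ecoregion_id.ravel()
        cap = cell_capacity(small_landscape, maxb)[0]
        expected = 500.0 + 10.0 * anpp[3, eco[0]] * (1.0 - 500.0 / cap)
        out = step_growth(comm, small_landscape, growth, "baseline", 10)
        assert out.biomass[0, 3, 4] == pytest.approx(expected)

    def test_growth_never_pushes_cell_past_capacity(
        self, small_landscape, pool, growth
    ):
        """Crowded cells cannot grow past the site capacity (cells already
        above it, e.g. after planting, gain nothing)."""
        rngc = np.random.default_rng(5)
        comm = _empty_like(small_landscape, pool)
        comm.biomass[:, :, 4] = rngc.uniform(0, 2000, comm.biomass[:, :, 4].shape)
        _, _, maxb = growth.lookup("baseline", 10)
        cap = cell_capacity(small_landscape, maxb)
        out = step_growth(comm, small_landscape, growth, "baseline", 10)
        ceiling = np.maximum(cap, comm.total_per_cell())
        assert (out.total_per_cell() <= ceiling * (1 + 1e-9)).all()

    def test_no_cohort_exceeds_species_ceiling(self, small_landscape, pool, growth):
        comm = generate_initial_communities(small_landscape, pool, growth, rng_seed=4)
        out = comm
        for year in (10, 20, 30):
            out = step_growth(out, small_landscape, growth, "baseline", year)
        _, _, maxb = growth.lookup("baseline", 30)
        eco = small_landscape.ecoregion_id.ravel()
        cells, sp, cls = np.nonzero(out.biomass)
        assert (out.biomass[cells, sp, cls] <= maxb[sp, eco[cells]] + 1e-9).all()


class TestMortalityAging:
    def test_ages_advance_one_class(self, small_landscape, pool):
        comm = _empty_like(small_landscape, pool)
        comm.biomass[0, 0, 3] = 100.0
        out = step_mortality_and_aging(comm, pool, SuccessionConfig(background_mortality=0.0))
        assert out.biomass[0, 0, 3] == 0.0
        assert out.biomass[0, 0, 4] == pytest.approx(100.0)

    def test_longevity_death(self, small_landscape, pool):
        """A cohort at its longevity dies the next step; one class younger
        survives it."""
        s = 0
        # oldest class whose nominal age (10k+5) is still within longevity
        last = int((pool[s].longevity - 5) // 10)
        comm = _empty_like(small_landscape, pool)
        comm.biomass[0, s, last] = 100.0
        comm.biomass[1, s, last - 1] = 100.0
        cfg = SuccessionConfig(background_mortality=0.0)
        out = step_mortality_and_aging(comm, pool, cfg)
        assert out.biomass[0, s].sum() == 0.0
        assert out.biomass[1, s].sum() == pytest.approx(100.0)

    def test_hybrid_dies_at_half_longevity(self, pool, small_landscape):
        from triadscape.species import make_hybrid
        from triadscape.species import SpeciesPool

        base = pool[pool.index("tamarack")]
        hyb = make_hybrid(base)
        hpool = SpeciesPool([hyb])
        comm = Community(
            np.zeros((small_landscape.n_cells, 1, pool.n_age_classes)), [hyb.species_id]
        )
        k = int((base.longevity / 2) // 10)  # first class past hybrid longevity
        comm.biomass[0, 0, k - 1] = 50.0
        cfg = SuccessionConfig(background_mortality=0.0)
        out = step_mortality_and_aging(comm, hpool, cfg)
        assert out.biomass.sum() == 0.0  # would have survived at full longevity

    def test_zero_background_mortality_conserves_biomass(self, small_landscape, pool):
        comm = _empty_like(small_landscape, pool)
        comm.biomass[0, 0, 3] = 100.0
        comm.biomass[1, 2, 7] = 55.0
        cfg = SuccessionConfig(background_mortality=0.0)
        out = step_mortality_and_aging(comm, pool, cfg)
        assert out.biomass.sum() == pytest.approx(comm.biomass.sum())

    def test_background_mortality_fraction(self, small_landscape, pool):
        comm = _empty_like(small_landscape, pool)
        comm.biomass[0, 0, 3] = 100.0
        out = step_mortality_and_aging(comm, pool, SuccessionConfig(background_mortality=0.1))
        assert out.biomass[0, 0, 4] == pytest.approx(90.0)


class TestEstablishment:
    def test_no_source_no_recruitment(self, small_landscape, pool, growth, rng):
        comm = _empty_like(small_landscape, pool)
        out = step_establishment(
            small_landscape, comm, pool, growth, "baseline", 10, rng
        )
        assert not out.biomass.any()

    def test_dispersal_limit(self, small_landscape, pool, growth, rng):
        """A species present at one corner cannot recruit beyond its radius."""
        comm = _empty_like(small_landscape, pool)
        comm.biomass[0, 0, 5] = 1000.0  # top-left corner cell
        cfg = SuccessionConfig(dispersal_radius=2)
        out = step_establishment(
            small_landscape, comm, pool, growth, "baseline", 10, rng, cfg
        )
        n_cols = small_landscape.shape[1]
        recruited = np.flatnonzero(out.biomass[:, 0, 0])
        for cell in recruited:
            r, c = divmod(cell, n_cols)
            assert r <= 2 and c <= 2

    def test_probability_one_recruits_everywhere_open(
        self, small_landscape, pool, growth, rng
    ):
        """With establishment probability forced to 1 and open ground, every
        reachable cell recruits (Monte-Carlo across the neighbourhood)."""
        import dataclasses

        comm = _empty_like(small_landscape, pool)
        comm.biomass[0, 0, 5] = 1000.0
        g2 = dataclasses.replace(
            growth, establishment_prob=np.ones_like(growth.establishment_prob)
        )
        out = step_establishment(
            small_landscape, comm, pool, growth=g2, climate="baseline",
            year=10, rng=rng,
        )
        n_cols = small_landscape.shape[1]
        reachable = [
            r * n_cols + c for r in range(3) for c in range(3)
        ]
        assert all(out.biomass[cell, 0, 0] > 0 for cell in reachable if cell != 0)

    def test_probability_zero_blocks_recruitment(
        self, small_landscape, pool, growth, rng
    ):
        import dataclasses

        comm = _empty_like(small_landscape, pool)
        comm.biomass[0, 0, 5] = 1000.0
        g0 = dataclasses.replace(
            growth, establishment_prob=np.zeros_like(growth.establishment_prob)
        )
        out = step_establishment(
            small_landscape, comm, pool, growth=g0, climate="baseline",
            year=10, rng=rng,
        )
        assert not out.biomass[:, :, 0].any()

    def test_shade_gate_blocks_intolerant_species(
        self, small_landscape, pool, growth, rng
    ):
        """On a crowded cell only shade-tolerant species may recruit."""
        import dataclasses

        intolerant = min(range(len(pool)), key=lambda i: pool[i].shade_tolerance)
        assert pool[intolerant].shade_tolerance < 2.0
        comm = _empty_like(small_landscape, pool)
        _, _, maxb = growth.lookup("baseline", 10)
        cap = cell_capacity(small_landscape, maxb)
        # saturate a block of cells with a tolerant species, seed the intolerant one
        comm.biomass[:, intolerant, 5] = cap * 0.99 / 1.0
        g1 = dataclasses.replace(
            growth, establishment_prob=np.ones_like(growth.establishment_prob)
        )
        out = step_establishment(
            small_landscape, comm, pool, growth=g1, climate="baseline",
            year=10, rng=rng,
        )
        assert not out.biomass[:, intolerant, 0].any()

    def test_seeded_determinism(self, small_landscape, pool, growth):
        comm = _empty_like(small_landscape, pool)
        comm.biomass[50, 4, 5] = 800.0
        outs = [
            step_establishment(
                small_landscape, comm, pool, growth, "baseline", 10,
                np.random.default_rng(77),
            )
            for _ in range(2)
        ]
        assert np.array_equal(outs[0].biomass, outs[1].biomass)


class TestUndisturbedTrend:
    def test_biomass_non_decreasing_before_longevity_deaths(
        self, small_landscape, pool, growth, rng
    ):
        """With disturbances off, zero background mortality and baseline
        climate, total biomass rises until cohorts start dying of age."""
        comm = generate_initial_communities(small_landscape, pool, growth, rng_seed=4)
        cfg = SuccessionConfig(background_mortality=0.0)
        prev = comm.biomass.sum()
        out = comm
        for year in (10, 20, 30):
            out = step_growth(out, small_landscape, growth, "baseline", year, cfg)
            out = step_establishment(
                small_landscape, out, pool, growth, "baseline", year, rng, cfg
            )
            cur = out.biomass.sum()
            assert cur >= prev
            prev = cur
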