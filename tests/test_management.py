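"""Zoning, prescriptions, planting selection, harvest scheduling."""

import numpy as np
import pytest

from triadscape.communities import Community, generate_initial_communities
from triadscape.functional import FunctionalGrouping
from triadscape.growth import generate_growth_tables
from triadscape.landscape import (
    ZONE_CONSERVATION,
    ZONE_EXTENSIVE,
    ZONE_INTENSIVE,
    generate_landscape,
)
from triadscape.management import (
    SCENARIOS,
    HarvestState,
    add_hybrid,
    allocate_zones,
    apply_prescription,
    removal_fraction,
    schedule_harvest,
    select_planting_species,
)


def _grouping(pool):
    return FunctionalGrouping(
        mapping={s.species_id: s.true_group for s in pool}, n_groups=5
    )


# ------------------------------------------------------------------- zoning

class TestZoning:
    def test_triad_fractions(self, pool):
        ls = generate_landscape(100, 100, protected_fraction=0.09, rng_seed=5)
        growth = generate_growth_tables(pool, 4, rng_seed=2)
        zoned, rep = allocate_zones(ls, growth)
        assert rep["conservation_frac"] == pytest.approx(0.24, abs=0.01)
        assert rep["intensive_frac"] == pytest.approx(0.16, abs=0.01)
        assert rep["extensive_frac"] == pytest.approx(0.60, abs=0.02)
        # zones partition the active area
        zone = zoned.zone[zoned.active]
        assert (zone > 0).all()

    def test_protected_core_kept_in_conservation(self, pool, growth):
        ls = generate_landscape(100, 100, protected_fraction=0.09, rng_seed=5)
        zoned, _ = allocate_zones(ls, growth)
        assert (zoned.zone[ls.protected] == ZONE_CONSERVATION).all()

    def test_bau_style_zoning_without_intensive(self, small_landscape, growth):
        zoned, rep = allocate_zones(
            small_landscape, growth, intensive_frac=0.0, conservation_frac=0.09
        )
        assert rep["intensive_frac"] == 0.0
        assert set(np.unique(zoned.zone[zoned.active])) == {
            ZONE_EXTENSIVE, ZONE_CONSERVATION,
        }

    def test_intensive_more_productive_than_extensive(self, pool, growth):
        """The allocator puts the intensive zone on the best sites."""
        ls = generate_landscape(100, 100, protected_fraction=0.09, rng_seed=5)
        zoned, _ = allocate_zones(ls, growth)
        _, anpp0, _ = growth.lookup("baseline", 0)
        pot = anpp0.max(axis=0)[zoned.ecoregion_id.ravel()]
        sq = np.ones(zoned.n_cells)
        sid = zoned.stand_id.ravel()
        sq[sid >= 0] = zoned.site_quality[sid[sid >= 0]]
        index = pot * sq
        zone = zoned.zone.ravel()
        assert index[zone == ZONE_INTENSIVE].mean() > index[zone == ZONE_EXTENSIVE].mean()

    def test_determinism(self, small_landscape, growth):
        a, _ = allocate_zones(small_landscape, growth)
        b, _ = allocate_zones(small_landscape, growth)
        assert np.array_equal(a.zone, b.zone)


# ------------------------------------------------------------ hybridisation

class TestHybridGrowth:
    def test_growth_transform(self, pool, growth):
        """ANPP x2, max biomass x1.15, establishment copied."""
        p2, g2 = add_hybrid(pool, growth, "trembling_aspen", "hybrid_poplar")
        si = pool.index("trembling_aspen")
        hi = p2.index("hybrid_poplar")
        assert np.allclose(g2.max_anpp[:, :, hi], growth.max_anpp[:, :, si] * 2)
        assert np.allclose(g2.max_biomass[:, :, hi], growth.max_biomass[:, :, si] * 1.15)
        assert np.allclose(
            g2.establishment_prob[:, :, hi], growth.establishment_prob[:, :, si]
        )
        assert p2[hi].longevity == pool[si].longevity / 2

    def test_worked_numbers(self):
        """(ANPP 500, maxB 10000, longevity 150) -> (1000, 11500, 75)."""
        from triadscape.species import generate_species_pool
        import dataclasses

        pool = generate_species_pool(17, 5, rng_seed=0)
        base = dataclasses.replace(pool[pool.index("tamarack")], longevity=150.0)
        pool.species[pool.index("tamarack")] = base
        growth = generate_growth_tables(pool, 1, rng_seed=0)
        si = pool.index("tamarack")
        growth.max_anpp[:, :, si, :] = 500.0
        growth.max_biomass[:, :, si, :] = 10000.0
        p2, g2 = add_hybrid(pool, growth, "tamarack", "hybrid_larch")
        hi = p2.index("hybrid_larch")
        assert np.allclose(g2.max_anpp[:, :, hi], 1000.0)
        assert np.allclose(g2.max_biomass[:, :, hi], 11500.0)
        assert p2[hi].longevity == 75.0


# ------------------------------------------------------------- prescriptions

class TestPrescriptions:
    def test_selection_cut_age_filter(self):
        """SC removes 30% of cohorts aged >= 30 and spares younger ones."""
        ages = np.array([20.0, 40.0, 80.0])
        frac = removal_fraction("SC", ages)
        removed = frac * 100.0
        assert removed == pytest.approx([0.0, 30.0, 30.0])

    def test_clearcut_spares_regeneration(self):
        assert removal_fraction("CC-NoPlant", np.array([5.0]))[0] == 0.0
        assert removal_fraction("CC-NoPlant", np.array([15.0]))[0] == 0.9

    def test_intensive_clearcut_total(self):
        assert (removal_fraction("CC-PlantIntens", np.array([5.0, 95.0])) == 1.0).all()

    @pytest.mark.parametrize(
        "age,frac",
        [(25.0, 0.80), (35.0, 0.66), (45.0, 0.66), (75.0, 0.60), (95.0, 0.40),
         (105.0, 0.05), (155.0, 0.05)],
    )
    def test_commercial_thinning_schedule(self, age, frac):
        assert removal_fraction("CT", np.array([age]))[0] == pytest.approx(frac)

    def test_thinning_declines_with_age(self):
        ages = np.arange(5.0, 200.0, 10.0)
        frac = removal_fraction("CT", ages)
        assert (np.diff(frac) <= 0).all()

    def test_unknown_prescription_rejected(self):
        with pytest.raises(ValueError):
            removal_fraction("CC-Bogus", np.array([10.0]))

    def test_apply_prescription_removed_amount(self, pool):
        b = np.zeros((3, len(pool), pool.n_age_classes))
        b[0, 0, 3] = 100.0  # age 35: CT bin 66%
        comm = Community(b, pool.ids)
        out, removed = apply_prescription(comm, np.array([0]), "CT")
        assert removed == pytest.approx(66.0 * 0.01)
        assert out.biomass[0, 0, 3] == pytest.approx(34.0)
        assert comm.biomass[0, 0, 3] == 100.0  # input untouched


# ------------------------------------------------------------------ planting

class TestPlantingSelection:
    def _setup(self, pool):
        labels = np.asarray([s.true_group for s in pool])
        estab = np.linspace(0.2, 0.6, len(pool))
        return labels, estab

    def test_missing_groups_each_get_one_species(self, pool, rng):
        labels, estab = self._setup(pool)
        b = np.zeros(len(pool))
        for g in (1, 2, 3):  # groups 4 and 5 absent
            b[np.flatnonzero(labels == g)[0]] = 100.0
        chosen = select_planting_species(b, labels, estab, "functional", rng)
        assert len(chosen) == 2
        assert sorted(labels[chosen]) == [4, 5]

    def test_all_present_plants_rarest_group(self, pool, rng):
        labels, estab = self._setup(pool)
        b = np.zeros(len(pool))
        for g in range(1, 6):
            b[np.flatnonzero(labels == g)[0]] = 100.0 * g  # group 1 rarest
        chosen = select_planting_species(b, labels, estab, "functional", rng)
        assert len(chosen) == 1
        assert labels[chosen[0]] == 1

    def test_tie_break_uniform(self, pool):
        """Equal establishment probabilities split ~50/50 over seeded draws."""
        labels = np.asarray([s.true_group for s in pool])
        estab = np.full(len(pool), 0.4)  # all tied
        b = np.zeros(len(pool))
        for g in (1, 2, 3, 4):
            b[np.flatnonzero(labels == g)[0]] = 100.0
        members = np.flatnonzero(labels == 5)
        counts = {int(i): 0 for i in members}
        for seed in range(200):
            r = np.random.default_rng(seed)
            (c,) = select_planting_species(b, labels, estab, "functional", r)
            counts[c] += 1
        freqs = np.array(list(counts.values())) / 200
        assert freqs.max() - freqs.min() < 0.25  # roughly uniform over the group

    def test_normal_mode_plants_dominant(self, pool, rng):
        labels, estab = self._setup(pool)
        b = np.zeros(len(pool))
        b[7] = 500.0
        b[2] = 100.0
        assert select_planting_species(b, labels, estab, "normal", rng) == [7]

    def test_intensive_mode_uses_pair(self, pool, rng):
        labels, estab = self._setup(pool)
        chosen = select_planting_species(
            np.zeros(len(pool)), labels, estab, "intensive", rng, intensive_pair=(3, 9)
        )
        assert chosen == [3, 9]


# ---------------------------------------------------------------- scheduling

class TestScheduling:
    def test_zero_target_touches_nothing(self, inputs):
        ls = inputs.zoned["TRIAD+"]
        comm = inputs.initial_community
        out, removed, rows = schedule_harvest(
            ls, comm, inputs.pool, inputs.growth, inputs.grouping, "TRIAD+",
            0.0, 10.0, "baseline", HarvestState(), np.random.default_rng(0),
        )
        assert np.array_equal(out.biomass, comm.biomass)
        assert sum(removed.values()) == 0.0

    def test_shares_met_at_full_availability(self, inputs):
        """Each TRIAD+ prescription removes its Table-2 share of the target
        (within one partial cell of overshoot)."""
        ls = inputs.zoned["TRIAD+"]
        target = inputs.biomass_target
        out, removed, rows = schedule_harvest(
            ls, inputs.initial_community, inputs.pool, inputs.growth,
            inputs.grouping, "TRIAD+", target, 10.0, "baseline",
            HarvestState(), np.random.default_rng(0),
        )
        shares = {p: s for p, s, _ in SCENARIOS["TRIAD+"]}
        assert shares == {
            "CC-PlantIntens": 25.0, "CC-PlantFunct": 37.5, "SC": 12.5, "CT": 25.0,
        }
        max_cell = 300.0  # generous bound on one cell's removable biomass, Mg
        for p, share in shares.items():
            assert removed[p] >= share / 100 * target - 1e-6
            assert removed[p] <= share / 100 * target + max_cell

    def test_no_harvest_in_conservation(self, inputs):
        """Zone exclusivity: conservation cells are never cut, any scenario."""
        for mgmt in SCENARIOS:
            ls = inputs.zoned[mgmt]
            comm = inputs.initial_community
            out, _, _ = schedule_harvest(
                ls, comm, inputs.pool, inputs.growth, inputs.grouping, mgmt,
                inputs.biomass_target, 10.0, "baseline", HarvestState(),
                np.random.default_rng(0),
            )
            cons = ls.zone.ravel() == ZONE_CONSERVATION
            assert np.array_equal(out.biomass[cons], comm.biomass[cons])

    def test_equal_target_across_scenarios(self, inputs):
        """All four strategies remove (nearly) the same biomass from the same
        initial state; differences stay within the partial-cell overshoot."""
        totals = {}
        for mgmt in SCENARIOS:
            _, removed, rows = schedule_harvest(
                inputs.zoned[mgmt], inputs.initial_community, inputs.pool,
                inputs.growth, inputs.grouping, mgmt, inputs.biomass_target,
                10.0, "baseline", HarvestState(), np.random.default_rng(0),
            )
            shortfall = sum(
                r["removed_Mg"] for r in rows if r["event"] == "shortfall"
            )
            totals[mgmt] = sum(removed.values()) + shortfall
        vals = list(totals.values())
        assert max(vals) - min(vals) < 4 * 300.0  # four partial-cell overshoots

    def test_plantfunct_targets_low_diversity_stands(self, inputs):
        """CC-PlantFunct consumes stands of below-average FD."""
        from triadscape.functional import landscape_summaries

        ls = inputs.zoned["BAU-PlantFunct"]
        summ = landscape_summaries(ls, inputs.initial_community, inputs.grouping, inputs.pool)
        _, _, rows = schedule_harvest(
            ls, inputs.initial_community, inputs.pool, inputs.growth,
            inputs.grouping, "BAU-PlantFunct", inputs.biomass_target, 10.0,
            "baseline", HarvestState(), np.random.default_rng(0),
        )
        stands = [
            r["stand"] for r in rows
            if r["prescription"] == "CC-PlantFunct" and r["event"] == "harvest"
        ]
        assert stands
        chosen_fd = np.nanmean(summ.stand_fd_values[stands])
        assert chosen_fd <= np.nanmean(summ.stand_fd_values)

    def test_plantfunct_never_reduces_group_count(self, inputs):
        """Functional planting after the cut keeps or raises the number of
        functional groups present in every treated stand."""
        ls = inputs.zoned["TRIAD+"]
        comm = inputs.initial_community
        labels = inputs.grouping.labels(comm.species_ids)
        out, _, rows = schedule_harvest(
            ls, comm, inputs.pool, inputs.growth, inputs.grouping, "TRIAD+",
            inputs.biomass_target, 10.0, "baseline", HarvestState(),
            np.random.default_rng(0),
        )
        treated = [
            r["stand"] for r in rows
            if r["prescription"] == "CC-PlantFunct" and r["event"] == "harvest"
        ]
        assert treated
        for stand in treated:
            cells = ls.stand_cells(stand)

            def groups_present(community):
                sp = community.biomass[cells].sum(axis=(0, 2))
                return set(labels[sp > 0])
            assert groups_present(comm) <= groups_present(out)

    def test_sc_revisits_and_release(self, inputs):
        """SC stands are revisited at +30/+60 y and released after 90."""
        ls = inputs.zoned["TRIAD+"]
        state = HarvestState()
        _, _, rows = schedule_harvest(
            ls, inputs.initial_community, inputs.pool, inputs.growth,
            inputs.grouping, "TRIAD+", inputs.biomass_target, 10.0, "baseline",
            state, np.random.default_rng(0),
        )
        sc_stands = {
            r["stand"] for r in rows
            if r["prescription"] == "SC" and r["event"] == "harvest"
        }
        assert sc_stands
        due = {(y, s) for y, s, p, _ in state.revisits if p == "SC"}
        for s in sc_stands:
            assert (40.0, s) in due and (70.0, s) in due
            assert state.locked_until[s] == 100.0

    def test_unknown_scenario_rejected(self, inputs):
        with pytest.raises(ValueError):
            schedule_harvest(
                inputs.zoned["TRIAD+"], inputs.initial_community, inputs.pool,
                inputs.growth, inputs.grouping, "TRIAD++", 1.0, 10.0,
                "baseline", HarvestState(), np.random.default_rng(0),
            )
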