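"""Lattice metapopulation: layouts, dispersal, the three-step update,
replenishment, summaries, and agreement between the vectorised lattice
engine and the scalar per-deme reference operations."""

import numpy as np
import pytest

from plastipop import (
    NONPLASTIC,
    PLASTIC,
    STAGE_INDEX,
    LayoutSpec,
    ReplenishmentSchedule,
    ResourceState,
    SeedEntry,
    SeedingSpec,
    apply_predation,
    disperse_dauers,
    initialize_lattice,
    replenish,
    step_deme,
    step_metapopulation,
    summarize,
    von_neumann_neighbors,
)

D = STAGE_INDEX["D"]


class TestInitialize:
    def test_default_competition_setup(self):
        lat = initialize_lattice(20, LayoutSpec(diet=ResourceState.OP50, r0=500.0), SeedingSpec())
        assert lat.resource.shape == (20, 20)
        assert np.all(lat.resource == 500.0)
        assert lat.counts.sum() == 200.0  # 4 x 50 dauers
        for x, y, s in ((1, 1, PLASTIC), (20, 20, PLASTIC), (1, 20, NONPLASTIC), (20, 1, NONPLASTIC)):
            assert lat.counts[x - 1, y - 1, s, D] == 50.0

    def test_degenerate_quadrants(self):
        lat = initialize_lattice(2, LayoutSpec(kind="quadrants", pattern="A"), SeedingSpec())
        # each deme is its own quadrant: main diagonal OP50, anti-diagonal L76
        assert lat.diet_codes.tolist() == [[0, 1], [1, 0]]

    def test_quadrant_pattern_b_is_complement(self):
        a = LayoutSpec(kind="quadrants", pattern="A").diet_map(6)
        b = LayoutSpec(kind="quadrants", pattern="B").diet_map(6)
        assert np.array_equal(a, 1 - b)

    def test_random_layout_deterministic_per_seed(self):
        maps = [
            LayoutSpec(kind="random").diet_map(10, np.random.default_rng(99)) for _ in range(2)
        ]
        assert np.array_equal(maps[0], maps[1])

    def test_off_lattice_seed_rejected(self):
        seeding = SeedingSpec(entries=(SeedEntry(0, 3, PLASTIC, "D", 10.0),))
        with pytest.raises(ValueError, match="off"):
            initialize_lattice(5, LayoutSpec(), seeding)

    def test_randomized_seeding_draws_without_replacement(self):
        rng = np.random.default_rng(5)
        entries = SeedingSpec(randomize_locations=True).resolve(6, rng)
        locs = {(e.x, e.y) for e in entries}
        assert len(locs) == 4
        assert sum(e.strain == PLASTIC for e in entries) == 2


class TestNeighbors:
    @pytest.mark.parametrize(
        "x,y,expected_n",
        [(1, 1, 2), (20, 20, 2), (1, 5, 3), (20, 7, 3), (5, 5, 4)],
    )
    def test_counts(self, x, y, expected_n):
        nbrs = von_neumann_neighbors(x, y, 20)
        assert len(nbrs) == expected_n
        assert all(1 <= a <= 20 and 1 <= b <= 20 for a, b in nbrs)

    def test_interior_exact_set(self):
        assert set(von_neumann_neighbors(5, 5, 20)) == {(6, 5), (4, 5), (5, 6), (5, 4)}


class TestDispersal:
    def make_lattice(self, m=6, seed=0):
        rng = np.random.default_rng(seed)
        lat = initialize_lattice(m, LayoutSpec(), SeedingSpec(entries=()))
        lat.counts[:] = rng.random(lat.counts.shape) * 100
        return lat

    def test_zero_rate_identity(self):
        lat = self.make_lattice()
        out = disperse_dauers(lat, 0.0)
        np.testing.assert_array_equal(out.counts, lat.counts)

    def test_corner_exports_to_two_neighbors(self):
        lat = initialize_lattice(
            5, LayoutSpec(), SeedingSpec(entries=(SeedEntry(1, 1, PLASTIC, "D", 100.0),))
        )
        out = disperse_dauers(lat, 0.01)
        assert out.counts[0, 0, PLASTIC, D] == pytest.approx(98.0)
        assert out.counts[0, 1, PLASTIC, D] == pytest.approx(1.0)
        assert out.counts[1, 0, PLASTIC, D] == pytest.approx(1.0)

    def test_conserves_dauers_per_strain(self):
        lat = self.make_lattice(m=9, seed=3)
        before = lat.counts[:, :, :, D].sum(axis=(0, 1))
        after = disperse_dauers(lat, 0.02).counts[:, :, :, D].sum(axis=(0, 1))
        np.testing.assert_allclose(after, before, rtol=1e-13)

    def test_other_stages_untouched(self):
        lat = self.make_lattice()
        out = disperse_dauers(lat, 0.01)
        mask = np.ones(10, bool)
        mask[D] = False
        np.testing.assert_array_equal(out.counts[:, :, :, mask], lat.counts[:, :, :, mask])

    def test_excessive_rate_rejected(self):
        with pytest.raises(ValueError):
            disperse_dauers(self.make_lattice(), 0.3)

    def test_matches_neighbor_rule(self):
        # flows agree with the explicit von Neumann neighbour enumeration
        lat = self.make_lattice(m=4, seed=7)
        r = 0.01
        out = disperse_dauers(lat, r)
        for x in range(1, 5):
            for y in range(1, 5):
                nbrs = von_neumann_neighbors(x, y, 4)
                expected = lat.counts[x - 1, y - 1, :, D] * (1 - r * len(nbrs))
                for a, b in nbrs:
                    expected = expected + r * lat.counts[a - 1, b - 1, :, D]
                np.testing.assert_allclose(out.counts[x - 1, y - 1, :, D], expected, rtol=1e-12)


class TestStepMetapopulation:
    def test_empty_lattice_stays_empty(self, strains, global_params):
        lat = initialize_lattice(4, LayoutSpec(), SeedingSpec(entries=()))
        out = step_metapopulation(lat, strains, global_params)
        assert not out.counts.any()
        assert out.t == 1

    def test_matches_scalar_reference_ops(self, strains, global_params):
        # the vectorised engine computes the same update as per-deme
        # step_deme + apply_predation + dispersal
        rng = np.random.default_rng(11)
        lat = initialize_lattice(5, LayoutSpec(kind="random"), SeedingSpec(entries=()), rng)
        lat.counts[:] = rng.random(lat.counts.shape) * 2000
        lat.resource[:] = rng.random((5, 5)) * 10  # mixes fed and starved demes

        fast = step_metapopulation(lat, strains, global_params)

        ref = lat.copy()
        for x in range(1, 6):
            for y in range(1, 6):
                d = ref.deme(x, y)
                d = step_deme(d, strains, global_params)
                d = apply_predation(d, strains, global_params)
                ref.set_deme(x, y, d)
        ref = disperse_dauers(ref, global_params.dispersal)
        np.testing.assert_allclose(fast.counts, ref.counts, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(fast.resource, ref.resource, rtol=1e-12)

    def test_deterministic_reruns_bit_identical(self, strains, global_params):
        lat = initialize_lattice(6, LayoutSpec(), SeedingSpec())
        outs = []
        for _ in range(2):
            cur = lat.copy()
            for _ in range(30):
                cur = step_metapopulation(cur, strains, global_params)
            outs.append(cur)
        assert np.array_equal(outs[0].counts, outs[1].counts)
        assert np.array_equal(outs[0].resource, outs[1].resource)

    def test_colonized_demes_increase_with_dispersal(self, strains, global_params):
        import dataclasses

        seeding = SeedingSpec(entries=(SeedEntry(1, 1, PLASTIC, "D", 50.0),))
        colonized = []
        for r in (0.0, 0.01, 0.025):
            params = dataclasses.replace(global_params, dispersal=r)
            lat = initialize_lattice(5, LayoutSpec(), seeding)
            ever = np.zeros((5, 5), bool)
            for _ in range(600):
                lat = step_metapopulation(lat, strains, params)
                ever |= lat.counts.sum(axis=(2, 3)) > 0
            colonized.append(int(ever.sum()))
        assert colonized[0] == 1
        assert colonized[0] < colonized[1] <= colonized[2]


class TestReplenish:
    def test_resets_resource_on_schedule(self):
        lat = initialize_lattice(3, LayoutSpec(r0=500.0), SeedingSpec(entries=()))
        lat.resource[:] = 1.0
        lat.t = 1000
        out = replenish(lat, ReplenishmentSchedule(1000, r0=500.0), np.random.default_rng(0))
        assert np.all(out.resource == 500.0)

    @pytest.mark.parametrize("t", [0, 999, 1001])
    def test_noop_off_schedule(self, t):
        lat = initialize_lattice(3, LayoutSpec(r0=500.0), SeedingSpec(entries=()))
        lat.resource[:] = 1.0
        lat.t = t
        out = replenish(lat, ReplenishmentSchedule(1000), np.random.default_rng(0))
        assert np.all(out.resource == 1.0)

    def test_diet_reassignment_seeded(self):
        maps = []
        for _ in range(2):
            lat = initialize_lattice(6, LayoutSpec(), SeedingSpec(entries=()))
            lat.t = 1000
            out = replenish(lat, ReplenishmentSchedule(1000, reassign_diets=True),
                            np.random.default_rng(42))
            maps.append(out.diet_codes.copy())
        assert np.array_equal(maps[0], maps[1])

    def test_reassign_flag_off_keeps_diets(self):
        lat = initialize_lattice(4, LayoutSpec(kind="quadrants"), SeedingSpec(entries=()))
        lat.t = 500
        out = replenish(lat, ReplenishmentSchedule(500, reassign_diets=False),
                        np.random.default_rng(0))
        assert np.array_equal(out.diet_codes, lat.diet_codes)


class TestSummarize:
    def test_all_plastic_dauers(self):
        lat = initialize_lattice(
            3, LayoutSpec(), SeedingSpec(entries=(SeedEntry(2, 2, PLASTIC, "D", 30.0),))
        )
        stats = summarize(lat)
        assert stats.fhat_dauer_p[1, 1] == 1.0
        assert np.isnan(stats.fhat_dauer_p[0, 0])  # no dauers -> undefined
        assert stats.fhat_dauer_p_total == 1.0

    def test_even_split(self):
        lat = initialize_lattice(
            1,
            LayoutSpec(),
            SeedingSpec(entries=(
                SeedEntry(1, 1, PLASTIC, "D", 20.0),
                SeedEntry(1, 1, NONPLASTIC, "D", 20.0),
            )),
        )
        assert summarize(lat).fhat_dauer_p_total == pytest.approx(0.5)

    def test_no_dauers_is_none_not_zero(self):
        lat = initialize_lattice(2, LayoutSpec(), SeedingSpec(entries=()))
        assert summarize(lat).fhat_dauer_p_total is None

    def test_mean_of_homogeneous_lattice(self, strains, global_params):
        lat = initialize_lattice(3, LayoutSpec(), SeedingSpec(entries=()))
        lat.counts[:] = 7.0
        stats = summarize(lat)
        np.testing.assert_allclose(stats.mean_counts, lat.counts[0, 0], rtol=1e-12)


class TestSymmetry:
    def test_strain_swap_mirrors_outcome(self, strains, global_params):
        lat = initialize_lattice(6, LayoutSpec(), SeedingSpec())
        swapped = lat.copy()
        swapped.counts = swapped.counts[:, :, ::-1].copy()
        rev = (strains[1], strains[0])
        for _ in range(400):
            lat = step_metapopulation(lat, strains, global_params)
            swapped = step_metapopulation(swapped, rev, global_params)
        np.testing.assert_allclose(lat.counts, swapped.counts[:, :, ::-1], rtol=1e-9, atol=1e-9)

    def test_identical_strains_keep_even_dauer_share(self, strains, global_params):
        # symmetric seeding + identical parameters: f_hat stays 1/2
        twins = (strains[0], strains[0])
        lat = initialize_lattice(6, LayoutSpec(), SeedingSpec())
        for _ in range(500):
            lat = step_metapopulation(lat, twins, global_params)
        fhat = summarize(lat).fhat_dauer_p_total
        assert fhat == pytest.approx(0.5, abs=1e-9)
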