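import math

import numpy as np
import pytest

from spool import SPConfig, SpatialPooler
from spool.experiments import center_block_indices
from conftest import make_single_column_sp


class TestPotentialPool:
    def test_infinite_radius_full_fraction_includes_everything(self, flat_sp):
        assert flat_sp.potential.all()

    def test_radius_five_interior_pool_is_11x11(self):
        sp = SpatialPooler(SPConfig.topological(seed=0))
        interior = 17 * 32 + 17
        assert sp.potential[interior].sum() == 121
        # clipped at the corner: only a 6x6 quadrant is available
        assert sp.potential[0].sum() == 36

    def test_partial_fraction_thins_pool_binomially(self):
        sp = SpatialPooler(SPConfig.topological(potential_fraction=0.5, seed=1))
        interior = [r * 32 + c for r in range(8, 24) for c in range(8, 24)]
        sizes = sp.potential[interior].sum(axis=1)
        assert abs(sizes.mean() - 0.5 * 121) < 3.0   # binomial mean 60.5
        assert (sizes > 0).all()

    def test_pool_fixed_and_deterministic_given_seed(self):
        mk = lambda s: SPConfig.topological(potential_fraction=0.5, seed=s)
        a, b, c = (SpatialPooler(mk(s)) for s in (42, 42, 43))
        assert np.array_equal(a.potential, b.potential)
        assert np.array_equal(a.permanences, b.permanences)
        assert not np.array_equal(a.potential, c.potential)
        assert not np.array_equal(a.permanences, c.permanences)


class TestPermanences:
    def test_zero_outside_pool(self):
        sp = SpatialPooler(SPConfig.topological(seed=2))
        assert (sp.permanences[~sp.potential] == 0).all()

    def test_half_of_potential_synapses_connected_initially(self, flat_sp):
        frac = flat_sp.connected.sum() / flat_sp.potential.sum()
        assert abs(frac - 0.5) < 0.05

    def test_uniform_distribution_over_pool(self):
        from scipy import stats
        sp = SpatialPooler(SPConfig.dimensionless(n_columns=128,
                                                  input_dims=(32, 32), seed=3))
        sample = sp.permanences[sp.potential]
        assert sample.size > 1e5
        ks = stats.kstest(sample, "uniform").statistic
        assert ks < 0.01


class TestOverlap:
    def test_all_zero_input_gives_zero_overlap(self, flat_sp):
        o = flat_sp.compute_overlap(np.zeros(flat_sp.n_inputs))
        assert (o == 0).all()

    def test_hand_dot_product(self):
        sp = make_single_column_sp([1, 0, 1, 1])
        assert sp.compute_overlap([1, 1, 1, 0])[0] == 2.0

    def test_boost_scales_overlap(self):
        sp = make_single_column_sp([1, 0, 1, 1], boost=math.e)
        o = sp.compute_overlap([1, 1, 1, 0], boosted=True)[0]
        assert o == pytest.approx(2 * math.e, abs=1e-12)
        assert sp.compute_overlap([1, 1, 1, 0], boosted=False)[0] == 2.0

    def test_dimension_mismatch_raises(self, flat_sp):
        with pytest.raises(ValueError, match="bits"):
            flat_sp.compute_overlap(np.ones(5))


class TestNeighborhood:
    def test_global_inhibition_neighbors_everyone(self, flat_sp):
        n = flat_sp.neighborhood(10)
        assert len(n) == flat_sp.n_columns - 1
        assert 10 not in n

    def test_euclidean_ball_radius_1p5_has_8_neighbors(self, grid_sp):
        grid_sp.inhibition_radius = 1.5
        grid_sp._rebuild_neighborhoods()
        centre = 6 * 12 + 6
        nbrs = set(grid_sp.neighborhood(centre))
        expected = {(6 + dr) * 12 + (6 + dc)
                    for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                    if not (dr == 0 and dc == 0)}
        assert nbrs == expected

    def test_radius_at_most_1_gives_empty_neighborhood_and_self_win(self, grid_sp):
        grid_sp.inhibition_radius = 1.0
        grid_sp._rebuild_neighborhoods()
        assert len(grid_sp.neighborhood(6 * 12 + 6)) == 0
        o = np.full(grid_sp.n_columns, 5.0)
        assert grid_sp.inhibit(o).all()


class TestInhibition:
    def test_below_stimulus_threshold_nothing_active(self, flat_sp):
        o = np.full(flat_sp.n_columns, 0.5)   # theta_stim = 1
        assert not flat_sp.inhibit(o).any()

    def test_global_topk_matches_sort_oracle(self, rng):
        cfg = SPConfig.dimensionless(n_columns=1024, input_dims=(32, 32), seed=0)
        sp = SpatialPooler(cfg)
        o = rng.permutation(np.arange(1024)).astype(float)
        active = sp.inhibit(o)
        k = int(math.floor(0.5 + 0.02 * 1024))
        expected = np.argsort(-o, kind="stable")[:k]
        assert set(np.flatnonzero(active)) == set(expected)
        assert active.sum() == 20

    def test_topk_breaks_ties_by_column_index(self):
        cfg = SPConfig.dimensionless(n_columns=64, input_dims=(64,), seed=0)
        sp = SpatialPooler(cfg)   # quota = round(0.5 + 0.02*64) = 1
        o = np.full(64, 5.0)
        active = sp.inhibit(o)
        assert np.flatnonzero(active).tolist() == [0]

    def test_counting_rule_admits_all_ties(self):
        cfg = SPConfig.dimensionless(n_columns=4, input_dims=(8,),
                                     winner_rule="count", target_density=0.5,
                                     seed=0)
        sp = SpatialPooler(cfg)
        assert sp.inhibit(np.array([5.0, 5.0, 5.0, 5.0])).sum() == 4

    def test_local_counting_rule_matches_per_column_oracle(self, grid_sp, rng):
        o = rng.random(grid_sp.n_columns) * 10
        active = grid_sp.inhibit(o)
        s = grid_sp.config.target_density
        for i in range(grid_sp.n_columns):
            nbrs = grid_sp.neighborhood(i)
            quota = max(1, int(math.floor(0.5 + s * (len(nbrs) + 1))))
            bigger = int((o[nbrs] > o[i]).sum())
            expected = (bigger < quota) and o[i] >= grid_sp.config.stimulus_threshold
            assert active[i] == expected


class TestLearning:
    def _active_sp(self):
        sp = make_single_column_sp([1, 0, 0, 0])
        sp.permanences[0] = [0.45, 0.45, 0.01, 0.6]
        sp.connected = (sp.permanences >= 0.5) & sp.potential
        sp._Wf = sp.connected.astype(float)
        return sp

    def test_no_active_columns_leaves_permanences_unchanged(self):
        sp = self._active_sp()
        before = sp.permanences.copy()
        sp.learn([1, 1, 1, 1], np.array([False]))
        assert np.array_equal(sp.permanences, before)

    def test_increment_crosses_connection_threshold(self):
        sp = self._active_sp()
        sp.learn([1, 0, 0, 0], np.array([True]))
        assert sp.permanences[0, 0] == pytest.approx(0.55)
        assert sp.connected[0, 0]          # newly connected
        assert sp.permanences[0, 1] == pytest.approx(0.43)

    def test_decrement_clips_at_zero(self):
        sp = self._active_sp()
        sp.learn([1, 0, 0, 0], np.array([True]))
        assert sp.permanences[0, 2] == 0.0

    def test_increment_clips_at_one(self):
        sp = self._active_sp()
        sp.permanences[0, 0] = 0.95
        sp.learn([1, 0, 0, 0], np.array([True]))
        assert sp.permanences[0, 0] == 1.0


class TestHomeostasis:
    def test_duty_cycle_single_activation(self, flat_sp):
        a = np.zeros(flat_sp.n_columns, dtype=bool)
        a[3] = True
        flat_sp.update_duty_cycles(a)
        assert flat_sp.duty_cycles[3] == pytest.approx(1 / 1000)
        assert flat_sp.duty_cycles[4] == 0.0

    def test_duty_cycle_fixed_point_is_one(self):
        cfg = SPConfig.dimensionless(n_columns=4, input_dims=(8,),
                                     duty_cycle_period=10, seed=0)
        sp = SpatialPooler(cfg)
        a = np.ones(4, dtype=bool)
        for _ in range(300):
            sp.update_duty_cycles(a)
        assert np.allclose(sp.duty_cycles, 1.0, atol=1e-9)

    def test_equal_duty_cycles_give_unit_boosts(self, flat_sp):
        flat_sp.duty_cycles[:] = 0.02
        flat_sp.update_boosts()
        assert np.allclose(flat_sp.boosts, 1.0)

    def test_boost_is_e_for_deficit_of_001_at_beta_100(self):
        cfg = SPConfig.dimensionless(n_columns=2, input_dims=(8,), seed=0)
        sp = SpatialPooler(cfg)
        sp.duty_cycles[:] = [0.0, 0.01]
        sp.update_boosts()
        assert sp.boosts[0] == pytest.approx(math.e)
        assert sp.boosts[1] == pytest.approx(1 / math.e)

    def test_zero_beta_disables_boosting(self):
        cfg = SPConfig.dimensionless(n_columns=8, input_dims=(8,),
                                     boost_strength=0, seed=0)
        sp = SpatialPooler(cfg)
        sp.duty_cycles[:] = np.linspace(0, 0.5, 8)
        sp.update_boosts()
        assert (sp.boosts == 1.0).all()


class TestInhibitionRadius:
    def test_global_inhibition_radius_stays_infinite(self, flat_sp):
        flat_sp.update_inhibition_radius()
        assert math.isinf(flat_sp.inhibition_radius)

    def test_initial_radius_close_to_potential_radius(self):
        # full potential hypercubes of radius 5, ~50% connected, one column
        # per input -> connected span ~11 -> radius ~(11-1)/2 = 5
        sp = SpatialPooler(SPConfig.topological(seed=4))
        assert 4.0 < sp.inhibition_radius < 5.5

    def test_radius_from_connected_span(self, grid_sp):
        grid_sp.connected[:] = False
        rows, cols = np.meshgrid(range(5), range(5), indexing="ij")
        idx = (rows * 12 + cols).ravel()
        grid_sp.connected[0, idx] = True   # span 5 per dimension
        grid_sp.update_inhibition_radius()
        assert grid_sp.inhibition_radius == pytest.approx((5 * 1 - 1) / 2)

    def test_radius_clamped_to_at_least_one(self, grid_sp):
        grid_sp.connected[:] = False
        grid_sp.connected[0, 0] = True   # span 1 -> raw radius 0
        grid_sp.update_inhibition_radius()
        assert grid_sp.inhibition_radius == 1.0

    def test_no_connected_synapses_leaves_radius_unchanged(self, grid_sp):
        before = grid_sp.inhibition_radius
        grid_sp.connected[:] = False
        grid_sp.update_inhibition_radius()
        assert grid_sp.inhibition_radius == before


class TestCompute:
    def test_frozen_compute_is_pure(self, grid_sp, rng):
        z = (rng.random(grid_sp.n_inputs) < 0.1).astype(np.uint8)
        snapshot = {n: getattr(grid_sp, n).copy()
                    for n in SpatialPooler.STATE_ARRAYS}
        a1 = grid_sp.compute(z, learn=False)
        a2 = grid_sp.compute(z, learn=False)
        assert np.array_equal(a1.active, a2.active)
        for name, before in snapshot.items():
            assert np.array_equal(getattr(grid_sp, name), before)

    def test_repeated_pattern_reinforcement_without_boosting(self, rng):
        cfg = SPConfig.dimensionless(n_columns=64, input_dims=(64,),
                                     boost_strength=0, seed=1)
        sp = SpatialPooler(cfg)
        z = (rng.random(64) < 0.3).astype(np.uint8)
        first = sp.compute(z, learn=True)
        prev = first.overlaps[first.active]
        for _ in range(20):
            act = sp.compute(z, learn=True)
            assert np.array_equal(act.active, first.active)
            cur = act.overlaps[first.active]
            assert (cur >= prev - 1e-12).all()
            prev = cur

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(0)
        Z = (rng.random((50, 1024)) < 0.1).astype(np.uint8)
        outs = []
        for _ in range(2):
            sp = SpatialPooler(SPConfig.topological(seed=11))
            outs.append([sp.compute(z, learn=True).active for z in Z])
        for a, b in zip(*outs):
            assert np.array_equal(a, b)


class TestLesions:
    def test_empty_lesion_is_a_no_op(self, grid_sp):
        before = {n: getattr(grid_sp, n).copy()
                  for n in SpatialPooler.STATE_ARRAYS}
        grid_sp.lesion_columns([])
        grid_sp.lesion_inputs([])
        for name, arr in before.items():
            assert np.array_equal(getattr(grid_sp, name), arr)

    def test_central_block_kills_exactly_121_columns(self):
        sp = SpatialPooler(SPConfig.topological(seed=5))
        sp.lesion_columns(center_block_indices((32, 32), (11, 11)))
        assert (~sp.alive_mask).sum() == 121

    def test_dead_columns_never_activate_or_learn(self, grid_sp, rng):
        dead = [0, 5, 77]
        grid_sp.lesion_columns(dead)
        perms_before = grid_sp.permanences[dead].copy()
        for _ in range(20):
            z = (rng.random(grid_sp.n_inputs) < 0.2).astype(np.uint8)
            act = grid_sp.compute(z, learn=True)
            assert not act.active[dead].any()
        assert np.array_equal(grid_sp.permanences[dead], perms_before)

    def test_lesioning_every_column_is_an_error(self, grid_sp):
        with pytest.raises(ValueError):
            grid_sp.lesion_columns(np.arange(grid_sp.n_columns))

    def test_input_lesion_leaves_coverage_unchanged_immediately(self, grid_sp):
        from spool.experiments import coverage_map
        before = coverage_map(grid_sp)
        grid_sp.lesion_inputs(center_block_indices((12, 12), (4, 4)))
        assert np.array_equal(coverage_map(grid_sp), before)

    def test_lesioned_inputs_read_as_zero(self, grid_sp):
        grid_sp.lesion_inputs(np.arange(grid_sp.n_inputs // 2))
        z = np.ones(grid_sp.n_inputs, dtype=np.uint8)
        z_half = z.copy()
        z_half[:grid_sp.n_inputs // 2] = 0
        o_lesioned = grid_sp.compute_overlap(z)
        grid_sp.input_mask[:] = True
        assert np.array_equal(o_lesioned, grid_sp.compute_overlap(z_half))
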