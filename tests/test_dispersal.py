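"""Dispersal kernel construction and the cellular automaton."""

import numpy as np
import pytest

from rangecast import DispersalParams, GridSpec, Layer, build_kernel, run_dispersal
from rangecast.dispersal import DEFAULT_BASE_PROBS


def grid_layer(spec, vals):
    return Layer(spec, "b", np.asarray(vals, dtype=float))


def uniform_world(n=9):
    spec = GridSpec(n, n)
    suitable = grid_layer(spec, np.ones((n, n)))
    init = np.zeros((n, n))
    init[n // 2, n // 2] = 1.0
    return spec, grid_layer(spec, init), suitable


class TestBuildKernel:
    def test_zero_rappel_weight_kills_kernel(self):
        assert np.all(build_kernel(rappel_weight=0.0) == 0.0)

    def test_flat_base_full_weight(self):
        k = build_kernel(base_distances_km=[1, 5], base_probs=[0.3, 0.3], rappel_weight=1.0)
        assert len(k) == 5
        np.testing.assert_allclose(k, 0.3)

    def test_species_kernels_scale_by_rappel_ratio(self):
        k_fim = build_kernel(rappel_weight=0.766)
        k_pla = build_kernel(rappel_weight=0.59)
        np.testing.assert_allclose(k_fim, (0.766 / 0.59) * k_pla)

    def test_truncated_at_largest_base_distance(self):
        k = build_kernel(cellsize_km=2.0)
        assert len(k) == 2  # rings at 2 and 4 km; 6 km is beyond the 5 km extent

    def test_interpolates_base_curve(self):
        k = build_kernel(rappel_weight=1.0, cellsize_km=1.0)
        np.testing.assert_allclose(k, DEFAULT_BASE_PROBS)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_kernel(base_distances_km=[], base_probs=[])
        with pytest.raises(ValueError):
            build_kernel(base_distances_km=[2, 1], base_probs=[0.5, 0.4])


def _params(**kw):
    defaults = dict(
        kernel=np.array([1.0]),
        ldd_probability=0.0,
        maturity_age=0,
        replicates=1,
        steps_per_period={"t": 3},
        reachable_frequency_threshold=0.5,
    )
    defaults.update(kw)
    return DispersalParams(**defaults)


class TestRunDispersal:
    def test_no_dispersal_identity(self):
        spec, init, suit = uniform_world()
        params = _params(kernel=np.array([0.0]), replicates=5, steps_per_period={"t": 10})
        res = run_dispersal(init, {"t": suit}, params, master_seed=0)
        np.testing.assert_array_equal(res.colonization_frequency.values, init.values)

    @pytest.mark.parametrize("steps", [1, 2, 3])
    def test_unit_kernel_grows_chebyshev_ball(self, steps):
        spec, init, suit = uniform_world(9)
        params = _params(steps_per_period={"t": steps})
        res = run_dispersal(init, {"t": suit}, params, master_seed=1)
        rr, cc = np.meshgrid(np.arange(9), np.arange(9), indexing="ij")
        ball = (np.maximum(np.abs(rr - 4), np.abs(cc - 4)) <= steps).astype(float)
        np.testing.assert_array_equal(res.colonization_frequency.values, ball)

    def test_barrier_ring_contains_spread(self):
        spec, init, suit = uniform_world(9)
        barrier = np.zeros((9, 9), bool)
        barrier[2, 2:7] = barrier[6, 2:7] = True
        barrier[2:7, 2] = barrier[2:7, 6] = True
        params = _params(replicates=30, steps_per_period={"t": 20})
        res = run_dispersal(
            init, {"t": suit}, params, settlement_barrier=barrier, master_seed=3
        )
        outside = np.ones((9, 9), bool)
        outside[2:7, 2:7] = False
        assert res.colonization_frequency.values[outside].sum() == 0.0
        assert res.colonization_frequency.values[barrier].sum() == 0.0

    def test_maturity_delay_slows_front(self):
        """Initial cells are mature; first-generation colonists must wait
        maturity_age steps before seeding, so the radius after 3 steps is 2."""
        spec, init, suit = uniform_world(9)
        params = _params(maturity_age=2, steps_per_period={"t": 3})
        res = run_dispersal(init, {"t": suit}, params, master_seed=0)
        occ = res.colonization_frequency.values == 1.0
        rr, cc = np.meshgrid(np.arange(9), np.arange(9), indexing="ij")
        cheb = np.maximum(np.abs(rr - 4), np.abs(cc - 4))
        assert occ[cheb <= 2].all() and not occ[cheb > 2].any()

    def test_period_switch_decolonizes_lost_habitat(self):
        spec, init, suit = uniform_world(9)
        lost = np.ones((9, 9))
        lost[4, 4] = 0.0  # the seed cell turns unsuitable in period 2
        params = _params(
            kernel=np.array([0.0]), steps_per_period={"a": 1, "b": 1}
        )
        res = run_dispersal(
            init, {"a": suit, "b": grid_layer(spec, lost)}, params, master_seed=0
        )
        assert res.colonization_frequency.values[4, 4] == 0.0

    def test_reachable_contained_in_suitable_union_initial(self):
        rng = np.random.default_rng(5)
        spec = GridSpec(15, 15)
        suit_vals = (rng.uniform(size=(15, 15)) < 0.6).astype(float)
        init_vals = np.zeros((15, 15))
        init_vals[7, 7] = 1.0
        suit_vals[7, 7] = 1.0
        params = _params(
            kernel=np.array([0.8, 0.3]),
            ldd_probability=0.05,
            replicates=10,
            steps_per_period={"t": 10},
        )
        res = run_dispersal(
            grid_layer(spec, init_vals), {"t": grid_layer(spec, suit_vals)}, params, master_seed=2
        )
        allowed = (suit_vals == 1.0) | (init_vals == 1.0)
        assert np.all(res.reachable_mask <= allowed)

    def test_adding_barriers_never_enlarges_reachable_set(self):
        rng = np.random.default_rng(8)
        spec = GridSpec(15, 15)
        suit = grid_layer(spec, np.ones((15, 15)))
        init_vals = np.zeros((15, 15))
        init_vals[7, 7] = 1.0
        init = grid_layer(spec, init_vals)
        params = _params(
            kernel=np.array([0.5, 0.2]),
            ldd_probability=0.1,
            replicates=10,
            steps_per_period={"t": 8},
        )
        free = run_dispersal(init, {"t": suit}, params, master_seed=11)
        barrier = rng.uniform(size=(15, 15)) < 0.2
        barrier[7, 7] = False
        walled = run_dispersal(
            init, {"t": suit}, params, sdd_barrier=barrier, master_seed=11
        )
        assert np.all(walled.reachable_mask <= free.reachable_mask)
        walled2 = run_dispersal(
            init, {"t": suit}, params, settlement_barrier=barrier, master_seed=11
        )
        assert np.all(walled2.reachable_mask <= free.reachable_mask)

    def test_larger_kernel_spreads_no_less_on_average(self):
        spec = GridSpec(15, 15)
        suit = grid_layer(spec, np.ones((15, 15)))
        init_vals = np.zeros((15, 15))
        init_vals[7, 7] = 1.0
        init = grid_layer(spec, init_vals)
        small = _params(kernel=np.array([0.3, 0.1]), replicates=30, steps_per_period={"t": 6})
        large = _params(kernel=np.array([0.6, 0.3]), replicates=30, steps_per_period={"t": 6})
        res_s = run_dispersal(init, {"t": suit}, small, master_seed=4)
        res_l = run_dispersal(init, {"t": suit}, large, master_seed=4)
        # shared seeds pair the replicates
        assert np.all(res_l.occupied_counts[:, -1] >= res_s.occupied_counts[:, -1])

    def test_bit_identical_replication_and_frequency_grid(self):
        spec, init, suit = uniform_world(9)
        params = _params(
            kernel=np.array([0.4]), ldd_probability=0.05, replicates=8,
            steps_per_period={"t": 5},
        )
        a = run_dispersal(init, {"t": suit}, params, master_seed=13)
        b = run_dispersal(init, {"t": suit}, params, master_seed=13)
        np.testing.assert_array_equal(
            a.colonization_frequency.values, b.colonization_frequency.values
        )
        np.testing.assert_array_equal(a.occupied_counts, b.occupied_counts)
        freqs = a.colonization_frequency.values
        np.testing.assert_allclose((freqs * 8) % 1.0, 0.0, atol=1e-12)

    def test_ldd_jumps_over_barrier_ring(self):
        """A wide barrier ring stops the kernel but ballooning crosses it."""
        spec = GridSpec(21, 21)
        suit = grid_layer(spec, np.ones((21, 21)))
        init_vals = np.zeros((21, 21))
        init_vals[10, 10] = 1.0
        barrier = np.zeros((21, 21), bool)
        barrier[7:14, 7] = barrier[7:14, 13] = True
        barrier[7, 7:14] = barrier[13, 7:14] = True
        params = _params(
            kernel=np.array([1.0]),
            ldd_probability=0.5,
            ldd_distance=(5.0, 8.0),
            replicates=20,
            steps_per_period={"t": 10},
        )
        res = run_dispersal(
            grid_layer(spec, init_vals), {"t": suit}, params,
            settlement_barrier=barrier, master_seed=7,
        )
        outside = np.zeros((21, 21), bool)
        outside[:6, :] = True
        assert res.colonization_frequency.values[outside].sum() > 0
        assert res.colonization_frequency.values[barrier].sum() == 0.0

    def test_misconfigured_timeline_rejected_before_stepping(self):
        spec, init, suit = uniform_world(5)
        params = _params(steps_per_period={"other": 3})
        with pytest.raises(ValueError, match="no step count"):
            run_dispersal(init, {"t": suit}, params, master_seed=0)

    def test_per_pair_semantics_also_fills_unit_kernel_ball(self):
        spec, init, suit = uniform_world(7)
        params = _params(per_pair_draws=True, steps_per_period={"t": 2})
        res = run_dispersal(init, {"t": suit}, params, master_seed=0)
        rr, cc = np.meshgrid(np.arange(7), np.arange(7), indexing="ij")
        ball = (np.maximum(np.abs(rr - 3), np.abs(cc - 3)) <= 2).astype(float)
        np.testing.assert_array_equal(res.colonization_frequency.values, ball)
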