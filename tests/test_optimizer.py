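"""Block partition, exact block moves, sweeps, registration loop, parallel contract."""

import numpy as np
import pytest

from conftest import brute_force_min, brute_force_tables_min
from gcdeform import (
    DisplacementField,
    RegistrationConfig,
    Volume,
    apply_labeling,
    partition_blocks,
    register,
    run_blocks_parallel,
    solve_block_move,
    sweep,
)
from gcdeform.energy import MoveTerms, build_move_terms, move_energy, total_energy
from gcdeform.mincut import SubmodularityError, solve_binary_submodular


def random_submodular_terms(rng, shape=(2, 2, 2), spread=5.0, gamma=2.0, alpha=1.0):
    """Random move tables built from random fields via the move construction
    itself restricted to tiny blocks (guaranteed submodular for gamma >= 2)."""
    n = int(np.prod(shape))
    cfg = RegistrationConfig(alpha=alpha, gamma=gamma, epsilon=1.0, radius=1, block_size=2)
    vol_shape = tuple(s + 2 for s in shape)
    target = Volume(rng.uniform(0, 100, vol_shape))
    source = Volume(rng.uniform(0, 100, vol_shape))
    u = DisplacementField(rng.uniform(-spread, spread, size=(*vol_shape, 3)))
    axis = rng.integers(0, 3)
    delta = np.zeros(3)
    delta[axis] = rng.choice([-1.0, 1.0])
    block = tuple(slice(1, 1 + s) for s in shape)
    return build_move_terms(target, source, u, block, delta, cfg)


class TestPartition:
    def test_exact_tiling(self):
        p = partition_blocks((32, 32, 32), 16)
        assert len(p.blocks) == 8
        sizes = {tuple(s.stop - s.start for s in b) for b in p.blocks}
        assert sizes == {(16, 16, 16)}

    def test_remainder_blocks(self):
        p = partition_blocks((20, 20, 20), 16)
        assert len(p.blocks) == 8
        sizes = {tuple(s.stop - s.start for s in b) for b in p.blocks}
        assert sizes == {(16, 16, 16), (16, 16, 4), (16, 4, 16), (4, 16, 16),
                         (16, 4, 4), (4, 16, 4), (4, 4, 16), (4, 4, 4)}

    def test_shifted_tiling(self):
        p = partition_blocks((16, 16, 16), 16, (8, 0, 0))
        assert len(p.blocks) == 2
        assert {tuple(s.stop - s.start for s in b) for b in p.blocks} == {(8, 16, 16)}

    @pytest.mark.parametrize("shape,bs,off", [
        ((17, 9, 5), 4, (0, 0, 0)),
        ((17, 9, 5), 4, (3, 1, 2)),
        ((8, 8, 8), 3, (2, 2, 2)),
    ])
    def test_disjoint_cover(self, shape, bs, off):
        p = partition_blocks(shape, bs, off)
        count = np.zeros(shape, dtype=int)
        for b in p.blocks:
            count[b] += 1
        assert np.all(count == 1)

    def test_coloring_separates_adjacent_blocks(self):
        p = partition_blocks((32, 32, 32), 16)
        colors = p.colors()
        for i, bi in enumerate(p.index):
            for j, bj in enumerate(p.index):
                if np.abs(bi - bj).sum() == 1:  # 6-adjacent in the block grid
                    assert colors[i] != colors[j]


class TestSolveBlockMove:
    def test_decoupled_problem_takes_unary_argmin(self):
        n = 8
        unary = np.stack([np.zeros(n), np.ones(n)], axis=1)
        terms = MoveTerms(
            voxels=np.zeros((n, 3), dtype=int),
            unary=unary,
            pairs=np.empty((0, 2), dtype=int),
            pairwise_inner=np.empty((0, 4)),
            boundary_index=np.empty(0, dtype=int),
            pairwise_boundary=np.empty((0, 2)),
        )
        labels, delta = solve_block_move(terms)
        assert not labels.any() and delta == 0.0

    def test_matches_brute_force_on_random_blocks(self, rng):
        """Min-cut labeling energy equals exhaustive enumeration (oracle)."""
        for _ in range(50):
            terms = random_submodular_terms(rng)
            labels, delta = solve_block_move(terms)
            _, best = brute_force_min(terms)
            assert move_energy(terms, labels) == pytest.approx(best, abs=1e-9)
            assert delta <= 1e-12

    def test_true_shift_move_strictly_improves(self, rng):
        base = rng.random((8, 8, 8)) * 100
        target = Volume(base)
        shifted = np.roll(base, -1, axis=0)  # source(x) = target(x - (-1)) -> u=+1 aligns
        source = Volume(shifted)
        cfg = RegistrationConfig(alpha=0.05, epsilon=1.0, radius=1, block_size=4)
        u = DisplacementField.zeros((8, 8, 8))
        block = (slice(2, 6), slice(2, 6), slice(2, 6))
        terms = build_move_terms(target, source, u, block, (1.0, 0, 0), cfg)
        labels, delta = solve_block_move(terms)
        assert delta < 0
        assert labels.any()

    def test_non_submodular_table_raises(self):
        unary = np.zeros((2, 2))
        pairs = np.array([[0, 1]])
        pairwise = np.array([[5.0, 0.0, 0.0, 5.0]])  # violates the inequality
        with pytest.raises(SubmodularityError):
            solve_binary_submodular(unary, pairs, pairwise)

    def test_raw_solver_matches_brute_force_tables(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 9))
            unary = rng.uniform(-5, 5, (n, 2))
            m = int(rng.integers(0, 2 * n))
            pairs = (
                np.array([rng.choice(n, 2, replace=False) for _ in range(m)])
                if m else np.empty((0, 2), dtype=int)
            )
            pw = rng.uniform(0, 5, (m, 4))
            if m:
                excess = pw[:, 0] + pw[:, 3] - pw[:, 1] - pw[:, 2]
                pw[:, 1] += np.maximum(excess, 0)
            labels = solve_binary_submodular(unary, pairs, pw)
            e = unary[np.arange(n), labels].sum()
            for (i, j), tab in zip(pairs, pw):
                e += tab[2 * labels[i] + labels[j]]
            assert e == pytest.approx(brute_force_tables_min(unary, pairs, pw), abs=1e-9)


class TestApplyLabeling:
    def test_all_zero_is_identity(self, rng):
        u = DisplacementField(rng.normal(size=(4, 4, 4, 3)))
        block = (slice(0, 2), slice(0, 2), slice(0, 2))
        out = apply_labeling(u, block, np.zeros(8, dtype=int), (0.5, 0, 0))
        assert np.array_equal(out.vectors, u.vectors)

    def test_all_one_shifts_block_only(self, rng):
        u = DisplacementField(rng.normal(size=(4, 4, 4, 3)))
        block = (slice(1, 3), slice(1, 3), slice(1, 3))
        out = apply_labeling(u, block, np.ones(8, dtype=int), (0.5, 0, 0))
        np.testing.assert_allclose(
            out.vectors[block][..., 0], u.vectors[block][..., 0] + 0.5
        )
        outside = np.ones((4, 4, 4), dtype=bool)
        outside[block] = False
        assert np.array_equal(out.vectors[outside], u.vectors[outside])

    def test_mixed_labeling_elementwise(self, rng):
        u = DisplacementField(rng.normal(size=(4, 4, 4, 3)))
        block = (slice(0, 2), slice(0, 2), slice(0, 2))
        labels = rng.integers(0, 2, 8)
        delta = np.array([0.0, -0.5, 0.0])
        out = apply_labeling(u, block, labels, delta)
        expected = u.vectors[block].reshape(-1, 3) + labels[:, None] * delta
        np.testing.assert_allclose(out.vectors[block].reshape(-1, 3), expected)


class TestSweepAndRegister:
    def test_identical_images_accept_nothing(self, rng):
        vol = Volume(rng.random((12, 12, 12)) * 50)
        cfg = RegistrationConfig(block_size=6, radius=1)
        u = DisplacementField.zeros(vol.shape)
        _, report = sweep(vol, vol, u, cfg)
        assert report.changed_voxels == 0

    def test_energy_never_increases(self, rng):
        target = Volume(rng.random((12, 12, 12)) * 50)
        source = Volume(np.roll(target.data, 1, axis=1))
        cfg = RegistrationConfig(block_size=6, radius=1, n_levels=1, max_sweeps_per_level=4)
        u, reports = register(target, source, cfg)
        for r in reports:
            assert r.energy_after <= r.energy_before + 1e-9

    def test_true_translation_reduces_energy(self, rng):
        base = rng.random((12, 12, 12)) * 50
        target = Volume(base)
        source = Volume(np.roll(base, -1, axis=0))
        cfg = RegistrationConfig(alpha=0.05, epsilon=1.0, radius=1, block_size=6)
        u = DisplacementField.zeros(target.shape)
        _, report = sweep(target, source, u, cfg)
        assert report.energy_after < report.energy_before

    def test_incremental_deltas_match_global_energy_change(self, rng):
        target = Volume(rng.random((10, 10, 10)) * 50)
        source = Volume(np.roll(target.data, 1, axis=2))
        cfg = RegistrationConfig(block_size=5, radius=1)
        u = DisplacementField.zeros(target.shape)
        _, report = sweep(target, source, u, cfg)
        change = report.energy_after - report.energy_before
        assert report.accepted_delta_sum == pytest.approx(change, rel=1e-5, abs=1e-7)

    def test_sweep_energy_matches_independent_recompute(self, rng):
        target = Volume(rng.random((10, 10, 10)) * 50)
        source = Volume(np.roll(target.data, 1, axis=0))
        cfg = RegistrationConfig(block_size=5, radius=1)
        u = DisplacementField.zeros(target.shape)
        out, report = sweep(target, source, u, cfg)
        assert report.energy_before == pytest.approx(
            total_energy(target, source, u, cfg), rel=1e-12
        )
        assert report.energy_after == pytest.approx(
            total_energy(target, source, out, cfg), rel=1e-12
        )

    def test_no_op_configuration_returns_input(self, rng):
        vol = Volume(rng.random((8, 8, 8)))
        cfg = RegistrationConfig(n_levels=1, max_sweeps_per_level=0, block_size=4)
        u0 = DisplacementField(rng.normal(size=(8, 8, 8, 3)))
        u, reports = register(vol, vol, cfg, u0)
        assert reports == []
        np.testing.assert_array_equal(u.vectors, u0.vectors)

    def test_deterministic_given_inputs(self, rng):
        target = Volume(rng.random((10, 10, 10)))
        source = Volume(np.roll(target.data, 1, axis=0))
        cfg = RegistrationConfig(block_size=5, radius=1, n_levels=1, max_sweeps_per_level=2)
        u1, _ = register(target, source, cfg)
        u2, _ = register(target, source, cfg)
        assert np.array_equal(u1.vectors, u2.vectors)


class TestParallelContract:
    def test_single_worker_degenerate_pool(self):
        jobs = [lambda i=i: i * i for i in range(5)]
        assert run_blocks_parallel(jobs, 1) == [0, 1, 4, 9, 16]

    def test_results_in_submission_order(self):
        jobs = [lambda i=i: i for i in range(20)]
        assert run_blocks_parallel(jobs, 4) == list(range(20))

    def test_worker_count_does_not_change_registration(self, rng):
        target = Volume(rng.random((12, 12, 12)) * 50)
        source = Volume(np.roll(target.data, -1, axis=1))
        cfg1 = RegistrationConfig(block_size=6, radius=1, n_levels=1,
                                  max_sweeps_per_level=3, n_workers=1)
        cfg4 = RegistrationConfig(block_size=6, radius=1, n_levels=1,
                                  max_sweeps_per_level=3, n_workers=4)
        u1, _ = register(target, source, cfg1)
        u4, _ = register(target, source, cfg4)
        assert np.array_equal(u1.vectors, u4.vectors)
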