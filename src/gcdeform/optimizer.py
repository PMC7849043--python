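"""Iterative move-making optimization of the registration energy.

Each iteration proposes a move: add a fixed step delta = +/- epsilon * e_i to
the displacement of a binary subset of voxels. Restricted to one block of the
grid, the optimal subset is found exactly as a minimum s-t cut over the move's
unary/pairwise tables. A sweep tries all six signed axis steps over all
blocks; sweeps repeat until no block accepts a flip, at every level of a
coarse-to-fine pyramid. The block tiling alternates its offset between sweeps
so block boundaries do not pin the solution.

Blocks are processed in two checkerboard colors (by parity of the block index
sum) so that no two concurrently processed blocks share a neighbor pair; the
result is therefore identical for any worker count.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import DisplacementField, Volume, build_pyramid, downsample_field, upsample_field
from .energy import (
    MoveTerms,
    RegistrationConfig,
    _data_terms,
    build_move_terms,
    move_energy,
    regularizer_total,
    window_offsets,
)
from .mincut import solve_binary_submodular

__all__ = [
    "BlockPartition",
    "SweepReport",
    "partition_blocks",
    "solve_block_move",
    "apply_labeling",
    "sweep",
    "register",
    "run_blocks_parallel",
    "preprocess_pair",
]

# Moves that tie the null move within this slack keep the null labeling,
# guaranteeing termination.
_ACCEPT_TOL = 1e-9


@dataclass
class BlockPartition:
    """Axis-aligned tiling of the voxel grid into disjoint blocks.

    ``blocks`` are tuples of slices; ``index`` holds the integer block-grid
    coordinates of each block (used for checkerboard coloring).
    """

    blocks: list[tuple[slice, slice, slice]]
    index: np.ndarray
    shape: tuple[int, int, int]
    block_size: tuple[int, int, int]
    offset: tuple[int, int, int]

    def colors(self) -> np.ndarray:
        """Checkerboard color per block: no two blocks of one color are 6-adjacent."""
        return self.index.sum(axis=1) % 2


@dataclass
class SweepReport:
    """Observability record for one sweep (all six moves over all blocks)."""

    level: int
    sweep: int
    moves_attempted: int = 0
    moves_accepted: int = 0
    changed_voxels: int = 0
    energy_before: float = float("nan")
    energy_after: float = float("nan")
    accepted_delta_sum: float = 0.0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def partition_blocks(shape, block_size, offset=(0, 0, 0)) -> BlockPartition:
    """Tile the grid into blocks of ``block_size``, shifted by ``offset``.

    The shift leaves a smaller leading block at the origin; trailing blocks
    may also be smaller. Blocks are disjoint and cover the grid exactly.
    """
    shape = tuple(int(n) for n in shape)
    if np.isscalar(block_size):
        block_size = (block_size,) * 3
    block_size = tuple(int(b) for b in block_size)
    if np.isscalar(offset):
        offset = (offset,) * 3
    offset = tuple(int(o) for o in offset)
    if any(b < 1 for b in block_size):
        raise ValueError(f"block_size must be >= 1, got {block_size}")
    if any(not (0 <= o < b) for o, b in zip(offset, block_size)):
        raise ValueError(f"offset must lie in [0, block_size), got {offset}")
    edges = []
    for n, b, o in zip(shape, block_size, offset):
        starts = [0] if o == 0 else [0, o]
        starts += list(range(starts[-1] + b, n, b))
        starts = [s for s in starts if s < n]
        edges.append([(s, min(s + b, n) if s >= o else min(o, n)) for s in starts])
    blocks = []
    index = []
    for i, (x0, x1) in enumerate(edges[0]):
        for j, (y0, y1) in enumerate(edges[1]):
            for k, (z0, z1) in enumerate(edges[2]):
                blocks.append((slice(x0, x1), slice(y0, y1), slice(z0, z1)))
                index.append((i, j, k))
    return BlockPartition(
        blocks=blocks,
        index=np.asarray(index, dtype=np.int64),
        shape=shape,
        block_size=block_size,
        offset=offset,
    )


def solve_block_move(terms: MoveTerms) -> tuple[np.ndarray, float]:
    """Exactly minimize one block's move energy.

    Boundary-pair tables (outside endpoint frozen at label 0) are folded into
    the unary tables, then the submodular binary problem is solved as a min
    cut. Returns the optimal labeling over the block's voxels and its energy
    relative to the null (all-zero) move; the null move is always feasible, so
    the delta is <= 0 up to float round-off.
    """
    eff_unary = terms.unary.copy()
    if len(terms.boundary_index):
        np.add.at(eff_unary[:, 0], terms.boundary_index, terms.pairwise_boundary[:, 0])
        np.add.at(eff_unary[:, 1], terms.boundary_index, terms.pairwise_boundary[:, 1])
    labels = solve_binary_submodular(eff_unary, terms.pairs, terms.pairwise_inner)
    delta = move_energy(terms, labels) - move_energy(
        terms, np.zeros(len(labels), dtype=np.int64)
    )
    return labels, float(delta)


def apply_labeling(
    u: DisplacementField, block: tuple[slice, slice, slice], labels: np.ndarray, delta
) -> DisplacementField:
    """Return a field with u'(v) = u(v) + L(v) * delta inside ``block``."""
    out = u.copy()
    _apply_inplace(out, block, labels, np.asarray(delta, dtype=np.float64))
    return out


def _apply_inplace(u: DisplacementField, block, labels, delta) -> None:
    sub = u.vectors[block]
    mask = np.asarray(labels).reshape(sub.shape[:3]).astype(bool)
    sub[mask] += delta


def run_blocks_parallel(block_jobs, n_workers: int):
    """Run independent block jobs, returning results in submission order.

    Jobs passed together must be mutually independent (one checkerboard
    color); any interleaving then yields the same results as serial
    execution, so the output is identical for every ``n_workers``.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    block_jobs = list(block_jobs)
    if n_workers == 1 or len(block_jobs) <= 1:
        return [job() for job in block_jobs]
    with ThreadPoolExecutor(max_workers=n_workers) as pool:
        futures = [pool.submit(job) for job in block_jobs]
        return [f.result() for f in futures]


def preprocess_pair(
    target: Volume, source: Volume, cfg: RegistrationConfig
) -> tuple[Volume, Volume]:
    """Input preprocessing applied by :func:`register`: Gaussian smoothing of
    both volumes with ``cfg.presmooth_sigma`` (no-op when 0). The energies in
    sweep reports refer to the preprocessed pair."""
    if cfg.presmooth_sigma <= 0:
        return target, source
    return (
        Volume(gaussian_filter(target.data, cfg.presmooth_sigma, mode="nearest"), target.spacing),
        Volume(gaussian_filter(source.data, cfg.presmooth_sigma, mode="nearest"), source.spacing),
    )


def _signed_moves(epsilon: float) -> list[np.ndarray]:
    moves = []
    for ax in range(3):
        for sign in (1.0, -1.0):
            d = np.zeros(3)
            d[ax] = sign * epsilon
            moves.append(d)
    return moves


def sweep(
    target: Volume,
    source: Volume,
    u: DisplacementField,
    cfg: RegistrationConfig,
    sweep_index: int = 0,
    level: int = 0,
    offsets: np.ndarray | None = None,
) -> tuple[DisplacementField, SweepReport]:
    """One full sweep: all six signed axis moves over all blocks.

    The block tiling offset alternates with the sweep parity (0 on even
    sweeps, block_size // 2 on odd sweeps). Returns the updated field and a
    report; the globally recomputed energy never increases.
    """
    if target.shape != u.shape:
        raise ValueError(f"field shape {u.shape} != target shape {target.shape}")
    if offsets is None:
        offsets = window_offsets(cfg.radius)
    shape = u.shape
    shift = 0 if sweep_index % 2 == 0 else cfg.block_size // 2
    part = partition_blocks(shape, cfg.block_size, tuple(min(shift, n - 1) for n in shape))
    colors = part.colors()
    report = SweepReport(level=level, sweep=sweep_index)
    out = u.copy()

    vox_all = np.stack(
        np.meshgrid(*(np.arange(n, dtype=np.int64) for n in shape), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)

    def unary_volume(delta_vec) -> np.ndarray:
        disp = out.vectors.reshape(-1, 3)
        if delta_vec is not None:
            disp = disp + delta_vec
        return _data_terms(target, source, vox_all, disp, cfg, offsets).reshape(shape)

    # Label-0 data term per voxel, maintained incrementally: a voxel's data
    # term depends only on its own displacement, so accepted voxels simply
    # take over their label-1 value.
    data0 = unary_volume(None)
    report.energy_before = float(data0.sum() + cfg.alpha * regularizer_total(out, cfg.gamma))

    for delta in _signed_moves(cfg.epsilon):
        data1 = unary_volume(delta)
        for color in (0, 1):
            idx = [i for i in range(len(part.blocks)) if colors[i] == color]
            if not idx:
                continue

            def job(block):
                un = np.stack(
                    [data0[block].ravel(), data1[block].ravel()], axis=1
                )
                terms = build_move_terms(
                    target, source, out, block, delta, cfg, offsets, unary=un
                )
                return solve_block_move(terms)

            jobs = [(lambda b: (lambda: job(b)))(part.blocks[i]) for i in idx]
            results = run_blocks_parallel(jobs, cfg.n_workers)
            for i, (labels, edelta) in zip(idx, results):
                report.moves_attempted += 1
                if edelta < -_ACCEPT_TOL and labels.any():
                    block = part.blocks[i]
                    mask = labels.reshape(out.vectors[block].shape[:3]).astype(bool)
                    out.vectors[block][mask] += delta
                    data0[block][mask] = data1[block][mask]
                    report.moves_accepted += 1
                    report.changed_voxels += int(labels.sum())
                    report.accepted_delta_sum += edelta

    report.energy_after = float(data0.sum() + cfg.alpha * regularizer_total(out, cfg.gamma))
    if not np.isfinite(report.energy_after):
        raise FloatingPointError(
            f"non-finite energy after sweep {sweep_index} at level {level}"
        )
    return out, report


def register(
    target: Volume,
    source: Volume,
    cfg: RegistrationConfig | None = None,
    u0: DisplacementField | None = None,
) -> tuple[DisplacementField, list[SweepReport]]:
    """Coarse-to-fine registration of ``source`` onto ``target``.

    Starts from ``u0`` (or the identity transform), runs sweeps at each
    pyramid level until a sweep accepts no flips or ``max_sweeps_per_level``
    is reached — then repeats with the step halved, ``epsilon_refinements``
    times — and upsamples the field between levels. The returned field u
    maps the target grid into the source: sampling the source at v + u(v)
    reconstructs the target. Fully deterministic given the inputs and config.
    """
    cfg = cfg or RegistrationConfig()
    if target.shape != source.shape:
        raise ValueError(f"target shape {target.shape} != source shape {source.shape}")
    if u0 is not None and u0.shape != target.shape:
        raise ValueError(f"initial field shape {u0.shape} != target shape {target.shape}")
    target, source = preprocess_pair(target, source, cfg)
    pyramid = build_pyramid(target, source, cfg.n_levels)
    offsets = window_offsets(cfg.radius)

    if u0 is not None:
        u = u0.copy()
        for _ in range(len(pyramid) - 1):
            u = downsample_field(u)
    else:
        u = DisplacementField.zeros(pyramid.levels[0][0].shape, pyramid.levels[0][0].spacing)

    reports: list[SweepReport] = []
    for level, (tgt, src) in enumerate(pyramid.levels):
        if u.shape != tgt.shape:
            u = upsample_field(u, tgt.shape, tgt.spacing)
        sweep_index = 0
        for refine in range(cfg.epsilon_refinements + 1):
            stage_cfg = replace(cfg, epsilon=cfg.epsilon / 2**refine)
            for _ in range(cfg.max_sweeps_per_level):
                u, rep = sweep(tgt, src, u, stage_cfg, sweep_index, level, offsets)
                reports.append(rep)
                sweep_index += 1
                if rep.changed_voxels == 0:
                    break
    return u, reports
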