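"""Registration energy: windowed-PCC data term, diffusion regularizer, move terms.

The objective is f(u) = D(u) + alpha * R(u). The data term D sums, over target
voxels v, the dissimilarity 1/2 * (1 - PCC) between the target patch in a
small spherical window around v and the corresponding source patch sampled at
the displaced window positions. The window is assumed rigid with respect to
its center voxel: the center's displacement u(v) is applied to every window
point. The regularizer R sums ||u(v) - u(w)||^gamma over 6-neighbor pairs.

A candidate move adds a fixed step delta = +/- epsilon * e_i to the
displacement of a binary subset of voxels. Restricted to one block, the move
energy decomposes into unary tables (data term at labels 0/1, plus
block-boundary pair terms with the outside endpoint frozen at label 0) and
pairwise tables over in-block neighbor pairs. For gamma >= 2 every pairwise
table is submodular, so the optimal move is an s-t min cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.ndimage import map_coordinates

from .core import DisplacementField, Volume

__all__ = [
    "RegistrationConfig",
    "MoveTerms",
    "pcc",
    "data_term_voxel",
    "regularizer_pair",
    "binary_term",
    "build_move_terms",
    "window_offsets",
    "total_energy",
    "move_energy",
]

_AXES = np.eye(3, dtype=np.int64)


@dataclass
class RegistrationConfig:
    """Tunable parameters of the registration.

    alpha
        Balance between data term and regularizer (weight on the pairwise
        terms). 0 disables regularization.
    gamma
        Regularizer exponent; must be >= 2 — submodularity of the move
        pairwise terms, and hence exactness of the min-cut step, is only
        guaranteed in that range.
    epsilon
        Move step length in voxel units; the displacement search grid.
        Sub-voxel steps give sub-voxel registration precision.
    epsilon_refinements
        Number of step halvings appended per pyramid level: after sweeps at
        epsilon converge, sweeps continue at epsilon/2, epsilon/4, ... Large
        steps escape local minima, the halved steps refine the quantization.
    radius
        Radius (voxels) of the spherical PCC window. Larger windows average
        more samples (less noise-driven drift) at the price of a stronger
        rigid-window approximation and more computation.
    presmooth_sigma
        Gaussian smoothing (voxels) applied to both input volumes before
        registration. Suppresses the correlation estimate's sensitivity to
        uncorrelated acquisition noise; structure wider than a couple of
        voxels is essentially unaffected. 0 disables.
    block_size
        Per-axis extent of the subregions each move is restricted to.
    n_levels
        Number of resolution pyramid levels (1 = no pyramid).
    max_sweeps_per_level
        Upper bound on full sweeps (all 6 signed axis moves over all blocks)
        per level; a level also stops when a sweep accepts no flips.
    metric
        "pcc" (windowed Pearson) or "ssd" (pointwise squared difference).
    n_workers
        Worker threads for block processing; results are identical to serial.
    """

    alpha: float = 0.25
    gamma: float = 4.0
    epsilon: float = 0.5
    epsilon_refinements: int = 1
    radius: int = 3
    presmooth_sigma: float = 1.5
    block_size: int = 16
    n_levels: int = 3
    max_sweeps_per_level: int = 50
    metric: str = "pcc"
    n_workers: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 2:
            raise ValueError(
                f"gamma must be >= 2 (submodularity guarantee), got {self.gamma}"
            )
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.epsilon_refinements < 0:
            raise ValueError("epsilon_refinements must be >= 0")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")
        if self.presmooth_sigma < 0:
            raise ValueError("presmooth_sigma must be >= 0")
        if self.block_size < 2:
            raise ValueError(f"block_size must be >= 2, got {self.block_size}")
        if self.n_levels < 1:
            raise ValueError(f"n_levels must be >= 1, got {self.n_levels}")
        if self.max_sweeps_per_level < 0:
            raise ValueError("max_sweeps_per_level must be >= 0")
        if self.metric not in ("pcc", "ssd"):
            raise ValueError(f"metric must be 'pcc' or 'ssd', got {self.metric!r}")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")


@dataclass
class MoveTerms:
    """Unary and pairwise energy tables for one candidate move on one block.

    ``voxels`` lists the block's voxel coordinates (n, 3). ``unary`` is the
    (n, 2) data-term table phi_v(l). ``pairs``/``pairwise_inner`` hold the
    in-block 6-neighbor pairs (indices into ``voxels``) and their (m, 4)
    tables ordered [phi(0,0), phi(0,1), phi(1,0), phi(1,1)], already weighted
    by alpha. ``boundary_index``/``pairwise_boundary`` hold pairs with the
    outside endpoint frozen at label 0: a (k,) inside-voxel index and the
    (k, 2) table [phi(0,0), phi(1,0)].
    """

    voxels: np.ndarray
    unary: np.ndarray
    pairs: np.ndarray
    pairwise_inner: np.ndarray
    boundary_index: np.ndarray
    pairwise_boundary: np.ndarray
    delta: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def submodularity_violation(self) -> float:
        """Max of phi(0,0)+phi(1,1)-phi(0,1)-phi(1,0) over inner pairs (<= 0 iff submodular)."""
        if len(self.pairwise_inner) == 0:
            return 0.0
        t = self.pairwise_inner
        return float(np.max(t[:, 0] + t[:, 3] - t[:, 1] - t[:, 2]))


def window_offsets(radius: int) -> np.ndarray:
    """Integer offsets of the spherical window: all o with ||o||_2 <= radius."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid[np.einsum("ij,ij->i", grid, grid) <= r * r]


def pcc(patch_a, patch_b) -> float:
    """Pearson's correlation coefficient between two equal-length patches.

    Returns 0 if either patch has zero variance (flat patches carry no
    linear-correlation evidence).
    """
    a = np.asarray(patch_a, dtype=np.float64).ravel()
    b = np.asarray(patch_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"patch lengths differ: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("patches must contain at least 2 samples")
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va <= 0.0 or vb <= 0.0:
        return 0.0
    return float(np.clip((da @ db) / np.sqrt(va * vb), -1.0, 1.0))


@njit(cache=True)
def _pcc_terms_kernel(tdata, sdata, voxels, disp, offsets, out):  # pragma: no cover - numba
    """Windowed-PCC data term, fused: window gather, trilinear source
    sampling (border-replicated), and one-pass correlation sums per voxel.

    Windows are truncated at the target border; the source patch is the whole
    window translated rigidly by the center displacement. Zero-variance
    patches (relative to their magnitude) give PCC = 0, data term 0.5.
    """
    nx, ny, nz = tdata.shape
    K = offsets.shape[0]
    for idx in range(voxels.shape[0]):
        i = voxels[idx, 0]
        j = voxels[idx, 1]
        k = voxels[idx, 2]
        dx = disp[idx, 0]
        dy = disp[idx, 1]
        dz = disp[idx, 2]
        m = 0.0
        st = ss = stt = sss = sts = 0.0
        for o in range(K):
            wi = i + offsets[o, 0]
            wj = j + offsets[o, 1]
            wk = k + offsets[o, 2]
            if wi < 0 or wi >= nx or wj < 0 or wj >= ny or wk < 0 or wk >= nz:
                continue
            tv = tdata[wi, wj, wk]
            # trilinear sample of the source at the displaced window point
            x = wi + dx
            y = wj + dy
            z = wk + dz
            if x < 0.0:
                x = 0.0
            elif x > nx - 1:
                x = float(nx - 1)
            if y < 0.0:
                y = 0.0
            elif y > ny - 1:
                y = float(ny - 1)
            if z < 0.0:
                z = 0.0
            elif z > nz - 1:
                z = float(nz - 1)
            x0 = int(x)
            y0 = int(y)
            z0 = int(z)
            x1 = x0 + 1 if x0 + 1 < nx else x0
            y1 = y0 + 1 if y0 + 1 < ny else y0
            z1 = z0 + 1 if z0 + 1 < nz else z0
            fx = x - x0
            fy = y - y0
            fz = z - z0
            sv = (
                (1 - fx) * ((1 - fy) * ((1 - fz) * sdata[x0, y0, z0] + fz * sdata[x0, y0, z1])
                            + fy * ((1 - fz) * sdata[x0, y1, z0] + fz * sdata[x0, y1, z1]))
                + fx * ((1 - fy) * ((1 - fz) * sdata[x1, y0, z0] + fz * sdata[x1, y0, z1])
                        + fy * ((1 - fz) * sdata[x1, y1, z0] + fz * sdata[x1, y1, z1]))
            )
            m += 1.0
            st += tv
            ss += sv
            stt += tv * tv
            sss += sv * sv
            sts += tv * sv
        vt = stt - st * st / m
        vs = sss - ss * ss / m
        cov = sts - st * ss / m
        if vt <= 1e-12 * stt or vs <= 1e-12 * sss or vt <= 0.0 or vs <= 0.0:
            rho = 0.0
        else:
            rho = cov / np.sqrt(vt * vs)
            if rho > 1.0:
                rho = 1.0
            elif rho < -1.0:
                rho = -1.0
        out[idx] = 0.5 * (1.0 - rho)


def _data_terms(
    target: Volume,
    source: Volume,
    voxels: np.ndarray,
    disp: np.ndarray,
    cfg: RegistrationConfig,
    offsets: np.ndarray | None = None,
) -> np.ndarray:
    """Data term for each voxel in ``voxels`` given per-voxel displacement ``disp``.

    PCC metric: window positions on the target grid are truncated at the
    image border; the source patch is the whole window translated rigidly by
    the center displacement (border-replicated sampling).
    """
    voxels = np.ascontiguousarray(np.asarray(voxels, dtype=np.int64))
    disp = np.ascontiguousarray(np.asarray(disp, dtype=np.float64))
    if cfg.metric == "ssd":
        t_center = target.data[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
        pts = voxels + disp
        s_center = map_coordinates(
            source.data, pts.T, order=1, mode="nearest", prefilter=False
        )
        return (t_center - s_center) ** 2
    if offsets is None:
        offsets = window_offsets(cfg.radius)
    out = np.empty(len(voxels), dtype=np.float64)
    _pcc_terms_kernel(
        target.data, source.data, voxels, disp,
        np.ascontiguousarray(offsets, dtype=np.int64), out,
    )
    return out


def data_term_voxel(
    target: Volume, source: Volume, v, disp, cfg: RegistrationConfig
) -> float:
    """Data term at a single voxel ``v`` for a candidate displacement ``disp``."""
    out = _data_terms(
        target, source, np.asarray(v).reshape(1, 3), np.asarray(disp, float).reshape(1, 3), cfg
    )
    return float(out[0])


def regularizer_pair(uv, uw, gamma: float) -> float:
    """Diffusion penalty ||u(v) - u(w)||^gamma for one neighbor pair."""
    if gamma < 2:
        raise ValueError(f"gamma must be >= 2, got {gamma}")
    d = np.asarray(uv, dtype=np.float64) - np.asarray(uw, dtype=np.float64)
    return float(np.linalg.norm(d) ** gamma)


def binary_term(uv, uw, delta, labels, gamma: float) -> float:
    """Pairwise move energy ||(u(v) + l_v delta) - (u(w) + l_w delta)||^gamma."""
    lv, lw = labels
    uv = np.asarray(uv, dtype=np.float64)
    uw = np.asarray(uw, dtype=np.float64)
    delta = np.asarray(delta, dtype=np.float64)
    return regularizer_pair(uv + lv * delta, uw + lw * delta, gamma)


def _norm_pow(d: np.ndarray, gamma: float) -> np.ndarray:
    sq = np.einsum("ij,ij->i", d, d)
    if gamma == 2.0:
        return sq
    return sq ** (gamma / 2.0)


def _check_delta(delta, cfg: RegistrationConfig) -> np.ndarray:
    delta = np.asarray(delta, dtype=np.float64)
    nz = np.flatnonzero(delta)
    if len(nz) != 1 or abs(abs(delta[nz[0]]) - cfg.epsilon) > 1e-12:
        raise ValueError(
            f"move step must be +/- epsilon along one axis, got {delta} (epsilon={cfg.epsilon})"
        )
    return delta


def build_move_terms(
    target: Volume,
    source: Volume,
    u: DisplacementField,
    block: tuple[slice, slice, slice],
    delta,
    cfg: RegistrationConfig,
    offsets: np.ndarray | None = None,
    unary: np.ndarray | None = None,
) -> MoveTerms:
    """Assemble the unary/pairwise tables for one candidate move on one block.

    Unary: data term with the source sampled at v + u(v) + l*delta, for
    l in {0, 1}. Pairwise: the move form of the diffusion penalty, weighted
    by alpha, over in-block 6-neighbor pairs; pairs crossing the block
    boundary keep the outside endpoint at label 0 and contribute a
    unary-like table on the inside endpoint.

    ``unary`` may carry a precomputed (n, 2) data-term table (the sweep loop
    evaluates both labels for the whole volume at once and slices per block);
    when omitted it is computed here, with identical arithmetic.
    """
    delta = _check_delta(delta, cfg)
    shape = u.shape
    ranges = [np.arange(s.start, s.stop, dtype=np.int64) for s in block]
    nx, ny, nz = (len(r) for r in ranges)
    vox = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    uv = u.vectors[block].reshape(-1, 3)

    if unary is None:
        unary = np.empty((len(vox), 2), dtype=np.float64)
        unary[:, 0] = _data_terms(target, source, vox, uv, cfg, offsets)
        unary[:, 1] = _data_terms(target, source, vox, uv + delta, cfg, offsets)
    else:
        unary = np.asarray(unary, dtype=np.float64)
        if unary.shape != (len(vox), 2):
            raise ValueError(f"precomputed unary has shape {unary.shape}, want {(len(vox), 2)}")

    lin = np.arange(len(vox)).reshape(nx, ny, nz)
    pair_idx = []
    for ax, n in enumerate((nx, ny, nz)):
        if n < 2:
            continue
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, n - 1)
        hi[ax] = slice(1, n)
        pair_idx.append(
            np.stack([lin[tuple(lo)].ravel(), lin[tuple(hi)].ravel()], axis=1)
        )
    pairs = (
        np.concatenate(pair_idx, axis=0) if pair_idx else np.empty((0, 2), dtype=np.int64)
    )
    du = uv[pairs[:, 0]] - uv[pairs[:, 1]]
    a00 = cfg.alpha * _norm_pow(du, cfg.gamma)  # == phi(1,1): delta cancels
    a01 = cfg.alpha * _norm_pow(du - delta[None, :], cfg.gamma)
    a10 = cfg.alpha * _norm_pow(du + delta[None, :], cfg.gamma)
    pairwise_inner = np.stack([a00, a01, a10, a00], axis=1)

    # Boundary pairs: inside voxel v on a block face, neighbor w outside the
    # block but inside the grid; w's label is frozen at 0 (its current u).
    b_idx = []
    b_terms = []
    dims = (nx, ny, nz)
    for ax in range(3):
        for sign in (-1, 1):
            face = [slice(None)] * 3
            face[ax] = slice(0, 1) if sign < 0 else slice(dims[ax] - 1, dims[ax])
            inside = lin[tuple(face)].ravel()
            w = vox[inside] + sign * _AXES[ax]
            ok = (w[:, ax] >= 0) & (w[:, ax] < shape[ax])
            # exclude neighbors that are still inside the block
            in_block = (w[:, ax] >= block[ax].start) & (w[:, ax] < block[ax].stop)
            ok &= ~in_block
            if not np.any(ok):
                continue
            inside = inside[ok]
            w = w[ok]
            uw = u.vectors[w[:, 0], w[:, 1], w[:, 2]]
            dub = uv[inside] - uw
            t0 = cfg.alpha * _norm_pow(dub, cfg.gamma)
            t1 = cfg.alpha * _norm_pow(dub + delta[None, :], cfg.gamma)
            b_idx.append(inside)
            b_terms.append(np.stack([t0, t1], axis=1))
    boundary_index = (
        np.concatenate(b_idx) if b_idx else np.empty((0,), dtype=np.int64)
    )
    pairwise_boundary = (
        np.concatenate(b_terms, axis=0) if b_terms else np.empty((0, 2), dtype=np.float64)
    )
    return MoveTerms(
        voxels=vox,
        unary=unary,
        pairs=pairs,
        pairwise_inner=pairwise_inner,
        boundary_index=boundary_index,
        pairwise_boundary=pairwise_boundary,
        delta=delta.copy(),
    )


def move_energy(terms: MoveTerms, labels: np.ndarray) -> float:
    """Energy of a labeling under the move tables (block + boundary restriction)."""
    labels = np.asarray(labels, dtype=np.int64)
    e = float(terms.unary[np.arange(len(labels)), labels].sum())
    if len(terms.pairs):
        col = 2 * labels[terms.pairs[:, 0]] + labels[terms.pairs[:, 1]]
        e += float(terms.pairwise_inner[np.arange(len(col)), col].sum())
    if len(terms.boundary_index):
        e += float(
            terms.pairwise_boundary[
                np.arange(len(terms.boundary_index)), labels[terms.boundary_index]
            ].sum()
        )
    return e


def regularizer_total(u: DisplacementField, gamma: float) -> float:
    """Unweighted diffusion penalty summed over all 6-neighbor pairs."""
    shape = u.shape
    reg = 0.0
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, shape[ax] - 1)
        hi[ax] = slice(1, shape[ax])
        d = (u.vectors[tuple(lo)] - u.vectors[tuple(hi)]).reshape(-1, 3)
        reg += float(_norm_pow(d, gamma).sum())
    return reg


def total_energy(
    target: Volume,
    source: Volume,
    u: DisplacementField,
    cfg: RegistrationConfig,
    offsets: np.ndarray | None = None,
) -> float:
    """Global objective f(u) = sum_v D_v(u(v)) + alpha * sum_pairs ||u(v)-u(w)||^gamma."""
    shape = u.shape
    vox = np.stack(
        np.meshgrid(*(np.arange(n, dtype=np.int64) for n in shape), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    data = _data_terms(target, source, vox, u.vectors.reshape(-1, 3), cfg, offsets).sum()
    return float(data + cfg.alpha * regularizer_total(u, cfg.gamma))
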