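"""Exact binary minimization of submodular unary+pairwise energies via s-t min cut.

The energy E(L) = sum_v theta_v(L_v) + sum_(v,w) theta_vw(L_v, L_w) with every
pairwise table submodular (theta(0,0) + theta(1,1) <= theta(0,1) + theta(1,0))
is reduced to a max-flow problem with the standard construction: each pairwise
table is rewritten as a constant, two unary addends, and a single non-negative
interaction on the (L_v=0, L_w=1) configuration, which becomes one arc of the
flow network. A minimum s-t cut then yields a global minimizer; the source
side of the cut is the set of label-1 nodes.

The max flow itself is computed by a Dinic solver compiled with numba that
works directly on float64 capacities, so the cut — and hence the labeling —
is exact up to floating-point arithmetic, with no capacity quantization.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["solve_binary_submodular", "SubmodularityError"]

_SUBMOD_TOL = 1e-9


class SubmodularityError(ValueError):
    """A pairwise table violates submodularity; the cut would not be exact."""


@njit(cache=True)
def _dinic(n_nodes, head, nxt, arc_to, cap, s, t):  # pragma: no cover - numba
    """Dinic max flow on a linked-list arc representation.

    Arcs come in pairs: arc a and its reverse a^1. ``cap`` is modified in
    place to the residual capacities. Termination with real capacities is
    guaranteed because every augmentation zeroes its bottleneck arc exactly.
    """
    level = np.empty(n_nodes, dtype=np.int64)
    queue = np.empty(n_nodes, dtype=np.int64)
    it = np.empty(n_nodes, dtype=np.int64)
    # stack of nodes on the current DFS path and the arc taken from each
    path_arc = np.empty(n_nodes + 1, dtype=np.int64)
    total = 0.0
    while True:
        # BFS phase: level graph over arcs with positive residual
        level[:] = -1
        level[s] = 0
        queue[0] = s
        qh, qt = 0, 1
        while qh < qt:
            v = queue[qh]
            qh += 1
            a = head[v]
            while a != -1:
                w = arc_to[a]
                if cap[a] > 0.0 and level[w] < 0:
                    level[w] = level[v] + 1
                    queue[qt] = w
                    qt += 1
                a = nxt[a]
        if level[t] < 0:
            return total
        # blocking flow via iterative DFS with current-arc pointers
        it[:] = head
        depth = 0
        node = s
        while True:
            if node == t:
                # bottleneck along path_arc[0:depth]
                bn = np.inf
                for i in range(depth):
                    if cap[path_arc[i]] < bn:
                        bn = cap[path_arc[i]]
                for i in range(depth):
                    a = path_arc[i]
                    cap[a] -= bn
                    cap[a ^ 1] += bn
                total += bn
                # retreat to the first saturated arc on the path
                for i in range(depth):
                    if cap[path_arc[i]] <= 0.0:
                        depth = i
                        break
                node = s if depth == 0 else arc_to[path_arc[depth - 1]]
                continue
            a = it[node]
            advanced = False
            while a != -1:
                w = arc_to[a]
                if cap[a] > 0.0 and level[w] == level[node] + 1:
                    path_arc[depth] = a
                    depth += 1
                    node = w
                    advanced = True
                    break
                a = nxt[a]
                it[node] = a
            if advanced:
                continue
            # dead end: remove node from the level graph and retreat
            level[node] = -1
            if node == s:
                break
            depth -= 1
            node = s if depth == 0 else arc_to[path_arc[depth - 1]]


@njit(cache=True)
def _reachable(n_nodes, head, nxt, arc_to, cap, s):  # pragma: no cover - numba
    seen = np.zeros(n_nodes, dtype=np.int8)
    queue = np.empty(n_nodes, dtype=np.int64)
    seen[s] = 1
    queue[0] = s
    qh, qt = 0, 1
    while qh < qt:
        v = queue[qh]
        qh += 1
        a = head[v]
        while a != -1:
            w = arc_to[a]
            if cap[a] > 0.0 and seen[w] == 0:
                seen[w] = 1
                queue[qt] = w
                qt += 1
            a = nxt[a]
    return seen


@njit(cache=True)
def _link_arcs(n_nodes, tail_of):  # pragma: no cover - numba
    head = np.full(n_nodes, -1, dtype=np.int64)
    nxt = np.empty(len(tail_of), dtype=np.int64)
    for a in range(len(tail_of)):
        v = tail_of[a]
        nxt[a] = head[v]
        head[v] = a
    return head, nxt


def _build_graph(n_nodes: int, tails: np.ndarray, heads_: np.ndarray, caps: np.ndarray):
    """Paired forward/reverse arc lists with linked-list adjacency."""
    m = len(tails)
    arc_to = np.empty(2 * m, dtype=np.int64)
    cap = np.zeros(2 * m, dtype=np.float64)
    arc_to[0::2] = heads_
    arc_to[1::2] = tails
    cap[0::2] = caps
    tail_of = np.empty(2 * m, dtype=np.int64)
    tail_of[0::2] = tails
    tail_of[1::2] = heads_
    head, nxt = _link_arcs(n_nodes, tail_of)
    return head, nxt, arc_to, cap


def solve_binary_submodular(
    unary: np.ndarray, pairs: np.ndarray, pairwise: np.ndarray
) -> np.ndarray:
    """Globally minimize a submodular binary labeling energy.

    Parameters
    ----------
    unary : (n, 2) float array
        theta_v(0), theta_v(1) per node.
    pairs : (m, 2) int array
        Node index pairs (v, w).
    pairwise : (m, 4) float array
        Tables ordered [theta(0,0), theta(0,1), theta(1,0), theta(1,1)].

    Returns
    -------
    (n,) int8 array of labels in {0, 1} attaining the global minimum.
    """
    unary = np.asarray(unary, dtype=np.float64)
    if not np.all(np.isfinite(unary)):
        raise ValueError("non-finite unary terms")
    n = unary.shape[0]
    theta0 = unary[:, 0].copy()
    theta1 = unary[:, 1].copy()

    if len(pairs):
        pairs = np.asarray(pairs, dtype=np.int64)
        pw = np.asarray(pairwise, dtype=np.float64)
        if not np.all(np.isfinite(pw)):
            raise ValueError("non-finite pairwise terms")
        A, B, C, D = pw[:, 0], pw[:, 1], pw[:, 2], pw[:, 3]
        beta = B + C - A - D
        worst = float(beta.min())
        if worst < -_SUBMOD_TOL:
            bad = int(np.argmin(beta))
            raise SubmodularityError(
                f"pair {tuple(pairs[bad])} violates submodularity by {-worst:.3e}"
            )
        beta = np.maximum(beta, 0.0)
        # E = const + (C-A) L_v + (D-C) L_w + beta (1-L_v) L_w
        np.add.at(theta1, pairs[:, 0], C - A)
        np.add.at(theta1, pairs[:, 1], D - C)
    else:
        beta = np.empty(0)
        pairs = np.empty((0, 2), dtype=np.int64)

    # Normalize unaries to non-negative terminal capacities.
    m = np.minimum(theta0, theta1)
    cap_s = theta0 - m  # s -> v, cut when L_v = 0 (v on the sink side)
    cap_t = theta1 - m  # v -> t, cut when L_v = 1 (v on the source side)

    s, t = n, n + 1
    tails = np.concatenate([np.full(n, s), np.arange(n), pairs[:, 1]])
    heads_ = np.concatenate([np.arange(n), np.full(n, t), pairs[:, 0]])
    caps = np.concatenate([cap_s, cap_t, beta])
    keep = caps > 0.0
    head, nxt, arc_to, cap = _build_graph(n + 2, tails[keep], heads_[keep], caps[keep])

    _dinic(n + 2, head, nxt, arc_to, cap, s, t)
    seen = _reachable(n + 2, head, nxt, arc_to, cap, s)
    return seen[:n].astype(np.int8)
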