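"""Saitou–Nei neighbor joining from a distance matrix.

Exact on additive matrices. Negative branch-length estimates are clamped
to zero with the deficit shifted to the sibling edge (the usual NJ
post-hoc fix), so output lengths are always non-negative.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .trees import Node, Tree

__all__ = ["nj_tree"]


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb = max(lb + la, 0.0)
        la = 0.0
    if lb < 0:
        la = max(la + lb, 0.0)
        lb = 0.0
    return la, lb


def nj_tree(distances: np.ndarray, labels: Sequence[str]) -> Tree:
    """Agglomerate ``labels`` into an unrooted tree (degree-3 root node).

    ``distances`` must be a symmetric, zero-diagonal matrix with
    ``n >= 3`` rows matching ``labels``.
    """
    d = np.asarray(distances, dtype=float).copy()
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix / labels shape mismatch")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes: list[Node] = [Node(lbl) for lbl in labels]
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    la, lb = _clamp_pair(la, lb)
    lb, lc = _clamp_pair(lb, lc)
    la, lc = _clamp_pair(la, lc)
    root = Node()
    for node, length in ((a, la), (b, lb), (c, lc)):
        node.length = length
        root.add_child(node)
    return Tree(root)
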