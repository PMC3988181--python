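"""Module detection by modularity maximization.

The network is partitioned into co-expression modules with a
Qcut-style modularity optimizer: recursive spectral bisection on the
(generalized) modularity matrix ``B = A - k k^T / 2m`` using the leading
eigenvector's sign pattern, each candidate split refined by
Kernighan-Lin-style single-node flips, recursing while the best split still
raises modularity by at least ``min_delta_q``; a final global refinement
pass moves single nodes between modules to a local maximum of Q.  Connected
components are partitioned independently, and a component that no split
improves stays a single module, so modules can be as small as two nodes.

The statistical-significance stopping rule of the original Qcut algorithm is
approximated here by the ``min_delta_q`` threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg

__all__ = ["ModulePartition", "modularity", "detect_modules", "module_summary"]

_FLIP_TOL = 1e-12


@dataclass
class ModulePartition:
    """Disjoint modules over network nodes plus an unassigned remainder.

    Module ids are contiguous integers from 1, ordered by decreasing module
    size (ties broken by smallest member id), so module 1 is always the
    largest.  ``q`` is the Newman modularity of the assignment.
    """

    assignment: dict[str, int]
    q: float
    unassigned: set[str] = field(default_factory=set)

    def labels(self) -> pd.Series:
        return pd.Series(self.assignment, name="module_id").sort_index()

    def members(self, module_id: int) -> list[str]:
        return sorted(n for n, c in self.assignment.items() if c == module_id)

    def module_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def to_frame(self) -> pd.DataFrame:
        frame = self.labels().rename_axis("gene_id").reset_index()
        if self.unassigned:
            extra = pd.DataFrame({"gene_id": sorted(self.unassigned), "module_id": 0})
            frame = pd.concat([frame, extra], ignore_index=True)
        return frame


def _as_graph(net) -> nx.Graph:
    return net if isinstance(net, nx.Graph) else net.to_graph()


def modularity(net, partition: dict) -> float:
    """Newman modularity Q of a node -> module-id assignment.

    ``Q = sum_c [ L_c/m - (D_c/2m)^2 ]`` with ``L_c`` the intra-module edge
    count and ``D_c`` the module degree sum — the pairwise form
    ``(1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j)`` summed in module
    blocks.  Unweighted adjacency (edges were thresholded upstream).
    """
    g = _as_graph(net)
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for a network without edges")
    unknown = set(partition) - set(g.nodes)
    if unknown:
        raise KeyError(f"partition mentions nodes outside the network: {sorted(unknown)[:5]}")
    q = 0.0
    modules: dict[int, set] = {}
    for node, c in partition.items():
        modules.setdefault(c, set()).add(node)
    for members in modules.values():
        l_c = sum(1 for u, v in g.edges(members) if u in members and v in members)
        d_c = sum(g.degree(v) for v in members)
        q += l_c / m - (d_c / (2 * m)) ** 2
    return q


def _leading_split(bg: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sign vector of the leading eigenvector of a (sub)modularity matrix."""
    n = bg.shape[0]
    _w, vec = linalg.eigh(bg, subset_by_index=[n - 1, n - 1])
    u = vec[:, 0]
    s = np.sign(u)
    zeros = s == 0
    if zeros.any():  # rare ties: seeded assignment
        s[zeros] = rng.choice([-1.0, 1.0], size=int(zeros.sum()))
    return s


def _refine_split(bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin-style single-node flips maximizing s^T B s."""
    n = len(s)
    bs = bg @ s
    for _ in range(10 * n):
        gains = -4.0 * s * bs + 4.0 * np.diag(bg)
        order = np.argsort(-gains)
        moved = False
        for i in order:
            if gains[i] <= _FLIP_TOL:
                break
            side = s[i]
            if np.sum(s == side) == 1:  # would empty one side
                continue
            s[i] = -side
            bs += 2.0 * s[i] * bg[:, i]
            moved = True
            break
        if not moved:
            break
    return s


def detect_modules(net, min_delta_q: float = 1e-6, seed: int = 0) -> ModulePartition:
    """Partition a network into modules by recursive spectral bisection.

    Deterministic for a fixed seed; the seed only breaks ties (zero entries
    of the leading eigenvector).
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("cannot partition a network without edges")
    a = np.zeros((n, n))
    for u, v in g.edges():
        a[index[u], index[v]] = 1.0
        a[index[v], index[u]] = 1.0
    k = a.sum(axis=1)
    rng = np.random.default_rng(seed)

    def generalized_b(group: np.ndarray) -> np.ndarray:
        bg = a[np.ix_(group, group)] - np.outer(k[group], k[group]) / (2 * m)
        bg[np.diag_indices_from(bg)] -= bg.sum(axis=1)
        return bg

    final: list[np.ndarray] = []
    stack: list[np.ndarray] = [
        np.array(sorted(index[v] for v in comp)) for comp in nx.connected_components(g)
    ]
    stack.sort(key=lambda grp: grp[0])
    while stack:
        group = stack.pop()
        if len(group) < 2:
            final.append(group)
            continue
        bg = generalized_b(group)
        s = _refine_split(bg, _leading_split(bg, rng))
        delta_q = float(s @ bg @ s) / (4 * m)
        left, right = group[s > 0], group[s < 0]
        if delta_q >= min_delta_q and len(left) and len(right):
            stack.append(left)
            stack.append(right)
        else:
            final.append(group)

    comm = np.empty(n, dtype=int)
    for cid, group in enumerate(final):
        comm[group] = cid
    comm = _global_refine(a, k, m, comm)

    # relabel by decreasing size, ties by smallest member index
    ids, sizes = np.unique(comm, return_counts=True)
    first_member = [int(np.flatnonzero(comm == c).min()) for c in ids]
    order = sorted(range(len(ids)), key=lambda j: (-sizes[j], first_member[j]))
    relabel = {ids[j]: rank + 1 for rank, j in enumerate(order)}
    assignment = {nodes[i]: relabel[comm[i]] for i in range(n)}
    q = modularity(g, assignment)
    return ModulePartition(assignment=assignment, q=q, unassigned=set())


def _global_refine(a: np.ndarray, k: np.ndarray, m: int, comm: np.ndarray,
                   max_passes: int = 100) -> np.ndarray:
    """Single-node moves between existing modules to a local Q maximum."""
    comm = comm.copy()
    n = len(comm)
    n_comm = comm.max() + 1
    d_tot = np.zeros(n_comm)
    for i in range(n):
        d_tot[comm[i]] += k[i]
    neighbors = [np.flatnonzero(a[i]) for i in range(n)]
    for _ in range(max_passes):
        moved = False
        for v in range(n):
            cur = comm[v]
            nb = neighbors[v]
            if len(nb) == 0:
                continue
            links = np.bincount(comm[nb], minlength=n_comm).astype(float)
            base = links[cur]
            delta = (links - base) / m - k[v] * (d_tot - (d_tot[cur] - k[v]) + np.where(
                np.arange(n_comm) == cur, -k[v], 0.0)) / (2 * m**2)
            delta[cur] = 0.0
            best = int(np.argmax(delta))
            if delta[best] > _FLIP_TOL:
                d_tot[cur] -= k[v]
                d_tot[best] += k[v]
                comm[v] = best
                moved = True
        if not moved:
            break
    # drop emptied module ids
    ids = np.unique(comm)
    remap = {c: i for i, c in enumerate(ids)}
    return np.array([remap[c] for c in comm])


def module_summary(partition: ModulePartition, net) -> pd.DataFrame:
    """Per-module gene and intra-module edge counts, sorted by module id."""
    g = _as_graph(net)
    rows = []
    for cid in partition.module_ids():
        members = set(partition.members(cid))
        n_edges = sum(1 for u, v in g.edges(members) if u in members and v in members)
        rows.append((cid, len(members), n_edges))
    return pd.DataFrame(rows, columns=["module_id", "n_genes", "n_edges"])
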