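"""Weighted co-expression network construction.

Redundancy-aware sample weights, weighted Pearson correlation, the density
scan used to pick the correlation cutoff, and assembly of the thresholded
network.

Sample weighting down-weights near-duplicate hybridizations: with
``r_st`` the Pearson correlation between sample columns ``s`` and ``t``,

    w_s = 1 / sum_t max(0, r_st)^2        (sum includes t = s, r_ss = 1)

so ``d`` exact copies of an otherwise uncorrelated sample each receive
weight ``1/d`` and an unrelated sample keeps weight 1.  Gene-gene
similarity is the weighted Pearson correlation under these weights, and an
edge is kept when the (positive) correlation reaches the cutoff.  The cutoff
itself is chosen from the density-versus-cutoff curve: density over the
retained (degree >= 1) genes first falls, reaches an interior minimum, then
rises as only tightly co-expressed cliques survive; the working cutoff is
the argmin plus a small offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "EmptyNetworkError",
    "CoexpressionNetwork",
    "sample_weights",
    "weighted_pcc",
    "weighted_corr_matrix",
    "density_scan",
    "select_cutoff",
    "build_network",
]

DEFAULT_CUTOFF_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


class EmptyNetworkError(RuntimeError):
    """No gene pair reaches the correlation cutoff."""


@dataclass
class CoexpressionNetwork:
    """Undirected co-expression network: genes with at least one retained edge.

    ``edges`` has columns ``gene_a``, ``gene_b``, ``r`` with
    ``gene_a < gene_b`` lexicographically and rows sorted canonically.
    """

    nodes: list[str]
    edges: pd.DataFrame
    cutoff: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(
            self.edges.itertuples(index=False, name=None), weight="r"
        )
        return g

    def write_edges(self, path) -> None:
        out = self.edges.copy()
        out["r"] = out["r"].map(lambda v: f"{v:.6f}")
        out.to_csv(path, sep="\t", index=False)


def sample_weights(x: pd.DataFrame) -> pd.Series:
    """Redundancy-penalizing weight per sample column (in (0, 1])."""
    if x.shape[1] < 3:
        raise ValueError("sample weighting needs at least 3 samples")
    vals = x.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vals, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance sample column(s); "
            "their correlations are treated as 0 (weight 1)",
            stacklevel=2,
        )
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    denom = (np.clip(r, 0.0, None) ** 2).sum(axis=1)
    w = np.where(degenerate, 1.0, 1.0 / np.where(denom > 0, denom, 1.0))
    return pd.Series(w, index=x.columns, name="weight")


def weighted_pcc(x_g: np.ndarray, x_h: np.ndarray, w: np.ndarray | pd.Series) -> float:
    """Weighted Pearson correlation of two expression profiles."""
    w = np.asarray(w, dtype=float)
    x_g = np.asarray(x_g, dtype=float)
    x_h = np.asarray(x_h, dtype=float)
    if not (len(x_g) == len(x_h) == len(w)):
        raise ValueError("profiles and weights must be aligned")
    sw = w.sum()
    dg = x_g - (w @ x_g) / sw
    dh = x_h - (w @ x_h) / sw
    vg = w @ dg**2
    vh = w @ dh**2
    if vg <= 0 or vh <= 0:
        raise ValueError("zero weighted variance; correlation undefined")
    return float(np.clip((w @ (dg * dh)) / np.sqrt(vg * vh), -1.0, 1.0))


def weighted_corr_matrix(x: pd.DataFrame, w: pd.Series) -> pd.DataFrame:
    """Gene x gene weighted Pearson correlation matrix.

    Genes with zero weighted variance get NaN rows/columns (skipped upstream
    with a warning).
    """
    vals = x.to_numpy(dtype=float)
    wv = w.reindex(x.columns).to_numpy(dtype=float)
    sw = wv.sum()
    centered = vals - (vals @ wv)[:, None] / sw
    cov = (centered * wv) @ centered.T
    var = np.diag(cov).copy()
    bad = var <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} gene(s) with zero weighted variance skipped", stacklevel=2
        )
        var[bad] = np.nan
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore"):
        r = np.clip(cov / denom, -1.0, 1.0)
    return pd.DataFrame(r, index=x.index, columns=x.index)


def _edge_values(corr: pd.DataFrame, use_abs: bool) -> np.ndarray:
    iu = np.triu_indices(len(corr), k=1)
    vals = corr.to_numpy()[iu]
    return np.abs(vals) if use_abs else vals


def density_scan(
    x: pd.DataFrame,
    w: pd.Series,
    cutoffs: np.ndarray = DEFAULT_CUTOFF_GRID,
    *,
    corr: pd.DataFrame | None = None,
    use_abs: bool = False,
) -> pd.DataFrame:
    """Network density over retained nodes at each correlation cutoff.

    Density at cutoff ``c`` is ``2 E_c / (N_c (N_c - 1))`` where ``N_c``
    counts genes with at least one retained edge (0 when ``N_c < 2``).
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    if cutoffs.size == 0:
        raise ValueError("cutoff grid is empty")
    if not (np.all(np.diff(cutoffs) > 0) and cutoffs.min() > 0 and cutoffs.max() < 1):
        raise ValueError("cutoffs must be strictly increasing within (0, 1)")
    if corr is None:
        corr = weighted_corr_matrix(x, w)
    mat = np.abs(corr.to_numpy()) if use_abs else corr.to_numpy()
    mat = np.nan_to_num(mat, nan=-np.inf)
    np.fill_diagonal(mat, -np.inf)
    rows = []
    for c in cutoffs:
        adj = mat >= c
        deg = adj.sum(axis=1)
        n = int((deg > 0).sum())
        e = int(deg.sum()) // 2
        density = 2 * e / (n * (n - 1)) if n >= 2 else 0.0
        rows.append((float(c), density, n, e))
    return pd.DataFrame(rows, columns=["cutoff", "density", "n_nodes", "n_edges"])


def select_cutoff(scan: pd.DataFrame, offset: float = 0.05) -> float:
    """Cutoff at the density minimum plus ``offset``, clipped to the grid max.

    Ties at the minimum resolve to the smallest such cutoff (logged).
    Cutoffs where fewer than 2 genes survive (density defined as 0 there)
    are not candidates for the minimum.
    """
    if scan.empty:
        raise ValueError("density scan is empty")
    scan = scan.sort_values("cutoff", ignore_index=True)
    if "n_nodes" in scan.columns:
        scan = scan[scan["n_nodes"] >= 2].reset_index(drop=True)
        if scan.empty:
            raise ValueError("no cutoff retains a non-degenerate network")
    dens = scan["density"].to_numpy()
    idx = int(np.argmin(dens))
    if (dens == dens[idx]).sum() > 1:
        warnings.warn("density minimum is tied; using the smallest such cutoff", stacklevel=2)
    chosen = scan["cutoff"].iloc[idx] + offset
    return float(min(chosen, scan["cutoff"].iloc[-1]))


def build_network(
    x: pd.DataFrame,
    w: pd.Series,
    cutoff: float,
    *,
    corr: pd.DataFrame | None = None,
    use_abs: bool = False,
) -> CoexpressionNetwork:
    """Threshold the weighted correlation matrix into a network.

    Edges connect gene pairs with (by default, positive) weighted PCC at or
    above ``cutoff``; genes with no retained edge are excluded.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    if corr is None:
        corr = weighted_corr_matrix(x, w)
    genes = np.asarray(corr.index)
    mat = np.abs(corr.to_numpy()) if use_abs else corr.to_numpy()
    mat = np.nan_to_num(mat, nan=-np.inf)
    ia, ib = np.triu_indices(len(genes), k=1)
    keep = mat[ia, ib] >= cutoff
    if not keep.any():
        raise EmptyNetworkError(f"no gene pair reaches cutoff {cutoff}")
    ga, gb = genes[ia[keep]], genes[ib[keep]]
    swap = ga > gb
    ga2 = np.where(swap, gb, ga)
    gb2 = np.where(swap, ga, gb)
    edges = pd.DataFrame(
        {"gene_a": ga2, "gene_b": gb2, "r": corr.to_numpy()[ia[keep], ib[keep]]}
    ).sort_values(["gene_a", "gene_b"], ignore_index=True)
    nodes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    return CoexpressionNetwork(nodes=nodes, edges=edges, cutoff=float(cutoff))
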