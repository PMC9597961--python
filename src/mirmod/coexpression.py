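"""WGCNA-style co-expression: soft-threshold adjacency, topological overlap,
module detection, and top-connected neighborhoods for candidate targets.

The network is unsigned by default (adjacency = |Pearson r| ** beta). Module
detection uses average-linkage hierarchical clustering on 1 - TOM with a
static cut height — a deterministic stand-in for dynamic tree cutting that
is sufficient for the downstream use here, extracting each candidate
target's most connected co-expressed genes. Clusters smaller than the
minimum module size (default 30 genes) are relabeled "grey".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

GREY = "grey"


@dataclass
class CoexpressionNetwork:
    genes: list[str]
    adjacency: np.ndarray
    tom_matrix: np.ndarray
    beta: int
    modules: pd.Series            # gene -> module label ("M1", ..., or "grey")


def adjacency(expr: pd.DataFrame, beta: int, signed: bool = False) -> np.ndarray:
    """|Pearson correlation| ** beta over genes (rows) x samples (columns).

    Zero-variance genes must be removed first (see :func:`drop_invariant`).
    With ``signed=True`` the WGCNA signed transform ((1 + r) / 2) ** beta is
    used instead.
    """
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        raise ValueError("zero-variance genes present; call drop_invariant first")
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def drop_invariant(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.to_numpy(dtype=float).std(axis=1)
    dropped = int((sd == 0).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} zero-variance genes from the network")
    return expr.loc[sd > 0]


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) vs log10 k regression over connectivity bins.

    Returns 0 when the slope is positive (not scale-free-like) or the
    connectivities are too degenerate to bin.
    """
    k = adj.sum(axis=0)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    bin_idx = np.digitize(k, edges[1:-1])
    mean_k, freq = [], []
    for b in range(n_bins):
        sel = bin_idx == b
        if sel.any():
            mean_k.append(k[sel].mean())
            freq.append(sel.sum() / k.size)
    if len(mean_k) < 3:
        return 0.0
    x = np.log10(mean_k)
    y = np.log10(freq)
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        return 0.0
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def pick_beta(expr: pd.DataFrame, candidates: range = range(1, 21),
              r2_target: float = 0.8, signed: bool = False) -> int:
    """Smallest power whose scale-free-topology fit reaches ``r2_target``.

    Falls back to 6 (with a warning) when no candidate qualifies.
    """
    for beta in candidates:
        if scale_free_fit(adjacency(expr, beta, signed=signed)) >= r2_target:
            return beta
    warnings.warn(
        f"no soft threshold in {candidates!r} reached scale-free fit {r2_target}; using 6")
    return 6


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    The diagonal is set to 1. Values stay within [0, 1] for adjacencies in
    [0, 1] with zero diagonal.
    """
    a = np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (shared + a) / denom
    np.fill_diagonal(t, 1.0)
    return t


def detect_modules(tom_matrix: np.ndarray, genes: list[str], min_size: int = 30,
                   cut_height: float = 0.25) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Clusters are cut at dissimilarity ``cut_height``; clusters below
    ``min_size`` become "grey". Module labels are assigned in decreasing
    size order (ties by smallest member gene id) so the labeling does not
    depend on input order.
    """
    n = len(genes)
    if tom_matrix.shape != (n, n):
        raise ValueError("TOM shape does not match gene list")
    if n < 2:
        return pd.Series([GREY] * n, index=genes)
    dissim = 1.0 - tom_matrix
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(np.maximum(dissim, 0.0), checks=False)
    Z = linkage(condensed, method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")

    labels = pd.Series(raw, index=genes)
    groups = []
    for cid, members in labels.groupby(labels).groups.items():
        groups.append((len(members), sorted(members)[0], cid, list(members)))
    groups.sort(key=lambda g: (-g[0], g[1]))
    out = pd.Series(GREY, index=genes, dtype=object)
    next_id = 1
    for size, _, _, members in groups:
        if size >= min_size:
            out[members] = f"M{next_id}"
            next_id += 1
    return out


@dataclass(frozen=True)
class Neighborhood:
    target: str
    neighbors: tuple[tuple[str, float], ...]   # (gene, TOM), descending


def top_neighbors(tom_matrix: np.ndarray, genes: list[str], targets: list[str],
                  k: int = 20) -> list[Neighborhood]:
    """The k genes most topologically overlapping each target.

    Sorted by TOM descending, ties broken by gene id; a target never lists
    itself.
    """
    index = {g: i for i, g in enumerate(genes)}
    missing = [t for t in targets if t not in index]
    if missing:
        raise KeyError(f"targets not in network: {missing[:5]}")
    out = []
    for target in targets:
        i = index[target]
        scored = sorted(
            ((genes[j], float(tom_matrix[i, j])) for j in range(len(genes)) if j != i),
            key=lambda gt: (-gt[1], gt[0]),
        )
        out.append(Neighborhood(target=target, neighbors=tuple(scored[:k])))
    return out


def build_network(expr: pd.DataFrame, beta: int | None = None, min_size: int = 30,
                  cut_height: float = 0.25, signed: bool = False) -> CoexpressionNetwork:
    """Adjacency -> TOM -> modules in one call; picks beta when not given."""
    expr = drop_invariant(expr)
    if beta is None:
        beta = pick_beta(expr, signed=signed)
    adj = adjacency(expr, beta, signed=signed)
    t = tom(adj)
    genes = list(expr.index)
    modules = detect_modules(t, genes, min_size=min_size, cut_height=cut_height)
    return CoexpressionNetwork(genes=genes, adjacency=adj, tom_matrix=t,
                               beta=beta, modules=modules)
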