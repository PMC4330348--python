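"""Signed weighted correlation network, topological overlap and tree cutting.

The adjacency uses the signed soft-threshold transform
``a_ij = ((1 + cor_ij) / 2) ** beta`` so that anticorrelated proteins get
connection strength near zero and only positive co-binding survives the
power. Topological overlap follows the classic unsigned formula applied to
the (already nonnegative) signed adjacency. Modules come from average-linkage
clustering of ``1 - TOM`` followed by a deterministic adaptive branch cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .ingest import RatioMatrix

logger = logging.getLogger(__name__)

GREY = "grey"

#: module colour vocabulary, assigned to modules by decreasing size
MODULE_COLORS: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
    "sienna", "yellowgreen", "skyblue3", "plum", "orangered", "mediumpurple",
)


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    protein_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class AdjacencyMatrix:
    values: np.ndarray
    protein_ids: list[str]
    beta: int = 15


@dataclass
class TOMatrix:
    values: np.ndarray
    protein_ids: list[str]

    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.values


@dataclass
class Dendrogram:
    """Average-linkage merge tree in scipy linkage format over protein leaves."""

    merges: np.ndarray          # (n-1, 4) scipy linkage matrix
    protein_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.protein_ids)

    def heights(self) -> np.ndarray:
        return self.merges[:, 2] if len(self.merges) else np.empty(0)

    def to_newick(self) -> str:
        """Newick export for inspection (branch lengths from merge heights)."""
        n = self.n_leaves
        if n == 1:
            return f"{self.protein_ids[0]};"
        height = {i: 0.0 for i in range(n)}
        text = {i: self.protein_ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            node = n + k
            text[node] = (
                f"({text[a]}:{h - height[a]:.6g},{text[b]}:{h - height[b]:.6g})"
            )
            height[node] = h
        return text[2 * n - 2] + ";"


@dataclass
class ModuleAssignment:
    """Protein -> module colour map; ``grey`` marks unassigned proteins."""

    labels: pd.Series
    min_module_size: int = 5

    def module_names(self, include_grey: bool = False) -> list[str]:
        names = [m for m in self.labels.unique() if m != GREY]
        # stable: decreasing size, then name
        sizes = self.labels.value_counts()
        names.sort(key=lambda m: (-sizes[m], m))
        if include_grey and (self.labels == GREY).any():
            names.append(GREY)
        return names

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def to_tsv(self, path) -> None:
        self.labels.rename("Module").rename_axis("ProteinID").to_frame().to_csv(
            path, sep="\t"
        )


def pairwise_correlation(matrix: RatioMatrix) -> CorrelationMatrix:
    """Pearson correlation between protein rows over all samples.

    Expects the zero-imputed matrix (imputed zeros participate, matching the
    network-construction convention). Constant rows have undefined
    correlation; they are removed with a logged warning.
    """
    values = matrix.values.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("pairwise_correlation expects an imputed (NaN-free) matrix")
    variances = values.var(axis=1)
    constant = variances == 0
    if constant.any():
        dropped = [pid for pid, c in zip(matrix.protein_ids, constant) if c]
        logger.warning(
            "pairwise_correlation: removing %d constant rows (%s%s)",
            len(dropped), ", ".join(dropped[:5]), "..." if len(dropped) > 5 else "",
        )
        values = values[~constant]
    ids = [pid for pid, c in zip(matrix.protein_ids, constant) if not c]
    cor = np.corrcoef(values)
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return CorrelationMatrix(values=cor, protein_ids=ids)


def signed_adjacency(cor: CorrelationMatrix, beta: int = 15) -> AdjacencyMatrix:
    """Soft-thresholded signed adjacency ``((1 + c) / 2) ** beta``, zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    adj = ((1.0 + cor.values) / 2.0) ** beta
    np.fill_diagonal(adj, 0.0)
    return AdjacencyMatrix(values=adj, protein_ids=list(cor.protein_ids), beta=beta)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit index of a connectivity distribution.

    Bins connectivity into ~``n_bins`` equal-occupancy bins (quantile edges),
    estimates the frequency density per bin, and regresses log10(density) on
    log10(mean connectivity). Returns ``(signed_r2, slope)`` where the fit
    index carries the opposite sign of the slope (a decaying power law scores
    positively). Degenerate inputs (fewer than 3 usable bins) return NaN.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[np.isfinite(k) & (k > 0)]
    if k.size < 4:
        return (float("nan"), float("nan"))
    edges = np.unique(np.quantile(k, np.linspace(0.0, 1.0, n_bins + 1)))
    if len(edges) < 4:
        return (float("nan"), float("nan"))
    counts, _ = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    bin_idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(widths) - 1)
    mean_k = np.full(len(widths), np.nan)
    for b in range(len(widths)):
        in_bin = bin_idx == b
        if in_bin.any():
            mean_k[b] = k[in_bin].mean()
    density = counts / (k.size * widths)
    usable = (counts > 0) & (density > 0) & np.isfinite(mean_k) & (mean_k > 0)
    if usable.sum() < 3:
        return (float("nan"), float("nan"))
    x = np.log10(mean_k[usable])
    y = np.log10(density[usable])
    slope, _intercept = np.polyfit(x, y, 1)
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return (float(-np.sign(slope) * r2), float(slope))


def pick_soft_threshold(
    matrix: RatioMatrix, candidates: list[int], n_bins: int = 10
) -> pd.DataFrame:
    """Scale-free fit and mean connectivity for candidate soft powers.

    The default pipeline records this table but always proceeds with beta=15.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    cor = pairwise_correlation(matrix)
    rows = []
    for beta in candidates:
        adj = signed_adjacency(cor, beta=beta)
        k = adj.values.sum(axis=1)
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {
                "beta": beta,
                "scale_free_r2": r2,
                "slope": slope,
                "mean_connectivity": float(k.mean()),
            }
        )
    return pd.DataFrame(rows)


def topological_overlap(adj: AdjacencyMatrix) -> TOMatrix:
    """Topological overlap of a nonnegative adjacency with zero diagonal.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    l_ij = sum_u a_iu a_uj over u != i, j and k_i the row sum; unit diagonal.
    """
    a = np.asarray(adj.values, dtype=float)
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    if np.abs(np.diag(a)).max(initial=0.0) != 0:
        raise ValueError("adjacency diagonal must be zero")
    l = a @ a                       # zero diagonal makes u = i, j terms vanish
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return TOMatrix(values=tom, protein_ids=list(adj.protein_ids))


def cluster_dendrogram(tom: TOMatrix) -> Dendrogram:
    """Average-linkage agglomerative clustering of the TOM dissimilarity."""
    n = len(tom.protein_ids)
    if n == 1:
        return Dendrogram(merges=np.empty((0, 4)), protein_ids=list(tom.protein_ids))
    dissim = tom.dissimilarity()
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    merges = linkage(squareform(dissim, checks=False), method="average")
    return Dendrogram(merges=merges, protein_ids=list(tom.protein_ids))


def _subtree_leaves(merges: np.ndarray, n: int) -> dict[int, list[int]]:
    """Leaf list per node (leaves 0..n-1, internal nodes n..2n-2)."""
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (a, b, _h, _c) in enumerate(merges):
        leaves[n + k] = leaves[int(a)] + leaves[int(b)]
    return leaves


def dynamic_tree_cut(
    dendro: Dendrogram,
    tom: TOMatrix | None = None,
    min_module_size: int = 5,
    cut_fraction: float = 0.99,
    split_ratio: float | None = 0.5,
    static_cut_height: float | None = None,
) -> ModuleAssignment:
    """Adaptive branch decomposition of the dendrogram into modules.

    First a static cut at ``static_cut_height`` (default ``cut_fraction`` x
    the maximum merge height) yields candidate branches; if the cut produces
    no structure at all the whole tree is treated as one branch. Each branch
    is then decomposed top-down: a merge is split when the mean topological
    overlap between its two sub-branches falls below ``split_ratio`` times
    the more cohesive sub-branch's internal overlap — i.e. branches are kept
    together exactly where the TOM block structure says they belong
    together. Fragments smaller than ``min_module_size`` (including stray
    leaves chained high onto real branches) are pooled into grey. Modules
    are named from the fixed colour list by decreasing size (ties broken by
    the lexicographically smallest member id).

    ``split_ratio=None`` disables adaptive splitting (plain static cut);
    adaptive splitting requires ``tom``.
    """
    if min_module_size < 1:
        raise ValueError("min_module_size must be >= 1")
    n = dendro.n_leaves
    ids = dendro.protein_ids
    if n == 0:
        return ModuleAssignment(
            labels=pd.Series(dtype=object), min_module_size=min_module_size
        )
    if n == 1 or len(dendro.merges) == 0:
        label = GREY if n < min_module_size else MODULE_COLORS[0]
        return ModuleAssignment(
            labels=pd.Series([label] * n, index=ids),
            min_module_size=min_module_size,
        )
    if split_ratio is not None and tom is None:
        raise ValueError("adaptive splitting requires the TOM")

    merges = dendro.merges
    max_height = float(merges[:, 2].max())
    cut_height = (
        float(static_cut_height)
        if static_cut_height is not None
        else cut_fraction * max_height
    )
    flat = fcluster(merges, t=cut_height, criterion="distance")
    leaves = _subtree_leaves(merges, n)

    cluster_sizes = pd.Series(flat).value_counts()
    if (cluster_sizes == 1).all():
        # no merge below the cut height: treat the whole tree as one branch
        branch_roots = [2 * n - 2]
    else:
        branch_roots = []
        # cluster -> root node: the unique node whose leaf set is the cluster
        remaining = {c: int(s) for c, s in cluster_sizes.items()}
        leaf_cluster = flat
        for node in range(2 * n - 1):
            node_leaves = leaves[node]
            c = leaf_cluster[node_leaves[0]]
            if len(node_leaves) == remaining.get(c, -1) and all(
                leaf_cluster[v] == c for v in node_leaves
            ):
                branch_roots.append(node)
                remaining.pop(c, None)

    t = tom.values if tom is not None else None

    def mean_within(group: list[int]) -> float:
        if len(group) < 2:
            return 1.0
        block = t[np.ix_(group, group)]
        m = len(group)
        return float((block.sum() - np.trace(block)) / (m * (m - 1)))

    def split(root: int) -> list[list[int]]:
        """Top-down TOM-block decomposition of one branch (iterative)."""
        if split_ratio is None:
            return [leaves[root]]
        groups: list[list[int]] = []
        stack = [root]
        while stack:
            node = stack.pop()
            if node < n:
                groups.append([node])
                continue
            k = node - n
            a, b = int(merges[k, 0]), int(merges[k, 1])
            ga, gb = leaves[a], leaves[b]
            cross = float(t[np.ix_(ga, gb)].mean())
            cohesion = max(mean_within(ga), mean_within(gb))
            if cross < split_ratio * cohesion:
                stack.append(a)
                stack.append(b)
            else:
                groups.append(leaves[node])
        return groups

    groups: list[list[int]] = []
    grey_leaves: list[int] = []
    for root in branch_roots:
        branch_leaves = leaves[root]
        if len(branch_leaves) < min_module_size:
            grey_leaves.extend(branch_leaves)
            continue
        for group in split(root):
            if len(group) >= min_module_size:
                groups.append(group)
            else:
                grey_leaves.extend(group)

    # deterministic naming: decreasing size, ties by smallest member id
    groups.sort(key=lambda g: (-len(g), min(ids[v] for v in g)))
    labels = pd.Series(GREY, index=ids, dtype=object)
    for rank, group in enumerate(groups):
        name = (
            MODULE_COLORS[rank]
            if rank < len(MODULE_COLORS)
            else f"module{rank + 1}"
        )
        labels.iloc[group] = name
    labels.iloc[grey_leaves] = GREY
    logger.info(
        "dynamic_tree_cut: %d modules, %d grey of %d proteins",
        len(groups), int((labels == GREY).sum()), n,
    )
    return ModuleAssignment(labels=labels, min_module_size=min_module_size)
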