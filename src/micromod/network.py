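"""Weighted correlation network construction and two-stage module
discovery.

The pipeline is the classic weighted co-expression recipe: soft-power
adjacency on stabilized expression, topological-overlap dissimilarity,
average-linkage clustering, branch-sensitive (dynamic hybrid) tree
cutting, and eigengene-based merging of near-duplicate modules.  A
second clustering round re-cuts each first-order module using only its
genes and the samples of conditions where it is active, resolving
sub-programs invisible at panel scale.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .data import ExpressionPanel, ModuleSet, StudyDesign

__all__ = [
    "NetworkConfig",
    "Dendrogram",
    "adjacency",
    "select_soft_power",
    "topological_overlap",
    "cluster_dendrogram",
    "dynamic_tree_cut",
    "module_merge",
    "two_stage_clustering",
    "FIRST_ORDER_CODES",
    "SECOND_ORDER_COLORS",
]

log = logging.getLogger(__name__)

# naming palettes: two-letter codes for first-order modules (by size,
# descending), color suffixes for second-order children
FIRST_ORDER_CODES = [
    "BR", "PI", "CY", "YE", "TQ", "PU", "GR", "OR", "MA", "SA", "LA", "VI",
    "AQ", "BE", "CO", "DE", "EM", "FU", "GO", "HA", "IN", "JA", "KH", "LI",
    "MI", "NA", "OL", "PE", "QU", "RO", "SI", "TA", "UM", "VE", "WI", "XA",
]
SECOND_ORDER_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "grey60",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of network construction and tree cutting."""

    soft_power: float | None = None
    signed: bool = False
    use_topological_overlap: bool = True
    min_cluster_size: int = 20
    deep_split: int = 1
    pam_stage: bool = True
    merge_cut_height: float = 0.25
    scale_free_r2_threshold: float = 0.80
    cut_height: float | None = None

    def __post_init__(self) -> None:
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.deep_split not in (0, 1, 2, 3, 4):
            raise ValueError("deep_split must be in {0, 1, 2, 3, 4}")
        if not (0.0 <= self.merge_cut_height <= 1.0):
            raise ValueError("merge_cut_height must be in [0, 1]")


@dataclass
class Dendrogram:
    """Average-linkage merge tree over gene leaves."""

    merges: np.ndarray            # scipy linkage matrix, shape (n-1, 4)
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.leaf_ids[i] for i in leaves_list(self.merges)]


def _as_matrix(expr) -> tuple[np.ndarray, list[str]]:
    if isinstance(expr, ExpressionPanel):
        return expr.values, list(expr.gene_ids)
    x = np.asarray(expr, dtype=float)
    return x, [f"g{i}" for i in range(x.shape[0])]


def adjacency(expr, beta: float, signed: bool = False) -> np.ndarray:
    """Soft-thresholded correlation adjacency.

    Unsigned: ``|cor|**beta``; signed: ``((1 + cor) / 2)**beta``.  The
    diagonal is 1 and the matrix is symmetric.  Zero-variance gene rows
    raise an error naming the genes.
    """
    x, gene_ids = _as_matrix(expr)
    if x.shape[1] < 3:
        raise ValueError("adjacency needs >= 3 samples")
    sd = x.std(axis=1)
    bad = [g for g, s in zip(gene_ids, sd) if s == 0]
    if bad:
        raise ValueError(f"zero-variance genes: {', '.join(bad[:10])}")
    r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return (a + a.T) / 2.0


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of the log10 p(k) ~ log10 k regression over
    equal-occupancy connectivity bins."""
    k = k[k > 0]
    edges = np.unique(np.quantile(k, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 3:
        raise ValueError("fewer than 3 non-empty connectivity bins")
    counts, edges = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    density = counts / (counts.sum() * widths)
    centers = np.array([k[(k >= lo) & (k <= hi)].mean()
                        for lo, hi in zip(edges[:-1], edges[1:])])
    ok = (density > 0) & (centers > 0)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 non-empty connectivity bins")
    fit = stats.linregress(np.log10(centers[ok]), np.log10(density[ok]))
    return float(fit.rvalue ** 2), float(fit.slope)


def select_soft_power(expr, candidates=range(1, 21),
                      r2_threshold: float = 0.80, signed: bool = False,
                      n_bins: int = 10) -> int:
    """Lowest soft power whose connectivity distribution fits a scale-free
    law with R^2 at or above ``r2_threshold``.

    If no candidate qualifies, the power with the highest R^2 is
    returned with a warning.
    """
    candidates = sorted(candidates)
    x, gene_ids = _as_matrix(expr)
    base = adjacency(x, 1.0, signed=signed)  # validates input once
    r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    del base
    r2s = []
    for beta in candidates:
        a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2, _ = _scale_free_r2(k, n_bins=n_bins)
        r2s.append(r2)
        if r2 >= r2_threshold:
            return int(beta)
    best = candidates[int(np.argmax(r2s))]
    warnings.warn(
        f"no candidate power reached scale-free R^2 >= {r2_threshold}; "
        f"using argmax beta={best} (R^2={max(r2s):.3f})")
    return int(best)


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological-overlap dissimilarity ``1 - TOM`` with zero diagonal.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    where sums and connectivities exclude the diagonal.
    """
    adj = np.asarray(adj, dtype=float)
    if adj.shape[0] != adj.shape[1] or not np.allclose(adj, adj.T, atol=1e-10):
        raise ValueError("adjacency must be a symmetric square matrix")
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    d = 1.0 - tom
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def cluster_dendrogram(dissimilarity: np.ndarray,
                       leaf_ids: list[str] | None = None) -> Dendrogram:
    """Average-linkage agglomerative tree from a dissimilarity matrix."""
    d = np.asarray(dissimilarity, dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if np.isnan(d).any():
        raise ValueError("dissimilarity contains NaN entries")
    if not np.allclose(d, d.T, atol=1e-10) or not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    if leaf_ids is None:
        leaf_ids = [f"g{i}" for i in range(d.shape[0])]
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(z, list(leaf_ids))


# ---------------------------------------------------------------------------
# dynamic hybrid tree cut
# ---------------------------------------------------------------------------

# published deep-split ladder: maximum core scatter (relative to the
# height range above the reference quantile) per deep_split level, with
# the minimum gap at three quarters of the remainder
_MAX_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


def _branch_stats(z: np.ndarray, n: int, min_size: int):
    """Per-node sizes and the smallest internal merge heights.

    Only the ``cap`` lowest joining heights are kept per node — the core
    scatter never looks deeper than the core size, which grows like the
    square root of the branch size.
    """
    cap = int(min_size / 2 + 1 + np.sqrt(n)) + 2
    sizes = [1] * n + [int(c) for c in z[:, 3]]
    heights: list[list[float]] = [[] for _ in range(n)] + [None] * (n - 1)
    for i in range(n - 1):
        a, b = int(z[i, 0]), int(z[i, 1])
        merged = sorted(heights[a] + heights[b])[: cap - 1]
        merged.append(float(z[i, 2]))  # merges come in non-decreasing height
        heights[n + i] = sorted(merged)[:cap]
    return sizes, heights


def _core_scatter(internal_heights: list[float], size: int, min_size: int) -> float:
    if size <= 1:
        return 0.0
    base = min_size / 2.0 + 1.0
    core = size if base >= size else int(base + np.sqrt(size - base))
    return float(np.mean(internal_heights[:max(core - 1, 1)]))


def dynamic_tree_cut(dendrogram: Dendrogram, dissimilarity: np.ndarray,
                     config: NetworkConfig = NetworkConfig(),
                     module_codes: list[str] | None = None) -> ModuleSet:
    """Branch-sensitive cut of the dendrogram (dynamic hybrid).

    A branch qualifies as a cluster when it has at least
    ``min_cluster_size`` leaves, its core scatter (mean joining height of
    the first core leaves) is below a deep-split-dependent ceiling, and
    it is separated from its surroundings by a sufficient gap between
    its attachment height and its core scatter.  The tree is split as
    deeply as branches on both sides keep qualifying.  With
    ``pam_stage``, leaves left unassigned are attached to the nearest
    qualifying cluster by average dissimilarity (capped at the cut
    height).  Modules are labeled with two-letter codes in size order.
    """
    z = dendrogram.merges
    n = dendrogram.n_leaves
    if config.min_cluster_size > n:
        raise ValueError("min_cluster_size exceeds the number of leaves")
    d = np.asarray(dissimilarity, dtype=float)

    merge_heights = np.sort(z[:, 2])
    ref_idx = min(max(int(round(0.05 * (n - 1))) - 1, 0), n - 2)
    ref = float(merge_heights[ref_idx])
    top = float(merge_heights[-1])
    cut_height = (config.cut_height if config.cut_height is not None
                  else 0.99 * (top - ref) + ref)
    span = max(cut_height - ref, 1e-12)
    mcs = _MAX_CORE_SCATTER[config.deep_split]
    max_abs_scatter = ref + mcs * span
    min_abs_gap = (1.0 - mcs) * 0.75 * span

    sizes, internals = _branch_stats(z, n, config.min_cluster_size)
    scatter = [_core_scatter(internals[v], sizes[v], config.min_cluster_size)
               for v in range(2 * n - 1)]

    def qualifies(node: int, attach: float) -> bool:
        return (sizes[node] >= config.min_cluster_size
                and scatter[node] <= max_abs_scatter
                and attach - scatter[node] >= min_abs_gap)

    children = {n + i: (int(z[i, 0]), int(z[i, 1])) for i in range(n - 1)}
    node_height = {n + i: float(z[i, 2]) for i in range(n - 1)}

    def collect_leaves(node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend(children[v])
        return out

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * n + 100))

    def descend(node: int, attach: float) -> list[list[int]]:
        """Clusters found within a branch attaching to the tree at
        ``attach``; leaves outside the returned clusters are unassigned."""
        if node < n:
            return []
        h = node_height[node]
        a, b = children[node]
        if h > cut_height:
            # the two sub-branches are separate at the static cut level
            return descend(a, cut_height) + descend(b, cut_height)
        sub = descend(a, h) + descend(b, h)
        if len(sub) >= 2:
            return sub
        if qualifies(node, attach):
            return [collect_leaves(node)]
        return sub

    root = 2 * n - 2
    try:
        clusters = descend(root, cut_height)
    finally:
        sys.setrecursionlimit(old_limit)

    # proximity trim: a detected branch may have accreted loosely attached
    # leaves below the cut level; release members whose average
    # dissimilarity to their cluster exceeds the core-scatter ceiling
    for _ in range(2):
        trimmed = []
        for members in clusters:
            members = np.asarray(members)
            if len(members) < 2:
                continue
            avg = (d[np.ix_(members, members)].sum(axis=1)) / (len(members) - 1)
            keep = members[avg <= max_abs_scatter]
            if len(keep):
                trimmed.append(list(keep))
        clusters = trimmed
    clusters = [c for c in clusters if len(c) >= config.min_cluster_size]
    clusters.sort(key=len, reverse=True)

    labels = np.full(n, -1, dtype=int)
    for ci, members in enumerate(clusters):
        labels[members] = ci

    if config.pam_stage and clusters:
        unassigned = np.where(labels == -1)[0]
        if len(unassigned):
            avg = np.column_stack([d[np.ix_(unassigned, c)].mean(axis=1)
                                   for c in clusters])
            nearest = np.argmin(avg, axis=1)  # ties -> smaller cluster index
            best = avg[np.arange(len(unassigned)), nearest]
            ok = best <= min(cut_height, max_abs_scatter)
            labels[unassigned[ok]] = nearest[ok]

    codes = module_codes if module_codes is not None else FIRST_ORDER_CODES
    assignments: dict[str, str] = {}
    for ci in range(len(clusters)):
        code = codes[ci] if ci < len(codes) else f"X{ci:02d}"
        for leaf in np.where(labels == ci)[0]:
            assignments[dendrogram.leaf_ids[leaf]] = code
    lineage = {m: (None, 1) for m in dict.fromkeys(assignments.values())}
    counts: dict[str, int] = {}
    for m in assignments.values():
        counts[m] = counts.get(m, 0) + 1
    min_sz = min(counts.values()) if counts else config.min_cluster_size
    return ModuleSet(assignments, lineage,
                     min_size=min(config.min_cluster_size, min_sz))


# ---------------------------------------------------------------------------
# eigengene merging and second-round clustering
# ---------------------------------------------------------------------------

def module_merge(modules: ModuleSet, expr: ExpressionPanel,
                 merge_cut_height: float = 0.25) -> ModuleSet:
    """Iteratively merge module pairs whose eigengene dissimilarity
    (1 - correlation) falls below ``merge_cut_height``.

    The closest pair is merged first and eigengenes are recomputed after
    every merge; the merged module keeps the larger member's label.
    Running the function twice equals running it once.
    """
    from .states import eigengene_matrix

    current = {m: list(g) for m, g in modules.modules().items()}
    if not current:
        return modules
    while len(current) > 1:
        ms = ModuleSet({g: m for m, genes in current.items() for g in genes},
                       min_size=1)
        eig = eigengene_matrix(expr, ms)
        ids = list(eig.index)
        r = np.corrcoef(eig.to_numpy())
        diss = 1.0 - r
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut_height:
            break
        a, b = ids[i], ids[j]
        keep, drop = (a, b) if len(current[a]) >= len(current[b]) else (b, a)
        log.info("merging module %s into %s (eigengene dissimilarity %.3f)",
                 drop, keep, diss[i, j])
        current[keep] = current[keep] + current.pop(drop)
    assignments = {g: m for m, genes in current.items() for g in genes}
    lineage = {m: modules.lineage.get(m, (None, 1)) for m in current}
    return ModuleSet(assignments, lineage, min_size=min(modules.min_size,
                                                        min(map(len, current.values()))))


def _restricted_samples(activity_row, design: StudyDesign) -> list[str]:
    """Samples of conditions where the module is significantly active,
    plus all control samples (the contrast anchor)."""
    active_conditions = [c for c, sig in activity_row.items() if sig]
    samples = list(design.control_samples())
    for c in active_conditions:
        samples.extend(design.samples_of(c))
    return list(dict.fromkeys(samples))


def two_stage_clustering(expr: ExpressionPanel, design: StudyDesign,
                         modules1: ModuleSet,
                         config2: NetworkConfig | None = None,
                         soft_power: float = 4.0,
                         signed: bool = False) -> ModuleSet:
    """Second clustering round inside each first-order module.

    Each first-order module is re-clustered using only its genes and the
    samples of conditions where its eigengene is significantly active
    (Bonferroni p below 0.05) plus all controls.  Modules whose second
    cut returns a single cluster are retained unchanged; otherwise the
    children are named ``<parent>_<color>`` and recorded with order-2
    lineage.  First-order modules with no active condition are retained
    unchanged and flagged in the log.
    """
    from .states import eigengene_matrix, module_activity

    if config2 is None:
        config2 = NetworkConfig(deep_split=4, pam_stage=False, min_cluster_size=20)

    eig = eigengene_matrix(expr, modules1)
    activity = module_activity(eig, design)
    sig = activity.to_frame("significant")

    assignments: dict[str, str] = {}
    lineage: dict[str, tuple[str | None, int]] = {}
    min_size = modules1.min_size
    for parent, genes in modules1.modules().items():
        row = sig.loc[parent]
        samples = _restricted_samples(row, design)
        if not row.any():
            log.warning("module %s has no significantly active condition; "
                        "retained unchanged", parent)
            _retain(assignments, lineage, parent, genes)
            continue
        sub = expr.subset(genes=genes, samples=samples)
        try:
            a = adjacency(sub, soft_power, signed=signed)
        except ValueError:
            _retain(assignments, lineage, parent, genes)
            continue
        diss = topological_overlap(a) if config2.use_topological_overlap else 1.0 - a
        if len(genes) <= config2.min_cluster_size:
            _retain(assignments, lineage, parent, genes)
            continue
        dend = cluster_dendrogram(diss, leaf_ids=list(sub.gene_ids))
        children = dynamic_tree_cut(dend, diss, config2,
                                    module_codes=SECOND_ORDER_COLORS)
        child_map = children.modules()
        if len(child_map) <= 1:
            _retain(assignments, lineage, parent, genes)
            continue
        for ci, (_, child_genes) in enumerate(
                sorted(child_map.items(), key=lambda kv: -len(kv[1]))):
            color = SECOND_ORDER_COLORS[ci] if ci < len(SECOND_ORDER_COLORS) else f"c{ci}"
            child_id = f"{parent}_{color}"
            lineage[child_id] = (parent, 2)
            for g in child_genes:
                assignments[g] = child_id
            min_size = min(min_size, len(child_genes))
    return ModuleSet(assignments, lineage, min_size=min_size)


def _retain(assignments, lineage, parent, genes):
    lineage[parent] = (parent, 2)
    for g in genes:
        assignments[g] = parent
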