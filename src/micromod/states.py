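"""Module eigengenes, differential activity, hub genes, combinatorial
codes, and activation-state classification.

The eigengene of a module is the first principal component of its
standardized (per-gene z-scored) expression submatrix; its per-sample
scores summarize module activity.  Activity in a condition is the mean
eigengene score of the condition's samples minus the control mean, with
a two-sided Mann-Whitney U test against control and Bonferroni
correction over the full module-by-condition family.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, leaves_list

from .data import (CodeTable, EigengeneActivity, ExpressionPanel, ModuleSet,
                   StudyDesign, Unit)

__all__ = [
    "Eigengene",
    "HubGene",
    "CodeSearchResult",
    "compute_eigengene",
    "eigengene_matrix",
    "module_activity",
    "module_median_response",
    "cluster_conditions",
    "select_hub_gene",
    "build_code_table",
    "classify_state",
    "overlay_gene_list",
]


@dataclass
class Eigengene:
    """First-PC summary of a module's standardized expression."""

    module_id: str
    sample_ids: list[str]
    scores: np.ndarray
    explained_variance_fraction: float
    orientation_sign: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids),):
            raise ValueError("scores length does not match sample_ids")


@dataclass
class HubGene:
    """Selected single-gene reporter of a module's activity."""

    module_id: str
    gene_id: str
    eigengene_correlation: float
    coefficient_of_variation: float
    min_condition_tpm: float


def _standardize_rows(x: np.ndarray, gene_ids: list[str]):
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    dropped = [g for g, k in zip(gene_ids, keep) if not k]
    if dropped:
        warnings.warn(f"excluding zero-variance genes: {', '.join(dropped[:5])}"
                      + ("..." if len(dropped) > 5 else ""))
    x = x[keep]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return z, [g for g, k in zip(gene_ids, keep) if k]


def compute_eigengene(expr: ExpressionPanel, module_genes: list[str],
                      module_id: str = "module") -> Eigengene:
    """First principal component of the module's standardized expression.

    The sign is fixed so the score correlates non-negatively with the
    mean standardized member expression; scores have zero mean and unit
    Euclidean norm.  Zero-variance member genes are excluded with a
    warning.
    """
    sub = expr.subset(genes=module_genes)
    if sub.n_genes < 2 or sub.n_samples < 3:
        raise ValueError("eigengene needs >= 2 genes and >= 3 samples")
    z, kept = _standardize_rows(sub.values, sub.gene_ids)
    if len(kept) < 2:
        raise ValueError("fewer than 2 usable genes after excluding zero variance")
    # rows are centered, so the first right singular vector has zero mean
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    ev = float(s[0] ** 2 / np.sum(s ** 2))
    mean_profile = z.mean(axis=0)
    sign = 1
    if float(np.dot(scores, mean_profile)) < 0:
        sign = -1
        scores = -scores
    return Eigengene(module_id, list(sub.sample_ids), scores, ev, sign)


def eigengene_matrix(expr: ExpressionPanel, modules: ModuleSet) -> pd.DataFrame:
    """Module-by-sample matrix of eigengene scores."""
    rows = {}
    for mid, genes in modules.modules().items():
        rows[mid] = compute_eigengene(expr, genes, mid).scores
    return pd.DataFrame.from_dict(rows, orient="index", columns=expr.sample_ids)


def _mwu_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # degenerate, all scores tied
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue)


def module_activity(eigengenes: pd.DataFrame | dict[str, Eigengene],
                    design: StudyDesign,
                    conditions: list[str] | None = None,
                    alpha: float = 0.05) -> EigengeneActivity:
    """Differential eigengene activity of every module in every condition.

    ``activity[m, c]`` is the mean eigengene score of condition ``c``'s
    samples minus the control mean.  Raw two-sided Mann-Whitney p-values
    are Bonferroni-corrected over the whole module-by-condition family.
    """
    if isinstance(eigengenes, dict):
        eigengenes = pd.DataFrame.from_dict(
            {m: e.scores for m, e in eigengenes.items()}, orient="index",
            columns=next(iter(eigengenes.values())).sample_ids)
    if conditions is None:
        conditions = design.test_conditions
    sample_pos = {s: j for j, s in enumerate(eigengenes.columns)}
    module_ids = list(eigengenes.index)
    scores = eigengenes.to_numpy()

    activity = np.zeros((len(module_ids), len(conditions)))
    pvalues = np.ones_like(activity)
    for j, cond in enumerate(conditions):
        cond_idx = [sample_pos[s] for s in design.samples_of(cond) if s in sample_pos]
        ctrl_idx = [sample_pos[s]
                    for s in design.control_samples(design.timepoint_of(cond))
                    if s in sample_pos]
        if len(cond_idx) < 2 or len(ctrl_idx) < 2:
            raise ValueError(f"condition {cond!r}: need >= 2 condition and control samples")
        for i in range(len(module_ids)):
            a, b = scores[i, cond_idx], scores[i, ctrl_idx]
            activity[i, j] = a.mean() - b.mean()
            pvalues[i, j] = _mwu_pvalue(a, b)
    adjusted = np.minimum(pvalues * pvalues.size, 1.0)
    return EigengeneActivity(module_ids, list(conditions), activity, pvalues,
                             adjusted, adjusted < alpha, alpha)


def module_median_response(log2fc: pd.DataFrame, modules: ModuleSet,
                           normalize: str = "none",
                           reference: str | None = None) -> pd.DataFrame:
    """Module-by-condition matrix of median member log2 fold changes.

    ``normalize``: ``"none"``; ``"per_condition"`` divides each column by
    its maximum absolute entry; ``"to_reference"`` divides each gene's
    response by its response in ``reference`` before taking the median.
    """
    if normalize not in ("none", "per_condition", "to_reference"):
        raise ValueError(f"unknown normalization {normalize!r}")
    fc = log2fc
    if normalize == "to_reference":
        if reference is None or reference not in fc.columns:
            raise ValueError("to_reference normalization needs a reference condition")
        ref = fc[reference].replace(0.0, np.nan)
        fc = fc.div(ref, axis=0)
    rows = {}
    for mid, genes in modules.modules().items():
        present = [g for g in genes if g in fc.index]
        if not present:
            raise ValueError(f"module {mid!r} has no genes in the fold-change table")
        rows[mid] = fc.loc[present].median(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index")[list(log2fc.columns)]
    if normalize == "per_condition":
        colmax = out.abs().max(axis=0).replace(0.0, np.nan)
        out = out.div(colmax, axis=1).fillna(0.0)
    return out


def cluster_conditions(matrix: pd.DataFrame):
    """Average-linkage clustering of condition columns with correlation
    distance (1 - Pearson).  Returns ``(linkage_matrix, leaf_order)``."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 conditions to cluster")
    x = matrix.to_numpy().T
    sd = x.std(axis=1)
    constant = [c for c, s in zip(matrix.columns, sd) if s == 0]
    if constant:
        raise ValueError(f"constant condition columns: {', '.join(map(str, constant))}")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)
    from scipy.spatial.distance import squareform
    z = linkage(squareform(d, checks=False), method="average")
    order = [matrix.columns[i] for i in leaves_list(z)]
    return z, order


def select_hub_gene(expr_tpm: ExpressionPanel, eigengene: Eigengene,
                    module_genes: list[str], design: StudyDesign,
                    n_candidates: int = 10, min_tpm: float = 5.0,
                    ranking_expr: ExpressionPanel | None = None) -> HubGene:
    """Pick the module's hub gene.

    Members are ranked by ``|cor(gene, eigengene)|`` (on the expression
    scale the eigengene was derived from when ``ranking_expr`` is given,
    otherwise on TPM); among the top ``n_candidates``, genes whose
    minimum condition-mean TPM falls below ``min_tpm`` are dropped, and
    of the rest the gene with the lowest coefficient of variation across
    control replicates is selected (ties break toward higher eigengene
    correlation).  If no candidate survives the TPM floor the search
    widens to the top 2x candidates with a warning before failing.
    """
    if expr_tpm.unit is not Unit.TPM:
        raise ValueError("hub selection requires a TPM panel")
    sub = expr_tpm.subset(genes=module_genes, samples=eigengene.sample_ids)
    rank_panel = ranking_expr if ranking_expr is not None else expr_tpm
    rsub = rank_panel.subset(genes=module_genes, samples=eigengene.sample_ids)
    scores = eigengene.scores
    sd = rsub.values.std(axis=1)
    centered = rsub.values - rsub.values.mean(axis=1, keepdims=True)
    sc = scores - scores.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        cors = centered @ sc / (sd * rsub.n_samples * sc.std())
    cors = np.nan_to_num(cors)
    order = np.argsort(-np.abs(cors), kind="stable")

    cond_means = {c: sub.values[:, sub.sample_index(
        [s for s in design.samples_of(c) if s in set(sub.sample_ids)])].mean(axis=1)
        for c in design.condition_ids}
    min_cond = np.min(np.column_stack(list(cond_means.values())), axis=1)

    ctrl = [s for s in design.control_samples() if s in set(sub.sample_ids)]
    cx = sub.values[:, sub.sample_index(ctrl)]
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(cx.mean(axis=1) > 0,
                      cx.std(axis=1, ddof=1) / cx.mean(axis=1), np.inf)

    for n_top in (n_candidates, 2 * n_candidates):
        top = order[:n_top]
        eligible = [i for i in top if min_cond[i] >= min_tpm]
        if eligible:
            if n_top > n_candidates:
                warnings.warn("no hub candidate in the top "
                              f"{n_candidates} passed the {min_tpm}-TPM floor; "
                              f"widened to top {n_top}")
            best = min(eligible, key=lambda i: (cv[i], -abs(cors[i])))
            return HubGene(eigengene.module_id, sub.gene_ids[best],
                           float(cors[best]), float(cv[best]), float(min_cond[best]))
    raise ValueError(
        f"module {eigengene.module_id!r}: no candidate gene reaches {min_tpm} TPM "
        "in every condition")


@dataclass
class CodeSearchResult:
    """Full induction table plus the minimal distinguishing marker set."""

    table: CodeTable
    minimal_markers: list[str]
    indistinguishable: list[tuple[str, str]]


def _distinguishes(induced: np.ndarray, marker_idx: tuple[int, ...],
                   required_pairs: list[tuple[int, int]]) -> bool:
    sub = induced[list(marker_idx), :]
    return all(not np.array_equal(sub[:, a], sub[:, b]) for a, b in required_pairs)


def build_code_table(activity: EigengeneActivity,
                     conditions: list[str] | None = None,
                     markers: list[str] | None = None,
                     max_exhaustive: int = 4) -> CodeSearchResult:
    """Binary induction code and a minimal distinguishing marker subset.

    ``induced[m, c]`` is true when the module is significantly active
    with positive activity.  When ``markers`` is None, the smallest
    module subset whose induction patterns are pairwise distinct across
    the requested conditions is found by exhaustive search up to
    ``max_exhaustive`` markers and greedy forward selection beyond.
    Conditions with identical full-table patterns are reported as
    indistinguishable and exempted from the search.
    """
    if conditions is None:
        conditions = list(activity.condition_ids)
    cidx = [activity.condition_ids.index(c) for c in conditions]
    induced = (activity.significant & (activity.activity > 0))[:, cidx]
    module_ids = list(activity.module_ids)
    if markers is not None:
        midx = [module_ids.index(m) for m in markers]
        table = CodeTable(list(markers), list(conditions), induced[midx, :])
        return CodeSearchResult(table, list(markers), table.indistinguishable_pairs())

    table = CodeTable(module_ids, list(conditions), induced)
    twins = table.indistinguishable_pairs()
    twin_set = {frozenset(p) for p in twins}
    required = [(i, j) for i in range(len(conditions)) for j in range(i + 1, len(conditions))
                if frozenset((conditions[i], conditions[j])) not in twin_set]

    n = len(module_ids)
    minimal: list[str] | None = None
    for size in range(1, min(max_exhaustive, n) + 1):
        for combo in itertools.combinations(range(n), size):
            if _distinguishes(induced, combo, required):
                minimal = [module_ids[i] for i in combo]
                break
        if minimal is not None:
            break
    if minimal is None:
        # greedy forward selection: add the marker resolving the most pairs
        chosen: list[int] = []
        unresolved = list(required)
        while unresolved and len(chosen) < n:
            def resolved_count(k):
                return sum(induced[k, a] != induced[k, b] for a, b in unresolved)
            best = max((k for k in range(n) if k not in chosen), key=resolved_count)
            if resolved_count(best) == 0:
                break
            chosen.append(best)
            unresolved = [(a, b) for a, b in unresolved
                          if not _distinguishes(induced, tuple(chosen), [(a, b)])]
        if unresolved:
            minimal = None
        else:
            minimal = [module_ids[i] for i in sorted(chosen)]
    return CodeSearchResult(table, minimal or [], twins)


def classify_state(observed_induction: dict[str, bool], code: CodeTable
                   ) -> list[str | tuple[str, str]]:
    """Match an observed induction pattern against the code table.

    Returns all conditions whose code column equals the pattern exactly.
    If none matches, condition *pairs* whose OR-combined columns match
    are returned (additive combined stimuli).  An empty list means a
    novel / unknown state.
    """
    missing = [m for m in observed_induction if m not in code.marker_ids]
    if missing:
        raise KeyError(f"observed markers not in code table: {missing}")
    markers = [m for m in code.marker_ids if m in observed_induction]
    sub = code.restrict(markers)
    pattern = np.array([bool(observed_induction[m]) for m in markers])
    singles = [c for j, c in enumerate(sub.condition_ids)
               if np.array_equal(sub.induced[:, j], pattern)]
    if singles:
        return singles
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(sub.condition_ids):
        for j in range(i + 1, len(sub.condition_ids)):
            b = sub.condition_ids[j]
            if np.array_equal(sub.induced[:, i] | sub.induced[:, j], pattern):
                pairs.append((a, b))
    return pairs


def induction_pattern(stabilized: ExpressionPanel, design: StudyDesign,
                      modules: ModuleSet, alpha: float = 0.05) -> dict[str, bool]:
    """Observed module induction flags for a new (control + query) draw.

    Computes each module's eigengene on the new samples, tests its
    activity against the draw's own controls, and returns
    ``module -> induced`` (significantly active with positive shift) —
    the pattern that :func:`classify_state` matches against a code table.
    """
    eig = eigengene_matrix(stabilized, modules)
    activity = module_activity(eig, design, alpha=alpha)
    induced = activity.significant & (activity.activity > 0)
    return {m: bool(induced[i].any()) for i, m in enumerate(activity.module_ids)}


def overlay_gene_list(gene_list: list[str], modules: ModuleSet):
    """Partition an external gene list by module membership.

    Returns ``(partition, fractions)`` where ``partition`` maps each
    module (plus ``"unassigned"``) to the intersecting genes and
    ``fractions`` gives each part's share of the list (summing to 1 for
    a non-empty list).
    """
    genes = list(dict.fromkeys(gene_list))
    partition: dict[str, list[str]] = {}
    rest: list[str] = []
    for g in genes:
        m = modules.module_of(g)
        if m is None:
            rest.append(g)
        else:
            partition.setdefault(m, []).append(g)
    if rest:
        partition["unassigned"] = rest
    total = len(genes)
    fractions = {m: len(v) / total for m, v in partition.items()} if total else {}
    return partition, fractions
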