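"""Replicate QC, negative-binomial error model, variance stabilization,
and the replicate-wise differential-expression rule.

The error model is the NB parameterization ``var = mu + phi * mu**2``;
``phi = 0`` is the Poisson limit.  Differential expression compares each
treated replicate against the control-fitted NB model with a two-sided
tail test, and a gene is called significant in a condition only when
every replicate's p-value is <= 0.05.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionPanel, StudyDesign, Unit

__all__ = [
    "NBModel",
    "DEResult",
    "condition_reproducibility",
    "fit_nb_model",
    "nb_vst",
    "stabilize_panel",
    "estimate_panel_dispersion",
    "differential_expression",
    "de_significance_matrix",
    "log2fc_matrix",
    "select_genes",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# replicate QC
# ---------------------------------------------------------------------------

def condition_reproducibility(panel: ExpressionPanel, design: StudyDesign,
                              genes: list[str] | None = None) -> dict[str, float]:
    """Mean pairwise Pearson correlation between replicates, per condition.

    Conditions with fewer than two samples get ``nan`` (flagged, value
    undefined).  Correlations are computed across the selected gene rows
    (all genes when ``genes`` is None).
    """
    sub = panel.subset(genes=genes) if genes is not None else panel
    out: dict[str, float] = {}
    for cond in design.condition_ids:
        samples = [s for s in design.samples_of(cond) if s in set(sub.sample_ids)]
        if len(samples) < 2:
            out[cond] = float("nan")
            continue
        x = sub.values[:, sub.sample_index(samples)]
        r = np.corrcoef(x, rowvar=False)
        iu = np.triu_indices(len(samples), k=1)
        out[cond] = float(np.mean(r[iu]))
    return out


# ---------------------------------------------------------------------------
# NB error model
# ---------------------------------------------------------------------------

@dataclass
class NBModel:
    """Per-gene NB(mu, phi) fitted on control replicates by method of
    moments: ``mu = mean``, ``phi = max(0, (var - mu) / mu**2)``."""

    gene_ids: list[str]
    mu: np.ndarray
    phi: np.ndarray
    fitted_on: str = "control"

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if np.any(self.mu < 0) or np.any(self.phi < 0):
            raise ValueError("mu and phi must be non-negative")

    def tail_pvalues(self, x: np.ndarray) -> np.ndarray:
        """Two-sided tail p-values ``2 * min(P(X<=x), P(X>=x), 0.5)`` for
        observations ``x`` (genes x replicates) under the per-gene model."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        mu = self.mu[:, None]
        phi = self.phi[:, None]
        lower = np.empty_like(x)
        upper = np.empty_like(x)
        pois = np.broadcast_to(phi == 0, x.shape)
        if np.any(pois):
            m = np.broadcast_to(mu, x.shape)[pois]
            lower[pois] = stats.poisson.cdf(x[pois], m)
            upper[pois] = stats.poisson.sf(x[pois] - 1, m)
        nb = ~pois
        if np.any(nb):
            phi_b = np.broadcast_to(phi, x.shape)[nb]
            mu_b = np.broadcast_to(mu, x.shape)[nb]
            n = 1.0 / phi_b
            p = 1.0 / (1.0 + phi_b * mu_b)
            lower[nb] = stats.nbinom.cdf(x[nb], n, p)
            upper[nb] = stats.nbinom.sf(x[nb] - 1, n, p)
        pvals = 2.0 * np.minimum(np.minimum(lower, upper), 0.5)
        # genes with mu == 0: the model is degenerate at zero
        zero = np.broadcast_to(mu == 0, x.shape)
        pvals[zero] = np.where(x[zero] == 0, 1.0, 0.0)
        return pvals


def fit_nb_model(panel: ExpressionPanel, design: StudyDesign,
                 condition: str | None = None) -> NBModel:
    """Fit the per-gene NB model on a condition's replicates (default:
    the full control pool).

    TPM panels are accepted as pseudo-counts with a logged warning; the
    model is meant for integer counts.
    """
    if panel.unit is Unit.TPM:
        log.warning("fitting NB model on TPM values; treating them as pseudo-counts")
    elif panel.unit is not Unit.COUNT:
        raise ValueError("NB model requires a COUNT (or TPM pseudo-count) panel")
    if condition is None:
        samples = design.control_samples()
        fitted_on = "control"
    else:
        samples = design.samples_of(condition)
        fitted_on = condition
    samples = [s for s in samples if s in set(panel.sample_ids)]
    if len(samples) < 2:
        raise ValueError("need at least 2 replicates to fit the NB model")
    x = panel.values[:, panel.sample_index(samples)]
    mu = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mu > 0, np.maximum(0.0, (var - mu) / mu ** 2), 0.0)
    return NBModel(list(panel.gene_ids), mu, phi, fitted_on)


# ---------------------------------------------------------------------------
# variance stabilization
# ---------------------------------------------------------------------------

def nb_vst(x: np.ndarray | float, phi: np.ndarray | float) -> np.ndarray | float:
    """Delta-method variance-stabilizing transform for NB data.

    ``g(x) = (2 / sqrt(phi)) * asinh(sqrt(phi * x))`` for ``phi > 0``,
    reducing to ``2 * sqrt(x)`` in the Poisson limit ``phi = 0``.  The
    transform is strictly increasing and maps 0 to 0; the variance of
    ``g(X)`` is approximately 1 for NB(mu, phi) across the mean range.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("nb_vst requires non-negative input")
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0):
        raise ValueError("dispersion phi must be >= 0")
    x_b, phi_b = np.broadcast_arrays(x_arr, phi_arr)
    out = np.empty_like(x_b, dtype=float)
    pos = phi_b > 0
    out[pos] = 2.0 / np.sqrt(phi_b[pos]) * np.arcsinh(np.sqrt(phi_b[pos] * x_b[pos]))
    out[~pos] = 2.0 * np.sqrt(x_b[~pos])
    if np.isscalar(x) and np.isscalar(phi):
        return float(out)
    return out


def estimate_panel_dispersion(panel: ExpressionPanel, design: StudyDesign | None = None,
                              min_mean: float = 5.0) -> float:
    """Panel-wide dispersion for the VST: median of per-gene
    method-of-moments phi-hat over genes with mean >= ``min_mean``.

    Estimated on control replicates when a design is given (so stimulus
    responses do not inflate phi), otherwise across all samples.
    """
    if design is not None:
        samples = [s for s in design.control_samples() if s in set(panel.sample_ids)]
        x = panel.values[:, panel.sample_index(samples)]
    else:
        x = panel.values
    mu = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    ok = mu >= min_mean
    if not np.any(ok):
        raise ValueError(f"no gene has mean >= {min_mean}; cannot estimate dispersion")
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.maximum(0.0, (var[ok] - mu[ok]) / mu[ok] ** 2)
    return float(np.median(phi))


def stabilize_panel(panel: ExpressionPanel, phi: float | None = None,
                    design: StudyDesign | None = None) -> ExpressionPanel:
    """Apply the NB VST to a COUNT (or TPM pseudo-count) panel."""
    if panel.unit is Unit.STABILIZED:
        return panel
    if phi is None:
        phi = estimate_panel_dispersion(panel, design)
    values = nb_vst(panel.values, phi)
    return ExpressionPanel(list(panel.gene_ids), list(panel.sample_ids),
                           values, Unit.STABILIZED)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-gene, per-condition differential-expression call."""

    gene_id: str
    condition_id: str
    log2fc: float
    p_median: float
    p_per_replicate: list[float] = field(default_factory=list)
    significant: bool = False


def _de_arrays(panel: ExpressionPanel, design: StudyDesign, condition: str,
               model: NBModel | None, pseudocount: float = 1.0):
    samples = design.samples_of(condition)
    if not samples:
        raise ValueError(f"condition {condition!r} has no samples")
    if model is None:
        controls = design.control_samples(design.timepoint_of(condition))
        if not controls:
            raise ValueError(f"no control samples available for condition {condition!r}")
        ctrl_design = StudyDesign(design.table.loc[
            design.table["sample_id"].isin(controls)].assign(is_control=True))
        model = fit_nb_model(panel, ctrl_design)
    x = panel.values[:, panel.sample_index(samples)]
    pvals = model.tail_pvalues(x)
    treated_mean = x.mean(axis=1)
    log2fc = np.log2((treated_mean + pseudocount) / (model.mu + pseudocount))
    p_median = np.median(pvals, axis=1)
    significant = np.all(pvals <= 0.05, axis=1)
    return log2fc, p_median, pvals, significant


def differential_expression(panel: ExpressionPanel, design: StudyDesign,
                            condition: str, model: NBModel | None = None,
                            pseudocount: float = 1.0) -> list[DEResult]:
    """Replicate-wise NB tail test of a condition against control.

    Each replicate is tested against the control-fitted NB model; a gene
    is ``significant`` only when all replicate p-values are <= 0.05.
    ``p_median`` (the median over replicates) is reported for ranking.
    Fold changes are condition mean over control mean with a pseudocount.
    """
    log2fc, p_median, pvals, significant = _de_arrays(panel, design, condition,
                                                      model, pseudocount)
    return [
        DEResult(g, condition, float(log2fc[i]), float(p_median[i]),
                 [float(p) for p in pvals[i]], bool(significant[i]))
        for i, g in enumerate(panel.gene_ids)
    ]


def de_significance_matrix(panel: ExpressionPanel, design: StudyDesign,
                           conditions: list[str] | None = None,
                           model: NBModel | None = None) -> pd.DataFrame:
    """Boolean genes-by-conditions significance matrix (vectorized path
    used by gene selection)."""
    if conditions is None:
        conditions = design.test_conditions
    if model is None:
        model = fit_nb_model(panel, design)
    cols = {}
    for cond in conditions:
        _, _, _, significant = _de_arrays(panel, design, cond, model)
        cols[cond] = significant
    return pd.DataFrame(cols, index=panel.gene_ids)


def log2fc_matrix(panel: ExpressionPanel, design: StudyDesign,
                  conditions: list[str] | None = None,
                  model: NBModel | None = None,
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """Genes-by-conditions log2 fold changes versus control."""
    if conditions is None:
        conditions = design.test_conditions
    if model is None:
        model = fit_nb_model(panel, design)
    cols = {}
    for cond in conditions:
        log2fc, _, _, _ = _de_arrays(panel, design, cond, model, pseudocount)
        cols[cond] = log2fc
    return pd.DataFrame(cols, index=panel.gene_ids)


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------

def select_genes(panel: ExpressionPanel, design: StudyDesign,
                 n_variable: int = 4000,
                 de_genes=None) -> list[str]:
    """Union of the top ``n_variable`` variable genes and all genes
    differentially expressed in at least one condition.

    Variability is ranked by the variance of stabilized condition-mean
    expression across conditions.  ``de_genes`` may be a collection of
    gene IDs, a list of :class:`DEResult`, or a significance matrix from
    :func:`de_significance_matrix`; when None it is computed from the
    panel (COUNT unit required for that path).
    """
    if n_variable > panel.n_genes:
        raise ValueError(
            f"n_variable={n_variable} exceeds the {panel.n_genes} genes in the panel")
    stab = stabilize_panel(panel, design=design) if panel.unit is not Unit.STABILIZED else panel
    cond_means = np.column_stack([
        stab.values[:, stab.sample_index(design.samples_of(c))].mean(axis=1)
        for c in design.condition_ids
    ])
    variability = cond_means.var(axis=1, ddof=0)
    order = np.argsort(-variability, kind="stable")
    top = [panel.gene_ids[i] for i in order[:n_variable]]

    if de_genes is None:
        sig = de_significance_matrix(panel, design)
        de_set = set(sig.index[sig.any(axis=1)])
    elif isinstance(de_genes, pd.DataFrame):
        de_set = set(de_genes.index[de_genes.any(axis=1)])
    elif de_genes and isinstance(next(iter(de_genes)), DEResult):
        de_set = {r.gene_id for r in de_genes if r.significant}
    else:
        de_set = set(de_genes)

    selected = set(top) | de_set
    return [g for g in panel.gene_ids if g in selected]
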