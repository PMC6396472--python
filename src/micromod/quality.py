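"""Module reproducibility statistics.

The reproducibility statistic is the *intra-module correlation score*:
rank the member genes by their mean Pearson correlation against the
other members, and report the mean correlation of the gene sitting at
the 75th percentile of that ranking.  Bootstrapping the score over
random half-subsets of the samples (drawn per condition) yields a mean
and spread; modules with a bootstrap mean above 0.35 are called
reproducible.  The same score, restricted to responding genes, decides
whether a module is preserved or broken in an independent (in vivo)
dataset.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionPanel, ModuleQuality, ModuleSet, QualityReport, StudyDesign

__all__ = [
    "BootstrapSpec",
    "intramodule_score",
    "bootstrap_module_quality",
    "invivo_module_status",
]


@dataclass(frozen=True)
class BootstrapSpec:
    """Half-sampling bootstrap: each iteration draws
    ``ceil(fraction * n_c)`` samples per condition without replacement."""

    n_iterations: int = 100
    fraction_per_condition: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction_per_condition <= 1.0):
            raise ValueError("fraction_per_condition must be in (0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def intramodule_score(expr, module_genes: list[str] | None = None) -> float:
    """Mean member correlation of the gene at the 75th percentile of the
    within-module ranking.

    Each member's mean Pearson correlation against all other members is
    computed; genes are ranked ascending and the value at 0-based index
    ``ceil(0.75 * (n - 1))`` is returned — a gene better correlated than
    three quarters of the module.  Zero-variance members are excluded
    with a warning; fewer than 3 usable genes is an error.
    """
    if isinstance(expr, ExpressionPanel):
        x = expr.subset(genes=module_genes).values if module_genes is not None \
            else expr.values
        names = module_genes if module_genes is not None else expr.gene_ids
    else:
        x = np.asarray(expr, dtype=float)
        names = [f"g{i}" for i in range(x.shape[0])]
    if x.shape[0] < 3 or x.shape[1] < 3:
        raise ValueError("intramodule score needs >= 3 genes and >= 3 samples")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [names[i] for i in np.where(sd == 0)[0]]
        warnings.warn(f"excluding zero-variance module genes: {', '.join(bad[:5])}")
        x = x[sd > 0]
    m = x.shape[0]
    if m < 3:
        raise ValueError("fewer than 3 usable genes after excluding zero variance")
    r = np.corrcoef(x)
    mean_r = (r.sum(axis=1) - 1.0) / (m - 1)
    ranked = np.sort(mean_r)
    idx = int(np.ceil(0.75 * (m - 1)))
    return float(ranked[idx])


def bootstrap_module_quality(expr: ExpressionPanel, design: StudyDesign,
                             modules: ModuleSet,
                             spec: BootstrapSpec = BootstrapSpec(),
                             threshold: float = 0.35) -> QualityReport:
    """Bootstrap the intra-module score over per-condition half-subsets.

    Returns a :class:`QualityReport` with the bootstrap mean and SD per
    module; a module is reproducible when its mean exceeds
    ``threshold``.  Bit-reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cond_samples = {c: [s for s in design.samples_of(c) if s in set(expr.sample_ids)]
                    for c in design.condition_ids}
    cond_samples = {c: v for c, v in cond_samples.items() if len(v) >= 2}
    module_map = modules.modules()
    gene_idx = {m: expr.gene_index(g) for m, g in module_map.items()}
    sample_pos = {s: j for j, s in enumerate(expr.sample_ids)}

    scores = {m: np.empty(spec.n_iterations) for m in module_map}
    for it in range(spec.n_iterations):
        chosen: list[int] = []
        for c, samples in cond_samples.items():
            k = int(np.ceil(spec.fraction_per_condition * len(samples)))
            pick = rng.choice(len(samples), size=k, replace=False)
            chosen.extend(sample_pos[samples[i]] for i in pick)
        chosen = sorted(chosen)
        for m, gi in gene_idx.items():
            scores[m][it] = intramodule_score(expr.values[np.ix_(gi, chosen)])

    report = QualityReport()
    for m in module_map:
        mean = float(scores[m].mean())
        sd = float(scores[m].std(ddof=1)) if spec.n_iterations > 1 else 0.0
        report[m] = ModuleQuality(mean, sd, spec.n_iterations,
                                  mean > threshold, threshold)
    return report


def invivo_module_status(log2fc: pd.Series | dict, expr: ExpressionPanel,
                         modules: ModuleSet, fc_threshold: float = 1.5,
                         frac: float = 1.0 / 3.0,
                         score_threshold: float = 0.35) -> dict[str, str]:
    """Activation / preservation status of each module in an independent
    dataset.

    A member gene is *active* when its absolute fold change versus the
    dataset's control reaches ``fc_threshold`` (both directions, i.e.
    ``|log2 FC| >= log2(fc_threshold)``).  A module with fewer than
    ``frac`` of its genes active is ``"inactive"``; otherwise it is
    ``"preserved"`` when the intra-module score over the active genes on
    these samples exceeds ``score_threshold`` and ``"broken"`` when not.
    Modules active by fraction but with fewer than 3 usable active genes
    are ``"undeterminable"``.
    """
    if isinstance(log2fc, dict):
        log2fc = pd.Series(log2fc)
    lfc_cut = np.log2(fc_threshold)
    status: dict[str, str] = {}
    for m, genes in modules.modules().items():
        present = [g for g in genes if g in log2fc.index]
        active = [g for g in present if abs(log2fc[g]) >= lfc_cut]
        if len(present) == 0 or len(active) / len(genes) < frac:
            status[m] = "inactive"
            continue
        if len(active) < 3:
            warnings.warn(f"module {m}: active fraction reached but fewer than "
                          "3 active genes; status undeterminable")
            status[m] = "undeterminable"
            continue
        score = intramodule_score(expr, active)
        status[m] = "preserved" if score > score_threshold else "broken"
    return status
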