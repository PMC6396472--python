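"""Model/Results facade over the full discovery pipeline.

``ModuleDiscovery`` is constructed from a counts (or TPM) panel and its
study design; ``fit()`` runs variance stabilization, gene selection,
soft-power search, topological overlap, dynamic tree cutting and
eigengene merging (optionally followed by the second clustering round)
and returns a ``ModuleDiscoveryResults`` carrying the module set,
eigengene activities, bootstrap quality and hub genes, with a
``summary()`` table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (EigengeneActivity, ExpressionPanel, ModuleSet, QualityReport,
                   StudyDesign, Unit)
from . import io as _io
from .network import (NetworkConfig, adjacency, cluster_dendrogram,
                      dynamic_tree_cut, module_merge, select_soft_power,
                      topological_overlap, two_stage_clustering)
from .preprocess import (condition_reproducibility, estimate_panel_dispersion,
                         de_significance_matrix, log2fc_matrix,
                         select_genes, stabilize_panel)
from .quality import BootstrapSpec, bootstrap_module_quality
from .simulate import tpm_from_counts
from .states import (HubGene, build_code_table, compute_eigengene,
                     eigengene_matrix, module_activity, select_hub_gene)

__all__ = ["ModuleDiscovery", "ModuleDiscoveryResults"]

log = logging.getLogger(__name__)


class ModuleDiscovery:
    """Co-expression module discovery on a multi-condition stimulus panel.

    Parameters
    ----------
    panel
        Expression panel (COUNT preferred; TPM accepted as pseudo-counts).
    design
        Sample-to-condition design.
    config
        Network construction / tree-cut parameters.
    n_variable
        Number of most-variable genes entering the network (unioned with
        all differentially expressed genes).
    """

    def __init__(self, panel: ExpressionPanel, design: StudyDesign,
                 config: NetworkConfig = NetworkConfig(),
                 n_variable: int = 4000, dispersion: float | None = None):
        self.panel = panel
        self.design = design
        self.config = config
        self.n_variable = min(n_variable, panel.n_genes)
        self.dispersion = (dispersion if dispersion is not None
                           else estimate_panel_dispersion(panel, design))

    @classmethod
    def from_files(cls, expression_path, design_path,
                   unit: Unit | str = Unit.COUNT, **kwargs) -> "ModuleDiscovery":
        panel = _io.read_expression(expression_path, unit)
        design = _io.read_design(design_path)
        return cls(panel, design, **kwargs)

    def fit(self, two_stage: bool = False, bootstrap: BootstrapSpec | None = None,
            compute_hubs: bool = True) -> "ModuleDiscoveryResults":
        cfg = self.config
        stabilized = stabilize_panel(self.panel, phi=self.dispersion)
        de_matrix = de_significance_matrix(self.panel, self.design)
        selected = select_genes(stabilized, self.design, self.n_variable, de_matrix)
        expr = stabilized.subset(genes=selected)
        # genes flat across every sample carry no network information
        sd = expr.values.std(axis=1)
        expr = expr.subset(genes=[g for g, s in zip(expr.gene_ids, sd) if s > 0])

        beta = cfg.soft_power
        if beta is None:
            beta = select_soft_power(expr, r2_threshold=cfg.scale_free_r2_threshold,
                                     signed=cfg.signed)
        log.info("soft power: %s", beta)
        adj = adjacency(expr, beta, signed=cfg.signed)
        diss = topological_overlap(adj) if cfg.use_topological_overlap else 1.0 - adj
        np.fill_diagonal(diss, 0.0)
        dend = cluster_dendrogram(diss, leaf_ids=list(expr.gene_ids))
        modules = dynamic_tree_cut(dend, diss, cfg)
        modules = module_merge(modules, expr, cfg.merge_cut_height)
        order1 = modules
        if two_stage:
            cfg2 = NetworkConfig(deep_split=4, pam_stage=False,
                                 min_cluster_size=cfg.min_cluster_size,
                                 use_topological_overlap=cfg.use_topological_overlap)
            modules = two_stage_clustering(expr, self.design, modules, cfg2,
                                           soft_power=beta, signed=cfg.signed)

        eigengenes = eigengene_matrix(expr, modules)
        activity = module_activity(eigengenes, self.design)
        quality = (bootstrap_module_quality(expr, self.design, modules, bootstrap)
                   if bootstrap is not None else None)

        hubs: dict[str, HubGene] = {}
        if compute_hubs:
            tpm = (self.panel if self.panel.unit is Unit.TPM
                   else tpm_from_counts(self.panel))
            for mid, genes in modules.modules().items():
                eig = compute_eigengene(expr, genes, mid)
                try:
                    hubs[mid] = select_hub_gene(tpm, eig, genes, self.design,
                                                ranking_expr=expr)
                except ValueError as e:
                    log.warning("no hub gene for %s: %s", mid, e)

        return ModuleDiscoveryResults(
            model=self, soft_power=float(beta), selected_genes=list(expr.gene_ids),
            stabilized=expr, modules=modules, order1_modules=order1,
            eigengenes=eigengenes, activity=activity, quality=quality, hubs=hubs,
        )


@dataclass
class ModuleDiscoveryResults:
    """Fitted module structure and its per-condition activity."""

    model: ModuleDiscovery
    soft_power: float
    selected_genes: list[str]
    stabilized: ExpressionPanel
    modules: ModuleSet
    order1_modules: ModuleSet
    eigengenes: pd.DataFrame
    activity: EigengeneActivity
    quality: QualityReport | None = None
    hubs: dict[str, HubGene] = field(default_factory=dict)

    def condition_reproducibility(self) -> dict[str, float]:
        return condition_reproducibility(self.stabilized, self.model.design)

    def median_response(self, normalize: str = "none",
                        reference: str | None = None) -> pd.DataFrame:
        lfc = log2fc_matrix(self.model.panel, self.model.design)
        from .states import module_median_response
        return module_median_response(lfc, self.modules, normalize, reference)

    def code(self, conditions: list[str] | None = None, max_exhaustive: int = 4):
        return build_code_table(self.activity, conditions,
                                max_exhaustive=max_exhaustive)

    def summary(self) -> str:
        """Human-readable per-module summary table."""
        sizes = self.modules.sizes
        lines = [
            f"Module discovery: {len(sizes)} modules over "
            f"{len(self.selected_genes)} selected genes "
            f"({self.model.panel.n_genes} total), soft power {self.soft_power:g}",
            "",
            f"{'module':<16}{'size':>6}{'active':>8}{'hub':>16}{'quality':>10}",
        ]
        n_active = self.activity.significant.sum(axis=1)
        for i, mid in enumerate(self.activity.module_ids):
            hub = self.hubs.get(mid)
            q = self.quality.get(mid) if self.quality else None
            lines.append(
                f"{mid:<16}{sizes[mid]:>6}{int(n_active[i]):>8}"
                f"{hub.gene_id if hub else '-':>16}"
                f"{format(q.score_mean, '.3f') if q else '-':>10}"
            )
        return "\n".join(lines)

    def plot_activity(self, path=None):
        """Optional heatmap export of eigengene activity (needs matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frame = self.activity.to_frame("activity")
        fig, ax = plt.subplots(figsize=(max(6, 0.25 * frame.shape[1]),
                                        max(4, 0.3 * frame.shape[0])))
        im = ax.imshow(frame.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(frame.shape[1]), frame.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(frame.shape[0]), frame.index, fontsize=7)
        fig.colorbar(im, ax=ax, label="eigengene activity vs control")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig
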