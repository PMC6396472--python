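"""Synthetic stimulus-panel generator with planted co-expression modules.

The generative model is a log-linear latent-factor model with negative
binomial counts:

* each module ``m`` carries one latent factor per sample,
  ``f_m(s) = response_m(condition(s)) + eps``, with replicate noise
  ``eps ~ N(0, 1)`` on the latent (natural-log) scale;
* gene ``g`` in module ``m`` has log-mean
  ``log mu_g(s) = baseline_g + loading_g * f_m(s)``, background genes
  have loading 0;
* counts are NB with ``var = mu + phi * mu**2`` after multiplying the
  mean by a log-normal library-size factor.

Baselines are expressed on a TPM-equivalent scale: a global depth factor
rescales them so that one sample totals roughly one million counts, so
TPM computed from the emitted counts reproduces the planted baselines.
Each module contains a few designated *marker* genes (high baseline,
highest loadings, low dispersion) emulating the highly expressed,
tightly regulated genes that serve as practical module markers; the
remaining members are modestly expressed, so a strongly suppressive
condition pushes them below the 5-TPM quantifiability floor used for
hub-gene selection.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionPanel, ModuleSet, StudyDesign, Unit

__all__ = [
    "ConditionSpec",
    "ModuleSpec",
    "PanelSpec",
    "PanelTruth",
    "generate_panel",
    "default_panel",
    "default_panel_spec",
    "redraw_panel",
    "invivo_companion",
    "stimulus_code_spec",
    "heldout_draw",
    "two_factor_module_panel",
    "score_recovery",
    "tpm_from_counts",
]

BACKGROUND = "background"


@dataclass(frozen=True)
class ConditionSpec:
    condition_id: str
    n_replicates: int = 4
    is_control: bool = False
    timepoint_hours: float = 24.0


@dataclass(frozen=True)
class ModuleSpec:
    """A planted module: ``size`` genes sharing one latent factor.

    ``response`` maps condition -> latent response (natural-log scale;
    conditions absent from the map respond 0).  ``loading`` is the
    module-level loading scale; per-gene loadings are ``loading`` times
    a uniform draw, except ``n_markers`` designated marker genes which
    receive the highest loadings.
    """

    module_id: str
    size: int
    loading: float = 0.8
    response: dict[str, float] = field(default_factory=dict)
    n_markers: int = 3


@dataclass(frozen=True)
class PanelSpec:
    n_genes: int
    modules: tuple[ModuleSpec, ...]
    conditions: tuple[ConditionSpec, ...]
    baseline_log_tpm_range: tuple[float, float] = (1.6, 3.2)
    background_log_tpm_range: tuple[float, float] = (0.7, 6.5)
    marker_log_tpm_range: tuple[float, float] = (5.8, 6.8)
    dispersion: float = 0.2
    marker_dispersion: float = 0.05
    library_size_cv: float = 0.1
    seed: int = 0

    @property
    def n_background(self) -> int:
        return self.n_genes - sum(m.size for m in self.modules)

    def __post_init__(self) -> None:
        if self.n_background < 0:
            raise ValueError("module sizes exceed n_genes")
        if not any(c.is_control for c in self.conditions):
            raise ValueError("panel spec needs a control condition")
        if self.dispersion < 0 or self.marker_dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class PanelTruth:
    """Ground truth aligned index-for-index with the emitted panel."""

    gene_ids: list[str]
    module_of: dict[str, str]            # gene -> module; background omitted
    loading: np.ndarray                  # per gene, 0 for background
    baseline_log_tpm: np.ndarray         # per gene, natural log of TPM-scale mean
    dispersion: np.ndarray               # per gene phi
    is_marker: np.ndarray                # per gene bool
    factors: pd.DataFrame                # module x sample latent factor values
    responses: dict[str, dict[str, float]]  # module -> condition -> response
    depth_factor: float

    def module_set(self, min_size: int = 1) -> ModuleSet:
        return ModuleSet(dict(self.module_of), min_size=min_size)

    def hub_ranking(self, module_id: str) -> list[str]:
        """Member genes ordered by planted loading, descending."""
        members = [g for g, m in self.module_of.items() if m == module_id]
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        return sorted(members, key=lambda g: -self.loading[idx[g]])


# ---------------------------------------------------------------------------
# core engine
# ---------------------------------------------------------------------------

def _design_from_conditions(conditions) -> StudyDesign:
    rows = []
    for c in conditions:
        for r in range(1, c.n_replicates + 1):
            rows.append({
                "sample_id": f"{c.condition_id}_r{r}",
                "condition_id": c.condition_id,
                "replicate": r,
                "timepoint_hours": c.timepoint_hours,
                "is_control": c.is_control,
            })
    return StudyDesign(pd.DataFrame(rows))


def _draw_counts(rng: np.random.Generator, log_mean: np.ndarray,
                 phi: np.ndarray) -> np.ndarray:
    """NB draws with per-gene dispersion; phi == 0 falls back to Poisson."""
    mu = np.exp(log_mean)
    phi_b = np.broadcast_to(phi[:, None], mu.shape)
    counts = np.empty(mu.shape, dtype=float)
    pois = phi_b == 0
    if np.any(pois):
        counts[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if np.any(nb):
        n = 1.0 / phi_b[nb]
        p = 1.0 / (1.0 + phi_b[nb] * mu[nb])
        counts[nb] = rng.negative_binomial(n, p)
    return counts


def _gene_params(spec: PanelSpec, rng: np.random.Generator):
    """Draw per-gene baselines, loadings, dispersions and module labels."""
    gene_ids: list[str] = []
    module_of: dict[str, str] = {}
    loading: list[float] = []
    baseline: list[float] = []
    phi: list[float] = []
    marker: list[bool] = []
    lo, hi = spec.baseline_log_tpm_range
    mlo, mhi = spec.marker_log_tpm_range
    for mod in spec.modules:
        n_mark = min(mod.n_markers, mod.size)
        # markers take the top loadings with a deterministic ladder so the
        # planted hub ranking is unambiguous
        mark_load = [mod.loading * x for x in (1.0, 0.97, 0.94, 0.91, 0.88)][:n_mark]
        other_load = mod.loading * rng.uniform(0.6, 0.9, size=mod.size - n_mark)
        for j in range(mod.size):
            g = f"{mod.module_id}_g{j + 1:03d}"
            gene_ids.append(g)
            module_of[g] = mod.module_id
            if j < n_mark:
                loading.append(mark_load[j])
                baseline.append(rng.uniform(mlo, mhi))
                phi.append(spec.marker_dispersion)
                marker.append(True)
            else:
                loading.append(float(other_load[j - n_mark]))
                baseline.append(rng.uniform(lo, hi))
                phi.append(spec.dispersion)
                marker.append(False)
    blo, bhi = spec.background_log_tpm_range
    for j in range(spec.n_background):
        gene_ids.append(f"bg_g{j + 1:04d}")
        loading.append(0.0)
        baseline.append(rng.uniform(blo, bhi))
        phi.append(spec.dispersion)
        marker.append(False)
    return (gene_ids, module_of, np.asarray(loading), np.asarray(baseline),
            np.asarray(phi), np.asarray(marker, dtype=bool))


def generate_panel(spec: PanelSpec, seed: int | None = None
                   ) -> tuple[ExpressionPanel, StudyDesign, PanelTruth]:
    """Generate a counts panel, its design, and the planted truth.

    Fully reproducible from ``(spec, seed)``; ``seed`` defaults to
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    design = _design_from_conditions(spec.conditions)
    gene_ids, module_of, loading, baseline, phi, marker = _gene_params(spec, rng)

    # anchor baselines on an absolute TPM scale: rescale the background so
    # one library totals ~1e6 counts, making counts ~ TPM at baseline
    is_module = np.array([g in module_of for g in gene_ids])
    module_mass = float(np.exp(baseline[is_module]).sum())
    bg_mass = float(np.exp(baseline[~is_module]).sum())
    if bg_mass > 0 and module_mass < 1e6:
        baseline[~is_module] += np.log((1e6 - module_mass) / bg_mass)
        depth = 1.0
    else:
        depth = 1e6 / float(np.exp(baseline).sum())

    sample_ids = design.sample_ids
    cond_of_sample = dict(zip(design.table["sample_id"], design.table["condition_id"]))
    module_ids = [m.module_id for m in spec.modules]
    responses = {m.module_id: dict(m.response) for m in spec.modules}

    factors = np.empty((len(module_ids), len(sample_ids)))
    for i, mod in enumerate(spec.modules):
        resp = np.array([mod.response.get(cond_of_sample[s], 0.0) for s in sample_ids])
        factors[i] = resp + rng.normal(0.0, 1.0, size=len(sample_ids))

    mod_index = {m: i for i, m in enumerate(module_ids)}
    gene_factor = np.zeros((len(gene_ids), len(sample_ids)))
    for k, g in enumerate(gene_ids):
        m = module_of.get(g)
        if m is not None:
            gene_factor[k] = factors[mod_index[m]]

    lib_sigma = np.sqrt(np.log1p(spec.library_size_cv ** 2))
    lib = rng.normal(-0.5 * lib_sigma ** 2, lib_sigma, size=len(sample_ids))

    log_mean = (baseline[:, None] + np.log(depth)
                + loading[:, None] * gene_factor + lib[None, :])
    counts = _draw_counts(rng, log_mean, phi)

    panel = ExpressionPanel(gene_ids, sample_ids, counts, Unit.COUNT)
    truth = PanelTruth(
        gene_ids=gene_ids, module_of=module_of, loading=loading,
        baseline_log_tpm=baseline, dispersion=phi, is_marker=marker,
        factors=pd.DataFrame(factors, index=module_ids, columns=sample_ids),
        responses=responses, depth_factor=depth,
    )
    return panel, design, truth


def redraw_panel(truth: PanelTruth, conditions: tuple[ConditionSpec, ...],
                 responses: dict[str, dict[str, float]], seed: int,
                 library_size_cv: float = 0.1, coherent: bool = True
                 ) -> tuple[ExpressionPanel, StudyDesign]:
    """Draw a companion panel over the *same* genes as ``truth``.

    ``responses`` maps module -> condition -> latent response for the new
    conditions.  With ``coherent=True`` module genes share one latent
    factor per module (module structure carries over); with
    ``coherent=False`` each gene receives its own factor realization and
    a random response sign, so genes still respond individually but the
    co-expression structure is destroyed (module breakdown).
    """
    rng = np.random.default_rng(seed)
    design = _design_from_conditions(conditions)
    sample_ids = design.sample_ids
    cond_of_sample = dict(zip(design.table["sample_id"], design.table["condition_id"]))
    n_genes, n_samples = len(truth.gene_ids), len(sample_ids)

    gene_factor = np.zeros((n_genes, n_samples))
    if coherent:
        shared = {}
        for m, resp_map in responses.items():
            resp = np.array([resp_map.get(cond_of_sample[s], 0.0) for s in sample_ids])
            shared[m] = resp + rng.normal(0.0, 1.0, size=n_samples)
        for k, g in enumerate(truth.gene_ids):
            m = truth.module_of.get(g)
            if m in shared:
                gene_factor[k] = shared[m]
    else:
        for k, g in enumerate(truth.gene_ids):
            m = truth.module_of.get(g)
            if m in responses:
                resp = np.array([responses[m].get(cond_of_sample[s], 0.0)
                                 for s in sample_ids])
                sign = rng.choice([-1.0, 1.0])
                gene_factor[k] = sign * resp + rng.normal(0.0, 1.0, size=n_samples)

    lib_sigma = np.sqrt(np.log1p(library_size_cv ** 2))
    lib = rng.normal(-0.5 * lib_sigma ** 2, lib_sigma, size=n_samples)
    log_mean = (truth.baseline_log_tpm[:, None] + np.log(truth.depth_factor)
                + truth.loading[:, None] * gene_factor + lib[None, :])
    counts = _draw_counts(rng, log_mean, truth.dispersion)
    return ExpressionPanel(list(truth.gene_ids), sample_ids, counts, Unit.COUNT), design


def tpm_from_counts(panel: ExpressionPanel) -> ExpressionPanel:
    """Counts-per-million normalization (all genes are treated as equal
    length, as the generator models gene-level abundances directly)."""
    totals = panel.values.sum(axis=0)
    tpm = panel.values / totals[None, :] * 1e6
    return ExpressionPanel(list(panel.gene_ids), list(panel.sample_ids), tpm, Unit.TPM)


# ---------------------------------------------------------------------------
# canonical panels
# ---------------------------------------------------------------------------

_DEFAULT_SIZES = (20, 24, 28, 33, 38, 43, 48, 54, 60, 66, 73, 80)
_MODULE_CODES = ("BR", "PI", "CY", "YE", "TQ", "PU", "GR", "OR", "MA", "SA", "LA", "VI")


def default_panel_spec(seed: int = 0) -> PanelSpec:
    """The canonical study-scale panel: 3000 genes, 12 planted modules of
    sizes 20-80 at loading 0.8, 40 conditions (1 control) x 4 replicates,
    dispersion 0.2.

    Each module is activated (latent response ~ N(2.8, 0.3)) in a
    round-robin share of the 39 stimulus conditions plus two extra
    random conditions, and strongly suppressed (response -4) in one
    condition, mirroring panels in which stimuli both induce and shut
    down programs.
    """
    rng = np.random.default_rng(seed)
    n_modules = 12
    stim = [f"stim{i + 1:02d}" for i in range(39)]
    conditions = tuple([ConditionSpec("control", 4, True)]
                       + [ConditionSpec(c, 4, False) for c in stim])
    modules = []
    for m in range(n_modules):
        active = {i for i in range(39) if i % n_modules == m}
        extra = rng.choice([i for i in range(39) if i not in active], size=2,
                           replace=False)
        active |= set(int(i) for i in extra)
        suppress_pool = [i for i in range(39) if i not in active]
        suppressed = int(rng.choice(suppress_pool))
        response = {stim[i]: float(rng.normal(2.8, 0.3)) for i in sorted(active)}
        response[stim[suppressed]] = -4.0
        modules.append(ModuleSpec(f"M{_MODULE_CODES[m]}", _DEFAULT_SIZES[m],
                                  loading=0.8, response=response))
    return PanelSpec(n_genes=3000, modules=tuple(modules), conditions=conditions,
                     dispersion=0.2, seed=seed)


def default_panel(seed: int = 0) -> tuple[ExpressionPanel, StudyDesign, PanelTruth]:
    return generate_panel(default_panel_spec(seed))


def invivo_companion(truth: PanelTruth, seed: int, coherent: bool = True,
                     response: float = 2.2, n_per_group: int = 6,
                     modules: list[str] | None = None
                     ) -> tuple[ExpressionPanel, StudyDesign]:
    """Companion two-group draw (control vs one in vivo stimulus).

    ``coherent=True`` shares module factors with the planted structure
    (modules should be preserved); ``coherent=False`` re-randomizes
    per-gene responses (modules should break down).
    """
    if modules is None:
        modules = list(truth.factors.index)
    conditions = (ConditionSpec("invivo_control", n_per_group, True, 4.0),
                  ConditionSpec("invivo_stim", n_per_group, False, 4.0))
    responses = {m: {"invivo_stim": response} for m in modules}
    return redraw_panel(truth, conditions, responses, seed, coherent=coherent)


# ---------------------------------------------------------------------------
# stimulus-class coding scenario
# ---------------------------------------------------------------------------

_CLASS_CODES: dict[str, tuple[str, ...]] = {
    "S1": ("M1", "M2"),
    "S2": ("M3", "M4"),
    "S3": ("M5", "M6"),
    "S4": ("M1", "M3", "M5"),
    "S5": ("M2", "M6"),
}


def stimulus_code_spec(seed: int = 0, n_replicates: int = 12, amplitude: float = 3.5
                       ) -> tuple[PanelSpec, dict[str, tuple[str, ...]]]:
    """Five stimulus classes driving distinct module subsets, plus one
    additive combined stimulus (S1+S2) whose module responses are the sum
    of the single-stimulus responses."""
    conditions = tuple([ConditionSpec("control", n_replicates, True)]
                       + [ConditionSpec(s, n_replicates, False) for s in _CLASS_CODES]
                       + [ConditionSpec("S1+S2", n_replicates, False)])
    modules = []
    for mid in ("M1", "M2", "M3", "M4", "M5", "M6"):
        response = {s: amplitude for s, mods in _CLASS_CODES.items() if mid in mods}
        combo = sum(response.get(s, 0.0) for s in ("S1", "S2"))
        if combo:
            response["S1+S2"] = combo
        modules.append(ModuleSpec(mid, 30, loading=0.8, response=response))
    spec = PanelSpec(n_genes=800, modules=tuple(modules), conditions=conditions,
                     dispersion=0.2, seed=seed)
    return spec, dict(_CLASS_CODES)


def heldout_draw(truth: PanelTruth, class_id: str | tuple[str, ...], seed: int,
                 n_replicates: int = 12, amplitude: float = 3.5
                 ) -> tuple[ExpressionPanel, StudyDesign]:
    """Fresh control + one unknown-stimulus draw over the training genes.

    ``class_id`` may be a single class or a tuple of classes applied
    additively (combined stimulus).
    """
    classes = (class_id,) if isinstance(class_id, str) else tuple(class_id)
    conditions = (ConditionSpec("control", n_replicates, True),
                  ConditionSpec("query", n_replicates, False))
    responses: dict[str, dict[str, float]] = {}
    for m in truth.factors.index:
        r = sum(amplitude for c in classes if m in _CLASS_CODES[c])
        if r:
            responses[m] = {"query": float(r)}
    return redraw_panel(truth, conditions, responses, seed)


# ---------------------------------------------------------------------------
# two-sub-factor module scenario (second-round clustering substrate)
# ---------------------------------------------------------------------------

def two_factor_module_panel(seed: int = 0, sub_size: int = 25, n_replicates: int = 8
                            ) -> tuple[ExpressionPanel, StudyDesign, PanelTruth,
                                       tuple[str, str]]:
    """A panel whose first planted module is secretly two sub-modules.

    Both halves share one strong on/off response over six active
    conditions, so panel-wide they form a single module; within the
    active conditions each half additionally follows its own sub-factor
    with opposite fine structure, so restricting to the active samples
    separates them.  Returns the panel, design, truth whose labels are
    the *sub*-modules, and the pair of sub-module IDs.
    """
    rng = np.random.default_rng(seed)
    stim = [f"c{i + 1:02d}" for i in range(12)]
    conditions = tuple([ConditionSpec("control", n_replicates, True)]
                       + [ConditionSpec(c, n_replicates, False) for c in stim])
    active = stim[:6]
    base = {c: 6.0 for c in active}
    delta = {c: (1.0 if i < 3 else -1.0) for i, c in enumerate(active)}

    resp_a = {c: base[c] + delta[c] for c in active}
    resp_b = {c: base[c] - delta[c] for c in active}
    other = ModuleSpec("MX", 30, loading=0.8,
                       response={stim[8]: 3.0, stim[9]: 3.0, stim[10]: -4.0})
    sub_a = ModuleSpec("MA_sub1", sub_size, loading=0.8, response=resp_a)
    sub_b = ModuleSpec("MA_sub2", sub_size, loading=0.8, response=resp_b)
    spec = PanelSpec(n_genes=600, modules=(sub_a, sub_b, other),
                     conditions=conditions, dispersion=0.2, seed=seed)
    panel, design, truth = generate_panel(spec)

    # correlate the two sub-factors through a shared component: re-draw the
    # factor matrix so that f_A = shared + own, f_B = shared - own
    sample_ids = design.sample_ids
    cond_of_sample = dict(zip(design.table["sample_id"], design.table["condition_id"]))
    shared_resp = np.array([base.get(cond_of_sample[s], 0.0) for s in sample_ids])
    delta_resp = np.array([delta.get(cond_of_sample[s], 0.0) for s in sample_ids])
    in_active = np.array([cond_of_sample[s] in active for s in sample_ids])
    shared = shared_resp + rng.normal(0.0, 1.0, size=len(sample_ids))
    own_a = (delta_resp + rng.normal(0.0, 0.5, size=len(sample_ids))) * in_active
    own_b = (-delta_resp + rng.normal(0.0, 0.5, size=len(sample_ids))) * in_active
    factors = truth.factors.copy()
    factors.loc["MA_sub1"] = shared + own_a
    factors.loc["MA_sub2"] = shared + own_b

    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    gene_factor = np.zeros((len(truth.gene_ids), len(sample_ids)))
    for g, m in truth.module_of.items():
        gene_factor[gene_index[g]] = factors.loc[m].to_numpy()
    lib_sigma = np.sqrt(np.log1p(spec.library_size_cv ** 2))
    lib = rng.normal(-0.5 * lib_sigma ** 2, lib_sigma, size=len(sample_ids))
    log_mean = (truth.baseline_log_tpm[:, None] + np.log(truth.depth_factor)
                + truth.loading[:, None] * gene_factor + lib[None, :])
    counts = _draw_counts(rng, log_mean, truth.dispersion)
    panel = ExpressionPanel(list(truth.gene_ids), sample_ids, counts, Unit.COUNT)
    truth.factors = factors
    return panel, design, truth, ("MA_sub1", "MA_sub2")


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def score_recovery(predicted: ModuleSet, truth: PanelTruth
                   ) -> tuple[float, dict[str, float]]:
    """Adjusted Rand index and per-module best-match Jaccard of a
    predicted partition against the planted truth.

    The ARI is computed over genes assigned in either partition, with
    background / unassigned acting as their own label.
    """
    from sklearn.metrics import adjusted_rand_score

    pred = predicted.assignments
    in_either = [g for g in truth.gene_ids if g in truth.module_of or g in pred]
    t_labels = [truth.module_of.get(g, "__background__") for g in in_either]
    p_labels = [pred.get(g, "__unassigned__") for g in in_either]
    ari = float(adjusted_rand_score(t_labels, p_labels)) if in_either else 1.0

    pred_modules = predicted.modules()
    jaccard: dict[str, float] = {}
    true_modules: dict[str, set[str]] = {}
    for g, m in truth.module_of.items():
        true_modules.setdefault(m, set()).add(g)
    for m, genes in true_modules.items():
        best = 0.0
        for pgenes in pred_modules.values():
            pset = set(pgenes)
            j = len(genes & pset) / len(genes | pset)
            best = max(best, j)
        jaccard[m] = best
    return ari, jaccard
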