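"""Eigengenes, activity testing, hubs, codes, classification, overlays."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import micromod as mm
from micromod.data import CodeTable, EigengeneActivity
from micromod.states import (build_code_table, classify_state,
                             cluster_conditions, compute_eigengene,
                             module_activity, module_median_response,
                             overlay_gene_list, select_hub_gene)
from conftest import make_design, make_panel


class TestEigengene:
    def test_identical_genes_give_standardized_profile(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        x = np.vstack([base, 2 * base + 1, 0.5 * base - 2])
        panel = make_panel(x, mm.Unit.STABILIZED)
        eig = compute_eigengene(panel, panel.gene_ids)
        assert eig.explained_variance_fraction == pytest.approx(1.0)
        z = (base - base.mean()) / base.std()
        r = np.corrcoef(eig.scores, z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_scores_zero_mean(self, rng):
        panel = make_panel(rng.gamma(3, 2, size=(10, 20)), mm.Unit.STABILIZED)
        eig = compute_eigengene(panel, panel.gene_ids)
        assert abs(eig.scores.mean()) < 1e-10

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        x = rng.normal(size=(10, 20))
        panel = make_panel(x, mm.Unit.STABILIZED)
        eig = compute_eigengene(panel, panel.gene_ids)
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        w, v = np.linalg.eigh(z.T @ z)
        top = v[:, -1]
        r = np.corrcoef(eig.scores, top)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10
        assert eig.explained_variance_fraction == pytest.approx(
            w[-1] / w.sum(), rel=1e-10)

    def test_orientation_contract_on_random_modules(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(8, 15)) + 0.5 * rng.normal(size=(1, 15))
            panel = make_panel(np.abs(x) + 0.1, mm.Unit.STABILIZED)
            eig = compute_eigengene(panel, panel.gene_ids)
            zc = (panel.values - panel.values.mean(1, keepdims=True))
            zc = zc / panel.values.std(1, keepdims=True)
            assert np.corrcoef(eig.scores, zc.mean(0))[0, 1] >= -1e-12

    def test_zero_variance_gene_excluded(self, rng):
        x = rng.normal(size=(5, 12))
        x[1] = 3.0
        panel = make_panel(np.abs(x) + 4, mm.Unit.STABILIZED)
        with pytest.warns(UserWarning, match="zero-variance"):
            eig = compute_eigengene(panel, panel.gene_ids)
        assert len(eig.scores) == 12


def exact_mwu_two_sided(a, b):
    """Two-sided Mann-Whitney p by complete enumeration of group labels."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.array(us)
    mean_u = us.mean()
    p = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return p


class TestModuleActivity:
    def _activity(self, cond_scores, ctrl_scores):
        design = make_design({"control": len(ctrl_scores), "stim": len(cond_scores)})
        scores = pd.DataFrame([list(ctrl_scores) + list(cond_scores)],
                              index=["m"], columns=design.sample_ids)
        return module_activity(scores, design)

    def test_identical_distribution_not_significant(self, rng):
        act = self._activity(rng.normal(size=8), rng.normal(size=8))
        assert not act.significant[0, 0]

    def test_complete_separation_4v4_exact_p(self):
        act = self._activity([5.0, 6.0, 7.0, 8.0], [1.0, 2.0, 3.0, 4.0])
        assert act.pvalues[0, 0] == pytest.approx(2 / 70, rel=1e-9)
        # independent enumeration oracle
        oracle = exact_mwu_two_sided(np.array([5.0, 6, 7, 8]), np.array([1.0, 2, 3, 4]))
        assert act.pvalues[0, 0] == pytest.approx(oracle, rel=1e-9)
        assert act.activity[0, 0] == pytest.approx(4.0)

    def test_bonferroni_multiplies_by_family_size(self, rng):
        n_mod, n_cond = 33, 40
        design = make_design({"control": 4, **{f"c{j}": 4 for j in range(n_cond)}})
        scores = pd.DataFrame(rng.normal(size=(n_mod, 4 + 4 * n_cond)),
                              index=[f"m{i}" for i in range(n_mod)],
                              columns=design.sample_ids)
        act = module_activity(scores, design)
        expected = np.minimum(act.pvalues * (n_mod * n_cond), 1.0)
        np.testing.assert_allclose(act.pvalues_adjusted, expected, rtol=1e-12)
        assert act.pvalues_adjusted.max() == 1.0

    def test_degenerate_tied_scores_p_one(self):
        act = self._activity([1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0])
        assert act.pvalues[0, 0] == 1.0


class TestMedianResponse:
    def _modules(self):
        return mm.ModuleSet({"a": "m1", "b": "m1", "c": "m1", "d": "m2", "e": "m2"},
                            min_size=1)

    def test_uniform_response_passes_through(self):
        lfc = pd.DataFrame({"c1": [1.0, 1, 1, 2, 2]}, index=list("abcde"))
        out = module_median_response(lfc, self._modules())
        assert out.loc["m1", "c1"] == 1.0
        assert out.loc["m2", "c1"] == 2.0

    def test_per_condition_normalization_unit_max(self, rng):
        lfc = pd.DataFrame(rng.normal(size=(5, 4)), index=list("abcde"),
                           columns=[f"c{j}" for j in range(4)])
        out = module_median_response(lfc, self._modules(), "per_condition")
        assert np.allclose(out.abs().max(axis=0), 1.0)

    def test_matches_direct_median_oracle(self, rng):
        lfc = pd.DataFrame(rng.normal(size=(5, 3)), index=list("abcde"),
                           columns=["x", "y", "z"])
        out = module_median_response(lfc, self._modules())
        for mod, genes in (("m1", list("abc")), ("m2", list("de"))):
            for c in lfc.columns:
                assert out.loc[mod, c] == pytest.approx(
                    np.median(lfc.loc[genes, c]), abs=1e-12)

    def test_reference_normalization(self):
        lfc = pd.DataFrame({"ref": [2.0] * 5, "c": [1.0] * 5}, index=list("abcde"))
        out = module_median_response(lfc, self._modules(), "to_reference",
                                     reference="ref")
        assert out.loc["m1", "c"] == pytest.approx(0.5)

    def test_empty_module_rejected(self):
        lfc = pd.DataFrame({"c": [1.0]}, index=["zz"])
        with pytest.raises(ValueError, match="m1|m2"):
            module_median_response(lfc, self._modules())


class TestClusterConditions:
    def test_duplicate_columns_merge_at_zero(self, rng):
        col = rng.normal(size=6)
        m = pd.DataFrame({"a": col, "b": col, "c": rng.normal(size=6)})
        z, order = cluster_conditions(m)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_groups_split_at_top(self, rng):
        base = rng.normal(size=8)
        cols = {"a1": base + 0.01 * rng.normal(size=8),
                "a2": base + 0.01 * rng.normal(size=8),
                "b1": -base + 0.01 * rng.normal(size=8),
                "b2": -base + 0.01 * rng.normal(size=8)}
        z, order = cluster_conditions(pd.DataFrame(cols))
        assert {tuple(sorted(order[:2])), tuple(sorted(order[2:]))} == \
            {("a1", "a2"), ("b1", "b2")}

    def test_constant_column_named(self, rng):
        m = pd.DataFrame({"ok": rng.normal(size=5), "flat": np.ones(5)})
        with pytest.raises(ValueError, match="flat"):
            cluster_conditions(m)


class TestHubGene:
    def _setup(self, min_tpm_rank1=8.0):
        design = make_design({"control": 4, "a": 4})
        rng = np.random.default_rng(0)
        f = np.array([0.0] * 4 + [3.0] * 4) + 0.3 * rng.normal(size=8)
        loadings = np.array([1.0, 0.9, 0.8, 0.7] + [0.4] * 8)
        x = loadings[:, None] * f[None, :] + 0.2 * rng.normal(size=(12, 8))
        stab = make_panel(x, mm.Unit.STABILIZED, samples=design.sample_ids)
        tpm = np.exp(x * 0.5) * 20
        tpm[0] *= min_tpm_rank1 / tpm[0].min()
        tpm[0, :4] = max(min_tpm_rank1, 8.0)  # flat controls: gene 0 has CV 0
        tpm_panel = make_panel(tpm, mm.Unit.TPM, samples=design.sample_ids)
        eig = compute_eigengene(stab, stab.gene_ids)
        return tpm_panel, eig, stab, design

    def test_high_correlation_low_cv_gene_selected(self):
        tpm, eig, stab, design = self._setup()
        hub = select_hub_gene(tpm, eig, stab.gene_ids, design, ranking_expr=stab)
        assert hub.gene_id == "g0"
        assert hub.min_condition_tpm >= 5.0

    def test_tpm_floor_excludes_rank_one_gene(self):
        tpm, eig, stab, design = self._setup(min_tpm_rank1=4.9)
        # rescale gene 0 so its minimum condition-mean TPM is below 5
        cond_means = [tpm.values[0, tpm.sample_index(design.samples_of(c))].mean()
                      for c in design.condition_ids]
        tpm.values[0] *= 4.9 / min(cond_means)
        hub = select_hub_gene(tpm, eig, stab.gene_ids, design, ranking_expr=stab)
        assert hub.gene_id != "g0"

    def test_cv_tie_breaks_toward_higher_correlation(self):
        design = make_design({"control": 4, "a": 4})
        rng = np.random.default_rng(5)
        f = np.array([0.0] * 4 + [3.0] * 4) + 0.1 * rng.normal(size=8)
        x = np.vstack([f,
                       0.9 * f + 0.5 * rng.normal(size=8),
                       0.5 * f + 1.0 * rng.normal(size=8)])
        stab = make_panel(x, mm.Unit.STABILIZED, samples=design.sample_ids)
        tpm = make_panel(np.full((3, 8), 10.0) + np.abs(x), mm.Unit.TPM,
                         samples=design.sample_ids)
        # identical control values -> identical CV = 0 for every gene
        tpm.values[:, :4] = 10.0
        eig = compute_eigengene(stab, stab.gene_ids)
        hub = select_hub_gene(tpm, eig, stab.gene_ids, design, ranking_expr=stab)
        assert hub.gene_id == "g0"


class TestCodeTable:
    def _activity(self, induced):
        induced = np.asarray(induced, dtype=bool)
        m, c = induced.shape
        p = np.where(induced, 1e-6, 0.9)
        return EigengeneActivity([f"m{i}" for i in range(m)],
                                 [f"c{j}" for j in range(c)],
                                 np.where(induced, 1.0, 0.0), p,
                                 np.minimum(p * m * c, 1.0),
                                 np.minimum(p * m * c, 1.0) < 0.05)

    def test_minimal_subset_found_by_exhaustive_search(self):
        induced = [[1, 0, 0, 1, 0],
                   [0, 1, 0, 1, 0],
                   [0, 0, 1, 0, 0],
                   [1, 1, 0, 0, 0]]
        res = build_code_table(self._activity(induced))
        assert res.minimal_markers
        assert len(res.minimal_markers) <= 4
        # verify minimality by enumeration
        table = res.table
        k = len(res.minimal_markers)
        for size in range(1, k):
            for combo in itertools.combinations(table.marker_ids, size):
                sub = table.restrict(list(combo))
                assert sub.indistinguishable_pairs(), \
                    f"smaller subset {combo} distinguishes all conditions"

    def test_identical_condition_columns_flagged(self):
        induced = [[1, 1, 0], [0, 0, 1]]
        res = build_code_table(self._activity(induced))
        assert ("c0", "c1") in res.indistinguishable

    def test_suppression_not_counted_as_induction(self):
        act = self._activity([[1, 0]])
        act.activity[0, 0] = -1.0  # significant but suppressed
        res = build_code_table(act)
        assert not res.table.induced[0, 0]


class TestClassifyState:
    def _code(self):
        induced = np.array([[1, 0, 0],
                            [0, 1, 0],
                            [1, 1, 0]], dtype=bool)
        return CodeTable(["m0", "m1", "m2"], ["A", "B", "control"], induced)

    def test_unique_column_match(self):
        code = self._code()
        assert classify_state({"m0": True, "m1": False, "m2": True}, code) == ["A"]

    def test_or_pattern_reported_as_pair(self):
        code = self._code()
        out = classify_state({"m0": True, "m1": True, "m2": True}, code)
        assert out == [("A", "B")]

    def test_all_false_matches_control(self):
        code = self._code()
        out = classify_state({"m0": False, "m1": False, "m2": False}, code)
        assert out == ["control"]

    def test_novel_state_empty(self):
        induced = np.array([[1, 0], [0, 1]], dtype=bool)
        code = CodeTable(["m0", "m1"], ["A", "B"], induced)
        # no single column or OR-pair yields (False, False) here except none
        assert classify_state({"m0": False, "m1": False}, code) == []

    def test_unknown_marker_rejected(self):
        with pytest.raises(KeyError):
            classify_state({"zz": True}, self._code())


class TestOverlay:
    def _modules(self):
        return mm.ModuleSet({f"a{i}": "m1" for i in range(5)} |
                            {f"b{i}": "m2" for i in range(5)}, min_size=1)

    def test_list_inside_single_module(self):
        part, frac = overlay_gene_list(["a0", "a1", "a2"], self._modules())
        assert set(part) == {"m1"}
        assert frac["m1"] == 1.0

    def test_empty_list(self):
        part, frac = overlay_gene_list([], self._modules())
        assert part == {} and frac == {}

    def test_matches_set_operations_oracle(self, rng):
        modules = self._modules()
        universe = list(modules.assignments) + [f"x{i}" for i in range(10)]
        picks = [universe[i] for i in rng.choice(len(universe), 8, replace=False)]
        part, frac = overlay_gene_list(picks, modules)
        for m, genes in modules.modules().items():
            expect = [g for g in picks if g in set(genes)]
            assert part.get(m, []) == expect
        assert part.get("unassigned", []) == [g for g in picks
                                              if modules.module_of(g) is None]
        assert sum(frac.values()) == pytest.approx(1.0)
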