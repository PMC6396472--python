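# micromod

Co-expression module discovery and activation-state coding for
multi-condition transcriptome stimulus panels.

Microglia (and other responsive cell types) do not occupy a few discrete
activation states; their transcriptional response to dozens of stimuli is
better described by a modest set of co-regulated gene **modules** whose
combinatorial induction pattern identifies the stimulus. `micromod`
implements that analysis as a tested, reusable pipeline for gene-by-sample
expression panels (integer counts or TPM) with a sample design table:

1. **Preprocessing** — sample QC (a sample must express ≥ 6500 genes at
   TPM > 5), replicate reproducibility (mean pairwise Pearson *r* per
   condition), a per-gene negative-binomial error model fitted on control
   replicates (`var = μ + φμ²`), a variance-stabilizing transform
   `g(x) = (2/√φ)·asinh(√(φx))`, a replicate-wise differential-expression
   rule (two-sided NB tail test; a gene is significant in a condition only
   if *every* replicate has p ≤ 0.05), and gene selection (top-variable ∪
   differentially expressed).
2. **Network / module discovery** — soft-thresholded correlation adjacency
   `a_ij = |cor(x_i, x_j)|^β` with β chosen as the lowest power reaching a
   scale-free fit R² ≥ 0.8, topological-overlap dissimilarity,
   average-linkage clustering, a dynamic hybrid tree cut
   (minimum module size 20, deep-split levels 0–4, optional PAM stage),
   eigengene-based merging of near-duplicate modules (cut height 0.25), and
   an optional second clustering round inside each module restricted to the
   samples of its active conditions.
3. **Module statistics** — module eigengenes (first principal component of
   the standardized member expression), differential activity per condition
   (Mann-Whitney U vs control, Bonferroni over the module × condition
   family), the intra-module correlation score (the mean member correlation
   of the gene at the 75th percentile of the within-module ranking) with a
   half-sampling bootstrap (reproducible ⇔ mean score > 0.35), hub-gene
   selection (top-10 eigengene correlation, ≥ 5 TPM in every condition,
   lowest control CV), median-response summaries, and in vivo
   activation/preservation calls (≥ 1.5-fold responders, score > 0.35).
4. **Combinatorial codes** — binary module × condition induction tables, a
   provably minimal marker subset that distinguishes the conditions, and
   classification of new replicate sets against the code, including
   additive two-stimulus superpositions.
5. **Synthetic panels** — a log-linear latent-factor NB generator that
   plants modules, condition response profiles, marker genes and library
   effects, with aligned ground truth; it is the test substrate for the
   whole package.

## Worked example

```python
import micromod as mm

spec, codes = mm.stimulus_code_spec(0)        # 5 stimulus classes, 6 planted modules
panel, design, truth = mm.generate_panel(spec)

model = mm.ModuleDiscovery(panel, design, n_variable=200)
results = model.fit(bootstrap=mm.BootstrapSpec(n_iterations=100, seed=0))
print(results.summary())
```

```
Module discovery: 6 modules over 200 selected genes (800 total), soft power 1

module            size  active             hub   quality
BR                  34       2         M5_g020     0.775
PI                  34       2         M4_g002     0.718
CY                  32       3         M2_g014     0.861
YE                  31       3         M1_g002     0.836
TQ                  31       2         M6_g001     0.825
PU                  36       3         M3_g013     0.680
```

Each row is a discovered module: its size, the number of conditions where
its eigengene is significantly active (Bonferroni p < 0.05), the selected
hub gene, and the bootstrap mean of the intra-module correlation score
(all > 0.35, i.e. reproducible). The induction code across the five
stimulus classes and its minimal distinguishing subset:

```python
code = results.code(conditions=list(codes))
print(code.table.to_frame())
print(code.minimal_markers)
```

```
    S1  S2  S3  S4  S5
BR   0   0   1   1   0
PI   0   1   0   0   0
CY   1   0   0   0   1
YE   1   0   0   1   0
TQ   0   0   1   0   1
PU   0   1   0   1   0

['BR', 'PI', 'YE']
```

Three module markers suffice to tell the five stimulus classes apart;
`classify_state` maps the observed induction pattern of a new replicate
set to its class, and a pattern matching the OR of two columns is reported
as that stimulus pair.

On the canonical study-scale panel (3000 genes, 12 planted modules,
40 conditions × 4 replicates; `mm.default_panel(seed)`) the same pipeline
recovers the planted partition with an adjusted Rand index of 1.000
(seed 0) and every hub gene lands among its module's three highest-loading
planted genes.

A `micromod` command-line interface chains the same stages over text files
(`micromod simulate | qc | select-genes | modules | quality | eigengenes |
hubs | code | classify | preserve | summarize`); see `micromod --help`.

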