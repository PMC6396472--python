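import numpy as np
import pandas as pd
import pytest

from micromod import ExpressionPanel, StudyDesign, Unit


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_panel(values, unit=Unit.TPM, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionPanel(genes, samples, values, unit)


def make_design(condition_sizes, controls=("control",), timepoint=24.0):
    """condition_sizes: dict condition -> n replicates."""
    rows = []
    for cond, n in condition_sizes.items():
        for r in range(1, n + 1):
            rows.append({"sample_id": f"{cond}_r{r}", "condition_id": cond,
                         "replicate": r, "timepoint_hours": timepoint,
                         "is_control": cond in controls})
    return StudyDesign(pd.DataFrame(rows))


@pytest.fixture
def small_counts_panel(rng):
    """Counts panel with one control and two test conditions, 4 reps each."""
    design = make_design({"control": 4, "stimA": 4, "stimB": 4})
    n_genes = 30
    base = rng.uniform(2.0, 4.0, size=n_genes)
    factor = np.array([0.0] * 4 + [2.0] * 4 + [0.0] * 4)
    load = np.zeros(n_genes)
    load[:10] = 0.8  # first ten genes respond to stimA
    logmean = base[:, None] + load[:, None] * factor[None, :]
    counts = rng.poisson(np.exp(logmean))
    panel = make_panel(counts.astype(float), Unit.COUNT,
                       samples=design.sample_ids)
    return panel, design
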