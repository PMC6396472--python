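"""Core data containers for stimulus-panel co-expression analysis.

The containers are deliberately thin wrappers around numpy arrays and a
pandas design table: every analysis stage consumes and produces one of
them, so validation lives here rather than in each algorithm.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Unit",
    "ExpressionPanel",
    "StudyDesign",
    "ModuleSet",
    "EigengeneActivity",
    "CodeTable",
    "ModuleQuality",
    "QualityReport",
]


class Unit(str, Enum):
    """Scale of an expression matrix."""

    TPM = "TPM"
    COUNT = "COUNT"
    STABILIZED = "STABILIZED"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {what}: {', '.join(map(str, dups))}")


@dataclass
class ExpressionPanel:
    """A gene-by-sample expression matrix with an explicit unit.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique row / column identifiers (opaque strings).
    values
        Non-negative matrix of shape ``(len(gene_ids), len(sample_ids))``.
        Integer-valued when ``unit`` is COUNT.
    unit
        TPM, COUNT, or STABILIZED (output of the variance-stabilizing
        transform; may take any real value).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: Unit = Unit.TPM

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.unit = Unit(self.unit)
        _check_unique(self.gene_ids, "gene IDs")
        _check_unique(self.sample_ids, "sample IDs")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.unit in (Unit.TPM, Unit.COUNT):
            if np.any(self.values < 0):
                raise ValueError(f"negative values not allowed for unit {self.unit.value}")
        if self.unit is Unit.COUNT:
            if not np.allclose(self.values, np.round(self.values), atol=1e-8):
                raise ValueError("COUNT panel contains non-integer values")

    # -- indexing helpers -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.asarray([lookup[g] for g in genes], dtype=int)
        except KeyError as e:  # pragma: no cover - message formatting
            raise KeyError(f"gene {e.args[0]!r} not in panel") from None

    def sample_index(self, samples: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.asarray([lookup[s] for s in samples], dtype=int)
        except KeyError as e:  # pragma: no cover
            raise KeyError(f"sample {e.args[0]!r} not in panel") from None

    def subset(self, genes: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "ExpressionPanel":
        genes = list(genes) if genes is not None else self.gene_ids
        samples = list(samples) if samples is not None else self.sample_ids
        gi = self.gene_index(genes)
        si = self.sample_index(samples)
        return ExpressionPanel(genes, samples, self.values[np.ix_(gi, si)], self.unit)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, unit: Unit | str = Unit.TPM) -> "ExpressionPanel":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float), Unit(unit))


_DESIGN_COLUMNS = ["sample_id", "condition_id", "replicate", "timepoint_hours", "is_control"]


@dataclass
class StudyDesign:
    """Sample-to-condition mapping for a stimulus panel.

    One row per sample; ``is_control`` marks the reference (unstimulated)
    samples against which differential statistics are computed. Controls
    may be supplied per timepoint.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        t = self.table.loc[:, _DESIGN_COLUMNS].copy().reset_index(drop=True)
        t["sample_id"] = t["sample_id"].astype(str)
        t["condition_id"] = t["condition_id"].astype(str)
        t["replicate"] = t["replicate"].astype(int)
        t["timepoint_hours"] = t["timepoint_hours"].astype(float)
        t["is_control"] = t["is_control"].astype(bool)
        self.table = t
        _check_unique(list(t["sample_id"]), "sample IDs")
        if not t["is_control"].any():
            raise ValueError("design has no control samples")

    @classmethod
    def from_records(cls, records: Iterable[tuple | dict]) -> "StudyDesign":
        records = list(records)
        if records and isinstance(records[0], dict):
            frame = pd.DataFrame.from_records(records)
        else:
            frame = pd.DataFrame(records, columns=_DESIGN_COLUMNS)
        return cls(frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def condition_ids(self) -> list[str]:
        """Unique condition IDs in first-appearance order."""
        return list(dict.fromkeys(self.table["condition_id"]))

    @property
    def control_conditions(self) -> list[str]:
        t = self.table
        return [c for c in self.condition_ids
                if t.loc[t["condition_id"] == c, "is_control"].all()]

    @property
    def test_conditions(self) -> list[str]:
        ctrl = set(self.control_conditions)
        return [c for c in self.condition_ids if c not in ctrl]

    def samples_of(self, condition: str) -> list[str]:
        t = self.table
        return list(t.loc[t["condition_id"] == condition, "sample_id"])

    def control_samples(self, timepoint: float | None = None) -> list[str]:
        """Control sample IDs; restricted to a timepoint when controls for
        that timepoint exist, otherwise the full control pool."""
        t = self.table
        ctrl = t.loc[t["is_control"]]
        if timepoint is not None:
            matched = ctrl.loc[ctrl["timepoint_hours"] == float(timepoint)]
            if len(matched):
                return list(matched["sample_id"])
        return list(ctrl["sample_id"])

    def timepoint_of(self, condition: str) -> float:
        t = self.table
        vals = t.loc[t["condition_id"] == condition, "timepoint_hours"].unique()
        return float(vals[0])

    def subset(self, samples: Iterable[str]) -> "StudyDesign":
        keep = set(samples)
        return StudyDesign(self.table.loc[self.table["sample_id"].isin(keep)])


@dataclass
class ModuleSet:
    """Gene-to-module assignment with module lineage.

    ``assignments`` maps gene -> module (unassigned genes are absent).
    ``lineage`` maps module -> (first-order parent or None, order in
    {1, 2}).  Every module must have at least ``min_size`` members.
    """

    assignments: dict[str, str]
    lineage: dict[str, tuple[str | None, int]] = field(default_factory=dict)
    min_size: int = 20

    def __post_init__(self) -> None:
        for mod in self.module_ids:
            if mod not in self.lineage:
                self.lineage[mod] = (None, 1)
        for mod, (parent, order) in self.lineage.items():
            if order not in (1, 2):
                raise ValueError(f"module {mod}: order must be 1 or 2, got {order}")
        sizes = self.sizes
        small = [m for m, n in sizes.items() if n < self.min_size]
        if small:
            raise ValueError(
                f"modules below min_size={self.min_size}: "
                + ", ".join(f"{m} ({sizes[m]})" for m in small)
            )

    @property
    def module_ids(self) -> list[str]:
        return list(dict.fromkeys(self.assignments.values()))

    @property
    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for mod in self.assignments.values():
            out[mod] = out.get(mod, 0) + 1
        return out

    def members(self, module_id: str) -> list[str]:
        return [g for g, m in self.assignments.items() if m == module_id]

    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, m in self.assignments.items():
            out.setdefault(m, []).append(g)
        return out

    def module_of(self, gene: str) -> str | None:
        return self.assignments.get(gene)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModuleSet):
            return NotImplemented
        return (self.assignments == other.assignments
                and self.lineage == other.lineage
                and self.min_size == other.min_size)


@dataclass
class EigengeneActivity:
    """Module-by-condition eigengene activity with significance calls.

    ``activity`` is the mean eigengene score of a condition's samples
    minus the control mean; ``pvalues`` are raw two-sided Mann-Whitney
    p-values and ``pvalues_adjusted`` their Bonferroni correction over
    the whole module-by-condition family.  ``significant`` is exactly
    ``pvalues_adjusted < alpha``.
    """

    module_ids: list[str]
    condition_ids: list[str]
    activity: np.ndarray
    pvalues: np.ndarray
    pvalues_adjusted: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05

    def __post_init__(self) -> None:
        shape = (len(self.module_ids), len(self.condition_ids))
        for name in ("activity", "pvalues", "pvalues_adjusted", "significant"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        if np.any((self.pvalues < 0) | (self.pvalues > 1)):
            raise ValueError("raw p-values outside [0, 1]")
        expected = self.pvalues_adjusted < self.alpha
        if not np.array_equal(self.significant.astype(bool), expected):
            raise ValueError("significant flags inconsistent with adjusted p-values")

    def to_frame(self, what: str = "activity") -> pd.DataFrame:
        return pd.DataFrame(getattr(self, what), index=self.module_ids,
                            columns=self.condition_ids)


@dataclass
class CodeTable:
    """Binary induction code: marker (module or hub gene) x condition."""

    marker_ids: list[str]
    condition_ids: list[str]
    induced: np.ndarray

    def __post_init__(self) -> None:
        self.induced = np.asarray(self.induced, dtype=bool)
        shape = (len(self.marker_ids), len(self.condition_ids))
        if self.induced.shape != shape:
            raise ValueError(f"induced has shape {self.induced.shape}, expected {shape}")

    def column(self, condition: str) -> tuple[bool, ...]:
        j = self.condition_ids.index(condition)
        return tuple(bool(x) for x in self.induced[:, j])

    def indistinguishable_pairs(self) -> list[tuple[str, str]]:
        """Condition pairs whose full induction patterns coincide."""
        pairs = []
        cols = {c: self.column(c) for c in self.condition_ids}
        for i, a in enumerate(self.condition_ids):
            for b in self.condition_ids[i + 1:]:
                if cols[a] == cols[b]:
                    pairs.append((a, b))
        return pairs

    def restrict(self, markers: Sequence[str]) -> "CodeTable":
        idx = [self.marker_ids.index(m) for m in markers]
        return CodeTable(list(markers), list(self.condition_ids), self.induced[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.induced.astype(int), index=self.marker_ids,
                            columns=self.condition_ids)


@dataclass
class ModuleQuality:
    """Bootstrap summary of a module's intra-module correlation score."""

    score_mean: float
    score_sd: float
    n_bootstrap: int
    reproducible: bool
    threshold: float

    def __post_init__(self) -> None:
        if self.score_sd < 0:
            raise ValueError("score_sd must be >= 0")
        if self.reproducible != (self.score_mean > self.threshold):
            raise ValueError("reproducible flag inconsistent with threshold")


class QualityReport(dict):
    """module_id -> :class:`ModuleQuality`."""

    def to_frame(self) -> pd.DataFrame:
        rows = {m: vars(q) for m, q in self.items()}
        return pd.DataFrame.from_dict(rows, orient="index")

    def to_jsonable(self) -> dict:
        return {m: {k: (bool(v) if isinstance(v, (bool, np.bool_)) else
                        int(v) if isinstance(v, (int, np.integer)) else float(v))
                    for k, v in vars(q).items()}
                for m, q in self.items()}
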