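"""Readers, writers and sample QC for panel inputs.

Expression tables are genes-by-samples text matrices (TSV or CSV,
auto-detected from the header line).  Module gene sets use the GMT
dialect: ``module_id <TAB> description <TAB> gene1 <TAB> gene2 ...``,
where the description field optionally carries lineage as
``order=<1|2>[;parent=<module_id>]``.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionPanel, ModuleSet, StudyDesign, Unit

__all__ = [
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
    "read_modules_gmt",
    "write_modules_gmt",
    "filter_samples",
    "write_json_report",
]


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_expression(path: str | Path, unit: Unit | str = Unit.TPM) -> ExpressionPanel:
    """Read a genes-by-samples expression table.

    First column holds gene IDs, header row holds sample IDs.  Duplicate
    gene or sample IDs and negative values raise ``ValueError`` naming
    the offenders (via panel validation).
    """
    path = Path(path)
    sep = _sniff_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_ids = header[1:]
    frame = pd.read_csv(path, sep=sep, index_col=0, skiprows=1, header=None,
                        float_precision="round_trip")
    gene_ids = [str(g) for g in frame.index]
    return ExpressionPanel(gene_ids, sample_ids, frame.to_numpy(dtype=float), Unit(unit))


def write_expression(panel: ExpressionPanel, path: str | Path, sep: str | None = None) -> None:
    """Write a panel so that ``read_expression`` recovers it exactly.

    Values are serialized with ``repr``-level precision, so numeric
    content round-trips bit-for-bit.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, "w") as fh:
        fh.write("gene_id" + sep + sep.join(panel.sample_ids) + "\n")
        for g, row in zip(panel.gene_ids, panel.values):
            fh.write(g + sep + sep.join(repr(float(x)) for x in row) + "\n")


def read_design(path: str | Path) -> StudyDesign:
    frame = pd.read_csv(path, sep=_sniff_sep(Path(path)))
    return StudyDesign(frame)


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.table.to_csv(path, index=False)


def _format_lineage(module_id: str, lineage: dict) -> str:
    parent, order = lineage.get(module_id, (None, 1))
    desc = f"order={order}"
    if parent is not None:
        desc += f";parent={parent}"
    return desc


def _parse_lineage(desc: str) -> tuple[str | None, int]:
    parent, order = None, 1
    for token in desc.split(";"):
        token = token.strip()
        if token.startswith("order="):
            order = int(token[len("order="):])
        elif token.startswith("parent="):
            parent = token[len("parent="):]
    return parent, order


def read_modules_gmt(path: str | Path, min_size: int = 1) -> ModuleSet:
    """Read a GMT file into a :class:`ModuleSet`.

    A gene listed under two modules, or a module line with no genes,
    raises ``ValueError``.  Lineage defaults to order 1 with no parent
    when the description field does not encode it.
    """
    assignments: dict[str, str] = {}
    lineage: dict[str, tuple[str | None, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: module {fields[0]!r} has no genes")
            module_id, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: module {module_id!r} is empty")
            if module_id in lineage:
                raise ValueError(f"{path}:{lineno}: duplicate module {module_id!r}")
            for g in genes:
                if g in assignments:
                    raise ValueError(
                        f"gene {g!r} assigned to both {assignments[g]!r} and {module_id!r}"
                    )
                assignments[g] = module_id
            lineage[module_id] = _parse_lineage(desc)
    return ModuleSet(assignments, lineage, min_size=min_size)


def write_modules_gmt(modules: ModuleSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for module_id, genes in modules.modules().items():
            desc = _format_lineage(module_id, modules.lineage)
            fh.write("\t".join([module_id, desc, *genes]) + "\n")


def filter_samples(panel: ExpressionPanel, min_genes: int = 6500,
                   tpm_floor: float = 5.0) -> ExpressionPanel:
    """Drop samples expressing fewer than ``min_genes`` genes above
    ``tpm_floor`` TPM.

    The defaults implement the panel QC rule: a sample must express at
    least 6500 genes at TPM > 5 to be retained.  Raises if no sample
    survives.  Idempotent: filtering a filtered panel is a no-op.
    """
    if panel.unit is not Unit.TPM:
        raise ValueError("filter_samples requires a TPM panel")
    expressed = (panel.values > tpm_floor).sum(axis=0)
    keep = [s for s, n in zip(panel.sample_ids, expressed) if n >= min_genes]
    if not keep:
        raise ValueError(
            f"all samples removed: no sample has >= {min_genes} genes with TPM > {tpm_floor}"
        )
    if len(keep) == panel.n_samples:
        return panel
    return panel.subset(samples=keep)


def write_json_report(obj, path: str | Path) -> None:
    def _default(x):
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, (np.bool_,)):
            return bool(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
        raise TypeError(f"not JSON serializable: {type(x)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
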