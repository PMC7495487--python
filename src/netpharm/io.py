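"""Readers and writers for the pipeline's plain-text file dialects.

All formats are simple TSV/CSV or GMT; the synthetic-data writers emit
exactly the dialects the pipeline readers consume, so generated fixtures
double as format tests.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .diffexpr import ExpressionStudy
from .organ_localization import TissueExpression
from .target_assembly import TargetSet

__all__ = [
    "read_compound_table",
    "write_compound_table",
    "read_target_list",
    "write_target_list",
    "write_target_set",
    "read_alias_map",
    "read_expression_study",
    "write_expression_study",
    "write_string_edges",
    "read_tissue_matrix",
    "write_tissue_matrix",
    "read_probe_map",
    "read_panel",
    "write_panel",
    "read_compound_target_map",
    "write_compound_target_map",
]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_compound_table(path: str | Path) -> pd.DataFrame:
    """Read a compound table (TSV, or CSV by extension)."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep(path))
    required = {"compound_id", "name", "ob", "dl"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


def write_compound_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    table.to_csv(path, sep=_sep(path), index=False)


def read_target_list(path: str | Path) -> list[str]:
    """One raw symbol per line; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out


def write_target_list(symbols: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sorted(symbols):
            fh.write(f"{s}\n")


def write_target_set(ts: TargetSet, path: str | Path) -> None:
    """Merged TSV: symbol, comma-joined provenance tags."""
    with open(path, "w") as fh:
        fh.write("symbol\tprovenance\n")
        for s in sorted(ts.symbols):
            fh.write(f"{s}\t{','.join(sorted(ts.provenance[s]))}\n")


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping raw identifiers to preferred symbols."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: alias map needs two columns")
    return dict(zip(table[0].str.strip(), table[1].str.strip()))


def read_expression_study(
    matrix_path: str | Path, sheet_path: str | Path
) -> ExpressionStudy:
    """Expression TSV (gene rows x sample columns) + sample sheet TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    required = {"sample", "group", "batch"}
    if not required <= set(sheet.columns):
        raise ValueError(f"{sheet_path}: needs columns {sorted(required)}")
    sheet = sheet.set_index("sample").loc[list(matrix.columns)]
    return ExpressionStudy(
        matrix=matrix, groups=sheet["group"], batches=sheet["batch"]
    )


def write_expression_study(
    study: ExpressionStudy, matrix_path: str | Path, sheet_path: str | Path
) -> None:
    study.matrix.to_csv(matrix_path, sep="\t", float_format="%.6f")
    sheet = pd.DataFrame(
        {
            "sample": study.matrix.columns,
            "group": study.groups.to_numpy(),
            "batch": study.batches.to_numpy(),
        }
    )
    sheet.to_csv(sheet_path, sep="\t", index=False)


def write_string_edges(
    edges: Iterable[tuple[str, str, int]], path: str | Path, header: bool = True
) -> None:
    """STRING-dialect edge TSV: node1, node2, combined_score (0-1000)."""
    with open(path, "w") as fh:
        if header:
            fh.write("node1\tnode2\tcombined_score\n")
        for u, v, score in edges:
            fh.write(f"{u}\t{v}\t{int(score)}\n")


def read_tissue_matrix(
    path: str | Path, missing_path: str | Path | None = None
) -> TissueExpression:
    """Gene (or probe) rows x tissue columns TSV; optional missing-gene list."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    missing: set[str] = set()
    if missing_path is not None and Path(missing_path).exists():
        missing = set(read_target_list(missing_path))
    return TissueExpression(values=values, missing=missing)


def write_tissue_matrix(
    expr: TissueExpression, path: str | Path, missing_path: str | Path | None = None
) -> None:
    expr.values.to_csv(path, sep="\t", float_format="%.6f")
    if missing_path is not None:
        write_target_list(expr.missing, missing_path)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping probe ids to gene symbols."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: probe map needs two columns")
    return dict(zip(table[0].str.strip(), table[1].str.strip()))


def read_panel(path: str | Path) -> list[str]:
    """Organ panel file: one tissue per line, '#' comments skipped."""
    return read_target_list(path)


def write_panel(panel: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in panel:
            fh.write(f"{t}\n")


def read_compound_target_map(path: str | Path) -> dict[str, list[str]]:
    """TSV with columns compound, target (one pair per row)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"compound", "target"} <= set(table.columns):
        raise ValueError(f"{path}: needs columns compound, target")
    out: dict[str, list[str]] = {}
    for _, row in table.iterrows():
        out.setdefault(str(row["compound"]), []).append(str(row["target"]))
    return out


def write_compound_target_map(
    mapping: dict[str, Iterable[str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("compound\ttarget\n")
        for comp in sorted(mapping):
            for t in sorted(set(mapping[comp])):
                fh.write(f"{comp}\t{t}\n")
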