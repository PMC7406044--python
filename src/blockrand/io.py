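"""Reading cohort tables from delimited text and writing result reports.

Cohorts arrive as TSV/CSV with a header row — the same shape a spreadsheet
paste produces: one row per experimental unit, with the unit id, the numeric
covariates and optionally a physical marker in named columns.  Column
selection is by name, so column order in the file is free.  Values use '.'
as the decimal separator; ',' is also accepted whenever it is not the field
delimiter, so European-locale exports parse unchanged.

Reports are plain TSV (machine-readable leaderboard) plus a human-readable
text summary; means and SDs in reports are rounded to the per-covariate
display decimals, while all computation upstream is full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .model import (
    BlockDesign,
    BlockSet,
    CohortError,
    CohortTable,
    ExperimentalUnit,
    GroupAllocation,
)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ColumnMap:
    """Names of the id, covariate and (optional) marker columns."""

    id_column: str
    covariate_columns: tuple[str, ...]
    marker_column: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "covariate_columns", tuple(self.covariate_columns)
        )
        names = [self.id_column, *self.covariate_columns]
        if self.marker_column is not None:
            names.append(self.marker_column)
        if len(set(names)) != len(names):
            raise CohortError(f"column names must be disjoint, got {names}")

    def check_against(self, header: Sequence[str]) -> None:
        missing = [
            c
            for c in (self.id_column, *self.covariate_columns)
            if c not in header
        ]
        if self.marker_column is not None and self.marker_column not in header:
            missing.append(self.marker_column)
        if missing:
            raise CohortError(f"columns {missing} not found in header {list(header)}")


def _parse_number(raw: str, delimiter: str, row: int, column: str) -> float:
    text = raw.strip()
    if delimiter != "," and "," in text and "." not in text:
        text = text.replace(",", ".")
    try:
        value = float(text)
    except ValueError:
        raise CohortError(
            f"non-numeric covariate value {raw!r} at row {row}, column {column!r}"
        ) from None
    if math.isnan(value):
        raise CohortError(
            f"missing covariate value at row {row}, column {column!r}"
        )
    return value


def read_cohort(
    source, colmap: ColumnMap, delimiter: str = "\t"
) -> CohortTable:
    """Parse a delimited cohort table (path or file-like) into a CohortTable.

    One experimental unit per data row, in file order.  Raises
    :class:`CohortError` on duplicate ids, non-numeric covariates (with row
    and column named in the message) or an empty table.
    """
    df = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=False)
    colmap.check_against(df.columns)
    if len(df) == 0:
        raise CohortError("cohort table has no data rows")
    units = []
    for pos, (_, row) in enumerate(df.iterrows()):
        uid = str(row[colmap.id_column]).strip()
        covs = tuple(
            _parse_number(row[c], delimiter, pos + 1, c)
            for c in colmap.covariate_columns
        )
        marker = None
        if colmap.marker_column is not None:
            marker = str(row[colmap.marker_column]).strip() or None
        units.append(ExperimentalUnit(id=uid, covariates=covs, marker=marker))
    return CohortTable(
        covariate_names=tuple(colmap.covariate_columns), units=tuple(units)
    )


def write_cohort(
    cohort: CohortTable, path: PathLike, delimiter: str = "\t"
) -> Path:
    """Write a cohort back to delimited text at full float precision
    (round-trips exactly through :func:`read_cohort`)."""
    path = Path(path)
    header = ["id", *cohort.covariate_names]
    if cohort.has_markers:
        header.append("marker")
    lines = [delimiter.join(header)]
    for u in cohort.units:
        fields = [str(u.id), *(repr(c) for c in u.covariates)]
        if cohort.has_markers:
            fields.append(str(u.marker))
        lines.append(delimiter.join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def default_colmap(cohort: CohortTable) -> ColumnMap:
    """Column map matching :func:`write_cohort` output."""
    return ColumnMap(
        id_column="id",
        covariate_columns=cohort.covariate_names,
        marker_column="marker" if cohort.has_markers else None,
    )


_BLOCK_ID_SEP = ";"


def write_report(
    leaderboard,
    cohort: CohortTable,
    design: BlockDesign,
    path: PathLike,
    *,
    seed=None,
    stats=None,
) -> tuple[Path, Path]:
    """Write the leaderboard as TSV plus a text summary next to it.

    Per ranked set: rank, ranking value at full precision and display
    rounding, marker modifications when applicable, per-block unit ids and
    per-block per-covariate mean±SD rounded to the design decimals.
    Returns (tsv_path, summary_path).
    """
    if len(leaderboard) == 0:
        raise CohortError("cannot write a report for an empty leaderboard")
    tsv_path = Path(path)
    txt_path = tsv_path.with_suffix(".txt")
    decimals = design.decimals or tuple(2 for _ in cohort.covariate_names)

    n_blocks = len(leaderboard.entries[0].block_set.blocks)
    cols = ["rank", "ranking_value", "ranking_value_display"]
    has_mods = any(e.marker_modifications is not None for e in leaderboard)
    if has_mods:
        cols.append("marker_modifications")
    for j in range(n_blocks):
        cols.append(f"block{j + 1}_ids")
        for name in cohort.covariate_names:
            cols.append(f"block{j + 1}_{name}_mean_sd")

    rows = []
    for rank, entry in enumerate(leaderboard, start=1):
        row: dict = {
            "rank": rank,
            "ranking_value": repr(entry.ranking_value),
            "ranking_value_display": f"{entry.ranking_value:.4f}",
        }
        if has_mods:
            row["marker_modifications"] = (
                "" if entry.marker_modifications is None else entry.marker_modifications
            )
        for j, block in enumerate(entry.block_set.blocks):
            row[f"block{j + 1}_ids"] = _BLOCK_ID_SEP.join(
                sorted((str(u) for u in block))
            )
            for i, name in enumerate(cohort.covariate_names):
                s = entry.summaries[i]
                d = decimals[i]
                row[f"block{j + 1}_{name}_mean_sd"] = (
                    f"{s.block_means[j]:.{d}f}±{s.block_sds[j]:.{d}f}"
                )
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(tsv_path, sep="\t", index=False)

    lines = ["Block randomization report", "=" * 26]
    if seed is not None:
        lines.append(f"seed: {seed}")
    if stats is not None:
        lines.append(
            f"attempts: {stats.attempts}  unique: {stats.unique_created}  "
            f"duplicates: {stats.duplicates_rejected}  "
            f"total unique possible: {stats.total_unique}"
        )
    lines.append(
        f"SD convention: {'sample (n-1)' if design.sample_sd else 'population (n)'}; "
        f"CV as {'percentage' if design.cv_percent else 'proportion'}"
    )
    lines.append("")
    for rank, entry in enumerate(leaderboard, start=1):
        head = f"#{rank}  ranking value {entry.ranking_value:.6f}"
        if entry.marker_modifications is not None:
            head += f"  marker modifications {entry.marker_modifications}"
        lines.append(head)
        for j, block in enumerate(entry.block_set.blocks):
            ids = ", ".join(sorted((str(u) for u in block)))
            lines.append(f"  block {j + 1} (n={len(block)}): {ids}")
            for i, name in enumerate(cohort.covariate_names):
                s = entry.summaries[i]
                d = decimals[i]
                lines.append(
                    f"    {name}: {s.block_means[j]:.{d}f}±{s.block_sds[j]:.{d}f}"
                )
        if entry.block_set.leftover:
            lines.append(
                "  leftover: " + ", ".join(sorted(map(str, entry.block_set.leftover)))
            )
        lines.append("")
    txt_path.write_text("\n".join(lines))
    return tsv_path, txt_path


def read_report_blocks(path: PathLike, rank: int = 1) -> BlockSet:
    """Recover the block set at a given rank from a leaderboard TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    match = df[df["rank"].astype(int) == rank]
    if match.empty:
        raise CohortError(f"no entry with rank {rank} in {path}")
    row = match.iloc[0]
    blocks = []
    for col in df.columns:
        if col.endswith("_ids") and col.startswith("block"):
            blocks.append(frozenset(str(row[col]).split(_BLOCK_ID_SEP)))
    return BlockSet(blocks=tuple(blocks))


def write_allocation(
    allocation: GroupAllocation,
    block_set: BlockSet,
    path: PathLike,
    delimiter: str = "\t",
) -> Path:
    """Write the unit -> group assignment as a delimited table."""
    path = Path(path)
    mapping = allocation.unit_to_group(block_set)
    rows = []
    for j, block in enumerate(block_set.blocks):
        for uid in sorted(block, key=str):
            rows.append(
                {"id": uid, "block": j + 1, "group": allocation.labels_by_block[j]}
            )
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
    assert set(mapping) == {r["id"] for r in rows}
    return path
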