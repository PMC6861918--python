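"""TSV readers and writers for the pipeline's tabular dialects.

All tables are UTF-8, tab-separated, LF-terminated, with "NA" (or an
empty cell) for missing values. Readers validate headers and cell types
and report malformed input with file, line and column so a bad export is
caught at the boundary rather than deep inside an analysis.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .concordance import ConcordanceRecord
from .engagement import QpcrMeasurement
from .scoring import CompoundEvidence, ScoreCard
from .signatures import DifferentialExpressionRecord, ExpressionSignature, IdMappingTable

__all__ = [
    "read_de_table",
    "read_mapping_table",
    "write_signature",
    "read_signature",
    "read_concordance_table",
    "read_plate_table",
    "read_ct_table",
    "read_panel_table",
    "read_evidence_table",
    "write_scorecards",
    "write_table",
]

NA_VALUES = {"", "NA", "No score"}


class TableFormatError(ValueError):
    """Malformed tabular input, reported with file, line and column."""


def _rows(path: Path | str, expected_header: Sequence[str]):
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise TableFormatError(f"{path}: empty table")
    header = lines[0].split("\t")
    if header != list(expected_header):
        raise TableFormatError(
            f"{path}, line 1: expected header {list(expected_header)}, got {header}"
        )
    for line_no, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise TableFormatError(
                f"{path}, line {line_no}: expected {len(header)} columns, got {len(cells)}"
            )
        yield path, line_no, dict(zip(header, cells))


def _num(cell: str, path, line_no: int, column: str, allow_na: bool = False):
    if cell in NA_VALUES:
        if allow_na:
            return None
        raise TableFormatError(f"{path}, line {line_no}, column {column!r}: missing value")
    try:
        value = float(cell)
    except ValueError:
        raise TableFormatError(
            f"{path}, line {line_no}, column {column!r}: non-numeric cell {cell!r}"
        ) from None
    if math.isnan(value):
        return None if allow_na else value
    return value


# ---------------------------------------------------------------------------
# stage-specific readers


def read_de_table(path) -> list[DifferentialExpressionRecord]:
    """`gene_id  log2fc  fdr` — "NA" permitted in fdr."""
    records = []
    for p, ln, row in _rows(path, ("gene_id", "log2fc", "fdr")):
        records.append(
            DifferentialExpressionRecord(
                gene_id=row["gene_id"],
                log2_fold_change=_num(row["log2fc"], p, ln, "log2fc"),
                fdr=_num(row["fdr"], p, ln, "fdr", allow_na=True),
            )
        )
    return records


def read_mapping_table(path) -> IdMappingTable:
    """`source_id  target_id`."""
    pairs = tuple(
        (row["source_id"], row["target_id"])
        for _, _, row in _rows(path, ("source_id", "target_id"))
    )
    return IdMappingTable(pairs=pairs)


def write_signature(
    sig: ExpressionSignature,
    path,
    fc_threshold: float | None = None,
    fdr_threshold: float | None = None,
) -> None:
    """Signature TSV with a one-line comment carrying label and thresholds."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            f"# label={sig.label}\tfc_threshold={fc_threshold}\t"
            f"fdr_threshold={fdr_threshold}\n"
        )
        fh.write("gene_id\tdirection\tlog2fc\n")
        for gene_id, direction, lfc in sig.entries:
            fh.write(f"{gene_id}\t{direction}\t{lfc:.6g}\n")


def read_signature(path) -> ExpressionSignature:
    label = "signature"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("# label="):
        label = first.removeprefix("# label=").split("\t")[0].strip()
    entries = tuple(
        (row["gene_id"], row["direction"], _num(row["log2fc"], p, ln, "log2fc"))
        for p, ln, row in _rows(path, ("gene_id", "direction", "log2fc"))
    )
    return ExpressionSignature(label=label, entries=entries)


def read_concordance_table(path) -> list[ConcordanceRecord]:
    """`compound  timepoint  concordance  cell_line  signature_id`;
    "No score" or an empty cell encodes an absent concordance."""
    records = []
    header = ("compound", "timepoint", "concordance", "cell_line", "signature_id")
    for p, ln, row in _rows(path, header):
        if row["timepoint"] not in ("acute", "chronic"):
            raise TableFormatError(
                f"{p}, line {ln}, column 'timepoint': expected acute/chronic, "
                f"got {row['timepoint']!r}"
            )
        records.append(
            ConcordanceRecord(
                compound=row["compound"],
                timepoint=row["timepoint"],
                concordance=_num(row["concordance"], p, ln, "concordance", allow_na=True),
                cell_line=row["cell_line"],
                signature_id=row["signature_id"],
            )
        )
    return records


def read_plate_table(path) -> pd.DataFrame:
    """`experiment_id  well_id  treatment  concentration_uM  analyte  value`."""
    header = ("experiment_id", "well_id", "treatment", "concentration_uM", "analyte", "value")
    rows = []
    for p, ln, row in _rows(path, header):
        rows.append(
            {
                "experiment_id": row["experiment_id"],
                "well_id": row["well_id"],
                "treatment": row["treatment"],
                "concentration": _num(row["concentration_uM"], p, ln, "concentration_uM"),
                "analyte": row["analyte"],
                "value": _num(row["value"], p, ln, "value"),
            }
        )
    return pd.DataFrame(rows)


def read_ct_table(path) -> list[QpcrMeasurement]:
    """`sample_id  gene  ct  batch  condition  treatment`."""
    header = ("sample_id", "gene", "ct", "batch", "condition", "treatment")
    out = []
    for p, ln, row in _rows(path, header):
        out.append(
            QpcrMeasurement(
                sample_id=row["sample_id"],
                gene=row["gene"],
                ct=_num(row["ct"], p, ln, "ct"),
                batch=row["batch"],
                condition=row["condition"],
                treatment=row["treatment"],
            )
        )
    return out


def read_panel_table(path) -> pd.DataFrame:
    """`animal_id  group  day  cytokine  concentration` (long format)."""
    header = ("animal_id", "group", "day", "cytokine", "concentration")
    rows = []
    for p, ln, row in _rows(path, header):
        rows.append(
            {
                "animal_id": row["animal_id"],
                "group": row["group"],
                "day": int(_num(row["day"], p, ln, "day")),
                "cytokine": row["cytokine"],
                "concentration": _num(row["concentration"], p, ln, "concentration"),
            }
        )
    return pd.DataFrame(rows)


def read_evidence_table(path) -> list[CompoundEvidence]:
    """`compound  component  points  note` -> one CompoundEvidence per compound."""
    points: dict[str, dict[str, int]] = {}
    notes: dict[str, dict[str, str]] = {}
    for p, ln, row in _rows(path, ("compound", "component", "points", "note")):
        value = _num(row["points"], p, ln, "points")
        if value != int(value):
            raise TableFormatError(
                f"{p}, line {ln}, column 'points': expected integer, got {row['points']!r}"
            )
        points.setdefault(row["compound"], {})[row["component"]] = int(value)
        notes.setdefault(row["compound"], {})[row["component"]] = row["note"]
    return [
        CompoundEvidence(compound=c, points=points[c], notes=notes[c]) for c in points
    ]


def write_scorecards(cards: Iterable[ScoreCard], path) -> None:
    """Component rows, cumulative subtotal rows and the total per compound."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("compound\trow\tpoints\tcontribution\n")
        for card in cards:
            for name, pts, contrib in card.contributions:
                fh.write(f"{card.compound}\t{name}\t{pts}\t{contrib:.6g}\n")
            for block, value in card.subtotals.items():
                fh.write(f"{card.compound}\tsubtotal_{block}\tNA\t{value:.6g}\n")
            fh.write(f"{card.compound}\ttotal\tNA\t{card.total:.6g}\n")


def write_table(df: pd.DataFrame, path, rename: dict | None = None) -> None:
    """Uniform TSV writer: UTF-8, LF, NA for missing."""
    out = df.rename(columns=rename or {})
    out.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")
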