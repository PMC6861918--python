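"""Transcriptomic signature construction from differential-expression tables.

A *signature* is the directioned gene set surviving a joint fold-change /
FDR filter applied to a differential-expression (DE) table, one signature
per post-injury timepoint (e.g. an acute 32-h microarray contrast and a
chronic 3-month RNA-seq contrast, injured vs control cortex). Signatures
are the query objects submitted to connectivity-mapping services; this
module only builds and translates them, it never computes the DE
statistics themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DifferentialExpressionRecord",
    "ExpressionSignature",
    "IdMappingTable",
    "build_signature",
    "translate_ids",
    "fold_change_percent",
]


@dataclass(frozen=True)
class DifferentialExpressionRecord:
    """One gene's DE result: log2 fold change and BH-adjusted p (FDR).

    ``fdr`` is ``None`` when the DE fit produced no adjusted p-value
    (printed "NA" in tables); such records never enter a signature.
    """

    gene_id: str
    log2_fold_change: float
    fdr: float | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must lie in [0, 1], got {self.fdr!r}")


@dataclass(frozen=True)
class ExpressionSignature:
    """A labelled, directioned gene set.

    ``entries`` holds ``(gene_id, direction, log2_fold_change)`` tuples with
    direction in {"up", "down"} matching the sign of the fold change.
    """

    label: str
    entries: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene_id, direction, lfc in self.entries:
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id in signature: {gene_id}")
            seen.add(gene_id)
            if direction not in ("up", "down"):
                raise ValueError(f"invalid direction {direction!r} for {gene_id}")
            if (direction == "up") != (lfc > 0):
                raise ValueError(
                    f"direction {direction!r} inconsistent with log2FC {lfc} for {gene_id}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene_id", "direction", "log2fc"])


@dataclass(frozen=True)
class IdMappingTable:
    """Source→target identifier pairs (e.g. rat probe IDs to human NCBI IDs).

    One source may map to several targets (one-to-many expansion); duplicated
    (source, target) pairs are rejected.
    """

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicated (source, target) pair in mapping table")

    def targets_of(self, source_id: str) -> tuple[str, ...]:
        return tuple(t for s, t in self.pairs if s == source_id)


def build_signature(
    records: Iterable[DifferentialExpressionRecord],
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    label: str = "signature",
) -> ExpressionSignature:
    """Filter a DE table into a signature.

    A record is included iff ``|log2FC| > log2(fc_threshold)`` (strict) and
    its FDR is present and ``< fdr_threshold`` (strict). ``fc_threshold`` is
    on the linear scale (1.5 means a 1.5-fold change either way).
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1 (linear fold change)")
    if not (0 < fdr_threshold <= 1):
        raise ValueError("fdr_threshold must lie in (0, 1]")

    records = list(records)
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id in DE table: {rec.gene_id}")
        seen.add(rec.gene_id)

    cut = math.log2(fc_threshold)
    entries = tuple(
        (r.gene_id, "up" if r.log2_fold_change > 0 else "down", r.log2_fold_change)
        for r in records
        if r.fdr is not None and r.fdr < fdr_threshold and abs(r.log2_fold_change) > cut
    )
    return ExpressionSignature(label=label, entries=entries)


def translate_ids(
    sig: ExpressionSignature,
    mapping: IdMappingTable,
    fdr_by_gene: Mapping[str, float] | None = None,
) -> tuple[ExpressionSignature, int]:
    """Re-key a signature through an ID mapping table.

    Unmapped entries are dropped (the count of dropped sources is returned
    alongside the translated signature). A source with several targets is
    expanded to all of them, each carrying the source's direction and
    fold change. When several sources collapse onto one target:

    * conflicting directions → rejected (the translation is ambiguous);
    * same direction → the entry with the smallest FDR wins when
      ``fdr_by_gene`` is given, else ties break by source gene_id
      lexicographic order.
    """
    if not mapping.pairs:
        raise ValueError("mapping table is empty")

    by_target: dict[str, list[tuple[str, str, float]]] = {}
    dropped = 0
    for gene_id, direction, lfc in sig.entries:
        targets = mapping.targets_of(gene_id)
        if not targets:
            dropped += 1
            continue
        for t in targets:
            by_target.setdefault(t, []).append((gene_id, direction, lfc))

    entries: list[tuple[str, str, float]] = []
    for target in sorted(by_target):
        candidates = by_target[target]
        directions = {c[1] for c in candidates}
        if len(directions) > 1:
            sources = sorted(c[0] for c in candidates)
            raise ValueError(
                f"mapping collision on target {target}: sources {sources} "
                "carry conflicting directions"
            )

        def sort_key(c: tuple[str, str, float]) -> tuple[float, str]:
            fdr = fdr_by_gene.get(c[0], math.inf) if fdr_by_gene else math.inf
            return (fdr, c[0])

        src, direction, lfc = min(candidates, key=sort_key)
        entries.append((target, direction, lfc))

    return ExpressionSignature(label=sig.label, entries=tuple(entries)), dropped


def fold_change_percent(log2fc: float, integer: bool = True) -> float | int:
    """Convert a log2 fold change to percent-of-control (2^log2FC x 100).

    A log2FC of 0 is 100% (no change); 2.860 is 726% (a strong induction).
    With ``integer=True`` the result is rounded half-up to the nearest
    whole percent, matching how such effects are reported.
    """
    if not math.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    percent = (2.0**log2fc) * 100.0
    if integer:
        return math.floor(percent + 0.5)
    return percent
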