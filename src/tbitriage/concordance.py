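"""Percentile banding of compound-vs-signature concordance scores.

Connectivity-mapping services return a signed concordance in [-1, 1] per
(compound, disease signature) pair: how strongly the compound's induced
expression signature matches (or mirrors) the disease signature. Within a
candidate list, compounds are ranked by |concordance| and the rank
percentile is converted to 0-5 integer points per timepoint: top 10% of
the ranking earns 5 points, top 10-20% earns 4, and so on down to 1 point
for top 40-50%; anything weaker (or a compound without a score) earns 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "ConcordanceRecord",
    "PercentileBandScale",
    "DEFAULT_BAND_SCALE",
    "percentile_rank",
    "concordance_points",
    "score_concordance",
]

Timepoint = Literal["acute", "chronic"]


@dataclass(frozen=True)
class ConcordanceRecord:
    """One compound's concordance with a signature at one timepoint.

    ``concordance=None`` encodes a "No score" cell (the compound is absent
    from the library, or the query returned nothing).
    """

    compound: str
    timepoint: Timepoint
    concordance: float | None
    cell_line: str = ""
    signature_id: str = ""

    def __post_init__(self) -> None:
        if self.concordance is not None and abs(self.concordance) > 1:
            raise ValueError(
                f"|concordance| must be <= 1, got {self.concordance} for {self.compound}"
            )


@dataclass(frozen=True)
class PercentileBandScale:
    """Ordered (upper-edge, points) bands over the rank percentile.

    ``bands`` maps an inclusive percentile upper edge to the integer points
    earned by any percentile at or below it; percentiles beyond the last
    edge (and absent scores) earn ``default_points``.
    """

    bands: tuple[tuple[float, int], ...] = (
        (0.10, 5),
        (0.20, 4),
        (0.30, 3),
        (0.40, 2),
        (0.50, 1),
    )
    default_points: int = 0

    def __post_init__(self) -> None:
        edges = [e for e, _ in self.bands]
        points = [p for _, p in self.bands]
        if any(not (0 < e <= 1) for e in edges):
            raise ValueError("band edges must lie in (0, 1]")
        if edges != sorted(edges) or len(set(edges)) != len(edges):
            raise ValueError("band edges must be strictly increasing")
        if points != sorted(points, reverse=True):
            raise ValueError("band points must be weakly decreasing")


DEFAULT_BAND_SCALE = PercentileBandScale()


def percentile_rank(
    records: Iterable[ConcordanceRecord], timepoint: Timepoint
) -> dict[str, float]:
    """Rank compounds at one timepoint by |concordance|; percentile = rank/N.

    Rank 1 is the strongest |concordance|; tied absolute scores share the
    worst (largest) percentile of the tied block, so a tie never inflates a
    compound's band. Compounds with an absent score receive no percentile.
    """
    rows = [r for r in records if r.timepoint == timepoint]
    seen: set[str] = set()
    for r in rows:
        if r.compound in seen:
            raise ValueError(
                f"duplicate ({r.compound}, {timepoint}) concordance record"
            )
        seen.add(r.compound)

    scored = [(r.compound, abs(r.concordance)) for r in rows if r.concordance is not None]
    if not scored:
        raise ValueError(f"no scored concordance records at timepoint {timepoint!r}")

    n = len(scored)
    # max-rank tie policy: percentile = (#compounds with |c| >= own) / N
    out: dict[str, float] = {}
    for compound, a in scored:
        rank = sum(1 for _, b in scored if b >= a)
        out[compound] = rank / n
    return out


def concordance_points(
    percentile: float | None,
    scale: PercentileBandScale = DEFAULT_BAND_SCALE,
    concordance: float | None = None,
    negative_scores_eligible: bool = False,
) -> int:
    """Convert a rank percentile to integer band points.

    Ranking is on |concordance|, so a strongly *negative* concordance can in
    principle earn points; by default (``negative_scores_eligible=False``)
    a negative signed score is floored to 0 points — reversal of the
    disease signature is not rewarded unless explicitly requested. Pass the
    signed ``concordance`` to enable that gate; absent percentile → 0.
    """
    if percentile is None:
        return scale.default_points
    if not (0 < percentile <= 1):
        raise ValueError(f"percentile must lie in (0, 1], got {percentile}")
    if (
        not negative_scores_eligible
        and concordance is not None
        and concordance < 0
    ):
        return scale.default_points
    for edge, points in scale.bands:
        if percentile <= edge:
            return points
    return scale.default_points


def score_concordance(
    records: Iterable[ConcordanceRecord],
    timepoint: Timepoint,
    scale: PercentileBandScale = DEFAULT_BAND_SCALE,
    negative_scores_eligible: bool = False,
) -> pd.DataFrame:
    """Full banding of a concordance table at one timepoint.

    Returns one row per compound: signed concordance (NaN when absent),
    percentile (NaN when absent) and integer points.
    """
    records = list(records)
    percentiles = percentile_rank(records, timepoint)
    rows = []
    for r in records:
        if r.timepoint != timepoint:
            continue
        pct = percentiles.get(r.compound)
        pts = concordance_points(
            pct,
            scale=scale,
            concordance=r.concordance,
            negative_scores_eligible=negative_scores_eligible,
        )
        rows.append(
            {
                "compound": r.compound,
                "timepoint": timepoint,
                "concordance": float("nan") if r.concordance is None else r.concordance,
                "percentile": float("nan") if pct is None else pct,
                "points": pts,
            }
        )
    return pd.DataFrame(rows)
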