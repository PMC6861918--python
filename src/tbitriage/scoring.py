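"""Weighted go/no-go composite scoring of candidate compounds.

Evidence about each compound — concordance band points per timepoint,
blood-brain-barrier penetration and water solubility, banded co-culture
biomarker effects, and per-gene target-engagement calls — is combined
into a single weighted score. Default weights: 10% for each of the two
concordance timepoints and the two pharmacokinetic properties, 15% for
the TNFa and nitrite assays, 20% for neuronal viability, and 1.25% for
each of the eight engagement slots (4 genes x 2 culture conditions).
The default scheme's achievable totals span -3.6 to 4.6.

Contributions are points x weight; printed subtotals are *cumulative*
running sums in component order, and the total is the final cumulative
sum. Arithmetic uses exact rationals so reported decimals are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import yaml

__all__ = [
    "SchemeComponent",
    "ScoringScheme",
    "CompoundEvidence",
    "ScoreCard",
    "default_scheme",
    "weighted_score",
    "score_bounds",
    "rank_compounds",
    "load_scheme",
    "save_scheme",
]

ENGAGEMENT_GENES = ("Nfe2l2", "Gclm", "Hmox1", "Nqo1")


@dataclass(frozen=True)
class SchemeComponent:
    name: str
    category: str
    weight: Fraction  # fraction of the total, e.g. Fraction(1, 10) for 10%
    min_points: int
    max_points: int
    block: str

    def check_points(self, points: int) -> None:
        if not (self.min_points <= points <= self.max_points):
            raise ValueError(
                f"points {points} outside [{self.min_points}, {self.max_points}] "
                f"for component {self.name!r}"
            )


@dataclass(frozen=True)
class ScoringScheme:
    components: tuple[SchemeComponent, ...]
    #: blocks after which a cumulative subtotal is reported
    subtotal_blocks: tuple[str, ...] = ("pharmacokinetics", "coculture")

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("duplicate component name in scheme")

    def component(self, name: str) -> SchemeComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def total_weight(self) -> Fraction:
        return sum((c.weight for c in self.components), Fraction(0))


@dataclass(frozen=True)
class CompoundEvidence:
    """Per-component integer points for one compound; absent components
    (e.g. engagement never assayed) contribute 0 with a warning."""

    compound: str
    points: Mapping[str, int]
    notes: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ScoreCard:
    compound: str
    #: (component name, points, weighted contribution) in scheme order
    contributions: tuple[tuple[str, int, float], ...]
    #: cumulative running sum at the end of each subtotal block
    subtotals: Mapping[str, float]
    total: float


def default_scheme() -> ScoringScheme:
    """The shipped scheme: weights and bands used for the TBI triage."""
    pct = lambda x: Fraction(x, 100)
    comps: list[SchemeComponent] = [
        SchemeComponent("concordance_acute", "concordance_acute", pct(10), 0, 5, "time_window"),
        SchemeComponent("concordance_chronic", "concordance_chronic", pct(10), 0, 5, "time_window"),
        SchemeComponent("bbb", "bbb", pct(10), -5, 5, "pharmacokinetics"),
        SchemeComponent("water_solubility", "water_solubility", pct(10), -5, 5, "pharmacokinetics"),
        SchemeComponent("tnfa", "tnfa", pct(15), -5, 5, "coculture"),
        SchemeComponent("nitrite", "nitrite", pct(15), -5, 5, "coculture"),
        SchemeComponent("viability", "viability", pct(20), -5, 5, "coculture"),
    ]
    for cond in ("inflammatory", "non_inflammatory"):
        for gene in ENGAGEMENT_GENES:
            comps.append(
                SchemeComponent(
                    f"engagement_{cond}_{gene}",
                    "engagement",
                    Fraction(125, 10000),  # 1.25%
                    -1,
                    1,
                    f"engagement_{cond}",
                )
            )
    return ScoringScheme(components=tuple(comps))


def weighted_score(
    evidence: CompoundEvidence | Mapping[str, int],
    scheme: ScoringScheme | None = None,
    compound: str | None = None,
) -> ScoreCard:
    """Apply a scheme to one compound's points.

    Contribution_i = points_i x weight_i; subtotals are cumulative sums in
    scheme component order; total is the final cumulative sum.
    """
    scheme = scheme or default_scheme()
    if isinstance(evidence, CompoundEvidence):
        points_map, name = evidence.points, evidence.compound
    else:
        points_map, name = evidence, compound or "compound"

    unknown = set(points_map) - {c.name for c in scheme.components}
    if unknown:
        raise ValueError(f"evidence names unknown components: {sorted(unknown)}")

    running = Fraction(0)
    contributions: list[tuple[str, int, float]] = []
    subtotals: dict[str, float] = {}
    prev_block: str | None = None
    for comp in scheme.components:
        if prev_block in scheme.subtotal_blocks and comp.block != prev_block:
            subtotals[prev_block] = float(running)
        if comp.name in points_map:
            pts = int(points_map[comp.name])
            comp.check_points(pts)
        else:
            warnings.warn(
                f"{name}: no evidence for component {comp.name!r}, scoring 0",
                stacklevel=2,
            )
            pts = 0
        contrib = comp.weight * pts
        running += contrib
        contributions.append((comp.name, pts, float(contrib)))
        prev_block = comp.block
    if prev_block in scheme.subtotal_blocks:
        subtotals[prev_block] = float(running)

    return ScoreCard(
        compound=name,
        contributions=tuple(contributions),
        subtotals=subtotals,
        total=float(running),
    )


def score_bounds(scheme: ScoringScheme | None = None) -> tuple[float, float]:
    """(min_total, max_total) achievable under a scheme."""
    scheme = scheme or default_scheme()
    lo = sum((c.weight * c.min_points for c in scheme.components), Fraction(0))
    hi = sum((c.weight * c.max_points for c in scheme.components), Fraction(0))
    return float(lo), float(hi)


def rank_compounds(cards: Sequence[ScoreCard]) -> list[tuple[ScoreCard, bool]]:
    """Descending by total; ties by co-culture cumulative subtotal, then
    alphabetically. The top-ranked compound is flagged for advancement."""
    if not cards:
        raise ValueError("need at least one score card")

    def key(card: ScoreCard):
        return (-card.total, -card.subtotals.get("coculture", 0.0), card.compound)

    ordered = sorted(cards, key=key)
    return [(card, i == 0) for i, card in enumerate(ordered)]


# ---------------------------------------------------------------------------
# scheme (de)serialization: YAML with weights written as decimal strings so
# they round-trip through Fraction exactly

def load_scheme(path) -> ScoringScheme:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    comps = []
    for c in raw["components"]:
        w = c["weight"]
        weight = Fraction(str(w).rstrip("%")) / (100 if str(w).endswith("%") else 1)
        comps.append(
            SchemeComponent(
                name=c["name"],
                category=c.get("category", c["name"]),
                weight=weight,
                min_points=int(c["min_points"]),
                max_points=int(c["max_points"]),
                block=c.get("block", c["name"]),
            )
        )
    blocks = tuple(raw.get("subtotal_blocks", ("pharmacokinetics", "coculture")))
    return ScoringScheme(components=tuple(comps), subtotal_blocks=blocks)


def save_scheme(scheme: ScoringScheme, path) -> None:
    data = {
        "subtotal_blocks": list(scheme.subtotal_blocks),
        "components": [
            {
                "name": c.name,
                "category": c.category,
                "weight": f"{float(c.weight * 100):g}%",
                "min_points": c.min_points,
                "max_points": c.max_points,
                "block": c.block,
            }
            for c in scheme.components
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
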