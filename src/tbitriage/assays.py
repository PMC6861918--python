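"""Neuron-microglia co-culture plate analytics.

Three monitoring biomarkers are read from each plate: secreted TNFa
(neuroinflammation), nitrite (nitric-oxide-mediated neurotoxicity) and a
MAP2 immunostaining signal (neuronal viability). For TNFa and nitrite a
*lower* treated value is the favourable outcome (inhibition assays); for
viability a *higher* value is favourable. Each treated condition is
summarised as percent of the untreated control, tested against the
control wells with a two-sided Mann-Whitney U-test, and banded into
integer points for the composite go/no-go score.

The exact Mann-Whitney branch (small samples, ties allowed) is computed
by full enumeration of group assignments; larger samples fall back to the
tie-corrected normal approximation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WellMeasurement",
    "AssayResult",
    "INHIBITION_ANALYTES",
    "percent_of_control",
    "mann_whitney_vs_control",
    "dose_dependence",
    "assay_points",
    "analyze_plate",
    "compound_assay_points",
]

Analyte = Literal["TNFa", "nitrite", "viability"]

#: analytes where a reduction relative to control is the favourable effect
INHIBITION_ANALYTES = frozenset({"TNFa", "nitrite"})

EXACT_LIMIT = 16  # enumerate the null distribution up to this pooled size


@dataclass(frozen=True)
class WellMeasurement:
    """One raw well read (pg/mL TNFa, uM nitrite or absorbance)."""

    experiment_id: str
    well_id: str
    treatment: str  # compound name, "control", or a positive control
    concentration: float  # uM; 0 for control
    analyte: Analyte
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"assay value must be >= 0, got {self.value}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")


@dataclass(frozen=True)
class AssayResult:
    treatment: str
    concentration: float
    analyte: Analyte
    percent_of_control: float
    p_value: float
    significant: bool
    n_wells: int


def percent_of_control(
    treated: Sequence[float], control: Sequence[float]
) -> float:
    """mean(treated) / mean(control) x 100."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("treated and control must be non-empty")
    if (treated < 0).any() or (control < 0).any():
        raise ValueError("assay values must be non-negative")
    c = control.mean()
    if c <= 0:
        raise ValueError("control mean must be positive")
    return float(treated.mean() / c * 100.0)


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _exact_mw_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumeration (ties handled by midranks).

    p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))) over all C(n, n_a)
    equally likely assignments of the pooled values to the two groups.
    """
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0

    n = na + nb
    le = ge = total = 0
    for subset in itertools.combinations(range(n), na):
        u = ranks[list(subset)].sum() - na * (na + 1) / 2.0
        total += 1
        # tolerance for midrank float sums
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def mann_whitney_vs_control(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact by enumeration when the pooled size is <= 16, tie-corrected
    normal approximation otherwise. Completely tied data gives p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.unique(np.concatenate([a, b])).size == 1:
        return 1.0  # zero separation, no evidence
    if len(a) + len(b) <= EXACT_LIMIT:
        return _exact_mw_p(a, b)
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    )


def dose_dependence(
    lower_conc_wells: Sequence[float],
    higher_conc_wells: Sequence[float],
    lower_conc: float,
    higher_conc: float,
    inhibition: bool = True,
) -> tuple[float, bool]:
    """Compare two concentration groups of the same treatment and analyte.

    Returns ``(p, more_effective)`` where ``more_effective`` is True when
    the higher concentration's mean effect is stronger (lower mean for
    inhibition assays, higher for viability) *and* the Mann-Whitney p is
    below 0.05.
    """
    if lower_conc == higher_conc:
        raise ValueError("concentration labels must differ")
    p = mann_whitney_vs_control(lower_conc_wells, higher_conc_wells)
    lo = float(np.mean(lower_conc_wells))
    hi = float(np.mean(higher_conc_wells))
    stronger = hi < lo if inhibition else hi > lo
    return p, bool(stronger and p < 0.05)


# (upper edge of percent-of-control, points) for inhibition assays;
# a significant *increase* past 100% scores -5
_INHIBITION_BANDS = ((10.0, 5), (30.0, 4), (50.0, 3), (70.0, 2), (90.0, 1))
# (lower edge of percent-of-control, points) for the viability assay;
# a significant *decrease* below 100% scores -5
_VIABILITY_BANDS = ((300.0, 5), (250.0, 4), (200.0, 3), (150.0, 2), (115.0, 1))


def assay_points(analyte: str, percent: float, significant: bool) -> int:
    """Band a percent-of-control effect into -5..5 integer points.

    Non-significant effects always score 0. Band edges are inclusive on the
    favourable side (exactly 70% of control earns the "<70%" band's 2
    points for an inhibition assay).
    """
    if percent < 0:
        raise ValueError("percent must be >= 0")
    if analyte in INHIBITION_ANALYTES:
        if not significant:
            return 0
        if percent > 100.0:
            return -5
        for edge, pts in _INHIBITION_BANDS:
            if percent <= edge:
                return pts
        return 0  # significant but within (90, 100]: no credit
    if analyte == "viability":
        if not significant:
            return 0
        if percent < 100.0:
            return -5
        for edge, pts in _VIABILITY_BANDS:
            if percent > edge:
                return pts
        return 0  # significant but within [100, 115]: no credit
    raise ValueError(f"unknown analyte {analyte!r}")


def analyze_plate(
    wells: pd.DataFrame | Iterable[WellMeasurement],
    control_treatment: str = "control",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (treatment, concentration, analyte) percent-of-control and p-value.

    Wells are pooled across experiments (replicate plates); every treated
    cell is compared against the pooled control wells of the same analyte.
    """
    df = _as_frame(wells)
    results: list[AssayResult] = []
    for analyte, sub in df.groupby("analyte", sort=False):
        control = sub.loc[sub["treatment"] == control_treatment, "value"].to_numpy()
        if control.size == 0:
            raise ValueError(f"no {control_treatment!r} wells for analyte {analyte!r}")
        treated_rows = sub[sub["treatment"] != control_treatment]
        for (treatment, conc), cell in treated_rows.groupby(
            ["treatment", "concentration"], sort=False
        ):
            values = cell["value"].to_numpy()
            pct = percent_of_control(values, control)
            p = mann_whitney_vs_control(values, control)
            results.append(
                AssayResult(
                    treatment=treatment,
                    concentration=float(conc),
                    analyte=analyte,
                    percent_of_control=pct,
                    p_value=p,
                    significant=bool(p < alpha),
                    n_wells=int(values.size),
                )
            )
    out = pd.DataFrame([r.__dict__ for r in results])
    return out


def compound_assay_points(results: pd.DataFrame) -> pd.DataFrame:
    """One banded point value per (treatment, analyte).

    Table-style reporting assigns a compound a single point value per
    biomarker across its tested concentrations: the strongest significant
    concentration is banded (minimum percent for inhibition assays,
    maximum for viability); with no significant concentration the
    compound scores 0 for that biomarker.
    """
    rows = []
    for (treatment, analyte), sub in results.groupby(["treatment", "analyte"], sort=False):
        sig = sub[sub["significant"]]
        if sig.empty:
            pts, pct = 0, float("nan")
        else:
            pct = (
                float(sig["percent_of_control"].min())
                if analyte in INHIBITION_ANALYTES
                else float(sig["percent_of_control"].max())
            )
            pts = assay_points(analyte, pct, True)
        rows.append(
            {
                "treatment": treatment,
                "analyte": analyte,
                "percent_of_control": pct,
                "points": pts,
            }
        )
    return pd.DataFrame(rows)


def _as_frame(wells: pd.DataFrame | Iterable[WellMeasurement]) -> pd.DataFrame:
    if isinstance(wells, pd.DataFrame):
        required = {"experiment_id", "well_id", "treatment", "concentration", "analyte", "value"}
        missing = required - set(wells.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        return wells
    return pd.DataFrame([w.__dict__ for w in wells])
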