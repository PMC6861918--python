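"""qPCR target-engagement quantification by the delta-Ct method.

Target engagement asks whether a compound actually regulates the genes
the in silico analysis predicted (here the Nrf2 axis: Nfe2l2 and its
target genes Gclm, Hmox1, Nqo1). Expression is quantified relative to a
reference gene (Gapdh) as 2^-(Ct_gene - Ct_reference); treatment effects
are estimated on the -dCt scale - i.e. directly in log2 expression units -
by ordinary least squares with the experiment replicate (batch) as a
fixed-effect covariate, so a constant per-batch Ct offset is absorbed.
A per-gene, per-condition call (up / down / none at p < 0.05) maps to a
+1 / -1 / 0 engagement point for the composite score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd
import statsmodels.api as sm

__all__ = [
    "QpcrMeasurement",
    "EngagementCall",
    "relative_expression",
    "engagement_effect",
    "call_engagement",
    "engagement_points",
    "analyze_qpcr",
]

Condition = Literal["inflammatory", "non_inflammatory"]
Call = Literal["up", "down", "none"]

REFERENCE_GENE = "Gapdh"


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    gene: str
    ct: float
    batch: str
    condition: Condition
    treatment: str

    def __post_init__(self) -> None:
        if not (self.ct > 0 and math.isfinite(self.ct)):
            raise ValueError(f"Ct must be a finite positive value, got {self.ct}")


@dataclass(frozen=True)
class EngagementCall:
    gene: str
    condition: Condition
    log2_fold_change: float
    p_value: float
    call: Call
    point: int

    def __post_init__(self) -> None:
        expected = {"up": 1, "down": -1, "none": 0}[self.call]
        if self.point != expected:
            raise ValueError(f"call {self.call!r} requires point {expected}")


def relative_expression(ct_gene: float, ct_reference: float) -> float:
    """2^-(Ct_gene - Ct_reference): one extra cycle halves the estimate."""
    for name, ct in (("ct_gene", ct_gene), ("ct_reference", ct_reference)):
        if not (math.isfinite(ct) and ct > 0):
            raise ValueError(f"{name} must be finite and > 0, got {ct}")
    return 2.0 ** (-(ct_gene - ct_reference))


def _delta_ct_frame(measurements: Iterable[QpcrMeasurement], gene: str) -> pd.DataFrame:
    """Per-sample -dCt for one target gene, joined with its Gapdh read."""
    df = pd.DataFrame([m.__dict__ for m in measurements])
    target = df[df["gene"] == gene]
    ref = df[df["gene"] == REFERENCE_GENE].set_index("sample_id")["ct"]
    rows = []
    for _, row in target.iterrows():
        if row["sample_id"] not in ref.index:
            raise ValueError(
                f"sample {row['sample_id']!r} has no {REFERENCE_GENE} reference Ct"
            )
        rows.append(
            {
                "sample_id": row["sample_id"],
                "batch": row["batch"],
                "response": -(row["ct"] - ref[row["sample_id"]]),  # log2 expression scale
            }
        )
    return pd.DataFrame(rows)


def engagement_effect(
    treated: Sequence[QpcrMeasurement],
    control: Sequence[QpcrMeasurement],
    gene: str,
    condition: Condition,
) -> tuple[float, float]:
    """Batch-adjusted treatment effect on log2 expression of one gene.

    Fits ``-dCt ~ treated + batch`` by OLS; the returned coefficient is the
    log2 fold change of treated vs control and the p-value is its two-sided
    t-test. A design in which treatment and batch are confounded (no batch
    contains both groups) is rejected as inestimable.
    """
    t = _delta_ct_frame([m for m in treated if m.condition == condition], gene)
    c = _delta_ct_frame([m for m in control if m.condition == condition], gene)
    if len(t) < 2 or len(c) < 2:
        raise ValueError("need at least 2 samples per group")
    t = t.assign(treated=1)
    c = c.assign(treated=0)
    data = pd.concat([t, c], ignore_index=True)

    shared = data.groupby("batch")["treated"].nunique()
    if not (shared == 2).any():
        raise ValueError(
            "treatment is confounded with batch: no batch contains both groups"
        )

    X = pd.get_dummies(
        data[["treated", "batch"]], columns=["batch"], drop_first=True, dtype=float
    )
    X = sm.add_constant(X)
    fit = sm.OLS(data["response"].astype(float), X).fit()
    log2fc = float(fit.params["treated"])
    p = float(fit.pvalues["treated"])
    if math.isnan(p) or fit.ssr <= 1e-12:
        # degenerate zero-residual fits: a zero effect carries no evidence,
        # a nonzero one is recovered exactly
        p = 1.0 if abs(log2fc) < 1e-12 else 0.0
    return log2fc, p


def call_engagement(
    gene: str,
    condition: Condition,
    log2_fold_change: float,
    p_value: float,
    alpha: float = 0.05,
) -> EngagementCall:
    """Direction call at the significance gate; p >= alpha is always 'none'."""
    if p_value < alpha and log2_fold_change != 0:
        call: Call = "up" if log2_fold_change > 0 else "down"
    else:
        call = "none"
    return EngagementCall(
        gene=gene,
        condition=condition,
        log2_fold_change=log2_fold_change,
        p_value=p_value,
        call=call,
        point=engagement_points(call),
    )


def engagement_points(call: Call) -> int:
    """up -> +1, down -> -1, none -> 0."""
    try:
        return {"up": 1, "down": -1, "none": 0}[call]
    except KeyError:
        raise ValueError(f"invalid call {call!r}") from None


def analyze_qpcr(
    measurements: Iterable[QpcrMeasurement],
    treatment: str,
    control_treatment: str = "control",
    genes: Sequence[str] = ("Nfe2l2", "Gclm", "Hmox1", "Nqo1"),
    conditions: Sequence[Condition] = ("inflammatory", "non_inflammatory"),
    alpha: float = 0.05,
) -> list[EngagementCall]:
    """Engagement calls for one treatment across genes x conditions."""
    ms = list(measurements)
    treated = [m for m in ms if m.treatment == treatment]
    control = [m for m in ms if m.treatment == control_treatment]
    calls = []
    for condition in conditions:
        for gene in genes:
            lfc, p = engagement_effect(treated, control, gene, condition)
            calls.append(call_engagement(gene, condition, lfc, p, alpha=alpha))
    return calls
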