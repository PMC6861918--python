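"""Seeded synthetic inputs for every pipeline stage.

These generators stand in for the wet-lab data the analyses consume:
differential-expression tables, compound concordance tables, co-culture
plate reads, qPCR Ct tables and longitudinal plasma-cytokine panels.
They reproduce the *statistical structure* the analyses assume — planted
effect sizes, log-normal measurement noise, batch offsets, per-animal
random intercepts — not the absolute scales of any particular assay.

Every generator is a pure function of its arguments; per-stage random
streams are independent substreams of the master seed, so adding a
generator never perturbs another's output.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ml import CYTOKINES

__all__ = [
    "stage_rng",
    "simulate_de_table",
    "simulate_concordance_table",
    "simulate_coculture_plate",
    "simulate_qpcr",
    "simulate_cytokine_panel",
]

_STAGES = ("de_table", "concordance", "plate", "qpcr", "panel")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream of the master seed for one pipeline stage."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    idx = _STAGES.index(stage)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))


def simulate_de_table(
    n_genes: int = 100,
    n_signal: int = 10,
    signal_log2fc_range: tuple[float, float] = (1.0, 3.0),
    seed: int = 0,
) -> pd.DataFrame:
    """DE table in which exactly ``n_signal`` genes pass the default
    signature filters (|FC| > 1.5, FDR < 0.05).

    Null genes: log2FC ~ Normal(0, 0.1), FDR ~ Uniform(0.05, 1) — they
    fail on FDR by construction. Signal genes: |log2FC| uniform in the
    given range (floored above log2(1.5)), random sign, FDR < 0.05.
    """
    if n_signal > n_genes:
        raise ValueError("n_signal must be <= n_genes")
    rng = stage_rng(seed, "de_table")
    lo, hi = signal_log2fc_range
    lo = max(lo, math.log2(1.5) + 1e-6)
    if hi < lo:
        raise ValueError("signal_log2fc_range upper bound below the FC filter")

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    signal = rng.choice(n_genes, size=n_signal, replace=False)
    is_signal = np.zeros(n_genes, dtype=bool)
    is_signal[signal] = True

    log2fc = rng.normal(0.0, 0.1, size=n_genes)
    fdr = rng.uniform(0.05, 1.0, size=n_genes)
    mag = rng.uniform(lo, hi, size=n_genes)
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    log2fc[is_signal] = (mag * sign)[is_signal]
    fdr[is_signal] = rng.uniform(1e-8, 0.0499, size=n_genes)[is_signal]

    return pd.DataFrame({"gene_id": gene_ids, "log2fc": log2fc, "fdr": fdr})


def simulate_concordance_table(
    compound_scores: Mapping[str, Mapping[str, float | None]] | None = None,
    n_decoys: int = 16,
    decoy_scale: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Concordance table for named compounds plus ranked decoy compounds.

    ``compound_scores`` maps compound -> {timepoint: concordance or None}
    (None encodes "No score"); decoys get concordance ~ Uniform(-s, s) at
    both timepoints, filling out the ranked list the percentile bands are
    computed against.
    """
    rng = stage_rng(seed, "concordance")
    compound_scores = compound_scores or {}
    rows = []
    for compound, scores in compound_scores.items():
        for timepoint in ("acute", "chronic"):
            c = scores.get(timepoint)
            rows.append(
                {
                    "compound": compound,
                    "timepoint": timepoint,
                    "concordance": np.nan if c is None else float(c),
                    "cell_line": "NEU",
                    "signature_id": f"SIM_{compound[:8].upper()}",
                }
            )
    for i in range(n_decoys):
        for timepoint in ("acute", "chronic"):
            rows.append(
                {
                    "compound": f"decoy{i:03d}",
                    "timepoint": timepoint,
                    "concordance": float(rng.uniform(-decoy_scale, decoy_scale)),
                    "cell_line": "NEU",
                    "signature_id": f"SIM_DECOY{i:03d}",
                }
            )
    return pd.DataFrame(rows)


DEFAULT_CONTROL_LEVELS = {"TNFa": 500.0, "nitrite": 20.0, "viability": 1.0}


def simulate_coculture_plate(
    treatment_effects: Mapping[tuple[str, float, str], float],
    cv: float = 0.1,
    wells_per_cell: int = 4,
    experiments: int = 2,
    seed: int = 0,
    control_levels: Mapping[str, float] = DEFAULT_CONTROL_LEVELS,
) -> pd.DataFrame:
    """Plate table with log-normal well noise around planted effects.

    ``treatment_effects`` maps (treatment, concentration_uM, analyte) to
    the true percent-of-control; control wells sit at the per-analyte
    baseline. Each cell gets ``wells_per_cell`` quadruplicate wells per
    experiment; the whole plate is replicated ``experiments`` times.
    """
    if not (0 < cv < 1):
        raise ValueError("cv must lie in (0, 1)")
    if any(e <= 0 for e in treatment_effects.values()):
        raise ValueError("planted effects must be positive percentages")
    rng = stage_rng(seed, "plate")
    analytes = sorted({a for (_, _, a) in treatment_effects} | set(control_levels))
    rows = []
    for exp in range(1, experiments + 1):
        for analyte in analytes:
            mu0 = math.log(control_levels[analyte])
            for w in range(wells_per_cell):
                rows.append(
                    {
                        "experiment_id": f"exp{exp}",
                        "well_id": f"exp{exp}_{analyte}_control_{w}",
                        "treatment": "control",
                        "concentration": 0.0,
                        "analyte": analyte,
                        "value": float(np.exp(rng.normal(mu0, cv))),
                    }
                )
        for (treatment, conc, analyte), effect in treatment_effects.items():
            mu = math.log(control_levels[analyte]) + math.log(effect / 100.0)
            for w in range(wells_per_cell):
                rows.append(
                    {
                        "experiment_id": f"exp{exp}",
                        "well_id": f"exp{exp}_{analyte}_{treatment}_{conc}_{w}",
                        "treatment": treatment,
                        "concentration": float(conc),
                        "analyte": analyte,
                        "value": float(np.exp(rng.normal(mu, cv))),
                    }
                )
    return pd.DataFrame(rows)


GENE_BASELINE_CT = {"Nfe2l2": 24.0, "Gclm": 23.0, "Hmox1": 22.0, "Nqo1": 25.0}
REFERENCE_BASELINE_CT = 18.0


def simulate_qpcr(
    planted_log2fc: Mapping[tuple[str, str], float],
    batch_shift_ct: float = 0.0,
    n_per_group: int = 4,
    batches: int = 2,
    seed: int = 0,
    sigma: float = 0.15,
    treatment: str = "compound",
) -> pd.DataFrame:
    """Ct table with planted treatment effects and a target-gene batch offset.

    Target-gene Ct = baseline - planted_log2fc x (treated) + batch_shift x
    (batch index) + Normal(0, sigma); the Gapdh reference is unaffected by
    treatment and batch, so the planted offset survives into -dCt where
    the regression must absorb it.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = stage_rng(seed, "qpcr")
    conditions = sorted({c for (_, c) in planted_log2fc})
    genes = sorted({g for (g, _) in planted_log2fc})
    rows = []
    sample_no = 0
    for condition in conditions:
        for b in range(1, batches + 1):
            for group in ("control", treatment):
                for _ in range(n_per_group):
                    sample_no += 1
                    sid = f"s{sample_no:04d}"
                    rows.append(
                        {
                            "sample_id": sid,
                            "gene": "Gapdh",
                            "ct": float(REFERENCE_BASELINE_CT + rng.normal(0, sigma)),
                            "batch": f"batch{b}",
                            "condition": condition,
                            "treatment": group,
                        }
                    )
                    for gene in genes:
                        planted = planted_log2fc.get((gene, condition), 0.0)
                        ct = (
                            GENE_BASELINE_CT.get(gene, 24.0)
                            - planted * (group == treatment)
                            + batch_shift_ct * (b - 1)
                            + rng.normal(0, sigma)
                        )
                        rows.append(
                            {
                                "sample_id": sid,
                                "gene": gene,
                                "ct": float(ct),
                                "batch": f"batch{b}",
                                "condition": condition,
                                "treatment": group,
                            }
                        )
    return pd.DataFrame(rows)


def simulate_cytokine_panel(
    n_vehicle: int = 15,
    n_treated: int = 11,
    days: Sequence[int] = (7, 14, 28),
    group_effect_day28: float = 1.0,
    within_animal_sd: float = 0.3,
    noise_sd: float = 0.4,
    seed: int = 0,
    cytokines: Sequence[str] = CYTOKINES,
    affected_cytokines: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Longitudinal two-group cytokine panel (long format).

    Log-concentration = per-cytokine baseline + day effect (declining from
    the first to the last sampling day in both groups, mirroring the
    post-injury resolution of the plasma response) + per-animal random
    intercept + log(group_effect_day28) for treated animals at the final
    day + measurement noise. ``group_effect_day28=1`` is the null;
    ``affected_cytokines`` restricts the planted shift (default: all).
    """
    if group_effect_day28 < 1:
        raise ValueError("group_effect_day28 must be >= 1")
    rng = stage_rng(seed, "panel")
    days = sorted(days)
    affected = set(affected_cytokines if affected_cytokines is not None else cytokines)
    baselines = dict(
        zip(cytokines, np.linspace(math.log(10.0), math.log(200.0), len(cytokines)))
    )
    day_offsets = dict(zip(days, np.linspace(0.6, 0.0, len(days))))
    last_day = days[-1]

    animals = [(f"v{i:02d}", "vehicle") for i in range(1, n_vehicle + 1)]
    animals += [(f"t{i:02d}", "treated") for i in range(1, n_treated + 1)]
    rows = []
    for animal_id, group in animals:
        intercept = rng.normal(0.0, within_animal_sd)
        for day in days:
            for cyt in cytokines:
                mu = baselines[cyt] + day_offsets[day] + intercept
                if group == "treated" and day == last_day and cyt in affected:
                    mu += math.log(group_effect_day28)
                rows.append(
                    {
                        "animal_id": animal_id,
                        "group": group,
                        "day": day,
                        "cytokine": cyt,
                        "concentration": float(np.exp(mu + rng.normal(0, noise_sd))),
                    }
                )
    return pd.DataFrame(rows)
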