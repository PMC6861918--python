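# tbitriage

Multi-criteria triage of drug-repurposing candidates for traumatic
brain injury (TBI) — and, by configuration, other indications where
compounds are nominated by connectivity-mapping of disease
transcriptomics and validated through staged in vitro and in vivo
evidence.

## What it does

Candidate compounds arrive from a LINCS-style analysis: a disease
expression signature (genes differentially expressed after injury,
with directions) is compared against compound-induced signatures and
each compound receives a signed concordance score. Whether such a
compound actually *helps* is then a multi-criteria question. This
package implements the full evidence-to-decision pipeline:

1. **Signatures** — filter differential-expression tables
   (|fold change| > 1.5, BH FDR < 0.05) into directioned gene sets;
   translate IDs; convert log2 effects to percent of control
   (2^log2FC × 100).
2. **Concordance banding** — rank compounds by |concordance| and award
   0–5 points by rank percentile (top 10% → 5, …, top 50% → 1).
3. **Co-culture assays** — percent-of-control, exact Mann–Whitney
   significance, dose-dependence and band points for TNFα
   (neuroinflammation), nitrite (NO-mediated neurotoxicity) and MAP2
   viability readouts from neuron–microglia plates.
4. **Target engagement** — ΔCt qPCR quantification
   (2^−(Ct_gene − Ct_Gapdh)), batch-adjusted OLS on the −ΔCt scale,
   and ±1/0 engagement calls per gene × condition at p < 0.05.
5. **Composite score** — the weighted go/no-go total
   S = Σᵢ wᵢ·pᵢ with default weights
   w = (10, 10, 10, 10, 15, 15, 20, 8×1.25)% and cumulative subtotals;
   achievable range −3.6 … +4.6.
6. **Cytokine ML** — nested cross-validation (leave-one-out outer,
   stratified 10-fold inner grid search) of gradient-boosted trees on
   longitudinal plasma-cytokine features, pooled-AUC evaluation over
   repeats, an AUC > 0.75 gate and permutation significance.
7. **Synthetic data** — seeded generators for all five input tables,
   so the whole pipeline runs and is tested without any wet-lab data.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import warnings
from tbitriage.scoring import weighted_score, score_bounds

points = {
    "concordance_acute": 0, "concordance_chronic": 3,
    "bbb": 5, "water_solubility": 5,
    "tnfa": 2, "nitrite": 1, "viability": 0,
    "engagement_inflammatory_Nfe2l2": 1,
    "engagement_non_inflammatory_Nfe2l2": 1,
}
with warnings.catch_warnings():
    warnings.simplefilter("ignore")   # unassayed engagement slots score 0
    card = weighted_score(points, compound="desmethylclomipramine")
print(card.subtotals)   # {'pharmacokinetics': 1.3, 'coculture': 1.75}
print(card.total)       # 1.775
print(score_bounds())   # (-3.6, 4.6)
```

The compound earns 1.3 points through concordance and pharmacokinetics
(0·10% + 3·10% + 5·10% + 5·10%), rises to 1.75 after the co-culture
biomarkers (+2·15% +1·15% +0·20%), and finishes at 1.775 with two
engagement calls (+1·1.25% each) — against a best achievable 4.6 and a
worst −3.6.

From the shell, the same pipeline runs end-to-end on synthetic data:

```sh
tbitriage simulate --seed 1 --out sim/
tbitriage build-sig --de-table sim/de_table.tsv --out sim/signature.tsv
tbitriage score-concordance --table sim/concordance.tsv --out sim/conc_points.tsv
tbitriage analyze-assays --plate sim/plate.tsv --out sim/assays.tsv
tbitriage engagement --ct-table sim/qpcr.tsv --treatment cand_strong --out sim/engagement.tsv
tbitriage ml-evaluate --panel sim/panel.tsv --seed 1 --out sim/ml.tsv
```

or in one step via `tbitriage run-all --config pipeline.yaml --out run/`,
which writes a manifest recording input digests and parameters.

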