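# amlstack

Stacked-ensemble prediction of ex-vivo drug response for acute myeloid
leukemia (AML), with bootstrap confidence scores for every prediction
and a network-enrichment view of how molecular subtypes relate to drug
targets.

AML is genetically heterogeneous and responses to the same inhibitor
vary widely across patients, so choosing a therapy from a panel of
candidate drugs benefits from a per-patient, per-drug prediction — and,
just as importantly, from knowing which of those predictions to trust.
`amlstack` is aimed at computational researchers working with cohorts
that pair tumor gene expression and somatic mutations with large-scale
drug screening (AUC / IC50 / DSS readouts).

## The model

Two layers, each with one RBF-kernel support-vector regressor per drug:

1. **Base layer** — for drug *D*, an SVR fit on AML-context genomic
   features: molecular-subtype genes, pathway activation scores over
   mutated genes, the drug's targets and their network neighbours,
   mutated-gene expression, curated AML-relevant genes, plus
   data-driven selections (100 highest-variance genes, 100 genes most
   Spearman-correlated with *D*'s response), redundancy-filtered at
   |ρ| > 0.90. No hyperparameter tuning: C = 1, ε = 0.1, γ = 1/p.
2. **Ensemble layer** — every base model predicts for every sample,
   giving a complete samples × drugs meta-feature matrix; the ensemble
   SVR for *D* is fit on this matrix, exploiting correlated responses
   among drugs that share targets and rescuing drugs screened on few
   patients.

Prediction uncertainty: the training cohort is resampled N = 100 times
by patient, the full pipeline retrained per replicate, and the
confidence score of a prediction is

CS = #{Pr_i ≤ T} / N,

the fraction of bootstrap predictions on the good-response side of the
drug's threshold (IC50 ≤ 1, or the AUC value mapped from IC50 = 1 by a
local-linear regression of AUC on IC50).

Subtype–drug associations use the network-enrichment z-score
z = (d_AF − d̄_AF)/σ_AF, where d_AF counts functional-network edges
between a subtype's gene set and a drug's targets and the null moments
come from degree-preserving edge-swap randomizations (z > 1.96
significant).

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Cohort data are access-controlled in practice, so the example uses the
built-in synthetic cohort generator (which plants recoverable signal
genes, correlated drug pairs and a monotone IC50–AUC map):

```python
import numpy as np
from amlstack import (CohortSpec, DrugResponseTable, FeatureSpec,
                      generate_cohort, predict, spearman_eval,
                      train_stacked_model)

cohort = generate_cohort(CohortSpec(seed=3))          # 200 patients, 10 drugs
patients = cohort.expression.samples
train, test = patients[:140], patients[140:]

model = train_stacked_model(cohort.cohort_inputs(train),
                            cohort.responses_for(train),
                            FeatureSpec(), metric="AUC")
preds = predict(model, cohort.cohort_inputs(test))
obs = DrugResponseTable(cohort.responses_for(test).for_metric("AUC"))
report = spearman_eval(preds, obs)
print(f"overall Spearman rho = {report.overall_rho:.2f}")
print(f"median per-drug rho  = {report.median_per_drug():.2f}")
```

```
overall Spearman rho = 0.55
median per-drug rho  = 0.41
```

The overall correlation pools all (patient, drug) points — it benefits
from between-drug differences in mean response — while the per-drug
median reflects within-drug ranking of patients; both are printed by the
evaluation report.

The same pipeline is scriptable from the shell:

```bash
amlstack simulate --seed 7 --outdir cohort/
amlstack train    --indir cohort/ --metric AUC --out model.bin
amlstack predict  --model model.bin --indir cohort/ --out pred.tsv
amlstack evaluate --pred pred.tsv --obs cohort/responses.tsv --out eval.json
amlstack nea      --network cohort/network.tsv --sets-a cohort/subtype_sets.gmt \
                  --sets-b cohort/drug_targets.tsv --nperm 1000 --seed 7 --out nea.tsv
```

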