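"""Validation machinery: cohort splitting, cross-validation, correlation
reports, the drug-average baseline, bootstrap confidence intervals and
permutation variable importance.

Correlations are Spearman with average-rank tie handling throughout;
per-patient summaries are additionally reported as Pearson, since both
conventions appear in the field.  The overall correlation pools all
(patient, drug) pairs; it is never an average of per-drug values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import CohortInputs, FeatureMatrix, FeatureSpec, spearman_safe
from .io import AmlstackError, DrugResponseTable, LOWER_IS_BETTER
from .stacking import BaseModel, predict, train_stacked_model

logger = logging.getLogger("amlstack")


@dataclass
class EvaluationReport:
    per_drug_rho: dict[str, float] = field(default_factory=dict)
    per_patient_rho: dict[str, float] = field(default_factory=dict)
    per_patient_pearson: dict[str, float] = field(default_factory=dict)
    overall_rho: float = float("nan")
    overall_pearson: float = float("nan")
    #: expected correlation sign for the metric pair (e.g. AUC vs DSS -> -1)
    direction: int = 1
    n_pairs: int = 0

    def median_per_drug(self) -> float:
        vals = [v for v in self.per_drug_rho.values() if np.isfinite(v)]
        return float(np.median(vals)) if vals else float("nan")


def expected_direction(pred_metric: str, obs_metric: str) -> int:
    """+1 when both metrics share direction semantics, -1 otherwise
    (e.g. predicted AUC vs observed DSS)."""
    return 1 if LOWER_IS_BETTER[pred_metric] == LOWER_IS_BETTER[obs_metric] else -1


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_by_center(
    centers: pd.Series, train_fraction: float = 0.6
) -> tuple[list[str], list[str], float]:
    """Center-disjoint train/test split.

    Centers are assigned greedily, largest first (ties by center name),
    to the training side while it stays within ``train_fraction``; the
    achieved fraction is returned since an exact split is generally
    unattainable.
    """
    if centers.isna().any():
        raise AmlstackError("every sample needs a center ID")
    sizes = centers.value_counts()
    if len(sizes) < 2 and train_fraction < 1.0:
        raise AmlstackError("center split needs >= 2 centers")
    total = len(centers)
    order = sorted(sizes.index, key=lambda c: (-sizes[c], str(c)))
    train_centers, n_train = [], 0
    for c in order:
        if (n_train + sizes[c]) / total <= train_fraction + 1e-12:
            train_centers.append(c)
            n_train += sizes[c]
    train = [s for s in centers.index if centers[s] in set(train_centers)]
    test = [s for s in centers.index if centers[s] not in set(train_centers)]
    if not test:
        logger.warning("center split produced an empty test set")
    achieved = n_train / total
    return train, test, achieved


# ---------------------------------------------------------------------------
# Correlation reports
# ---------------------------------------------------------------------------


def _paired_frame(
    predictions: DrugResponseTable | pd.DataFrame,
    observations: DrugResponseTable | pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    def to_long(x):
        if isinstance(x, DrugResponseTable):
            return x.records[["sample", "drug", "metric", "value"]]
        return x

    p = to_long(predictions).rename(columns={"value": "pred"})
    o = to_long(observations).rename(columns={"value": "obs"})
    merged = pd.merge(
        p[["sample", "drug", "pred"]], o[["sample", "drug", "obs"]],
        on=["sample", "drug"], how="inner",
    )
    direction = 1
    if "metric" in to_long(predictions).columns and "metric" in to_long(observations).columns:
        pm = to_long(predictions)["metric"].iloc[0] if len(to_long(predictions)) else "AUC"
        om = to_long(observations)["metric"].iloc[0] if len(to_long(observations)) else "AUC"
        direction = expected_direction(pm, om)
    return merged, direction


def spearman_eval(
    predictions: DrugResponseTable | pd.DataFrame,
    observations: DrugResponseTable | pd.DataFrame,
    min_pairs: int = 3,
) -> EvaluationReport:
    """Per-drug, per-patient and pooled correlations between predicted and
    observed responses; groups with < ``min_pairs`` pairs are omitted."""
    merged, direction = _paired_frame(predictions, observations)
    report = EvaluationReport(direction=direction, n_pairs=len(merged))
    if len(merged) >= min_pairs:
        report.overall_rho = spearman_safe(
            merged["pred"].to_numpy(), merged["obs"].to_numpy()
        )
        report.overall_pearson = float(
            stats.pearsonr(merged["pred"], merged["obs"]).statistic
        )
    skipped = 0
    for drug, grp in merged.groupby("drug"):
        if len(grp) < min_pairs:
            skipped += 1
            continue
        report.per_drug_rho[drug] = spearman_safe(
            grp["pred"].to_numpy(), grp["obs"].to_numpy()
        )
    for sample, grp in merged.groupby("sample"):
        if len(grp) < min_pairs:
            skipped += 1
            continue
        report.per_patient_rho[sample] = spearman_safe(
            grp["pred"].to_numpy(), grp["obs"].to_numpy()
        )
        if grp["pred"].nunique() > 1 and grp["obs"].nunique() > 1:
            report.per_patient_pearson[sample] = float(
                stats.pearsonr(grp["pred"], grp["obs"]).statistic
            )
    if skipped:
        logger.info("%d groups omitted (fewer than %d pairs)", skipped, min_pairs)
    return report


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def kfold_cv(
    cohort: CohortInputs,
    responses: DrugResponseTable,
    spec: FeatureSpec,
    metric: str,
    k: int = 10,
    seed: int = 0,
) -> list[EvaluationReport]:
    """Patient-level k-fold cross-validation of the full pipeline.

    Patients are partitioned into k seeded folds; features and both model
    layers are refit on each training portion and evaluated on the held-
    out patients.
    """
    samples = list(cohort.expr_norm.samples)
    if k < 2 or k > len(samples):
        raise ValueError(f"k={k} incompatible with {len(samples)} patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    folds = np.array_split(order, k)
    reports = []
    rec = responses.records
    for fold in folds:
        held = {samples[i] for i in fold}
        kept = [s for s in samples if s not in held]
        train_cohort = _subset_cohort(cohort, kept)
        test_cohort = _subset_cohort(cohort, sorted(held))
        train_resp = DrugResponseTable(rec[rec["sample"].isin(kept)].reset_index(drop=True))
        test_resp = DrugResponseTable(
            rec[rec["sample"].isin(held)].reset_index(drop=True)
        )
        model = train_stacked_model(train_cohort, train_resp, spec, metric)
        preds = predict(model, test_cohort)
        reports.append(spearman_eval(preds, DrugResponseTable(test_resp.for_metric(metric))))
    return reports


def _subset_cohort(cohort: CohortInputs, samples: list[str]) -> CohortInputs:
    mut = None
    if cohort.mutations is not None:
        mut = type(cohort.mutations)(cohort.mutations.data.loc[samples])
    return CohortInputs(
        expr_norm=type(cohort.expr_norm)(cohort.expr_norm.data[samples]),
        mutations=mut,
        subtype_sets=cohort.subtype_sets,
        pathway_sets=cohort.pathway_sets,
        aml_relevant_genes=cohort.aml_relevant_genes,
        drug_targets=cohort.drug_targets,
        network=cohort.network,
    )


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------


def drug_average_baseline(train_responses: DrugResponseTable, metric: str):
    """Predictor returning each drug's training-mean response for every
    patient.  Its within-drug variance is zero, so per-patient correlation
    against it is only informative across drugs."""
    means = train_responses.for_metric(metric).groupby("drug")["value"].mean()

    def predict_baseline(samples: list[str], drugs: list[str] | None = None) -> DrugResponseTable:
        use = [d for d in (drugs or list(means.index)) if d in means.index]
        rows = [(s, d, metric, float(means[d])) for s in samples for d in use]
        return DrugResponseTable(
            pd.DataFrame(rows, columns=["sample", "drug", "metric", "value"])
        )

    return predict_baseline


# ---------------------------------------------------------------------------
# Bootstrap CI
# ---------------------------------------------------------------------------


def bootstrap_correlation_ci(
    train_cohort: CohortInputs,
    train_responses: DrugResponseTable,
    test_cohort: CohortInputs,
    test_responses: DrugResponseTable,
    spec: FeatureSpec,
    metric: str,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """95% percentile CI of the median per-drug correlation over bootstrap
    replicates of the full train-and-evaluate procedure."""
    from .confidence import _resample_cohort

    if n_boot < 20:
        raise ValueError("n_boot must be >= 20 for a percentile interval")
    rng = np.random.default_rng(seed)
    obs = DrugResponseTable(test_responses.for_metric(metric))
    medians = []
    for b in range(n_boot):
        boot_cohort, boot_resp = _resample_cohort(train_cohort, train_responses, rng)
        try:
            model = train_stacked_model(boot_cohort, boot_resp, spec, metric)
        except AmlstackError as exc:
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            continue
        preds = predict(model, test_cohort)
        medians.append(spearman_eval(preds, obs).median_per_drug())
    lo, hi = np.percentile([m for m in medians if np.isfinite(m)], [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------


def permutation_importance(
    model: BaseModel,
    features: FeatureMatrix | pd.DataFrame,
    response: pd.Series,
    n_repeats: int = 5,
    seed: int = 0,
    loss: str = "spearman",
) -> pd.Series:
    """Model-reliance importance: mean increase in prediction loss when a
    feature column is permuted.

    Default loss is 1 - Spearman rho (rank loss); ``loss="mse"`` uses mean
    squared error.  Permuting a constant column changes nothing, so its
    importance is exactly 0.
    """
    X = features.values if isinstance(features, FeatureMatrix) else features
    obs = response.dropna()
    ids = [s for s in X.index if s in obs.index]
    if len(ids) < 3:
        raise AmlstackError("permutation importance needs >= 3 evaluation samples")
    Xe = X.loc[ids]
    y = obs[ids].to_numpy(dtype=float)

    def _loss(pred: np.ndarray) -> float:
        if loss == "mse":
            return float(np.mean((pred - y) ** 2))
        return 1.0 - spearman_safe(pred, y)

    base_pred = model.regressor.predict(Xe.to_numpy())
    base_loss = _loss(base_pred)
    rng = np.random.default_rng(seed)
    scores = {}
    for col in Xe.columns:
        if Xe[col].nunique() == 1:
            scores[col] = 0.0
            continue
        deltas = []
        for _ in range(n_repeats):
            Xp = Xe.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            deltas.append(_loss(model.regressor.predict(Xp.to_numpy())) - base_loss)
        scores[col] = float(np.mean(deltas))
    return pd.Series(scores, name="importance").sort_values(ascending=False)
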