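"""Good-response thresholds and bootstrap confidence scores.

A good response is defined as IC50 <= 1, or AUC below a drug-specific
threshold T_AUC mapped from IC50 = 1 through a nonparametric regression
of AUC on IC50.  The confidence score (CS) of a prediction is the
fraction of N bootstrap-model predictions falling on the good-response
side of the threshold:

    CS = #{Pr_i <= T} / N

so CS is an exact rational in [0, 1] reflecting how consistently the
model calls the (patient, drug) pair a good responder across bootstrap
replicates of the training cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.kernel_regression import KernelReg

from .features import CohortInputs, FeatureSpec
from .io import (
    AmlstackError,
    DrugResponseTable,
    InsufficientDataError,
    ValidationError,
)
from .stacking import (
    StackedModel,
    base_layer_predictions,
    predict,
    train_base_model,
    train_ensemble_model,
    train_stacked_model,
)

logger = logging.getLogger("amlstack")

DEFAULT_T_IC50 = 1.0
DEFAULT_N_BOOT = 100

#: CS bin edges: four confidence categories
DEFAULT_CS_BINS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class ResponseThreshold:
    """Per-drug good-response cutoff on one metric."""

    drug: str
    metric: str  # AUC or IC50
    T: float
    source: str  # "fixed" or "derived-from-IC50"

    def __post_init__(self) -> None:
        if not np.isfinite(self.T):
            raise ValidationError(f"non-finite threshold for drug {self.drug!r}")


def ic50_threshold(drug: str, t: float = DEFAULT_T_IC50) -> ResponseThreshold:
    return ResponseThreshold(drug=drug, metric="IC50", T=t, source="fixed")


def derive_auc_threshold(
    ic50: np.ndarray,
    auc: np.ndarray,
    drug: str,
    t_ic50: float = DEFAULT_T_IC50,
    method: str = "local-linear",
) -> ResponseThreshold:
    """Map the IC50 cutoff onto the AUC scale for one drug.

    Fits a nonparametric regression of AUC on IC50 over the drug's paired
    observations and evaluates it at IC50 = ``t_ic50``.  The default is a
    local linear smoother with cross-validated bandwidth; an isotonic
    (monotone) fit is available for noisy or sparse relationships.
    """
    ic50 = np.asarray(ic50, dtype=float)
    auc = np.asarray(auc, dtype=float)
    ok = np.isfinite(ic50) & np.isfinite(auc)
    ic50, auc = ic50[ok], auc[ok]
    if len(ic50) < 10:
        raise InsufficientDataError(
            f"drug {drug!r}: {len(ic50)} paired IC50/AUC observations (need >= 10)"
        )
    if not (ic50.min() <= t_ic50 <= ic50.max()):
        raise AmlstackError(
            f"drug {drug!r}: t_ic50={t_ic50} outside observed IC50 range "
            f"[{ic50.min():.3g}, {ic50.max():.3g}]"
        )
    if method == "local-linear":
        kr = KernelReg(endog=auc, exog=ic50, var_type="c", reg_type="ll", bw="cv_ls")
        T = float(kr.fit(np.array([t_ic50]))[0][0])
    elif method == "isotonic":
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        iso.fit(ic50, auc)
        T = float(iso.predict([t_ic50])[0])
    else:
        raise ValueError(f"unknown method {method!r}")
    return ResponseThreshold(drug=drug, metric="AUC", T=T, source="derived-from-IC50")


def derive_all_auc_thresholds(
    responses: DrugResponseTable, t_ic50: float = DEFAULT_T_IC50, method: str = "local-linear"
) -> dict[str, ResponseThreshold]:
    """AUC thresholds for every drug with enough paired IC50/AUC data."""
    auc = responses.pivot("AUC")
    ic50 = responses.pivot("IC50")
    out: dict[str, ResponseThreshold] = {}
    for drug in sorted(set(auc.columns) & set(ic50.columns)):
        pair = pd.concat([ic50[drug], auc[drug]], axis=1).dropna()
        try:
            out[drug] = derive_auc_threshold(
                pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy(), drug, t_ic50, method
            )
        except AmlstackError as exc:
            logger.warning("no AUC threshold for drug %s: %s", drug, exc)
    return out


# ---------------------------------------------------------------------------
# Bootstrap models
# ---------------------------------------------------------------------------


def _resample_cohort(
    cohort: CohortInputs, responses: DrugResponseTable, rng: np.random.Generator
) -> tuple[CohortInputs, DrugResponseTable]:
    """With-replacement resample of patients; repeated draws are aliased
    so sample IDs stay unique."""
    samples = list(cohort.expr_norm.samples)
    draw = rng.integers(0, len(samples), size=len(samples))
    aliases = [f"{samples[i]}@{j}" for j, i in enumerate(draw)]
    expr = cohort.expr_norm.data.iloc[:, list(draw)].copy()
    expr.columns = aliases
    mut = None
    if cohort.mutations is not None:
        mut_df = cohort.mutations.data.iloc[list(draw)].copy()
        mut_df.index = aliases
        mut = type(cohort.mutations)(mut_df)
    rec = responses.records
    by_sample = {s: grp for s, grp in rec.groupby("sample")}
    frames = []
    for j, i in enumerate(draw):
        grp = by_sample.get(samples[i])
        if grp is None:
            continue
        sub = grp.copy()
        sub["sample"] = aliases[j]
        frames.append(sub)
    new_rec = pd.concat(frames, ignore_index=True) if frames else rec.iloc[:0].copy()
    new_cohort = CohortInputs(
        expr_norm=type(cohort.expr_norm)(expr),
        mutations=mut,
        subtype_sets=cohort.subtype_sets,
        pathway_sets=cohort.pathway_sets,
        aml_relevant_genes=cohort.aml_relevant_genes,
        drug_targets=cohort.drug_targets,
        network=cohort.network,
    )
    return new_cohort, DrugResponseTable(new_rec)


def bootstrap_models(
    cohort: CohortInputs,
    responses: DrugResponseTable,
    spec: FeatureSpec,
    metric: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    freeze_features: bool = False,
) -> list[StackedModel]:
    """Train N stacked models on with-replacement patient resamples.

    The resampling unit is the patient, preserving within-patient
    cross-drug correlation.  By default the whole pipeline (feature
    selection included) is retrained per replicate; ``freeze_features``
    reuses the full-cohort feature sets and only refits the regressors.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    reference: StackedModel | None = None
    if freeze_features:
        reference = train_stacked_model(cohort, responses, spec, metric)
    models: list[StackedModel] = []
    for b in range(n_boot):
        boot_cohort, boot_resp = _resample_cohort(cohort, responses, rng)
        try:
            if reference is None:
                models.append(train_stacked_model(boot_cohort, boot_resp, spec, metric))
            else:
                models.append(
                    _refit_frozen(reference, boot_cohort, boot_resp, metric)
                )
        except AmlstackError as exc:
            logger.warning("bootstrap replicate %d unusable: %s", b, exc)
    if not models:
        raise AmlstackError("no bootstrap replicate produced a model")
    return models


def _refit_frozen(
    reference: StackedModel,
    cohort: CohortInputs,
    responses: DrugResponseTable,
    metric: str,
) -> StackedModel:
    """Refit regressors on a resample, keeping the reference feature sets."""
    from .features import FeatureMatrix

    wide = responses.pivot(metric)
    base = {}
    for drug, ref in reference.base.items():
        if drug not in wide.columns:
            continue
        X = ref.feature_values(cohort)
        fm = FeatureMatrix(X, dict(ref.provenance))
        response = wide[drug].reindex(X.index)
        try:
            base[drug] = train_base_model(
                fm, response, drug, pas_members=ref.pas_members, pas_mode=ref.pas_mode
            )
        except InsufficientDataError:
            continue
    if not base:
        raise AmlstackError("frozen-feature refit produced no base models")
    meta = base_layer_predictions(base, cohort)
    ensemble = {}
    for drug in sorted(base):
        response = wide[drug].reindex(meta.index)
        ensemble[drug] = train_ensemble_model(meta, response, drug)
    return StackedModel(
        metric=metric,
        base=base,
        ensemble=ensemble,
        feature_spec=reference.feature_spec,
        imputation_values={d: float(wide[d].mean()) for d in sorted(base)},
    )


def collect_bootstrap_predictions(
    models: list[StackedModel], cohort: CohortInputs
) -> dict[str, pd.DataFrame]:
    """Per drug: samples x replicate matrix of bootstrap predictions.

    Replicates in which a drug could not be trained are simply absent
    from that drug's columns (shrinking its effective N).
    """
    per_drug: dict[str, dict[int, pd.Series]] = {}
    for b, model in enumerate(models):
        preds = predict(model, cohort)
        wide = preds.pivot(model.metric)
        for drug in wide.columns:
            per_drug.setdefault(drug, {})[b] = wide[drug]
    return {
        drug: pd.DataFrame(cols).sort_index(axis=1)
        for drug, cols in per_drug.items()
    }


# ---------------------------------------------------------------------------
# Confidence score
# ---------------------------------------------------------------------------


def confidence_score(
    bootstrap_predictions, threshold: ResponseThreshold
) -> float:
    """Exact fraction of bootstrap predictions at or below the threshold."""
    preds = list(bootstrap_predictions)
    if not preds:
        raise ValueError("empty bootstrap prediction list")
    count = sum(1 for p in preds if p <= threshold.T)
    return float(Fraction(count, len(preds)))


def confidence_report(
    models: list[StackedModel],
    cohort: CohortInputs,
    thresholds: dict[str, ResponseThreshold],
    point_model: StackedModel | None = None,
) -> pd.DataFrame:
    """Per (sample, drug): point prediction, CS, threshold and effective N.

    The point prediction comes from ``point_model`` (typically the model
    trained on the full cohort) or, failing that, the per-replicate mean.
    """
    boots = collect_bootstrap_predictions(models, cohort)
    point = None
    if point_model is not None:
        point = predict(point_model, cohort).pivot(point_model.metric)
    rows = []
    metric = models[0].metric
    for drug in sorted(boots):
        if drug not in thresholds:
            logger.warning("no threshold for drug %s; skipped in report", drug)
            continue
        thr = thresholds[drug]
        if thr.metric != metric:
            raise ValidationError(
                f"threshold metric {thr.metric} does not match predictions ({metric})"
            )
        mat = boots[drug]
        for sample in mat.index:
            vals = mat.loc[sample].dropna()
            cs = confidence_score(vals.tolist(), thr)
            pt = (
                float(point.loc[sample, drug])
                if point is not None and drug in point.columns
                else float(vals.mean())
            )
            rows.append((sample, drug, pt, metric, cs, thr.T, len(vals)))
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "drug", "predicted_value", "metric",
            "confidence_score", "threshold", "n_boot",
        ],
    )


# ---------------------------------------------------------------------------
# Calibration and ranking
# ---------------------------------------------------------------------------


def calibration_table(
    reports: pd.DataFrame,
    observed: DrugResponseTable,
    bins: tuple[float, ...] = DEFAULT_CS_BINS,
) -> pd.DataFrame:
    """Validated good-response proportion per confidence-score bin.

    A report row is a validated good response when the observed value is
    at or below the drug's threshold.  Empty bins report NaN, not 0.
    """
    metric = reports["metric"].iloc[0]
    wide = observed.pivot(metric)
    rows = []
    merged = reports.copy()
    merged["observed"] = [
        wide.loc[s, d] if (s in wide.index and d in wide.columns) else np.nan
        for s, d in zip(merged["sample"], merged["drug"])
    ]
    merged = merged.dropna(subset=["observed"])
    merged["good"] = merged["observed"] <= merged["threshold"]
    for lo, hi in zip(bins[:-1], bins[1:]):
        last = hi == bins[-1]
        mask = (merged["confidence_score"] >= lo) & (
            (merged["confidence_score"] <= hi) if last else (merged["confidence_score"] < hi)
        )
        n = int(mask.sum())
        prop = float(merged.loc[mask, "good"].mean()) if n else float("nan")
        rows.append((lo, hi, n, prop))
    return pd.DataFrame(rows, columns=["cs_lo", "cs_hi", "n", "proportion_good"])


def rank_by_confidence(reports: pd.DataFrame) -> list[str]:
    """Drugs sorted by CS descending, ties broken by better (lower)
    predicted value."""
    if reports.empty:
        return []
    ordered = reports.sort_values(
        ["confidence_score", "predicted_value", "drug"],
        ascending=[False, True, True],
    )
    return ordered["drug"].tolist()


def rank_by_extreme(predictions: pd.Series, k: int | None = None) -> list[str]:
    """Drugs sorted by predicted value ascending (lower-is-better)."""
    ordered = predictions.sort_values(ascending=True, kind="mergesort")
    drugs = ordered.index.tolist()
    return drugs[:k] if k is not None else drugs
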