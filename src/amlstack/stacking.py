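"""Two-layer stacked ensemble for per-drug response prediction.

Layer 1 holds one support-vector regressor (RBF kernel) per drug, fit on
that drug's genomic feature matrix.  Layer 2 holds one SVR per drug whose
inputs are the predictions of *all* base models, so a drug's final
prediction can borrow strength from correlated drugs and from drugs
screened on more patients.  Hyperparameters are fixed (no tuning):
cost C = 1, epsilon = 0.1, gamma = 1 / n_features, inputs standardized.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.compose import TransformedTargetRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .features import CohortInputs, FeatureMatrix, FeatureSpec, assemble_features
from .io import (
    AmlstackError,
    DrugResponseTable,
    FeatureAlignmentError,
    InsufficientDataError,
    ValidationError,
)

logger = logging.getLogger("amlstack")

#: fewest observed responses needed to fit a per-drug regressor
MIN_TRAIN_SAMPLES = 5

SERIALIZATION_VERSION = 1


def _make_svr() -> TransformedTargetRegressor:
    # gamma="auto" = 1 / n_features; both X and y are standardized before
    # fitting, matching the untuned reference defaults (epsilon = 0.1 is on
    # the standardized response scale)
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svr", SVR(kernel="rbf", C=1.0, epsilon=0.1, gamma="auto"))]
    )
    return TransformedTargetRegressor(regressor=pipe, transformer=StandardScaler())


@dataclass
class BaseModel:
    """First-layer per-drug regressor and the feature recipe it was fit with."""

    drug: str
    feature_names: list[str]
    provenance: dict[str, str]
    pas_members: dict[str, list[str]]  # PAS feature -> member genes used
    pas_mode: str
    regressor: TransformedTargetRegressor
    training_sample_ids: list[str]

    def feature_values(self, cohort: CohortInputs) -> pd.DataFrame:
        """Rebuild this model's feature columns for new (normalized) samples."""
        expr = cohort.expr_norm.data
        gene_feats = [f for f in self.feature_names if f not in self.pas_members]
        missing = [g for g in gene_feats if g not in expr.index]
        if missing:
            raise FeatureAlignmentError(
                f"drug {self.drug!r}: samples are missing required genes {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        out = expr.loc[gene_feats].T if gene_feats else pd.DataFrame(index=expr.columns)
        for f in self.feature_names:
            if f in self.pas_members:
                members = [g for g in self.pas_members[f] if g in expr.index]
                if not members:
                    raise FeatureAlignmentError(
                        f"drug {self.drug!r}: no measured genes for feature {f!r}"
                    )
                block = expr.loc[members]
                out[f] = block.sum(axis=0) if self.pas_mode == "sum" else block.mean(axis=0)
        return out[self.feature_names]

    def predict(self, cohort: CohortInputs) -> pd.Series:
        X = self.feature_values(cohort)
        if X.shape[0] == 0:
            return pd.Series(dtype=float)
        return pd.Series(self.regressor.predict(X.to_numpy()), index=X.index)


@dataclass
class EnsembleModel:
    """Second-layer per-drug regressor over all base-model outputs."""

    drug: str
    base_drug_order: list[str]
    regressor: TransformedTargetRegressor

    def predict(self, meta: pd.DataFrame) -> pd.Series:
        missing = [d for d in self.base_drug_order if d not in meta.columns]
        if missing:
            raise FeatureAlignmentError(
                f"meta-feature matrix missing base drugs {missing}"
            )
        X = meta[self.base_drug_order].to_numpy()
        if X.shape[0] == 0:
            return pd.Series(dtype=float)
        return pd.Series(self.regressor.predict(X), index=meta.index)


@dataclass
class StackedModel:
    """Complete two-layer model for one response metric (AUC or IC50)."""

    metric: str
    base: dict[str, BaseModel]
    ensemble: dict[str, EnsembleModel]
    feature_spec: FeatureSpec
    imputation_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.base) != set(self.ensemble):
            raise ValidationError("base and ensemble layers keyed on different drugs")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.base)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train_base_model(
    features: FeatureMatrix, response: pd.Series, drug: str, pas_members=None, pas_mode="mean"
) -> BaseModel:
    """Fit a single first-layer SVR on samples with an observed response."""
    obs = response.dropna()
    train_ids = [s for s in features.samples if s in obs.index]
    if len(train_ids) < MIN_TRAIN_SAMPLES:
        raise InsufficientDataError(
            f"drug {drug!r}: {len(train_ids)} observed responses "
            f"(need >= {MIN_TRAIN_SAMPLES})"
        )
    X = features.values.loc[train_ids].to_numpy()
    y = obs[train_ids].to_numpy(dtype=float)
    reg = _make_svr()
    reg.fit(X, y)
    return BaseModel(
        drug=drug,
        feature_names=features.features,
        provenance=dict(features.provenance),
        pas_members=dict(pas_members or {}),
        pas_mode=pas_mode,
        regressor=reg,
        training_sample_ids=train_ids,
    )


def _pas_members_of(features: FeatureMatrix, cohort: CohortInputs) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {}
    if cohort.pathway_sets is None:
        return members
    gene_index = set(cohort.expr_norm.data.index)
    for feat, src in features.provenance.items():
        if src == "pas" and feat.startswith("PAS:"):
            name = feat[len("PAS:"):]
            members[feat] = [g for g in cohort.pathway_sets[name] if g in gene_index]
    return members


def train_base_layer(
    cohort: CohortInputs,
    responses: DrugResponseTable,
    spec: FeatureSpec,
    metric: str,
) -> dict[str, BaseModel]:
    """One base model per drug with enough observed responses; drugs below
    the minimum are skipped with a logged warning."""
    wide = responses.pivot(metric)
    base: dict[str, BaseModel] = {}
    for drug in sorted(wide.columns):
        response = wide[drug].reindex(cohort.expr_norm.samples)
        try:
            features = assemble_features(cohort, spec, drug, response.dropna())
            base[drug] = train_base_model(
                features,
                response,
                drug,
                pas_members=_pas_members_of(features, cohort),
                pas_mode=spec.pas_mode,
            )
        except (InsufficientDataError, ValidationError) as exc:
            logger.warning("skipping drug %s at base layer: %s", drug, exc)
    if not base:
        raise AmlstackError(f"no drug had enough data to train a base model ({metric})")
    return base


def base_layer_predictions(
    base: dict[str, BaseModel], cohort: CohortInputs
) -> pd.DataFrame:
    """Complete samples x drugs meta-feature matrix: every base model
    predicts for every sample, screened or not."""
    cols = {drug: model.predict(cohort) for drug, model in sorted(base.items())}
    return pd.DataFrame(cols, index=cohort.expr_norm.samples)


def train_ensemble_model(
    meta: pd.DataFrame, response: pd.Series, drug: str
) -> EnsembleModel:
    """Fit a second-layer SVR on the full meta-feature matrix (all base
    outputs, including the drug's own)."""
    obs = response.dropna()
    train_ids = [s for s in meta.index if s in obs.index]
    if len(train_ids) < MIN_TRAIN_SAMPLES:
        raise InsufficientDataError(
            f"drug {drug!r}: {len(train_ids)} observed responses for ensemble"
        )
    X = meta.loc[train_ids].to_numpy()
    y = obs[train_ids].to_numpy(dtype=float)
    reg = _make_svr()
    reg.fit(X, y)
    return EnsembleModel(drug=drug, base_drug_order=list(meta.columns), regressor=reg)


def _out_of_fold_meta(
    cohort: CohortInputs,
    responses: DrugResponseTable,
    spec: FeatureSpec,
    metric: str,
    base: dict[str, BaseModel],
    k: int,
    seed: int,
) -> pd.DataFrame:
    """Optional k-fold out-of-fold meta-features for ensemble training."""
    rng = np.random.default_rng(seed)
    samples = list(cohort.expr_norm.samples)
    order = rng.permutation(len(samples))
    folds = np.array_split(order, k)
    meta = pd.DataFrame(
        np.nan, index=samples, columns=sorted(base), dtype=float
    )
    wide = responses.pivot(metric)
    for fold in folds:
        held = [samples[i] for i in fold]
        kept = [s for s in samples if s not in set(held)]
        sub_cohort = CohortInputs(
            expr_norm=type(cohort.expr_norm)(cohort.expr_norm.data[kept]),
            mutations=cohort.mutations,
            subtype_sets=cohort.subtype_sets,
            pathway_sets=cohort.pathway_sets,
            aml_relevant_genes=cohort.aml_relevant_genes,
            drug_targets=cohort.drug_targets,
            network=cohort.network,
        )
        held_cohort = CohortInputs(
            expr_norm=type(cohort.expr_norm)(cohort.expr_norm.data[held]),
            pathway_sets=cohort.pathway_sets,
        )
        for drug in sorted(base):
            response = wide[drug].reindex(kept) if drug in wide.columns else None
            try:
                feats = assemble_features(
                    sub_cohort, spec, drug,
                    response.dropna() if response is not None else None,
                )
                m = train_base_model(
                    feats, response, drug,
                    pas_members=_pas_members_of(feats, sub_cohort),
                    pas_mode=spec.pas_mode,
                )
                meta.loc[held, drug] = m.predict(held_cohort)[held]
            except (InsufficientDataError, ValidationError):
                continue
    # any column the folds could not predict falls back to in-sample output
    in_sample = base_layer_predictions(base, cohort)
    return meta.fillna(in_sample)


def train_stacked_model(
    cohort: CohortInputs,
    responses: DrugResponseTable,
    spec: FeatureSpec,
    metric: str,
    out_of_fold: int | None = None,
    seed: int = 0,
) -> StackedModel:
    """Train the full two-layer model for one metric.

    ``out_of_fold`` switches ensemble training to k-fold out-of-fold base
    predictions; by default the ensemble sees in-sample base outputs.
    """
    if metric not in ("AUC", "IC50"):
        raise ValidationError(f"stacked models support AUC or IC50, not {metric!r}")
    base = train_base_layer(cohort, responses, spec, metric)
    if out_of_fold:
        meta = _out_of_fold_meta(cohort, responses, spec, metric, base, out_of_fold, seed)
    else:
        meta = base_layer_predictions(base, cohort)
    wide = responses.pivot(metric)
    ensemble: dict[str, EnsembleModel] = {}
    for drug in sorted(base):
        response = wide[drug].reindex(cohort.expr_norm.samples)
        ensemble[drug] = train_ensemble_model(meta, response, drug)
    imputation = {d: float(wide[d].mean()) for d in sorted(base)}
    return StackedModel(
        metric=metric,
        base=base,
        ensemble=ensemble,
        feature_spec=spec,
        imputation_values=imputation,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict(
    model: StackedModel, cohort: CohortInputs, layer: str = "ensemble"
) -> DrugResponseTable:
    """Predict every drug for every sample; records carry the model metric."""
    meta = base_layer_predictions(model.base, cohort)
    rows = []
    for drug in model.drugs:
        preds = (
            meta[drug] if layer == "base" else model.ensemble[drug].predict(meta)
        )
        for sample, value in preds.items():
            rows.append((sample, drug, model.metric, float(value)))
    df = pd.DataFrame(rows, columns=["sample", "drug", "metric", "value"])
    return DrugResponseTable(df)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: StackedModel, path) -> None:
    payload = {"version": SERIALIZATION_VERSION, "model": model}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> StackedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != SERIALIZATION_VERSION:
        raise ValidationError(
            f"unsupported model archive version {payload.get('version')!r}"
        )
    return payload["model"]
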