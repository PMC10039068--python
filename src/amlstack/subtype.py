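"""Molecular-subtype classifier for new samples.

AML molecular subtypes (11 classes in the reference taxonomy) are
normally assigned from driver lesions; here an RBF-kernel SVC predicts
the subtype of a new sample from the same drug-agnostic genomic feature
set the response models use (subtype genes, PAS, mutated genes,
AML-relevant genes, high-variance genes).  Multi-class handling is
one-vs-one voting; hyperparameters are the untuned defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import CohortInputs, FeatureSpec, assemble_features
from .io import FeatureAlignmentError, InsufficientDataError, ValidationError

logger = logging.getLogger("amlstack")

#: drug-agnostic feature sources for the subtype classifier
SUBTYPE_SOURCES = ("subtype", "pas", "mutated", "aml_relevant", "high_variance")


@dataclass
class SubtypeModel:
    labels: list[str]
    feature_names: list[str]
    pas_members: dict[str, list[str]]
    pas_mode: str
    classifier: Pipeline

    def feature_values(self, cohort: CohortInputs) -> pd.DataFrame:
        expr = cohort.expr_norm.data
        gene_feats = [f for f in self.feature_names if f not in self.pas_members]
        missing = [g for g in gene_feats if g not in expr.index]
        if missing:
            raise FeatureAlignmentError(
                f"samples missing subtype-model genes {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        out = expr.loc[gene_feats].T if gene_feats else pd.DataFrame(index=expr.columns)
        for f in self.feature_names:
            if f in self.pas_members:
                members = [g for g in self.pas_members[f] if g in expr.index]
                if not members:
                    raise FeatureAlignmentError(f"no measured genes for {f!r}")
                block = expr.loc[members]
                out[f] = block.sum(axis=0) if self.pas_mode == "sum" else block.mean(axis=0)
        return out[self.feature_names]


def train_subtype_model(
    cohort: CohortInputs, labels: pd.Series, spec: FeatureSpec | None = None
) -> SubtypeModel:
    """Fit the multi-class subtype classifier.

    Labels represented by a single sample are dropped with a warning;
    a single remaining class is a degenerate error.
    """
    spec = spec or FeatureSpec()
    spec = replace(
        spec,
        feature_sources=tuple(s for s in spec.feature_sources if s in SUBTYPE_SOURCES),
    )
    labels = labels.reindex(cohort.expr_norm.samples).dropna()
    counts = labels.value_counts()
    singletons = counts.index[counts < 2].tolist()
    for lab in singletons:
        logger.warning("subtype %s has a single sample; dropped from training", lab)
    labels = labels[~labels.isin(singletons)]
    if labels.nunique() < 2:
        raise InsufficientDataError(
            "subtype training needs >= 2 classes with >= 2 samples each"
        )
    features = assemble_features(cohort, spec, drug=None)
    train_ids = [s for s in features.samples if s in labels.index]
    X = features.values.loc[train_ids].to_numpy()
    y = labels[train_ids].to_numpy()
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", C=1.0, gamma="auto", decision_function_shape="ovo")),
        ]
    )
    clf.fit(X, y)
    pas_members = {}
    if cohort.pathway_sets is not None:
        gene_index = set(cohort.expr_norm.data.index)
        for feat, src in features.provenance.items():
            if src == "pas":
                name = feat[len("PAS:"):]
                pas_members[feat] = [
                    g for g in cohort.pathway_sets[name] if g in gene_index
                ]
    return SubtypeModel(
        labels=sorted(labels.unique()),
        feature_names=features.features,
        pas_members=pas_members,
        pas_mode=spec.pas_mode,
        classifier=clf,
    )


def predict_subtype(
    model: SubtypeModel, cohort: CohortInputs
) -> tuple[pd.Series, pd.DataFrame]:
    """One predicted label per sample, plus per-class-pair decision scores."""
    X = model.feature_values(cohort)
    if X.shape[0] == 0:
        return pd.Series(dtype=object), pd.DataFrame()
    pred = model.classifier.predict(X.to_numpy())
    scores = model.classifier.decision_function(X.to_numpy())
    scores = np.atleast_2d(scores)
    if not np.isfinite(scores).all():
        raise ValidationError("non-finite decision scores")
    return (
        pd.Series(pred, index=X.index, name="subtype"),
        pd.DataFrame(scores, index=X.index),
    )
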