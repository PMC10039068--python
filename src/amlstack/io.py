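"""Readers, writers and validated in-memory containers.

All tabular inputs are plain TSV/CSV (delimiter picked from the file
extension, ties broken toward tab).  Gene sets use the standard GMT
layout, functional networks a two-column undirected edge list, and
drug targets a two-column (drug, gene) table with one target per row.

Every container validates its invariants on construction, so the rest
of the package can assume identifiers are unique and values finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("amlstack")

VALID_METRICS = ("AUC", "IC50", "DSS")

#: direction semantics per response metric: True = lower value is better
LOWER_IS_BETTER = {"AUC": True, "IC50": True, "DSS": False}


class AmlstackError(Exception):
    """Base class for all package errors."""


class FormatError(AmlstackError):
    """Malformed file structure (header, field counts, empty file)."""


class ParseError(AmlstackError):
    """A cell could not be parsed as the expected type."""


class ValidationError(AmlstackError):
    """An in-memory object violates a container invariant."""


class InsufficientDataError(AmlstackError):
    """Too few observations to perform an operation."""


class DegenerateSampleError(AmlstackError):
    """A sample column is constant and cannot be normalized."""


class FeatureAlignmentError(AmlstackError):
    """A prediction input is missing genes a model requires."""


def _detect_sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix (CPM-like, non-negative before
    normalization; arbitrary real after per-sample standardization)."""

    data: pd.DataFrame  # index = genes, columns = samples

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at gene {idx[bad[0]]!r}, "
                f"sample {cols[bad[1]]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[present])


def read_expression(
    path: str | Path, orientation: str = "genes-in-rows"
) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV.

    The file must have one header row (sample IDs for the default
    orientation) and one leading ID column.  Duplicate gene rows are an
    error rather than being silently collapsed.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing expression file: {path}")
    try:
        df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"malformed expression file {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"expression file {path} has no sample columns")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ParseError(
                f"non-numeric expression value in column {col!r}, "
                f"row {bad[0]!r} of {path}"
            )
    if df.isna().any().any():
        raise ParseError(f"missing values in expression matrix {path}")
    if orientation == "samples-in-rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep=_detect_sep(path), index_label="gene")


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------


@dataclass
class MutationProfile:
    """Binary sample x gene mutation call matrix (1 = mutated)."""

    data: pd.DataFrame  # index = samples, columns = genes

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValidationError("duplicate sample or gene IDs in mutation profile")
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValidationError("mutation calls must be binary (0/1)")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def mutated_genes(self) -> list[str]:
        """Genes mutated in at least one sample, in column order."""
        sums = self.data.sum(axis=0)
        return list(sums.index[sums > 0])

    def filter_recurrent(self, min_samples: int = 2) -> "MutationProfile":
        """Keep only genes mutated in >= ``min_samples`` samples."""
        keep = self.data.sum(axis=0) >= min_samples
        return MutationProfile(self.data.loc[:, keep])


def read_mutations(
    path: str | Path, recurrence_filter: bool = True, min_samples: int = 2
) -> MutationProfile:
    """Read a sample x gene binary mutation table.

    By default genes mutated in fewer than two samples are dropped,
    matching the recurrence rule applied to the training cohort.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing mutation file: {path}")
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    prof = MutationProfile(df)
    if recurrence_filter:
        prof = prof.filter_recurrent(min_samples)
    return prof


def write_mutations(prof: MutationProfile, path: str | Path) -> None:
    prof.data.to_csv(path, sep=_detect_sep(path), index_label="sample")


# ---------------------------------------------------------------------------
# Drug response
# ---------------------------------------------------------------------------


@dataclass
class DrugResponseTable:
    """Long-format (sample, drug, metric, value) response records.

    AUC and IC50 are lower-is-better; DSS is higher-is-better.  At most
    one record per (sample, drug, metric).
    """

    records: pd.DataFrame  # columns: sample, drug, metric, value

    REQUIRED = ("sample", "drug", "metric", "value")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"drug-response table missing columns {missing}")
        bad_metric = set(df["metric"]) - set(VALID_METRICS)
        if bad_metric:
            raise ValidationError(
                f"unknown metric(s) {sorted(bad_metric)}; accepted: {VALID_METRICS}"
            )
        dup = df.duplicated(subset=["sample", "drug", "metric"])
        if dup.any():
            first = df.loc[dup, ["sample", "drug", "metric"]].iloc[0].tolist()
            raise ValidationError(f"duplicate response record for {tuple(first)}")
        if len(df) and (
            df["value"].isna().any()
            or not np.isfinite(df["value"].astype(float)).all()
        ):
            raise ValidationError("non-finite response values")

    def for_metric(self, metric: str) -> pd.DataFrame:
        if metric not in VALID_METRICS:
            raise ValidationError(f"unknown metric {metric!r}")
        return self.records[self.records["metric"] == metric]

    def pivot(self, metric: str) -> pd.DataFrame:
        """Sample x drug wide matrix for one metric; NaN = not screened."""
        sub = self.for_metric(metric)
        return sub.pivot(index="sample", columns="drug", values="value")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.records["drug"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample"].unique())

    def check_ic50_convention(self) -> None:
        """Assert IC50 values lie in the [0, 10] assay range."""
        ic = self.for_metric("IC50")["value"]
        if len(ic) and ((ic < 0) | (ic > 10)).any():
            raise ValidationError("IC50 values outside the [0, 10] assay range")


def read_drug_response(path: str | Path) -> DrugResponseTable:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing drug-response file: {path}")
    df = pd.read_csv(path, sep=_detect_sep(path))
    missing = [c for c in DrugResponseTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"drug-response file {path} missing columns {missing}")
    df["sample"] = df["sample"].astype(str)
    df["drug"] = df["drug"].astype(str)
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    return DrugResponseTable(df.reset_index(drop=True))


def write_drug_response(table: DrugResponseTable, path: str | Path) -> None:
    table.records.to_csv(path, sep=_detect_sep(path), index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named, rank-ordered gene sets (order encodes top-k truncation)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if any(not isinstance(g, str) or not g for g in genes):
                raise ValidationError(f"gene set {name!r} has empty gene symbols")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def top(self, k: int) -> "GeneSetCollection":
        """Truncate every set to its first ``k`` genes."""
        return GeneSetCollection({n: g[:k] for n, g in self.sets.items()})


def read_gmt(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing GMT file: {path}")
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno} has {len(fields)} fields (need >= 3)"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValidationError(f"duplicate gene-set name {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# Drug targets
# ---------------------------------------------------------------------------


@dataclass
class DrugTargetMap:
    """Drug -> primary target gene symbols (possibly empty per drug)."""

    targets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug, genes in self.targets.items():
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate targets for drug {drug!r}")

    def __getitem__(self, drug: str) -> list[str]:
        return self.targets[drug]

    def get(self, drug: str, default: list[str] | None = None) -> list[str]:
        return self.targets.get(drug, default if default is not None else [])

    def drugs(self) -> list[str]:
        return list(self.targets)


def read_drug_targets(path: str | Path) -> DrugTargetMap:
    """Two-column TSV (drug TAB gene), one target per row."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing drug-target file: {path}")
    targets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split(_detect_sep(path))
            if len(fields) != 2:
                raise FormatError(f"drug-target line {lineno}: expected 2 fields")
            drug, gene = fields
            if not drug or not gene:
                raise FormatError(f"drug-target line {lineno}: empty symbol")
            targets.setdefault(drug, [])
            if gene not in targets[drug]:
                targets[drug].append(gene)
    return DrugTargetMap(targets)


def write_drug_targets(tmap: DrugTargetMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for drug, genes in tmap.targets.items():
            for gene in genes:
                fh.write(f"{drug}\t{gene}\n")


# ---------------------------------------------------------------------------
# Functional network
# ---------------------------------------------------------------------------


@dataclass
class FunctionalNetwork:
    """Undirected functional gene-interaction graph.

    Self-loops are dropped at load time; duplicate edges deduplicated.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"network contains self-loops: {loops[:3]}")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def neighbors(self, gene: str) -> list[str]:
        if gene not in self.graph:
            return []
        return list(self.graph.neighbors(gene))


def network_from_edges(edges: Iterable[tuple[str, str]]) -> FunctionalNetwork:
    g = nx.Graph()
    for u, v in edges:
        if not u or not v:
            raise FormatError(f"edge with empty gene symbol: {(u, v)!r}")
        if u == v:
            logger.warning("dropping self-loop edge (%s, %s)", u, v)
            continue
        g.add_edge(u, v)
    return FunctionalNetwork(g)


def read_network(path: str | Path) -> FunctionalNetwork:
    """Two-column undirected edge list."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing network file: {path}")
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split(_detect_sep(path))
            if len(fields) < 2:
                raise FormatError(f"network line {lineno}: expected 2 fields")
            edges.append((fields[0], fields[1]))
    return network_from_edges(edges)


def write_network(net: FunctionalNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in net.graph.edges:
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# Prediction / confidence report
# ---------------------------------------------------------------------------


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write a prediction or confidence report TSV."""
    df.to_csv(path, sep=_detect_sep(path), index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_detect_sep(path))
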