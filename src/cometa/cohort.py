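"""Cohort data model and I/O.

A cohort is one case/control expression study: a genes x samples matrix of
log2-scale intensities plus a binary phenotype.  This module reads the TSV
dialect used throughout the package, quantile-normalizes samples, collapses
probe-level rows to gene symbols, and keeps the bookkeeping registry of
studies (sample counts per disease) with audit sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

#: intensities above this are treated as linear scale and log2(x+1)-transformed
LOG2_THRESHOLD = 50.0


class CohortError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass
class ExpressionDataset:
    """One cohort: a genes x samples expression matrix with phenotype labels.

    Values are log2-scale intensities.  Gene symbols are unique, upper-cased
    and whitespace-stripped; every sample carries exactly one label in
    {"case", "control"} and each class has at least two samples so that group
    variances are defined.
    """

    dataset_id: str
    expr: pd.DataFrame            # genes (index) x samples (columns)
    labels: pd.Series             # sample -> "case" | "control"
    source_tissue: str = ""

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.expr.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise CohortError(
                f"{self.dataset_id}: samples without phenotype label: {missing}"
            )
        bad = set(self.labels.unique()) - {CASE, CONTROL}
        if bad:
            raise CohortError(f"{self.dataset_id}: unknown labels {sorted(bad)}")
        if self.expr.index.duplicated().any():
            dups = list(self.expr.index[self.expr.index.duplicated()].unique()[:5])
            raise CohortError(f"{self.dataset_id}: duplicate gene symbols {dups}")
        if self.expr.columns.duplicated().any():
            dups = list(self.expr.columns[self.expr.columns.duplicated()].unique()[:5])
            raise CohortError(f"{self.dataset_id}: duplicate sample ids {dups}")
        for cls in (CASE, CONTROL):
            n = int((self.labels == cls).sum())
            if n < 2:
                raise CohortError(
                    f"{self.dataset_id}: needs >=2 '{cls}' samples, found {n}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.expr.index)

    @property
    def samples(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def n_case(self) -> int:
        return int((self.labels == CASE).sum())

    @property
    def n_control(self) -> int:
        return int((self.labels == CONTROL).sum())

    def case_matrix(self) -> pd.DataFrame:
        return self.expr.loc[:, self.labels == CASE]

    def control_matrix(self) -> pd.DataFrame:
        return self.expr.loc[:, self.labels == CONTROL]

    def with_expr(self, expr: pd.DataFrame) -> "ExpressionDataset":
        return replace(self, expr=expr)


def _clean_symbols(index: pd.Index) -> pd.Index:
    return pd.Index([str(g).strip().upper() for g in index], name=index.name)


def read_expression(
    matrix_path: str | Path, phenotype_path: str | Path,
    dataset_id: str | None = None, source_tissue: str = "",
) -> ExpressionDataset:
    """Read a cohort from a matrix TSV and a phenotype TSV.

    The matrix has a header row of sample ids and one gene per row (first
    column the gene/probe id).  The phenotype file has columns ``sample_id``
    and ``label`` (case|control).  Samples present in the matrix but absent
    from the phenotype file are dropped with a warning; values on a linear
    scale (max > 50) are log2(x+1)-transformed; genes with any missing value
    are dropped from this cohort.
    """
    matrix_path = Path(matrix_path)
    expr = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if expr.shape[1] == 0:
        raise CohortError(f"{matrix_path}: no sample columns in header")
    pheno = pd.read_csv(phenotype_path, sep="\t")
    if not {"sample_id", "label"}.issubset(pheno.columns):
        raise CohortError(f"{phenotype_path}: needs columns sample_id, label")
    if pheno["sample_id"].duplicated().any():
        dup = pheno["sample_id"][pheno["sample_id"].duplicated()].iloc[0]
        raise CohortError(f"{phenotype_path}: duplicate sample id {dup!r}")
    labels = pd.Series(
        pheno["label"].values, index=pheno["sample_id"].astype(str), name="label"
    )

    unknown = labels.index.difference(expr.columns)
    if len(unknown):
        logger.warning(
            "%s: %d phenotype sample(s) not in matrix, ignored: %s",
            matrix_path.name, len(unknown), list(unknown[:5]),
        )
        labels = labels.drop(unknown)
    unlabeled = expr.columns.difference(labels.index)
    if len(unlabeled):
        logger.warning(
            "%s: dropping %d sample(s) without phenotype: %s",
            matrix_path.name, len(unlabeled), list(unlabeled[:5]),
        )
        expr = expr.drop(columns=unlabeled)

    expr.index = _clean_symbols(expr.index)
    try:
        expr = expr.astype(float)
    except (TypeError, ValueError) as exc:
        raise CohortError(f"{matrix_path}: non-numeric expression values: {exc}")

    n_missing = int(expr.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%s: dropping %d gene(s) with missing values",
                       matrix_path.name, n_missing)
        expr = expr.dropna(axis=0)
    expr = log2_if_needed(expr)

    return ExpressionDataset(
        dataset_id=dataset_id or matrix_path.stem,
        expr=expr,
        labels=labels,
        source_tissue=source_tissue,
    )


def log2_if_needed(expr: pd.DataFrame) -> pd.DataFrame:
    """Apply log2(x+1) when the matrix looks linear-scale (max > 50)."""
    if expr.size and float(expr.values.max()) > LOG2_THRESHOLD:
        logger.info("matrix max %.1f > %.0f: applying log2(x+1)",
                    expr.values.max(), LOG2_THRESHOLD)
        return np.log2(expr.clip(lower=0) + 1.0)
    return expr


def quantile_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Quantile-normalize samples to a common distribution.

    Each sample's sorted values are replaced by the across-sample mean of
    sorted values; within-sample ranks are preserved, ties receive the mean
    of their would-be values.  Idempotent: the reference distribution of an
    already-normalized matrix is itself.
    """
    values = dataset.expr.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise CohortError(f"{dataset.dataset_id}: missing values; drop or impute first")
    n_genes, n_samples = values.shape
    mean_sorted = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty(n_genes)
        ranked[order] = mean_sorted
        # average assigned values across ties so equal inputs stay equal
        s = pd.Series(ranked).groupby(col).transform("mean")
        out[:, j] = s.to_numpy()
    return dataset.with_expr(
        pd.DataFrame(out, index=dataset.expr.index, columns=dataset.expr.columns)
    )


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_to_gene: dict[str, str] | pd.Series,
    rule: Literal["mean", "max_variance"] = "mean",
) -> pd.DataFrame:
    """Collapse probe-level rows to one row per gene symbol.

    ``rule="mean"`` averages a gene's probes; ``"max_variance"`` keeps the
    most variable probe.  Unmapped probes are dropped (counted in the log).
    """
    if isinstance(probe_to_gene, dict):
        probe_to_gene = pd.Series(probe_to_gene)
    if probe_to_gene.empty:
        raise CohortError("empty probe-to-gene map")
    probe_to_gene = probe_to_gene.astype(str).str.strip().str.upper()

    mapped = probe_matrix.index.intersection(probe_to_gene.index)
    n_dropped = probe_matrix.shape[0] - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropping %d unmapped probe(s)", n_dropped)
    sub = probe_matrix.loc[mapped]
    genes = probe_to_gene.loc[mapped]

    if rule == "mean":
        out = sub.groupby(genes.values).mean()
    elif rule == "max_variance":
        var = sub.var(axis=1, ddof=1).fillna(0.0)
        best = var.groupby(genes.values).idxmax()
        out = sub.loc[best]
        out.index = best.index
    else:
        raise ValueError(f"unknown collapse rule {rule!r}")
    out.index.name = "gene"
    return out.sort_index()


# -- study registry (bookkeeping mirroring the published cohort table) ---------

@dataclass
class DatasetRegistry:
    """Audit table of studies: per-dataset case/control/used counts by disease."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("dataset_id", "source", "case", "control", "used", "disease")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise CohortError(f"registry missing columns {sorted(missing)}")
        bad = self.table[self.table["used"] != self.table["case"] + self.table["control"]]
        if len(bad):
            raise CohortError(
                "registry rows where used != case + control: "
                f"{list(bad['dataset_id'])}"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DatasetRegistry":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def bundled(cls) -> "DatasetRegistry":
        """The registry of the 14 autoimmune-disease cohorts shipped with the package."""
        ref = resources.files("cometa.data").joinpath("study_registry.tsv")
        with resources.as_file(ref) as p:
            return cls.from_tsv(p)

    def diseases(self) -> list[str]:
        return sorted(self.table["disease"].unique())


def registry_totals(registry: DatasetRegistry, disease: str) -> tuple[int, int, int]:
    """Sum (n_case, n_control, n_used) over a disease's entries; "all" sums everything."""
    t = registry.table
    if disease != "all":
        t = t[t["disease"] == disease]
        if t.empty:
            raise CohortError(f"unknown disease label {disease!r}")
    return int(t["case"].sum()), int(t["control"].sum()), int(t["used"].sum())
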