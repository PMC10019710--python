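"""Signature scoring, AUROC pooling, dataset curation and cross-disease overlap.

A discovered signature (up- and down-regulated gene lists) is evaluated on a
cohort by a per-sample meta-score — geometric mean of up-gene expression
minus geometric mean of down-gene expression on within-cohort standardized
values — whose case/control discrimination is summarized by the AUROC.
Per-cohort AUROCs are pooled on the logit scale; a greedy add/remove search
curates the cohort subset that maximizes the pooled AUROC; and two diseases'
differential gene lists are intersected and classified as concordant or
antagonistic by the signs of their pooled effects.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ExpressionDataset
from .meta import MetaGeneResult, filter_degs, run_meta

logger = logging.getLogger(__name__)


@dataclass
class AurocEstimate:
    """AUROC with sample sizes and a Hanley–McNeil 95% confidence interval."""

    auroc: float
    ci_low: float
    ci_high: float
    n_case: int
    n_control: int

    @property
    def se(self) -> float:
        return _hanley_mcneil_se(self.auroc, self.n_case, self.n_control)


@dataclass
class Signature:
    """Directed gene signature of one disease with its AUROC performance."""

    disease: str
    up_genes: list[str]
    down_genes: list[str]
    per_dataset_auroc: dict[str, AurocEstimate] = field(default_factory=dict)
    summary_auroc: AurocEstimate | None = None

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"up/down gene sets overlap: {sorted(overlap)[:5]}")


CONCORDANT_UP = "concordant_up"
CONCORDANT_DOWN = "concordant_down"
ANTAGONISTIC = "antagonistic"


@dataclass
class CommonGene:
    gene: str
    g_s_a: float
    g_s_b: float
    concordance: str


@dataclass
class CommonSignature:
    """Genes differential in both diseases, with concordance labels."""

    genes: list[CommonGene]
    persistent: list[str]          # measured in every cohort of both diseases

    def counts(self) -> dict[str, int]:
        out = {CONCORDANT_UP: 0, CONCORDANT_DOWN: 0, ANTAGONISTIC: 0}
        for g in self.genes:
            out[g.concordance] += 1
        return out


# -- meta-score ----------------------------------------------------------------

def meta_score(dataset: ExpressionDataset, signature: Signature) -> pd.Series:
    """Per-sample composite score contrasting up- against down-signature genes.

    Expression is z-scored per gene within the cohort, shifted positive
    (z + |min z| + 1 over the cohort), and the score is the geometric mean
    over the up genes minus the geometric mean over the down genes.  Genes the
    cohort does not measure are skipped; with an empty up (down) side that
    side contributes 0.
    """
    up = [g for g in signature.up_genes if g in dataset.expr.index]
    down = [g for g in signature.down_genes if g in dataset.expr.index]
    if not up and not down:
        raise ValueError(
            f"{dataset.dataset_id}: no signature gene measured in this cohort"
        )
    sd = dataset.expr.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = dataset.expr.sub(dataset.expr.mean(axis=1), axis=0).div(sd, axis=0)
    z = z.dropna(axis=0)
    shifted = z + abs(float(z.values.min())) + 1.0
    up = [g for g in up if g in shifted.index]
    down = [g for g in down if g in shifted.index]

    def gmean(genes: list[str]) -> pd.Series:
        if not genes:
            return pd.Series(0.0, index=shifted.columns)
        return np.exp(np.log(shifted.loc[genes]).mean(axis=0))

    score = gmean(up) - gmean(down)
    score.name = "meta_score"
    return score


# -- AUROC ---------------------------------------------------------------------

def _hanley_mcneil_se(a: float, n1: int, n0: int) -> float:
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
    return math.sqrt(max(var, 0.0))


def auroc(scores, labels) -> AurocEstimate:
    """Mann–Whitney AUROC (ties count 1/2) with a Hanley–McNeil 95% CI.

    ``labels`` are "case"/"control" (or booleans, True = case); the AUROC is
    the probability that a random case scores above a random control.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype.kind == "b":
        is_case = lab
    else:
        is_case = lab == "case"
    n1 = int(is_case.sum())
    n0 = int(len(lab) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUROC")
    ranks = stats.rankdata(s)                      # midranks handle ties
    a = (ranks[is_case].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    se = _hanley_mcneil_se(float(a), n1, n0)
    return AurocEstimate(
        auroc=float(a),
        ci_low=max(0.0, float(a) - 1.96 * se),
        ci_high=min(1.0, float(a) + 1.96 * se),
        n_case=n1, n_control=n0,
    )


def summary_auroc(
    per_dataset: dict[str, AurocEstimate],
    method: str = "logit_ivw",
) -> AurocEstimate:
    """Pool per-cohort AUROCs into one summary value with a 95% CI.

    Default: inverse-variance weighted mean on the logit scale (delta-method
    variances from Hanley–McNeil SEs), back-transformed; degenerate AUROCs
    are nudged off {0, 1} by 0.5/(n1*n0) so the logit is finite.  Alternative
    ``method="sample_weighted"``: mean weighted by cohort size.
    """
    if not per_dataset:
        raise ValueError("no per-dataset AUROCs to pool")
    ests = list(per_dataset.values())
    if len(ests) == 1:
        return ests[0]
    if method == "sample_weighted":
        w = np.array([e.n_case + e.n_control for e in ests], dtype=float)
        a = np.array([e.auroc for e in ests])
        pooled = float(np.sum(w * a) / np.sum(w))
        se = float(np.sqrt(np.sum(w**2 * np.array([e.se for e in ests]) ** 2))
                   / np.sum(w))
        return AurocEstimate(pooled, max(0.0, pooled - 1.96 * se),
                             min(1.0, pooled + 1.96 * se),
                             int(sum(e.n_case for e in ests)),
                             int(sum(e.n_control for e in ests)))
    if method != "logit_ivw":
        raise ValueError(f"unknown pooling method {method!r}")

    logits, variances = [], []
    for e in ests:
        eps = 0.5 / (e.n_case * e.n_control)
        a = min(max(e.auroc, eps), 1.0 - eps)
        se = max(_hanley_mcneil_se(a, e.n_case, e.n_control), 1e-12)
        logits.append(math.log(a / (1 - a)))
        variances.append((se / (a * (1 - a))) ** 2)   # delta method
    w = 1.0 / np.asarray(variances)
    mu = float(np.sum(w * np.asarray(logits)) / np.sum(w))
    se_mu = float(math.sqrt(1.0 / np.sum(w)))
    inv = lambda x: 1.0 / (1.0 + math.exp(-x))
    return AurocEstimate(
        auroc=inv(mu), ci_low=inv(mu - 1.96 * se_mu), ci_high=inv(mu + 1.96 * se_mu),
        n_case=int(sum(e.n_case for e in ests)),
        n_control=int(sum(e.n_control for e in ests)),
    )


# -- signature evaluation ------------------------------------------------------

def evaluate_signature(
    datasets: list[ExpressionDataset], signature: Signature,
    pooling: str = "logit_ivw",
) -> Signature:
    """Fill per-cohort and summary AUROC for a signature on the given cohorts."""
    per = {}
    for ds in datasets:
        try:
            scores = meta_score(ds, signature)
        except ValueError:
            logger.warning("%s: signature not measurable, skipped", ds.dataset_id)
            continue
        per[ds.dataset_id] = auroc(scores.values, ds.labels.values)
    if not per:
        raise ValueError("signature not measurable in any cohort")
    signature.per_dataset_auroc = per
    signature.summary_auroc = summary_auroc(per, method=pooling)
    return signature


def discover_and_evaluate(
    datasets: list[ExpressionDataset],
    disease: str = "",
    es_threshold: float = 0.40,
    fdr_threshold: float = 0.05,
    min_studies: int = 4,
    pooling: str = "logit_ivw",
) -> tuple[Signature, list[MetaGeneResult]]:
    """Meta-analyze the cohorts, apply the DEG filter, and score the signature."""
    results = run_meta(datasets)
    min_st = min(min_studies, len(datasets))
    up, down = filter_degs(results, es_threshold, fdr_threshold, min_st)
    sig = Signature(disease=disease, up_genes=up, down_genes=down)
    if not up and not down:
        logger.warning("no gene passed the filter; empty signature")
        sig.summary_auroc = AurocEstimate(0.5, 0.0, 1.0, 0, 0)
        return sig, results
    return evaluate_signature(datasets, sig, pooling=pooling), results


# -- greedy dataset curation ---------------------------------------------------

def _subset_objective(
    subset: tuple[str, ...],
    by_id: dict[str, ExpressionDataset],
    **kwargs,
) -> float:
    datasets = [by_id[i] for i in subset]
    try:
        sig, _ = discover_and_evaluate(datasets, **kwargs)
    except ValueError:
        return 0.5
    return sig.summary_auroc.auroc if sig.summary_auroc else 0.5


def greedy_dataset_selection(
    candidate_datasets: list[ExpressionDataset],
    tolerance: float = 0.005,
    min_subset: int = 2,
    tissue_minimums: dict[str, int] | None = None,
    **objective_kwargs,
) -> tuple[list[str], pd.DataFrame]:
    """Add/remove cohorts one at a time to maximize the pooled AUROC.

    Starts from the full candidate set; at each step every admissible single
    add or remove is scored by re-running the meta-analysis + DEG filter +
    summary AUROC on the working subset, and the best move is applied if it
    improves the objective by more than ``tolerance``.  Ties prefer the
    smaller subset, then the lexically smaller move.  ``tissue_minimums``
    maps source tissue to the minimum number of cohorts that must remain.
    Returns (selected dataset ids, decision trace).
    """
    if len(candidate_datasets) < 2:
        raise ValueError("need >= 2 candidate cohorts")
    by_id = {ds.dataset_id: ds for ds in candidate_datasets}
    tissues = {ds.dataset_id: ds.source_tissue for ds in candidate_datasets}
    if tissue_minimums:
        for tissue, need in tissue_minimums.items():
            have = sum(1 for t in tissues.values() if t == tissue)
            if have < need:
                raise ValueError(
                    f"constraint unsatisfiable: tissue {tissue!r} needs {need} "
                    f"cohort(s), only {have} candidate(s)"
                )

    def admissible(subset: set[str]) -> bool:
        if len(subset) < min_subset:
            return False
        if tissue_minimums:
            for tissue, need in tissue_minimums.items():
                if sum(1 for i in subset if tissues[i] == tissue) < need:
                    return False
        return True

    current = set(by_id)
    current_score = _subset_objective(tuple(sorted(current)), by_id, **objective_kwargs)
    trace = [{"step": 0, "move": "init", "dataset_id": "",
              "subset_size": len(current), "summary_auroc": current_score}]

    step = 0
    while True:
        step += 1
        moves = []  # (score, prefers-smaller, move-kind, dataset_id, new_subset)
        for ds_id in sorted(current):
            new = current - {ds_id}
            if admissible(new):
                score = _subset_objective(tuple(sorted(new)), by_id, **objective_kwargs)
                moves.append((score, 0, "remove", ds_id, new))
        for ds_id in sorted(set(by_id) - current):
            new = current | {ds_id}
            if admissible(new):
                score = _subset_objective(tuple(sorted(new)), by_id, **objective_kwargs)
                moves.append((score, 1, "add", ds_id, new))
        if not moves:
            break
        moves.sort(key=lambda m: (-m[0], m[1], m[3]))
        best = moves[0]
        if best[0] - current_score <= tolerance:
            break
        current, current_score = best[4], best[0]
        trace.append({"step": step, "move": best[2], "dataset_id": best[3],
                      "subset_size": len(current), "summary_auroc": current_score})
    return sorted(current), pd.DataFrame(trace)


def exhaustive_dataset_selection(
    candidate_datasets: list[ExpressionDataset],
    min_subset: int = 2,
    **objective_kwargs,
) -> tuple[list[str], float]:
    """Score every cohort subset; reference oracle for the greedy search.

    Ties broken by smaller subset, then lexically smaller id tuple — the same
    ordering the greedy search prefers.
    """
    by_id = {ds.dataset_id: ds for ds in candidate_datasets}
    ids = sorted(by_id)
    best, best_key = None, None
    for r in range(min_subset, len(ids) + 1):
        for subset in itertools.combinations(ids, r):
            score = _subset_objective(subset, by_id, **objective_kwargs)
            key = (-score, len(subset), subset)
            if best_key is None or key < best_key:
                best, best_key = (list(subset), score), key
    assert best is not None
    return best


# -- cross-disease overlap -----------------------------------------------------

def classify_concordance(g_a: float, g_b: float) -> str:
    """Concordant if the two pooled effects share sign, antagonistic otherwise."""
    if g_a > 0 and g_b > 0:
        return CONCORDANT_UP
    if g_a < 0 and g_b < 0:
        return CONCORDANT_DOWN
    return ANTAGONISTIC


def common_signature(
    results_a: list[MetaGeneResult],
    results_b: list[MetaGeneResult],
    n_datasets_a: int | None = None,
    n_datasets_b: int | None = None,
    es_threshold: float = 0.40,
    fdr_threshold: float = 0.05,
    min_studies: int = 4,
) -> CommonSignature:
    """Intersect two diseases' DEG sets and classify each shared gene.

    A gene is "persistent" when it was measured in every cohort of both
    diseases (n_studies equal to the cohort count on each side).
    """
    up_a, down_a = filter_degs(results_a, es_threshold, fdr_threshold, min_studies)
    up_b, down_b = filter_degs(results_b, es_threshold, fdr_threshold, min_studies)
    degs_a, degs_b = set(up_a) | set(down_a), set(up_b) | set(down_b)
    by_gene_a = {r.gene: r for r in results_a}
    by_gene_b = {r.gene: r for r in results_b}

    genes, persistent = [], []
    for gene in sorted(degs_a & degs_b):
        ra, rb = by_gene_a[gene], by_gene_b[gene]
        genes.append(
            CommonGene(gene=gene, g_s_a=ra.g_s, g_s_b=rb.g_s,
                       concordance=classify_concordance(ra.g_s, rb.g_s))
        )
        if (n_datasets_a is not None and n_datasets_b is not None
                and ra.n_studies == n_datasets_a and rb.n_studies == n_datasets_b):
            persistent.append(gene)
    return CommonSignature(genes=genes, persistent=persistent)


def classify_effect_table(table: pd.DataFrame) -> pd.DataFrame:
    """Label a table of per-disease pooled effects by concordance.

    Expects a ``gene`` column plus two pooled-effect columns (the first two
    non-gene columns are used, disease A then disease B).  Returns the table
    with a ``concordance`` column appended.
    """
    cols = [c for c in table.columns if c != "gene"]
    if len(cols) < 2:
        raise ValueError("need two pooled-effect columns")
    a, b = cols[0], cols[1]
    out = table.copy()
    out["concordance"] = [
        classify_concordance(ga, gb) for ga, gb in zip(out[a], out[b])
    ]
    return out
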