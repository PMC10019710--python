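"""Random-effects gene-expression meta-analysis.

Per-dataset standardized mean differences (Hedges' g with small-sample
correction), DerSimonian–Laird between-study variance, inverse-variance
random-effects pooling, Fisher's combined p, Benjamini–Hochberg FDR, and the
differential-expression filter (|g_s|, FDR, minimum study count).

Conventions: g > 0 means higher expression in cases ("upregulated").  For a
gene measured in k datasets with per-study effects g_i and variances V_i:

    w_i = 1/V_i                       (fixed-effect weights)
    Q   = sum w_i (g_i - gbar_w)^2    (Cochran heterogeneity)
    T2  = max(0, (Q - (k-1)) / (sum w_i - sum w_i^2 / sum w_i))
    W_i = 1/(V_i + T2)
    g_s = sum W_i g_i / sum W_i,   se_s = sqrt(1 / sum W_i)

Per-study two-sided normal p-values from z = g_i / sqrt(V_i) are combined by
Fisher's method, X = -2 sum ln p_i ~ chi^2(2k), and BH-adjusted across genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionDataset

logger = logging.getLogger(__name__)

_TINY_P = float(np.nextafter(0, 1))


class DegenerateEffect(ValueError):
    """Zero pooled variance: the effect size is undefined for this gene."""


@dataclass
class GeneEffect:
    """Hedges' g of one gene in one dataset (case minus control)."""

    gene: str
    dataset_id: str
    g: float
    V: float
    n1: int
    n0: int
    X1bar: float
    X0bar: float
    S1: float
    S0: float
    J: float

    @property
    def se(self) -> float:
        return math.sqrt(self.V)

    def p_two_sided(self) -> float:
        """Two-sided normal p for g/sqrt(V)."""
        z = self.g / self.se
        return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class MetaGeneResult:
    """Pooled random-effects summary for one gene across datasets."""

    gene: str
    g_s: float
    se_s: float
    T2: float
    Q: float
    p_fisher: float
    n_studies: int
    per_study: list[GeneEffect] = field(default_factory=list)
    fdr: float = float("nan")

    @property
    def direction(self) -> str:
        return "up" if self.g_s > 0 else "down"

    def ci95(self) -> tuple[float, float]:
        return self.g_s - 1.96 * self.se_s, self.g_s + 1.96 * self.se_s


def hedges_g(
    case_values, control_values, gene: str = "", dataset_id: str = ""
) -> GeneEffect:
    """Small-sample-corrected standardized mean difference, case minus control.

    g = J * (X1bar - X0bar) / S_pooled with
    S_pooled = sqrt(((n1-1) S1^2 + (n0-1) S0^2) / (n1 + n0 - 2)),
    J = 1 - 3/(4 df - 1), df = n1 + n0 - 2, and
    V = J^2 * [(n1+n0)/(n1 n0) + d^2/(2 (n1+n0))] where d is the uncorrected
    difference.  Raises :class:`DegenerateEffect` when both groups are constant.
    """
    x1 = np.asarray(case_values, dtype=float)
    x0 = np.asarray(control_values, dtype=float)
    n1, n0 = len(x1), len(x0)
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs >= 2 observations")
    if not (np.isfinite(x1).all() and np.isfinite(x0).all()):
        raise ValueError("non-finite expression values")
    s1 = x1.std(ddof=1)
    s0 = x0.std(ddof=1)
    df = n1 + n0 - 2
    sp2 = ((n1 - 1) * s1**2 + (n0 - 1) * s0**2) / df
    if sp2 <= 0.0:
        raise DegenerateEffect(
            f"gene {gene or '?'} in {dataset_id or '?'}: zero pooled variance"
        )
    d = (x1.mean() - x0.mean()) / math.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = J * d
    V = J**2 * ((n1 + n0) / (n1 * n0) + d**2 / (2.0 * (n1 + n0)))
    return GeneEffect(
        gene=gene, dataset_id=dataset_id, g=float(g), V=float(V),
        n1=n1, n0=n0, X1bar=float(x1.mean()), X0bar=float(x0.mean()),
        S1=float(s1), S0=float(s0), J=float(J),
    )


def dersimonian_laird_tau2(effects: list[GeneEffect]) -> tuple[float, float]:
    """Moment estimate of the between-study variance; returns (T2, Q).

    Uses fixed-effect weights w_i = 1/V_i; T2 is truncated at zero.  With a
    single study heterogeneity is unidentifiable and (0, 0) is returned.
    """
    k = len(effects)
    if k < 2:
        if k == 1:
            logger.debug("tau2 with k=1 set to 0 (unidentifiable)")
        return 0.0, 0.0
    g = np.array([e.g for e in effects])
    w = np.array([1.0 / e.V for e in effects])
    gbar = float(np.sum(w * g) / np.sum(w))
    Q = float(np.sum(w * (g - gbar) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    T2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    return T2, Q


def pool_effect_size(effects: list[GeneEffect]) -> MetaGeneResult:
    """Random-effects pooled effect with weights W_i = 1/(V_i + T2)."""
    if not effects:
        raise ValueError("need at least one per-study effect")
    T2, Q = dersimonian_laird_tau2(effects)
    W = np.array([1.0 / (e.V + T2) for e in effects])
    g = np.array([e.g for e in effects])
    g_s = float(np.sum(W * g) / np.sum(W))
    se_s = float(math.sqrt(1.0 / np.sum(W)))
    p_fisher = fisher_combined_p([e.p_two_sided() for e in effects])
    return MetaGeneResult(
        gene=effects[0].gene, g_s=g_s, se_s=se_s, T2=T2, Q=Q,
        p_fisher=p_fisher, n_studies=len(effects), per_study=list(effects),
    )


def fisher_combined_p(p_values: list[float]) -> float:
    """Fisher's method: -2 sum ln p ~ chi^2 with 2k df, upper tail."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values to combine")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        logger.warning("p=0 clipped to smallest positive float")
        p = np.clip(p, _TINY_P, 1.0)
    X = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(X, df=2 * len(p)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_meta(datasets: list[ExpressionDataset]) -> list[MetaGeneResult]:
    """Meta-analyze every gene present in at least one dataset.

    Each dataset contributes an independent Hedges' g for the genes it
    measures; genes absent from a platform simply contribute no effect there.
    Zero-variance (constant) genes are excluded per dataset.  FDR is
    BH-adjusted over the Fisher combined p of all emitted genes.
    """
    if len(datasets) < 2:
        raise ValueError("need >= 2 datasets for a meta-analysis")
    shared = set(datasets[0].genes)
    for ds in datasets[1:]:
        shared &= set(ds.genes)
    if not shared:
        logger.warning("no gene is present in every dataset; proceeding per gene")

    per_gene: dict[str, list[GeneEffect]] = {}
    for ds in datasets:
        case = ds.case_matrix().to_numpy()
        ctrl = ds.control_matrix().to_numpy()
        n1, n0 = case.shape[1], ctrl.shape[1]
        df = n1 + n0 - 2
        m1, m0 = case.mean(axis=1), ctrl.mean(axis=1)
        s1, s0 = case.std(axis=1, ddof=1), ctrl.std(axis=1, ddof=1)
        sp2 = ((n1 - 1) * s1**2 + (n0 - 1) * s0**2) / df
        ok = sp2 > 0.0
        n_bad = int((~ok).sum())
        if n_bad:
            logger.info("%s: excluding %d zero-variance gene(s)", ds.dataset_id, n_bad)
        d = np.where(ok, (m1 - m0) / np.sqrt(np.where(ok, sp2, 1.0)), np.nan)
        J = 1.0 - 3.0 / (4.0 * df - 1.0)
        g = J * d
        V = J**2 * ((n1 + n0) / (n1 * n0) + d**2 / (2.0 * (n1 + n0)))
        for i, gene in enumerate(ds.genes):
            if not ok[i]:
                continue
            per_gene.setdefault(gene, []).append(
                GeneEffect(
                    gene=gene, dataset_id=ds.dataset_id, g=float(g[i]), V=float(V[i]),
                    n1=n1, n0=n0, X1bar=float(m1[i]), X0bar=float(m0[i]),
                    S1=float(s1[i]), S0=float(s0[i]), J=float(J),
                )
            )

    results = [pool_effect_size(effects) for effects in per_gene.values()]
    results.sort(key=lambda r: r.gene)
    fdr = bh_fdr([r.p_fisher for r in results])
    for r, q in zip(results, fdr):
        r.fdr = float(q)
    return results


def filter_degs(
    results: list[MetaGeneResult],
    es_threshold: float = 0.40,
    fdr_threshold: float = 0.05,
    min_studies: int = 4,
    signed_es: bool = False,
) -> tuple[list[str], list[str]]:
    """Select differentially expressed genes and split by direction.

    Keeps genes with |g_s| > es_threshold (signed g_s > threshold when
    ``signed_es``), fdr < fdr_threshold and n_studies >= min_studies;
    returns (up_genes, down_genes) sorted alphabetically.
    """
    up, down = [], []
    for r in results:
        es = r.g_s if signed_es else abs(r.g_s)
        if es > es_threshold and r.fdr < fdr_threshold and r.n_studies >= min_studies:
            (up if r.g_s > 0 else down).append(r.gene)
    return sorted(up), sorted(down)


def results_table(results: list[MetaGeneResult]) -> pd.DataFrame:
    """Flat per-gene summary table (one row per gene)."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "g_s": [r.g_s for r in results],
            "se": [r.se_s for r in results],
            "T2": [r.T2 for r in results],
            "Q": [r.Q for r in results],
            "p_fisher": [r.p_fisher for r in results],
            "fdr": [r.fdr for r in results],
            "n_studies": [r.n_studies for r in results],
            "direction": [r.direction for r in results],
        }
    )


def per_study_table(results: list[MetaGeneResult]) -> pd.DataFrame:
    """Long-format per-study effects (forest-plot source data)."""
    rows = []
    for r in results:
        for e in r.per_study:
            rows.append(
                {"gene": e.gene, "dataset_id": e.dataset_id, "g": e.g, "V": e.V,
                 "n1": e.n1, "n0": e.n0}
            )
    return pd.DataFrame(rows)
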