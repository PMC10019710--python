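"""Over-representation analysis of gene lists against GMT gene-set collections.

For each term the one-sided (greater) Fisher's exact p is the hypergeometric
upper tail of the 2x2 overlap table; BH-adjusted q-values are reported
alongside, but the significance flag follows the conventional raw p < 0.05
call for ontology terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .meta import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    name: str
    sets: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set {term!r}")
            if self.universe is not None and not genes <= self.universe:
                raise ValueError(f"gene set {term!r} not contained in the universe")


@dataclass
class EnrichmentResult:
    term: str
    k: int        # overlap
    n: int        # query list size (within universe)
    K: int        # term size (within universe)
    N: int        # universe size
    p: float
    fdr: float
    genes: list[str]

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (term, description, member genes); symbols upper-cased."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, set[str]] = {}
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            parts = [p for p in line.rstrip("\n").split("\t")]
            if len(parts) < 3:
                if line.strip():
                    n_skipped += 1
                continue
            term = parts[0].strip()
            genes = {g.strip().upper() for g in parts[2:] if g.strip()}
            if genes:
                sets[term] = genes
    if n_skipped:
        logger.warning("%s: skipped %d malformed line(s)", path.name, n_skipped)
    if not sets:
        raise ValueError(f"{path}: no gene sets parsed")
    return GeneSetCollection(name=path.stem, sets=sets)


def enrich(
    gene_list: list[str],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
) -> list[EnrichmentResult]:
    """One-sided Fisher's exact over-representation test per term.

    The universe defaults to the collection's, else to the union of the
    collection's sets with the query.  Genes outside the universe are dropped
    from the query with a warning.  Results sorted by ascending p.
    """
    if not gene_list:
        raise ValueError("empty gene list")
    query = {g.strip().upper() for g in gene_list}
    if universe is None:
        universe = collection.universe
    if universe is None:
        universe = set().union(*collection.sets.values()) | query
        logger.info("no universe given; using collection union (%d genes)",
                    len(universe))
    universe = {g.strip().upper() for g in universe}
    if len(universe) < len(query):
        raise ValueError("universe smaller than the query list")
    outside = query - universe
    if outside:
        logger.warning("%d query gene(s) outside the universe dropped", len(outside))
        query &= universe

    N, n = len(universe), len(query)
    results = []
    for term, genes in collection.sets.items():
        term_genes = genes & universe
        K = len(term_genes)
        overlap = sorted(query & term_genes)
        k = len(overlap)
        # P(X >= k) under Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        results.append(
            EnrichmentResult(term=term, k=k, n=n, K=K, N=N, p=min(p, 1.0),
                             fdr=float("nan"), genes=overlap)
        )
    qvals = bh_fdr([r.p for r in results])
    for r, q in zip(results, qvals):
        r.fdr = float(q)
    results.sort(key=lambda r: (r.p, r.term))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
            "significant": [r.significant for r in results],
            "genes": [",".join(r.genes) for r in results],
        }
    )
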