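"""Pipeline orchestration and report tables.

Runs the full workflow — quantile normalization, per-disease random-effects
meta-analysis, DEG filtering, cross-disease common signature, meta-score
AUROCs, PPI hub analysis and gene-set enrichment — from a single config, and
exports the tabular sources behind the standard figures (forest plots,
per-study effect-size heatmaps, Venn region counts).  Plot images are a
convenience; the tables are the canonical, tested output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import ExpressionDataset, quantile_normalize, read_expression
from .enrichment import enrich, enrichment_table, read_gmt
from .meta import MetaGeneResult, per_study_table, results_table, run_meta
from .network import centrality, load_interactome, rank_hubs, seed_subnetwork
from .signature import common_signature, discover_and_evaluate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run (thresholds default to the
    conventional multi-cohort DEG filter: |ES| > 0.40, FDR < 0.05, >= 4 studies)."""

    manifests: dict[str, list[dict]] = dc_field(default_factory=dict)
    # disease -> list of {"matrix": path, "phenotype": path, "dataset_id": str}
    es_threshold: float = 0.40
    fdr_threshold: float = 0.05
    min_studies: int = 4
    selection_tolerance: float = 0.005
    interactome: str | None = None
    gmt: str | None = None
    out_dir: str = "cometa_out"
    seed: int = 0
    quantile_normalize: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for thr in (self.es_threshold, self.fdr_threshold):
            if thr <= 0:
                raise ValueError("thresholds must be positive")
        for disease, entries in self.manifests.items():
            for e in entries:
                for key in ("matrix", "phenotype"):
                    if not Path(e[key]).exists():
                        raise FileNotFoundError(f"{disease}: {e[key]}")


@dataclass
class ForestPlotData:
    """Per-study effects with 95% CIs plus the pooled summary for one gene."""

    gene: str
    rows: pd.DataFrame           # dataset_id, g, ci_low, ci_high
    summary_g: float
    summary_ci: tuple[float, float]


def forest_plot_data(gene: str, results: list[MetaGeneResult]) -> ForestPlotData:
    """Per-study g with Wald 95% CIs, ordered by dataset id, plus the summary."""
    match = [r for r in results if r.gene == gene]
    if not match:
        raise KeyError(f"gene {gene!r} not in the meta-analysis results")
    r = match[0]
    rows = pd.DataFrame(
        {
            "dataset_id": [e.dataset_id for e in r.per_study],
            "g": [e.g for e in r.per_study],
            "ci_low": [e.g - 1.96 * e.se for e in r.per_study],
            "ci_high": [e.g + 1.96 * e.se for e in r.per_study],
        }
    ).sort_values("dataset_id", ignore_index=True)
    return ForestPlotData(gene=gene, rows=rows, summary_g=r.g_s, summary_ci=r.ci95())


def effect_size_heatmap_table(
    results: list[MetaGeneResult], gene_subset: list[str]
) -> pd.DataFrame:
    """Genes x datasets matrix of per-study g; unmeasured cells stay NaN."""
    if not gene_subset:
        raise ValueError("empty gene subset")
    by_gene = {r.gene: r for r in results}
    datasets = sorted({e.dataset_id for r in results for e in r.per_study})
    table = pd.DataFrame(float("nan"), index=list(gene_subset), columns=datasets)
    for gene in gene_subset:
        r = by_gene.get(gene)
        if r is None:
            continue
        for e in r.per_study:
            table.loc[gene, e.dataset_id] = e.g
    table.index.name = "gene"
    return table


def venn_counts(deg_sets: dict[str, set[str]]) -> dict[str, int]:
    """Disjoint region counts for two or three labeled gene sets."""
    names = list(deg_sets)
    if len(names) not in (2, 3):
        raise ValueError("venn_counts supports 2 or 3 sets")
    out: dict[str, int] = {}
    import itertools
    for r in range(1, len(names) + 1):
        for inc in itertools.combinations(names, r):
            region = set.intersection(*(deg_sets[n] for n in inc))
            for other in names:
                if other not in inc:
                    region -= deg_sets[other]
            out["&".join(inc)] = len(region)
    return out


def _load_cohorts(entries: list[dict]) -> list[ExpressionDataset]:
    return [
        read_expression(e["matrix"], e["phenotype"],
                        dataset_id=e.get("dataset_id"),
                        source_tissue=e.get("source_tissue", ""))
        for e in entries
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write all artifact tables.

    Returns a summary dict (also serialized as ``run_log.json``); any stage
    failure is re-raised annotated with the stage name, partial outputs kept.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "seed": config.seed,
                 "thresholds": {"es": config.es_threshold,
                                "fdr": config.fdr_threshold,
                                "min_studies": config.min_studies},
                 "stages": {}}
    stage = "load"
    try:
        per_disease: dict[str, list[ExpressionDataset]] = {}
        for disease, entries in config.manifests.items():
            cohorts = _load_cohorts(entries)
            if config.quantile_normalize:
                cohorts = [quantile_normalize(ds) for ds in cohorts]
            per_disease[disease] = cohorts
            log["stages"].setdefault("load", {})[disease] = [
                {"dataset_id": ds.dataset_id, "n_genes": len(ds.genes),
                 "n_case": ds.n_case, "n_control": ds.n_control}
                for ds in cohorts
            ]

        stage = "meta"
        results: dict[str, list[MetaGeneResult]] = {}
        signatures = {}
        deg_sets: dict[str, set[str]] = {}
        for disease, cohorts in per_disease.items():
            sig, res = discover_and_evaluate(
                cohorts, disease=disease,
                es_threshold=config.es_threshold,
                fdr_threshold=config.fdr_threshold,
                min_studies=config.min_studies,
            )
            results[disease] = res
            signatures[disease] = sig
            deg_sets[disease] = set(sig.up_genes) | set(sig.down_genes)
            results_table(res).to_csv(out / f"meta_{disease}.tsv", sep="\t",
                                      index=False, float_format="%.10g")
            per_study_table(res).to_csv(out / f"effects_{disease}.tsv", sep="\t",
                                        index=False, float_format="%.10g")
            sig_json = {
                "disease": disease, "up_genes": sig.up_genes,
                "down_genes": sig.down_genes,
                "summary_auroc": sig.summary_auroc.auroc if sig.summary_auroc else None,
                "per_dataset_auroc": {k: v.auroc
                                      for k, v in sig.per_dataset_auroc.items()},
            }
            (out / f"signature_{disease}.json").write_text(
                json.dumps(sig_json, indent=2))
            log["stages"].setdefault("meta", {})[disease] = {
                "n_genes": len(res), "n_up": len(sig.up_genes),
                "n_down": len(sig.down_genes),
                "summary_auroc": sig_json["summary_auroc"],
            }

        stage = "common_signature"
        common_genes: list[str] = []
        if len(results) == 2:
            (da, db) = list(results)
            common = common_signature(
                results[da], results[db],
                n_datasets_a=len(per_disease[da]),
                n_datasets_b=len(per_disease[db]),
                es_threshold=config.es_threshold,
                fdr_threshold=config.fdr_threshold,
                min_studies=config.min_studies,
            )
            pd.DataFrame(
                {"gene": [g.gene for g in common.genes],
                 f"g_s_{da}": [g.g_s_a for g in common.genes],
                 f"g_s_{db}": [g.g_s_b for g in common.genes],
                 "concordance": [g.concordance for g in common.genes],
                 "persistent": [g.gene in set(common.persistent)
                                for g in common.genes]}
            ).to_csv(out / "common_signature.tsv", sep="\t", index=False,
                     float_format="%.10g")
            common_genes = [g.gene for g in common.genes]
            log["stages"]["common_signature"] = {
                "n_common": len(common.genes), "counts": common.counts(),
                "n_persistent": len(common.persistent),
            }
        venn = venn_counts(deg_sets) if len(deg_sets) in (2, 3) else {}
        (out / "venn_counts.json").write_text(json.dumps(venn, indent=2))

        stage = "network"
        if config.interactome:
            if not Path(config.interactome).exists():
                raise FileNotFoundError(config.interactome)
            seeds = common_genes or sorted(set().union(*deg_sets.values()))
            reference = load_interactome(config.interactome)
            net = centrality(seed_subnetwork(reference, seeds))
            net.node_table().to_csv(out / "network_nodes.tsv", sep="\t", index=False,
                                    float_format="%.10g")
            rank_hubs(net, top_k=20).to_csv(out / "hubs.tsv", sep="\t", index=False,
                                            float_format="%.10g")
            log["stages"]["network"] = {
                "n_seeds": net.n_seeds, "n_connectors": net.n_connectors,
                "n_edges": net.graph.number_of_edges(),
            }

        stage = "enrichment"
        if config.gmt:
            collection = read_gmt(config.gmt)
            universe = set().union(
                *(set(ds.genes) for cohorts in per_disease.values() for ds in cohorts)
            )
            for disease, genes in deg_sets.items():
                if not genes:
                    continue
                res = enrich(sorted(genes), collection, universe=universe)
                enrichment_table(res).to_csv(out / f"enrichment_{disease}.tsv",
                                             sep="\t", index=False,
                                             float_format="%.10g")
            log["stages"]["enrichment"] = {"n_terms": len(collection.sets)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return log


def plot_forest(data: ForestPlotData, path: str | Path) -> None:
    """Render a forest plot (untested convenience; the table is canonical)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.4 * len(data.rows) + 1.5))
    y = range(len(data.rows))
    ax.errorbar(
        data.rows["g"], list(y),
        xerr=[data.rows["g"] - data.rows["ci_low"],
              data.rows["ci_high"] - data.rows["g"]],
        fmt="s", color="tab:blue", capsize=3,
    )
    lo, hi = data.summary_ci
    ax.errorbar([data.summary_g], [len(data.rows)],
                xerr=[[data.summary_g - lo], [hi - data.summary_g]],
                fmt="D", color="gold", capsize=3)
    ax.set_yticks(list(y) + [len(data.rows)])
    ax.set_yticklabels(list(data.rows["dataset_id"]) + ["summary"])
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("standardized mean difference (Hedges' g)")
    ax.set_title(data.gene)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
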