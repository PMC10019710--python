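"""Synthetic multi-cohort case/control expression data with known ground truth.

The generator emulates the structure of a multi-study autoimmune-disease
compendium: several independent cohorts of very different sizes, a planted
set of signature genes sharing a true standardized effect with between-study
heterogeneity (tau^2), per-cohort platform dropout (genes simply absent from
some studies), per-cohort location offsets, and a large background of null
genes.  Everything downstream — per-study Hedges' g, DerSimonian–Laird
pooling, the DEG filter, meta-scores and AUROCs — can therefore be tested
against known truth without any external download.

Generative model (log2 scale):
  baseline_j ~ N(8, 2) per gene, shared across cohorts;
  per-cohort offset_i ~ N(0, 0.5) added to every gene (location/platform shift);
  per (gene, cohort) realized effect delta_ij ~ N(+-true_effect, tau2),
  negative sign for down-signature genes, exactly 0 for null genes;
  control values ~ N(baseline_j + offset_i, noise_sd),
  case values    ~ N(baseline_j + offset_i + delta_ij * noise_sd, noise_sd),
so delta_ij IS the standardized mean difference in pooled-SD units.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CASE, CONTROL, ExpressionDataset, read_expression

logger = logging.getLogger(__name__)

#: case/control arm sizes of the seven RA cohorts of the study compendium,
#: used as the default heterogeneous cohort-size profile.
TABLE1_RA_SIZES: tuple[tuple[int, int], ...] = (
    (18, 15), (15, 19), (112, 53), (15, 15), (13, 9), (232, 43), (10, 11),
)


@dataclass
class SimulationConfig:
    """Parameters of the multi-cohort simulator.

    ``true_effect`` is the common standardized mean difference (pooled-SD
    units) of signature genes; ``tau2`` the between-study variance of the
    realized per-study effect; ``dropout_fraction`` the per-cohort fraction
    of genes absent (platform emulation).
    """

    n_datasets: int = 7
    sizes: tuple[tuple[int, int], ...] = TABLE1_RA_SIZES  # (n_case, n_control) per cohort
    n_genes: int = 1200
    n_signature_up: int = 100
    n_signature_down: int = 100
    true_effect: float = 0.8
    tau2: float = 0.05
    dropout_fraction: float = 0.1
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    dataset_offset_sd: float = 0.5
    seed: int = 0
    disease: str = "SIM"

    def __post_init__(self) -> None:
        if self.true_effect < 0:
            raise ValueError("true_effect must be >= 0")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.n_signature_up + self.n_signature_down > self.n_genes:
            raise ValueError("signature genes exceed n_genes")
        if len(self.sizes) != self.n_datasets:
            if len(self.sizes) < self.n_datasets:
                raise ValueError(
                    f"{self.n_datasets} datasets requested but only "
                    f"{len(self.sizes)} (n_case, n_control) sizes given"
                )
            self.sizes = tuple(self.sizes[: self.n_datasets])


@dataclass
class GroundTruth:
    """Planted truth: signed true pooled effect, realized per-study effects, presence."""

    true_effect: pd.Series            # gene -> signed true pooled effect (0 for nulls)
    realized: pd.DataFrame            # genes x datasets, realized delta_ij (NaN if absent)
    presence: pd.DataFrame            # genes x datasets, bool
    up_genes: list[str] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)

    @property
    def null_genes(self) -> list[str]:
        return list(self.true_effect.index[self.true_effect == 0.0])


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Draw the full multi-cohort bundle; bit-reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    up = genes[: config.n_signature_up]
    down = genes[config.n_signature_up: config.n_signature_up + config.n_signature_down]

    signs = pd.Series(0.0, index=genes)
    signs[up] = 1.0
    signs[down] = -1.0
    true_pooled = signs * config.true_effect

    baseline = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes),
        index=genes,
    )

    datasets: list[ExpressionDataset] = []
    ids = [f"{config.disease}{i + 1:02d}" for i in range(config.n_datasets)]
    realized = pd.DataFrame(np.nan, index=genes, columns=ids)
    presence = pd.DataFrame(False, index=genes, columns=ids)
    tau = np.sqrt(config.tau2)

    for ds_id, (n1, n0) in zip(ids, config.sizes):
        offset = rng.normal(0.0, config.dataset_offset_sd)
        delta = true_pooled.to_numpy() + np.where(
            signs.to_numpy() != 0.0,
            rng.normal(0.0, tau, config.n_genes),
            0.0,
        )
        keep = np.ones(config.n_genes, dtype=bool)
        n_drop = int(round(config.dropout_fraction * config.n_genes))
        if n_drop:
            keep[rng.choice(config.n_genes, size=n_drop, replace=False)] = False

        mu = baseline.to_numpy() + offset
        control = rng.normal(
            mu[:, None], config.noise_sd, (config.n_genes, n0)
        )
        case = rng.normal(
            (mu + delta * config.noise_sd)[:, None],
            config.noise_sd,
            (config.n_genes, n1),
        )
        values = np.hstack([case, control])[keep]
        sample_ids = [f"{ds_id}_case{k}" for k in range(n1)] + [
            f"{ds_id}_ctrl{k}" for k in range(n0)
        ]
        expr = pd.DataFrame(values, index=np.array(genes)[keep], columns=sample_ids)
        labels = pd.Series([CASE] * n1 + [CONTROL] * n0, index=sample_ids)
        datasets.append(
            ExpressionDataset(dataset_id=ds_id, expr=expr, labels=labels,
                              source_tissue="synthetic")
        )
        realized.loc[keep, ds_id] = delta[keep]
        presence.loc[keep, ds_id] = True

    truth = GroundTruth(
        true_effect=true_pooled, realized=realized, presence=presence,
        up_genes=up, down_genes=down,
    )
    return datasets, truth


def write_fixture_bundle(
    datasets: list[ExpressionDataset],
    truth: GroundTruth,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Serialize cohorts (matrix + phenotype TSVs) plus the truth table; return the manifest."""
    if not datasets:
        raise ValueError("empty dataset list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for ds in datasets:
        mpath = out_dir / f"{ds.dataset_id}.matrix.tsv"
        ppath = out_dir / f"{ds.dataset_id}.pheno.tsv"
        ds.expr.to_csv(mpath, sep="\t", index_label="gene_id")
        pd.DataFrame(
            {"sample_id": ds.samples, "label": ds.labels.values}
        ).to_csv(ppath, sep="\t", index=False)
        entries.append(
            {"dataset_id": ds.dataset_id, "matrix": mpath.name, "phenotype": ppath.name}
        )
    truth_table = pd.DataFrame(
        {
            "gene": truth.true_effect.index,
            "true_effect": truth.true_effect.values,
            "direction": np.sign(truth.true_effect.values).astype(int),
        }
    )
    truth_table.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    manifest = {"datasets": entries, "truth": "truth.tsv", "seed": seed}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_fixture_bundle(out_dir: str | Path) -> list[ExpressionDataset]:
    """Load every cohort listed in a bundle manifest."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    return [
        read_expression(
            out_dir / e["matrix"], out_dir / e["phenotype"], dataset_id=e["dataset_id"]
        )
        for e in manifest["datasets"]
    ]
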