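# Methods

## Model

`cometa` treats each cohort as an independent two-group study of the same
genes. For gene *j* in cohort *i* the observed standardized mean difference
(Hedges' g) estimates a study-specific true effect θᵢⱼ; under the
random-effects model θᵢⱼ ~ N(μⱼ, τ²ⱼ), where μⱼ is the cross-study mean
effect and τ²ⱼ the between-study variance produced by platform, tissue and
population heterogeneity. μⱼ is estimated by inverse-variance pooling with
DerSimonian–Laird moment estimation of τ²ⱼ; the model is deliberately
conservative — it widens intervals instead of "correcting" batch structure,
which is what makes independent cohorts poolable without cross-cohort
normalization.

Assumptions worth stating plainly:

- expression is approximately Gaussian on the log2 scale within each group,
  and the standardized effect is comparable across platforms once each
  cohort is quantile-normalized and standardized internally;
- cohorts are independent (the model has no term for shared samples);
- the Hedges variance formula `V = J²[(n₁+n₀)/(n₁n₀) + d²/(2(n₁+n₀))]` is the
  standard large-sample approximation; the small-sample correction
  `J = 1 − 3/(4·df − 1)` removes most of the positive bias of Cohen's d;
- per-study p-values entering Fisher's method are two-sided normal tails of
  `g/√V`, so the combined p is two-sided in the effect but agnostic to
  direction consistency (direction is enforced later by the sign of the
  pooled effect).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `es_threshold` | 0.40 | minimum absolute pooled effect (pooled-SD units) for a DEG |
| `fdr_threshold` | 0.05 | BH-adjusted Fisher-combined p cutoff |
| `min_studies` | 4 | minimum cohorts measuring the gene |
| `selection_tolerance` | 0.005 | AUROC gain a greedy add/remove move must exceed |
| `true_effect` (simulator) | 0.8 | planted standardized effect of signature genes |
| `tau2` (simulator) | 0.05 | between-study variance of the planted effect |
| `dropout_fraction` (simulator) | 0.10 | per-cohort fraction of genes absent |
| `noise_sd` (simulator) | 1.0 | residual SD on the log2 scale |

The DEG filter applies the effect threshold to |g_s|: published multi-cohort
signatures report both up- and down-regulated genes against a single "ES"
cutoff, and magnitude is the only reading consistent with negative-effect
DEGs. A signed mode (`signed_es=True`) is available.

## The synthetic generator

The simulator emulates the structure that matters to the statistics: seven
cohorts whose case/control arm sizes follow the heterogeneous profile of a
real autoimmune compendium (from 13/9 to 232/43), gene baselines
~ N(8, 2) shared across cohorts, a per-cohort location offset ~ N(0, 0.5)
standing in for platform/site effects, per-(gene, cohort) realized effects
drawn once so that τ² estimation has a real target, and uniform platform
dropout. It does **not** emulate probe-level structure, heavy-tailed or
heteroscedastic intensity noise, correlated gene modules, or confounding
between label and batch. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under the stated model — not
that any particular biological dataset satisfies that model.

## Numerical choices

- **Quantile normalization** assigns each sample the across-sample mean of
  sorted values at its ranks; ties receive the mean of their would-be values,
  which keeps equal inputs equal and makes the transform idempotent up to the
  last floating-point ulp.
- **Degenerate genes** (zero pooled variance within a cohort) are excluded
  from that cohort only, logged, and may still be meta-analyzed from other
  cohorts.
- **τ² truncation** at zero follows the moment estimator's definition; with a
  single study τ² is set to 0 (unidentifiable).
- **p = 0** entering Fisher's method is clipped to the smallest positive
  double and logged.
- **Meta-score**: within-cohort z-scores are shifted by |min z| + 1 so the
  geometric mean is defined; the score is the up-gene geometric mean minus
  the down-gene geometric mean. Any strictly monotone variant yields the same
  AUROC for single-sided signatures.
- **Summary AUROC** pools per-cohort AUROCs by inverse variance on the logit
  scale (Hanley–McNeil SEs, delta method); AUROCs of exactly 0 or 1 are
  nudged by 0.5/(n₁n₀) so the logit is finite. A sample-size-weighted mean is
  available as `method="sample_weighted"`.
- **Greedy cohort curation** starts from the full candidate set and applies
  the best single add/remove while the pooled AUROC improves by more than the
  tolerance; ties prefer the smaller subset, then the lexically smaller
  cohort id, making the search fully deterministic. The exhaustive-search
  oracle used in tests applies the same tie rule. Equality between greedy
  and exhaustive search is checked at tolerance 0 — a positive tolerance
  makes the greedy search stop early by design.
- **Betweenness** is reported unnormalized over unordered pairs (Brandes),
  the convention under which published PPI hub scores on ~10³-node
  subnetworks reach 10⁴–10⁵.
- **Enrichment** uses the exact hypergeometric upper tail
  (`P(X ≥ k)`), equivalent to the one-sided Fisher's exact test; the
  significance flag follows raw p < 0.05 with BH q-values reported alongside,
  and the background universe defaults to all genes measured in the run.

## Problem sizes and validation design

Unit and acceptance tests validate on simulations of 7 cohorts × 1200 genes
(200 signature + 1000 null) at the cohort sizes above — large enough that
binomial/Monte-Carlo error is small relative to every margin tested, small
enough to run in seconds. CI coverage of the DerSimonian–Laird Wald interval
is estimated by pooling 20 replicate simulations (~4000 intervals): at k = 7
cohorts and τ² = 0.05 the interval's true coverage is ≈ 0.90–0.91, slightly
below nominal, a well-documented property of the DL Wald construction at
moderate study counts (Knapp–Hartung corrections, deliberately out of scope,
address it). Greedy-vs-exhaustive curation is checked on 4-cohort instances
containing one label-permuted (pure noise) cohort, where the optimum is
well-separated.

## Known limitations

- The DL Wald CI undercovers slightly at small k (see above).
- The meta-score requires at least one signature gene per cohort and gives
  equal weight to every gene; no gene-level weighting by effect size.
- Quantile normalization assumes comparable global distributions; it will
  mask genuine global shifts (e.g. global transcriptional amplification).
- The concordance classifier treats a pooled effect of exactly 0 as
  antagonistic-by-default; in practice pooled effects passing the DEG filter
  are bounded away from 0.
- Hub ranking depends entirely on the supplied interactome snapshot; degree
  and betweenness values are not comparable across interactome versions.
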