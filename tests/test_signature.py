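"""Meta-scores, AUROC, summary pooling, dataset curation and concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cometa.meta import MetaGeneResult, run_meta
from cometa.signature import (
    ANTAGONISTIC,
    CONCORDANT_DOWN,
    CONCORDANT_UP,
    AurocEstimate,
    Signature,
    auroc,
    classify_concordance,
    classify_effect_table,
    common_signature,
    discover_and_evaluate,
    exhaustive_dataset_selection,
    greedy_dataset_selection,
    meta_score,
    summary_auroc,
)
from cometa.simulate import SimulationConfig, simulate_cohorts

from conftest import make_dataset


class TestAuroc:
    def test_perfect_separation(self):
        est = auroc([1, 2, 3, 4], ["control", "control", "case", "case"])
        assert est.auroc == 1.0

    def test_all_tied_scores(self):
        est = auroc([5, 5, 5, 5], ["case", "case", "control", "control"])
        assert est.auroc == 0.5

    def test_three_quarters_by_pair_enumeration(self):
        # cases score (2, 4), controls (1, 3): 3 of 4 pairs won
        est = auroc([2, 4, 1, 3], ["case", "case", "control", "control"])
        assert est.auroc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2], ["case", "case"])

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=12)
        labels = np.array(["case"] * 5 + ["control"] * 7)
        a = auroc(scores, labels).auroc
        b = auroc(np.exp(scores * 2.0), labels).auroc
        assert a == pytest.approx(b, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_complement_identity(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, size=14).astype(float)  # ties likely
        labels = np.array(["case"] * 6 + ["control"] * 8)
        a = auroc(scores, labels).auroc
        b = auroc(-scores, labels).auroc
        assert a + b == pytest.approx(1.0, abs=1e-10)

    def test_hanley_mcneil_ci_brackets_estimate(self):
        est = auroc([2, 4, 1, 3], ["case", "case", "control", "control"])
        assert 0.0 <= est.ci_low <= est.auroc <= est.ci_high <= 1.0


class TestMetaScore:
    def test_single_up_gene_matches_gene_auroc(self, toy_dataset):
        sig = Signature(disease="d", up_genes=["G0"], down_genes=[])
        scores = meta_score(toy_dataset, sig)
        a = auroc(scores.values, toy_dataset.labels.values).auroc
        b = auroc(toy_dataset.expr.loc["G0"].values, toy_dataset.labels.values).auroc
        assert a == b  # monotone transform of the same gene

    def test_swapping_up_down_negates(self, toy_dataset):
        s1 = meta_score(toy_dataset, Signature("d", ["G0"], ["G2"]))
        s2 = meta_score(toy_dataset, Signature("d", ["G2"], ["G0"]))
        assert np.allclose(s1.values, -s2.values)

    def test_absent_genes_skipped(self, toy_dataset):
        sig = Signature("d", ["G0", "NOT_THERE"], [])
        scores = meta_score(toy_dataset, sig)
        ref = meta_score(toy_dataset, Signature("d", ["G0"], []))
        assert np.allclose(scores.values, ref.values)

    def test_no_measurable_gene_rejected(self, toy_dataset):
        with pytest.raises(ValueError):
            meta_score(toy_dataset, Signature("d", ["NOPE"], ["NADA"]))

    def test_planted_signature_separates_classes(self, small_bundle):
        datasets, truth = small_bundle
        sig = Signature("d", truth.up_genes, truth.down_genes)
        ds = datasets[0]
        scores = meta_score(ds, sig)
        case = scores[ds.labels == "case"].mean()
        ctrl = scores[ds.labels == "control"].mean()
        assert case > ctrl


class TestSummaryAuroc:
    def test_single_dataset_identity(self):
        est = AurocEstimate(0.9, 0.8, 1.0, 20, 20)
        assert summary_auroc({"a": est}).auroc == 0.9

    def test_all_random_stays_half(self):
        per = {f"d{i}": AurocEstimate(0.5, 0.3, 0.7, 30, 30) for i in range(4)}
        assert summary_auroc(per).auroc == pytest.approx(0.5, abs=1e-10)

    def test_convexity_on_transformed_scale(self):
        per = {"a": AurocEstimate(0.8, 0.7, 0.9, 50, 50),
               "b": AurocEstimate(0.9, 0.8, 1.0, 50, 50)}
        pooled = summary_auroc(per).auroc
        assert 0.8 < pooled < 0.9

    def test_sample_weighted_alternative(self):
        per = {"a": AurocEstimate(0.6, 0.5, 0.7, 10, 10),
               "b": AurocEstimate(0.9, 0.8, 1.0, 90, 90)}
        pooled = summary_auroc(per, method="sample_weighted").auroc
        # weights 20/200 and 180/200
        assert pooled == pytest.approx(0.1 * 0.6 + 0.9 * 0.9)

    def test_degenerate_one_handled(self):
        per = {"a": AurocEstimate(1.0, 0.9, 1.0, 25, 25),
               "b": AurocEstimate(0.95, 0.85, 1.0, 25, 25)}
        pooled = summary_auroc(per)
        assert 0.9 < pooled.auroc < 1.0


class TestDiscovery:
    def test_planted_signature_high_summary_auroc(self, small_bundle):
        datasets, truth = small_bundle
        sig, _ = discover_and_evaluate(datasets, disease="sim")
        assert sig.summary_auroc.auroc > 0.85
        found = set(sig.up_genes) | set(sig.down_genes)
        planted = set(truth.up_genes) | set(truth.down_genes)
        # the >=4-study filter can only recover genes every cohort measured
        eligible = {g for g in planted if truth.presence.loc[g].sum() >= 4}
        assert len(found & eligible) / len(eligible) > 0.8


class TestGreedySelection:
    @staticmethod
    def noisy_instance(seed):
        cfg = SimulationConfig(
            seed=seed, n_datasets=4, sizes=((30, 30), (25, 20), (40, 30), (30, 25)),
            n_genes=200, n_signature_up=20, n_signature_down=20,
            true_effect=1.0, dropout_fraction=0.0,
        )
        datasets, _ = simulate_cohorts(cfg)
        rng = np.random.default_rng(seed + 1000)
        bad = datasets[3]
        bad.labels = pd.Series(rng.permutation(bad.labels.values),
                               index=bad.labels.index)
        return datasets

    def test_noise_dataset_excluded(self):
        datasets = self.noisy_instance(0)
        selected, trace = greedy_dataset_selection(datasets, tolerance=0.0,
                                                   min_studies=2)
        assert "SIM04" not in selected
        assert trace.iloc[0]["move"] == "init"

    def test_infinite_tolerance_keeps_initial_subset(self):
        datasets = self.noisy_instance(1)
        selected, trace = greedy_dataset_selection(datasets,
                                                   tolerance=float("inf"))
        assert selected == sorted(ds.dataset_id for ds in datasets)
        assert len(trace) == 1

    def test_unsatisfiable_constraint_named(self):
        datasets = self.noisy_instance(2)
        with pytest.raises(ValueError, match="muscle"):
            greedy_dataset_selection(datasets, tissue_minimums={"muscle": 1})

    def test_matches_exhaustive_small_instances(self):
        for seed in range(3):  # full 20-seed sweep lives in the acceptance suite
            datasets = self.noisy_instance(seed + 50)
            sel, _ = greedy_dataset_selection(datasets, tolerance=0.0,
                                              min_studies=2)
            ex, _ = exhaustive_dataset_selection(datasets, min_studies=2)
            assert sel == ex


def mk_result(gene, g_s, fdr=0.01, n=4):
    return MetaGeneResult(gene=gene, g_s=g_s, se_s=0.1, T2=0, Q=0,
                          p_fisher=fdr, n_studies=n, fdr=fdr)


class TestCommonSignature:
    def test_set_logic_and_labels(self):
        a = [mk_result("G1", 0.5), mk_result("G2", -0.6), mk_result("G3", 0.7)]
        b = [mk_result("G2", -0.5), mk_result("G3", -0.6), mk_result("G4", 0.5)]
        common = common_signature(a, b)
        by_gene = {g.gene: g.concordance for g in common.genes}
        assert by_gene == {"G2": CONCORDANT_DOWN, "G3": ANTAGONISTIC}

    def test_persistence_requires_full_study_counts(self):
        a = [mk_result("G1", 0.5, n=4), mk_result("G2", 0.6, n=3)]
        b = [mk_result("G1", 0.5, n=5), mk_result("G2", 0.6, n=5)]
        common = common_signature(a, b, n_datasets_a=4, n_datasets_b=5)
        assert common.persistent == ["G1"]

    def test_empty_intersection_valid(self):
        common = common_signature([mk_result("G1", 0.5)], [mk_result("G9", 0.5)])
        assert common.genes == [] and common.counts()[ANTAGONISTIC] == 0

    def test_published_pooled_effect_pairs(self):
        # pooled effect pairs reported for the two-disease overlap
        assert classify_concordance(0.709280042, -0.435212793) == ANTAGONISTIC
        assert classify_concordance(0.723657312, 1.336283459) == CONCORDANT_UP
        assert classify_concordance(-0.590595045, -0.50551105) == CONCORDANT_DOWN

    def test_effect_table_classifier(self):
        table = pd.DataFrame({"gene": ["A", "B"], "x": [0.5, -0.4],
                              "y": [0.6, 0.4]})
        out = classify_effect_table(table)
        assert list(out["concordance"]) == [CONCORDANT_UP, ANTAGONISTIC]


def test_permuted_labels_auroc_near_half(small_bundle):
    """Label permutation destroys the signal: mean AUROC ~ 0.5."""
    datasets, truth = small_bundle
    sig = Signature("d", truth.up_genes, truth.down_genes)
    ds = datasets[2]
    scores = meta_score(ds, sig)
    rng = np.random.default_rng(123)
    aurocs = []
    for _ in range(50):
        perm = rng.permutation(ds.labels.values)
        aurocs.append(auroc(scores.values, perm).auroc)
    assert abs(np.mean(aurocs) - 0.5) < 0.05
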