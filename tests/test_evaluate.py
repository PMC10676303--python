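"""Robustness, specificity, clustering/embedding views, genomic partition."""

import numpy as np
import pandas as pd
import pytest

from episig import (
    PlantedRegion,
    SimConfig,
    cross_specificity,
    dmr_features,
    embed_2d,
    genomic_partition,
    hierarchical_clusters,
    missing_probe_experiment,
    simulate_cohort,
)


@pytest.fixture(scope="module")
def robustness_report(study, trained_models):
    models = {
        "dmc": {"plr": trained_models["dmc"]["plr"]},
        "dmr": {"plr": trained_models["dmr"]["plr"]},
    }
    return missing_probe_experiment(
        study.test.betas,
        study.test.labels,
        study.test.manifest,
        models=models,
        signatures={"dmc": study.dmc_sig, "dmr": study.dmr_sig},
        fractions=(0.0, 0.10, 0.30),
        n_repeats=3,
        base_seed=11,
    )


class TestRobustness:
    def test_report_shape_contract(self, robustness_report):
        rec = robustness_report.records
        # 2 nonzero fractions x 3 repeats x 2 paradigms x 1 model + fraction-0 rows
        assert len(rec) == 2 * 3 * 2 * 1 + 2
        assert rec["mcc"].between(-1, 1).all()
        assert set(rec["fraction"].unique()) == {0.0, 0.10, 0.30}

    def test_fraction_zero_is_single_deterministic_evaluation(self, robustness_report):
        zero = robustness_report.summary.query("fraction == 0")
        assert (zero["n"] == 1).all()
        assert (zero["std_mcc"] == 0).all()

    def test_strong_signal_stays_accurate(self, robustness_report):
        assert (robustness_report.summary["mean_mcc"] > 0.8).all()

    def test_invalid_fraction_rejected(self, study, trained_models):
        with pytest.raises(ValueError):
            missing_probe_experiment(
                study.test.betas, study.test.labels, study.test.manifest,
                models={"dmr": {"plr": trained_models["dmr"]["plr"]}},
                signatures={"dmr": study.dmr_sig},
                fractions=(1.0,),
            )


class TestSpecificity:
    def test_disjoint_signature_cohort_predicted_all_control(self, study, trained_models):
        # cohort B: same array baseline, planted signal elsewhere; the
        # null_regions keep signature-A probes in their control state
        other = simulate_cohort(
            SimConfig(
                n_probes=2000, n_case=10, n_control=10,
                planted_regions=[PlantedRegion("chr1", 60 + i * 40, 12, 0.35) for i in range(4)],
                null_regions=[PlantedRegion("chr1", 300 + i * 300, 12, 0.35) for i in range(4)],
                null_dmcs=[(1600 + 3 * i, 0.35) for i in range(20)],
                seed=123, baseline_seed=42,
            )
        )
        rep = cross_specificity(
            trained_models["dmr"]["svm"], study.dmr_sig, other.betas, other.manifest
        )
        assert rep.specificity == 1.0
        assert rep.n_predicted_case == 0
        assert rep.n_predicted_control == other.betas.shape[1]

    def test_self_consistency_on_own_samples(self, study, trained_models):
        model = trained_models["dmr"]["svm"]
        controls = study.train.betas.loc[:, study.train.labels == "control"]
        cases = study.train.betas.loc[:, study.train.labels == "case"]
        rep_c = cross_specificity(model, study.dmr_sig, controls, study.train.manifest)
        assert rep_c.specificity == 1.0
        rep_x = cross_specificity(model, study.dmr_sig, cases, study.train.manifest)
        assert rep_x.n_predicted_case == cases.shape[1]  # sensitivity check

    def test_empty_cohort_rejected(self, study, trained_models):
        with pytest.raises(ValueError):
            cross_specificity(
                trained_models["dmr"]["svm"], study.dmr_sig,
                study.train.betas.iloc[:, :0], study.train.manifest,
            )


class TestClustering:
    def test_two_separated_groups_recovered(self, study, train_features):
        feats = train_features["dmr"]
        clusters = hierarchical_clusters(feats, k=2)
        labels = study.train.labels.loc[feats.index]
        a = clusters[labels == "case"]
        b = clusters[labels == "control"]
        assert a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] != b.iloc[0]

    def test_duplicate_samples_share_cluster(self):
        feats = pd.DataFrame(
            [[0.1, 0.1], [0.1, 0.1], [0.9, 0.9]], index=["a", "a2", "b"]
        )
        clusters = hierarchical_clusters(feats, k=2)
        assert clusters["a"] == clusters["a2"] != clusters["b"]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_clusters(pd.DataFrame([[0.0]]), k=2)


class TestEmbedding:
    def test_shape_determinism_and_zero_variance_guard(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(rng.random((12, 6)))
        feats.iloc[:, 0] = 0.5  # constant feature must not break scaling
        a = embed_2d(feats, seed=3)
        b = embed_2d(feats, seed=3)
        assert a.shape == (12, 2)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            embed_2d(pd.DataFrame(np.eye(3)), seed=0)


class TestGenomicPartition:
    @pytest.fixture()
    def setup(self):
        manifest = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [9500, 7000, 12000, 50_000, 21_000],
            },
            index=["prom", "up", "body", "inter", "prom_minus"],
        )
        genes = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [10_000, 15_000],
                "end": [14_000, 20_000],
                "strand": ["+", "-"],
                "name": ["geneA", "geneB"],
            }
        )
        return manifest, genes

    def test_category_assignment_with_precedence(self, setup):
        manifest, genes = setup
        rep = genomic_partition(
            ["prom", "up", "body", "inter", "prom_minus"], manifest, genes
        )
        counts = rep.counts["signature"]
        # 9500 is 500 bp upstream of + TSS(10000); 7000 is 3 kb upstream;
        # 12000 sits in geneA's body; 21000 is 1 kb upstream of the - strand
        # TSS at 20000; 50000 touches nothing.
        assert counts["promoter"] == 2
        assert counts["upstream_1to5kb"] == 1
        assert counts["gene_body"] == 1
        assert counts["intergenic"] == 1

    def test_fractions_sum_to_one_and_order_invariant(self, setup):
        manifest, genes = setup
        ids = list(manifest.index)
        a = genomic_partition(ids, manifest, genes, background_ids=ids)
        b = genomic_partition(ids[::-1], manifest, genes, background_ids=ids)
        assert a.fractions["signature"].sum() == pytest.approx(1.0)
        assert a.fractions["background"].sum() == pytest.approx(1.0)
        pd.testing.assert_frame_equal(a.fractions, b.fractions)

    def test_malformed_gene_model_rejected(self, setup):
        manifest, genes = setup
        bad = genes.assign(start=genes["end"] + 1)
        with pytest.raises(ValueError):
            genomic_partition(["prom"], manifest, bad)
        bad_strand = genes.assign(strand=["+", "?"])
        with pytest.raises(ValueError):
            genomic_partition(["prom"], manifest, bad_strand)
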