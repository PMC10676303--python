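"""Bump-hunting DMR caller: clustering, scanning, permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from episig import (
    DMRParams,
    PlantedRegion,
    SimConfig,
    assign_region_pvalues,
    build_dmr_signature,
    candidate_runs,
    cluster_probes,
    find_candidate_regions,
    group_coefficients,
    null_region_areas,
    pick_cutoff,
    simulate_cohort,
)
from episig.cohort import make_manifest
from episig.dmr import _smooth_within_clusters, permuted_coefficients


def _manifest(positions, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": positions},
        index=[f"p{i}" for i in range(len(positions))],
    )


class TestClusterProbes:
    def test_gap_scan_example(self):
        man = _manifest([100, 350, 380, 2000, 2100])
        assert list(cluster_probes(man, 500)) == [1, 1, 1, 2, 2]

    def test_single_probe(self):
        assert list(cluster_probes(_manifest([100]), 1000)) == [1]

    def test_zero_gap_gives_singleton_clusters(self):
        man = _manifest([100, 200, 300])
        assert list(cluster_probes(man, 0)) == [1, 2, 3]

    def test_chromosome_boundary_splits(self):
        man = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2"], "pos": [100, 200, 300]},
            index=["a", "b", "c"],
        )
        assert list(cluster_probes(man, 10_000)) == [1, 1, 2]

    def test_unsorted_manifest_rejected(self):
        with pytest.raises(ValueError):
            cluster_probes(_manifest([500, 100]), 1000)


class TestGroupCoefficients:
    def test_mean_difference(self):
        betas = pd.DataFrame(
            [[0.8, 0.9, 0.2, 0.4]], index=["p0"], columns=list("abcd")
        )
        labels = pd.Series(["case", "case", "control", "control"], index=list("abcd"))
        assert group_coefficients(betas, labels)[0] == pytest.approx(0.55)

    def test_identical_groups_zero(self, study):
        betas = study.train.betas.iloc[:50]
        half = betas.copy()
        labels = pd.Series(
            np.where(np.arange(betas.shape[1]) % 2 == 0, "case", "control"),
            index=betas.columns,
        )
        doubled = pd.concat([betas, betas], axis=0)
        # same samples in both groups -> exactly zero everywhere
        same = pd.concat([half, half.add_suffix("_dup")], axis=1)
        lab = pd.Series(
            ["case"] * betas.shape[1] + ["control"] * betas.shape[1],
            index=same.columns,
        )
        assert np.allclose(group_coefficients(same, lab), 0.0)

    def test_running_mean_boundary_shrink(self):
        coef = np.array([0.0, 0.3, 0.6])
        out = _smooth_within_clusters(coef, np.ones(3, dtype=int), 3)
        assert np.allclose(out, [0.15, 0.3, 0.45])


class TestPickCutoff:
    def test_nearest_rank_examples(self):
        pool = [0.1] * 98 + [0.5, 0.9]
        assert pick_cutoff(pool, 0.99) == pytest.approx(0.5)
        assert pick_cutoff(np.arange(1, 11) / 10.0, 0.5) == pytest.approx(0.5)

    def test_constant_pool(self):
        assert pick_cutoff([0.3, 0.3, 0.3], 0.9) == pytest.approx(0.3)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pick_cutoff([], 0.99)


def _oracle_runs(coef, clusters, cutoff):
    """Brute-force run scanner, structurally independent of the kernel."""
    signs = [
        0 if (c != c) else (1 if c >= cutoff else (-1 if c <= -cutoff else 0))
        for c in coef
    ]
    runs, i, n = [], 0, len(coef)
    while i < n:
        if signs[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and signs[j + 1] == signs[i] and clusters[j + 1] == clusters[i]:
            j += 1
        runs.append((i, j, signs[i]))
        i = j + 1
    return runs


class TestCandidateRegions:
    def test_positive_run_worked_example(self):
        man = _manifest([1000, 1500, 2000, 2500, 3000])
        coef = np.array([0.05, 0.40, 0.45, 0.50, 0.02])
        out = find_candidate_regions(coef, np.ones(5, dtype=int), man, 0.3)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.start_index, row.end_index, row.L) == (1, 3, 3)
        assert row.value == pytest.approx(0.45)
        assert row.area == pytest.approx(1.35)
        assert (row.start, row.end, row.width) == (1500, 2500, 1001)

    def test_negative_run(self):
        man = _manifest([100, 200])
        out = find_candidate_regions(
            np.array([-0.40, -0.35]), np.ones(2, dtype=int), man, 0.3
        )
        assert len(out) == 1
        assert out.iloc[0].value == pytest.approx(-0.375)
        assert out.iloc[0].area == pytest.approx(0.75)

    def test_subthreshold_profile_yields_nothing(self):
        man = _manifest([100, 200, 300])
        out = find_candidate_regions(
            np.array([0.1, -0.2, 0.05]), np.ones(3, dtype=int), man, 0.3
        )
        assert len(out) == 0

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            candidate_runs(np.array([0.5]), np.array([1]), 0.0)

    @settings(deadline=None, max_examples=150)
    @given(
        st.lists(
            st.sampled_from([-0.6, -0.3, 0.0, 0.2, 0.35, 0.6]),
            min_size=1,
            max_size=12,
        ),
        st.data(),
    )
    def test_matches_brute_force_oracle(self, coef, data):
        clusters = np.cumsum(
            [1] + [data.draw(st.integers(0, 1)) for _ in range(len(coef) - 1)]
        )
        got = candidate_runs(np.array(coef), clusters, 0.3)
        assert got == _oracle_runs(coef, clusters, 0.3)

    def test_area_and_value_bounds(self, study):
        for _, row in study.dmr_candidates.iterrows():
            assert row.area >= row.L * study.dmr_sig.params["resolved_cutoff"] - 1e-12
            assert abs(row.value) >= study.dmr_sig.params["resolved_cutoff"] - 1e-12

    def test_raising_cutoff_never_adds_candidates(self):
        rng = np.random.default_rng(0)
        coef = rng.normal(0, 0.3, 200)
        clusters = np.repeat(np.arange(1, 21), 10)
        counts = [
            len(candidate_runs(coef, clusters, c)) for c in (0.1, 0.2, 0.3, 0.5)
        ]
        assert counts == sorted(counts, reverse=True)


class TestNullAndPValues:
    def test_identity_permutation_reproduces_observed_areas(self):
        c = simulate_cohort(SimConfig(n_probes=200, n_case=2, n_control=2, seed=0))
        clusters = cluster_probes(c.manifest, 1000)
        coef = group_coefficients(c.betas, c.labels)
        cutoff = 0.1
        observed = find_candidate_regions(coef, clusters, c.manifest, cutoff)
        identity_seed = next(
            s
            for s in range(10_000)
            if (np.random.default_rng(s + 1).permutation(4) == np.arange(4)).all()
        )
        null = null_region_areas(
            c.betas, c.labels, clusters, cutoff, n_permutations=1, seed=identity_seed
        )
        assert np.allclose(np.sort(null), np.sort(observed["area"].to_numpy()), atol=1e-5)

    def test_null_area_distribution_matches_observed_on_null_data(self):
        from scipy.stats import ks_2samp

        c = simulate_cohort(SimConfig(n_probes=3000, n_case=10, n_control=10, seed=21))
        clusters = cluster_probes(c.manifest, 1000)
        coef = group_coefficients(c.betas, c.labels)
        cutoff = pick_cutoff(np.abs(coef), 0.95)
        observed = find_candidate_regions(coef, clusters, c.manifest, cutoff)
        null = null_region_areas(
            c.betas, c.labels, clusters, cutoff, n_permutations=50, seed=4
        )
        assert ks_2samp(observed["area"], null).pvalue > 0.01

    def test_empirical_p_counting_examples(self):
        cands = pd.DataFrame({"area": [1.35]})
        null = np.array([2.0] * 4 + [0.5] * 95)  # 4 of 99 null areas >= observed
        out = assign_region_pvalues(cands, null)
        assert out["p"].iloc[0] == pytest.approx(0.05)

        smaller = assign_region_pvalues(pd.DataFrame({"area": [0.1]}), null)
        assert smaller["p"].iloc[0] == 1.0
        larger = assign_region_pvalues(pd.DataFrame({"area": [5.0]}), null)
        assert larger["p"].iloc[0] == pytest.approx(0.01)

    def test_empty_candidates_allowed_empty_null_rejected(self):
        out = assign_region_pvalues(pd.DataFrame({"area": []}), np.array([1.0]))
        assert len(out) == 0
        with pytest.raises(ValueError):
            assign_region_pvalues(pd.DataFrame({"area": [1.0]}), np.array([]))

    def test_permutation_b_uses_seed_plus_b(self):
        c = simulate_cohort(SimConfig(n_probes=100, n_case=5, n_control=5, seed=0))
        a = permuted_coefficients(c.betas, c.labels, n_permutations=3, seed=10)
        b = permuted_coefficients(c.betas, c.labels, n_permutations=1, seed=12)
        assert np.allclose(a[:, 2], b[:, 0])


class TestBuildDMRSignature:
    def test_planted_regions_recovered(self, study):
        truth = study.train.truth.regions
        regions = study.dmr_sig.regions
        recovered = 0
        for _, t in truth.iterrows():
            for _, r in regions.iterrows():
                inter = min(r.end_index, t.end_index) - max(r.start_index, t.start_index) + 1
                if inter >= 0.5 * t.n_probes and inter >= 0.5 * r.L:
                    recovered += 1
                    break
        assert recovered == len(truth)

    def test_min_probes_drops_short_region_despite_huge_delta(self):
        c = simulate_cohort(
            SimConfig(
                n_probes=500, n_case=10, n_control=10,
                planted_regions=[PlantedRegion("chr1", 100, 5, 0.6)], seed=3,
            )
        )
        sig, cands = build_dmr_signature(
            c.betas, c.labels, c.manifest,
            DMRParams(n_permutations=30, min_probes=10, seed=3),
        )
        assert len(sig) == 0
        assert (cands["L"] < 10).all() or not cands["retained"].any()

    def test_raising_min_probes_never_adds_regions(self, study):
        from episig import DMRParams, build_dmr_signature

        betas, labels, man = study.train.betas, study.train.labels, study.train.manifest
        n5 = len(build_dmr_signature(betas, labels, man, DMRParams(n_permutations=30, min_probes=5, seed=1))[0])
        n10 = len(build_dmr_signature(betas, labels, man, DMRParams(n_permutations=30, min_probes=10, seed=1))[0])
        n13 = len(build_dmr_signature(betas, labels, man, DMRParams(n_permutations=30, min_probes=13, seed=1))[0])
        assert n5 >= n10 >= n13

    def test_retained_regions_satisfy_filters_and_do_not_overlap(self, study):
        params = study.dmr_sig.params
        regions = study.dmr_sig.regions
        assert (regions["adj_p"] < params["adj_p_threshold"]).all()
        assert (regions["L"] >= params["min_probes"]).all()
        assert ((regions["p"] > 0) & (regions["p"] <= 1)).all()
        for chrom, grp in regions.groupby("chrom"):
            grp = grp.sort_values("start")
            assert (grp["start"].to_numpy()[1:] > grp["end"].to_numpy()[:-1]).all()

    def test_permuted_labels_rarely_yield_regions(self):
        zero = 0
        for s in range(10):
            c = simulate_cohort(SimConfig(n_probes=2000, n_case=10, n_control=10, seed=60 + s))
            sig, _ = build_dmr_signature(
                c.betas, c.labels, c.manifest, DMRParams(n_permutations=50, seed=60 + s)
            )
            zero += len(sig) == 0
        assert zero >= 9

    def test_signature_json_round_trip_and_bed(self, study):
        from episig import DMREpisignature

        text = study.dmr_sig.to_json()
        back = DMREpisignature.from_json(text)
        assert back.region_ids == study.dmr_sig.region_ids
        assert back.to_json() == text
        bed = study.dmr_sig.to_bed()
        first = bed.splitlines()[0].split("\t")
        assert int(first[1]) == study.dmr_sig.regions["start"].iloc[0] - 1  # 0-based
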