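"""Aberrant-methylation calls, variable-block selection, clustering,
and methylated-CGI fractions, validated against planted truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import euclidean
from sklearn.metrics import adjusted_rand_score

import methylscreen as ms
from methylscreen.aberrant import AberrantCallConfig
from tests.conftest import tumors_normals


class TestNormallyUnmethylatedCgiBlocks:
    def test_threshold_filter(self, default_cohort):
        blocks = default_cohort["blocks"]
        bb = pd.DataFrame(
            {
                "N1": [0.05, 0.05, 0.5],
                "N2": [0.10, 0.35, 0.6],
            },
            index=[b.block_id for b in blocks[:3]],
        )
        island_blocks = [b for b in blocks[:3]]
        # force all three to be islands by picking island blocks from the cohort
        island = [b for b in blocks if b.cgi_relation == "Island"][:3]
        bb.index = [b.block_id for b in island]
        out = ms.normally_unmethylated_cgi_blocks(bb, island, ["N1", "N2"])
        assert out == [island[0].block_id]

    def test_non_cgi_block_excluded(self, tiny_block_beta):
        bb, normals, _ = tiny_block_beta
        blocks = [
            ms.GenomicBlock(bid, bid.split("|")[0], *bid.split("|")[1:3], None)
            for bid in bb.index
        ]
        out = ms.normally_unmethylated_cgi_blocks(bb, blocks, normals)
        # block D is open sea: excluded despite beta 0.01 in all normals
        assert "D|Body|OpenSea|NA" not in out
        assert set(out) == {"A|TSS200|Island|CGI_A", "B|TSS200|Island|CGI_B"}

    def test_no_normals_is_config_error(self, tiny_block_beta):
        bb, _, _ = tiny_block_beta
        with pytest.raises(ValueError, match="normal"):
            ms.normally_unmethylated_cgi_blocks(bb, [], [])

    def test_recovers_planted_set_noise_free(self):
        cfg = ms.SimulationConfig(seed=2, noise_free=True)
        probes = ms.simulate_manifest(cfg)
        blocks = ms.assemble_blocks(probes)
        beta, samples, truth = ms.simulate_beta_cohort(cfg, probes)
        bb = ms.block_beta(beta, blocks)
        _, normals = tumors_normals(samples)
        out = ms.normally_unmethylated_cgi_blocks(bb, blocks, normals)
        assert out == truth.normally_unmethylated_cgi_blocks


class TestCallAberrantBlocks:
    def test_more_than_five_of_28_rule(self, tiny_block_beta):
        bb, normals, tumors = tiny_block_beta
        out = ms.call_aberrant_blocks(bb, tumors, normals, AberrantCallConfig(min_tumor_count=6))
        assert set(out.index) == {"A|TSS200|Island|CGI_A", "D|Body|OpenSea|NA"}
        assert out.loc["A|TSS200|Island|CGI_A", "n_methylated_tumors"] == 7
        # sorted by descending tumor count
        assert out["n_methylated_tumors"].is_monotonic_decreasing

    def test_raising_min_count_excludes(self, tiny_block_beta):
        bb, normals, tumors = tiny_block_beta
        out = ms.call_aberrant_blocks(bb, tumors, normals, AberrantCallConfig(min_tumor_count=8))
        assert "A|TSS200|Island|CGI_A" not in out.index

    def test_methylated_normal_disqualifies(self, tiny_block_beta):
        bb, normals, tumors = tiny_block_beta
        out = ms.call_aberrant_blocks(bb, tumors, normals)
        assert "C|TSS200|Island|CGI_C" not in out.index

    def test_empty_or_overlapping_sample_sets_rejected(self, tiny_block_beta):
        bb, normals, tumors = tiny_block_beta
        with pytest.raises(ValueError):
            ms.call_aberrant_blocks(bb, [], normals)
        with pytest.raises(ValueError):
            ms.call_aberrant_blocks(bb, tumors, tumors[:1])

    def test_recovers_planted_blocks_noise_free(self):
        cfg = ms.SimulationConfig(
            seed=3, noise_free=True, n_silenced_genes=0, high_methylator_extra_fraction=0.0
        )
        probes = ms.simulate_manifest(cfg)
        beta, samples, truth = ms.simulate_beta_cohort(cfg, probes)
        bb = ms.block_beta(beta, ms.assemble_blocks(probes))
        tumors, normals = tumors_normals(samples)
        out = ms.call_aberrant_blocks(bb, tumors, normals)
        assert set(out.index) == set(truth.aberrant_blocks)
        assert len(truth.aberrant_blocks) == 40
        for bid, planted_tumors in truth.aberrant_blocks.items():
            assert out.loc[bid, "n_methylated_tumors"] == len(planted_tumors)

    def test_monotone_in_thresholds(self, default_cohort):
        bb = default_cohort["block_beta"]
        tumors, normals = tumors_normals(default_cohort["samples"])
        base = set(ms.call_aberrant_blocks(bb, tumors, normals).index)
        stricter = set(
            ms.call_aberrant_blocks(bb, tumors, normals, AberrantCallConfig(min_tumor_count=12)).index
        )
        looser = set(
            ms.call_aberrant_blocks(
                bb, tumors, normals, AberrantCallConfig(meth_threshold=0.3)
            ).index
        )
        assert stricter <= base <= looser


class TestSelectVariableBlocks:
    def test_ranking(self):
        bb = pd.DataFrame(
            {
                "S1": [0.5, 0.5, 0.1, 0.3],
                "S2": [0.5, 0.6, 0.5, 0.1],
                "S3": [0.5, 0.7, 0.3, 0.5],
            },
            index=["b0", "b1", "b2", "b3"],
        )
        var = bb.var(axis=1, ddof=1)
        expected = sorted(bb.index, key=lambda b: (-var[b], b))[:2]
        out = ms.select_variable_blocks(bb, list(bb.columns), n=2)
        assert out == expected

    def test_identity_case_returns_all(self):
        bb = pd.DataFrame(np.random.default_rng(0).random((5, 4)))
        bb.index = [f"b{i}" for i in range(5)]
        assert len(ms.select_variable_blocks(bb, list(bb.columns), n=5)) == 5

    def test_n_too_large_is_error(self):
        bb = pd.DataFrame(np.random.default_rng(0).random((5, 4)))
        with pytest.raises(ValueError, match="complete data"):
            ms.select_variable_blocks(bb, list(bb.columns), n=6)

    def test_matches_exhaustive_variance_sort(self):
        rng = np.random.default_rng(5)
        bb = pd.DataFrame(
            rng.random((5000, 30)),
            index=[f"b{i:05d}" for i in range(5000)],
            columns=[f"S{j}" for j in range(30)],
        )
        out = ms.select_variable_blocks(bb, list(bb.columns), n=500)
        var = bb.var(axis=1, ddof=1)
        expected = sorted(bb.index, key=lambda b: (-var[b], b))[:500]
        assert out == expected

    def test_invariant_to_sample_column_order(self, default_cohort):
        bb = default_cohort["block_beta"]
        tumors, _ = tumors_normals(default_cohort["samples"])
        assert ms.select_variable_blocks(bb, tumors, 100) == ms.select_variable_blocks(
            bb, tumors[::-1], 100
        )


class TestClusterSamples:
    def test_two_samples_merge_at_euclidean_distance(self):
        bb = pd.DataFrame({"S1": [0.1, 0.2, 0.9], "S2": [0.8, 0.2, 0.1]}, index=["a", "b", "c"])
        result = ms.cluster_samples(bb, ["a", "b", "c"], seed=0)
        assert len(result.linkage) == 1
        expected = euclidean(bb["S1"], bb["S2"])
        assert result.linkage[0, 2] == pytest.approx(expected)

    def test_fewer_than_two_samples_rejected(self):
        bb = pd.DataFrame({"S1": [0.1]}, index=["a"])
        with pytest.raises(ValueError, match="2 samples"):
            ms.cluster_samples(bb, ["a"], samples=["S1"], seed=0)

    def test_recovers_planted_high_methylator_subgroup(self, default_cohort):
        bb = default_cohort["block_beta"]
        truth = default_cohort["truth"]
        tumors, normals = tumors_normals(default_cohort["samples"])
        reference = ms.normally_unmethylated_cgi_blocks(bb, default_cohort["blocks"], normals)
        result = ms.cluster_samples(bb, reference, samples=tumors, seed=4)
        labels = result.labels(2)
        true_labels = [truth.cluster_labels[t] for t in labels.index]
        assert adjusted_rand_score(true_labels, labels.to_numpy()) == 1.0

    def test_tree_invariant_to_sample_order(self, default_cohort):
        bb = default_cohort["block_beta"]
        tumors, normals = tumors_normals(default_cohort["samples"])
        reference = ms.normally_unmethylated_cgi_blocks(bb, default_cohort["blocks"], normals)
        a = ms.cluster_samples(bb, reference, samples=tumors, seed=0)
        b = ms.cluster_samples(bb, reference, samples=tumors[::-1], seed=0)
        assert np.array_equal(a.linkage, b.linkage)
        assert a.sample_ids == b.sample_ids

    def test_element_cap_subsamples_deterministically(self, default_cohort):
        bb = default_cohort["block_beta"]
        tumors, _ = tumors_normals(default_cohort["samples"])
        blocks = list(bb.index)
        a = ms.cluster_samples(bb, blocks, samples=tumors, element_cap=500, seed=11)
        b = ms.cluster_samples(bb, blocks, samples=tumors, element_cap=500, seed=11)
        assert a.blocks_used == b.blocks_used
        assert len(a.blocks_used) <= 500
        assert a.subsample_seed == 11

    def test_merge_heights_non_decreasing(self, default_cohort):
        bb = default_cohort["block_beta"]
        tumors, _ = tumors_normals(default_cohort["samples"])
        result = ms.cluster_samples(bb, list(bb.index)[:300], samples=tumors, seed=0)
        heights = result.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()


class TestMethylatedFraction:
    def test_counting(self):
        bb = pd.DataFrame({"S": [0.5, 0.6, 0.7, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]})
        bb.index = [f"b{i}" for i in range(10)]
        assert ms.methylated_fraction(bb, "S", list(bb.index), "tissue") == pytest.approx(0.3)

    def test_zero_case(self):
        bb = pd.DataFrame({"S": [0.05] * 4}, index=list("abcd"))
        assert ms.methylated_fraction(bb, "S", list("abcd"), "tissue") == 0.0

    def test_all_missing_is_error(self):
        bb = pd.DataFrame({"S": [np.nan, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            ms.methylated_fraction(bb, "S", ["a", "b"], "tissue")

    def test_permutation_invariant_and_bounded(self, tiny_block_beta):
        bb, _, _ = tiny_block_beta
        ref = list(bb.index)
        f1 = ms.methylated_fraction(bb, "T1", ref, "tissue")
        f2 = ms.methylated_fraction(bb, "T1", ref[::-1], "tissue")
        assert f1 == f2
        assert 0.0 <= f1 <= 1.0

    def test_planted_rate_within_binomial_interval(self):
        # high-methylator with only the 20% planted extra blocks methylated
        cfg = ms.SimulationConfig(
            seed=5, aberrant_block_fraction=0.0, n_silenced_genes=0
        )
        probes = ms.simulate_manifest(cfg)
        blocks = ms.assemble_blocks(probes)
        beta, samples, truth = ms.simulate_beta_cohort(cfg, probes)
        bb = ms.block_beta(beta, blocks)
        _, normals = tumors_normals(samples)
        reference = ms.normally_unmethylated_cgi_blocks(bb, blocks, normals)
        sample = truth.high_methylator_samples[0]
        frac = ms.methylated_fraction(bb, sample, reference, "tissue")
        p, n = 0.20, len(reference)
        half_width = 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= half_width
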