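"""The integrated methylation-silencing screen and demethylation deltas."""

import numpy as np
import pandas as pd
import pytest

import methylscreen as ms
from methylscreen.aberrant import AberrantCallConfig
from methylscreen.core import GenomicBlock
from methylscreen.screen import ScreenCriteria
from tests.conftest import tumors_normals


def _block(gene, tss="TSS200", cgi="Island", cgi_id=None):
    cgi_id = cgi_id or (f"CGI_{gene}" if cgi != "OpenSea" else None)
    bid = f"{gene}|{tss}|{cgi}|{cgi_id or 'NA'}"
    return GenomicBlock(bid, gene, tss, cgi, cgi_id, (f"p_{gene}",))


class TestEligibleGeneUniverse:
    def _toy(self):
        """Five genes; exactly G1 and G2 satisfy all conditions."""
        blocks = [
            _block("G1"),
            _block("G2"),
            _block("G3"),                      # not expressed in baseline
            _block("G4", tss="Body", cgi="OpenSea"),  # only a gene-body block
            _block("G5"),                      # not on the expression platform
        ]
        normals = ["N1", "N2"]
        tumors = [f"T{i}" for i in range(1, 11)]
        rows = {}
        for b in blocks:
            rows[b.block_id] = [0.05, 0.05] + [0.6] * 7 + [0.1] * 3
        bb = pd.DataFrame(rows, index=normals + tumors).T
        expressed = {"G1", "G2", "G4", "G5"}
        platform = {"G1", "G2", "G3", "G4"}
        return blocks, bb, tumors, normals, expressed, platform

    def test_brute_force_conditions(self):
        blocks, bb, tumors, normals, expressed, platform = self._toy()
        universe = ms.eligible_gene_universe(blocks, bb, tumors, normals, expressed, platform)
        assert set(universe.index) == {"G1", "G2"}
        assert (universe["n_methylated_tumors"] == 7).all()

    def test_gene_body_block_does_not_qualify(self):
        blocks, bb, tumors, normals, expressed, platform = self._toy()
        universe = ms.eligible_gene_universe(blocks, bb, tumors, normals, expressed, platform)
        assert "G4" not in universe.index

    def test_gene_off_platform_excluded(self):
        blocks, bb, tumors, normals, expressed, platform = self._toy()
        universe = ms.eligible_gene_universe(blocks, bb, tumors, normals, expressed, platform)
        assert "G5" not in universe.index

    def test_empty_baseline_is_error(self):
        blocks, bb, tumors, normals, _, platform = self._toy()
        with pytest.raises(ValueError, match="baseline"):
            ms.eligible_gene_universe(blocks, bb, tumors, normals, set(), platform)

    def test_most_methylated_block_represents_gene(self):
        b1 = _block("G1", cgi_id="CGI_a")
        b2 = GenomicBlock("G1|TSS200|Island|CGI_b", "G1", "TSS200", "Island", "CGI_b", ("p2",))
        normals, tumors = ["N1"], [f"T{i}" for i in range(1, 11)]
        bb = pd.DataFrame(
            {
                b1.block_id: [0.05] + [0.6] * 7 + [0.1] * 3,
                b2.block_id: [0.05] + [0.6] * 9 + [0.1],
            },
            index=normals + tumors,
        ).T
        universe = ms.eligible_gene_universe([b1, b2], bb, tumors, normals, {"G1"}, {"G1"})
        assert universe.loc["G1", "block_id"] == b2.block_id
        assert universe.loc["G1", "n_methylated_tumors"] == 9


class TestRunScreen:
    def _universe(self):
        return pd.DataFrame(
            {"block_id": ["G1|TSS200|Island|CGI_G1", "G2|TSS200|Island|CGI_G2"],
             "n_methylated_tumors": [7, 8]},
            index=pd.Index(["G1", "G2"], name="gene"),
        )

    def _induction(self, g1=1.5, g2=1.5):
        return pd.DataFrame(
            {"mock": [0.1, 0.1], "treated": [0.3, 0.3], "log2_ratio": [g1, g2],
             "induced": [g1 >= 1, g2 >= 1]},
            index=pd.Index(["G1", "G2"], name="gene"),
        )

    def test_methylated_and_induced_is_candidate(self):
        clb = pd.Series({"G1|TSS200|Island|CGI_G1": 0.9, "G2|TSS200|Island|CGI_G2": 0.9})
        out = ms.run_screen(self._universe(), clb, self._induction())
        assert out["passes"].all()

    def test_partially_methylated_cell_line_not_candidate(self):
        # beta 0.5 is 'partial' under the cell-line scheme, not methylated
        clb = pd.Series({"G1|TSS200|Island|CGI_G1": 0.5, "G2|TSS200|Island|CGI_G2": 0.9})
        out = ms.run_screen(self._universe(), clb, self._induction())
        assert not out.loc["G1", "passes"]
        assert out.loc["G2", "passes"]

    def test_cell_line_requirement_can_be_dropped(self):
        clb = pd.Series({"G1|TSS200|Island|CGI_G1": 0.5, "G2|TSS200|Island|CGI_G2": 0.9})
        crit = ScreenCriteria(require_cell_line_methylated=False)
        out = ms.run_screen(self._universe(), clb, self._induction(), crit)
        assert out["passes"].all()

    def test_infinite_threshold_empties_candidates(self):
        clb = pd.Series({"G1|TSS200|Island|CGI_G1": 0.9, "G2|TSS200|Island|CGI_G2": 0.9})
        crit = ScreenCriteria(induction_log2_threshold=np.inf)
        out = ms.run_screen(self._universe(), clb, self._induction(), crit)
        assert not out["passes"].any()

    def test_missing_cell_line_beta_is_error(self):
        clb = pd.Series({"G1|TSS200|Island|CGI_G1": 0.9})
        with pytest.raises(KeyError):
            ms.run_screen(self._universe(), clb, self._induction())

    def test_end_to_end_planted_recovery(self, screen_cohort):
        """50 silenced-and-reactivated genes planted among 2,000."""
        c = screen_cohort
        tumors, normals = tumors_normals(c["samples"])
        es = c["expr_samples"]
        msc = sorted(es.index[es["group"] == "msc"])
        ob = sorted(es.index[es["group"] == "osteoblast"])
        expressed = ms.expressed_in_baseline(c["gene_expr"], msc, ob)
        universe = ms.eligible_gene_universe(
            c["blocks"], c["block_beta"], tumors, normals, expressed, set(c["gene_expr"].index)
        )
        induction = ms.induction_screen(c["gene_expr"], "CL1_mock", "CL1_aza")
        out = ms.run_screen(universe, c["block_beta"]["CL1_mock"], induction)
        candidates = set(out.index[out["passes"]])
        planted = set(c["truth"].silenced_genes)
        recall = len(candidates & planted) / len(planted)
        fdp = len(candidates - planted) / max(len(candidates), 1)
        assert recall >= 0.95
        assert fdp <= 0.02
        # candidates are always a subset of the eligible universe
        assert candidates <= set(universe.index)

    def test_tightening_a_criterion_never_enlarges_candidates(self, screen_cohort):
        c = screen_cohort
        tumors, normals = tumors_normals(c["samples"])
        es = c["expr_samples"]
        expressed = ms.expressed_in_baseline(
            c["gene_expr"],
            sorted(es.index[es["group"] == "msc"]),
            sorted(es.index[es["group"] == "osteoblast"]),
        )
        universe = ms.eligible_gene_universe(
            c["blocks"], c["block_beta"], tumors, normals, expressed, set(c["gene_expr"].index)
        )
        induction = ms.induction_screen(c["gene_expr"], "CL1_mock", "CL1_aza")
        base = ms.run_screen(universe, c["block_beta"]["CL1_mock"], induction)
        tight = ms.run_screen(
            universe,
            c["block_beta"]["CL1_mock"],
            induction,
            ScreenCriteria(induction_log2_threshold=1.8),
        )
        strict_universe = ms.eligible_gene_universe(
            c["blocks"], c["block_beta"], tumors, normals, expressed,
            set(c["gene_expr"].index),
            ScreenCriteria(aberrant_config=AberrantCallConfig(min_tumor_count=12)),
        )
        assert set(tight.index[tight["passes"]]) <= set(base.index[base["passes"]])
        assert set(strict_universe.index) <= set(universe.index)


class TestDemethylationDelta:
    def test_subtraction_in_percentage_points(self):
        before = pd.Series({"b1": 0.80})
        after = pd.Series({"b1": 0.35})
        out = ms.demethylation_delta(before, after, {"G1": "b1"})
        assert out["G1"] == pytest.approx(45.0)

    def test_no_change_gives_zero(self):
        s = pd.Series({"b1": 0.7})
        assert ms.demethylation_delta(s, s, {"G1": "b1"})["G1"] == 0.0

    def test_unmatched_blocks_rejected(self):
        with pytest.raises(KeyError, match="unmatched"):
            ms.demethylation_delta(pd.Series({"b1": 0.8}), pd.Series({"b2": 0.3}), {"G1": "b1"})

    def test_planted_deltas_fall_in_generated_interval(self, screen_cohort):
        c = screen_cohort
        truth = c["truth"]
        gene_blocks = {g: truth.gene_tss200_block[g] for g in truth.silenced_genes}
        out = ms.demethylation_delta(
            c["block_beta"]["CL1_mock"], c["block_beta"]["CL1_aza"], gene_blocks
        )
        lo, hi = c["config"].demethylation_range
        assert (out >= lo * 100 - 1e-6).all()
        assert (out <= hi * 100 + 1e-6).all()
        for g in list(truth.silenced_genes)[:10]:
            assert out[g] == pytest.approx(truth.demethylation_delta[g] * 100, abs=1e-6)
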