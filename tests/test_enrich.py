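"""Gene scores, probability weighting function, odds, and the three tests."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from methenrich import (
    GeneSetCollection,
    GenesetTester,
    SignificantSet,
    adjust_pvalues,
    build_gene_index,
    compute_gene_scores,
    compute_odds,
    enrichment_statistic,
    estimate_pwf,
)
from methenrich.enrich import _tricube_smooth
from methenrich.enrich import test_gene_sets as run_gene_set_test

from conftest import make_annotation


def no_bias_annotation(n_genes=40):
    """Every gene has exactly one exclusive CpG: no probe-number or
    multi-gene bias exists."""
    return make_annotation(
        [(f"cg{i:03d}", "chr1", 100 * (i + 1), [(f"G{i:03d}", "Body")])
         for i in range(n_genes)]
    )


class TestGeneScores:
    def test_single_exclusive_significant_cpg_scores_one(self):
        annot = make_annotation([("cg1", "chr1", 10, [("A", "")]),
                                 ("cg2", "chr1", 20, [("A", "")])])
        scores = compute_gene_scores(SignificantSet({"cg1"}), build_gene_index(annot))
        assert scores["A"] == 1.0

    def test_shared_significant_cpg_scores_half(self, fig2_annot):
        scores = compute_gene_scores({"cg03"}, build_gene_index(fig2_annot))
        assert scores["GENE1"] == 0.5 and scores["GENE2"] == 0.5

    def test_score_capped_at_one(self):
        # weights 1, 0.5, 0.5 on three significant CpGs -> S = min(2, 1) = 1
        annot = make_annotation([
            ("cg1", "chr1", 10, [("A", "")]),
            ("cg2", "chr1", 20, [("A", ""), ("B", "")]),
            ("cg3", "chr1", 30, [("A", ""), ("C", "")]),
        ])
        scores = compute_gene_scores({"cg1", "cg2", "cg3"}, build_gene_index(annot))
        assert scores["A"] == 1.0

    def test_unscored_genes_retained_at_zero(self, fig2_annot):
        scores = compute_gene_scores({"cg01"}, build_gene_index(fig2_annot))
        assert scores["GENE2"] == 0.0 and set(scores.index) == {"GENE1", "GENE2"}

    def test_empty_set_warns_and_zeroes(self, fig2_annot):
        with pytest.warns(UserWarning, match="empty"):
            scores = compute_gene_scores(SignificantSet([]), build_gene_index(fig2_annot))
        assert (scores == 0).all()

    def test_scores_bounded(self, small_synth):
        annot, _ = small_synth
        index = build_gene_index(annot)
        rng = np.random.default_rng(0)
        sig = rng.choice(annot.cpg_ids.to_numpy(), 200, replace=False)
        scores = compute_gene_scores(set(sig), index)
        assert ((scores >= 0) & (scores <= 1)).all()


class TestPWF:
    def test_all_zero_indicator_gives_zero_pwf(self, small_synth):
        annot, _ = small_synth
        index = build_gene_index(annot)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = compute_gene_scores(set(), index)
        pwf = estimate_pwf(scores, index)
        assert (pwf["pwf"] == 0).all()

    def test_all_one_indicator_gives_unit_pwf(self, small_synth):
        annot, _ = small_synth
        index = build_gene_index(annot)
        scores = pd.Series(1.0, index=index.genes)
        pwf = estimate_pwf(scores, index)
        np.testing.assert_allclose(pwf["pwf"], 1.0, atol=1e-12)

    def test_smoother_against_direct_kernel_arithmetic(self):
        # L=5, span=1 -> window 5, half=2, kernel on u = offset/3
        dm = np.array([0.0, 0, 1, 0, 0])
        k = (1 - (np.abs(np.arange(-2, 3)) / 3) ** 3) ** 3
        expected = []
        for i in range(5):
            num = den = 0.0
            for j in range(5):
                if abs(j - i) <= 2:
                    num += k[j - i + 2] * dm[j]
                    den += k[j - i + 2]
            expected.append(num / den)
        np.testing.assert_allclose(_tricube_smooth(dm, 1.0), expected, atol=1e-12)

    def test_pwf_ordering_and_bounds(self, small_synth):
        annot, _ = small_synth
        index = build_gene_index(annot)
        rng = np.random.default_rng(1)
        sig = set(rng.choice(annot.cpg_ids.to_numpy(), 300, replace=False))
        pwf = estimate_pwf(compute_gene_scores(sig, index), index)
        assert (np.diff(pwf["N"].to_numpy()) >= 0).all()
        assert pwf["pwf"].between(0, 1).all()
        assert len(pwf) == len(index)

    def test_invalid_span_rejected(self, small_synth):
        annot, _ = small_synth
        index = build_gene_index(annot)
        scores = pd.Series(0.0, index=index.genes)
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                estimate_pwf(scores, index, span=bad)


class TestOdds:
    def test_constant_pwf_gives_unit_odds(self):
        table = pd.DataFrame({"gene_id": list("ABCD"), "N": [1, 2, 3, 4],
                              "dm": [0, 1, 0, 1], "pwf": [0.3] * 4})
        assert compute_odds(table, ["A", "B"]) == pytest.approx(1.0)

    def test_top_pwf_set_has_odds_above_one(self):
        table = pd.DataFrame({"gene_id": list("ABCD"), "N": [1, 2, 3, 4],
                              "dm": [0, 0, 1, 1], "pwf": [0.1, 0.2, 0.6, 0.8]})
        assert compute_odds(table, ["C", "D"]) > 1.0

    def test_direct_arithmetic(self):
        table = pd.DataFrame({"gene_id": list("ABCD"), "N": [1, 2, 3, 4],
                              "dm": [0, 0, 0, 1], "pwf": [0.1, 0.2, 0.3, 0.4]})
        assert compute_odds(table, ["A", "B"]) == pytest.approx((0.15) / (0.35))

    def test_degenerate_sets_rejected(self):
        table = pd.DataFrame({"gene_id": list("AB"), "N": [1, 2],
                              "dm": [0, 1], "pwf": [0.1, 0.2]})
        with pytest.raises(ValueError):
            compute_odds(table, ["X"])
        with pytest.raises(ValueError):
            compute_odds(table, ["A", "B"])


class TestEnrichmentStatistic:
    def test_sum_of_scores(self):
        scores = pd.Series({"A": 1.0, "B": 1.0, "C": 0.0})
        assert enrichment_statistic(scores, ["A", "B", "C"]) == 2.0

    def test_22_gene_cluster_contributes_one(self, shared22_annot):
        scores = compute_gene_scores({"cgSHARED"}, build_gene_index(shared22_annot))
        es = enrichment_statistic(scores, [f"PC{k:02d}" for k in range(22)])
        assert es == pytest.approx(1.0)

    def test_empty_set_is_zero(self):
        assert enrichment_statistic(pd.Series({"A": 1.0}), []) == 0.0


class TestAdjustPvalues:
    def test_bh_textbook_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "BH"), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.2], "Holm")[0] == pytest.approx(0.2)

    def test_holm_capped_at_one(self):
        np.testing.assert_allclose(adjust_pvalues([1.0, 1.0], "Holm"), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "BH")


class TestTestGeneSets:
    def test_hgt_matches_textbook_hypergeometric_without_bias(self):
        annot = no_bias_annotation(40)
        sets = GeneSetCollection.from_dict({
            "S1": [f"G{i:03d}" for i in range(10)],
            "S2": [f"G{i:03d}" for i in range(10, 30)],
        })
        sig = {f"cg{i:03d}" for i in range(8)}  # genes 0-7 significant
        res = run_gene_set_test(sig, annot, sets, method="HGT").set_index("set_id")
        for sid, J, x in [("S1", 10, 8), ("S2", 20, 0)]:
            expected = hypergeom.sf(x - 1, 40, J, 8)
            assert res.loc[sid, "p"] == pytest.approx(expected, abs=1e-12)

    def test_zero_statistic_gives_p_one(self, shared22_annot, shared22_sets):
        sig = {"cgBG00_0"}  # one background gene significant
        res = run_gene_set_test(sig, shared22_annot, shared22_sets, method="GOmeth")
        cluster = res.set_index("set_id").loc["CLUSTER"]
        assert cluster["ES"] == 0.0 and cluster["p"] == 1.0

    def test_multi_gene_bias_correction(self, shared22_annot, shared22_sets):
        """One shared significant CpG: HGT sees overlap 22, the corrected
        statistic collapses to 1, so HGT grossly overstates significance."""
        sig = SignificantSet({"cgSHARED"})
        hgt = run_gene_set_test(sig, shared22_annot, shared22_sets, method="HGT")
        gometh = run_gene_set_test(sig, shared22_annot, shared22_sets, method="GOmeth")
        hgt_c = hgt.set_index("set_id").loc["CLUSTER"]
        go_c = gometh.set_index("set_id").loc["CLUSTER"]
        assert hgt_c["ES"] == 22
        assert np.floor(go_c["ES"] + 1e-9) == 1
        assert hgt_c["p"] < go_c["p"] / 1e6

    def test_es_bounded_by_set_size(self, small_synth):
        annot, sets = small_synth
        rng = np.random.default_rng(5)
        sig = set(rng.choice(annot.cpg_ids.to_numpy(), 500, replace=False))
        res = run_gene_set_test(sig, annot, sets, method="GOmeth")
        assert (res["ES"] <= res["J"] + 1e-9).all()
        assert (res["ES"] >= 0).all()

    def test_no_multi_gene_makes_gometh_equal_hgtmod_counts(self):
        annot = no_bias_annotation(30)
        sets = GeneSetCollection.from_dict({"S1": [f"G{i:03d}" for i in range(12)]})
        sig = {f"cg{i:03d}" for i in range(0, 30, 3)}
        a = run_gene_set_test(sig, annot, sets, method="GOmeth")
        b = run_gene_set_test(sig, annot, sets, method="HGT-mod")
        np.testing.assert_allclose(a["ES"], b["ES"])

    def test_all_methods_coincide_when_pwf_constant(self):
        # every gene significant -> dm constant -> PWF identically 1, odds 1
        annot = no_bias_annotation(20)
        sets = GeneSetCollection.from_dict({"S1": [f"G{i:03d}" for i in range(7)]})
        sig = {f"cg{i:03d}" for i in range(20)}
        ps = [
            run_gene_set_test(sig, annot, sets, method=m)["p"].iloc[0]
            for m in ("HGT", "HGT-mod", "GOmeth")
        ]
        assert max(ps) - min(ps) < 1e-10

    def test_irrelevant_cpg_changes_no_es(self, shared22_annot, shared22_sets):
        sig = {"cgSHARED", "cgPC00_0"}
        before = run_gene_set_test(sig, shared22_annot, shared22_sets, method="GOmeth")
        extra = shared22_annot.sites.iloc[:1].copy()
        extra["cpg_id"] = ["cgNEW"]
        extra["pos"] = [999_999]
        sites = pd.concat([shared22_annot.sites, extra])
        links = pd.concat([
            shared22_annot.links,
            pd.DataFrame({"cpg_id": ["cgNEW"], "gene": ["LONEGENE"],
                          "features": [frozenset({"Body"})]}),
        ])
        from methenrich import AnnotationTable
        grown = AnnotationTable(sites, links)
        after = run_gene_set_test(sig, grown, shared22_sets, method="GOmeth")
        pd.testing.assert_series_equal(
            before.set_index("set_id")["ES"], after.set_index("set_id")["ES"]
        )

    def test_results_sorted_by_p_with_stable_ties(self, small_synth):
        annot, sets = small_synth
        rng = np.random.default_rng(9)
        sig = set(rng.choice(annot.cpg_ids.to_numpy(), 400, replace=False))
        res = run_gene_set_test(sig, annot, sets, method="GOmeth")
        p = res["p"].to_numpy()
        assert (np.diff(p) >= 0).all()
        ties = res[res["p"].duplicated(keep=False)]
        for _, grp in ties.groupby("p"):
            assert list(grp["set_id"]) == sorted(grp["set_id"])

    def test_empty_collection_rejected(self, fig2_annot):
        with pytest.raises(ValueError):
            GenesetTester(fig2_annot, GeneSetCollection([]))

    def test_significant_set_io(self, tmp_path):
        path = tmp_path / "sig.txt"
        path.write_text("cg1\ncg2\n\ncg3\n")
        assert SignificantSet.from_file(path).cpg_ids == {"cg1", "cg2", "cg3"}
        ranked = pd.DataFrame({"cpg": ["a", "b", "c", "d"], "p": [0.2, 0.01, 0.9, 0.05]})
        top = SignificantSet.from_ranked(ranked, top=2)
        assert top.cpg_ids == {"b", "d"}
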