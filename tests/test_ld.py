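"""LD operators against exhaustive brute-force oracles on toy panels."""

import numpy as np
import pandas as pd
import pytest

from cm3.ld import (
    LdPanel,
    annotation_scores,
    clump_loci,
    exclude_xmhc,
    heterozygosity,
    random_prune,
    selective_prune,
    total_ld,
)
from conftest import brute_force_prune_check, brute_force_r2


class TestHeterozygosity:
    @pytest.mark.parametrize("maf,expected", [(0.5, 0.5), (0.0, 0.0), (0.1, 0.18)])
    def test_values(self, maf, expected):
        assert heterozygosity(maf) == pytest.approx(expected)

    def test_domain(self):
        with pytest.raises(ValueError):
            heterozygosity(0.6)


class TestXmhcExclusion:
    def test_boundaries(self):
        snps = pd.DataFrame(
            {
                "snp_id": ["a", "b", "c", "d", "e"],
                "chrom": ["6", "6", "6", "7", "6"],
                "pos": [30_000_000, 25_652_428, 25_652_429, 30_000_000, 33_368_334],
            }
        )
        kept = exclude_xmhc(snps)
        assert set(kept["snp_id"]) == {"b", "d", "e"}


class TestR2:
    def test_self_and_symmetry(self, toy_ld_panel):
        for i in range(toy_ld_panel.m):
            assert toy_ld_panel.r2(i, i) == 1.0
        for i, j in [(0, 1), (3, 5), (2, 9)]:
            assert toy_ld_panel.r2(i, j) == pytest.approx(toy_ld_panel.r2(j, i))
            assert 0.0 <= toy_ld_panel.r2(i, j) <= 1.0

    def test_matches_brute_force(self, toy_ld_panel):
        for i in range(toy_ld_panel.m):
            for j in range(toy_ld_panel.m):
                assert toy_ld_panel.r2(i, j) == pytest.approx(
                    brute_force_r2(toy_ld_panel, i, j) if i != j else 1.0
                )

    def test_out_of_window_zero(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(100, 2)).astype(float)
        snps = pd.DataFrame(
            {"snp_id": ["a", "b"], "chrom": "1", "pos": [1, 3_000_000]}
        )
        panel = LdPanel(g, snps, window_bp=1_000_000)
        assert panel.r2(0, 1) == 0.0

    def test_monomorphic_zero(self):
        g = np.column_stack([np.ones(50), np.random.default_rng(1).integers(0, 3, 50)])
        snps = pd.DataFrame({"snp_id": ["a", "b"], "chrom": "1", "pos": [1, 2]})
        panel = LdPanel(g.astype(float), snps)
        assert panel.r2(0, 1) == 0.0


def _perfect_pair_panel():
    """3-SNP panel: s0 and s1 identical columns, s2 independent."""
    rng = np.random.default_rng(7)
    a = rng.integers(0, 3, 300).astype(float)
    b = rng.integers(0, 3, 300).astype(float)
    snps = pd.DataFrame(
        {"snp_id": ["s0", "s1", "s2"], "chrom": "1", "pos": [100, 200, 300]}
    )
    return LdPanel(np.column_stack([a, a.copy(), b]), snps)


class TestAnnotationScores:
    def test_single_perfect_pair_inclusive_bound(self):
        panel = _perfect_pair_panel()
        cats = {"exon": {("1", 200)}}  # s1 is exonic
        tags = pd.DataFrame({"snp_id": ["s0"]})
        res = annotation_scores(panel, cats, tags)
        assert res["exon"].iloc[0] == pytest.approx(1.0)
        assert res["category"].iloc[0] == "exon"  # inclusive lower bound

    def test_sub_threshold_is_intergenic(self, toy_ld_panel):
        # s6..s8 form the weak block (r2 well below 1)
        cats = {"exon": {("1", int(toy_ld_panel.snps["pos"].iat[7]))}}
        tags = pd.DataFrame({"snp_id": ["s6"]})
        res = annotation_scores(toy_ld_panel, cats, tags)
        assert res["exon"].iloc[0] < 1.0
        assert res["category"].iloc[0] == "intergenic"

    def test_matches_brute_force_sum(self, toy_ld_panel):
        positions = set(
            zip(toy_ld_panel.snps["chrom"], toy_ld_panel.snps["pos"].astype(int))
        )
        exonic = {p for i, p in enumerate(sorted(positions)) if i % 3 == 0}
        cats = {"exon": exonic}
        tags = pd.DataFrame({"snp_id": list(toy_ld_panel.snps["snp_id"])})
        res = annotation_scores(toy_ld_panel, cats, tags)
        for t, tag in enumerate(tags["snp_id"]):
            i = toy_ld_panel.index_of(tag)
            expected = 0.0
            for j in range(toy_ld_panel.m):
                key = (
                    toy_ld_panel.snps["chrom"].iat[j],
                    int(toy_ld_panel.snps["pos"].iat[j]),
                )
                if key in exonic:
                    expected += brute_force_r2(toy_ld_panel, i, j) if i != j else 1.0
            assert res["exon"].iloc[t] == pytest.approx(expected, abs=1e-10)

    def test_absent_tag_flagged(self, toy_ld_panel):
        res = annotation_scores(
            toy_ld_panel, {"exon": set()}, pd.DataFrame({"snp_id": ["nope"]})
        )
        assert np.isnan(res["exon"].iloc[0])
        assert res["category"].iloc[0] == "missing"


class TestTotalLd:
    def test_isolated_snp_self_term(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(200, 2)).astype(float)
        snps = pd.DataFrame(
            {"snp_id": ["a", "b"], "chrom": ["1", "2"], "pos": [100, 100]}
        )
        panel = LdPanel(g, snps)
        tld = total_ld(panel, pd.DataFrame({"snp_id": ["a"]}))
        assert tld.iloc[0] == pytest.approx(1.0)

    def test_matches_brute_force_and_bounds_category_score(self, toy_ld_panel):
        tags = pd.DataFrame({"snp_id": list(toy_ld_panel.snps["snp_id"])})
        tld = total_ld(toy_ld_panel, tags)
        cats = {
            "exon": set(
                zip(toy_ld_panel.snps["chrom"], toy_ld_panel.snps["pos"].astype(int))
            )
        }
        scores = annotation_scores(toy_ld_panel, cats, tags)
        for t in range(len(tags)):
            i = toy_ld_panel.index_of(tags["snp_id"].iloc[t])
            expected = sum(
                brute_force_r2(toy_ld_panel, i, j) if i != j else 1.0
                for j in range(toy_ld_panel.m)
            )
            assert tld.iloc[t] == pytest.approx(expected, abs=1e-10)
            # TLD sums over a superset of any category's pairs
            assert tld.iloc[t] >= scores["exon"].iloc[t] - 1e-12

    def test_exclude_self_option(self, toy_ld_panel):
        tags = pd.DataFrame({"snp_id": ["s0"]})
        with_self = total_ld(toy_ld_panel, tags, include_self=True)
        without = total_ld(toy_ld_panel, tags, include_self=False)
        assert with_self.iloc[0] - without.iloc[0] == pytest.approx(1.0)


class TestPruning:
    def _snps_with_p(self, panel, ps):
        df = panel.snps.copy()
        df["p"] = ps
        return df

    def test_one_block_keeps_single_best(self):
        panel = _perfect_pair_panel()
        snps = self._snps_with_p(panel, [0.5, 0.01, 0.9])
        kept = selective_prune(snps.iloc[:2], panel, 0.8, "p")
        assert list(kept["snp_id"]) == ["s1"]

    def test_independent_snps_all_survive(self, toy_ld_panel):
        rng = np.random.default_rng(5)
        # take one SNP from each independent block
        sub = self._snps_with_p(toy_ld_panel, rng.uniform(size=12)).iloc[[0, 3, 6, 9]]
        kept = selective_prune(sub, toy_ld_panel, 0.5, "p")
        # blocks are mutually independent, so survivors = any below-threshold set
        assert brute_force_prune_check(kept, toy_ld_panel, 0.5)

    def test_two_block_min_p_oracle(self, toy_ld_panel):
        # blocks 0-2 (r2=1) and 9-11 (r2=0 within): min-p SNP survives per block
        sub = toy_ld_panel.snps.iloc[[0, 1, 2, 9, 10, 11]].copy()
        sub["p"] = [0.3, 0.05, 0.6, 0.2, 0.1, 0.4]
        kept = selective_prune(sub, toy_ld_panel, 0.5, "p")
        assert "s1" in set(kept["snp_id"])  # min p of the perfect block
        assert brute_force_prune_check(kept, toy_ld_panel, 0.5)
        # the independent block members all survive
        assert {"s9", "s10", "s11"} <= set(kept["snp_id"])

    def test_random_prune_invariant_and_determinism(self, toy_ld_panel):
        snps = toy_ld_panel.snps.copy()
        a = random_prune(snps, toy_ld_panel, 0.5, seed=11)
        b = random_prune(snps, toy_ld_panel, 0.5, seed=11)
        pd.testing.assert_frame_equal(a, b)
        assert brute_force_prune_check(a, toy_ld_panel, 0.5)

    def test_random_prune_covers_block_uniformly(self):
        panel = _perfect_pair_panel()
        sub = panel.snps.iloc[:2]
        picks = []
        for seed in range(400):
            kept = random_prune(sub, panel, 0.8, seed=seed)
            assert len(kept) == 1
            picks.append(kept["snp_id"].iloc[0])
        frac = np.mean([p == "s0" for p in picks])
        assert 0.4 < frac < 0.6  # ~uniform over the 2-member block


class TestClumping:
    def _pred(self, panel, vals, idx=None):
        df = panel.snps.copy() if idx is None else panel.snps.iloc[idx].copy()
        df["pred_repl"] = vals
        df["a1"] = "A"
        df["p"] = 1e-8
        return df

    def test_distance_rule(self):
        rng = np.random.default_rng(9)
        g = rng.integers(0, 3, size=(300, 2)).astype(float)
        for gap, n_loci in [(300_000, 2), (200_000, 1)]:
            snps = pd.DataFrame(
                {"snp_id": ["a", "b"], "chrom": "1", "pos": [1_000, 1_000 + gap]}
            )
            panel = LdPanel(g, snps, window_bp=2_000_000)
            df = self._pred(panel, [0.85, 0.95])
            loci = clump_loci(df, panel)
            assert len(loci) == n_loci
            if n_loci == 1:
                assert loci["snp_id"].iloc[0] == "b"  # larger pred_repl leads

    def test_mixed_panel_against_partition_oracle(self, toy_ld_panel):
        rng = np.random.default_rng(13)
        df = self._pred(toy_ld_panel, rng.uniform(0.5, 1.0, size=5), idx=[0, 1, 4, 6, 10])
        loci = clump_loci(df, toy_ld_panel, dist_bp=8_000)
        # oracle: exhaustive pairwise constraints on the returned leads
        leads = [toy_ld_panel.index_of(s) for s in loci["snp_id"]]
        for a in range(len(leads)):
            for b in range(a + 1, len(leads)):
                same_chrom = (
                    toy_ld_panel.snps["chrom"].iat[leads[a]]
                    == toy_ld_panel.snps["chrom"].iat[leads[b]]
                )
                dist = abs(
                    int(toy_ld_panel.snps["pos"].iat[leads[a]])
                    - int(toy_ld_panel.snps["pos"].iat[leads[b]])
                )
                assert brute_force_r2(toy_ld_panel, leads[a], leads[b]) < 0.1
                if same_chrom:
                    assert dist > 8_000
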