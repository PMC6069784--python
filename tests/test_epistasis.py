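"""Di-genic epistasis: prescreen, pairwise scan, selection, grouping, aa."""

import numpy as np
import pandas as pd
import pytest

import magicpop as mp
from magicpop.epistasis import (
    aa_effect,
    aa_from_class_means,
    epistatic_variance,
    group_interactions,
    pairwise_scan,
    prescreen,
    select_interactions,
)


class TestAaFromClassMeans:
    @pytest.mark.parametrize(
        "jj,nn,jn,nj,expected",
        [
            (78.4, 96.2, 81.3, 79.6, 13.7),   # printed 2B x 7B interaction
            (79.8, 77.4, 81.9, 86.7, -11.4),  # printed 3A x 7B interaction
            (80.6, 81.8, 81.8, 72.2, 8.4),    # printed 1B x 2A interaction
            (80.0, 80.0, 80.0, 80.0, 0.0),
        ],
    )
    def test_contrast_of_homozygous_class_means(self, jj, nn, jn, nj, expected):
        assert aa_from_class_means(jj, nn, jn, nj) == pytest.approx(expected)


def _pair_geno(n_per_class, rng=None):
    rows, idx = [], []
    for i, (d1, d2) in enumerate([(2, 2), (2, 0), (0, 2), (0, 0)]):
        for j in range(n_per_class):
            rows.append([d1, d2])
            idx.append(f"c{i}_{j}")
    return pd.DataFrame(rows, columns=["s1", "s2"], index=idx, dtype=float)


class TestAaEffect:
    def test_noiseless_injection_recovered_exactly(self):
        geno = _pair_geno(10)
        model = mp.TraitModel(
            additive_qtl=(("s1", 3.0), ("s2", -2.0)),
            epistatic_pairs=(("s1", "s2", 13.7),),
            year_variance=0, gxy_variance=0, residual_variance=0,
        )
        ph = mp.simulate_phenotype(geno, model, np.random.default_rng(0))
        means = mp.line_means(ph)
        rec = aa_effect(geno, means, "s1", "s2")
        assert rec["aa"] == pytest.approx(13.7, abs=1e-9)

    def test_swap_symmetry_and_relabel_antisymmetry(self):
        rng = np.random.default_rng(1)
        geno = _pair_geno(8)
        means = pd.Series(rng.normal(80, 5, len(geno)), index=geno.index)
        a = aa_effect(geno, means, "s1", "s2")["aa"]
        b = aa_effect(geno, means, "s2", "s1")["aa"]
        assert a == pytest.approx(b)
        flipped = geno.assign(s1=2 - geno["s1"])
        c = aa_effect(flipped, means, "s1", "s2")["aa"]
        assert c == pytest.approx(-a)

    def test_na_rule_substitutes_twice_the_other_mixed_class(self):
        geno = _pair_geno(4)
        means = pd.Series(0.0, index=geno.index)
        means[geno.eval("s1 == 2 and s2 == 2")] = 73.9
        means[geno.eval("s1 == 0 and s2 == 0")] = 77.7
        means[geno.eval("s1 == 2 and s2 == 0")] = 89.0
        # NJ class absent entirely
        keep = ~geno.eval("s1 == 0 and s2 == 2")
        rec = aa_effect(geno[keep], means[keep], "s1", "s2")
        assert rec["na_rule_used"]
        assert rec["aa"] == pytest.approx((73.9 + 77.7) - 2 * 89.0)

    def test_empty_homozygous_class_is_undefined(self):
        geno = _pair_geno(4)
        keep = ~geno.eval("s1 == 2 and s2 == 2")
        means = pd.Series(80.0, index=geno.index)
        with pytest.raises(ValueError, match="homozygous"):
            aa_effect(geno[keep], means[keep], "s1", "s2")

    def test_heterozygous_lines_excluded_from_classes(self):
        geno = _pair_geno(5)
        het = pd.DataFrame([[1.0, 2.0]], columns=["s1", "s2"], index=["h0"])
        geno2 = pd.concat([geno, het])
        means = pd.Series(
            np.where(geno2["s1"].eq(2) & geno2["s2"].eq(2), 90.0, 80.0),
            index=geno2.index,
        )
        means["h0"] = 500.0  # would wreck a class mean if included
        rec = aa_effect(geno2, means, "s1", "s2")
        assert rec["JJ"] == pytest.approx(90.0)


class TestEpistaticVariance:
    def test_pure_balanced_interaction_is_all_interaction(self):
        geno = _pair_geno(10)
        x1, x2 = geno["s1"] - 1, geno["s2"] - 1
        means = pd.Series(80 + 3 * x1 * x2, index=geno.index)
        assert epistatic_variance(geno, means, "s1", "s2") == pytest.approx(100.0)

    def test_purely_additive_pair_near_zero(self):
        geno = _pair_geno(10)
        means = pd.Series(80 + 4 * (geno["s1"] - 1) - 2 * (geno["s2"] - 1),
                          index=geno.index)
        assert epistatic_variance(geno, means, "s1", "s2") == pytest.approx(0.0, abs=1e-9)

    def test_known_variance_share_recovered(self):
        rng = np.random.default_rng(2)
        geno = _pair_geno(150)
        x1, x2 = geno["s1"] - 1, geno["s2"] - 1
        means = pd.Series(80 + 2 * x1 + 2 * x2 + 2 * x1 * x2, index=geno.index)
        means += rng.normal(0, 0.5, len(means))
        # balanced classes, equal coefficients: interaction carries 1/3 of
        # the genotypic (between-class) sum of squares
        got = epistatic_variance(geno, means, "s1", "s2")
        assert got == pytest.approx(100 / 3, abs=3.0)


@pytest.fixture(scope="module")
def trait_population(wheat_population):
    lines, geno = wheat_population
    s1, s2 = geno.columns[100], geno.columns[301]
    model = mp.TraitModel(
        additive_qtl=((s1, 2.0),),
        epistatic_pairs=((s1, s2, 12.0),),
        year_variance=2.0, gxy_variance=2.0, residual_variance=8.0,
    )
    ph = mp.simulate_phenotype(geno, model, np.random.default_rng(3))
    return geno, mp.line_means(ph), (s1, s2)


class TestScanPipeline:
    def test_prescreen_keeps_trait_loci_and_all_at_alpha_one(self, trait_population):
        geno, means, (s1, s2) = trait_population
        cands = prescreen(means, geno, alpha=0.15)
        assert s1 in cands
        assert len(prescreen(means, geno, alpha=1.0)) == geno.shape[1]
        # null SNPs retained at roughly the nominal rate
        assert len(cands) < 0.4 * geno.shape[1]

    def test_pairwise_scan_finds_injected_pair_and_is_symmetric(self, trait_population):
        geno, means, (s1, s2) = trait_population
        cands = list({s1, s2} | set(prescreen(means, geno)[:40]))
        pairs = pairwise_scan(means, geno, cands)
        hit = pairs[(pairs["snp1"] == min(s1, s2)) & (pairs["snp2"] == max(s1, s2))]
        assert len(hit) == 1 and hit["significant"].iloc[0]
        # symmetry: p identical when the pair is tested in either order
        p1 = pairwise_scan(means, geno, [s1, s2])["p"].iloc[0]
        p2 = pairwise_scan(means, geno, [s2, s1])["p"].iloc[0]
        assert p1 == pytest.approx(p2)

    def test_select_interactions_dedupes_ld_proxies(self, trait_population):
        geno, means, (s1, s2) = trait_population
        proxy = geno[s1].rename("proxy")
        geno2 = pd.concat([geno[[s1, s2]], proxy], axis=1)
        pairs = pairwise_scan(means, geno2, [s1, s2, "proxy"])
        kept = select_interactions(pairs, means, geno2)
        involved = [frozenset((r["snp1"], r["snp2"])) for _, r in kept.iterrows()]
        assert len(involved) == 1  # one representative of the duplicated pair

    def test_empty_significant_set_selects_nothing(self, trait_population):
        geno, means, _ = trait_population
        pairs = pd.DataFrame(
            {"snp1": [], "snp2": [], "p": [], "p_fdr": [], "significant": []}
        )
        assert len(select_interactions(pairs, means, geno)) == 0

    def test_additive_trait_yields_no_fdr_discoveries(self, wheat_population):
        lines, geno = wheat_population
        rng = np.random.default_rng(4)
        discoveries = 0
        for rep in range(5):
            snps = [geno.columns[i] for i in (20 + rep, 200 + rep)]
            model = mp.TraitModel(
                additive_qtl=tuple((s, 3.0) for s in snps),
                year_variance=1.0, gxy_variance=2.0, residual_variance=8.0,
            )
            ph = mp.simulate_phenotype(geno, model, rng)
            means = mp.line_means(ph)
            cands = prescreen(means, geno)
            if len(cands) < 2:
                continue
            pairs = pairwise_scan(means, geno, cands[:60])
            discoveries += int(pairs["significant"].sum())
        assert discoveries <= 2  # FDR at 1%: almost always zero false pairs


class TestGroupInteractions:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["snp1", "snp2", "p", "p_fdr",
                                           "significant"])

    def test_identical_and_chained_pairs_merge(self):
        gmap = mp.GeneticMap(pd.DataFrame({
            "snp": ["a1", "a2", "a3", "b1", "b2", "b3"],
            "chrom": ["2B"] * 3 + ["7B"] * 3,
            "pos": [10.0, 16.0, 22.0, 50.0, 55.0, 60.0],
        }))
        # chain: (a1,b1)-(a2,b2) within 7 cM, (a2,b2)-(a3,b3) within 7 cM,
        # but (a1,b1)-(a3,b3) is 12 cM apart: single linkage joins all three
        pairs = self._pairs([
            ("a1", "b1", 1e-5, 1e-4, True),
            ("a2", "b2", 1e-6, 1e-5, True),
            ("a3", "b3", 1e-4, 1e-3, True),
        ])
        out = group_interactions(pairs, gmap)
        assert len(out) == 1
        assert out.iloc[0]["n_merged"] == 3
        assert out.iloc[0]["snp1"] == "a2"  # lowest FDR p represents

    def test_endpoints_beyond_window_not_merged(self):
        gmap = mp.GeneticMap(pd.DataFrame({
            "snp": ["a1", "a2", "b1", "b2"],
            "chrom": ["2B", "2B", "7B", "7B"],
            "pos": [10.0, 18.0, 50.0, 52.0],
        }))
        pairs = self._pairs([
            ("a1", "b1", 1e-5, 1e-4, True),
            ("a2", "b2", 1e-6, 1e-5, True),  # first endpoints 8 cM apart
        ])
        assert len(group_interactions(pairs, gmap)) == 2

    def test_orientation_swapped_endpoints_merge(self):
        gmap = mp.GeneticMap(pd.DataFrame({
            "snp": ["a1", "b1", "a2", "b2"],
            "chrom": ["2B", "7B", "7B", "2B"],
            "pos": [10.0, 50.0, 51.0, 11.0],
        }))
        pairs = self._pairs([
            ("a1", "b1", 1e-5, 1e-4, True),
            ("a2", "b2", 1e-6, 1e-5, True),  # same loci, endpoints swapped
        ])
        assert len(group_interactions(pairs, gmap)) == 1
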