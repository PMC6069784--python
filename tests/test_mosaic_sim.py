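"""Meiosis, funnel crossing, SSD inbreeding and genotyping."""

import numpy as np
import pandas as pd
import pytest

import magicpop as mp
from magicpop.mosaic import founder_mosaic, simulate_meiosis
from magicpop.sim import sample_unlinked_population


def _tiles_exactly(mosaic, gmap):
    for chrom in gmap.chromosomes:
        ends, founders = mosaic.segments[chrom]
        assert ends[-1] == gmap.lengths[chrom]
        assert np.all(np.diff(ends) > 0)
        assert len(ends) == len(founders)


class TestMeiosis:
    def test_zero_length_chromosome_returns_a_parental_chromatid(self):
        gmap = mp.GeneticMap(pd.DataFrame({"snp": ["s1"], "chrom": ["1A"], "pos": [0.0]}))
        rng = np.random.default_rng(0)
        parent = (founder_mosaic(gmap, 0), founder_mosaic(gmap, 1))
        picks = {int(simulate_meiosis(parent, gmap, rng).founder_at("1A", [0.0])[0])
                 for _ in range(40)}
        assert picks == {0, 1}  # both chromatids reachable, no recombination

    def test_identical_parents_give_identical_gamete(self, small_map):
        rng = np.random.default_rng(1)
        hap = founder_mosaic(small_map, 3)
        gamete = simulate_meiosis((hap, hap), small_map, rng)
        assert gamete == hap

    def test_gamete_tiles_map_and_uses_parental_founders(self, small_map):
        rng = np.random.default_rng(2)
        parent = (founder_mosaic(small_map, 0), founder_mosaic(small_map, 1))
        for _ in range(200):
            g = simulate_meiosis(parent, small_map, rng)
            _tiles_exactly(g, small_map)
            for chrom in small_map.chromosomes:
                assert set(g.segments[chrom][1]) <= {0, 1}

    def test_f1_gamete_founder_share_is_half(self):
        """Monte-Carlo vs the analytic 0.5 expectation on a 100 cM chromosome."""
        gmap = mp.uniform_map(n_snps=10, chromosomes=("1A",), length_cm=100.0)
        rng = np.random.default_rng(3)
        parent = (founder_mosaic(gmap, 0), founder_mosaic(gmap, 1))
        shares = np.array(
            [simulate_meiosis(parent, gmap, rng).founder_shares(2)[0]
             for _ in range(10_000)]
        )
        se = shares.std(ddof=1) / np.sqrt(len(shares))
        assert abs(shares.mean() - 0.5) < 3 * se

    def test_chromosome_mismatch_raises(self, small_map):
        other = mp.uniform_map(n_snps=10, chromosomes=("7D",), length_cm=50.0)
        parent = (founder_mosaic(other, 0), founder_mosaic(other, 1))
        with pytest.raises(ValueError):
            simulate_meiosis(parent, small_map, np.random.default_rng(0))


class TestBuildPopulation:
    def test_seed_budget_enforced(self, small_map, small_panel):
        cfg = mp.SimConfig(n_eight_way_seeds=4, n_f2_per_plant=2, target_lines=9)
        with pytest.raises(ValueError, match="seed budget"):
            mp.build_population(small_panel, small_map, cfg, np.random.default_rng(0))

    def test_ssd_zero_gives_eight_way_f1(self, small_map, small_panel):
        cfg = mp.SimConfig(ssd_generations=0, target_lines=50)
        lines = mp.build_population(small_panel, small_map, cfg, np.random.default_rng(4))
        assert len(lines) == 50
        for ln in lines:
            # one homolog from the ABCD funnel side, one from EFGH:
            # every locus is heterozygous for two founder origins
            for chrom in small_map.chromosomes:
                pos = small_map.positions_on(chrom)
                o1 = ln.haplotypes[0].founder_at(chrom, pos)
                o2 = ln.haplotypes[1].founder_at(chrom, pos)
                assert set(o1) <= {0, 1, 2, 3}
                assert set(o2) <= {4, 5, 6, 7}

    def test_f4_residual_heterozygosity_is_one_eighth(self, wheat_map, wheat_panel):
        rng = np.random.default_rng(5)
        cfg = mp.SimConfig(target_lines=300)
        lines = mp.build_population(wheat_panel, wheat_map, cfg, rng)
        het = []
        for ln in lines:
            for chrom in wheat_map.chromosomes:
                pos = wheat_map.positions_on(chrom)
                o1 = ln.haplotypes[0].founder_at(chrom, pos)
                o2 = ln.haplotypes[1].founder_at(chrom, pos)
                het.append(o1 != o2)
        frac = np.concatenate(het).mean()
        # per-line per-locus origin heterozygosity after 3 selfings: 2^-3
        assert frac == pytest.approx(0.125, abs=0.015)

    def test_founder_shares_sum_to_one_and_determinism(self, small_map, small_panel):
        cfg = mp.SimConfig(target_lines=40, rng_seed=21)
        lines1 = mp.build_population(small_panel, small_map, cfg, np.random.default_rng(21))
        lines2 = mp.build_population(small_panel, small_map, cfg, np.random.default_rng(21))
        for l1, l2 in zip(lines1, lines2):
            assert np.allclose(l1.founder_shares(), l2.founder_shares())
            assert l1.founder_shares().sum() == pytest.approx(1.0)
            assert l1.haplotypes[0] == l2.haplotypes[0]


@pytest.fixture(scope="module")
def selected(wheat_map, wheat_panel):
    rng = np.random.default_rng(6)
    cfg = mp.SimConfig(target_lines=700, n_f2_per_plant=15)
    lines = mp.build_population(wheat_panel, wheat_map, cfg, rng)
    locus_d = wheat_map.snps_on("4D")[10]
    locus_b = wheat_map.snps_on("4B")[10]
    dwarf_d = frozenset({"Patras", "Linus", "JB_Asano", "Julius"})  # 4 of 8
    dwarf_b = frozenset({"Tobak", "Safari"})                        # 2 of 8
    kept = mp.apply_dwarf_selection(
        lines, wheat_panel, (locus_d, locus_b), (dwarf_d, dwarf_b), wheat_map
    )
    return lines, kept, (locus_d, locus_b), (dwarf_d, dwarf_b)


class TestDwarfSelection:
    @staticmethod
    def _origin_freq(lines, gmap, panel, snp, founders):
        chrom, pos = gmap.chromosome(snp), gmap.position(snp)
        idx = {panel.founder_index(f) for f in founders}
        count = total = 0
        for ln in lines:
            for hap in ln.haplotypes:
                count += int(hap.founder_at(chrom, [pos])[0]) in idx
                total += 1
        return count / total

    def test_double_dwarfs_removed_single_dwarfs_kept(self, selected, wheat_map, wheat_panel):
        lines, kept, loci, sets = selected
        kept_names = {ln.name for ln in kept}
        assert kept_names < {ln.name for ln in lines}
        # order preserved
        assert [ln.name for ln in kept] == [ln.name for ln in lines if ln.name in kept_names]
        # no kept line is homozygous dwarf at both loci, and at least one
        # kept line is homozygous dwarf at exactly one locus
        singles = 0
        for ln in kept:
            homs = []
            for snp, founders in zip(loci, sets):
                chrom, pos = wheat_map.chromosome(snp), wheat_map.position(snp)
                idx = {wheat_panel.founder_index(f) for f in founders}
                homs.append(all(
                    int(h.founder_at(chrom, [pos])[0]) in idx for h in ln.haplotypes
                ))
            assert not all(homs)
            singles += sum(homs) == 1
        assert singles > 0

    def test_deficits_match_class_removal_oracle(self, selected, wheat_map, wheat_panel):
        """Exact enumeration of double-homozygote removal predicts a strictly
        positive deficit at both loci, larger at the rarer (2-founder) locus."""
        lines, kept, (locus_d, locus_b), (dwarf_d, dwarf_b) = selected
        pre_d = self._origin_freq(lines, wheat_map, wheat_panel, locus_d, dwarf_d)
        post_d = self._origin_freq(kept, wheat_map, wheat_panel, locus_d, dwarf_d)
        pre_b = self._origin_freq(lines, wheat_map, wheat_panel, locus_b, dwarf_b)
        post_b = self._origin_freq(kept, wheat_map, wheat_panel, locus_b, dwarf_b)
        assert post_d < pre_d and post_b < pre_b  # selection monotonicity
        # enumeration oracle (unlinked funnel law): deficits 0.056 vs 0.084
        assert (pre_b - post_b) > (pre_d - post_d)

    def test_no_double_dwarf_population_unchanged(self, small_map, small_panel):
        rng = np.random.default_rng(7)
        cfg = mp.SimConfig(target_lines=30)
        lines = mp.build_population(small_panel, small_map, cfg, rng)
        # dwarf sets empty at one locus: nobody is a double dwarf
        kept = mp.apply_dwarf_selection(
            lines, small_panel,
            (small_map.snps_on("1A")[0], small_map.snps_on("2B")[0]),
            (frozenset(), frozenset({"Julius"})),
            small_map,
        )
        assert [ln.name for ln in kept] == [ln.name for ln in lines]

    def test_same_chromosome_loci_rejected(self, small_map, small_panel, wheat_population):
        lines, _ = wheat_population
        snps = small_map.snps_on("1A")
        with pytest.raises(ValueError, match="distinct chromosomes"):
            mp.apply_dwarf_selection(
                lines[:5], small_panel, (snps[0], snps[1]),
                (frozenset({"Julius"}), frozenset({"Julius"})), small_map,
            )


class TestGenotyping:
    def test_clean_inbred_dosages_and_private_allele_frequency(
        self, wheat_map, wheat_panel, wheat_population
    ):
        lines, geno = wheat_population
        x = geno.to_numpy()
        assert not np.isnan(x).any()
        assert set(np.unique(x)) <= {0.0, 1.0, 2.0}
        # dosage-1 calls only at residual heterozygous loci (~12.5% ceiling)
        assert (x == 1).mean() < 0.125
        # SNPs private to the reference founder segregate near 12.5%
        from magicpop.segregation import assign_afg

        afg = assign_afg(wheat_panel).set_index("snp")
        afg1 = [s for s in geno.columns if afg.at[s, "afg"] == 1]
        freq = np.nanmean(x[:, [geno.columns.get_loc(s) for s in afg1]]) / 2
        # a single funnel population carries irreducible crossing-bottleneck
        # variance (sd ~ 0.012 at this SNP count); 3 sigma around 1/8
        assert freq == pytest.approx(0.125, abs=0.04)

    def test_missingness_injected_at_configured_rate(self, wheat_map, wheat_panel):
        rng = np.random.default_rng(8)
        cfg = mp.SimConfig(target_lines=200, missing_rate=0.05, het_error_rate=0.0)
        lines = mp.build_population(wheat_panel, wheat_map, cfg, rng)
        geno = mp.genotype_lines(lines, wheat_panel, wheat_map, cfg, rng)
        miss = np.isnan(geno.to_numpy())
        p_hat = miss.mean()
        se = np.sqrt(0.05 * 0.95 / miss.size)
        assert abs(p_hat - 0.05) < 3 * se


class TestUnlinkedSampler:
    def test_matches_funnel_law(self, wheat_panel):
        rng = np.random.default_rng(9)
        geno = sample_unlinked_population(4000, 50, wheat_panel, rng)
        x = geno.to_numpy()
        from magicpop.segregation import assign_afg

        afg = assign_afg(wheat_panel).set_index("snp")
        k = afg.loc[geno.columns, "afg"].to_numpy()
        freq = np.nanmean(x, axis=0) / 2
        # each SNP's frequency near its AFG expectation
        se = np.sqrt((k / 8) * (1 - k / 8) / (2 * 4000)) * np.sqrt(1 + 0.125)
        assert (np.abs(freq - k / 8) < 5 * se).mean() > 0.95
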