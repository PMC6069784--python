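"""Funnel-crossing MAGIC population simulator.

Reproduces the crossing design of an 8-way winter-wheat MAGIC population:
the eight founders (crossing positions A..H) are crossed in four fixed
pairs (AB, CD, EF, GH), the pair F1s are intercrossed into two 4-way
crosses (ABCD, EFGH), 4-way plants are intercrossed (including reciprocals,
modelled identically) into 8-way seeds, and each 8-way plant is selfed and
advanced by single-seed descent (SSD) to F4.  Every line is expected to
carry 12.5% of each founder's genome, and a locus heterozygous in the 8-way
F1 stays heterozygous with probability 2^-g after g selfing generations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .founders import FounderPanel
from .genmap import GeneticMap
from .mosaic import HaplotypeMosaic, founder_mosaic, simulate_meiosis

__all__ = [
    "SimConfig",
    "MagicLine",
    "build_population",
    "apply_dwarf_selection",
    "genotype_lines",
    "sample_unlinked_population",
    "simulate_magic",
]


@dataclass(frozen=True)
class SimConfig:
    """Crossing-design and genotyping-noise parameters.

    Defaults follow the study design: 141 8-way seeds, ~15 selfed F2 seeds
    per 8-way plant, three SSD selfing generations (F1 -> F4) and a final
    population of 910 lines.
    """

    rng_seed: int = 0
    n_eight_way_seeds: int = 141
    n_f2_per_plant: int = 15
    target_lines: int = 910
    ssd_generations: int = 3
    n_four_way_plants: int = 18         # per funnel side
    reciprocal_fraction: float = 85 / 141
    missing_rate: float = 0.02
    het_error_rate: float = 0.005
    selection_rule: tuple[tuple[str, str], tuple[frozenset, frozenset]] | None = None

    def __post_init__(self):
        for name in ("n_eight_way_seeds", "n_f2_per_plant", "target_lines",
                     "n_four_way_plants"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ssd_generations < 0:
            raise ValueError("ssd_generations must be >= 0")
        for name in ("missing_rate", "het_error_rate", "reciprocal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class MagicLine:
    """One inbred line: a pair of haplotype mosaics plus pedigree tags."""

    name: str
    haplotypes: tuple[HaplotypeMosaic, HaplotypeMosaic]
    eight_way_ancestor: int
    reciprocal: bool = False

    def founder_shares(self, n_founders: int = 8) -> np.ndarray:
        a, b = self.haplotypes
        return 0.5 * (a.founder_shares(n_founders) + b.founder_shares(n_founders))


def _self(plant, gmap, rng):
    return (simulate_meiosis(plant, gmap, rng), simulate_meiosis(plant, gmap, rng))


def build_population(
    panel: FounderPanel,
    gmap: GeneticMap,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[MagicLine]:
    """Run the funnel and SSD, returning ``target_lines`` F-generation lines.

    The seed budget is ``n_eight_way_seeds * n_f2_per_plant`` candidate F2
    plants (each advanced independently by SSD); requesting more lines than
    that raises a configuration error.
    """
    budget = config.n_eight_way_seeds * config.n_f2_per_plant
    if config.ssd_generations >= 1 and config.target_lines > budget:
        raise ValueError(
            f"target_lines={config.target_lines} exceeds the seed budget "
            f"{config.n_eight_way_seeds} x {config.n_f2_per_plant} = {budget}"
        )

    # 2-way crosses in fixed pairs: AB, CD, EF, GH
    pair_f1 = [
        (founder_mosaic(gmap, a), founder_mosaic(gmap, b))
        for a, b in ((0, 1), (2, 3), (4, 5), (6, 7))
    ]
    # 4-way crosses ABCD and EFGH
    four_way = {
        side: [
            (
                simulate_meiosis(pair_f1[2 * s], gmap, rng),
                simulate_meiosis(pair_f1[2 * s + 1], gmap, rng),
            )
            for _ in range(config.n_four_way_plants)
        ]
        for s, side in enumerate(("ABCD", "EFGH"))
    }

    # 8-way seeds, a configured fraction from the reciprocal cross direction
    # (reciprocals are genetically identical here: no cytoplasmic effects)
    n_recip = int(round(config.reciprocal_fraction * config.n_eight_way_seeds))
    recip_flags = np.zeros(config.n_eight_way_seeds, dtype=bool)
    recip_flags[:n_recip] = True
    rng.shuffle(recip_flags)

    eight_way = []
    for flag in recip_flags:
        ma = four_way["ABCD"][rng.integers(config.n_four_way_plants)]
        mb = four_way["EFGH"][rng.integers(config.n_four_way_plants)]
        eight_way.append(
            (
                (simulate_meiosis(ma, gmap, rng), simulate_meiosis(mb, gmap, rng)),
                bool(flag),
            )
        )

    if config.ssd_generations == 0:
        lines = [
            MagicLine(f"WM{(i + 1):04d}", plant, i, recip)
            for i, (plant, recip) in enumerate(eight_way)
        ]
        return lines[: config.target_lines]

    # allocate target_lines F2 seeds across 8-way plants (round robin keeps
    # the funnel balanced and the per-plant seed cap respected)
    lines: list[MagicLine] = []
    idx = 0
    per_plant = np.zeros(config.n_eight_way_seeds, dtype=int)
    while len(lines) < config.target_lines:
        plant_i = idx % config.n_eight_way_seeds
        idx += 1
        if per_plant[plant_i] >= config.n_f2_per_plant:
            continue
        per_plant[plant_i] += 1
        plant, recip = eight_way[plant_i]
        individual = _self(plant, gmap, rng)          # F2
        for _ in range(config.ssd_generations - 1):   # F2 -> ... -> F_{g+1}
            individual = _self(individual, gmap, rng)
        lines.append(
            MagicLine(f"WM{len(lines) + 1:04d}", individual, plant_i, recip)
        )
    return lines


def apply_dwarf_selection(
    lines: Sequence[MagicLine],
    panel: FounderPanel,
    locus_pair: tuple[str, str],
    dwarf_founder_sets: tuple[frozenset | set, frozenset | set],
    gmap: GeneticMap | None = None,
) -> list[MagicLine]:
    """Remove double dwarfs: lines homozygous for a dwarf-founder origin at
    BOTH loci.  Lines homozygous at only one locus (or heterozygous) are
    retained; output order is preserved.
    """
    if gmap is None:
        raise ValueError("a genetic map is required to locate the loci")
    for snp in locus_pair:
        if snp not in gmap:
            raise KeyError(f"locus {snp!r} not in map")
    chroms = [gmap.chromosome(s) for s in locus_pair]
    if chroms[0] == chroms[1]:
        raise ValueError("the two dwarfing loci must be on distinct chromosomes")
    dwarf_idx = [
        {panel.founder_index(f) for f in founders}
        for founders in dwarf_founder_sets
    ]
    kept = []
    for line in lines:
        double = True
        for snp, chrom, dwarfs in zip(locus_pair, chroms, dwarf_idx):
            pos = gmap.position(snp)
            o1 = int(line.haplotypes[0].founder_at(chrom, [pos])[0])
            o2 = int(line.haplotypes[1].founder_at(chrom, [pos])[0])
            if not (o1 in dwarfs and o2 in dwarfs):
                double = False
                break
        if not double:
            kept.append(line)
    return kept


def genotype_lines(
    lines: Sequence[MagicLine],
    panel: FounderPanel,
    gmap: GeneticMap,
    config: SimConfig,
    rng: np.random.Generator,
    return_raw: bool = False,
) -> pd.DataFrame:
    """IBS-coded genotype matrix (lines x SNPs) from the founder mosaics.

    Dosage is the count of reference-founder alleles {0, 1, 2}; residual
    heterozygous loci yield dosage 1.  Genotyping noise: each call is set
    missing (NaN) with ``missing_rate`` and, independently, rendered
    heterozygous with ``het_error_rate``.  With ``return_raw`` the matrix
    holds two-letter allele calls (e.g. ``"AB"``; missing ``""``) instead.
    """
    snp_ids = gmap.snp_ids
    carrier = panel.carrier_matrix(snp_ids)  # (8, m)
    n, m = len(lines), len(snp_ids)
    origin1 = np.empty((n, m), dtype=np.int64)
    origin2 = np.empty((n, m), dtype=np.int64)
    col = 0
    for chrom in gmap.chromosomes:
        pos = gmap.positions_on(chrom)
        k = len(pos)
        for i, line in enumerate(lines):
            origin1[i, col:col + k] = line.haplotypes[0].founder_at(chrom, pos)
            origin2[i, col:col + k] = line.haplotypes[1].founder_at(chrom, pos)
        col += k

    cols = np.arange(m)
    allele1 = carrier[origin1, cols[None, :]]
    allele2 = carrier[origin2, cols[None, :]]
    dosage = (allele1 + allele2).astype(float)

    if config.het_error_rate > 0:
        err = rng.random((n, m)) < config.het_error_rate
        dosage[err] = 1.0
    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosage[miss] = np.nan

    index = pd.Index([ln.name for ln in lines], name="line")
    if not return_raw:
        return pd.DataFrame(dosage, index=index, columns=snp_ids)

    ref = np.array([panel.reference_allele(s) for s in snp_ids])
    alt_table = panel.allele_table.loc[:, snp_ids].to_numpy()
    alt = np.where(alt_table[0] != ref, alt_table[0], "")
    for r in range(1, 8):
        alt = np.where(alt == "", np.where(alt_table[r] != ref, alt_table[r], ""), alt)
    calls = np.empty((n, m), dtype=object)
    for d, call in ((2.0, ref + ref), (0.0, alt + alt), (1.0, ref + alt)):
        calls[dosage == d] = np.broadcast_to(call, (n, m))[dosage == d]
    calls[np.isnan(dosage)] = ""
    return pd.DataFrame(calls, index=index, columns=snp_ids)


def sample_unlinked_population(
    n_lines: int,
    n_snps: int,
    panel: FounderPanel,
    rng: np.random.Generator,
    ssd_generations: int = 3,
    snp_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Exact single-locus funnel law with every SNP independent.

    At an unlinked locus the 8-way F1 carries one origin uniform over the
    ABCD funnel side and one uniform over EFGH; after ``g`` selfing
    generations the locus is still heterozygous (both origins) with
    probability 2^-g, otherwise fixed for either origin with equal chance.
    Used for calibration checks that require independent markers; linked
    mosaics come from :func:`build_population`.
    """
    if snp_ids is None:
        snp_ids = panel.snp_ids[:n_snps]
    snp_ids = list(snp_ids)
    if len(snp_ids) != n_snps:
        raise ValueError("snp_ids length must equal n_snps")
    carrier = panel.carrier_matrix(snp_ids)  # (8, m)

    ox = rng.integers(0, 4, size=(n_lines, n_snps))       # ABCD side
    oy = rng.integers(4, 8, size=(n_lines, n_snps))       # EFGH side
    het = rng.random((n_lines, n_snps)) < 0.5 ** ssd_generations
    pick_x = rng.random((n_lines, n_snps)) < 0.5
    o1 = np.where(het | pick_x, ox, oy)
    o2 = np.where(het | ~pick_x, oy, ox)

    cols = np.arange(n_snps)
    dosage = (carrier[o1, cols[None, :]] + carrier[o2, cols[None, :]]).astype(float)
    index = pd.Index([f"UL{i + 1:04d}" for i in range(n_lines)], name="line")
    return pd.DataFrame(dosage, index=index, columns=snp_ids)


def simulate_magic(
    panel: FounderPanel,
    gmap: GeneticMap,
    config: SimConfig,
    rng: np.random.Generator | None = None,
):
    """Convenience pipeline: build lines, optionally remove double dwarfs,
    and genotype.  Returns ``(lines, genotype matrix)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if config.selection_rule is not None:
        # keep the seed budget: oversample, select, then trim to target
        locus_pair, dwarf_sets = config.selection_rule
        pool_cfg = replace(
            config,
            selection_rule=None,
            target_lines=min(
                config.n_eight_way_seeds * config.n_f2_per_plant,
                int(config.target_lines * 1.6) + 50,
            ),
        )
        pool = build_population(panel, gmap, pool_cfg, rng)
        kept = apply_dwarf_selection(pool, panel, locus_pair, dwarf_sets, gmap)
        if len(kept) < config.target_lines:
            raise ValueError(
                "double-dwarf selection left fewer lines than target_lines"
            )
        lines = kept[: config.target_lines]
    else:
        lines = build_population(panel, gmap, config, rng)
    geno = genotype_lines(lines, panel, gmap, config, rng)
    return lines, geno
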