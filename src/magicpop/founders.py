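"""Founder panel: the eight parents of an 8-way MAGIC funnel.

The panel stores each founder's allele at every SNP together with the
identity of the *reference founder* — the cultivar whose allele defines the
IBS dosage coding (dosage = copies of the reference-founder allele).  A SNP's
allele-frequency group (AFG) is the number of founders, 1..7, that carry the
reference-founder allele; under the balanced funnel the expected population
frequency of that allele is k/8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Crossing positions A..H of the study-style panel of eight European winter
#: wheat cultivars; the reference founder sits at position H.
DEFAULT_FOUNDERS: tuple[str, ...] = (
    "Patras",      # A
    "Meister",     # B
    "Linus",       # C
    "JB_Asano",    # D
    "Tobak",       # E
    "Bernstein",   # F
    "Safari",      # G
    "Julius",      # H  (reference founder)
)
DEFAULT_REFERENCE = "Julius"

#: Default probability of a SNP falling in AFG k (k = 1..7), taken from the
#: observed per-AFG SNP counts of a 7,584-SNP wheat MAGIC array
#: (260, 531, 877, 842, 1315, 1582, 2177).
DEFAULT_AFG_PROFILE: tuple[float, ...] = tuple(
    np.array([260, 531, 877, 842, 1315, 1582, 2177]) / 7584.0
)

#: Semi-dwarfing (Rht) truth set used by the default simulated trait:
#: founders carrying the height-reducing allele at the two unlinked loci.
RHT_B1_DWARF_FOUNDERS = frozenset({"Tobak", "Safari"})
RHT_D1_DWARF_FOUNDERS = frozenset({"Patras", "Linus", "JB_Asano", "Julius"})


@dataclass
class FounderPanel:
    """Eight founders with bi-allelic calls at every SNP.

    ``allele_table`` is a founders x SNPs frame of single-letter allele
    calls (e.g. ``"A"``/``"B"``); no missing values are allowed and every
    SNP must be polymorphic among the founders.
    """

    founder_names: tuple[str, ...]
    allele_table: pd.DataFrame
    reference_founder: str = DEFAULT_REFERENCE
    _carrier: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self):
        self.founder_names = tuple(self.founder_names)
        if len(self.founder_names) != 8:
            raise ValueError("a MAGIC funnel panel has exactly 8 founders")
        if self.reference_founder not in self.founder_names:
            raise ValueError("reference founder must be one of the 8 founders")
        at = self.allele_table
        if list(at.index) != list(self.founder_names):
            at = at.loc[list(self.founder_names)]
        if at.isna().any().any():
            raise ValueError("founder allele table must be complete")
        ref = at.loc[self.reference_founder]
        carrier = at.eq(ref, axis=1)
        k = carrier.sum(axis=0)
        if (k == 8).any():
            mono = k.index[k == 8][0]
            raise ValueError(f"SNP {mono!r} is monomorphic among founders")
        self.allele_table = at
        self._carrier = carrier

    # -- derived views ---------------------------------------------------
    @property
    def snp_ids(self) -> list[str]:
        return list(self.allele_table.columns)

    @property
    def ref_carrier(self) -> pd.DataFrame:
        """Boolean founders x SNPs frame: founder carries the reference allele."""
        return self._carrier

    def carrier_matrix(self, snp_ids=None) -> np.ndarray:
        """uint8 array (8, n_snps) of reference-allele carriage, founder order A..H."""
        c = self._carrier if snp_ids is None else self._carrier.loc[:, list(snp_ids)]
        return c.to_numpy(dtype=np.uint8)

    def founder_index(self, name: str) -> int:
        return self.founder_names.index(name)

    def reference_allele(self, snp: str) -> str:
        return self.allele_table.at[self.reference_founder, snp]

    # -- io --------------------------------------------------------------
    def to_csv(self, path) -> None:
        out = self.allele_table.copy()
        out.index.name = "founder"
        out.to_csv(path)

    @classmethod
    def read_csv(cls, path, reference_founder: str = DEFAULT_REFERENCE) -> "FounderPanel":
        at = pd.read_csv(path, index_col=0)
        return cls(tuple(at.index), at, reference_founder)


def simulate_founder_alleles(
    snp_ids,
    rng: np.random.Generator,
    founder_names: tuple[str, ...] = DEFAULT_FOUNDERS,
    reference_founder: str = DEFAULT_REFERENCE,
    afg_profile=DEFAULT_AFG_PROFILE,
    forced_carriers: dict[str, frozenset | set] | None = None,
    gmap=None,
    haplotype_rho: float = 0.6,
    haplotype_range_cm: float = 10.0,
) -> FounderPanel:
    """Draw a founder panel with a realistic AFG composition.

    For each SNP an AFG ``k`` is drawn from ``afg_profile`` (probabilities of
    k = 1..7).  The reference founder always carries its own allele, so the
    ``k`` carriers are the reference founder plus ``k-1`` founders sampled
    uniformly from the other seven.  ``forced_carriers`` pins the carrier set
    of selected SNPs (e.g. to place a dwarfing allele in known founders);
    the set lists the founders carrying the *reference-founder* allele and
    must include the reference founder.

    When a genetic map is supplied, carrier sets are locally persistent
    along each chromosome: a SNP reuses its left neighbour's carrier set
    with probability ``haplotype_rho * exp(-distance / haplotype_range_cm)``,
    otherwise it draws a fresh set.  This emulates the shared founder
    haplotype blocks that give real marker panels their short-range LD;
    the marginal AFG composition is unchanged.
    """
    snp_ids = [str(s) for s in snp_ids]
    names = list(founder_names)
    ref_i = names.index(reference_founder)
    others = [i for i in range(8) if i != ref_i]
    profile = np.asarray(afg_profile, dtype=float)
    profile = profile / profile.sum()

    carrier = np.zeros((8, len(snp_ids)), dtype=bool)
    ks = rng.choice(np.arange(1, 8), size=len(snp_ids), p=profile)
    copy_src = np.full(len(snp_ids), -1, dtype=int)
    if gmap is not None and haplotype_rho > 0:
        col = {s: j for j, s in enumerate(snp_ids)}
        for chrom in gmap.chromosomes:
            chrom_snps = [s for s in gmap.snps_on(chrom) if s in col]
            for prev, cur in zip(chrom_snps, chrom_snps[1:]):
                gap = gmap.position(cur) - gmap.position(prev)
                p_copy = haplotype_rho * np.exp(-gap / haplotype_range_cm)
                if rng.random() < p_copy:
                    copy_src[col[cur]] = col[prev]
    for j, k in enumerate(ks):
        src = copy_src[j]
        if src >= 0 and (src < j or carrier[:, src].any()):
            carrier[:, j] = carrier[:, src]
            continue
        carrier[ref_i, j] = True
        if k > 1:
            picks = rng.choice(others, size=k - 1, replace=False)
            carrier[picks, j] = True
    if forced_carriers:
        col = {s: j for j, s in enumerate(snp_ids)}
        for snp, founders in forced_carriers.items():
            if reference_founder not in founders:
                raise ValueError(
                    "forced carrier set must include the reference founder "
                    f"(SNP {snp!r})"
                )
            j = col[snp]
            carrier[:, j] = False
            for f in founders:
                carrier[names.index(f), j] = True

    # attach concrete allele letters: the reference allele is A or B at random
    ref_letter = np.where(rng.random(len(snp_ids)) < 0.5, "A", "B")
    alt_letter = np.where(ref_letter == "A", "B", "A")
    letters = np.where(carrier, ref_letter[None, :], alt_letter[None, :])
    table = pd.DataFrame(letters, index=names, columns=snp_ids)
    return FounderPanel(tuple(names), table, reference_founder)
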