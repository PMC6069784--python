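"""Genetic map container.

A genetic map is an ordered table of SNPs with a chromosome label and a
position in centimorgan.  Chromosome length is defined as the maximum mapped
position, which is the convention used for consensus maps where the first
and last markers anchor the chromosome ends.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: hexaploid wheat chromosome labels, 7 homoeologous groups x 3 subgenomes
WHEAT_CHROMOSOMES: tuple[str, ...] = tuple(
    f"{g}{s}" for g in range(1, 8) for s in "ABD"
)


class GeneticMap:
    """Ordered SNP -> (chromosome, cM) lookup.

    Parameters
    ----------
    table:
        DataFrame with columns ``snp``, ``chrom``, ``pos`` (cM). Rows are
        sorted by chromosome (input order of first appearance) and position;
        ties keep input order.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"snp", "chrom", "pos"}
        if not required.issubset(table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        t = table.loc[:, ["snp", "chrom", "pos"]].copy()
        t["snp"] = t["snp"].astype(str)
        t["chrom"] = t["chrom"].astype(str)
        t["pos"] = t["pos"].astype(float)
        if t["snp"].duplicated().any():
            dup = t.loc[t["snp"].duplicated(), "snp"].iloc[0]
            raise ValueError(f"duplicate snp id in map: {dup!r}")
        if (t["pos"] < 0).any():
            raise ValueError("map positions must be >= 0")
        # stable sort: chromosome blocks in order of first appearance
        chrom_order = {c: i for i, c in enumerate(t["chrom"].drop_duplicates())}
        t["_c"] = t["chrom"].map(chrom_order)
        t = t.sort_values(["_c", "pos"], kind="stable").drop(columns="_c")
        t = t.reset_index(drop=True)
        self.table = t
        self.chromosomes: tuple[str, ...] = tuple(chrom_order)
        self.lengths: dict[str, float] = {
            c: float(g["pos"].max()) for c, g in t.groupby("chrom", sort=False)
        }
        self._by_chrom = {c: g for c, g in t.groupby("chrom", sort=False)}
        self._pos = dict(zip(t["snp"], t["pos"]))
        self._chr = dict(zip(t["snp"], t["chrom"]))
        self._order = {s: i for i, s in enumerate(t["snp"])}

    # -- lookups ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, snp: str) -> bool:
        return snp in self._pos

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp"])

    def position(self, snp: str) -> float:
        return self._pos[snp]

    def chromosome(self, snp: str) -> str:
        return self._chr[snp]

    def order_key(self, snp: str) -> int:
        """Genome-wide map order index (chromosome block, then cM)."""
        return self._order[snp]

    def snps_on(self, chrom: str) -> list[str]:
        return list(self._by_chrom[chrom]["snp"])

    def positions_on(self, chrom: str) -> np.ndarray:
        return self._by_chrom[chrom]["pos"].to_numpy()

    # -- io --------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path))


def uniform_map(
    n_snps: int = 2000,
    chromosomes: Sequence[str] = WHEAT_CHROMOSOMES,
    length_cm: float | Iterable[float] = 170.0,
    prefix: str = "S",
) -> GeneticMap:
    """Evenly spaced synthetic map.

    SNPs are distributed across chromosomes as equally as possible and
    placed uniformly over ``[0, length]``, first and last SNP anchoring the
    chromosome ends.  ``length_cm`` may be a scalar or one value per
    chromosome; the default of 170 cM matches a typical wheat consensus-map
    chromosome.
    """
    chromosomes = list(chromosomes)
    if np.isscalar(length_cm):
        lengths = [float(length_cm)] * len(chromosomes)
    else:
        lengths = [float(x) for x in length_cm]
        if len(lengths) != len(chromosomes):
            raise ValueError("one length per chromosome required")
    base, extra = divmod(n_snps, len(chromosomes))
    rows = []
    for i, (chrom, length) in enumerate(zip(chromosomes, lengths)):
        k = base + (1 if i < extra else 0)
        if k == 0:
            continue
        pos = np.linspace(0.0, length, k) if k > 1 else np.array([length / 2])
        for j, p in enumerate(pos):
            rows.append((f"{prefix}{chrom}_{j:04d}", chrom, round(float(p), 4)))
    return GeneticMap(pd.DataFrame(rows, columns=["snp", "chrom", "pos"]))
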