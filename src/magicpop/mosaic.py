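"""Founder-origin haplotype mosaics and meiosis.

A chromosome of a MAGIC line is a mosaic of founder segments.  Each
haplotype stores, per chromosome, the ordered segment end positions (cM)
and the founder index of each segment; segment *i* covers
``(ends[i-1], ends[i]]`` with the first segment starting at 0, and the
segments tile ``[0, L]`` exactly.

Meiosis follows the Haldane model: the number of crossovers per chromosome
is Poisson with mean L/100 (one expected crossover per Morgan, no
interference) and breakpoint positions are uniform on the chromosome.
"""

from __future__ import annotations

import numpy as np

from .genmap import GeneticMap

__all__ = ["HaplotypeMosaic", "founder_mosaic", "simulate_meiosis"]


class HaplotypeMosaic:
    """Per-chromosome founder-origin segments of one haploid genome."""

    def __init__(self, segments: dict[str, tuple[np.ndarray, np.ndarray]],
                 lengths: dict[str, float]):
        self.segments = segments          # chrom -> (ends f8, founders i8)
        self.lengths = lengths
        for chrom, (ends, founders) in segments.items():
            if len(ends) != len(founders) or len(ends) == 0:
                raise ValueError(f"malformed mosaic on {chrom}")
            if ends[-1] != lengths[chrom] or np.any(np.diff(ends) <= 0):
                raise ValueError(f"segments do not tile [0, L] on {chrom}")

    @property
    def chromosomes(self):
        return list(self.segments)

    def founder_at(self, chrom: str, pos) -> np.ndarray:
        """Founder index at each query position (positions in [0, L])."""
        ends, founders = self.segments[chrom]
        idx = np.searchsorted(ends, np.asarray(pos, dtype=float), side="left")
        idx = np.minimum(idx, len(ends) - 1)  # pos == 0 on a [0,L] segment
        return founders[idx]

    def founder_shares(self, n_founders: int = 8) -> np.ndarray:
        """Fraction of total map length inherited from each founder."""
        total = sum(self.lengths.values())
        shares = np.zeros(n_founders)
        for chrom, (ends, founders) in self.segments.items():
            seg_len = np.diff(np.concatenate(([0.0], ends)))
            np.add.at(shares, founders, seg_len)
        if total > 0:
            shares /= total
        return shares

    def __eq__(self, other) -> bool:
        if not isinstance(other, HaplotypeMosaic):
            return NotImplemented
        if self.segments.keys() != other.segments.keys():
            return False
        return all(
            np.array_equal(self.segments[c][0], other.segments[c][0])
            and np.array_equal(self.segments[c][1], other.segments[c][1])
            for c in self.segments
        )


def founder_mosaic(gmap: GeneticMap, founder: int) -> HaplotypeMosaic:
    """Single-founder haplotype covering the whole map."""
    segs = {
        c: (np.array([gmap.lengths[c]]), np.array([founder], dtype=np.int64))
        for c in gmap.chromosomes
    }
    return HaplotypeMosaic(segs, dict(gmap.lengths))


def _simplify(ends: list[float], founders: list[int]):
    """Merge consecutive segments with the same founder origin."""
    out_e, out_f = [], []
    for e, f in zip(ends, founders):
        if out_f and out_f[-1] == f:
            out_e[-1] = e
        else:
            out_e.append(e)
            out_f.append(f)
    return np.asarray(out_e, dtype=float), np.asarray(out_f, dtype=np.int64)


def _recombine_chrom(hap_a, hap_b, length: float, rng: np.random.Generator):
    """One gamete chromosome from two parental chromatids (Haldane)."""
    n_xo = rng.poisson(length / 100.0) if length > 0 else 0
    current = int(rng.integers(2))  # starting chromatid
    if n_xo == 0:
        ends, founders = (hap_a, hap_b)[current]
        return ends.copy(), founders.copy()
    breaks = np.sort(rng.uniform(0.0, length, size=n_xo))
    sources = (hap_a, hap_b)
    out_e: list[float] = []
    out_f: list[int] = []
    start = 0.0
    for cut in np.append(breaks, length):
        if cut > start:
            ends, founders = sources[current]
            i0 = np.searchsorted(ends, start, side="right")
            i1 = np.searchsorted(ends, cut, side="left")
            for i in range(i0, min(i1, len(ends) - 1) + 1):
                out_e.append(min(float(ends[i]), cut))
                out_f.append(int(founders[i]))
            start = cut
        current ^= 1
    return _simplify(out_e, out_f)


def simulate_meiosis(parent: tuple[HaplotypeMosaic, HaplotypeMosaic],
                     gmap: GeneticMap,
                     rng: np.random.Generator) -> HaplotypeMosaic:
    """Produce one gamete from a diploid parent.

    Crossover counts per chromosome are Poisson(L_cM/100) with uniform
    breakpoints; the gamete alternates between the two parental chromatids
    at each breakpoint, starting from a fair coin.
    """
    hap1, hap2 = parent
    if set(hap1.segments) != set(gmap.chromosomes) or set(hap2.segments) != set(
        gmap.chromosomes
    ):
        raise ValueError("parental mosaics do not cover the map's chromosomes")
    segs = {}
    for chrom in gmap.chromosomes:
        segs[chrom] = _recombine_chrom(
            hap1.segments[chrom], hap2.segments[chrom], gmap.lengths[chrom], rng
        )
    return HaplotypeMosaic(segs, dict(gmap.lengths))
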