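"""Genotype quality control, IBS encoding, mean imputation and map placement.

Filters follow the array-genotyping conventions of wheat MAGIC studies:
SNPs with missing data > 10%, heterozygous calls > 10% or minor allele
frequency < 1% are removed.  Dosages count copies of the reference-founder
allele (homozygous reference = 2, heterozygous = 1, homozygous alternative
= 0) and missing calls are replaced by the SNP mean across lines (MNI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .founders import FounderPanel
from .genmap import GeneticMap

__all__ = ["QCReport", "qc_filter", "encode_ibs", "impute_mni", "assign_unmapped"]


@dataclass
class QCReport:
    """Per-SNP QC metrics and the primary removal reason (if removed)."""

    table: pd.DataFrame  # snp, missing_frac, het_frac, maf, kept, reason

    @property
    def removed(self) -> pd.DataFrame:
        return self.table[~self.table["kept"]]

    def counts(self) -> dict[str, int]:
        out = {"kept": int(self.table["kept"].sum())}
        for reason, n in self.table["reason"].value_counts().items():
            if reason:
                out[reason] = int(n)
        return out


def _snp_stats(matrix: pd.DataFrame):
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    miss = np.isnan(x)
    n_obs = n - miss.sum(axis=0)
    missing_frac = miss.sum(axis=0) / n
    het_frac = np.where(
        n_obs > 0, np.nansum(x == 1, axis=0) / np.maximum(n_obs, 1), 0.0
    )
    # allele-count MAF: heterozygotes contribute one allele each
    ref = np.nansum(x, axis=0)
    tot = 2.0 * n_obs
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, ref / tot, np.nan)
    maf = np.minimum(p, 1.0 - p)
    return missing_frac, het_frac, maf


def qc_filter(
    matrix: pd.DataFrame,
    max_missing: float = 0.10,
    max_het: float = 0.10,
    min_maf: float = 0.01,
) -> tuple[pd.DataFrame, QCReport]:
    """Remove SNPs with missing > ``max_missing``, het > ``max_het`` or
    MAF < ``min_maf`` (all strict comparisons, computed on non-missing
    calls).  Filters are attributed in the order missing, het, MAF, so a
    SNP failing several gets the first reason.  Lines are never removed.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    missing_frac, het_frac, maf = _snp_stats(matrix)
    reason = np.full(matrix.shape[1], "", dtype=object)
    reason[np.isnan(maf) | (maf < min_maf)] = "maf"
    reason[het_frac > max_het] = "het"
    reason[missing_frac > max_missing] = "missing"
    kept = reason == ""
    report = QCReport(
        pd.DataFrame(
            {
                "snp": matrix.columns,
                "missing_frac": missing_frac,
                "het_frac": het_frac,
                "maf": maf,
                "kept": kept,
                "reason": reason,
            }
        )
    )
    return matrix.loc[:, kept], report


def encode_ibs(raw_calls: pd.DataFrame, panel: FounderPanel) -> pd.DataFrame:
    """Two-letter allele calls -> reference-founder allele dosage.

    ``raw_calls`` holds diploid calls like ``"AA"``, ``"AB"``, ``"BB"``;
    empty strings (or NaN) are missing and stay missing (NaN).
    """
    unknown = [s for s in raw_calls.columns if s not in panel.allele_table.columns]
    if unknown:
        raise KeyError(f"SNPs absent from founder panel: {unknown[:5]}")
    ref = np.array([panel.reference_allele(s) for s in raw_calls.columns])
    calls = raw_calls.fillna("").to_numpy(dtype=object)
    dosage = np.full(calls.shape, np.nan)
    for i in range(calls.shape[0]):
        row = calls[i]
        ok = row != ""
        a1 = np.array([c[0] if c else "" for c in row], dtype=object)
        a2 = np.array([c[1] if len(c) > 1 else "" for c in row], dtype=object)
        dosage[i, ok] = ((a1 == ref).astype(int) + (a2 == ref).astype(int))[ok]
    return pd.DataFrame(dosage, index=raw_calls.index, columns=raw_calls.columns)


def impute_mni(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean imputation: each missing cell <- that SNP's mean dosage across lines.

    Raises if any SNP is entirely missing (such SNPs should have been
    removed by :func:`qc_filter`).
    """
    x = matrix.to_numpy(dtype=float)
    all_missing = np.all(np.isnan(x), axis=0)
    if all_missing.any():
        snp = matrix.columns[all_missing][0]
        raise ValueError(f"SNP {snp!r} has no observed calls; run qc_filter first")
    means = np.nanmean(x, axis=0)
    out = np.where(np.isnan(x), means[None, :], x)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def assign_unmapped(
    snp: pd.Series,
    mapped: pd.DataFrame,
    gmap: GeneticMap,
    alpha: float = 0.05,
) -> tuple[str, float] | None:
    """Place an unmapped SNP at the position of its best chi-square anchor.

    For each mapped SNP a 2x2 contingency of homozygous dosage classes
    (query 0/2 vs anchor 0/2, lines with either call heterozygous or
    missing excluded) is tested; the anchor with the largest chi-square
    statistic wins, ties broken by smaller p then map order.  If the best
    association is not significant at a Bonferroni-corrected ``alpha``
    across anchors, the SNP is left unassigned (returns None).
    """
    q = snp.to_numpy(dtype=float)
    q_hom = (q == 0) | (q == 2)
    best = None  # (chi2, p, order, anchor)
    n_anchor = 0
    for anchor in mapped.columns:
        if anchor not in gmap:
            continue
        a = mapped[anchor].to_numpy(dtype=float)
        ok = q_hom & ((a == 0) | (a == 2))
        if ok.sum() < 4:
            continue
        n_anchor += 1
        tab = pd.crosstab(q[ok], a[ok]).to_numpy()
        if tab.shape != (2, 2):
            continue
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        key = (-chi2, p, gmap.order_key(anchor))
        if best is None or key < best[0]:
            best = (key, anchor, p)
    if best is None or n_anchor == 0:
        return None
    _, anchor, p = best
    if p > alpha / n_anchor:
        return None
    return gmap.chromosome(anchor), gmap.position(anchor)
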