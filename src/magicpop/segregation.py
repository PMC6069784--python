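"""Allele-frequency groups, segregation distortion, SDRs and founder selection.

Bi-allelic SNPs in an 8-way MAGIC population do not segregate 1:1; the
expected frequency of the reference-founder allele is k/8 where k is the
number of founders carrying it (the allele-frequency group, AFG 1..7).
Segregation distortion is tested per SNP with a 1-df chi-square of allele
counts against (k/8, 1-k/8), Bonferroni-Holm corrected genome-wide.  A
segregation-distortion region (SDR) is a run of at least three adjacent
mapped SNPs significant after correction, and AFG 1/7 SNPs trace
distortion to a single founder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .founders import FounderPanel
from .genmap import GeneticMap

__all__ = [
    "assign_afg",
    "unique_snp_summary",
    "sd_test",
    "SDRegion",
    "detect_sdr",
    "founder_selection_events",
]


def assign_afg(panel: FounderPanel) -> pd.DataFrame:
    """AFG table: per SNP the carrier count k, expected frequency k/8 and,
    for k in {1, 7}, the unique founder (reference founder for k = 1; the
    sole non-carrier for k = 7).  SNPs monomorphic among the founders
    (k in {0, 8}) are excluded; k = 8 cannot occur in a valid panel.
    """
    carrier = panel.ref_carrier
    k = carrier.sum(axis=0).astype(int)
    keep = (k >= 1) & (k <= 7)
    k = k[keep]
    # carriers per funnel side (crossing positions A-D vs E-H); the split
    # determines the null dosage variance used by sd_test
    k_abcd = carrier.iloc[:4].sum(axis=0).astype(int)[k.index]
    unique = pd.Series("", index=k.index, dtype=object)
    unique[k == 1] = panel.reference_founder
    k7 = k.index[k == 7]
    if len(k7):
        non_carrier = (~carrier.loc[:, k7]).idxmax(axis=0)
        unique[k7] = non_carrier
    return pd.DataFrame(
        {
            "snp": k.index,
            "afg": k.to_numpy(),
            "expected_freq": k.to_numpy() / 8.0,
            "unique_founder": unique.to_numpy(),
            "k_abcd": k_abcd.to_numpy(),
            "k_efgh": (k - k_abcd).to_numpy(),
        }
    ).reset_index(drop=True)


def unique_snp_summary(afg_counts: dict[int, int]) -> dict[str, float]:
    """Unique-SNP accounting from per-AFG SNP counts.

    Unique SNPs are those traceable to a single founder, i.e. AFG 1 plus
    AFG 7; the percentage is reported to one decimal, the precision such
    tables are printed at.
    """
    total = sum(afg_counts.values())
    if total == 0:
        raise ValueError("empty AFG counts")
    n_unique = afg_counts.get(1, 0) + afg_counts.get(7, 0)
    return {
        "n_unique": int(n_unique),
        "n_total": int(total),
        "percent_unique": round(100.0 * n_unique / total, 1),
    }


def sd_test(
    matrix: pd.DataFrame,
    afg: pd.DataFrame,
    calibration: float | str = "funnel",
) -> pd.DataFrame:
    """Per-SNP segregation-distortion chi-square on unimputed calls.

    Observed reference-allele count = sum of dosages over non-missing
    lines, out of 2 x n_nonmissing alleles; expected proportions are
    (k/8, 1-k/8).  Bonferroni-Holm is applied across all tested SNPs.

    The naive 2N-allele chi-square is anticonservative on inbred lines:
    the two alleles of a line are correlated, inflating the count
    variance.  ``calibration`` controls the null variance:

    - ``"funnel"`` (default): exact funnel-design dosage variance per SNP,
      Var(d) = (1-h)*4p(1-p) + h*[qA(1-qA) + qB(1-qB)], where qA, qB are
      the carrier fractions on the two funnel sides (from the AFG table's
      side split) and h, the residual origin heterozygosity, is estimated
      genome-wide from observed heterozygote counts.
    - ``"count"``: the uncorrected textbook allele-count chi-square.
    - a number F in [0, 1]: divide the count chi-square by (1 + F).
    """
    afg_idx = afg.set_index("snp")
    missing = [s for s in matrix.columns if s not in afg_idx.index]
    if missing:
        raise KeyError(f"SNPs absent from AFG table: {missing[:5]}")
    x = matrix.to_numpy(dtype=float)
    n_obs = (~np.isnan(x)).sum(axis=0)
    ref = np.nansum(x, axis=0)
    tot = 2.0 * n_obs
    k = afg_idx.loc[matrix.columns, "afg"].to_numpy(dtype=float)
    exp_p = k / 8.0
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_p = np.where(tot > 0, ref / tot, np.nan)
        chi2 = (ref - tot * exp_p) ** 2 / (tot * exp_p) + (
            (tot - ref) - tot * (1 - exp_p)
        ) ** 2 / (tot * (1 - exp_p))
    if calibration == "funnel":
        if not {"k_abcd", "k_efgh"}.issubset(afg_idx.columns):
            raise ValueError("AFG table lacks the funnel side split columns")
        qa = afg_idx.loc[matrix.columns, "k_abcd"].to_numpy(dtype=float) / 4.0
        qb = afg_idx.loc[matrix.columns, "k_efgh"].to_numpy(dtype=float) / 4.0
        het_factor = qa * (1 - qb) + (1 - qa) * qb
        het_obs = np.nansum(x == 1, axis=0) / np.maximum(n_obs, 1)
        denom = het_factor.sum()
        h_hat = float(np.clip(het_obs.sum() / denom, 0.0, 1.0)) if denom > 0 else 0.0
        var_d = (1 - h_hat) * 4 * exp_p * (1 - exp_p) + h_hat * (
            qa * (1 - qa) + qb * (1 - qb)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = (ref - tot * exp_p) ** 2 / (n_obs * var_d)
    elif calibration == "count":
        pass
    else:
        f = float(calibration)
        if not 0.0 <= f <= 1.0:
            raise ValueError("inbreeding coefficient must be in [0, 1]")
        chi2 = chi2 / (1.0 + f)
    p = stats.chi2.sf(chi2, df=1)
    ok = np.isfinite(p)
    p_adj = np.full_like(p, np.nan)
    if ok.any():
        p_adj[ok] = multipletests(p[ok], method="holm")[1]
    deviation = obs_p - exp_p
    return pd.DataFrame(
        {
            "snp": matrix.columns,
            "afg": k.astype(int),
            "ref_count": ref,
            "total_count": tot,
            "observed_freq": obs_p,
            "expected_freq": exp_p,
            "chi_square": chi2,
            "p": p,
            "p_adjusted": p_adj,
            "direction": np.sign(deviation).astype(int),
            "deviation": deviation,
        }
    )


@dataclass(frozen=True)
class SDRegion:
    chromosome: str
    start_cm: float
    end_cm: float
    snps: tuple[str, ...]
    mean_deviation: float

    @property
    def n_snps(self) -> int:
        return len(self.snps)


def detect_sdr(
    results: pd.DataFrame,
    gmap: GeneticMap,
    min_run: int = 3,
    alpha: float = 0.01,
) -> list[SDRegion]:
    """Maximal runs of >= ``min_run`` consecutive mapped SNPs with
    ``p_adjusted`` < ``alpha`` become regions (per chromosome, map order).
    Distortion direction is not required to be uniform within a region.
    """
    res = results.set_index("snp")
    regions: list[SDRegion] = []
    for chrom in gmap.chromosomes:
        snps = [s for s in gmap.snps_on(chrom) if s in res.index]
        if not snps:
            continue
        sig = (res.loc[snps, "p_adjusted"] < alpha).to_numpy()
        i = 0
        while i < len(snps):
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(snps) and sig[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                members = tuple(snps[i:j + 1])
                regions.append(
                    SDRegion(
                        chromosome=chrom,
                        start_cm=gmap.position(members[0]),
                        end_cm=gmap.position(members[-1]),
                        snps=members,
                        mean_deviation=float(
                            res.loc[list(members), "deviation"].mean()
                        ),
                    )
                )
            i = j + 1
    return regions


def founder_selection_events(
    results: pd.DataFrame,
    afg: pd.DataFrame,
    gmap: GeneticMap,
    min_snps: int = 10,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Chromosome-level selection for or against a single founder's allele.

    Significant AFG 1/7 SNPs are grouped by (chromosome, unique founder,
    direction of that founder's allele-frequency change); for AFG 7 an
    excess of the reference allele is a *deficit* of the unique non-carrier
    founder's allele, so the direction is inverted.  Groups with strictly
    more than ``min_snps`` members are reported.
    """
    merged = results.merge(
        afg[["snp", "unique_founder"]], on="snp", how="left", suffixes=("", "_afg")
    )
    uni = merged[
        merged["afg"].isin([1, 7])
        & (merged["p_adjusted"] < alpha)
        & (merged["unique_founder"] != "")
    ].copy()
    if uni.empty:
        return pd.DataFrame(columns=["chromosome", "founder", "direction", "n_snps"])
    uni["chromosome"] = [gmap.chromosome(s) if s in gmap else "" for s in uni["snp"]]
    uni = uni[uni["chromosome"] != ""]
    founder_dir = np.where(uni["afg"] == 1, uni["direction"], -uni["direction"])
    uni["founder_direction"] = founder_dir
    grouped = (
        uni.groupby(["chromosome", "unique_founder", "founder_direction"])
        .size()
        .reset_index(name="n_snps")
    )
    events = grouped[grouped["n_snps"] > min_snps].rename(
        columns={"unique_founder": "founder", "founder_direction": "direction"}
    )
    return events.reset_index(drop=True)
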