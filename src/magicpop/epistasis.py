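"""Di-genic epistasis scan and additive-by-additive effect estimation.

The scan proceeds in stages: (1) prescreen SNPs by single-marker
regression at p < 0.15; (2) test every candidate pair with the model
``trait ~ x1 + x2 + x1*x2`` on centered dosages, recording the
interaction-term p-value and applying Benjamini-Hochberg FDR across all
pairs (significant at adjusted p <= 0.01); (3) jointly re-select the
significant product terms by forward/backward selection; (4) merge
interactions whose endpoint SNPs co-locate within 7 cM.

The additive-by-additive effect of a pair is the contrast of the four
homozygous two-locus class means,

    aa = (JJ + NN) - (JN + NJ)

where J/N denote lines fixed for the reference-founder / alternative
allele.  If exactly one mixed class is empty (as happens when double
dwarfs were removed), the missing mixed-class sum term is substituted by
twice the mean of the other mixed class and the record is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genmap import GeneticMap

__all__ = [
    "prescreen",
    "pairwise_scan",
    "select_interactions",
    "group_interactions",
    "aa_from_class_means",
    "aa_effect",
    "epistatic_variance",
]


def _aligned(means: pd.Series, genotypes: pd.DataFrame):
    y = means.loc[genotypes.index].to_numpy(dtype=float)
    return y


def prescreen(
    means: pd.Series, genotypes: pd.DataFrame, alpha: float = 0.15
) -> list[str]:
    """SNPs whose single-marker regression on the trait has p < ``alpha``."""
    y = _aligned(means, genotypes)
    yc = y - y.mean()
    X = genotypes.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    n = len(y)
    sst = yc @ yc
    norm2 = (Xc**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(norm2 > 0, (Xc.T @ yc) ** 2 / (norm2 * sst), 0.0)
    r2 = np.clip(r2, 0, 1 - 1e-12)
    F = r2 * (n - 2) / (1 - r2)
    p = stats.f.sf(F, 1, n - 2)
    return [s for s, keep in zip(genotypes.columns, p < alpha) if keep]


def pairwise_scan(
    means: pd.Series,
    genotypes: pd.DataFrame,
    candidates: list[str],
    fdr_alpha: float = 0.01,
) -> pd.DataFrame:
    """Interaction p-value for every unordered candidate pair.

    Each pair is fitted as ``y ~ x1 + x2 + x1*x2`` on centered dosages;
    the product-term p is Benjamini-Hochberg adjusted across all tested
    pairs.  Pairs with an empty design cell are still tested through the
    product term; the aa NA rule handles them downstream.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    y = _aligned(means, genotypes)
    yc = y - y.mean()
    Xc = {
        s: genotypes[s].to_numpy(dtype=float)
        - genotypes[s].to_numpy(dtype=float).mean()
        for s in candidates
    }
    n = len(y)
    rows = []
    for s1, s2 in combinations(candidates, 2):
        x1, x2 = Xc[s1], Xc[s2]
        inter = x1 * x2
        design = np.column_stack([x1, x2, inter - inter.mean()])
        beta, _, rank, _ = np.linalg.lstsq(design, yc, rcond=None)
        resid = yc - design @ beta
        dfe = n - design.shape[1] - 1
        if dfe <= 0 or rank < design.shape[1]:
            p_int = 1.0
        else:
            s2e = resid @ resid / dfe
            cov = np.linalg.pinv(design.T @ design) * s2e
            se = np.sqrt(max(cov[2, 2], 1e-300))
            p_int = 2 * stats.t.sf(abs(beta[2]) / se, dfe)
        a, b = sorted((s1, s2))  # canonical orientation for stable output
        rows.append((a, b, p_int))
    out = pd.DataFrame(rows, columns=["snp1", "snp2", "p"])
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p_fdr"] <= fdr_alpha
    return out


def select_interactions(
    pairs: pd.DataFrame,
    means: pd.Series,
    genotypes: pd.DataFrame,
    alpha: float = 0.01,
    gmap: GeneticMap | None = None,
) -> pd.DataFrame:
    """Joint forward/backward selection over the significant product terms.

    The joint model always contains the main effects of every SNP involved
    in a significant pair; product terms are added by smallest partial p
    (<= ``alpha``) and dropped when their partial p rises above ``alpha``.
    Ties break by map position of the pair's first SNP, then snp ids.
    """
    sig = pairs[pairs["significant"]].reset_index(drop=True)
    if sig.empty:
        return sig.assign(selected=pd.Series(dtype=bool)).iloc[0:0]
    y = _aligned(means, genotypes)
    yc = y - y.mean()
    snps = sorted(set(sig["snp1"]) | set(sig["snp2"]))
    M = genotypes[snps].to_numpy(dtype=float)
    M = M - M.mean(axis=0)
    col = {s: i for i, s in enumerate(snps)}
    # collinear main effects (LD proxies) would zero the joint design's
    # rank; keep one representative column of each collinear family
    keep_cols: list[int] = []
    resid = M.copy()
    for i in range(M.shape[1]):
        nrm = np.linalg.norm(resid[:, i])
        if nrm > 1e-8 * max(np.linalg.norm(M[:, i]), 1e-30):
            keep_cols.append(i)
            q = resid[:, i] / nrm
            resid = resid - np.outer(q, q @ resid)
    M_main = M[:, keep_cols]
    terms = []
    for _, r in sig.iterrows():
        prod = M[:, col[r["snp1"]]] * M[:, col[r["snp2"]]]
        terms.append(prod - prod.mean())
    T = np.column_stack(terms)
    n = len(y)

    def keyfun(i):
        s1, s2 = sig.loc[i, "snp1"], sig.loc[i, "snp2"]
        if gmap is not None and s1 in gmap:
            return (gmap.order_key(s1), s1, s2)
        return (0, s1, s2)

    selected: list[int] = []
    changed = True
    guard = 0
    while changed and guard < 100:
        guard += 1
        changed = False
        # forward over product terms
        while True:
            remaining = [i for i in range(T.shape[1]) if i not in selected]
            if not remaining:
                break
            best = None
            for i in remaining:
                design = np.column_stack([M_main, T[:, selected + [i]]])
                p = _last_term_p(design, yc, n)
                cand = (p, keyfun(i), i)
                if best is None or cand < best:
                    best = cand
            if best is None or best[0] > alpha:
                break
            selected.append(best[2])
            changed = True
        # backward over product terms
        while selected:
            worst = None
            for pos, i in enumerate(selected):
                others = [j for j in selected if j != i]
                design = np.column_stack([M_main, T[:, others + [i]]])
                p = _last_term_p(design, yc, n)
                if worst is None or p > worst[0]:
                    worst = (p, pos)
            if worst is None or worst[0] <= alpha:
                break
            del selected[worst[1]]
            changed = True
    out = sig.loc[sorted(selected)].reset_index(drop=True)
    return out


def _last_term_p(design: np.ndarray, yc: np.ndarray, n: int) -> float:
    """Partial p-value of the last design column (centered design)."""
    beta, _, rank, _ = np.linalg.lstsq(design, yc, rcond=None)
    if rank < design.shape[1]:
        return 1.0  # collinear term: never enters, always drops
    resid = yc - design @ beta
    dfe = n - design.shape[1] - 1
    if dfe <= 0:
        return 1.0
    s2e = resid @ resid / dfe
    cov = np.linalg.pinv(design.T @ design) * s2e
    se = np.sqrt(max(cov[-1, -1], 1e-300))
    return float(2 * stats.t.sf(abs(beta[-1]) / se, dfe))


def group_interactions(
    pairs: pd.DataFrame,
    gmap: GeneticMap,
    window_cm: float = 7.0,
) -> pd.DataFrame:
    """Merge interactions whose endpoints co-locate within ``window_cm``.

    Two pairs merge when, in one of the two endpoint orientations, both
    endpoints lie on the same chromosomes within the window of the other's
    corresponding endpoints; merging is single linkage and the
    representative pair is the one with the lowest FDR-adjusted p.
    """
    if pairs.empty:
        return pairs.copy()
    locs = []
    for _, r in pairs.iterrows():
        locs.append(
            (
                (gmap.chromosome(r["snp1"]), gmap.position(r["snp1"])),
                (gmap.chromosome(r["snp2"]), gmap.position(r["snp2"])),
            )
        )

    def close(a, b):
        return a[0] == b[0] and abs(a[1] - b[1]) <= window_cm

    n = len(pairs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (a1, a2), (b1, b2) = locs[i], locs[j]
            if (close(a1, b1) and close(a2, b2)) or (
                close(a1, b2) and close(a2, b1)
            ):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    reps = []
    for members in groups.values():
        block = pairs.iloc[members]
        rep = block.loc[block["p_fdr"].idxmin()].copy()
        rep["n_merged"] = len(members)
        reps.append(rep)
    out = pd.DataFrame(reps).reset_index(drop=True)
    return out.sort_values("p_fdr").reset_index(drop=True)


def aa_from_class_means(jj: float, nn: float, jn: float, nj: float) -> float:
    """Additive-by-additive effect from the four homozygous class means."""
    return (jj + nn) - (jn + nj)


def _classify(dosage: np.ndarray) -> np.ndarray:
    """+1 reference homozygote (>=1.5), -1 alternative (<=0.5), 0 excluded."""
    out = np.zeros(len(dosage), dtype=int)
    out[dosage >= 1.5] = 1
    out[dosage <= 0.5] = -1
    out[np.isnan(dosage)] = 0
    return out


def aa_effect(
    genotypes: pd.DataFrame,
    means: pd.Series,
    snp1: str,
    snp2: str,
) -> dict:
    """Class means, aa effect and the NA-substitution flag for one pair.

    Lines are classified as homozygous reference (dosage >= 1.5) or
    alternative (<= 0.5) at each locus; intermediates are excluded from
    class means.  If exactly one mixed class (JN or NJ) is empty its sum
    term is replaced by twice the other mixed class's mean; an empty
    homozygous class leaves aa undefined (raises).
    """
    y = _aligned(means, genotypes)
    c1 = _classify(genotypes[snp1].to_numpy(dtype=float))
    c2 = _classify(genotypes[snp2].to_numpy(dtype=float))

    def cls_mean(a, b):
        sel = (c1 == a) & (c2 == b)
        return float(y[sel].mean()) if sel.any() else np.nan

    jj, nn = cls_mean(1, 1), cls_mean(-1, -1)
    jn, nj = cls_mean(1, -1), cls_mean(-1, 1)
    if np.isnan(jj) or np.isnan(nn):
        raise ValueError(
            f"empty homozygous class for pair ({snp1}, {snp2}); aa undefined"
        )
    na_rule_used = False
    if np.isnan(jn) and np.isnan(nj):
        raise ValueError(
            f"both mixed classes empty for pair ({snp1}, {snp2}); aa undefined"
        )
    if np.isnan(jn) or np.isnan(nj):
        mixed_sum = 2.0 * (nj if np.isnan(jn) else jn)
        na_rule_used = True
    else:
        mixed_sum = jn + nj
    aa = (jj + nn) - mixed_sum
    return {
        "snp1": snp1,
        "snp2": snp2,
        "JJ": jj,
        "NN": nn,
        "JN": jn,
        "NJ": nj,
        "aa": aa,
        "na_rule_used": na_rule_used,
    }


def epistatic_variance(
    genotypes: pd.DataFrame,
    means: pd.Series,
    snp1: str,
    snp2: str,
) -> float:
    """Percent of the pair's genotype-class sum of squares attributable to
    the interaction.

    On homozygous-classified lines, SS(genotypes) is the between-class sum
    of squares of the four two-locus classes and SS(interaction) the extra
    sum of squares of the interaction term over the two main effects;
    returns 100 * SS_int / SS_geno.
    """
    y = _aligned(means, genotypes)
    c1 = _classify(genotypes[snp1].to_numpy(dtype=float)).astype(float)
    c2 = _classify(genotypes[snp2].to_numpy(dtype=float)).astype(float)
    keep = (c1 != 0) & (c2 != 0)
    if keep.sum() < 5:
        raise ValueError("too few homozygous-classified lines")
    yk, a, b = y[keep], c1[keep], c2[keep]
    classes = (a > 0).astype(int) * 2 + (b > 0).astype(int)
    if len(np.unique(classes)) < 4:
        raise ValueError("degenerate two-locus classification")
    yc = yk - yk.mean()

    def rss(cols):
        if not cols:
            return float(yc @ yc)
        D = np.column_stack(cols)
        D = D - D.mean(axis=0)
        beta, *_ = np.linalg.lstsq(D, yc, rcond=None)
        return float(np.sum((yc - D @ beta) ** 2))

    rss_null = rss([])
    rss_main = rss([a, b])
    rss_full = rss([a, b, a * b])
    ss_geno = rss_null - rss_full
    ss_int = rss_main - rss_full
    if ss_geno <= 0:
        raise ValueError("no between-class variance; R2_epi undefined")
    return 100.0 * max(ss_int, 0.0) / ss_geno
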