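"""Cross-validated stepwise multiple-regression association scan.

The scan ("Model-A": no kinship or structure covariates) regresses line
means on SNP dosages with stepwise forward/backward selection at
p <= 0.001, repeated over 20 x 5-fold cross-validation (100 model fits on
80% training sets).  A SNP is a marker-trait association (MTA) when it is
selected in at least 35 of the 100 fits (detection rate >= 35%) and its
Bonferroni-Holm adjusted p-value from a full-data refit is < 0.01.  MTAs
within 5 cM on one chromosome with same-sign effects are grouped into a
QTL.  The reported effect of a SNP is the homozygous contrast: mean of
lines carrying two reference-founder alleles minus mean of lines carrying
none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genmap import GeneticMap

__all__ = ["ScanConfig", "ScanResult", "stepwise_fit", "cross_validated_scan",
           "call_mtas_and_group"]

_NORM_TOL = 1e-8  # relative residual-norm floor below which a SNP is collinear


@dataclass(frozen=True)
class ScanConfig:
    p_enter: float = 0.001
    p_stay: float = 0.001
    cv_repeats: int = 20
    cv_folds: int = 5
    detection_threshold: int = 35
    mta_alpha: float = 0.01
    qtl_window_cm: float = 5.0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("p_enter", "p_stay", "mta_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.cv_repeats < 1 or self.cv_folds < 2:
            raise ValueError("need >= 1 repeat and >= 2 folds")
        if not 0 <= self.detection_threshold <= self.cv_repeats * self.cv_folds:
            raise ValueError("detection_threshold outside [0, repeats*folds]")

    @property
    def n_fits(self) -> int:
        return self.cv_repeats * self.cv_folds


def _order_keys(snp_ids, gmap: GeneticMap | None):
    """Deterministic candidate ordering: map position, then snp id."""
    if gmap is None:
        return {s: (0, 0.0, s) for s in snp_ids}
    keys = {}
    chrom_rank = {c: i for i, c in enumerate(gmap.chromosomes)}
    for s in snp_ids:
        if s in gmap:
            keys[s] = (chrom_rank[gmap.chromosome(s)], gmap.position(s), s)
        else:
            keys[s] = (len(chrom_rank), np.inf, s)
    return keys


def _ols_partial_p(Xsel: np.ndarray, y: np.ndarray):
    """Coefficients and partial-F (= t**2) p-values of each column of a
    centered design, intercept implicit."""
    n, k = Xsel.shape
    beta, _, rank, _ = np.linalg.lstsq(Xsel, y, rcond=None)
    resid = y - Xsel @ beta
    dfe = n - k - 1  # centered data: intercept already absorbed
    if dfe <= 0:
        return beta, np.ones(k), resid
    s2 = resid @ resid / dfe
    xtx_inv = np.linalg.pinv(Xsel.T @ Xsel)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * s2, 1e-300))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dfe)
    return beta, p, resid


def stepwise_fit(
    means: pd.Series,
    genotypes: pd.DataFrame,
    p_enter: float = 0.001,
    p_stay: float = 0.001,
    gmap: GeneticMap | None = None,
    max_terms: int | None = None,
) -> pd.DataFrame:
    """Forward/backward stepwise selection of SNPs for a trait.

    Forward steps add the candidate with the smallest partial-F p-value if
    it is <= ``p_enter``; backward steps drop any selected SNP whose
    partial p-value rises above ``p_stay``; iterate to a fixed point.
    Ties are broken by lower map position then lexicographic snp id, so the
    procedure is deterministic.  Collinear candidates (residual norm below
    tolerance) are skipped.  Returns a table (snp, coef, p) in selection
    order; coefficients are per dosage unit on the centered design.
    """
    y0 = means.loc[genotypes.index].to_numpy(dtype=float)
    X0 = genotypes.to_numpy(dtype=float)
    n, m = X0.shape
    y = y0 - y0.mean()
    X = X0 - X0.mean(axis=0)
    orig_norm2 = (X**2).sum(axis=0)
    snp_ids = list(genotypes.columns)
    keys = _order_keys(snp_ids, gmap)
    sorted_cols = sorted(range(m), key=lambda j: keys[snp_ids[j]])
    order_rank = np.empty(m, dtype=int)
    order_rank[sorted_cols] = np.arange(m)  # rank of each column in map order

    if max_terms is None:
        max_terms = min(n - 3, m, 60)
    selected: list[int] = []
    Xres = X.copy()
    yres = y.copy()
    sst = y @ y
    if sst <= 0:
        return pd.DataFrame(columns=["snp", "coef", "p"])

    def rebuild():
        nonlocal Xres, yres
        if selected:
            Q, _ = np.linalg.qr(X[:, selected])
            Xres = X - Q @ (Q.T @ X)
            yres = y - Q @ (Q.T @ y)
        else:
            Xres = X.copy()
            yres = y.copy()

    changed = True
    guard = 0
    while changed and guard < 200:
        guard += 1
        changed = False
        # ---- forward ----
        while len(selected) < max_terms:
            k = len(selected)
            dfe = n - k - 2
            if dfe <= 0:
                break
            norm2 = (Xres**2).sum(axis=0)
            eligible = norm2 > _NORM_TOL * np.maximum(orig_norm2, 1e-30)
            eligible[selected] = False
            ynorm2 = yres @ yres
            if not eligible.any() or ynorm2 <= 1e-12 * sst:
                break
            num = Xres.T @ yres
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = np.where(eligible, num**2 / (norm2 * ynorm2), 0.0)
            r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
            F = r2 * dfe / (1.0 - r2)
            p = stats.f.sf(F, 1, dfe)
            p[~eligible] = np.inf
            pmin = p.min()
            if not np.isfinite(pmin) or pmin > p_enter:
                break
            tied = np.flatnonzero(p <= pmin * (1 + 1e-9) + 1e-300)
            j = int(tied[np.argmin(order_rank[tied])])
            selected.append(j)
            changed = True
            q = Xres[:, j] / np.sqrt(norm2[j])
            yres = yres - q * (q @ yres)
            Xres = Xres - np.outer(q, q @ Xres)
        # ---- backward ----
        while selected:
            _, pvals, _ = _ols_partial_p(X[:, selected], y)
            worst = int(np.argmax(pvals))
            if pvals[worst] <= p_stay:
                break
            del selected[worst]
            changed = True
            rebuild()
    beta, pvals, _ = (
        _ols_partial_p(X[:, selected], y)
        if selected
        else (np.array([]), np.array([]), y)
    )
    return pd.DataFrame(
        {"snp": [snp_ids[j] for j in selected], "coef": beta, "p": pvals}
    )


@dataclass
class ScanResult:
    detection: pd.Series            # per-SNP selection count over all fits
    r2_val: pd.Series               # mean held-out partial R2 (%), where selected
    final_model: pd.DataFrame       # snp, coef, p, p_adjusted, effect
    config: ScanConfig
    n_fits_done: int
    skipped_folds: int = 0

    @property
    def detection_rate(self) -> pd.Series:
        return 100.0 * self.detection / self.config.n_fits


def _holdout_partial_r2(y_val, X_val):
    """Semi-partial R2 of each design column, refit on the held-out fold."""
    yc = y_val - y_val.mean()
    Xc = X_val - X_val.mean(axis=0)
    sst = yc @ yc
    if sst <= 0:
        return np.zeros(X_val.shape[1])
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    rss_full = np.sum((yc - Xc @ beta) ** 2)
    out = np.empty(Xc.shape[1])
    for j in range(Xc.shape[1]):
        Xj = np.delete(Xc, j, axis=1)
        if Xj.shape[1]:
            bj, *_ = np.linalg.lstsq(Xj, yc, rcond=None)
            rss_red = np.sum((yc - Xj @ bj) ** 2)
        else:
            rss_red = sst
        out[j] = max(rss_red - rss_full, 0.0) / sst
    return out


def _holm_genomewide(p: np.ndarray, m_family: int) -> np.ndarray:
    """Bonferroni-Holm with the family = all scanned SNPs.

    The scan tests every SNP, so correcting the selected SNPs' p-values
    only among themselves would ignore the selection; the step-down
    factors therefore run from ``m_family`` downward (unselected SNPs
    implicitly carry larger p-values).
    """
    order = np.argsort(p)
    adj = np.empty_like(p, dtype=float)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(p[idx] * (m_family - rank), 1.0))
        adj[idx] = running
    return adj


def _homozygous_effect(y: np.ndarray, dosage: np.ndarray) -> float:
    """Mean(lines with dosage ~2) - mean(lines with dosage ~0)."""
    hi = dosage >= 1.5
    lo = dosage <= 0.5
    if not hi.any() or not lo.any():
        return float("nan")
    return float(y[hi].mean() - y[lo].mean())


def cross_validated_scan(
    means: pd.Series,
    genotypes: pd.DataFrame,
    config: ScanConfig = ScanConfig(),
    gmap: GeneticMap | None = None,
) -> ScanResult:
    """Run the stepwise scan over repeated cross-validation training sets.

    Detection count = number of the ``repeats x folds`` fits whose final
    model contains the SNP.  R2_val of a SNP = mean, over the fits that
    selected it, of its semi-partial coefficient of determination refit on
    the corresponding held-out fold (percent).  Final p-values come from a
    single stepwise fit on all lines, Bonferroni-Holm adjusted with the
    family of all scanned SNPs.
    """
    y = means.loc[genotypes.index].to_numpy(dtype=float)
    rng = np.random.default_rng(config.rng_seed)
    n = len(y)
    snp_ids = list(genotypes.columns)
    detection = pd.Series(0, index=snp_ids, dtype=int)
    r2_sum = pd.Series(0.0, index=snp_ids)
    r2_n = pd.Series(0, index=snp_ids, dtype=int)
    skipped = 0

    for _ in range(config.cv_repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, config.cv_folds)
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            sel = stepwise_fit(
                means, genotypes.iloc[mask], config.p_enter, config.p_stay,
                gmap=gmap,
            )
            chosen = list(sel["snp"])
            detection[chosen] += 1
            if not chosen:
                continue
            if len(fold) < 2 * (len(chosen) + 1):
                skipped += 1
                continue
            r2 = _holdout_partial_r2(
                y[fold], genotypes.iloc[fold][chosen].to_numpy(dtype=float)
            )
            r2_sum[chosen] += r2
            r2_n[chosen] += 1

    with np.errstate(invalid="ignore"):
        r2_val = 100.0 * r2_sum / r2_n.replace(0, np.nan)

    final = stepwise_fit(means, genotypes, config.p_enter, config.p_stay, gmap=gmap)
    if len(final):
        final["p_adjusted"] = _holm_genomewide(
            final["p"].to_numpy(), len(snp_ids)
        )
        final["effect"] = [
            _homozygous_effect(y, genotypes[s].to_numpy(dtype=float))
            for s in final["snp"]
        ]
    else:
        final["p_adjusted"] = pd.Series(dtype=float)
        final["effect"] = pd.Series(dtype=float)
    return ScanResult(
        detection=detection,
        r2_val=r2_val,
        final_model=final,
        config=config,
        n_fits_done=config.n_fits,
        skipped_folds=skipped,
    )


def call_mtas_and_group(
    result: ScanResult,
    gmap: GeneticMap,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Threshold MTAs and group them into QTL.

    MTAs are final-model SNPs with detection count >= threshold and
    adjusted p < ``mta_alpha``.  Single-linkage grouping joins MTAs on the
    same chromosome within the QTL window whose effects share a sign; the
    representative SNP is the one with the lowest adjusted p.
    """
    if config is None:
        config = result.config
    fm = result.final_model
    if fm.empty:
        return _empty_qtl_table()
    mta = fm[
        (result.detection[fm["snp"]].to_numpy() >= config.detection_threshold)
        & (fm["p_adjusted"] < config.mta_alpha)
        & fm["snp"].isin(gmap.snp_ids)
    ].copy()
    if mta.empty:
        return _empty_qtl_table()
    mta["chrom"] = [gmap.chromosome(s) for s in mta["snp"]]
    mta["pos"] = [gmap.position(s) for s in mta["snp"]]
    mta["sign"] = np.sign(mta["effect"]).astype(int)

    records = []
    for (chrom, sign), grp in mta.groupby(["chrom", "sign"]):
        grp = grp.sort_values("pos")
        cluster: list[pd.Series] = []
        clusters = []
        for _, row in grp.iterrows():
            if cluster and row["pos"] - cluster[-1]["pos"] > config.qtl_window_cm:
                clusters.append(cluster)
                cluster = []
            cluster.append(row)
        if cluster:
            clusters.append(cluster)
        for members in clusters:
            tab = pd.DataFrame(members)
            rep = tab.loc[tab["p_adjusted"].idxmin()]
            records.append(
                {
                    "snp": rep["snp"],
                    "chrom": chrom,
                    "pos": rep["pos"],
                    "range_min": tab["pos"].min(),
                    "range_max": tab["pos"].max(),
                    "n_members": len(tab),
                    "detection_rate": float(
                        result.detection_rate[rep["snp"]]
                    ),
                    "p_adjusted": rep["p_adjusted"],
                    "effect": rep["effect"],
                    "r2_val": float(result.r2_val.get(rep["snp"], np.nan)),
                    "members": ",".join(tab["snp"]),
                }
            )
    out = pd.DataFrame(records)
    out = out.sort_values(["chrom", "pos"]).reset_index(drop=True)
    out.insert(0, "qtl", [f"QTL.{r.chrom}.{i + 1}" for i, r in out.iterrows()])
    return out


def _empty_qtl_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "qtl", "snp", "chrom", "pos", "range_min", "range_max", "n_members",
            "detection_rate", "p_adjusted", "effect", "r2_val", "members",
        ]
    )
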