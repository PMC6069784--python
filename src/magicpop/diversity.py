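"""Genetic similarity, principal components and LD decay.

Similarity between two lines is the simple-matching proportion: the
fraction of SNPs, non-missing in both, at which the IBS dosage states
{0, 1, 2} agree exactly.  Population structure is examined by PCA of the
similarity matrix.  Linkage disequilibrium is the squared Pearson
correlation of dosages (r^2); intra-chromosomal pairs yield a decay curve
(degree-2 LOESS of r^2 on cM distance) and inter-chromosomal ("unlinked")
pairs yield the population-specific background r^2 as a high quantile of
their r^2 distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "genetic_similarity",
    "pca_on_similarity",
    "loess_quadratic",
    "LDResult",
    "ld_analysis",
]


def genetic_similarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Simple-matching similarity on pairwise-complete SNPs.

    A pair of lines sharing no non-missing SNP gets NaN (reported, not
    raised).  States are compared exactly, so heterozygous (1) matches
    only heterozygous.
    """
    x = matrix.to_numpy(dtype=float)
    obs = ~np.isnan(x)
    shared = obs.astype(float) @ obs.T.astype(float)
    match = np.zeros_like(shared)
    for state in (0.0, 1.0, 2.0):
        ind = ((x == state) & obs).astype(float)
        match += ind @ ind.T
    # non-integer (imputed) states: exact equality handled per unique value
    extra = np.setdiff1d(np.unique(x[obs]), [0.0, 1.0, 2.0])
    for state in extra:
        ind = ((x == state) & obs).astype(float)
        match += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(shared > 0, match / shared, np.nan)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=matrix.index, columns=matrix.index)


def pca_on_similarity(sim: pd.DataFrame, n_components: int | None = None):
    """PCA of the similarity matrix (lines as observations, similarity
    columns as variables, column-centered).

    Returns ``(scores, explained_fraction)``; fractions are non-increasing
    and sum to <= 1.
    """
    x = sim.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("similarity matrix has undefined entries")
    if not np.allclose(x, x.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    if n_components is None:
        n_components = min(10, x.shape[0] - 1)
    n_components = min(n_components, x.shape[0] - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    scores_df = pd.DataFrame(
        scores,
        index=sim.index,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    total_var = np.var(x, axis=0, ddof=1).sum()
    if total_var <= 1e-12:
        fractions = np.zeros(scores.shape[1])
    else:
        fractions = pca.explained_variance_ratio_.copy()
    return scores_df, fractions


def loess_quadratic(
    x: np.ndarray, y: np.ndarray, xout: np.ndarray, span: float = 0.3
) -> np.ndarray:
    """Degree-2 locally weighted polynomial regression with tricube weights.

    For each evaluation point the nearest ``span`` fraction of the data is
    fit by weighted quadratic least squares.  This is the classical LOESS
    smoother at degree 2 (no robustness iterations).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    k = max(int(np.ceil(span * n)), 8)
    k = min(k, n)
    out = np.empty(len(xout))
    for i, x0 in enumerate(np.asarray(xout, dtype=float)):
        d = np.abs(x - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        t = x[idx] - x0
        D = np.column_stack([np.ones(k), t, t**2])
        W = np.sqrt(np.maximum(w, 0))
        beta, *_ = np.linalg.lstsq(D * W[:, None], y[idx] * W, rcond=None)
        out[i] = beta[0]
    return out


@dataclass
class LDResult:
    pairs: pd.DataFrame            # snp1, snp2, distance_cm (NaN = unlinked), r2
    curve: pd.DataFrame            # distance_cm, r2_fit
    background_r2: float
    decay_distance: float | None   # first crossing of reference_r2, cM
    reference_r2: float
    n_monomorphic_excluded: int = 0


def _pair_r2(x: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns i and j."""
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    num = (xc[:, i] * xc[:, j]).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / (sd[i] * sd[j])
    return r**2


def ld_analysis(
    matrix: pd.DataFrame,
    gmap,
    reference_r2: float = 0.2,
    unlinked_quantile: float = 0.95,
    loess_span: float = 0.3,
    max_pairs: int = 100_000,
    rng_seed: int = 0,
) -> LDResult:
    """LD decay with a population-specific background threshold.

    Intra-chromosomal pairs give (distance, r^2) points; the degree-2
    LOESS fit of r^2 on distance is evaluated on a grid and
    ``decay_distance`` is the smallest distance at which the curve first
    crosses ``reference_r2`` from above.  Inter-chromosomal pairs (the
    unlinked set, subsampled to ``max_pairs`` with a seeded RNG) provide
    ``background_r2`` as their ``unlinked_quantile`` quantile.  Monomorphic
    SNPs are excluded and counted.
    """
    rng = np.random.default_rng(rng_seed)
    snps = [s for s in matrix.columns if s in gmap]
    x = matrix[snps].to_numpy(dtype=float)
    poly = x.std(axis=0) > 0
    n_mono = int((~poly).sum())
    snps = [s for s, ok in zip(snps, poly) if ok]
    x = x[:, poly]
    chroms = np.array([gmap.chromosome(s) for s in snps])
    pos = np.array([gmap.position(s) for s in snps])
    m = len(snps)

    iu, ju = np.triu_indices(m, k=1)
    same = chroms[iu] == chroms[ju]
    intra_i, intra_j = iu[same], ju[same]
    inter_i, inter_j = iu[~same], ju[~same]
    if len(intra_i) > max_pairs:
        pick = rng.choice(len(intra_i), size=max_pairs, replace=False)
        intra_i, intra_j = intra_i[pick], intra_j[pick]
    if len(inter_i) > max_pairs:
        pick = rng.choice(len(inter_i), size=max_pairs, replace=False)
        inter_i, inter_j = inter_i[pick], inter_j[pick]

    r2_intra = _pair_r2(x, intra_i, intra_j)
    r2_inter = _pair_r2(x, inter_i, inter_j)
    dist = np.abs(pos[intra_i] - pos[intra_j])

    pairs = pd.concat(
        [
            pd.DataFrame(
                {
                    "snp1": np.array(snps)[intra_i],
                    "snp2": np.array(snps)[intra_j],
                    "distance_cm": dist,
                    "r2": r2_intra,
                }
            ),
            pd.DataFrame(
                {
                    "snp1": np.array(snps)[inter_i],
                    "snp2": np.array(snps)[inter_j],
                    "distance_cm": np.nan,
                    "r2": r2_inter,
                }
            ),
        ],
        ignore_index=True,
    )

    background = (
        float(np.quantile(r2_inter, unlinked_quantile)) if len(r2_inter) else np.nan
    )

    if len(dist) > 10:
        grid = np.linspace(0.0, dist.max(), 200)
        fit = loess_quadratic(dist, r2_intra, grid, span=loess_span)
    else:
        grid = np.array([])
        fit = np.array([])
    curve = pd.DataFrame({"distance_cm": grid, "r2_fit": fit})

    decay = None
    for g, f0, f1 in zip(grid[1:], fit[:-1], fit[1:]):
        if f0 >= reference_r2 > f1:
            # linear interpolation inside the grid step
            g0 = g - (grid[1] - grid[0])
            decay = g0 + (f0 - reference_r2) / (f0 - f1) * (g - g0)
            break
    return LDResult(
        pairs=pairs,
        curve=curve,
        background_r2=background,
        decay_distance=decay,
        reference_r2=reference_r2,
        n_monomorphic_excluded=n_mono,
    )
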