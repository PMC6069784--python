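"""Line means, variance components, heritability and transgression.

Phenotypes come as long-format records (line, year, rep, value).  With a
fixed-genotype / random-year model and a balanced single-replicate layout,
the least-squares mean of a line is its arithmetic mean across years.
Variance components are estimated by method-of-moments expected-mean-squares
ANOVA on the line x year layout; broad-sense heritability on a line-mean
basis is

    h2 = V_G / (V_G + V_GY / y + V_R / (y * r))

with y years and r replicates per year.  With one replicate per year V_GY
and V_R are confounded and only their pooled sum V_E is estimable, giving
h2 = V_G / (V_G + V_E / y).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "line_means",
    "heritability",
    "variance_components",
    "transgressive_count",
]


@dataclass(frozen=True)
class VarianceComponents:
    V_G: float
    V_E: float                 # pooled V_GY + V_R when r == 1
    y: int
    r: int = 1
    V_GY: float | None = None  # separable only with r > 1
    V_R: float | None = None

    def __post_init__(self):
        for name in ("V_G", "V_E"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def line_means(table: pd.DataFrame) -> pd.Series:
    """Per-line mean value across all its records (cm).

    Equals the least-squares mean under the balanced fixed-genotype /
    random-year layout; lines missing a year use their available years.
    Lines with no records are simply absent from the result.
    """
    if not {"line", "value"}.issubset(table.columns):
        raise ValueError("phenotype table needs 'line' and 'value' columns")
    # average replicates within year first so unbalanced replication does
    # not weight years unequally
    if "year" in table.columns:
        per_year = table.groupby(["line", "year"], sort=False)["value"].mean()
        means = per_year.groupby("line", sort=False).mean()
    else:
        means = table.groupby("line", sort=False)["value"].mean()
    means.name = "mean"
    return means


def heritability(components: VarianceComponents) -> float:
    """Broad-sense heritability on a line-mean basis, in [0, 1]."""
    c = components
    if c.V_GY is not None and c.V_R is not None:
        denom = c.V_G + c.V_GY / c.y + c.V_R / (c.y * c.r)
    else:
        denom = c.V_G + c.V_E / c.y
    if denom <= 0:
        raise ValueError("all variance components are zero; h2 undefined")
    return c.V_G / denom


def variance_components(table: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments ANOVA on the line x year layout.

    Requires >= 2 years.  With one replicate per year the genotype-by-year
    and residual components are confounded; the residual mean square then
    estimates their pooled sum V_E.  Negative solutions are truncated to 0.
    Only lines observed in every year enter the estimation (the layout must
    be balanced for the expected mean squares to hold).
    """
    years = sorted(table["year"].unique())
    if len(years) < 2:
        raise ValueError("variance components need >= 2 years")
    y = len(years)
    cell = table.groupby(["line", "year"])["value"].agg(["mean", "count", "var"])
    wide = cell["mean"].unstack("year").dropna()
    n = len(wide)
    if n < 2:
        raise ValueError("need >= 2 lines observed in every year")
    reps = cell["count"].unstack("year").loc[wide.index]
    r = int(round(reps.to_numpy().mean()))

    x = wide.to_numpy()
    grand = x.mean()
    ms_g = y * r * np.var(x.mean(axis=1), ddof=1)
    ms_y = n * r * np.var(x.mean(axis=0), ddof=1)
    inter = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand
    ms_gy = r * (inter**2).sum() / ((n - 1) * (y - 1))

    if r > 1:
        within = cell["var"].unstack("year").loc[wide.index].to_numpy()
        ms_r = np.nanmean(within)
        v_gy = max((ms_gy - ms_r) / r, 0.0)
        v_g = max((ms_g - ms_gy) / (y * r), 0.0)
        return VarianceComponents(
            V_G=v_g, V_E=v_gy + max(ms_r, 0.0), y=y, r=r,
            V_GY=v_gy, V_R=max(ms_r, 0.0),
        )
    v_e = ms_gy                       # pooled V_GY + V_R
    v_g = max((ms_g - ms_gy) / y, 0.0)
    return VarianceComponents(V_G=v_g, V_E=v_e, y=y, r=1)


def transgressive_count(
    line_means_: pd.Series,
    founder_means: pd.Series,
    residual_variance: float,
    n_line_records: int = 2,
    n_founder_records: int = 2,
    alpha: float = 0.05,
) -> tuple[int, int]:
    """Lines significantly beyond the founder extremes.

    A line is transgressive-tall if its mean exceeds the tallest founder's
    mean by more than the two-sided ``alpha`` least-significant difference
    computed from ``residual_variance`` (variance of a single record) and
    the record counts behind each mean; symmetric for short.
    """
    if founder_means.empty:
        raise ValueError("founder means are required")
    z = stats.norm.ppf(1 - alpha / 2)
    lsd = z * np.sqrt(
        residual_variance / n_line_records + residual_variance / n_founder_records
    )
    top, bottom = founder_means.max(), founder_means.min()
    n_taller = int((line_means_ > top + lsd).sum())
    n_shorter = int((line_means_ < bottom - lsd).sum())
    return n_taller, n_shorter
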