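"""Quantitative-trait model for simulated phenotypes.

A plant-height-like trait is built from additive QTL, di-genic
additive-by-additive epistasis, a random year effect, genotype-by-year
interaction and a residual:

    y(line, year, rep) = mu + sum_q a_q x_q + sum_p (aa_p / 4) x1_p x2_p
                         + Y(year) + GY(line, year) + e(line, year, rep)

with x = dosage - 1 in {-1, 0, +1} (reference-founder allele coding).  The
(aa/4) scaling makes the two-locus homozygous class-mean contrast
(JJ + NN) - (JN + NJ) equal ``aa`` in expectation, which is how the
additive-by-additive effect is estimated downstream.  An additive effect
``a`` is half the homozygous contrast: lines fixed for the reference allele
sit ``2a`` above lines fixed for the alternative allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TraitModel", "simulate_phenotype", "default_height_model"]


@dataclass(frozen=True)
class TraitModel:
    additive_qtl: tuple[tuple[str, float], ...] = ()     # (snp, a in cm)
    epistatic_pairs: tuple[tuple[str, str, float], ...] = ()  # (snp1, snp2, aa)
    intercept: float = 80.0
    year_variance: float = 4.0
    gxy_variance: float = 5.0
    residual_variance: float = 20.0
    n_years: int = 2
    n_reps_per_year: int = 1

    def __post_init__(self):
        for name in ("year_variance", "gxy_variance", "residual_variance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_years < 1 or self.n_reps_per_year < 1:
            raise ValueError("n_years and n_reps_per_year must be >= 1")

    def loci(self) -> set[str]:
        out = {s for s, _ in self.additive_qtl}
        for s1, s2, _ in self.epistatic_pairs:
            out |= {s1, s2}
        return out


def genetic_values(genotypes: pd.DataFrame, model: TraitModel) -> pd.Series:
    """Noise-free genetic value per line (cm), intercept included."""
    missing = model.loci() - set(genotypes.columns)
    if missing:
        raise KeyError(f"trait loci absent from genotype matrix: {sorted(missing)}")
    g = np.full(len(genotypes), float(model.intercept))
    for snp, a in model.additive_qtl:
        x = genotypes[snp].to_numpy(dtype=float) - 1.0
        g = g + a * np.nan_to_num(x)
    for s1, s2, aa in model.epistatic_pairs:
        x1 = np.nan_to_num(genotypes[s1].to_numpy(dtype=float) - 1.0)
        x2 = np.nan_to_num(genotypes[s2].to_numpy(dtype=float) - 1.0)
        g = g + (aa / 4.0) * x1 * x2
    return pd.Series(g, index=genotypes.index, name="genetic_value")


def simulate_phenotype(
    genotypes: pd.DataFrame,
    model: TraitModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Phenotype records ``(line, year, rep, value)`` in long format.

    Missing dosages contribute nothing to the genetic value (x = 0), which
    matches mean-imputation of an average locus; simulated matrices are
    normally genotyped without missingness for phenotyping.
    """
    g = genetic_values(genotypes, model).to_numpy()
    n = len(g)
    years = np.arange(1, model.n_years + 1)
    year_eff = rng.normal(0.0, np.sqrt(model.year_variance), size=model.n_years)
    gxy = rng.normal(0.0, np.sqrt(model.gxy_variance), size=(n, model.n_years))
    rows = []
    for yi, year in enumerate(years):
        for rep in range(1, model.n_reps_per_year + 1):
            resid = rng.normal(0.0, np.sqrt(model.residual_variance), size=n)
            values = g + year_eff[yi] + gxy[:, yi] + resid
            rows.append(
                pd.DataFrame(
                    {
                        "line": genotypes.index,
                        "year": year,
                        "rep": rep,
                        "value": values,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def default_height_model(
    rht_b1_snp: str,
    rht_d1_snp: str,
    small_qtl: tuple[tuple[str, float], ...] = (),
    intercept: float = 80.0,
    year_variance: float = 4.0,
    gxy_variance: float = 5.0,
    residual_variance: float = 20.0,
) -> TraitModel:
    """Study-style height architecture.

    The two semi-dwarfing loci carry homozygous reference-allele contrasts
    of +12.8 cm (Rht-B1 role: the reference founder carries the tall allele)
    and -14.9 cm (Rht-D1 role: the reference founder carries the dwarf
    allele), and they interact with an additive-by-additive effect of
    +13.7 cm.  ``small_qtl`` supplies additional (snp, a) effects of a few
    cm each.
    """
    return TraitModel(
        additive_qtl=((rht_b1_snp, 12.8 / 2), (rht_d1_snp, -14.9 / 2)) + small_qtl,
        epistatic_pairs=((rht_b1_snp, rht_d1_snp, 13.7),),
        intercept=intercept,
        year_variance=year_variance,
        gxy_variance=gxy_variance,
        residual_variance=residual_variance,
    )
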