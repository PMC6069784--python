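"""CSV dialects shared by the simulator and the analysis modules.

All tables are plain CSV: genotype matrices have lines as rows and SNPs as
columns with dosages 0/1/2 (or real values after imputation) and empty
cells for missing; phenotypes are long format (line, year, rep, value);
pedigrees record each line's 8-way ancestor.
"""

from __future__ import annotations

import pandas as pd


def write_genotypes(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=True, na_rep="")


def read_genotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_pedigree(lines, path) -> None:
    pd.DataFrame(
        {
            "line": [ln.name for ln in lines],
            "eight_way_ancestor": [ln.eight_way_ancestor for ln in lines],
            "reciprocal": [ln.reciprocal for ln in lines],
        }
    ).to_csv(path, index=False)
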