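"""Packaged transcriptions of the published summary tables.

Three small TSV fixtures ship with the package so the whole attribution
path can be exercised without any download:

- ``table2_counts.tsv`` — the categorical clinical contrasts (2x2 counts
  per cohort) with the published Fisher p-values;
- ``table3_ubiquitination_pairs.tsv`` — the 21 ubiquitination-enzyme
  miRNA/target pairs with correlation and differential statistics;
- ``table4_integration.tsv`` — the printed concordant DEG/DEM rows
  (30 rows, 25 genes, 12 miRNAs).
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

__all__ = [
    "load_table2_counts",
    "load_table3_pairs",
    "load_table4_integration",
    "table4_attribution_inputs",
]


def _read(name: str) -> pd.DataFrame:
    with files("cortimir.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def load_table2_counts() -> pd.DataFrame:
    """Categorical clinical contrasts: variable, cohort, the 2x2 cell
    counts (mut_a, mut_b, wt_a, wt_b) and the published p-value."""
    return _read("table2_counts.tsv")


def load_table3_pairs() -> pd.DataFrame:
    """Ubiquitination-related miRNA/target pairs with enzyme class."""
    return _read("table3_ubiquitination_pairs.tsv")


def load_table4_integration() -> pd.DataFrame:
    """Concordant DEG/DEM attribution rows."""
    return _read("table4_integration.tsv")


def table4_attribution_inputs():
    """Decompose the attribution fixture into the three upstream tables
    that :func:`cortimir.integrate.attribute_degs` consumes.

    Returns (correlation_records, deg_table, dem_table). Where a feature
    recurs, the first printed differential statistics are used.
    """
    t4 = load_table4_integration()
    records = t4[["mirna_id", "gene_id", "rho", "corr_p"]].rename(
        columns={"corr_p": "p"}
    )
    records = records.assign(n=24)
    deg = (
        t4[["gene_id", "gene_fc", "gene_padj"]]
        .drop_duplicates("gene_id", keep="first")
        .rename(columns={"gene_fc": "fc", "gene_padj": "padj"})
        .set_index("gene_id")
        .assign(is_deg=True)
    )
    dem = (
        t4[["mirna_id", "mirna_fc", "mirna_padj"]]
        .drop_duplicates("mirna_id", keep="first")
        .rename(columns={"mirna_fc": "fc", "mirna_padj": "padj"})
        .set_index("mirna_id")
        .assign(is_dem=True)
    )
    return records, deg, dem
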