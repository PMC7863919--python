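"""Two-step miRNA-mRNA interaction screen and sign-concordance attribution.

Step one gates candidate pairs on predicted targeting confidence (only
the top "VeryHigh" class by default, as produced by an integrated
prediction resource consumed here as a table). Step two computes the
Spearman rank correlation of each surviving (DEM, predicted target) pair
across matched tumor samples on normalized expression and keeps pairs
with unadjusted p < 0.01 — deliberately without multiplicity adjustment,
since the screen is a candidate filter, not an inference.

Attribution then joins the retained pairs with both differential tables
and keeps pairs whose gene is a DEG, whose miRNA is a DEM, and whose
fold-change directions are concordant with the correlation sign:
negatively correlated pairs must change in opposite directions,
positively correlated pairs in the same direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONFIDENCE_ORDER",
    "filter_targets",
    "spearman",
    "correlation_screen",
    "split_by_sign",
    "concordance",
    "attribute_degs",
    "targets_per_mirna",
    "IntegrationAnalysis",
    "IntegrationResults",
]

# descending confidence
CONFIDENCE_ORDER = ("VeryHigh", "High", "Medium", "Low")
_CONF_RANK = {c: i for i, c in enumerate(CONFIDENCE_ORDER)}


def filter_targets(predictions: pd.DataFrame, min_class: str = "VeryHigh") -> pd.DataFrame:
    """Keep predictions whose confidence class is at or above ``min_class``.

    ``predictions`` columns: mirna_id, gene_id, confidence_class.
    Duplicate (mirna, gene) pairs are rejected.
    """
    if min_class not in _CONF_RANK:
        raise ValueError(f"unknown confidence class {min_class!r}")
    unknown = set(predictions["confidence_class"]) - set(CONFIDENCE_ORDER)
    if unknown:
        raise ValueError(f"unknown confidence class labels: {sorted(unknown)}")
    if predictions.duplicated(["mirna_id", "gene_id"]).any():
        dupes = predictions.loc[
            predictions.duplicated(["mirna_id", "gene_id"]), ["mirna_id", "gene_id"]
        ]
        raise ValueError(f"duplicate target predictions: {dupes.values.tolist()}")
    rank = predictions["confidence_class"].map(_CONF_RANK)
    return predictions.loc[rank <= _CONF_RANK[min_class]].reset_index(drop=True)


def spearman(x, y) -> tuple[float, float, int]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Missing values are removed pairwise; at least 4 complete pairs are
    required. rho is the Pearson correlation of average (mid-) ranks.
    p comes from t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df; for |rho| = 1
    the t statistic degenerates and the exact permutation limit 2/n! is
    reported instead. A constant vector leaves rho undefined (NaN, NaN, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan, n)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1 - 1e-13:
        rho = math.copysign(1.0, rho)
        p = 2.0 / math.factorial(n)
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return (rho, p, n)


def correlation_screen(
    dems,
    targets: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Spearman screen of (DEM, predicted target) pairs on matched samples.

    ``mirna_expr``/``mrna_expr`` are normalized expression matrices
    (features x samples); samples are matched by id. Records with
    unadjusted p < ``alpha`` are retained, with the per-pair n recorded.
    Returns columns mirna_id, gene_id, rho, p, n.
    """
    shared = [s for s in mirna_expr.columns if s in set(mrna_expr.columns)]
    if not shared:
        raise ValueError("no matched samples between the two expression matrices")
    dems = [m for m in dems]
    dem_set = set(dems)
    mirna_feats = set(mirna_expr.index)
    mrna_feats = set(mrna_expr.index)
    records = []
    for _, row in targets.iterrows():
        m, g = row["mirna_id"], row["gene_id"]
        if m not in dem_set or m not in mirna_feats or g not in mrna_feats:
            continue
        rho, p, n = spearman(
            mirna_expr.loc[m, shared].to_numpy(),
            mrna_expr.loc[g, shared].to_numpy(),
        )
        if not math.isnan(p) and p < alpha:
            records.append({"mirna_id": m, "gene_id": g, "rho": rho, "p": p, "n": n})
    return pd.DataFrame(records, columns=["mirna_id", "gene_id", "rho", "p", "n"])


def split_by_sign(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition correlation records by the sign of rho.

    Zero rho cannot survive a p < 0.01 screen at finite n; such records
    are dropped with a warning.
    """
    zero = records["rho"] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} record(s) with rho = 0 excluded", stacklevel=2)
        records = records.loc[~zero]
    negative = records.loc[records["rho"] < 0].reset_index(drop=True)
    positive = records.loc[records["rho"] > 0].reset_index(drop=True)
    return negative, positive


def concordance(rho: float, gene_fc: float, mirna_fc: float) -> bool:
    """Is a gene's expression change attributable to the miRNA's?

    Direction is up iff FC > 1. Negative correlation demands opposite
    directions; positive correlation the same direction. A fold change of
    exactly 1 has no direction: the pair is flagged non-concordant with a
    warning.
    """
    if gene_fc <= 0 or mirna_fc <= 0:
        raise ValueError("fold changes must be positive")
    if rho == 0:
        raise ValueError("rho must be non-zero")
    if gene_fc == 1 or mirna_fc == 1:
        warnings.warn("fold change exactly 1 has no direction; not concordant", stacklevel=2)
        return False
    gene_up = gene_fc > 1
    mirna_up = mirna_fc > 1
    return (rho < 0) != (gene_up == mirna_up)


def attribute_degs(
    records: pd.DataFrame, deg_table: pd.DataFrame, dem_table: pd.DataFrame
) -> pd.DataFrame:
    """Join correlation records with both differential tables and keep
    concordant (DEG, DEM) pairs.

    ``deg_table`` is indexed by gene id with columns fc, padj, is_deg;
    ``dem_table`` indexed by miRNA id with columns fc, padj, is_dem.
    Correlation records naming features absent from the respective table
    are an error (they indicate inconsistent upstream keying).

    Returns Table-4-style rows: gene_id, mirna_id, rho, corr_p, gene_fc,
    gene_padj, mirna_fc, mirna_padj, concordant (all retained rows True).
    """
    cols = ["gene_id", "mirna_id", "rho", "corr_p", "gene_fc", "gene_padj",
            "mirna_fc", "mirna_padj", "concordant"]
    if records.empty:
        return pd.DataFrame(columns=cols)
    orphan_genes = sorted(set(records["gene_id"]) - set(deg_table.index))
    orphan_mirnas = sorted(set(records["mirna_id"]) - set(dem_table.index))
    if orphan_genes or orphan_mirnas:
        raise KeyError(
            f"correlation records with no differential entry — genes: {orphan_genes}, "
            f"miRNAs: {orphan_mirnas}"
        )
    rows = []
    for _, rec in records.iterrows():
        g, m = rec["gene_id"], rec["mirna_id"]
        gene = deg_table.loc[g]
        mirna = dem_table.loc[m]
        if not (bool(gene["is_deg"]) and bool(mirna["is_dem"])):
            continue
        conc = concordance(rec["rho"], gene["fc"], mirna["fc"])
        if not conc:
            continue
        rows.append({
            "gene_id": g, "mirna_id": m, "rho": rec["rho"], "corr_p": rec["p"],
            "gene_fc": gene["fc"], "gene_padj": gene["padj"],
            "mirna_fc": mirna["fc"], "mirna_padj": mirna["padj"],
            "concordant": True,
        })
    return pd.DataFrame(rows, columns=cols)


def targets_per_mirna(records: pd.DataFrame) -> pd.DataFrame:
    """Distinct target genes per miRNA with min/median/max attached.

    Returns a one-row-per-miRNA frame (mirna_id, n_targets); the summary
    statistics are available via ``.attrs['min'|'median'|'max']``.
    """
    if records.empty:
        raise ValueError("no correlation records")
    counts = (
        records.groupby("mirna_id")["gene_id"].nunique().rename("n_targets").reset_index()
    )
    counts.attrs["min"] = int(counts["n_targets"].min())
    counts.attrs["median"] = float(counts["n_targets"].median())
    counts.attrs["max"] = int(counts["n_targets"].max())
    return counts


class IntegrationAnalysis:
    """Model joining differential, prediction, and correlation evidence.

    Parameters
    ----------
    dem_results, deg_results : DifferentialExpressionResults
        Fitted miRNA and mRNA differential stages (their ``normalized``
        matrices feed the correlation screen).
    targets : DataFrame
        Prediction table (mirna_id, gene_id, confidence_class).
    corr_alpha : retention threshold for unadjusted correlation p.
    min_class : confidence gate for predictions.
    """

    def __init__(
        self,
        dem_results,
        deg_results,
        targets: pd.DataFrame,
        *,
        corr_alpha: float = 0.01,
        min_class: str = "VeryHigh",
    ) -> None:
        self.dem_results = dem_results
        self.deg_results = deg_results
        self.targets = targets
        self.corr_alpha = corr_alpha
        self.min_class = min_class

    def fit(self) -> "IntegrationResults":
        gated = filter_targets(self.targets, self.min_class)
        records = correlation_screen(
            self.dem_results.dem_ids,
            gated,
            self.dem_results.normalized,
            self.deg_results.normalized,
            alpha=self.corr_alpha,
        )
        negative, positive = (
            split_by_sign(records) if not records.empty else (records, records)
        )
        dem_table = self.dem_results.table
        deg_table = self.deg_results.table
        attributed = attribute_degs(records, deg_table, dem_table)
        return IntegrationResults(
            correlation_records=records,
            negative=negative,
            positive=positive,
            attributed=attributed,
            model=self,
        )


@dataclass
class IntegrationResults:
    correlation_records: pd.DataFrame
    negative: pd.DataFrame
    positive: pd.DataFrame
    attributed: pd.DataFrame
    model: IntegrationAnalysis = field(repr=False, default=None)

    @property
    def n_interactions(self) -> int:
        return len(self.correlation_records)

    def target_genes(self, sign: str | None = None) -> list[str]:
        """Distinct putative target genes, optionally one correlation sign."""
        source = {
            None: self.correlation_records, "negative": self.negative,
            "positive": self.positive,
        }[sign]
        return sorted(source["gene_id"].unique()) if not source.empty else []

    def summary(self) -> str:
        rec = self.correlation_records
        att = self.attributed
        lines = [
            "miRNA-mRNA integration",
            f"  retained interactions       {len(rec)} "
            f"({len(self.negative)} negative / {len(self.positive)} positive)",
        ]
        if not rec.empty:
            tpm = targets_per_mirna(rec)
            lines.append(
                f"  miRNAs with >=1 target      {len(tpm)} "
                f"(targets per miRNA: min {tpm.attrs['min']}, "
                f"median {tpm.attrs['median']:g}, max {tpm.attrs['max']})"
            )
        lines += [
            f"  concordant DEG attributions {len(att)} rows: "
            f"{att['gene_id'].nunique() if not att.empty else 0} genes, "
            f"{att['mirna_id'].nunique() if not att.empty else 0} miRNAs",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.attributed.to_csv(path, sep="\t", index=False, float_format="%.6g",
                               lineterminator="\n")
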