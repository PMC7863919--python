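"""Differential expression of count data between mutated and wild-type groups.

The stage mirrors a standard bulk RNA-seq workflow: low-expression
filtering, median-of-ratios library-size normalization, a per-feature
negative-binomial Wald test on the log2 ratio of group means, and
Benjamini-Hochberg adjustment. Differentially expressed miRNAs (DEMs)
require both |FC| > 2 (i.e. fc > 2 or fc < 0.5, fold change being the
ratio of mean normalized counts mut/wt) and adjusted p < 0.05;
differentially expressed genes (DEGs) require adjusted p < 0.05 only.

The NB test is a deliberately simple, documented procedure — dispersion by
the method of moments with a 1/mean trend floor, Wald statistic from the
delta-method standard error of the log2 ratio of group means. It is not a
re-implementation of any particular external tool and parity with one is
not a goal; see docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix

__all__ = [
    "filter_low_expression",
    "size_factors_median_of_ratios",
    "nb_group_test",
    "bh_adjust",
    "classify_dem",
    "DifferentialExpression",
    "DifferentialExpressionResults",
]

MUT = "mut"
WT = "wt"

DISPERSION_FLOOR = 1e-8
DISPERSION_CEILING = 10.0


def filter_low_expression(
    counts: CountMatrix, min_reads: int = 5, fraction: float = 0.5
) -> CountMatrix:
    """Drop features with fewer than ``min_reads`` raw counts in at least
    ``fraction`` of the samples (ties at exactly half count as "at least half").

    Feature order among survivors and the sample set are preserved.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = counts.n_samples
    threshold = int(np.ceil(fraction * n))
    low = (counts.values() < min_reads).sum(axis=1)
    keep = low < threshold
    if not keep.any():
        raise ValueError("low-expression filter removed every feature")
    return CountMatrix(counts.data.loc[keep])


def size_factors_median_of_ratios(counts: CountMatrix) -> pd.Series:
    """Per-sample size factors: median across reference features of the
    count-to-geometric-mean ratio.

    Only features with a positive geometric mean across all samples (no
    zero in any sample) enter the reference set. With no such feature the
    factors are undefined and an error is raised — no silent fallback.
    """
    values = counts.values().astype(float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; size factors are "
            "undefined (a pseudo-reference fallback is not applied silently)"
        )
    ref = values[positive]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def _moments_dispersion(normalized: np.ndarray, mut_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature method-of-moments NB dispersion on normalized counts.

    Pools the within-group variance of both groups so the planted group
    effect does not inflate the estimate. Returns (dispersion, mean).
    """
    groups = [normalized[:, mut_mask], normalized[:, ~mut_mask]]
    n_total = normalized.shape[1]
    mean = normalized.mean(axis=1)
    ss = np.zeros(normalized.shape[0])
    for g in groups:
        ss += ((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss / (n_total - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean**2
    alpha = np.where(mean > 0, alpha, np.nan)
    return np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CEILING), mean


def _dispersion_trend(alpha: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Least-squares fit of dispersion ~ a/mean + b over informative features;
    returns the per-feature trend prediction clipped to the working range."""
    ok = np.isfinite(alpha) & (mean > 0)
    if ok.sum() < 2:
        return np.full_like(mean, DISPERSION_FLOOR)
    X = np.column_stack([1.0 / mean[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(X, alpha[ok], rcond=None)
    with np.errstate(divide="ignore"):
        trend = np.where(mean > 0, coef[0] / mean + coef[1], DISPERSION_FLOOR)
    return np.clip(trend, DISPERSION_FLOOR, DISPERSION_CEILING)


def nb_group_test(normalized: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-feature two-sided Wald test of mut vs wt mean normalized counts.

    Parameters
    ----------
    normalized : DataFrame, features x samples, median-of-ratios normalized.
    groups : Series mapping sample id -> {"mut", "wt"}.

    Returns a DataFrame indexed by feature with columns ``mean_mut``,
    ``mean_wt``, ``fc``, ``p``. All-zero features get p = 1 and fc = NaN;
    features with exactly one zero group mean get an infinite/zero fc
    sentinel and p = NaN (they cannot be tested on the log-ratio scale).
    """
    groups = groups.reindex(normalized.columns)
    if groups.isna().any():
        missing = list(normalized.columns[groups.isna()])
        raise ValueError(f"samples without group label: {missing}")
    bad = set(groups.unique()) - {MUT, WT}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    mut_mask = (groups == MUT).to_numpy()
    n_mut, n_wt = int(mut_mask.sum()), int((~mut_mask).sum())
    if n_mut < 2 or n_wt < 2:
        raise ValueError("each group needs at least 2 samples")

    values = normalized.to_numpy(dtype=float)
    mean_mut = values[:, mut_mask].mean(axis=1)
    mean_wt = values[:, ~mut_mask].mean(axis=1)

    alpha_hat, mean_all = _moments_dispersion(values, mut_mask)
    trend = _dispersion_trend(alpha_hat, mean_all)
    alpha = np.fmax(alpha_hat, trend)  # conservative: never below the trend

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_mut / mean_wt
        log2fc = np.log2(fc)
        # delta-method variance of log2(mean) under var(x) = mu + alpha*mu^2
        var_log2 = (
            (mean_mut + alpha * mean_mut**2) / (n_mut * mean_mut**2)
            + (mean_wt + alpha * mean_wt**2) / (n_wt * mean_wt**2)
        ) / np.log(2) ** 2
        z = log2fc / np.sqrt(var_log2)
    p = 2 * stats.norm.sf(np.abs(z))

    both_zero = (mean_mut == 0) & (mean_wt == 0)
    one_zero = ((mean_mut == 0) ^ (mean_wt == 0))
    p = np.where(both_zero, 1.0, p)
    p = np.where(one_zero, np.nan, p)
    fc = np.where(both_zero, np.nan, fc)
    if one_zero.any():
        warnings.warn(
            f"{int(one_zero.sum())} feature(s) have a zero group mean; "
            "fold change reported as 0/inf sentinel and excluded from testing",
            stacklevel=2,
        )
    return pd.DataFrame(
        {"mean_mut": mean_mut, "mean_wt": mean_wt, "fc": fc, "p": p},
        index=normalized.index,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, monotone).

    NaN entries are passed through as NaN and do not count toward the
    family size.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if vals.size:
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def classify_dem(fc: float, padj: float, fc_threshold: float = 2.0, alpha: float = 0.05) -> bool:
    """DEM call: adjusted p below alpha and fold change outside
    [1/fc_threshold, fc_threshold]."""
    if not np.isfinite(fc) or not np.isfinite(padj):
        return False
    return bool(padj < alpha and (fc > fc_threshold or fc < 1.0 / fc_threshold))


class DifferentialExpression:
    """Count-based differential expression model for a two-group cohort.

    Parameters
    ----------
    counts : CountMatrix
        Raw counts, features x samples.
    groups : Series or mapping
        Sample id -> {"mut", "wt"}. The mutated group is the fold-change
        numerator.
    min_reads, fraction : low-expression filter settings.
    fc_threshold, alpha : DEM/DEG call thresholds.

    ``fit()`` runs filter -> normalization -> NB Wald test -> BH adjustment
    and returns a :class:`DifferentialExpressionResults`.
    """

    def __init__(
        self,
        counts: CountMatrix,
        groups,
        *,
        min_reads: int = 5,
        fraction: float = 0.5,
        fc_threshold: float = 2.0,
        alpha: float = 0.05,
    ) -> None:
        self.counts = counts
        self.groups = pd.Series(groups).astype(str)
        extra = set(counts.sample_ids) - set(self.groups.index)
        if extra:
            raise ValueError(f"samples without annotation: {sorted(extra)}")
        self.min_reads = min_reads
        self.fraction = fraction
        self.fc_threshold = fc_threshold
        self.alpha = alpha

    def fit(self) -> "DifferentialExpressionResults":
        filtered = filter_low_expression(self.counts, self.min_reads, self.fraction)
        factors = size_factors_median_of_ratios(filtered)
        normalized = filtered.data.astype(float).div(factors, axis=1)
        groups = self.groups.reindex(filtered.sample_ids)
        table = nb_group_test(normalized, groups)
        table["padj"] = bh_adjust(table["p"].to_numpy())
        table["is_dem"] = [
            classify_dem(fc, padj, self.fc_threshold, self.alpha)
            for fc, padj in zip(table["fc"], table["padj"])
        ]
        table["is_deg"] = np.isfinite(table["padj"]) & (table["padj"] < self.alpha)
        table.index.name = "feature_id"
        return DifferentialExpressionResults(
            table=table, size_factors=factors, normalized=normalized, model=self
        )


@dataclass
class DifferentialExpressionResults:
    """Per-feature estimates from :meth:`DifferentialExpression.fit`.

    ``table`` holds mean_mut, mean_wt, fc, p, padj and the is_dem/is_deg
    flags; ``normalized`` the median-of-ratios normalized matrix the test
    ran on (the correlation screen re-uses it).
    """

    table: pd.DataFrame
    size_factors: pd.Series
    normalized: pd.DataFrame
    model: DifferentialExpression = field(repr=False)

    @property
    def dem_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_dem"]])

    @property
    def deg_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_deg"]])

    def summary(self) -> str:
        t = self.table
        n_dem = int(t["is_dem"].sum())
        n_deg = int(t["is_deg"].sum())
        up = int((t["is_dem"] & (t["fc"] > 1)).sum())
        lines = [
            "Differential expression (mut vs wt)",
            f"  features tested          {len(t)}",
            f"  samples (mut/wt)         {int((self.model.groups == MUT).sum())}/"
            f"{int((self.model.groups == WT).sum())}",
            f"  adjusted p < {self.model.alpha:g}         {n_deg}",
            f"  ... and |FC| > {self.model.fc_threshold:g} (DEM)  {n_dem} ({up} up in mut)",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")

    def plot_volcano(self, ax=None):
        """log2 fold change vs -log10 adjusted p, DEM calls highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table.dropna(subset=["fc", "padj"])
        x = np.log2(t["fc"])
        y = -np.log10(np.clip(t["padj"], 1e-300, None))
        ax.scatter(x[~t["is_dem"]], y[~t["is_dem"]], s=8, c="grey", alpha=0.6)
        ax.scatter(x[t["is_dem"]], y[t["is_dem"]], s=10, c="crimson")
        ax.axhline(-np.log10(self.model.alpha), ls="--", lw=0.8, c="k")
        for v in (1, -1):
            ax.axvline(v * np.log2(self.model.fc_threshold), ls="--", lw=0.8, c="k")
        ax.set_xlabel("log2 fold change (mut / wt)")
        ax.set_ylabel("-log10 adjusted p")
        return ax
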