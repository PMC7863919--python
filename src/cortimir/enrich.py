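"""Over-representation analysis of target gene lists against gene-set catalogs.

The enrichment question here is of the fixed-list kind: given the set of
putative miRNA target genes and a universe (all genes surviving the
expression filter), is a catalog set over-represented among the targets?
Each set is scored with the hypergeometric upper tail
P(X >= k | N, K, n) and the catalog's p-values are Benjamini-Hochberg
adjusted. Runs are performed for all targets and separately for the
negatively and positively correlated targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "GeneSetCatalog",
    "read_gmt",
    "ora",
    "run_signed_enrichment",
    "OverRepresentation",
    "ORAResults",
]


@dataclass(frozen=True)
class GeneSetCatalog:
    """Named, non-empty gene sets under one catalog name."""

    catalog_name: str
    sets: dict

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        object.__setattr__(
            self, "sets", {name: frozenset(m) for name, m in self.sets.items()}
        )

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCatalog:
    """Read a GMT file: one set per line, tab-separated
    name / description / members. Members are de-duplicated."""
    path = Path(path)
    sets: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: malformed GMT line (need name, description, "
                f">= 1 member), got {len(fields)} field(s)"
            )
        name = fields[0]
        members = frozenset(g for g in fields[2:] if g)
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        if not members:
            raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
        sets[name] = members
    return GeneSetCatalog(catalog_name=path.stem, sets=sets)


def ora(
    query_genes,
    universe_genes,
    catalog: GeneSetCatalog,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each catalog
    set, intersected with the universe before testing.

    Returns a frame sorted by p with columns set_name, overlap_k,
    set_size_K, query_size_n, universe_size_N, p, padj, significant,
    overlapping_genes.
    """
    universe = set(universe_genes)
    query = set(query_genes)
    offenders = sorted(query - universe)
    if offenders:
        raise ValueError(f"query genes outside the universe: {offenders}")
    N, n = len(universe), len(query)
    rows = []
    for name, members in catalog.sets.items():
        in_universe = members & universe
        if not in_universe:
            continue
        K = len(in_universe)
        overlap = sorted(in_universe & query)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "set_name": name, "overlap_k": k, "set_size_K": K,
            "query_size_n": n, "universe_size_N": N, "p": p,
            "overlapping_genes": ",".join(overlap),
        })
    result = pd.DataFrame(
        rows,
        columns=["set_name", "overlap_k", "set_size_K", "query_size_n",
                 "universe_size_N", "p", "overlapping_genes"],
    )
    if result.empty:
        result["padj"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    result["padj"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["padj"] < alpha
    result = result.sort_values(
        ["p", "set_name"], ignore_index=True
    )[["set_name", "overlap_k", "set_size_K", "query_size_n", "universe_size_N",
       "p", "padj", "significant", "overlapping_genes"]]
    return result


def run_signed_enrichment(
    integration_results,
    universe_genes,
    catalogs,
    alpha: float = 0.05,
) -> dict:
    """Three independently adjusted ORA runs per catalog: all retained
    targets, negative-correlation targets, positive-correlation targets.

    ``integration_results`` is an :class:`~cortimir.integrate.IntegrationResults`;
    empty target lists produce an empty result with a warning (a null
    finding, not an error). Returns
    {(catalog_name, side): result frame}.
    """
    queries = {
        "all": integration_results.target_genes(None),
        "negative": integration_results.target_genes("negative"),
        "positive": integration_results.target_genes("positive"),
    }
    if isinstance(catalogs, GeneSetCatalog):
        catalogs = [catalogs]
    out = {}
    for catalog in catalogs:
        for side, query in queries.items():
            if not query:
                warnings.warn(
                    f"{catalog.catalog_name}/{side}: empty target list, no test run",
                    stacklevel=2,
                )
                out[(catalog.catalog_name, side)] = ora([], universe_genes, catalog, alpha).iloc[0:0]
                continue
            out[(catalog.catalog_name, side)] = ora(query, universe_genes, catalog, alpha)
    return out


class OverRepresentation:
    """Model form of :func:`ora` for one query list and one catalog."""

    def __init__(self, query_genes, universe_genes, catalog: GeneSetCatalog,
                 alpha: float = 0.05) -> None:
        self.query_genes = list(query_genes)
        self.universe_genes = list(universe_genes)
        self.catalog = catalog
        self.alpha = alpha

    def fit(self) -> "ORAResults":
        table = ora(self.query_genes, self.universe_genes, self.catalog, self.alpha)
        return ORAResults(table=table, model=self)


@dataclass
class ORAResults:
    table: pd.DataFrame
    model: OverRepresentation = field(repr=False, default=None)

    def summary(self) -> str:
        t = self.table
        sig = int(t["significant"].sum()) if not t.empty else 0
        lines = [
            f"Over-representation ({self.model.catalog.catalog_name}): "
            f"{len(t)} sets tested, {sig} significant",
        ]
        for _, row in t.head(10).iterrows():
            mark = "*" if row["significant"] else " "
            lines.append(
                f" {mark} {row['set_name']:<30} k={row['overlap_k']}/{row['set_size_K']}"
                f"  p={row['p']:.3g}  padj={row['padj']:.3g}"
            )
        return "\n".join(lines)

    def plot_bars(self, ax=None, top: int = 10):
        """Horizontal -log10 adjusted-p bars, significant sets darkened."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table.head(top).iloc[::-1]
        colors = np.where(t["significant"], "0.3", "0.75")
        ax.barh(t["set_name"], -np.log10(np.clip(t["padj"], 1e-300, None)), color=colors)
        ax.axvline(-np.log10(self.model.alpha), ls="--", lw=0.8, c="k")
        ax.set_xlabel("-log10 adjusted p")
        return ax
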