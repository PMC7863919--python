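"""Synthetic matched miRNA/mRNA cohorts with known ground truth.

Emulates the structure of a two-group (mutated vs wild-type) tumor cohort
profiled with small-RNA and transcriptome sequencing: negative-binomially
distributed counts with sample-specific library sizes, a planted subset of
differential miRNAs, and planted miRNA->gene couplings that induce
negative or positive rank correlations between a miRNA and its target.

Each feature has a per-sample latent expression level
``baseline * group_effect * exp(bio_sd * eps)`` (log-normal biological
variability); counts are drawn NB(mean = latent * libsize, variance =
mu + dispersion * mu^2) conditional on it. A coupling of strength c and
sign s sets the target gene's latent log-level to
``c * s * u + sqrt(1 - c^2) * eta`` (scaled), where u is the miRNA's
standardized latent log-level: c = 0 is independence, c = 1 a
deterministic monotone link whose latent Spearman correlation is exactly
±1, and the correlation observed on counts is attenuated by counting
noise exactly as in real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CountMatrix

__all__ = ["SimConfig", "SyntheticCohort", "simulate_cohort"]

CONFIDENCE_CLASSES = ("VeryHigh", "High", "Medium", "Low")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults are the package's reference study conditions: a 10+10 cohort
    with 200 miRNAs / 500 genes, 20 planted DEMs at fold change 4 (80% up
    in the mutated group, matching the predominantly up-regulated profile
    of real cohorts), NB dispersion 0.1, and 40 couplings of which 30%
    carry a positive sign (real integration screens find roughly one
    positive pair for every two negative ones).
    """

    n_mut: int = 10
    n_wt: int = 10
    n_mirna: int = 200
    n_gene: int = 500
    n_dem: int = 20
    dem_fc: float = 4.0
    dispersion: float = 0.1
    libsize_range: tuple[float, float] = (0.7, 1.3)
    n_couplings: int = 40
    coupling_strength: float = 0.8
    frac_positive: float = 0.3
    seed: int = 0
    # latent-layer knobs (see module docstring)
    bio_sd: float = 0.5
    coupling_scale: float = 1.0
    frac_up: float = 0.8
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.2
    decoy_factor: int = 10

    def __post_init__(self) -> None:
        if min(self.n_mut, self.n_wt, self.n_mirna, self.n_gene) < 1:
            raise ValueError("sample and feature counts must be >= 1")
        if self.n_mut + self.n_wt < 4:
            raise ValueError("need at least 4 samples in total")
        if self.dem_fc <= 0:
            raise ValueError("dem_fc must be > 0")
        if not 0 <= self.n_dem <= self.n_mirna:
            raise ValueError("n_dem must be in [0, n_mirna]")
        if self.n_couplings > 0 and self.n_dem == 0:
            raise ValueError("couplings require planted DEMs")
        if self.n_couplings > self.n_gene:
            raise ValueError("couplings must target distinct genes")
        if not 0 <= self.frac_positive <= 1:
            raise ValueError("frac_positive must be in [0, 1]")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError("coupling_strength must be in [0, 1]")
        lo, hi = self.libsize_range
        if not 0 < lo <= hi:
            raise ValueError("libsize_range must satisfy 0 < min <= max")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class SyntheticCohort:
    """A simulated cohort plus its ground truth.

    ``truth_dems`` lists planted differential miRNAs with their true fold
    change; ``truth_couplings`` the planted (mirna, gene, sign) links;
    ``target_map`` a prediction table containing every planted coupling at
    VeryHigh confidence plus decoy entries across all confidence classes.
    The latent mean matrices are kept for diagnostics.
    """

    config: SimConfig
    mirna_counts: CountMatrix
    mrna_counts: CountMatrix
    annotations: pd.Series
    truth_dems: pd.DataFrame
    truth_couplings: pd.DataFrame
    target_map: pd.DataFrame
    mirna_latent: pd.DataFrame = field(repr=False, default=None)
    mrna_latent: pd.DataFrame = field(repr=False, default=None)

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.mirna_counts.to_tsv(outdir / "mirna_counts.tsv")
        self.mrna_counts.to_tsv(outdir / "mrna_counts.tsv")
        ann = self.annotations.rename("group").rename_axis("sample")
        ann.to_frame().to_csv(outdir / "annotations.tsv", sep="\t", lineterminator="\n")
        self.target_map.to_csv(outdir / "targets.tsv", sep="\t", index=False, lineterminator="\n")
        self.truth_dems.to_csv(
            outdir / "truth_dems.tsv", sep="\t", index=False,
            float_format="%.6g", lineterminator="\n",
        )
        self.truth_couplings.to_csv(
            outdir / "truth_couplings.tsv", sep="\t", index=False, lineterminator="\n"
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, var = mu + alpha mu^2) via gamma-Poisson; alpha=0 is Poisson."""
    if alpha == 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean * alpha)
    return rng.poisson(lam)


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw one cohort; identical config (including seed) gives an
    identical cohort."""
    rng = np.random.default_rng(config.seed)
    n = config.n_mut + config.n_wt
    samples = [f"mut{i+1:02d}" for i in range(config.n_mut)] + [
        f"wt{i+1:02d}" for i in range(config.n_wt)
    ]
    groups = pd.Series(
        ["mut"] * config.n_mut + ["wt"] * config.n_wt, index=samples, name="group"
    )
    mut_mask = (groups == "mut").to_numpy()

    mirna_ids = [f"mir{i+1:04d}" for i in range(config.n_mirna)]
    gene_ids = [f"gene{i+1:04d}" for i in range(config.n_gene)]

    lo, hi = config.libsize_range
    lib_mirna = rng.uniform(lo, hi, size=n)
    lib_mrna = rng.uniform(lo, hi, size=n)

    # --- miRNA layer: baselines, planted group effects, latent means
    base_mirna = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=config.n_mirna)
    )
    dem_idx = rng.choice(config.n_mirna, size=config.n_dem, replace=False)
    n_up = int(round(config.frac_up * config.n_dem))
    up = np.zeros(config.n_dem, dtype=bool)
    up[:n_up] = True
    rng.shuffle(up)
    true_fc = np.where(up, config.dem_fc, 1.0 / config.dem_fc)
    effect = np.ones(config.n_mirna)
    effect[dem_idx] = true_fc

    eps = rng.normal(0.0, 1.0, size=(config.n_mirna, n))
    log_latent_mirna = (
        np.log(base_mirna)[:, None]
        + np.log(effect)[:, None] * mut_mask[None, :]
        + config.bio_sd * eps
    )
    latent_mirna = np.exp(log_latent_mirna)
    mirna_counts = _nb_draw(rng, latent_mirna * lib_mirna[None, :], config.dispersion)

    # --- couplings: planted DEMs -> distinct genes
    coupled_genes = rng.choice(config.n_gene, size=config.n_couplings, replace=False)
    coupled_mirnas = (
        rng.choice(dem_idx, size=config.n_couplings, replace=True)
        if config.n_couplings
        else np.array([], dtype=int)
    )
    n_pos = int(round(config.frac_positive * config.n_couplings))
    signs = np.full(config.n_couplings, -1, dtype=int)
    signs[:n_pos] = 1
    rng.shuffle(signs)

    # --- mRNA layer
    base_gene = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=config.n_gene)
    )
    eta = rng.normal(0.0, 1.0, size=(config.n_gene, n))
    log_latent_gene = np.log(base_gene)[:, None] + config.bio_sd * eta
    c = config.coupling_strength
    for g_idx, m_idx, s in zip(coupled_genes, coupled_mirnas, signs):
        u = log_latent_mirna[m_idx]
        u = (u - u.mean()) / u.std()
        log_latent_gene[g_idx] = np.log(base_gene[g_idx]) + config.coupling_scale * (
            s * c * u + math.sqrt(1 - c**2) * eta[g_idx]
        )
    latent_gene = np.exp(log_latent_gene)
    mrna_counts = _nb_draw(rng, latent_gene * lib_mrna[None, :], config.dispersion)

    # --- target-prediction table: truths at VeryHigh + decoys across classes
    truths = {
        (mirna_ids[m], gene_ids[g]) for m, g in zip(coupled_mirnas, coupled_genes)
    }
    rows = [
        {"mirna_id": mirna_ids[m], "gene_id": gene_ids[g], "confidence_class": "VeryHigh"}
        for m, g in zip(coupled_mirnas, coupled_genes)
    ]
    n_decoys = config.decoy_factor * config.n_couplings
    seen = set(truths)
    while len(rows) < len(truths) + n_decoys:
        m = int(rng.integers(config.n_mirna))
        g = int(rng.integers(config.n_gene))
        key = (mirna_ids[m], gene_ids[g])
        if key in seen:
            continue
        seen.add(key)
        cls = CONFIDENCE_CLASSES[int(rng.integers(len(CONFIDENCE_CLASSES)))]
        rows.append({"mirna_id": key[0], "gene_id": key[1], "confidence_class": cls})
    target_map = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "confidence_class"])

    truth_dems = pd.DataFrame(
        {"mirna_id": [mirna_ids[i] for i in dem_idx], "true_fc": true_fc}
    ).sort_values("mirna_id", ignore_index=True)
    truth_couplings = pd.DataFrame(
        {
            "mirna_id": [mirna_ids[m] for m in coupled_mirnas],
            "gene_id": [gene_ids[g] for g in coupled_genes],
            "sign": np.where(signs > 0, "+", "-") if config.n_couplings else [],
        }
    ).sort_values(["mirna_id", "gene_id"], ignore_index=True)

    return SyntheticCohort(
        config=config,
        mirna_counts=CountMatrix(pd.DataFrame(mirna_counts, index=mirna_ids, columns=samples)),
        mrna_counts=CountMatrix(pd.DataFrame(mrna_counts, index=gene_ids, columns=samples)),
        annotations=groups,
        truth_dems=truth_dems,
        truth_couplings=truth_couplings,
        target_map=target_map,
        mirna_latent=pd.DataFrame(latent_mirna, index=mirna_ids, columns=samples),
        mrna_latent=pd.DataFrame(latent_gene, index=gene_ids, columns=samples),
    )


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a flat mapping (YAML-friendly)."""
    d = dict(d)
    if "libsize_range" in d:
        d["libsize_range"] = tuple(d["libsize_range"])
    return SimConfig(**d)


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["libsize_range"] = list(d["libsize_range"])
    return d
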