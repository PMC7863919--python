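"""End-to-end orchestration: filter -> DE -> target gate -> correlation
screen -> sign split -> enrichment -> concordance attribution.

Configuration is a flat key-value mapping (YAML on disk); every run
writes its stage outputs as TSV plus a JSON manifest echoing the
effective configuration, per-stage row counts and wall time, so a run is
reproducible from its own output directory. Identical configuration and
seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clinical import ContingencyTable, fisher_exact_two_sided
from .de import DifferentialExpression
from .enrich import read_gmt, run_signed_enrichment
from .fixtures import load_table2_counts, table4_attribution_inputs
from .integrate import IntegrationAnalysis, attribute_degs, targets_per_mirna
from .matrix import CountMatrix
from .simulate import SimConfig, config_from_dict, simulate_cohort

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_all",
    "validate_inputs",
    "run_paper_fixtures",
]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Either the four input paths are given, or ``simulate`` holds a
    :class:`~cortimir.simulate.SimConfig` mapping and the inputs are
    generated under ``outdir/inputs``.
    """

    outdir: str = "cortimir_run"
    mirna_counts: str | None = None
    mrna_counts: str | None = None
    annotations: str | None = None
    targets: str | None = None
    gmt: list[str] = field(default_factory=list)
    clinical: str | None = None
    dem_fc: float = 2.0
    de_alpha: float = 0.05
    corr_alpha: float = 0.01
    ora_alpha: float = 0.05
    min_reads: int = 5
    fraction: float = 0.5
    min_class: str = "VeryHigh"
    seed: int = 0
    simulate: dict | None = None

    def __post_init__(self) -> None:
        if not 0 < self.de_alpha < 1 or not 0 < self.corr_alpha < 1 or not 0 < self.ora_alpha < 1:
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if self.dem_fc <= 1:
            raise ValueError("dem_fc must exceed 1")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunManifest:
    """Reproducibility record written once per run."""

    config: dict
    version: str
    stage_rows: dict
    wall_time_s: float
    warnings: list

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_annotations(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError("annotations need columns: sample, group")
    return df.set_index("sample")["group"]


def read_targets(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"mirna_id", "gene_id", "confidence_class"}
    if not need <= set(df.columns):
        raise ValueError(f"target table needs columns: {sorted(need)}")
    return df


def _materialize_inputs(config: PipelineConfig) -> PipelineConfig:
    if config.simulate is None:
        return config
    indir = Path(config.outdir) / "inputs"
    sim = dict(config.simulate)
    sim.setdefault("seed", config.seed)
    cohort = simulate_cohort(config_from_dict(sim))
    cohort.to_dir(indir)
    config.mirna_counts = str(indir / "mirna_counts.tsv")
    config.mrna_counts = str(indir / "mrna_counts.tsv")
    config.annotations = str(indir / "annotations.tsv")
    config.targets = str(indir / "targets.tsv")
    return config


def validate_inputs(config: PipelineConfig) -> dict:
    """Check the declared inputs for internal consistency.

    Returns {"ok": bool, "problems": [...]}; problems are collected, not
    raised one by one.
    """
    problems: list[str] = []
    config = _materialize_inputs(config)
    matrices = {}
    for name in ("mirna_counts", "mrna_counts"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            problems.append(f"{name}: missing file {path}")
            continue
        try:
            matrices[name] = CountMatrix.from_tsv(path)
        except ValueError as exc:
            problems.append(f"{name}: {exc}")
    if config.annotations and Path(config.annotations).exists():
        try:
            ann = read_annotations(config.annotations)
            bad = set(ann.unique()) - {"mut", "wt"}
            if bad:
                problems.append(f"annotations: unknown group labels {sorted(bad)}")
            for name, mat in matrices.items():
                diff = set(mat.sample_ids) ^ set(ann.index)
                if diff:
                    problems.append(
                        f"{name}: sample ids disagree with annotations: {sorted(diff)}"
                    )
        except ValueError as exc:
            problems.append(f"annotations: {exc}")
    else:
        problems.append(f"annotations: missing file {config.annotations}")
    if config.targets and Path(config.targets).exists():
        try:
            targets = read_targets(config.targets)
            from .integrate import CONFIDENCE_ORDER

            bad = set(targets["confidence_class"]) - set(CONFIDENCE_ORDER)
            if bad:
                problems.append(f"targets: unknown confidence classes {sorted(bad)}")
        except ValueError as exc:
            problems.append(f"targets: {exc}")
    else:
        problems.append(f"targets: missing file {config.targets}")
    for gmt_path in config.gmt:
        try:
            read_gmt(gmt_path)
        except (OSError, ValueError) as exc:
            problems.append(f"gmt: {exc}")
    return {"ok": not problems, "problems": problems}


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute every stage and write outputs under ``config.outdir``."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    stage_rows: dict[str, int] = {}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    config = _materialize_inputs(config)
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        mirna = stage("read_mirna")(CountMatrix.from_tsv, config.mirna_counts)
        mrna = stage("read_mrna")(CountMatrix.from_tsv, config.mrna_counts)
        groups = stage("read_annotations")(read_annotations, config.annotations)
        targets = stage("read_targets")(read_targets, config.targets)

        de_mirna = stage("de_mirna")(
            DifferentialExpression(
                mirna, groups, min_reads=config.min_reads, fraction=config.fraction,
                fc_threshold=config.dem_fc, alpha=config.de_alpha,
            ).fit
        )
        de_mrna = stage("de_mrna")(
            DifferentialExpression(
                mrna, groups, min_reads=config.min_reads, fraction=config.fraction,
                fc_threshold=config.dem_fc, alpha=config.de_alpha,
            ).fit
        )
        de_mirna.to_tsv(outdir / "de_mirna.tsv")
        de_mrna.to_tsv(outdir / "de_mrna.tsv")
        stage_rows["de_mirna"] = len(de_mirna.table)
        stage_rows["de_mrna"] = len(de_mrna.table)

        integration = stage("integration")(
            IntegrationAnalysis(
                de_mirna, de_mrna, targets,
                corr_alpha=config.corr_alpha, min_class=config.min_class,
            ).fit
        )
        integration.correlation_records.to_csv(
            outdir / "correlations.tsv", sep="\t", index=False,
            float_format="%.6g", lineterminator="\n",
        )
        integration.to_tsv(outdir / "integration.tsv")
        stage_rows["correlations"] = integration.n_interactions
        stage_rows["correlations_negative"] = len(integration.negative)
        stage_rows["correlations_positive"] = len(integration.positive)
        stage_rows["attributed"] = len(integration.attributed)

        if config.gmt:
            universe = de_mrna.table.index.tolist()
            catalogs = [stage("read_gmt")(read_gmt, p) for p in config.gmt]
            enr = stage("enrichment")(
                run_signed_enrichment, integration, universe, catalogs,
                config.ora_alpha,
            )
            for (catalog, side), table in enr.items():
                table.to_csv(
                    outdir / f"enrichment_{catalog}_{side}.tsv", sep="\t",
                    index=False, float_format="%.6g", lineterminator="\n",
                )
                stage_rows[f"enrichment_{catalog}_{side}"] = len(table)
        caught = [str(w.message) for w in wlist]

    manifest = RunManifest(
        config={k: v for k, v in asdict(config).items()},
        version=__version__,
        stage_rows=stage_rows,
        wall_time_s=round(time.perf_counter() - t0, 3),
        warnings=caught,
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest


def run_paper_fixtures(outdir: str | Path) -> RunManifest:
    """Run the attribution and clinical paths on the packaged table
    fixtures (no expression matrices involved)."""
    t0 = time.perf_counter()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    t2 = load_table2_counts()
    t2 = t2.assign(
        p=[
            fisher_exact_two_sided(ContingencyTable(r.mut_a, r.mut_b, r.wt_a, r.wt_b))
            for r in t2.itertuples()
        ]
    )
    t2.to_csv(outdir / "table2_like.tsv", sep="\t", index=False,
              float_format="%.4f", lineterminator="\n")

    records, deg, dem = table4_attribution_inputs()
    attributed = attribute_degs(records, deg, dem)
    attributed.to_csv(outdir / "integration.tsv", sep="\t", index=False,
                      float_format="%.6g", lineterminator="\n")
    tpm = targets_per_mirna(records)
    tpm.to_csv(outdir / "targets_per_mirna.tsv", sep="\t", index=False,
               lineterminator="\n")

    manifest = RunManifest(
        config={"fixtures": "paper", "outdir": str(outdir)},
        version=__version__,
        stage_rows={
            "table2_like": len(t2),
            "attributed": len(attributed),
            "targets_per_mirna": len(tpm),
        },
        wall_time_s=round(time.perf_counter() - t0, 3),
        warnings=[],
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
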