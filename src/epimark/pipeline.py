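"""End-to-end orchestration: config schema, stage functions and an in-memory run.

Each stage reads the previous stage's TSV/BED artifacts from ``outdir`` and
writes its own, so stages can be re-run independently; ``discover_candidates``
performs the array → integration arm entirely in memory for programmatic use.
Every tunable threshold surfaces as a named config key with the workflow's
default value, and a run is deterministic given its config.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import array_meth, diagnostics, genome_integrate, pyroseq_quant, stats_tests, synthdata

logger = logging.getLogger(__name__)

TRACK_NAMES = ("cgi", "tss", "tf_peaks", "h3k4me1", "h3k27ac")


class GenomeCfg(BaseModel):
    n_chroms: int = Field(10, ge=1)
    chrom_length: int = Field(1_000_000, ge=10_000)


class SimulateCfg(BaseModel):
    n_genes: int = Field(200, ge=1)
    probes_per_gene: int = Field(3, ge=1)
    n_targets: int = Field(5, ge=0)
    decoys_per_class: int = Field(1, ge=0)
    planted_delta_beta: float = Field(-0.35, ge=-1.0, le=1.0)
    noise_sd: float = Field(0.0, ge=0.0)
    n_reps: int = Field(3, ge=1)
    case_label: str = "shTF"
    control_label: str = "control"


class CohortCfg(BaseModel):
    sizes: dict[str, int] = Field(default_factory=lambda: dict(synthdata.DEFAULT_GROUP_SIZES))
    n_im_serum: int = Field(3, ge=0)
    n_noncancer_serum: int = Field(20, ge=0)
    group_order: list[str] = Field(default_factory=lambda: ["gastritis", "IM", "cancer"])

    @field_validator("sizes")
    @classmethod
    def _nonneg(cls, v):
        for g, n in v.items():
            if n < 0:
                raise ValueError(f"negative size for group {g!r}")
        return v


class ThresholdCfg(BaseModel):
    delta_beta: float = Field(0.25, gt=0.0, lt=1.0)
    direction: Literal["hypo", "hyper", "both"] = "hypo"
    promoter_window: int = Field(genome_integrate.DEFAULT_PROMOTER_WINDOW, gt=0)
    flank: int = Field(genome_integrate.DEFAULT_FLANK, ge=0)
    format_mode: Literal["truncate1", "round1", "raw"] = "truncate1"


class RunConfig(BaseModel):
    outdir: str = "epimark_out"
    seed: int = 0
    genome: GenomeCfg = Field(default_factory=GenomeCfg)
    simulate: SimulateCfg = Field(default_factory=SimulateCfg)
    cohort: CohortCfg = Field(default_factory=CohortCfg)
    thresholds: ThresholdCfg = Field(default_factory=ThresholdCfg)

    @property
    def out(self) -> Path:
        return Path(self.outdir)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


class MissingArtifactError(FileNotFoundError):
    """A stage's input artifact is missing; names the stage to run first."""


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path}; run the '{producing_stage}' stage first"
        )
    return path


def _spec_truth(cfg: RunConfig) -> tuple[synthdata.GenomeSpec, synthdata.Manifest, synthdata.PlantedTruth]:
    spec = synthdata.GenomeSpec(
        n_chroms=cfg.genome.n_chroms,
        chrom_length=cfg.genome.chrom_length,
        rng_seed=cfg.seed,
    )
    manifest = synthdata.gen_probe_manifest(
        spec,
        n_genes=cfg.simulate.n_genes,
        probes_per_gene=cfg.simulate.probes_per_gene,
        promoter_window=cfg.thresholds.promoter_window,
    )
    truth = synthdata.default_truth(
        manifest,
        n_targets=cfg.simulate.n_targets,
        decoys_per_class=cfg.simulate.decoys_per_class,
        planted_delta_beta=cfg.simulate.planted_delta_beta,
        noise_sd=cfg.simulate.noise_sd,
    )
    return spec, manifest, truth


def stage_simulate(cfg: RunConfig) -> dict[str, str]:
    """Generate and write every pipeline input (array, tracks, cohort, pyro)."""
    out = cfg.out
    out.mkdir(parents=True, exist_ok=True)
    spec, manifest, truth = _spec_truth(cfg)
    logger.info(
        "simulate: %d genes on %d chrom(s), %d targets, Δβ=%.3f, noise_sd=%.3f, seed=%d",
        cfg.simulate.n_genes, cfg.genome.n_chroms, cfg.simulate.n_targets,
        cfg.simulate.planted_delta_beta, cfg.simulate.noise_sd, cfg.seed,
    )
    manifest.probes.to_csv(out / "manifest.tsv", sep="\t", index=False)
    manifest.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    tables = synthdata.gen_intensities(
        manifest,
        truth,
        conditions=(cfg.simulate.case_label, cfg.simulate.control_label),
        n_reps=cfg.simulate.n_reps,
        seed=cfg.seed,
    )
    for cond, table in tables.items():
        array_meth.write_intensity_table(table, out / f"intensities_{cond}.tsv")
    tracks = synthdata.gen_annotation_tracks(spec, manifest, truth)
    synthdata.write_tracks(tracks, out / "tracks")
    cohort, signals = synthdata.gen_cohort(
        sizes=cfg.cohort.sizes,
        truth=truth,
        seed=cfg.seed,
        n_im_serum=cfg.cohort.n_im_serum,
        n_noncancer_serum=cfg.cohort.n_noncancer_serum,
    )
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    signals.to_csv(out / "pyro_signals.tsv", sep="\t", index=False)
    with open(out / "planted_truth.tsv", "w") as fh:
        fh.write("gene\trole\n")
        for g in truth.target_genes:
            fh.write(f"{g}\ttarget\n")
        for g, klass in truth.decoy_genes.items():
            fh.write(f"{g}\tdecoy:{klass}\n")
    return {"outdir": str(out)}


def stage_array(cfg: RunConfig) -> pd.Series:
    """β matrices per condition, Δβ table and the differential probe list."""
    out = cfg.out
    case, control = cfg.simulate.case_label, cfg.simulate.control_label
    tables = {}
    for cond in (case, control):
        path = _require(out / f"intensities_{cond}.tsv", "simulate")
        tables[cond] = array_meth.beta_matrix(array_meth.read_intensity_table(path))
        tables[cond].to_csv(out / f"beta_{cond}.tsv", sep="\t")
    deltas = array_meth.delta_beta(tables[case], tables[control])
    array_meth.write_delta_table(deltas, out / "delta_beta.tsv")
    selected = array_meth.select_differential(
        deltas, threshold=cfg.thresholds.delta_beta, direction=cfg.thresholds.direction
    )
    deltas.loc[selected].sort_values().to_frame().to_csv(
        out / "differential_probes.tsv", sep="\t"
    )
    logger.info(
        "array: %d/%d probes pass |Δβ| threshold %.2f (%s)",
        len(selected), len(deltas), cfg.thresholds.delta_beta, cfg.thresholds.direction,
    )
    return deltas


def stage_integrate(cfg: RunConfig) -> list[genome_integrate.CandidateGene]:
    """Interval integration of differential probes with annotation tracks."""
    out = cfg.out
    diff = pd.read_csv(
        _require(out / "differential_probes.tsv", "array"), sep="\t", index_col="probe_id"
    )["delta_beta"]
    manifest = pd.read_csv(_require(out / "manifest.tsv", "simulate"), sep="\t")
    tracks = {
        name: genome_integrate.read_bed(_require(out / "tracks" / f"{name}.bed", "simulate"))
        for name in TRACK_NAMES
    }
    enh = genome_integrate.enhancers(tracks["h3k4me1"], tracks["h3k27ac"])
    promoters = genome_integrate.promoter_cgi_map(
        tracks["tss"], tracks["cgi"], window=cfg.thresholds.promoter_window
    )
    candidates = genome_integrate.candidate_genes(
        dict(diff),
        manifest,
        tracks["tf_peaks"],
        enh,
        promoters,
        flank=cfg.thresholds.flank,
    )
    genome_integrate.write_candidates(candidates, out / "candidates.tsv")
    logger.info("integrate: %d candidate gene(s)", len(candidates))
    return candidates


def stage_pyro(cfg: RunConfig) -> pd.DataFrame:
    """Per-sample pyrosequencing summaries from the per-site signal table."""
    out = cfg.out
    assay = pyroseq_quant.read_signal_table(
        _require(out / "pyro_signals.tsv", "simulate"), assay_name="promoter_assay"
    )
    summary = pyroseq_quant.summarize_all(assay)
    summary.to_csv(out / "pyro_summary.tsv", sep="\t", index=False)
    return summary


def stage_stats(cfg: RunConfig) -> stats_tests.TrendResult:
    """Progression-trend report over the configured group order."""
    out = cfg.out
    cohort = pd.read_csv(_require(out / "cohort.tsv", "simulate"), sep="\t")
    groups = stats_tests.groups_from_long(
        cohort, cfg.cohort.group_order, value_col="tissue_meth_pct"
    )
    trend = stats_tests.progression_trend(groups)
    rows = [
        {"comparison": f"{trend.labels[i]} vs {trend.labels[i+1]}",
         "U": r.U, "p": r.p, "mode": r.mode_used, "significant": r.significant}
        for i, r in enumerate(trend.pairwise)
    ]
    pd.DataFrame(rows).to_csv(out / "trend_tests.tsv", sep="\t", index=False)
    pd.DataFrame({"group": trend.labels, "median": trend.medians}).to_csv(
        out / "trend_medians.tsv", sep="\t", index=False
    )
    logger.info(
        "stats: medians %s, monotone=%s", dict(zip(trend.labels, trend.medians)), trend.monotone
    )
    return trend


def stage_diagnose(cfg: RunConfig) -> diagnostics.DxReport:
    """Serum-MSP diagnostic report (cancer-only and cancer-or-IM blocks)."""
    out = cfg.out
    cohort = pd.read_csv(_require(out / "cohort.tsv", "simulate"), sep="\t")
    report = diagnostics.table_report(cohort, mode=cfg.thresholds.format_mode)
    diagnostics.report_frame(report).to_csv(out / "dx_report.tsv", sep="\t", index=False)
    text = diagnostics.report_text(report)
    (out / "dx_report.txt").write_text(text + "\n")
    logger.info("diagnose:\n%s", text)
    return report


STAGES = {
    "simulate": stage_simulate,
    "array": stage_array,
    "integrate": stage_integrate,
    "pyro": stage_pyro,
    "stats": stage_stats,
    "diagnose": stage_diagnose,
}
STAGE_ORDER = tuple(STAGES)


def run(cfg: RunConfig, stages: Sequence[str] = STAGE_ORDER) -> dict[str, object]:
    """Run the requested stages in canonical order; returns stage results."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid: {list(STAGES)}")
    results = {}
    for name in STAGE_ORDER:
        if name in stages:
            results[name] = STAGES[name](cfg)
    return results


def discover_candidates(
    spec: synthdata.GenomeSpec,
    truth: synthdata.PlantedTruth,
    n_genes: int,
    probes_per_gene: int = 3,
    n_reps: int = 3,
    threshold: float = 0.25,
    direction: str = "hypo",
    promoter_window: int = genome_integrate.DEFAULT_PROMOTER_WINDOW,
    flank: int = genome_integrate.DEFAULT_FLANK,
    manifest: synthdata.Manifest | None = None,
) -> list[genome_integrate.CandidateGene]:
    """In-memory discovery arm: simulate → β/Δβ screen → interval integration.

    Uses ``spec.rng_seed`` for both placement and intensity noise.  When a
    pre-built manifest is supplied, placement is skipped (useful for holding
    the layout fixed while varying noise seeds).
    """
    if manifest is None:
        manifest = synthdata.gen_probe_manifest(
            spec, n_genes, probes_per_gene, promoter_window=promoter_window
        )
    tables = synthdata.gen_intensities(manifest, truth, n_reps=n_reps, seed=spec.rng_seed)
    (case, control) = tables
    betas = {c: array_meth.beta_matrix(t) for c, t in tables.items()}
    deltas = array_meth.delta_beta(betas[case], betas[control])
    selected = array_meth.select_differential(deltas, threshold=threshold, direction=direction)
    tracks = synthdata.gen_annotation_tracks(spec, manifest, truth)
    enh = genome_integrate.enhancers(tracks["h3k4me1"], tracks["h3k27ac"])
    promoters = genome_integrate.promoter_cgi_map(
        tracks["tss"], tracks["cgi"], window=promoter_window
    )
    return genome_integrate.candidate_genes(
        dict(deltas.loc[selected]),
        manifest.probes,
        tracks["tf_peaks"],
        enh,
        promoters,
        flank=flank,
    )
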