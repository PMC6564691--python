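"""Synthetic study generator with planted ground truth.

Emulates every input of the discovery-and-validation workflow:

* a two-condition methylation array (TF-knockdown vs control) in which the
  probes of planted target genes carry a known Δβ on the β scale;
* annotation tracks (CpG islands, TSS anchors, TF ChIP peaks, H3K4me1 and
  H3K27Ac peaks) in which planted targets carry the full evidence chain —
  promoter CpG island, TF peak inside an H3K4me1∩H3K27Ac enhancer near the
  island — while decoy genes carry deliberately incomplete evidence;
* a disease-progression cohort (gastritis → intestinal metaplasia → cancer)
  with per-group tissue methylation levels, per-CpG pyrosequencing signals
  consistent with each sample's methylation, and binary serum MSP calls
  drawn at configurable per-group positivity rates.

Noise is applied on the β scale and converted to (M, U) intensities at a
fixed total signal M + U = 1000 per probe, which keeps a planted Δβ exact at
zero noise and makes the β-formula's +100 offset observable.  A single
user-visible seed drives one RNG per operation; the draw order is fixed
(base β per probe, then noise per condition in argument order, replicate by
replicate; cohort draws group by group in size-map order: tissue %, then
MSP call, then pyro site noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .array_meth import BETA_OFFSET
from .genome_integrate import GenomicInterval, Track

TOTAL_INTENSITY = 1000.0
BETA_MAX = TOTAL_INTENSITY / (TOTAL_INTENSITY + BETA_OFFSET)  # largest representable β

#: slot width per gene; wide enough that one gene's evidence can never fall
#: within the default 5 kb flank of a neighbour's promoter island
GENE_SLOT = 20_000
TSS_JITTER = 1_000

DecoyClass = Literal["peak_no_enhancer", "enhancer_no_peak", "no_cgi", "no_delta"]
DECOY_CLASSES: tuple[str, ...] = ("peak_no_enhancer", "enhancer_no_peak", "no_cgi", "no_delta")

#: cohort defaults: tissue sample counts and group methylation means (%)
DEFAULT_GROUP_SIZES = {"gastritis": 34, "IM": 33, "cancer": 53}
DEFAULT_GROUP_MEANS = {
    "normal": 4.0,
    "gastritis": 5.0,
    "adjacent-normal": 10.0,
    "IM": 15.0,
    "cancer": 25.0,
}
#: serum MSP positivity: high in cancer, intermediate in IM, low in controls
DEFAULT_MSP_RATES = {
    "normal": 0.25,
    "gastritis": 0.25,
    "adjacent-normal": 0.25,
    "IM": 2 / 3,
    "cancer": 47 / 53,
}
N_PYRO_SITES = 6


class SizingError(ValueError):
    """Genome cannot accommodate the requested gene layout."""


@dataclass(frozen=True)
class GenomeSpec:
    n_chroms: int = 10
    chrom_length: int = 1_000_000
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_chroms < 1:
            raise ValueError("need at least one chromosome")
        if self.chrom_length < 10_000:
            raise ValueError("chrom_length must be at least 10 kb")

    def chrom_name(self, i: int) -> str:
        return f"chr{i + 1}"


@dataclass
class PlantedTruth:
    """Ground truth planted into the synthetic study.

    ``decoy_genes`` maps gene id → incomplete-evidence class; decoys (except
    class ``no_delta``) receive the planted Δβ too, so only the annotation
    filter separates them from true targets.
    """

    target_genes: list[str] = field(default_factory=list)
    decoy_genes: dict[str, str] = field(default_factory=dict)
    planted_delta_beta: float = -0.35
    noise_sd: float = 0.0
    control_beta: float = 0.70
    group_methylation_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MEANS)
    )
    group_methylation_sd: float = 6.0
    group_msp_positive_rate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MSP_RATES)
    )

    def __post_init__(self):
        if not -1.0 <= self.planted_delta_beta <= 1.0:
            raise ValueError("planted_delta_beta must be in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.control_beta + self.planted_delta_beta <= BETA_MAX:
            raise ValueError(
                f"control β {self.control_beta} + Δβ {self.planted_delta_beta} "
                f"falls outside the representable range [0, {BETA_MAX:.4f}]"
            )
        for g, m in self.group_methylation_means.items():
            if not 0 <= m <= 100:
                raise ValueError(f"group mean for {g!r} outside [0,100]: {m}")
        for g, p in self.group_msp_positive_rate.items():
            if not 0 <= p <= 1:
                raise ValueError(f"MSP positive rate for {g!r} outside [0,1]: {p}")
        bad = [c for c in self.decoy_genes.values() if c not in DECOY_CLASSES]
        if bad:
            raise ValueError(f"unknown decoy classes {sorted(set(bad))}; valid: {DECOY_CLASSES}")
        overlap = set(self.target_genes) & set(self.decoy_genes)
        if overlap:
            raise ValueError(f"genes listed as both target and decoy: {sorted(overlap)}")

    @property
    def delta_genes(self) -> set[str]:
        """Genes whose probes carry the planted Δβ (targets + non-``no_delta`` decoys)."""
        return set(self.target_genes) | {
            g for g, c in self.decoy_genes.items() if c != "no_delta"
        }


@dataclass
class Manifest:
    """Array manifest: probe coordinates plus the gene layout they derive from."""

    probes: pd.DataFrame  # probe_id, chrom, pos, gene
    genes: pd.DataFrame  # gene, chrom, tss
    promoter_window: int

    @property
    def gene_ids(self) -> list[str]:
        return self.genes["gene"].tolist()


def gen_probe_manifest(
    spec: GenomeSpec,
    n_genes: int,
    probes_per_gene: int = 3,
    promoter_window: int = 2000,
) -> Manifest:
    """Place genes on the genome and probes inside their promoter windows.

    Genes occupy non-overlapping 20 kb slots (filled chromosome by
    chromosome) so promoter windows never overlap and one gene's annotation
    cannot contaminate a neighbour's.  Probe positions are drawn uniformly
    without replacement within ±promoter_window of the TSS.  Deterministic
    for a fixed ``spec.rng_seed``.
    """
    if n_genes < 1:
        raise SizingError("n_genes must be at least 1")
    if probes_per_gene < 1:
        raise SizingError("probes_per_gene must be at least 1")
    slots_per_chrom = spec.chrom_length // GENE_SLOT
    if slots_per_chrom < 1 or n_genes > slots_per_chrom * spec.n_chroms:
        raise SizingError(
            f"genome ({spec.n_chroms} × {spec.chrom_length} bp) too short for "
            f"{n_genes} genes at one per {GENE_SLOT} bp slot"
        )
    rng = np.random.default_rng(spec.rng_seed)
    genes, probe_rows = [], []
    probe_counter = 0
    for gi in range(n_genes):
        chrom = spec.chrom_name(gi // slots_per_chrom)
        slot = gi % slots_per_chrom
        center = slot * GENE_SLOT + GENE_SLOT // 2
        tss = int(center + rng.integers(-TSS_JITTER, TSS_JITTER + 1))
        gene = f"gene{gi + 1:04d}"
        genes.append({"gene": gene, "chrom": chrom, "tss": tss})
        lo, hi = tss - promoter_window, tss + promoter_window
        positions = np.sort(rng.choice(np.arange(lo, hi), size=probes_per_gene, replace=False))
        for pos in positions:
            probe_counter += 1
            probe_rows.append(
                {
                    "probe_id": f"cg{probe_counter:08d}",
                    "chrom": chrom,
                    "pos": int(pos),
                    "gene": gene,
                }
            )
    return Manifest(
        probes=pd.DataFrame(probe_rows),
        genes=pd.DataFrame(genes),
        promoter_window=promoter_window,
    )


def gen_intensities(
    manifest: Manifest,
    truth: PlantedTruth,
    conditions: tuple[str, str] = ("shTF", "control"),
    n_reps: int = 3,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Two-condition intensity tables with the planted Δβ on target genes.

    The first condition label is the case (TF knockdown), the second the
    control.  Expected β is equal across conditions for unplanted probes and
    differs by exactly ``planted_delta_beta`` for planted ones; Gaussian
    noise of sd ``noise_sd`` is added on the β scale, clipped to the
    representable range, and converted to (M, U) at fixed total intensity.
    """
    if len(conditions) != 2 or conditions[0] == conditions[1]:
        raise ValueError("conditions must be two distinct labels (case, control)")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    known = set(manifest.gene_ids)
    for g in sorted(truth.delta_genes | set(truth.decoy_genes)):
        if g not in known:
            raise ValueError(f"planted gene {g!r} is not in the manifest")

    probes = manifest.probes
    rng = np.random.default_rng(seed)
    planted = probes["gene"].isin(truth.delta_genes).to_numpy()
    base = rng.uniform(0.05, 0.85, size=len(probes))
    base[planted] = truth.control_beta

    case, control = conditions
    out: dict[str, pd.DataFrame] = {}
    for cond in (case, control):
        expected = base.copy()
        if cond == case:
            expected = expected + np.where(planted, truth.planted_delta_beta, 0.0)
        table = probes.copy()
        for rep in range(1, n_reps + 1):
            noisy = expected + (
                rng.normal(0.0, truth.noise_sd, size=len(probes)) if truth.noise_sd > 0 else 0.0
            )
            beta = np.clip(noisy, 0.0, BETA_MAX)
            M = beta * (TOTAL_INTENSITY + BETA_OFFSET)
            U = TOTAL_INTENSITY - M
            name = f"{cond}_{rep}"
            table[f"M_{name}"] = M
            table[f"U_{name}"] = U
        out[cond] = table
    return out


def _evidence_intervals(gene: str, chrom: str, tss: int, window: int):
    """Canonical evidence geometry around one gene's TSS (full-evidence layout)."""
    cgi = GenomicInterval(chrom, max(0, tss - window), tss + window, f"CGI_{gene}")
    peak = GenomicInterval(chrom, tss + window + 500, tss + window + 900, f"TF_{gene}")
    k4 = GenomicInterval(chrom, tss + window + 400, tss + window + 1000, f"K4me1_{gene}")
    k27 = GenomicInterval(chrom, tss + window + 300, tss + window + 1100, f"K27Ac_{gene}")
    return cgi, peak, k4, k27


def gen_annotation_tracks(
    spec: GenomeSpec, manifest: Manifest, truth: PlantedTruth
) -> dict[str, Track]:
    """Five annotation tracks with complete evidence at targets, holes at decoys.

    Targets (and ``no_delta`` decoys) get a promoter CpG island, a TF peak
    ~500 bp downstream of it and both histone-mark peaks covering that peak.
    ``peak_no_enhancer`` decoys lack the H3K27Ac peak, ``enhancer_no_peak``
    decoys lack the TF peak, ``no_cgi`` decoys lack the island.  Plain genes
    get a CpG island and TSS anchor only.
    """
    window = manifest.promoter_window
    tracks: dict[str, Track] = {"cgi": [], "tss": [], "tf_peaks": [], "h3k4me1": [], "h3k27ac": []}
    for row in manifest.genes.itertuples():
        gene, chrom, tss = row.gene, row.chrom, int(row.tss)
        if tss + window + 1100 > spec.chrom_length:
            raise SizingError(f"gene {gene} evidence exceeds chromosome bounds")
        tracks["tss"].append(GenomicInterval(chrom, tss, tss + 1, gene))
        cgi, peak, k4, k27 = _evidence_intervals(gene, chrom, tss, window)
        klass = truth.decoy_genes.get(gene)
        is_planted = gene in truth.target_genes or klass is not None
        if klass != "no_cgi":
            tracks["cgi"].append(cgi)
        if not is_planted:
            continue
        if klass != "enhancer_no_peak":
            tracks["tf_peaks"].append(peak)
        tracks["h3k4me1"].append(k4)
        if klass != "peak_no_enhancer":
            tracks["h3k27ac"].append(k27)
    return tracks


def gen_cohort(
    sizes: Mapping[str, int] | None = None,
    truth: PlantedTruth | None = None,
    seed: int = 0,
    n_im_serum: int = 3,
    n_noncancer_serum: int = 20,
    cancer_group: str = "cancer",
    im_group: str = "IM",
    pyro_site_sd: float = 2.0,
    pyro_total_signal: float = 100.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disease-progression cohort with tissue %, serum MSP calls and pyro signals.

    Returns ``(cohort, pyro_signals)``: the cohort table (sample_id, group,
    tissue_meth_pct, msp_call, serum_available) and a long per-site signal
    table (sample_id, site_index, C, T) whose C/(C+T) is consistent with the
    sample's tissue methylation at each of the six CpG sites.

    Serum availability defaults mirror a serum substudy: every cancer
    sample, ``n_im_serum`` IM samples and ``n_noncancer_serum`` samples from
    the remaining (non-cancer, non-IM) groups.
    """
    truth = truth if truth is not None else PlantedTruth()
    sizes = dict(DEFAULT_GROUP_SIZES) if sizes is None else dict(sizes)
    for g, n in sizes.items():
        if n < 0:
            raise ValueError(f"negative group size for {g!r}")
        if n > 0 and g not in truth.group_methylation_means:
            raise ValueError(f"no methylation mean configured for group {g!r}")
        if n > 0 and g not in truth.group_msp_positive_rate:
            raise ValueError(f"no MSP positive rate configured for group {g!r}")
    rng = np.random.default_rng(seed)
    rows, signal_rows = [], []
    noncancer_serum_left = n_noncancer_serum
    im_serum_left = n_im_serum
    for group, n in sizes.items():
        mean = truth.group_methylation_means.get(group, 0.0)
        rate = truth.group_msp_positive_rate.get(group, 0.0)
        for i in range(n):
            sample_id = f"{group}_{i + 1:03d}"
            tissue = float(np.clip(rng.normal(mean, truth.group_methylation_sd), 0.0, 100.0))
            msp = "M" if rng.random() < rate else "U"
            if group == cancer_group:
                serum = 1
            elif group == im_group:
                serum = 1 if im_serum_left > 0 else 0
                im_serum_left -= serum
            else:
                serum = 1 if noncancer_serum_left > 0 else 0
                noncancer_serum_left -= serum
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "tissue_meth_pct": tissue,
                    "msp_call": msp,
                    "serum_available": serum,
                }
            )
            site_m = np.clip(
                tissue + rng.normal(0.0, pyro_site_sd, size=N_PYRO_SITES), 0.0, 100.0
            )
            C = site_m / 100.0 * pyro_total_signal
            for s in range(N_PYRO_SITES):
                signal_rows.append(
                    {
                        "sample_id": sample_id,
                        "site_index": s,
                        "C": float(C[s]),
                        "T": float(pyro_total_signal - C[s]),
                    }
                )
    columns = ["sample_id", "group", "tissue_meth_pct", "msp_call", "serum_available"]
    cohort = pd.DataFrame(rows, columns=columns)
    signals = pd.DataFrame(signal_rows, columns=["sample_id", "site_index", "C", "T"])
    return cohort, signals


def default_truth(
    manifest: Manifest,
    n_targets: int = 5,
    decoys_per_class: int = 1,
    planted_delta_beta: float = -0.35,
    noise_sd: float = 0.0,
) -> PlantedTruth:
    """Convenience truth assignment: first genes become targets, then decoys."""
    genes = manifest.gene_ids
    need = n_targets + decoys_per_class * len(DECOY_CLASSES)
    if need > len(genes):
        raise SizingError(f"manifest has {len(genes)} genes, need {need} for truth layout")
    targets = genes[:n_targets]
    decoys: dict[str, str] = {}
    k = n_targets
    for klass in DECOY_CLASSES:
        for _ in range(decoys_per_class):
            decoys[genes[k]] = klass
            k += 1
    return PlantedTruth(
        target_genes=list(targets),
        decoy_genes=decoys,
        planted_delta_beta=planted_delta_beta,
        noise_sd=noise_sd,
    )


def write_tracks(tracks: Mapping[str, Track], outdir) -> dict[str, str]:
    """Write each track as 4-column BED; returns name → path."""
    from pathlib import Path

    from .genome_integrate import write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, track in tracks.items():
        p = outdir / f"{name}.bed"
        write_bed(track, p)
        paths[name] = str(p)
    return paths
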