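"""Interval integration of annotation tracks to nominate candidate TF-target genes.

A gene is nominated when three pieces of evidence co-occur:

1. at least one differentially hypomethylated array probe lies within (or
   within a configurable flank of) the gene's promoter CpG island;
2. at least one TF ChIP peak overlaps a putative enhancer, where an enhancer
   is the base-wise intersection of H3K4me1 and H3K27Ac peak tracks;
3. that peak∩enhancer interval lies within the flank distance of the same
   promoter CpG island.

All coordinates are 0-based half-open (BED convention); overlap means at
least one shared base.  Interval set algebra is delegated to pyranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pyranges as pr

DEFAULT_PROMOTER_WINDOW = 2000
DEFAULT_FLANK = 5000


@dataclass(frozen=True)
class GenomicInterval:
    """A named genomic interval, 0-based half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.name}: {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r} on {self.name}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Bases separating two intervals on the same chrom; 0 if they overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(self.start - other.end, other.start - self.end, 0)

    @property
    def length(self) -> int:
        return self.end - self.start


Track = list[GenomicInterval]


def read_bed(path) -> Track:
    """Read a 4-column (or 6-column, with strand) BED file."""
    out: Track = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, name, strand))
    return out


def write_bed(track: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in track:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def _to_pyranges(track: Sequence[GenomicInterval]) -> pr.PyRanges:
    if not track:
        return pr.PyRanges(
            pd.DataFrame({"Chromosome": [], "Start": [], "End": []}).astype(
                {"Start": int, "End": int}
            )
        )
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [iv.chrom for iv in track],
                "Start": [iv.start for iv in track],
                "End": [iv.end for iv in track],
            }
        )
    )


def _from_pyranges(ranges: pr.PyRanges, prefix: str) -> Track:
    df = ranges.df
    if df.empty:
        return []
    df = df.sort_values(["Chromosome", "Start"]).reset_index(drop=True)
    return [
        GenomicInterval(str(row.Chromosome), int(row.Start), int(row.End), f"{prefix}_{i+1}")
        for i, row in enumerate(df.itertuples())
    ]


def _validate(track: Sequence[GenomicInterval]) -> None:
    # dataclass construction already enforces start < end; guard raw tuples too
    for iv in track:
        if not isinstance(iv, GenomicInterval):
            raise TypeError(f"expected GenomicInterval, got {type(iv).__name__}")


def intersect_tracks(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval], prefix: str = "int"
) -> Track:
    """Set-intersection geometry of two tracks.

    Returns the maximal sorted, non-overlapping intervals covered by at least
    one interval of ``a`` and at least one of ``b`` (per chromosome).  Inputs
    may be unsorted and internally overlapping.
    """
    _validate(a)
    _validate(b)
    if not a or not b:
        return []
    merged_a = _to_pyranges(a).merge()
    merged_b = _to_pyranges(b).merge()
    return _from_pyranges(merged_a.intersect(merged_b), prefix)


def merge_track(a: Sequence[GenomicInterval], prefix: str = "merged") -> Track:
    _validate(a)
    if not a:
        return []
    return _from_pyranges(_to_pyranges(a).merge(), prefix)


def enhancers(k4me1: Sequence[GenomicInterval], k27ac: Sequence[GenomicInterval]) -> Track:
    """Putative enhancers: bases carrying both H3K4me1 and H3K27Ac peaks."""
    return intersect_tracks(k4me1, k27ac, prefix="enh")


def promoter_cgi_map(
    tss: Sequence[GenomicInterval],
    cgi: Sequence[GenomicInterval],
    window: int = DEFAULT_PROMOTER_WINDOW,
) -> dict[str, Track]:
    """Map gene → CpG-island intervals overlapping its promoter window.

    The promoter window is ``[tss − window, tss + window)`` (anchored on the
    TSS interval's start, clipped at 0, symmetric so strand is moot).  Genes
    with no overlapping island are absent from the map.
    """
    _validate(tss)
    _validate(cgi)
    if window <= 0:
        raise ValueError("window must be positive")
    names = [iv.name for iv in tss]
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate gene ids in TSS track: {dups}")
    out: dict[str, Track] = {}
    for t in tss:
        lo, hi = max(0, t.start - window), t.start + window
        if lo >= hi:
            continue
        win = GenomicInterval(t.chrom, lo, hi, t.name)
        hits = [c for c in cgi if c.overlaps(win)]
        if hits:
            out[t.name] = sorted(hits, key=lambda c: (c.chrom, c.start, c.end))
    return out


@dataclass
class CandidateGene:
    """A gene passing the full evidence filter, with the intervals that qualified it."""

    gene: str
    probe_ids: list[str]
    probe_deltas: list[float]
    cgi: GenomicInterval
    tf_enhancer_site: GenomicInterval
    rank_key: float = field(init=False)

    def __post_init__(self):
        if not self.probe_ids:
            raise ValueError(f"candidate {self.gene} has no supporting probes")
        self.rank_key = min(self.probe_deltas)


def candidate_genes(
    diff_probes: Mapping[str, float],
    manifest: pd.DataFrame,
    tf_peaks: Sequence[GenomicInterval],
    enhancer_track: Sequence[GenomicInterval],
    promoters: Mapping[str, Sequence[GenomicInterval]],
    flank: int = DEFAULT_FLANK,
) -> list[CandidateGene]:
    """Genes with a differential promoter-CGI probe plus a nearby TF-bound enhancer.

    Parameters
    ----------
    diff_probes
        probe_id → Δβ for probes passing the differential filter.
    manifest
        Probe manifest with probe_id, chrom, pos columns.
    tf_peaks, enhancer_track
        ChIP peak track of the TF and the H3K4me1∩H3K27Ac track.
    promoters
        Output of :func:`promoter_cgi_map`.
    flank
        Maximum distance (bases) between evidence and the promoter CGI; a probe
        within ``flank`` of the island, and a peak∩enhancer site within
        ``flank`` of the island, both qualify.  Overlap counts as distance 0.

    Returns candidates sorted by rank_key ascending (most hypomethylated
    first), ties broken by gene id.
    """
    unknown = set(diff_probes) - set(manifest["probe_id"])
    if unknown:
        raise ValueError(f"differential probes absent from manifest: {sorted(unknown)}")
    probe_pos = manifest.set_index("probe_id")[["chrom", "pos"]]
    tf_in_enh = intersect_tracks(tf_peaks, enhancer_track, prefix="tf_enh")

    out: list[CandidateGene] = []
    for gene, islands in promoters.items():
        for island in islands:
            lo, hi = max(0, island.start - flank), island.end + flank
            hit_ids, hit_deltas = [], []
            for pid, db in diff_probes.items():
                row = probe_pos.loc[pid]
                if row["chrom"] == island.chrom and lo <= int(row["pos"]) < hi:
                    hit_ids.append(pid)
                    hit_deltas.append(float(db))
            if not hit_ids:
                continue
            site = next(
                (
                    s
                    for s in tf_in_enh
                    if s.chrom == island.chrom and s.gap_to(island) <= flank
                ),
                None,
            )
            if site is None:
                continue
            order = sorted(range(len(hit_ids)), key=lambda i: (hit_deltas[i], hit_ids[i]))
            out.append(
                CandidateGene(
                    gene=gene,
                    probe_ids=[hit_ids[i] for i in order],
                    probe_deltas=[hit_deltas[i] for i in order],
                    cgi=island,
                    tf_enhancer_site=site,
                )
            )
            break  # one qualifying island is enough per gene
    out.sort(key=lambda c: (c.rank_key, c.gene))
    return out


def write_candidates(candidates: Sequence[CandidateGene], path) -> None:
    rows = [
        {
            "gene": c.gene,
            "rank_key": c.rank_key,
            "probe_ids": ",".join(c.probe_ids),
            "probe_deltas": ",".join(f"{d:.6g}" for d in c.probe_deltas),
            "cgi": f"{c.cgi.chrom}:{c.cgi.start}-{c.cgi.end}",
            "tf_enhancer_site": (
                f"{c.tf_enhancer_site.chrom}:{c.tf_enhancer_site.start}-{c.tf_enhancer_site.end}"
            ),
        }
        for c in candidates
    ]
    pd.DataFrame(
        rows, columns=["gene", "rank_key", "probe_ids", "probe_deltas", "cgi", "tf_enhancer_site"]
    ).to_csv(path, sep="\t", index=False)
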