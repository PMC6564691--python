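import numpy as np
import pytest

from epimark import synthdata
from epimark.genome_integrate import GenomicInterval


@pytest.fixture(scope="session")
def small_spec():
    return synthdata.GenomeSpec(n_chroms=2, chrom_length=200_000, rng_seed=11)


@pytest.fixture(scope="session")
def small_manifest(small_spec):
    return synthdata.gen_probe_manifest(small_spec, n_genes=18, probes_per_gene=3)


@pytest.fixture(scope="session")
def planted_truth(small_manifest):
    """3 targets plus one decoy of every incomplete-evidence class, zero noise."""
    return synthdata.default_truth(small_manifest, n_targets=3, decoys_per_class=1)


def random_track(rng, chrom="chr1", n=20, genome=100_000, max_len=3_000):
    out = []
    for i in range(n):
        start = int(rng.integers(0, genome - 1))
        end = int(min(genome, start + 1 + rng.integers(0, max_len)))
        out.append(GenomicInterval(chrom, start, end, f"iv{i}"))
    return out


def coverage_mask(track, genome=100_000):
    """Per-base boolean coverage: the brute-force oracle for interval algebra."""
    mask = np.zeros(genome, dtype=bool)
    for iv in track:
        mask[iv.start : iv.end] = True
    return mask


def mask_to_intervals(mask):
    """Maximal runs of True, as (start, end) half-open pairs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[0::2], edges[1::2]))
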