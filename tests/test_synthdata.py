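"""Synthetic study generator: determinism, planted signal, cohort properties."""

import numpy as np
import pandas as pd
import pytest

from epimark import array_meth, synthdata
from epimark.synthdata import (
    BETA_MAX,
    GenomeSpec,
    PlantedTruth,
    SizingError,
    default_truth,
    gen_annotation_tracks,
    gen_cohort,
    gen_intensities,
    gen_probe_manifest,
)


class TestManifest:
    def test_counts_match_arguments(self):
        spec = GenomeSpec(n_chroms=1, chrom_length=1_000_000, rng_seed=0)
        m = gen_probe_manifest(spec, n_genes=10, probes_per_gene=3)
        assert len(m.probes) == 30
        assert m.probes["gene"].nunique() == 10
        assert m.probes["probe_id"].is_unique

    def test_probes_inside_promoter_windows(self, small_manifest):
        merged = small_manifest.probes.merge(small_manifest.genes, on="gene")
        assert (merged["chrom_x"] == merged["chrom_y"]).all()
        offset = (merged["pos"] - merged["tss"]).abs()
        assert (offset <= small_manifest.promoter_window).all()

    def test_promoter_windows_disjoint(self, small_manifest):
        w = small_manifest.promoter_window
        for _, sub in small_manifest.genes.groupby("chrom"):
            tss = np.sort(sub["tss"].to_numpy())
            assert (np.diff(tss) > 2 * w).all()

    def test_deterministic_for_fixed_seed(self):
        spec = GenomeSpec(n_chroms=2, chrom_length=100_000, rng_seed=9)
        a = gen_probe_manifest(spec, 5, 2)
        b = gen_probe_manifest(spec, 5, 2)
        pd.testing.assert_frame_equal(a.probes, b.probes)
        pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_sizing_errors(self):
        spec = GenomeSpec(n_chroms=1, chrom_length=40_000)
        with pytest.raises(SizingError):
            gen_probe_manifest(spec, n_genes=0)
        with pytest.raises(SizingError):
            gen_probe_manifest(spec, n_genes=1000)


class TestIntensities:
    def test_zero_noise_recovers_planted_delta_exactly(self, small_manifest, planted_truth):
        tables = gen_intensities(small_manifest, planted_truth, n_reps=3, seed=4)
        case, control = tables
        betas = {c: array_meth.beta_matrix(t) for c, t in tables.items()}
        deltas = array_meth.delta_beta(betas[case], betas[control])
        probes = small_manifest.probes.set_index("probe_id")
        planted_mask = probes["gene"].isin(planted_truth.delta_genes)
        assert np.allclose(deltas[planted_mask], -0.35, atol=1e-9)
        assert np.allclose(deltas[~planted_mask], 0.0, atol=1e-9)

    def test_intensities_nonnegative_beta_below_one(self, small_manifest, planted_truth):
        truth = PlantedTruth(**{**planted_truth.__dict__, "noise_sd": 0.2})
        tables = gen_intensities(small_manifest, truth, seed=0)
        for t in tables.values():
            m_cols = [c for c in t.columns if c.startswith("M_")]
            u_cols = [c for c in t.columns if c.startswith("U_")]
            assert (t[m_cols].to_numpy() >= 0).all()
            assert (t[u_cols].to_numpy() >= 0).all()
            beta = array_meth.beta_matrix(t).to_numpy()
            assert (beta >= 0).all() and (beta <= BETA_MAX + 1e-12).all()

    def test_null_truth_rarely_passes_threshold(self, small_manifest):
        # no planted effect + realistic noise: the |Δβ| ≥ 0.25 screen stays empty
        hits = 0
        for seed in range(100):
            truth = PlantedTruth(planted_delta_beta=0.0, noise_sd=0.05)
            tables = gen_intensities(small_manifest, truth, n_reps=3, seed=seed)
            case, control = tables
            betas = {c: array_meth.beta_matrix(t) for c, t in tables.items()}
            deltas = array_meth.delta_beta(betas[case], betas[control])
            if len(array_meth.select_differential(deltas, 0.25, "both")):
                hits += 1
        assert hits <= 1  # ≥ 99 % of seeds select nothing

    def test_deterministic_for_fixed_seed(self, small_manifest, planted_truth):
        a = gen_intensities(small_manifest, planted_truth, seed=3)
        b = gen_intensities(small_manifest, planted_truth, seed=3)
        for cond in a:
            pd.testing.assert_frame_equal(a[cond], b[cond])

    def test_unknown_target_gene_named(self, small_manifest):
        truth = PlantedTruth(target_genes=["nosuchgene"])
        with pytest.raises(ValueError, match="nosuchgene"):
            gen_intensities(small_manifest, truth)


class TestAnnotationTracks:
    def test_bed_invariants(self, small_spec, small_manifest, planted_truth):
        tracks = gen_annotation_tracks(small_spec, small_manifest, planted_truth)
        assert set(tracks) == {"cgi", "tss", "tf_peaks", "h3k4me1", "h3k27ac"}
        for track in tracks.values():
            for iv in track:
                assert 0 <= iv.start < iv.end <= small_spec.chrom_length

    def test_zero_targets_keep_decoy_peaks(self, small_spec, small_manifest):
        truth = default_truth(small_manifest, n_targets=0, decoys_per_class=1)
        tracks = gen_annotation_tracks(small_spec, small_manifest, truth)
        assert len(tracks["tf_peaks"]) > 0  # decoys still contribute

    def test_decoy_classes_lack_their_evidence(self, small_spec, small_manifest, planted_truth):
        tracks = gen_annotation_tracks(small_spec, small_manifest, planted_truth)
        cgi_genes = {iv.name.removeprefix("CGI_") for iv in tracks["cgi"]}
        tf_genes = {iv.name.removeprefix("TF_") for iv in tracks["tf_peaks"]}
        k27_genes = {iv.name.removeprefix("K27Ac_") for iv in tracks["h3k27ac"]}
        for gene, klass in planted_truth.decoy_genes.items():
            if klass == "no_cgi":
                assert gene not in cgi_genes
            elif klass == "enhancer_no_peak":
                assert gene not in tf_genes
            elif klass == "peak_no_enhancer":
                assert gene in tf_genes and gene not in k27_genes


class TestCohort:
    def test_default_sizes_and_serum_layout(self):
        cohort, signals = gen_cohort(seed=0)
        counts = cohort.groupby("group")["sample_id"].count()
        assert counts["gastritis"] == 34 and counts["IM"] == 33 and counts["cancer"] == 53
        serum = cohort[cohort["serum_available"] == 1].groupby("group").size()
        assert serum["cancer"] == 53 and serum["IM"] == 3 and serum["gastritis"] == 20
        assert len(signals) == len(cohort) * 6

    def test_percentages_bounded(self):
        cohort, signals = gen_cohort(seed=1)
        assert cohort["tissue_meth_pct"].between(0, 100).all()
        pct = 100 * signals["C"] / (signals["C"] + signals["T"])
        assert pct.between(0, 100).all()

    def test_degenerate_rates_give_perfect_calls(self):
        truth = PlantedTruth(
            group_msp_positive_rate={"cancer": 1.0, "gastritis": 0.0, "IM": 0.0}
        )
        cohort, _ = gen_cohort(truth=truth, seed=2)
        serum = cohort[cohort["serum_available"] == 1]
        assert (serum.loc[serum["group"] == "cancer", "msp_call"] == "M").all()
        assert (serum.loc[serum["group"] != "cancer", "msp_call"] == "U").all()

    def test_empty_cohort(self):
        cohort, signals = gen_cohort(sizes={}, seed=0)
        assert cohort.empty and signals.empty
        from epimark.diagnostics import table_report

        with pytest.raises(ValueError):
            table_report(cohort)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            PlantedTruth(group_msp_positive_rate={"cancer": 1.5})

    def test_deterministic_for_fixed_seed(self):
        a, sa = gen_cohort(seed=6)
        b, sb = gen_cohort(seed=6)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(sa, sb)


class TestTruthValidation:
    def test_group_mean_bounds(self):
        with pytest.raises(ValueError, match=r"\[0,100\]"):
            PlantedTruth(group_methylation_means={"cancer": 150.0})

    def test_unknown_decoy_class(self):
        with pytest.raises(ValueError, match="decoy"):
            PlantedTruth(decoy_genes={"g": "mystery"})

    def test_unrepresentable_delta(self):
        with pytest.raises(ValueError, match="representable"):
            PlantedTruth(planted_delta_beta=0.5, control_beta=0.7)
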