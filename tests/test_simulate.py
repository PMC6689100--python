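"""Synthetic-data generator: determinism, planted structure, round-trip."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from riskloci.ld import compute_r2
from riskloci.simulate import (
    SimulationConfig,
    define_loci,
    make_allele_counts,
    make_bundle,
    make_feature_layers,
    make_genotypes,
    make_haplotype_panel,
    make_segmentations,
)

from conftest import small_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("block_r2_decay", 1.5),
            ("overdispersion_alpha", -1.0),
            ("overdispersion_beta", 0.0),
            ("haplotypes_per_block", 2),
            ("qtl_effect_size", float("nan")),
        ],
    )
    def test_invalid_value_names_field(self, field, value):
        with pytest.raises(ValueError, match=field.split("_")[0]):
            SimulationConfig(**{field: value})

    def test_genome_not_multiple_of_bin_rejected(self):
        with pytest.raises(ValueError, match="bin_size"):
            SimulationConfig(genome_length=1_000_100)


class TestHaplotypePanel:
    def test_no_decay_copies_haplotypes(self):
        cfg = small_config(block_r2_decay=1.0)
        panel = make_haplotype_panel(cfg)
        block0 = panel.haplotypes[:, panel.block_ids == 0]
        # every within-block pair in perfect LD (up to the forced
        # polymorphism flip of at most one haplotype per SNP)
        r2 = np.corrcoef(block0.astype(float), rowvar=False) ** 2
        assert np.nanmin(r2) > 0.95

    def test_cross_block_independence(self):
        cfg = small_config(haplotypes_per_block=1000)
        panel = make_haplotype_panel(cfg)
        a = panel.haplotypes[:, panel.block_ids == 0][:, 0].astype(float)
        b = panel.haplotypes[:, panel.block_ids == 1][:, 0].astype(float)
        assert np.corrcoef(a, b)[0, 1] ** 2 < 0.02

    def test_lag1_r2_tracks_decay(self):
        cfg = small_config(haplotypes_per_block=1000, block_r2_decay=0.8)
        panel = make_haplotype_panel(cfg)
        r2s = []
        for j in range(panel.n_snps - 1):
            if panel.block_ids[j] == panel.block_ids[j + 1]:
                r2s.append(compute_r2(panel, panel.snp_ids[j], panel.snp_ids[j + 1]))
        assert abs(np.mean(r2s) - 0.8) < 0.1

    def test_sentinel_has_proxy_and_nonproxy(self, small_bundle):
        from riskloci.ld import r2_with_sentinel

        panel = small_bundle.panel
        for locus in small_bundle.loci:
            r2 = r2_with_sentinel(panel, locus.sentinel)
            others = np.delete(r2, panel.snp_index(locus.sentinel))
            assert (others >= 0.2).any()
            assert (others < 0.2).any()


class TestDeterminism:
    def test_identical_config_identical_bundle(self):
        cfg = small_config(seed=31)
        b1 = make_bundle(cfg)
        b2 = make_bundle(small_config(seed=31))
        np.testing.assert_array_equal(b1.panel.haplotypes, b2.panel.haplotypes)
        np.testing.assert_array_equal(b1.genotypes.dosages, b2.genotypes.dosages)
        for t1, t2 in zip(b1.tracks, b2.tracks):
            np.testing.assert_array_equal(t1.states, t2.states)
        for layer in b1.layers:
            np.testing.assert_array_equal(b1.layers[layer].values, b2.layers[layer].values)
        pd.testing.assert_frame_equal(b1.allele_counts.counts, b2.allele_counts.counts)
        for name in b1.truth:
            pd.testing.assert_frame_equal(b1.truth[name], b2.truth[name])

    def test_different_seeds_differ(self):
        b1 = make_bundle(small_config(seed=1))
        b2 = make_bundle(small_config(seed=2))
        assert not np.array_equal(b1.genotypes.dosages, b2.genotypes.dosages)


class TestFeatureLayers:
    def test_zero_effect_size_empty_truth(self):
        cfg = small_config(qtl_effect_size=0.0)
        panel = make_haplotype_panel(cfg)
        geno = make_genotypes(panel, cfg)
        loci = define_loci(panel, cfg)
        _, truth = make_feature_layers(panel, loci, geno, cfg)
        assert truth.empty

    def test_noiseless_limit_recovers_slope(self):
        cfg = small_config(noise_sd=0.0, n_latent_factors=0, qtl_effect_size=1.0)
        panel = make_haplotype_panel(cfg)
        geno = make_genotypes(panel, cfg)
        loci = define_loci(panel, cfg)
        layers, truth = make_feature_layers(panel, loci, geno, cfg)
        row = truth[truth["layer"] == "accessibility"].iloc[0]
        fm = layers["accessibility"]
        j = fm.feature_index(row["feature"])
        d = geno.dosage_of(row["sentinel"]).astype(float)
        beta = np.polyfit(d, fm.values[:, j], 1)[0]
        assert beta == pytest.approx(1.0, abs=1e-10)

    def test_ols_recovers_planted_beta_across_seeds(self):
        hits = 0
        seeds = range(40)
        for seed in seeds:
            rng = np.random.default_rng(seed)
            n = 200
            d = rng.binomial(2, 0.5, size=n).astype(float)
            y = 0.8 * d + rng.normal(size=n)
            beta = np.polyfit(d, y, 1)[0]
            hits += abs(beta - 0.8) < 0.2
        assert hits / len(seeds) >= 0.95

    def test_methylation_sign_opposes_accessibility(self, small_bundle):
        truth = small_bundle.truth["qtl"]
        acc = truth[truth["layer"] == "accessibility"]["beta"]
        meth = truth[truth["layer"] == "methylation"]["beta"]
        assert (acc > 0).all()
        assert (meth < 0).all()

    def test_nonfinite_effect_rejected(self):
        with pytest.raises(ValueError, match="qtl_effect_size"):
            small_config(qtl_effect_size=float("inf"))


class TestSegmentations:
    def test_background_frequencies(self):
        from riskloci.simulate import BACKGROUND_STATE_FREQS

        cfg = small_config(n_strong_active_loci=0, n_weak_active_loci=0)
        panel = make_haplotype_panel(cfg)
        tracks = make_segmentations(panel, [], cfg, ["s0"])
        frac = np.bincount(tracks[0].states, minlength=12) / tracks[0].states.size
        np.testing.assert_allclose(frac, BACKGROUND_STATE_FREQS, atol=0.02)

    def test_planted_strong_locus_active_coverage(self, small_bundle):
        from riskloci.containers import ACTIVE_STATES
        from riskloci.enrichment import state_coverage

        truth = small_bundle.truth["locus_activity"].set_index("sentinel")["activity"]
        strong = [l for l in small_bundle.loci if truth[l.sentinel] == "strong"][0]
        cov = state_coverage((strong.start, strong.end), small_bundle.tracks[0])
        active_frac = sum(cov.fraction_of(s) for s in ACTIVE_STATES)
        assert active_frac > 0.6

    def test_partition_no_gaps(self, small_bundle):
        t = small_bundle.tracks[0]
        assert t.extent == small_bundle.config.genome_length

    def test_bad_genome_length_rejected(self, small_bundle):
        cfg = small_config()
        object.__setattr__(cfg, "genome_length", cfg.genome_length + 1)
        with pytest.raises(ValueError, match="multiple"):
            make_segmentations(small_bundle.panel, [], cfg, ["s0"])


class TestAlleleCounts:
    def test_symmetric_null_pools_near_half(self):
        cfg = small_config(fraction_imbalanced_snps=0.0, overdispersion_alpha=20.0,
                           overdispersion_beta=20.0)
        panel = make_haplotype_panel(cfg)
        geno = make_genotypes(panel, cfg)
        loci = define_loci(panel, cfg)
        table, ai_geno, truth = make_allele_counts(panel, loci, geno, cfg)
        assert truth.empty
        from riskloci.imbalance import pooled_counts_per_snp

        pooled = pooled_counts_per_snp(table, ai_geno)
        ratio = pooled["pooled_ref"].sum() / pooled["pooled_total"].sum()
        assert ratio == pytest.approx(0.5, abs=0.02)

    def test_planted_ratio_visible_in_pooled_counts(self, small_bundle):
        from riskloci.imbalance import pooled_counts_per_snp

        pooled = pooled_counts_per_snp(small_bundle.allele_counts, small_bundle.ai_genotypes)
        planted = small_bundle.truth["imbalanced"]["snp"]
        hits = 0
        for snp in planted:
            r = pooled.loc[snp]
            ratio = r["pooled_ref"] / r["pooled_total"]
            hits += 0.7 <= ratio <= 0.9
        assert hits >= len(planted) - 1

    def test_homozygotes_near_monoallelic(self, small_bundle):
        counts = small_bundle.allele_counts.counts
        geno = small_bundle.ai_genotypes.to_frame().stack()
        geno.index.names = ["sample", "snp"]
        merged = counts.set_index(["sample", "snp"]).join(geno.rename("g"))
        hom_ref = merged[merged["g"] == 0]
        ratios = hom_ref["ref_count"] / (hom_ref["ref_count"] + hom_ref["alt_count"])
        assert ratios.mean() > 0.98

    def test_truth_references_existing_snps(self, small_bundle):
        planted = set(small_bundle.truth["imbalanced"]["snp"])
        assert planted <= set(small_bundle.allele_counts.snps.index)


class TestRoundTrip:
    def test_write_read_reproduces_bundle(self, tmp_path):
        from riskloci.io import read_fixture_bundle, write_fixture_bundle

        cfg = small_config(seed=17, n_samples=6, n_background_snps=30)
        b = make_bundle(cfg)
        write_fixture_bundle(b, tmp_path / "bundle")
        b2 = read_fixture_bundle(tmp_path / "bundle")
        assert b2.config == b.config
        np.testing.assert_array_equal(b2.panel.haplotypes, b.panel.haplotypes)
        np.testing.assert_array_equal(b2.genotypes.dosages, b.genotypes.dosages)
        assert b2.genotypes.sample_ids == b.genotypes.sample_ids
        assert [l.sentinel for l in b2.loci] == [l.sentinel for l in b.loci]
        for t2, t in zip(b2.tracks, b.tracks):
            np.testing.assert_array_equal(t2.states, t.states)
        for layer in b.layers:
            np.testing.assert_allclose(b2.layers[layer].values, b.layers[layer].values)
            np.testing.assert_array_equal(b2.layers[layer].presence, b.layers[layer].presence)
        np.testing.assert_array_equal(b2.background.intervals, b.background.intervals)
        pd.testing.assert_frame_equal(b2.allele_counts.counts, b.allele_counts.counts)
        np.testing.assert_allclose(b2.pwms[0].probs, b.pwms[0].probs, atol=1e-9)
        pd.testing.assert_frame_equal(b2.snp_contexts, b.snp_contexts)
        for name in b.truth:
            pd.testing.assert_frame_equal(b2.truth[name], b.truth[name])

    def test_bed_records_sorted_half_open(self, tmp_path):
        from riskloci.io import write_fixture_bundle

        cfg = small_config(seed=18, n_samples=4, n_background_snps=30)
        b = make_bundle(cfg)
        d = write_fixture_bundle(b, tmp_path / "bundle")
        bed = pd.read_csv(d / "loci.bed", sep="\t", header=None,
                          names=["contig", "start", "end", "name"])
        assert (bed["start"] < bed["end"]).all()
        assert bed["start"].is_monotonic_increasing

    def test_vcf_dosage_round_trip(self, tmp_path):
        from riskloci.io import read_genotypes_vcf, write_genotypes_vcf

        cfg = small_config(seed=19, n_samples=5)
        panel = make_haplotype_panel(cfg)
        geno = make_genotypes(panel, cfg)
        geno.dosages[0, 0] = -1  # a missing call survives the round trip
        write_genotypes_vcf(geno, tmp_path / "g.vcf")
        back = read_genotypes_vcf(tmp_path / "g.vcf")
        np.testing.assert_array_equal(back.dosages, geno.dosages)
        assert back.sample_ids == geno.sample_ids
        assert back.snp_ids == geno.snp_ids


def test_null_qtl_pvalues_uniform():
    """With no planted effects, scan p-values are uniform (KS check)."""
    import scipy.stats as sps

    from riskloci.qtl import qtl_test
    from riskloci.stats import inverse_normal_transform

    rng = np.random.default_rng(77)
    n = 99
    ps = []
    for _ in range(5000):
        d = rng.binomial(2, 0.4, size=n).astype(float)
        if d.std() == 0:
            continue
        y = inverse_normal_transform(rng.normal(size=n))
        ps.append(qtl_test(y, d)[2])
    assert sps.kstest(ps, "uniform").pvalue > 0.01
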