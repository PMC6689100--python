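"""Feature eligibility, residualization, QTL regression, TAD genes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from riskloci.containers import MISSING, FeatureMatrix, GenotypeMatrix
from riskloci.qtl import (
    TADMap,
    direction_concordance,
    feature_eligibility,
    qtl_test,
    residualize,
    run_layer_scan,
    tad_candidate_genes,
)
from riskloci.simulate import make_bundle
from riskloci.stats import inverse_normal_transform

from conftest import small_config


def _feature_matrix(values, presence=None, layer="accessibility"):
    n_s, n_f = values.shape
    return FeatureMatrix(
        layer=layer,
        sample_ids=[f"p{i}" for i in range(n_s)],
        feature_ids=[f"f{j}" for j in range(n_f)],
        starts=np.arange(n_f) * 1000,
        ends=np.arange(n_f) * 1000 + 500,
        contig="chrT",
        values=values,
        presence=np.ones_like(values, dtype=bool) if presence is None else presence,
    )


def _genotypes(dosage_col):
    n = len(dosage_col)
    return GenotypeMatrix(
        sample_ids=[f"p{i}" for i in range(n)],
        snp_ids=["rsA"],
        positions=np.array([100]),
        contig="chrT",
        dosages=np.asarray(dosage_col, dtype=np.int8).reshape(-1, 1),
    )


class TestEligibility:
    def _setup(self, present_n, subgroup=10):
        # one subgroup of `subgroup` hom-ref patients, rest het
        dosage = [0] * subgroup + [1] * 10
        presence = np.zeros((len(dosage), 1), dtype=bool)
        presence[:present_n, 0] = True  # present only in hom-ref patients
        values = np.zeros((len(dosage), 1))
        return _feature_matrix(values, presence), _genotypes(dosage)

    def test_minimum_of_two_binds(self):
        fm, g = self._setup(present_n=1)
        assert feature_eligibility(fm, g, "rsA") == []

    def test_two_of_ten_eligible(self):
        fm, g = self._setup(present_n=2)
        assert feature_eligibility(fm, g, "rsA") == ["f0"]

    def test_expression_floor_strict(self):
        values = np.full((12, 1), 4.5)  # exactly at floor: not expressed
        fm = _feature_matrix(values, layer="expression")
        g = _genotypes([0] * 6 + [1] * 6)
        assert feature_eligibility(fm, g, "rsA") == []
        fm.values[:] = 4.51
        assert feature_eligibility(fm, g, "rsA") == ["f0"]

    def test_methylation_always_eligible(self):
        fm = _feature_matrix(np.zeros((12, 3)), layer="methylation")
        g = _genotypes([0] * 6 + [1] * 6)
        assert feature_eligibility(fm, g, "rsA") == ["f0", "f1", "f2"]

    def test_missing_sentinel_rejected(self):
        fm, g = self._setup(present_n=2)
        with pytest.raises(KeyError):
            feature_eligibility(fm, g, "rsMissing")


class TestResidualize:
    def test_k_zero_unchanged(self):
        x = np.random.default_rng(0).normal(size=(20, 5))
        np.testing.assert_array_equal(residualize(x, 0), x)

    def test_rank_one_removed(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(30, 1))
        v = rng.normal(size=(1, 6))
        x = u @ v
        res = residualize(x, 1)
        assert np.abs(res).max() < 1e-10

    def test_residuals_orthogonal_to_components(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 8))
        centered = x - x.mean(0)
        sd = centered.std(0)
        u, _, _ = np.linalg.svd(centered / sd, full_matrices=False)
        res = residualize(x, 3)
        assert np.abs(u[:, :3].T @ res).max() < 1e-8

    def test_k_at_rank_rejected(self):
        x = np.random.default_rng(3).normal(size=(10, 4))
        with pytest.raises(ValueError):
            residualize(x, 4)

    def test_confounder_removal_helps_estimation(self):
        # planted factor inflates the naive slope; residualization restores it
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 100
            dosage = rng.binomial(2, 0.4, size=n).astype(float)
            factor = rng.normal(size=n) + 0.8 * dosage
            beta = 0.8
            n_feat = 30
            loadings = rng.normal(scale=1.5, size=n_feat)
            x = factor[:, None] * loadings[None, :] + rng.normal(scale=0.5, size=(n, n_feat))
            x[:, 0] += beta * dosage
            naive = qtl_test(x[:, 0], dosage)[0]
            # factor is estimable from the other features; remove it
            res = residualize(np.column_stack([x[:, 0] - beta * dosage, x[:, 1:]]), 1)
            cleaned = x[:, 0] - (x[:, 0] - beta * dosage - res[:, 0])
            adj = qtl_test(cleaned, dosage)[0]
            if abs(adj - beta) < abs(naive - beta):
                hits += 1
        assert hits >= 18


class TestQtlTest:
    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=50).astype(float)
        v = 0.5 * d + rng.normal(size=50)
        beta, t, p, n = qtl_test(v, d)
        ref = sps.linregress(d, v)
        assert beta == pytest.approx(ref.slope, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)
        assert n == 50

    def test_strong_signal_small_p(self):
        d = np.tile([0.0, 1.0, 2.0], 10)
        v = inverse_normal_transform(d + np.linspace(0, 1e-6, 30))
        beta, t, p, n = qtl_test(v, d)
        assert p < 1e-6
        assert beta > 0

    def test_duplication_same_beta_smaller_p(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=30).astype(float)
        v = 0.4 * d + rng.normal(size=30)
        b1, _, p1, _ = qtl_test(v, d)
        b2, _, p2, _ = qtl_test(np.tile(v, 2), np.tile(d, 2))
        assert b2 == pytest.approx(b1, abs=1e-12)
        assert p2 < p1

    def test_missing_dropped_pairwise(self):
        d = np.array([0, 1, 2, 0, 1, 2, MISSING], dtype=float)
        v = np.array([0.1, 1.2, 1.9, -0.1, 0.8, 2.2, 99.0])
        *_, n = qtl_test(v, d)
        assert n == 6

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            qtl_test(np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0]))


class TestLayerScan:
    def test_planted_qtls_recovered(self, small_bundle):
        res = run_layer_scan(
            small_bundle.layers["accessibility"],
            small_bundle.loci,
            small_bundle.genotypes,
            tad_map=small_bundle.tad_map,
            k_factors=small_bundle.config.n_latent_factors,
        )
        truth = set(
            small_bundle.truth["qtl"].query("layer == 'accessibility'")["sentinel"]
        )
        found = set(res.loc[res["significant"], "sentinel"])
        assert truth <= found

    def test_scan_invariant_to_orderings(self, small_bundle):
        fm = small_bundle.layers["h3k27ac"]
        res1 = run_layer_scan(fm, small_bundle.loci, small_bundle.genotypes,
                              tad_map=small_bundle.tad_map, k_factors=2)
        perm = np.random.default_rng(0).permutation(len(fm.feature_ids))
        fm2 = FeatureMatrix(
            layer=fm.layer,
            sample_ids=fm.sample_ids,
            feature_ids=[fm.feature_ids[j] for j in perm],
            starts=fm.starts[perm],
            ends=fm.ends[perm],
            contig=fm.contig,
            values=fm.values[:, perm],
            presence=fm.presence[:, perm],
        )
        res2 = run_layer_scan(fm2, small_bundle.loci, small_bundle.genotypes,
                              tad_map=small_bundle.tad_map, k_factors=2)
        m1 = res1.set_index(["sentinel", "feature"])["p"].sort_index()
        m2 = res2.set_index(["sentinel", "feature"])["p"].sort_index()
        pd.testing.assert_series_equal(m1, m2)

    def test_same_seed_identical(self):
        cfg = small_config(seed=19)
        r1 = run_layer_scan(
            make_bundle(cfg).layers["accessibility"],
            make_bundle(cfg).loci,
            make_bundle(cfg).genotypes,
        )
        b = make_bundle(cfg)
        r2 = run_layer_scan(b.layers["accessibility"], b.loci, b.genotypes)
        pd.testing.assert_frame_equal(r1, r2)

    def test_empty_scan_warns(self, small_bundle):
        fm = small_bundle.layers["accessibility"]
        empty = FeatureMatrix(
            layer="accessibility",
            sample_ids=fm.sample_ids,
            feature_ids=["far"],
            starts=np.array([9_999_000]),
            ends=np.array([9_999_500]),
            contig=fm.contig,
            values=np.random.default_rng(0).normal(size=(len(fm.sample_ids), 1)),
            presence=np.ones((len(fm.sample_ids), 1), dtype=bool),
        )
        with pytest.warns(UserWarning, match="no testable"):
            res = run_layer_scan(empty, small_bundle.loci[:1], small_bundle.genotypes)
        assert res.empty


class TestTadGenes:
    def _map(self):
        tads = pd.DataFrame(
            {"start": [0, 1000, 2000], "end": [1000, 2000, 3000]},
            index=pd.Index(["t0", "t1", "t2"], name="tad_id"),
        )
        genes = pd.DataFrame(
            {"start": [100, 900, 1500, 2000], "end": [200, 1100, 1600, 2100]},
            index=pd.Index(["A", "B", "C", "D"], name="gene_id"),
        )
        return TADMap(tads=tads, genes=genes)

    def _locus(self, start, end):
        from riskloci.containers import RiskLocus

        return RiskLocus(
            sentinel="rsL",
            sentinel_pos=start,
            contig="chrT",
            proxies=pd.DataFrame({"pos": [start]}, index=["rsL"]),
            start=start,
            end=end,
        )

    def test_single_tad(self):
        genes = tad_candidate_genes(self._locus(100, 500), self._map())
        assert genes == {"A", "B"}

    def test_two_tads_union(self):
        genes = tad_candidate_genes(self._locus(900, 1500), self._map())
        assert genes == {"A", "B", "C"}

    def test_abutting_gene_excluded(self):
        # gene D starts exactly at t2's start; locus only in t1
        genes = tad_candidate_genes(self._locus(1700, 1900), self._map())
        assert "D" not in genes

    def test_no_tad_warns_empty(self):
        genes_df = self._map()
        locus = self._locus(5000, 5100)
        with pytest.warns(UserWarning, match="no TAD"):
            assert tad_candidate_genes(locus, genes_df) == set()


class TestDirectionConcordance:
    def test_planted_signs_fully_concordant(self, small_bundle):
        results = {
            layer: run_layer_scan(
                small_bundle.layers[layer],
                small_bundle.loci,
                small_bundle.genotypes,
                tad_map=small_bundle.tad_map,
                k_factors=small_bundle.config.n_latent_factors,
            )
            for layer in ("accessibility", "h3k27ac", "methylation")
        }
        table = direction_concordance(results, small_bundle.layers)
        truth_sent = set(small_bundle.truth["qtl"]["sentinel"])
        planted_pairs = table[table["sentinel"].isin(truth_sent)]
        assert not planted_pairs.empty
        assert planted_pairs["concordant"].all()

    def test_no_overlap_empty(self):
        res = pd.DataFrame(
            {"sentinel": ["rsA"], "feature": ["f0"], "beta": [1.0], "significant": [True]}
        )
        fm_a = _feature_matrix(np.zeros((3, 1)), layer="accessibility")
        fm_b = _feature_matrix(np.zeros((3, 1)), layer="h3k27ac")
        fm_b.starts = np.array([90_000])
        fm_b.ends = np.array([90_500])
        out = direction_concordance(
            {"accessibility": res, "h3k27ac": res.copy()},
            {"accessibility": fm_a, "h3k27ac": fm_b},
        )
        assert out.empty

    def test_flipped_methylation_flagged(self):
        res_a = pd.DataFrame(
            {"sentinel": ["rsA"], "feature": ["f0"], "beta": [1.0], "significant": [True]}
        )
        res_m = res_a.copy()  # same positive sign: discordant for methylation
        fm = _feature_matrix(np.zeros((3, 1)), layer="accessibility")
        fm_m = _feature_matrix(np.zeros((3, 1)), layer="methylation")
        out = direction_concordance(
            {"accessibility": res_a, "methylation": res_m},
            {"accessibility": fm, "methylation": fm_m},
        )
        assert not out["concordant"].any()
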