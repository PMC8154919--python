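import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from caprascape.assoc import (
    DegenerateResponseError,
    StructureCovariates,
    annotate_hits,
    bh_adjust,
    broken_stick,
    fit_logistic_irls,
    genotype_indicators,
    lrt_association,
    run_association,
    structure_pca,
)
from caprascape.simulate import SimulationConfig, simulate_dataset

from conftest import make_matrix


def _covs(n, k=2, seed=0):
    rng = np.random.default_rng(seed)
    s = rng.normal(size=(n, k))
    return StructureCovariates(s - s.mean(axis=0), np.ones(k) / k, k, "test")


class TestStructurePCA:
    def test_two_clusters_separate_on_pc1(self):
        cfg = SimulationConfig(n_breeds=2, n_per_breed=40, n_snps_neutral=300,
                               n_snps_adaptive=0, fst=0.3, seed=1)
        g = simulate_dataset(cfg).genotypes
        covs = structure_pca(g, k=2)
        pc1 = covs.scores[:, 0]
        a, b = pc1[:40], pc1[40:]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
            max(b.min(), a.min()) > min(b.max(), a.max())  # zero overlap

    def test_permutation_equivariance(self, small_dataset):
        g = small_dataset.genotypes.take_individuals(range(40))
        covs = structure_pca(g, k=3)
        perm = np.random.default_rng(2).permutation(40)
        covs_p = structure_pca(g.take_individuals(perm), k=3)
        for ax in range(3):
            col, colp = covs.scores[perm, ax], covs_p.scores[:, ax]
            assert np.allclose(col, colp, atol=1e-8) or np.allclose(col, -colp, atol=1e-8)

    def test_single_cluster_pc1_noise_scale(self):
        # no structure: leading eigenvalue stays near the random-matrix bulk
        cfg = SimulationConfig(n_breeds=1, n_per_breed=100, n_snps_neutral=400,
                               n_snps_adaptive=0, fst=0.05, seed=3)
        g = simulate_dataset(cfg).genotypes
        covs = structure_pca(g, k=1)
        # Marchenko-Pastur edge for n/m aspect ratio, on the eigenvalue scale
        lam_max = (1 + np.sqrt(100 / 400)) ** 2 / 100
        assert covs.variance_explained[0] < 2 * lam_max

    def test_k_exceeding_rank_truncated_with_warning(self):
        g = make_matrix(np.random.default_rng(4).integers(0, 3, size=(5, 30)))
        with pytest.warns(UserWarning, match="truncat"):
            covs = structure_pca(g, k=10)
        assert covs.k <= 4

    def test_broken_stick_sums_to_one(self):
        assert broken_stick(10).sum() == pytest.approx(1.0)


class TestGenotypeIndicators:
    def test_three_two_and_zero_indicators(self):
        rng = np.random.default_rng(5)
        balanced = rng.choice([0, 1, 2], size=30)
        no_het = rng.choice([0, 2], size=30)
        mono = np.zeros(30, dtype=int)
        g = make_matrix(np.column_stack([balanced, no_het, mono]))
        by_snp = {}
        for ind in genotype_indicators(g, min_count=5):
            by_snp.setdefault(ind.snp_id, []).append(ind.genotype)
        assert len(by_snp.get("snp0000", [])) == 3
        assert len(by_snp.get("snp0001", [])) == 2
        assert "snp0002" not in by_snp  # monomorphic: degenerate, skipped

    def test_missing_calls_excluded(self):
        col = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, -1])
        g = make_matrix(col[:, None])
        inds = genotype_indicators(g, min_count=5)
        assert all(np.isnan(ind.y[-1]) for ind in inds)


class TestLRT:
    def test_strong_signal_detected(self):
        rng = np.random.default_rng(6)
        n = 500
        x = rng.normal(size=n)
        y = rng.binomial(1, expit(2.0 * x)).astype(float)
        res = lrt_association(y, x, _covs(n))
        assert res.p_value < 1e-6 and res.effect_sign == 1

    def test_covariate_copy_gives_zero_statistic(self):
        rng = np.random.default_rng(7)
        n = 300
        covs = _covs(n)
        y = rng.binomial(1, expit(covs.scores[:, 0])).astype(float)
        res = lrt_association(y, covs.scores[:, 0], covs)
        assert res.G == pytest.approx(0.0, abs=1e-6)

    def test_constant_response_rejected(self):
        with pytest.raises(DegenerateResponseError):
            lrt_association(np.ones(50), np.random.default_rng(8).normal(size=50),
                            _covs(50))

    def test_invariance_to_affine_x_and_pc_shift(self):
        rng = np.random.default_rng(9)
        n = 200
        x = rng.normal(size=n)
        y = rng.binomial(1, expit(0.5 * x)).astype(float)
        covs = _covs(n)
        g0 = lrt_association(y, x, covs).G
        g1 = lrt_association(y, 3.0 * x - 7.0, covs).G
        shifted = StructureCovariates(covs.scores + 5.0, covs.variance_explained,
                                      covs.k, "t")
        g2 = lrt_association(y, x, shifted).G
        assert g1 == pytest.approx(g0, abs=1e-6)
        assert g2 == pytest.approx(g0, abs=1e-6)

    def test_deviance_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        n = 400
        covs = _covs(n, k=3, seed=11)
        x = rng.normal(size=n)
        y = rng.binomial(1, expit(0.3 * x + 0.4 * covs.scores[:, 0])).astype(float)
        X1 = np.column_stack([np.ones(n), covs.scores, (x - x.mean()) / x.std()])
        _, dev, conv = fit_logistic_irls(X1, y)
        ref = sm.GLM(y, X1, family=sm.families.Binomial()).fit()
        assert conv
        assert dev == pytest.approx(ref.deviance, abs=1e-6)


class TestBHAdjust:
    def test_hand_computed_stepup(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_agrees_with_bruteforce_definition(self, ps):
        p = np.asarray(ps)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            q[i] = running
        assert np.allclose(bh_adjust(p), q, atol=1e-12)


class TestAnnotateHits:
    def _results(self, snps):
        return pd.DataFrame({"snp_id": snps})

    def test_interval_boundaries(self):
        g = make_matrix(np.zeros((2, 3), dtype=np.int8), positions=[101, 200, 201])
        genes = pd.DataFrame({"chromosome": ["1"], "start": [100], "end": [200],
                              "name": ["GENE1"]})
        out = annotate_hits(self._results(["snp0000", "snp0001", "snp0002"]), genes, g)
        assert list(out["gene"]) == ["GENE1", "GENE1", ""]  # 1-based 101 = first base

    def test_empty_gene_table(self):
        g = make_matrix(np.zeros((2, 1), dtype=np.int8))
        genes = pd.DataFrame(columns=["chromosome", "start", "end", "name"])
        out = annotate_hits(self._results(["snp0000"]), genes, g)
        assert list(out["gene"]) == [""]

    def test_malformed_interval_rejected(self):
        g = make_matrix(np.zeros((2, 1), dtype=np.int8))
        genes = pd.DataFrame({"chromosome": ["1"], "start": [500], "end": [400],
                              "name": ["BAD"]})
        with pytest.raises(ValueError, match="BAD"):
            annotate_hits(self._results(["snp0000"]), genes, g)


def test_run_association_family_options(small_dataset):
    from caprascape.assoc import env_for_individuals

    ds = small_dataset
    g = ds.genotypes.take_individuals(range(60)).take_loci(range(50))
    env = env_for_individuals(ds.env, g)
    covs = structure_pca(g, k=2)
    pooled = run_association(g, env, covs, bh_family="pooled")
    per_var = run_association(g, env, covs, bh_family="per_variable")
    assert np.allclose(pooled["p_value"], per_var["p_value"])
    assert (pooled["q_value"] >= pooled["p_value"] - 1e-12).all()
    assert (pooled["G"] >= -1e-8).all()
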