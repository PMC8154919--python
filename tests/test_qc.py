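import numpy as np
import pytest

from caprascape.qc import (
    EmptyPanelError,
    QCParams,
    build_datasets,
    filter_call_rate_maf,
    kinship_filter_second_degree,
    ld_prune,
    opposing_homozygote_counts,
    pihat_matrix,
    remove_duplicates_and_relatives,
    representative_subsample,
)

from conftest import make_matrix


def _hw_calls(rng, p, n, m):
    return rng.binomial(2, p, size=(n, m)).astype(np.int8)


class TestCallRateMaf:
    def test_planted_failures_reported_exactly(self):
        rng = np.random.default_rng(0)
        calls = _hw_calls(rng, 0.4, 100, 10)
        calls[:50, 2] = -1            # snp 2: 50% call rate
        calls[:, 5] = 0               # snp 5: monomorphic
        calls[3, :] = -1              # individual 3: nearly all missing
        calls[3, 0] = 1
        g = make_matrix(calls)
        g2, report = filter_call_rate_maf(g, QCParams())
        removed = set(report["item_id"])
        assert removed == {"snp0002", "snp0005", "ind003"}
        assert g2.n_snps == 8 and g2.n_individuals == 99
        reasons = dict(zip(report["item_id"], report["reason"]))
        assert reasons["snp0002"] == "snp_call_rate"
        assert reasons["snp0005"] == "maf"

    def test_all_loci_removed_raises(self):
        g = make_matrix(np.zeros((10, 3), dtype=np.int8))  # all monomorphic
        with pytest.raises(EmptyPanelError):
            filter_call_rate_maf(g, QCParams())


class TestLDPrune:
    def test_duplicated_column_removed(self):
        rng = np.random.default_rng(1)
        base = _hw_calls(rng, 0.5, 100, 5)
        calls = np.column_stack([base[:, :2], base[:, 1], base[:, 2:]])
        g = make_matrix(calls)
        retained, report = ld_prune(g, QCParams())
        assert g.loci[2].snp_id in set(report["item_id"])  # later duplicate goes
        assert g.loci[1].snp_id in retained

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(2)
        g = make_matrix(_hw_calls(rng, 0.5, 400, 30))
        retained, _ = ld_prune(g, QCParams())
        assert len(retained) == 30

    def test_window2_chain_matches_brute_force(self):
        # AR(1) latent chain: adjacent r ~ 0.8 (r2 ~ 0.64 > 0.2),
        # lag-2 r ~ 0.64 (r2 ~ 0.41) pruned transitively either way
        rng = np.random.default_rng(3)
        n, m, rho = 600, 12, 0.8
        z = np.empty((n, m))
        z[:, 0] = rng.normal(size=n)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
        calls = (z > 0).astype(np.int8) + (z > 1).astype(np.int8)
        g = make_matrix(calls)
        p = QCParams(ld_window_snps=2, ld_step_snps=1)
        retained, _ = ld_prune(g, p)

        # brute force on the same instance: scan pairs in map order
        X = calls - calls.mean(axis=0)
        X = X / X.std(axis=0)
        r2 = (X.T @ X / n) ** 2
        kept = np.ones(m, dtype=bool)
        for a in range(m):
            if not kept[a]:
                continue
            for b in range(a + 1, m):
                if kept[b] and b - a < 2 and r2[a, b] > p.ld_r2_max:
                    kept[b] = False
        brute = [g.loci[j].snp_id for j in range(m) if kept[j]]
        assert retained == brute


class TestDuplicatesRelatives:
    def test_identical_twins_one_removed(self):
        rng = np.random.default_rng(4)
        calls = _hw_calls(rng, 0.5, 10, 100)
        calls[1] = calls[0]
        g = make_matrix(calls)
        g2, report = remove_duplicates_and_relatives(
            g, QCParams(opposing_hom_max=0))
        assert g2.n_individuals == 9
        assert set(report["stage"]) == {"duplicates"}

    def test_shared_member_of_two_flagged_pairs_removed(self):
        # A-B and A-C related (few opposing homozygotes), B-C unrelated
        rng = np.random.default_rng(5)
        a = rng.choice([0, 2], size=200).astype(np.int8)
        b, c = a.copy(), a.copy()
        flip_b = rng.choice(200, 10, replace=False)
        flip_c = rng.choice(np.setdiff1d(np.arange(200), flip_b), 10, replace=False)
        b[flip_b] = 2 - b[flip_b]
        c[flip_c] = 2 - c[flip_c]
        g = make_matrix(np.vstack([a, b, c]))
        opp = opposing_homozygote_counts(g)
        assert opp[0, 1] == 10 and opp[0, 2] == 10 and opp[1, 2] == 20
        g2, report = remove_duplicates_and_relatives(
            g, QCParams(dup_ibs_min=0.999, opposing_hom_max=15))
        assert g2.sample_ids == ["ind001", "ind002"]
        assert list(report["item_id"]) == ["ind000"]

    def test_unrelated_panel_untouched(self):
        rng = np.random.default_rng(6)
        g = make_matrix(_hw_calls(rng, 0.5, 20, 300))
        g2, report = remove_duplicates_and_relatives(
            g, QCParams(opposing_hom_max=10))
        assert g2.n_individuals == 20 and len(report) == 0


class TestKinship:
    @staticmethod
    def _family_panel(rng, n_unrelated=20, m=600):
        p = rng.uniform(0.2, 0.8, size=m)
        pool = rng.binomial(1, p, size=(2 * (n_unrelated + 2), m))
        geno = pool[0::2] + pool[1::2]
        # child of individuals 0 and 1: one transmitted allele each
        child = pool[0] + pool[2]
        calls = np.vstack([geno, child]).astype(np.int8)
        return make_matrix(calls)

    def test_parent_offspring_detected_and_pruned(self):
        rng = np.random.default_rng(7)
        g = self._family_panel(rng)
        pihat = pihat_matrix(g)
        assert pihat[0, -1] > 0.35  # parent-offspring ~ 0.5
        g2, report = kinship_filter_second_degree(g, QCParams())
        assert g2.n_individuals == g.n_individuals - 1
        assert len(report) == 1

    def test_duplicate_pair_pihat_near_one(self):
        rng = np.random.default_rng(8)
        calls = _hw_calls(rng, 0.5, 10, 500)
        calls[1] = calls[0]
        pihat = pihat_matrix(make_matrix(calls))
        assert pihat[0, 1] > 0.9

    def test_unrelated_panel_unchanged(self):
        rng = np.random.default_rng(9)
        g = make_matrix(_hw_calls(rng, 0.5, 25, 600))
        g2, report = kinship_filter_second_degree(g, QCParams())
        assert g2.n_individuals == 25 and len(report) == 0


class TestRepresentativeSubsample:
    def test_breed_under_cap_untouched(self):
        rng = np.random.default_rng(10)
        g = make_matrix(_hw_calls(rng, 0.5, 24, 50))
        g2, report = representative_subsample(g, max_n=30, seed=0)
        assert g2.n_individuals == 24 and len(report) == 0

    def test_cap_and_diversity_preserved(self):
        rng = np.random.default_rng(11)
        g = make_matrix(_hw_calls(rng, 0.3, 60, 400))
        g2, _ = representative_subsample(g, max_n=30, seed=0)
        assert g2.n_individuals == 30

        def exp_het(mat):
            p = mat.snp_allele_freq()
            return float(np.nanmean(2 * p * (1 - p)))

        assert abs(exp_het(g2) - exp_het(g)) / exp_het(g) < 0.05

    def test_two_clusters_both_sampled(self):
        rng = np.random.default_rng(12)
        a = _hw_calls(rng, 0.9, 40, 100)
        b = _hw_calls(rng, 0.1, 40, 100)
        g = make_matrix(np.vstack([a, b]))
        g2, _ = representative_subsample(g, max_n=10, seed=0)
        kept = set(g2.sample_ids)
        assert any(f"ind{i:03d}" in kept for i in range(40))
        assert any(f"ind{i:03d}" in kept for i in range(40, 80))


def test_cascade_accounting(small_dataset):
    g = small_dataset.genotypes
    sets = build_datasets(g, QCParams(opposing_hom_max=5, max_per_breed=15), seed=0)
    counts = sets["counts"].set_index("stage")
    assert counts.loc["raw", "n_individuals"] == g.n_individuals
    # every removal attributed: report rows account for all drops
    rep = sets["report"]
    snp_drop = (rep["item_type"] == "snp").sum()
    assert counts.loc["raw", "n_snps"] - snp_drop == counts.loc["structure", "n_snps"]
    assert sets["structure"].n_individuals <= 15 * 5
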