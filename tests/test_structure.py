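import numpy as np
import pytest

from caprascape.core import allele_frequencies
from caprascape.simulate import SimulationConfig, simulate_dataset
from caprascape.structure import (
    DistanceError,
    DistanceMatrix,
    classical_mds,
    ibs_distance,
    nj_bootstrap_tree,
    nj_tree,
    reynolds_distance,
    reynolds_matrix,
)

from conftest import make_matrix


class TestIBSDistance:
    def test_identical_and_opposite(self):
        g = make_matrix([[0, 1, 2], [0, 1, 2]])
        assert ibs_distance(g).values[0, 1] == pytest.approx(0.0)
        g = make_matrix([[0, 0], [2, 2]])
        assert ibs_distance(g).values[0, 1] == pytest.approx(1.0)

    def test_half_shared_single_locus(self):
        g = make_matrix([[0], [1]])
        assert ibs_distance(g).values[0, 1] == pytest.approx(0.5)

    def test_no_joint_loci_names_pair(self):
        g = make_matrix([[0, -1], [-1, 2]])
        with pytest.raises(DistanceError, match="ind000.*ind001"):
            ibs_distance(g)

    def test_symmetry_and_permutation_equivariance(self, small_dataset):
        g = small_dataset.genotypes.take_individuals(range(20))
        d = ibs_distance(g)
        assert np.allclose(d.values, d.values.T)
        perm = np.random.default_rng(0).permutation(20)
        d2 = ibs_distance(g.take_individuals(perm))
        assert np.allclose(d2.values, d.values[np.ix_(perm, perm)])


class TestClassicalMDS:
    def test_collinear_points_reconstructed_exactly(self):
        # points at 0, 1, 3 on a line
        D = np.array([[0.0, 1, 3], [1, 0, 2], [3, 2, 0]])
        res = classical_mds(DistanceMatrix(["a", "b", "c"], D, "one-minus-IBS"), k=1)
        x = res.coordinates[:, 0]
        recon = np.abs(x[:, None] - x[None, :])
        assert np.allclose(recon, D, atol=1e-9)

    def test_planar_points_reconstructed(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = classical_mds(DistanceMatrix([str(i) for i in range(12)], D, "one-minus-IBS"), k=2)
        recon = np.linalg.norm(res.coordinates[:, None] - res.coordinates[None, :], axis=-1)
        assert np.allclose(recon, D, atol=1e-9)

    def test_label_permutation_permutes_rows(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = [f"x{i}" for i in range(8)]
        res = classical_mds(DistanceMatrix(labels, D, "one-minus-IBS"), k=2)
        perm = rng.permutation(8)
        res2 = classical_mds(DistanceMatrix([labels[i] for i in perm],
                                            D[np.ix_(perm, perm)], "one-minus-IBS"), k=2)
        # same embedding up to per-axis sign
        for ax in range(2):
            col, col2 = res.coordinates[perm, ax], res2.coordinates[:, ax]
            assert np.allclose(col, col2, atol=1e-9) or np.allclose(col, -col2, atol=1e-9)

    def test_k_beyond_positive_eigenvalues_warns(self):
        D = np.array([[0.0, 1], [1, 0]])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            res = classical_mds(DistanceMatrix(["a", "b"], D, "one-minus-IBS"), k=5)
        assert res.coordinates.shape[1] == 1

    def test_clusters_separate_with_silhouette(self):
        from sklearn.metrics import silhouette_score

        cfg = SimulationConfig(n_breeds=3, n_per_breed=25, n_snps_neutral=400,
                               n_snps_adaptive=0, fst=0.25, seed=6)
        ds = simulate_dataset(cfg)
        d = ibs_distance(ds.genotypes)
        res = classical_mds(d, k=2)
        assert silhouette_score(res.coordinates, ds.genotypes.breed_codes) > 0.5


class TestReynolds:
    def test_identity_and_fixed_difference(self):
        p = np.array([0.2, 0.7, 0.5])
        assert reynolds_distance(p, p) == pytest.approx(0.0)
        ones, zeros = np.ones(5), np.zeros(5)
        assert reynolds_distance(ones, zeros) == pytest.approx(1.0)

    def test_two_locus_hand_computation(self):
        p1, p2 = np.array([0.5, 0.8]), np.array([0.3, 0.6])
        num = 2 * ((0.5 - 0.3) ** 2 + (0.8 - 0.6) ** 2)
        den = 2 * ((1 - 0.5 * 0.3 - 0.5 * 0.7) + (1 - 0.8 * 0.6 - 0.2 * 0.4))
        assert reynolds_distance(p1, p2) == pytest.approx(num / den)

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p1 = rng.uniform(0.01, 0.99, size=8)
            p2 = rng.uniform(0.01, 0.99, size=8)
            num = den = 0.0
            for a, b in zip(p1, p2):
                num += (a - b) ** 2 + ((1 - a) - (1 - b)) ** 2
                den += 2 * (1 - a * b - (1 - a) * (1 - b))
            assert reynolds_distance(p1, p2) == pytest.approx(num / den, abs=1e-12)

    def test_nan_loci_skipped_and_empty_errors(self):
        p1 = np.array([0.5, np.nan]); p2 = np.array([0.1, 0.9])
        assert reynolds_distance(p1, p2) == reynolds_distance(p1[:1], p2[:1])
        with pytest.raises(DistanceError):
            reynolds_distance(np.array([np.nan]), np.array([0.5]))


class TestNJTree:
    def test_three_breeds_full_support(self, small_dataset):
        g = small_dataset.genotypes
        idx = [i for i, b in enumerate(g.breed_codes) if b in ("BR00", "BR01", "BR02")]
        tree = nj_bootstrap_tree(g.take_individuals(idx), n_boot=10, seed=0)
        assert sorted(lf.taxon.label for lf in tree.tree.leaf_node_iter()) == \
            ["BR00", "BR01", "BR02"]
        # a 3-leaf unrooted tree has a single topology: no internal bipartition
        # can disagree across replicates
        assert all(v == 100.0 for v in tree.support.values()) or not tree.support

    def test_seeded_determinism(self, small_dataset):
        g = small_dataset.genotypes
        t1 = nj_bootstrap_tree(g, n_boot=15, seed=4, outgroup="BR00")
        t2 = nj_bootstrap_tree(g, n_boot=15, seed=4, outgroup="BR00")
        assert t1.tree.as_string(schema="newick") == t2.tree.as_string(schema="newick")
        assert t1.support == t2.support

    def test_unknown_outgroup_rejected(self, small_dataset):
        with pytest.raises(DistanceError, match="outgroup"):
            nj_bootstrap_tree(small_dataset.genotypes, n_boot=2, outgroup="NOPE")

    def test_isolated_breed_has_longest_terminal_edge(self):
        # star-like: four mildly drifted breeds, one strongly isolated
        cfg = SimulationConfig(n_breeds=5, n_per_breed=30, n_snps_neutral=500,
                               n_snps_adaptive=0, fst=[0.03, 0.03, 0.03, 0.03, 0.4],
                               seed=8)
        ds = simulate_dataset(cfg)
        freqs = allele_frequencies(ds.genotypes)
        rng = np.random.default_rng(0)
        p = freqs.freq.to_numpy()
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            idx = rng.integers(0, p.shape[1], size=p.shape[1])
            pb = p[:, idx]
            n = len(freqs.groups)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = reynolds_distance(pb[i], pb[j])
            t = nj_tree(DistanceMatrix(freqs.groups, d, "reynolds"))
            edge_len = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
            if max(edge_len, key=edge_len.get) == "BR04":
                hits += 1
        assert hits / n_rep >= 0.95


def test_mds_axis_tracks_environmental_cline():
    """With most variation cline-driven, MDS axis 1 follows the gradient."""
    cfg = SimulationConfig(n_breeds=12, n_per_breed=15, n_snps_neutral=100,
                           n_snps_adaptive=200, fst=0.02, cline_slope=0.3, seed=10)
    ds = simulate_dataset(cfg)
    res = classical_mds(ibs_distance(ds.genotypes), k=1)
    env = ds.env[(ds.env.epoch == "current")].set_index("unit_id")["value"]
    env_ind = env.loc[ds.genotypes.breed_codes].to_numpy()
    r = np.corrcoef(res.coordinates[:, 0], env_ind)[0, 1]
    assert abs(r) > 0.8
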