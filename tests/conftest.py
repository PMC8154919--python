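import numpy as np
import pytest

from caprascape.core import GenotypeMatrix, Individual, SNPLocus
from caprascape.simulate import SimulationConfig, simulate_dataset


def make_matrix(calls, breeds=None, positions=None, chrom="1", alleles=("A", "G")):
    """Build a GenotypeMatrix from a calls array with minimal metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    breeds = breeds if breeds is not None else ["B1"] * n
    positions = positions if positions is not None else [(j + 1) * 1000 for j in range(m)]
    individuals = [Individual(f"ind{i:03d}", breeds[i]) for i in range(n)]
    loci = [SNPLocus(f"snp{j:04d}", chrom, positions[j], *alleles) for j in range(m)]
    return GenotypeMatrix(individuals, loci, calls)


@pytest.fixture(scope="session")
def small_dataset():
    """5 drifted breeds x 20 animals, 300 neutral + 10 cline SNPs."""
    cfg = SimulationConfig(n_breeds=5, n_per_breed=20, n_snps_neutral=300,
                           n_snps_adaptive=10, fst=0.07, cline_slope=0.3, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture
def tiny_plink(tmp_path):
    """2 individuals x 3 SNPs with one missing call, on disk."""
    ped = tmp_path / "toy.ped"
    map_ = tmp_path / "toy.map"
    map_.write_text(
        "1\tsnpA\t0\t1000\n1\tsnpB\t0\t2000\n1\tsnpC\t0\t3000\n")
    ped.write_text(
        "FAM1 s1 0 0 0 -9 A A A G 0 0\n"
        "FAM2 s2 0 0 0 -9 A G G G C C\n")
    return ped, map_
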