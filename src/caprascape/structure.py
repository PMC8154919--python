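"""Population structure: IBS distances, classical MDS, Reynolds distances,
and a bootstrapped neighbour-joining consensus tree over breeds.

IBS handling follows the pairwise-complete convention: each pair of
individuals is compared only over loci where both have calls.  Reynolds
distance is reported as the co-ancestry coefficient theta itself; square
root and -ln(1 - theta) variants are selectable.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .core import BreedFrequencyTable, GenotypeMatrix, allele_frequencies


class DistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str  # "one-minus-IBS" or "reynolds"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("negative distances")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab[:10].ljust(10) + " ".join(f"{x:.6f}" for x in row) + "\n")


@dataclass
class MDSResult:
    coordinates: np.ndarray  # n x k, axes ordered by decreasing eigenvalue
    eigenvalues: np.ndarray
    proportion: np.ndarray  # variance share per returned axis
    labels: list[str]


# ---------------------------------------------------------------------------
# IBS
# ---------------------------------------------------------------------------

def _code_indicators(g: GenotypeMatrix):
    c = g.calls
    return (c == 0), (c == 1), (c == 2), (c >= 0)


def ibs_similarity(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise shared-allele fraction and jointly non-missing locus counts."""
    i0, i1, i2, v = _code_indicators(g)
    i0 = i0.astype(np.float64); i1 = i1.astype(np.float64)
    i2 = i2.astype(np.float64); v = v.astype(np.float64)
    joint = v @ v.T
    # |gi - gj| summed over joint loci
    d1 = i0 @ i1.T + i1 @ i0.T + i1 @ i2.T + i2 @ i1.T
    d2 = i0 @ i2.T + i2 @ i0.T
    absdiff = d1 + 2.0 * d2
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 1.0 - absdiff / (2.0 * joint)
    return sim, joint


def ibs_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """1 - IBS similarity between individuals, pairwise-complete over loci."""
    if g.n_individuals < 2:
        raise DistanceError("need at least two individuals")
    sim, joint = ibs_similarity(g)
    off = ~np.eye(g.n_individuals, dtype=bool)
    if np.any(joint[off] == 0):
        i, j = np.argwhere((joint == 0) & off)[0]
        raise DistanceError(
            f"individuals {g.sample_ids[i]!r} and {g.sample_ids[j]!r} share no "
            "jointly genotyped locus"
        )
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(g.sample_ids, (d + d.T) / 2.0, "one-minus-IBS")


# ---------------------------------------------------------------------------
# classical MDS (principal coordinates)
# ---------------------------------------------------------------------------

def classical_mds(d: DistanceMatrix, k: int = 2) -> MDSResult:
    """Torgerson's classical scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and returns the top-k axes
    scaled by sqrt(eigenvalue).  Negative eigenvalues (non-Euclidean part)
    are excluded from the variance proportions; if fewer than k positive
    eigenvalues exist the embedding is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D2 = d.values ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-9 * abs(evals[0]) if evals.size else 0)
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating k={k}")
        k = max(n_pos, 1)
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    total = evals[pos].sum()
    proportion = evals[:k] / total if total > 0 else np.zeros(k)
    return MDSResult(coords, evals, proportion, list(d.labels))


# ---------------------------------------------------------------------------
# Reynolds distance
# ---------------------------------------------------------------------------

def reynolds_distance(p1: np.ndarray, p2: np.ndarray, variant: str = "theta") -> float:
    """Reynolds co-ancestry distance between two biallelic frequency vectors.

    theta = sum_l sum_alleles (p1 - p2)^2 / (2 sum_l (1 - sum_alleles p1*p2));
    loci where either frequency is absent (NaN) are skipped.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    ok = ~(np.isnan(p1) | np.isnan(p2))
    if not ok.any():
        raise DistanceError("no shared loci with frequencies in both groups")
    p1, p2 = p1[ok], p2[ok]
    num = np.sum((p1 - p2) ** 2 + ((1 - p1) - (1 - p2)) ** 2)
    den = 2.0 * np.sum(1.0 - p1 * p2 - (1 - p1) * (1 - p2))
    theta = 0.0 if den == 0 else float(num / den)
    theta = min(max(theta, 0.0), 1.0)
    if variant == "theta":
        return theta
    if variant == "sqrt":
        return float(np.sqrt(theta))
    if variant == "minus_log":
        return float(-np.log(max(1.0 - theta, 1e-300)))
    raise ValueError(f"unknown Reynolds variant {variant!r}")


def reynolds_matrix(freqs: BreedFrequencyTable, variant: str = "theta") -> DistanceMatrix:
    labels = freqs.groups
    p = freqs.freq.to_numpy()
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = reynolds_distance(p[i], p[j], variant)
    return DistanceMatrix(labels, d, "reynolds")


# ---------------------------------------------------------------------------
# neighbour-joining with bootstrap
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    tree: dendropy.Tree
    support: dict[frozenset, float]  # bipartition (smaller leaf side) -> pct
    labels: list[str]

    def write_newick(self, path: str | Path) -> None:
        self.tree.write(path=str(path), schema="newick",
                        suppress_rooting=True)


def _nj_from_distance(d: DistanceMatrix) -> dendropy.Tree:
    buf = io.StringIO()
    buf.write("," + ",".join(d.labels) + "\n")
    for lab, row in zip(d.labels, d.values):
        buf.write(lab + "," + ",".join(f"{x:.10f}" for x in row) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    return pdm.nj_tree()


def _collect_splits(tree: dendropy.Tree, all_labels: frozenset, ref: str):
    """Map each split to its edge length, normalised to the side without ref."""
    out: dict[frozenset, float] = {}
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in head.leaf_iter())
        if ref in side:
            side = all_labels - side
        if not side or side == all_labels:
            continue
        out[side] = out.get(side, 0.0) + (edge.length or 0.0)
    return out


def _min_side(side: frozenset, all_labels: frozenset) -> frozenset:
    other = all_labels - side
    return min(side, other, key=lambda s: (len(s), sorted(s)))


def _majority_consensus_newick(
    split_count: dict[frozenset, int],
    split_len: dict[frozenset, float],
    n_boot: int,
    labels: list[str],
    ref: str,
) -> str:
    """Majority-rule consensus as a newick string rooted on ref's edge.

    Splits are clusters excluding ref; majority clusters plus singletons
    form a laminar family, nested by containment.  Edge lengths are the
    mean over replicates containing the split; supports are percentages on
    internal nodes.
    """
    singles = [frozenset([x]) for x in labels if x != ref]
    majority = [s for s, c in split_count.items()
                if len(s) >= 2 and c / n_boot > 0.5]
    clusters = sorted(set(majority) | set(singles),
                      key=lambda s: (len(s), sorted(s)))
    parent: dict[frozenset, frozenset | None] = {}
    for i, c in enumerate(clusters):
        parent[c] = None
        for d in clusters[i + 1:]:
            if c < d:
                parent[c] = d
                break
    children: dict[frozenset | None, list[frozenset]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)

    def mean_len(c: frozenset) -> float:
        n = split_count.get(c, 0)
        return split_len.get(c, 0.0) / n if n else 0.0

    def render(c: frozenset) -> str:
        kids = sorted(children.get(c, []), key=lambda s: sorted(s))
        if not kids:  # singleton leaf cluster
            (leaf,) = c
            return f"{leaf}:{mean_len(c):.8f}"
        inner = ",".join(render(k) for k in kids)
        pct = round(100.0 * split_count.get(c, 0) / n_boot)
        return f"({inner}){pct}:{mean_len(c):.8f}"

    top = sorted(children.get(None, []), key=lambda s: sorted(s))
    ref_len = mean_len(frozenset(set(labels) - {ref})) if len(labels) > 1 else 0.0
    body = ",".join(render(c) for c in top)
    return f"({ref}:{ref_len:.8f},{body});"


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbour joining on a breed distance matrix."""
    return _nj_from_distance(d)


def nj_bootstrap_tree(
    g: GenotypeMatrix,
    n_boot: int = 100,
    seed: int = 0,
    outgroup: str | None = None,
    variant: str = "theta",
) -> PhyloTree:
    """Majority-rule consensus NJ tree of Reynolds distances between breeds.

    Loci are resampled with replacement per replicate (individuals fixed);
    supports are the percentage of replicates containing each internal
    bipartition.  The returned tree is rooted on the outgroup for display
    only; support is a property of the unrooted bipartitions.
    """
    breeds = list(dict.fromkeys(g.breed_codes))
    if len(breeds) < 3:
        raise DistanceError("need at least 3 breeds for a tree")
    if outgroup is not None and outgroup not in breeds:
        raise DistanceError(f"outgroup {outgroup!r} not among breeds {breeds}")
    rng = np.random.default_rng(seed)
    freqs = allele_frequencies(g)
    p = freqs.freq.to_numpy()
    m = p.shape[1]
    all_labels = frozenset(breeds)
    ref = outgroup if outgroup is not None else breeds[0]

    split_count: dict[frozenset, int] = {}
    split_len: dict[frozenset, float] = {}
    for _ in range(n_boot):
        idx = rng.integers(0, m, size=m)
        pb = p[:, idx]
        n = len(breeds)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = reynolds_distance(pb[i], pb[j], variant)
        t = _nj_from_distance(DistanceMatrix(breeds, d, "reynolds"))
        for side, length in _collect_splits(t, all_labels, ref).items():
            split_count[side] = split_count.get(side, 0) + 1
            split_len[side] = split_len.get(side, 0.0) + length

    newick = _majority_consensus_newick(split_count, split_len, n_boot, breeds, ref)
    con = dendropy.Tree.get(data=newick, schema="newick")
    support = {
        _min_side(side, all_labels): 100.0 * c / n_boot
        for side, c in split_count.items()
        if len(side) >= 2 and len(all_labels - side) >= 2
    }
    return PhyloTree(tree=con, support=support, labels=breeds)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST (diagnostic for simulated drift)
# ---------------------------------------------------------------------------

def weir_cockerham_fst(g: GenotypeMatrix) -> float:
    """Multi-population Weir-Cockerham FST estimate (ratio of sums over loci)."""
    groups = g.breed_indices()
    r = len(groups)
    if r < 2:
        raise DistanceError("need at least 2 breeds")
    valid = g.valid_mask()
    calls = np.where(valid, g.calls, 0)
    ni, pi, hi = [], [], []
    for idx in groups.values():
        v = valid[idx]
        n = v.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi.append(calls[idx].sum(axis=0) / (2.0 * n))
            hi.append(np.where(v, g.calls[idx] == 1, False).sum(axis=0) / n)
        ni.append(n)
    ni = np.asarray(ni); pi = np.asarray(pi); hi = np.asarray(hi)
    ok = (ni >= 2).all(axis=0) & ~np.isnan(pi).any(axis=0)
    ni, pi, hi = ni[:, ok], pi[:, ok], hi[:, ok]
    nbar = ni.mean(axis=0)
    nc = (r * nbar - (ni ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (ni * pi).sum(axis=0) / (r * nbar)
    s2 = (ni * (pi - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (ni * hi).sum(axis=0) / (r * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    poly = pbar * (1 - pbar) > 0
    return float(a[poly].sum() / (a + b + c)[poly].sum())
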