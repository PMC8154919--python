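"""Quality-control cascade for SNP-array panels.

The cascade reproduces the standard working-dataset construction for a
multi-breed survey: call-rate/MAF marker and sample filters, duplicate and
close-relative removal, LD pruning, per-breed representative subsampling,
and a second-degree kinship filter.  Three nested datasets come out of it:

* ``haplotype``  - call-rate/MAF + duplicate/relative filters;
* ``structure``  - additionally LD-pruned and subsampled to <= 30 per breed;
* ``landscape``  - additionally kinship-filtered and restricted to
  georeferenced individuals.

Every removal is attributed in a report with the stage, the reason, and the
statistic that triggered it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .structure import ibs_similarity


class EmptyPanelError(ValueError):
    pass


@dataclass
class QCParams:
    snp_call_rate_min: float = 0.98
    ind_call_rate_min: float = 0.95
    maf_min: float = 0.05
    ld_r2_max: float = 0.2
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    dup_ibs_min: float = 0.99
    #: pairs with fewer opposing homozygotes than this are flagged related
    opposing_hom_max: int = 100
    max_per_breed: int = 30
    kinship_second_degree: float = 0.25

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "ind_call_rate_min", "dup_ibs_min"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min outside [0, 0.5)")
        if self.ld_window_snps < 2 or self.ld_step_snps < 1:
            raise ValueError("bad LD window/step")


def _report(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["item_id", "item_type", "stage", "reason",
                                       "statistic"])


def filter_call_rate_maf(g: GenotypeMatrix, p: QCParams) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop SNPs at or below the call-rate/MAF thresholds, then individuals.

    Marker filters run first so a badly genotyped marker does not drag down
    sample call rates.
    """
    if g.n_snps == 0 or g.n_individuals == 0:
        raise EmptyPanelError("empty input panel")
    rows = []
    cr = g.snp_call_rate()
    maf = g.snp_maf()
    keep_snp = np.ones(g.n_snps, dtype=bool)
    for j, l in enumerate(g.loci):
        if cr[j] <= p.snp_call_rate_min:
            rows.append((l.snp_id, "snp", "call_rate_maf", "snp_call_rate", cr[j]))
            keep_snp[j] = False
        elif not (maf[j] > p.maf_min):  # NaN (all-missing) also fails
            rows.append((l.snp_id, "snp", "call_rate_maf", "maf", maf[j]))
            keep_snp[j] = False
    if not keep_snp.any():
        raise EmptyPanelError("all loci removed by call-rate/MAF filter")
    g2 = g.take_loci(np.flatnonzero(keep_snp))
    icr = g2.ind_call_rate()
    keep_ind = icr > p.ind_call_rate_min
    for i, ind in enumerate(g2.individuals):
        if not keep_ind[i]:
            rows.append((ind.sample_id, "individual", "call_rate_maf",
                         "ind_call_rate", icr[i]))
    g2 = g2.take_individuals(np.flatnonzero(keep_ind))
    g2.refresh_missing_rates()
    return g2, _report(rows)


def ld_prune(g: GenotypeMatrix, p: QCParams) -> tuple[list[str], pd.DataFrame]:
    """Greedy sliding-window LD pruning (indep-pairwise convention).

    Within each window of ``ld_window_snps`` markers advancing by
    ``ld_step_snps``, any pair with squared Pearson genotype correlation
    above ``ld_r2_max`` loses the later SNP in map order.  Deterministic.
    """
    m = g.n_snps
    X = g.calls.astype(float)
    X[g.calls < 0] = np.nan
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    n = X.shape[0]
    kept = np.ones(m, dtype=bool)
    rows = []
    starts = range(0, max(m - 1, 1), p.ld_step_snps)
    for s in starts:
        w = np.arange(s, min(s + p.ld_window_snps, m))
        w = w[kept[w]]
        if w.size < 2:
            continue
        r = (X[:, w].T @ X[:, w]) / n
        r2 = r ** 2
        for a in range(len(w)):
            if not kept[w[a]]:
                continue
            for b in range(a + 1, len(w)):
                jb = w[b]
                if kept[jb] and r2[a, b] > p.ld_r2_max:
                    kept[jb] = False
                    rows.append((g.loci[jb].snp_id, "snp", "ld_prune",
                                 f"r2_with_{g.loci[w[a]].snp_id}", r2[a, b]))
    retained = [l.snp_id for j, l in enumerate(g.loci) if kept[j]]
    return retained, _report(rows)


def opposing_homozygote_counts(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise counts of loci where one individual is 0 and the other 2."""
    hom0 = (g.calls == 0).astype(np.float64)
    hom2 = (g.calls == 2).astype(np.float64)
    return (hom0 @ hom2.T + hom2 @ hom0.T).astype(int)


def _prune_flagged_pairs(g: GenotypeMatrix, pairs: list[tuple[int, int]],
                         stage: str, reason: str, stat: np.ndarray, rows: list) -> np.ndarray:
    """Apply the removal rule: the individual occurring in multiple flagged
    pairs goes first; otherwise the member with the higher missingness."""
    miss = 1.0 - g.ind_call_rate()
    removed: set[int] = set()
    pairs = list(pairs)
    while True:
        live = [(i, j) for i, j in pairs if i not in removed and j not in removed]
        if not live:
            break
        degree: dict[int, int] = {}
        for i, j in live:
            degree[i] = degree.get(i, 0) + 1
            degree[j] = degree.get(j, 0) + 1
        max_deg = max(degree.values())
        if max_deg > 1:
            cands = [k for k, d in degree.items() if d == max_deg]
            victim = max(cands, key=lambda k: (miss[k], g.individuals[k].sample_id))
        else:
            i, j = live[0]
            victim = max((i, j), key=lambda k: (miss[k], g.individuals[k].sample_id))
        removed.add(victim)
        other = next(b if a == victim else a for a, b in live if victim in (a, b))
        rows.append((g.individuals[victim].sample_id, "individual", stage, reason,
                     float(stat[victim, other])))
    return np.asarray(sorted(removed), dtype=int)


def remove_duplicates_and_relatives(
    g: GenotypeMatrix, p: QCParams
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop duplicated individuals (IBS above threshold) and close relatives.

    Relatedness between animals without pedigrees is screened by the
    opposing-homozygote count: pairs with fewer than ``opposing_hom_max``
    discordant homozygous loci are flagged, and the flagged graph is pruned
    by removing animals occurring in multiple pairs, else the member with
    the higher missingness.
    """
    rows: list = []
    sim, _ = ibs_similarity(g)
    n = g.n_individuals
    iu = np.triu_indices(n, k=1)
    dup_pairs = [(int(i), int(j)) for i, j in zip(*iu) if sim[i, j] > p.dup_ibs_min]
    removed_dup = _prune_flagged_pairs(g, dup_pairs, "duplicates", "ibs_similarity",
                                       sim, rows)
    keep = np.setdiff1d(np.arange(n), removed_dup)
    g2 = g.take_individuals(keep)

    opp = opposing_homozygote_counts(g2)
    n2 = g2.n_individuals
    iu = np.triu_indices(n2, k=1)
    rel_pairs = [(int(i), int(j)) for i, j in zip(*iu)
                 if opp[i, j] < p.opposing_hom_max]
    removed_rel = _prune_flagged_pairs(g2, rel_pairs, "relatives",
                                       "opposing_homozygotes", opp.astype(float), rows)
    g3 = g2.take_individuals(np.setdiff1d(np.arange(n2), removed_rel))
    g3.refresh_missing_rates()
    return g3, _report(rows)


def pihat_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Method-of-moments IBD proportion (pi-hat) between all individual pairs.

    Uses the classic IBS-decomposition estimator with allele frequencies
    taken from the sample (no small-sample bias correction): per-locus
    expected IBS-state probabilities under IBD states 0/1/2 are summed over
    jointly non-missing loci and solved sequentially for P(IBD=0), P(IBD=1),
    P(IBD=2); pi-hat = P1/2 + P2, clamped to [0, 1].
    """
    p = g.snp_allele_freq()
    ok = ~np.isnan(p) & (p > 0) & (p < 1)
    gg = g.take_loci(np.flatnonzero(ok))
    p = gg.snp_allele_freq()
    q = 1.0 - p
    e0_ibs0 = 2 * p ** 2 * q ** 2
    e0_ibs1 = 4 * p ** 3 * q + 4 * p * q ** 3
    e1_ibs1 = 2 * p ** 2 * q + 2 * p * q ** 2
    e0_ibs2 = p ** 4 + q ** 4 + 4 * p ** 2 * q ** 2
    e1_ibs2 = p ** 3 + q ** 3 + p * q

    valid = gg.valid_mask().astype(np.float64)
    i0 = ((gg.calls == 0) & (valid > 0)).astype(np.float64)
    i1 = ((gg.calls == 1) & (valid > 0)).astype(np.float64)
    i2 = ((gg.calls == 2) & (valid > 0)).astype(np.float64)
    joint = valid @ valid.T
    n_ibs0 = i0 @ i2.T + i2 @ i0.T
    n_ibs2 = i0 @ i0.T + i1 @ i1.T + i2 @ i2.T
    n_ibs1 = joint - n_ibs0 - n_ibs2

    def _esum(e):
        return (valid * e[None, :]) @ valid.T

    E0_0, E0_1 = _esum(e0_ibs0), _esum(e0_ibs1)
    E1_1 = _esum(e1_ibs1)
    E0_2, E1_2 = _esum(e0_ibs2), _esum(e1_ibs2)
    with np.errstate(invalid="ignore", divide="ignore"):
        P0 = n_ibs0 / E0_0
        P1 = (n_ibs1 - P0 * E0_1) / E1_1
        P2 = (n_ibs2 - P0 * E0_2 - P1 * E1_2) / joint
    P0 = np.clip(P0, 0, 1)
    P1 = np.clip(P1, 0, 1)
    P2 = np.clip(P2, 0, 1)
    total = P0 + P1 + P2
    total[total == 0] = 1.0
    pihat = np.clip((0.5 * P1 + P2) / total, 0.0, 1.0)
    np.fill_diagonal(pihat, 1.0)
    return pihat


def kinship_filter_second_degree(
    g: GenotypeMatrix, p: QCParams
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Greedily remove individuals until no pair exceeds the pi-hat cut."""
    rows: list = []
    pihat = pihat_matrix(g)
    miss = 1.0 - g.ind_call_rate()
    n = g.n_individuals
    alive = np.ones(n, dtype=bool)
    while True:
        mat = np.where(np.outer(alive, alive), pihat, 0.0)
        np.fill_diagonal(mat, 0.0)
        over = mat > p.kinship_second_degree
        if not over.any():
            break
        degree = over.sum(axis=1)
        cand = np.flatnonzero(degree == degree.max())
        victim = max(cand, key=lambda k: (miss[k], g.individuals[k].sample_id))
        partner = int(np.argmax(mat[victim]))
        rows.append((g.individuals[victim].sample_id, "individual", "kinship",
                     "pi_hat", float(pihat[victim, partner])))
        alive[victim] = False
    g2 = g.take_individuals(np.flatnonzero(alive))
    return g2, _report(rows)


def representative_subsample(
    g: GenotypeMatrix, max_n: int = 30, seed: int = 0
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Cap each breed at ``max_n`` animals while preserving diversity.

    Breeds over the cap are reduced by farthest-point traversal on the
    within-breed 1-IBS distance matrix (seeded random start), which keeps
    the spread of the breed rather than a random core.
    """
    if max_n < 2:
        raise ValueError("max_n must be >= 2")
    rng = np.random.default_rng(seed)
    rows: list = []
    keep_global: list[int] = []
    sim, _ = ibs_similarity(g)
    dist = 1.0 - sim
    for breed, idx in g.breed_indices().items():
        if idx.size <= max_n:
            keep_global.extend(idx.tolist())
            continue
        d = dist[np.ix_(idx, idx)]
        start = int(rng.integers(idx.size))
        chosen = [start]
        mind = d[start].copy()
        while len(chosen) < max_n:
            mind[chosen] = -np.inf
            nxt = int(np.argmax(mind))
            chosen.append(nxt)
            mind = np.minimum(mind, d[nxt])
        chosen_set = set(chosen)
        for k in range(idx.size):
            if k not in chosen_set:
                rows.append((g.individuals[idx[k]].sample_id, "individual",
                             "subsample", f"breed_{breed}_over_{max_n}", float("nan")))
        keep_global.extend(idx[sorted(chosen_set)].tolist())
    g2 = g.take_individuals(sorted(keep_global))
    return g2, _report(rows)


def build_datasets(
    g: GenotypeMatrix, params: QCParams | None = None, seed: int = 0
) -> dict:
    """Run the full cascade and return the three nested working datasets.

    Returns a dict with keys ``haplotype``, ``structure``, ``landscape``
    (GenotypeMatrix each), ``report`` (concatenated removal report), and
    ``counts`` (per-stage individual/SNP sizes, the dataset-accounting log).
    """
    params = params or QCParams()
    reports = []
    counts = [("raw", g.n_individuals, g.n_snps)]

    g1, rep = filter_call_rate_maf(g, params)
    reports.append(rep)
    counts.append(("call_rate_maf", g1.n_individuals, g1.n_snps))

    hap, rep = remove_duplicates_and_relatives(g1, params)
    reports.append(rep)
    counts.append(("haplotype", hap.n_individuals, hap.n_snps))

    retained, rep = ld_prune(hap, params)
    reports.append(rep)
    pruned = hap.select_snp_ids(retained)
    struct, rep = representative_subsample(pruned, params.max_per_breed, seed)
    reports.append(rep)
    counts.append(("structure", struct.n_individuals, struct.n_snps))

    land, rep = kinship_filter_second_degree(struct, params)
    reports.append(rep)
    has_coords = [i for i, ind in enumerate(land.individuals)
                  if ind.latitude is not None and ind.longitude is not None]
    if has_coords and len(has_coords) < land.n_individuals:
        dropped = set(range(land.n_individuals)) - set(has_coords)
        reports.append(_report([
            (land.individuals[i].sample_id, "individual", "georeference",
             "no_coordinates", float("nan")) for i in sorted(dropped)
        ]))
        land = land.take_individuals(has_coords)
    counts.append(("landscape", land.n_individuals, land.n_snps))

    nonempty = [r for r in reports if len(r)]
    report = pd.concat(nonempty, ignore_index=True) if nonempty else _report([])
    return {
        "haplotype": hap,
        "structure": struct,
        "landscape": land,
        "report": report,
        "counts": pd.DataFrame(counts, columns=["stage", "n_individuals", "n_snps"]),
    }
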