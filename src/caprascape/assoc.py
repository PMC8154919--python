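"""Genotype-environment association with structure correction.

Each genotype at a biallelic SNP (AA, AB, BB) is treated as a separate
binary presence/absence response.  For every (genotype, environmental
variable) pair two logistic models are fitted by iteratively reweighted
least squares: a null with the population-structure principal components
only, and an alternative adding the focal variable.  The deviance drop is
the likelihood-ratio statistic G, referred to a chi-square with 1 df, and
p-values are Benjamini-Hochberg adjusted across the pooled test family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .core import GenotypeMatrix

MAX_IRLS_ITER = 50
DEVIANCE_TOL = 1e-8


class DegenerateResponseError(ValueError):
    pass


@dataclass
class StructureCovariates:
    scores: np.ndarray            # n x k, centered
    variance_explained: np.ndarray
    k: int
    method: str

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def broken_stick(n_components: int) -> np.ndarray:
    """Expected eigenvalue proportions under random partition of variance."""
    inv = 1.0 / np.arange(1, n_components + 1)
    return np.array([inv[i:].sum() for i in range(n_components)]) / n_components


def structure_pca(g: GenotypeMatrix, k: int | str = "auto") -> StructureCovariates:
    """PCA of the centered, unit-variance genotype matrix.

    Missing calls are mean-imputed per locus for the PCA only.  With
    ``k="auto"`` the number of retained axes is the count of eigenvalues
    above the broken-stick expectation, floored at 2.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    X = g.calls.astype(float)
    X[g.calls < 0] = np.nan
    mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mean, inds[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    max_rank = min(g.n_individuals - 1, X.shape[1])
    pca = PCA(n_components=max_rank, svd_solver="full")
    scores_full = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    if k == "auto":
        expect = broken_stick(max_rank)
        above = ratios > expect
        k_use = int(np.argmin(above)) if not above.all() else max_rank
        k_use = min(max(2, k_use), max_rank)
        method = f"broken-stick (k={k_use})"
    else:
        k_use = int(k)
        if k_use > max_rank:
            warnings.warn(f"k={k_use} exceeds rank {max_rank}; truncating")
            k_use = max_rank
        method = f"fixed (k={k_use})"
    scores = scores_full[:, :k_use]
    scores = scores - scores.mean(axis=0)
    return StructureCovariates(scores, ratios[:k_use], k_use, method)


@dataclass
class GenotypeIndicator:
    snp_id: str
    genotype: str        # nucleotide label, e.g. "GG"
    code: int            # 0, 1, 2
    y: np.ndarray        # float; NaN where the call is missing


def genotype_indicators(g: GenotypeMatrix, min_count: int = 5):
    """Binary presence vectors per observed genotype, skipping rare ones.

    Genotypes seen in fewer than ``min_count`` individuals are skipped, as
    is any locus where a genotype's indicator would be constant over the
    non-missing calls (degenerate response).
    """
    out: list[GenotypeIndicator] = []
    for j, locus in enumerate(g.loci):
        col = g.calls[:, j]
        valid = col >= 0
        n_valid = int(valid.sum())
        for code in (0, 1, 2):
            n_code = int((col[valid] == code).sum())
            if n_code < min_count or n_code > n_valid - min_count:
                continue
            y = np.where(valid, (col == code).astype(float), np.nan)
            out.append(GenotypeIndicator(locus.snp_id, locus.genotype_label(code),
                                         code, y))
    return out


def _logistic_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def fit_logistic_irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Logistic regression by IRLS; returns (coefficients, deviance, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    dev = _logistic_deviance(y, expit(eta))
    converged = False
    for _ in range(MAX_IRLS_ITER):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(X.T @ WX, WX.T @ z, rcond=None)
        eta = X @ beta
        new_dev = _logistic_deviance(y, expit(eta))
        if abs(dev - new_dev) < DEVIANCE_TOL:
            dev = new_dev
            converged = True
            break
        dev = new_dev
    separated = np.max(np.abs(eta)) > 30.0
    return beta, dev, converged and not separated


@dataclass
class AssociationResult:
    snp_id: str
    genotype: str
    variable: str
    deviance_null: float
    deviance_alt: float
    G: float
    p_value: float
    q_value: float
    effect_sign: int
    converged: bool
    n: int


def lrt_association(
    y: np.ndarray, x: np.ndarray, covariates: StructureCovariates,
    snp_id: str = "", genotype: str = "", variable: str = "",
) -> AssociationResult:
    """Likelihood-ratio test of one binary genotype response vs one variable.

    Null: intercept + structure PCs.  Alternative: adds the standardized
    focal variable.  G = deviance_null - deviance_alt ~ chi-square(1).
    Non-convergence (including quasi-separation) is flagged but the result
    is retained.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(x)
    y, x = y[ok], x[ok]
    S = covariates.scores[ok]
    if y.min() == y.max():
        raise DegenerateResponseError("response is constant")
    sd = x.std()
    xs = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    n = y.size
    X0 = np.column_stack([np.ones(n), S])
    X1 = np.column_stack([X0, xs])
    _, dev0, conv0 = fit_logistic_irls(X0, y)
    beta1, dev1, conv1 = fit_logistic_irls(X1, y)
    G = max(dev0 - dev1, 0.0)
    p = float(stats.chi2.sf(G, df=1))
    return AssociationResult(
        snp_id=snp_id, genotype=genotype, variable=variable,
        deviance_null=dev0, deviance_alt=dev1, G=G, p_value=p, q_value=np.nan,
        effect_sign=int(np.sign(beta1[-1])), converged=bool(conv0 and conv1), n=n,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def env_for_individuals(
    env_long: pd.DataFrame, g: GenotypeMatrix, epoch: str = "current"
) -> pd.DataFrame:
    """Broadcast a breed-level env table to individuals (n x variables)."""
    wide = env_long[env_long["epoch"] == epoch].pivot(
        index="unit_id", columns="variable", values="value")
    codes = g.breed_codes
    missing = set(codes) - set(wide.index)
    if missing:
        raise ValueError(f"no environmental values for breeds {sorted(missing)}")
    return wide.loc[codes].set_axis(g.sample_ids, axis=0)


def run_association(
    g: GenotypeMatrix,
    env_individual: pd.DataFrame,
    covariates: StructureCovariates | None = None,
    min_count: int = 5,
    bh_family: str = "pooled",
) -> pd.DataFrame:
    """All (genotype, variable) LRTs with pooled BH correction.

    ``env_individual`` has one row per individual (aligned with ``g``) and
    one column per variable.  ``bh_family`` is ``"pooled"`` (default) or
    ``"per_variable"``.
    """
    if list(env_individual.index) != g.sample_ids:
        raise ValueError("env table rows must align with panel individuals")
    covs = covariates if covariates is not None else structure_pca(g)
    indicators = genotype_indicators(g, min_count=min_count)
    rows = []
    for var in env_individual.columns:
        x = env_individual[var].to_numpy(dtype=float)
        for ind in indicators:
            res = lrt_association(ind.y, x, covs, snp_id=ind.snp_id,
                                  genotype=ind.genotype, variable=var)
            rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    if len(out):
        if bh_family == "per_variable":
            out["q_value"] = out.groupby("variable")["p_value"].transform(
                lambda s: bh_adjust(s.to_numpy()))
        else:
            out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def read_gene_bed(path) -> pd.DataFrame:
    """BED-like gene intervals: chromosome, start, end (0-based half-open), name."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chromosome", "start", "end", "name"],
                     dtype={"chromosome": str})
    return df


def annotate_hits(
    results: pd.DataFrame, gene_intervals: pd.DataFrame, g: GenotypeMatrix
) -> pd.DataFrame:
    """Attach every overlapping gene to each result row.

    Gene intervals are 0-based half-open; a SNP at 1-based position P lies
    in [start, end) iff start <= P - 1 < end.  Multiple genes are joined
    with ';'; rows without overlap get an empty string.
    """
    gi = gene_intervals
    if len(gi) and not (gi["end"] > gi["start"]).all():
        bad = gi[~(gi["end"] > gi["start"])].iloc[0]
        raise ValueError(f"malformed interval for {bad['name']}: end <= start")
    pos = {l.snp_id: (str(l.chromosome), l.position_bp) for l in g.loci}
    genes = []
    for snp in results["snp_id"]:
        chrom, p = pos[snp]
        zb = p - 1
        hit = gi[(gi["chromosome"] == chrom) & (gi["start"] <= zb) & (zb < gi["end"])]
        genes.append(";".join(hit["name"].tolist()))
    out = results.copy()
    out["gene"] = genes
    return out
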