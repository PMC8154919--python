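"""Core genotype containers and PLINK text I/O.

Conventions used throughout the package:

* Genotype calls are coded as copies of the B allele: 0, 1, 2, with -1
  marking a missing call.  By default the B allele is the minor allele
  observed when a panel is loaded; the nucleotide labels of both alleles
  are kept on each locus so genotype strings such as ``"AG"`` can be
  reconstructed for reporting.
* Physical positions are 1-based base pairs, as in PLINK MAP files, and
  segment intervals are closed ``[start, end]``.
* Missing calls are never imputed in this module; each downstream stage
  states its own handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: allele symbols accepted in PED files ('0' is the missing/unknown allele)
VALID_ALLELES = frozenset("ACGT012")


class MalformedFileError(ValueError):
    """A text input violates its format contract."""


class EmptyGroupError(ValueError):
    """A requested group contains no individuals."""


@dataclass(frozen=True)
class SNPLocus:
    """A biallelic marker with a stored (A, B) allele orientation."""

    snp_id: str
    chromosome: str
    position_bp: int
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"{self.snp_id}: position_bp must be >= 1")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must be distinct")

    def genotype_label(self, code: int) -> str:
        """Nucleotide genotype string for a call code (het sorted, e.g. 'AG')."""
        if code == 0:
            return self.allele_a * 2
        if code == 1:
            return "".join(sorted((self.allele_a, self.allele_b)))
        if code == 2:
            return self.allele_b * 2
        return "--"


@dataclass
class Individual:
    sample_id: str
    breed_code: str
    latitude: float | None = None
    longitude: float | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"{self.sample_id}: missing_rate outside [0, 1]")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype panel.

    ``calls[i, j]`` counts copies of locus j's B allele carried by
    individual i (-1 = missing).  When ``phased``, ``haplotypes`` holds the
    per-chromosome binary alleles with shape ``(n_individuals, 2, n_snps)``
    and must sum to ``calls`` wherever calls are non-missing.
    """

    individuals: list[Individual]
    loci: list[SNPLocus]
    calls: np.ndarray
    phased: bool = False
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        ids = [l.snp_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in panel")
        sids = [i.sample_id for i in self.individuals]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate sample_id in panel")
        if self.phased:
            if self.haplotypes is None:
                raise ValueError("phased matrix requires haplotypes")
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            expect = (len(self.individuals), 2, len(self.loci))
            if self.haplotypes.shape != expect:
                raise ValueError(f"haplotypes shape must be {expect}")
            hsum = self.haplotypes.sum(axis=1)
            ok = self.calls < 0
            if not np.array_equal(hsum[~ok], self.calls[~ok]):
                raise ValueError("haplotype sums disagree with calls")

    # ---- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.loci)

    @property
    def sample_ids(self) -> list[str]:
        return [i.sample_id for i in self.individuals]

    @property
    def snp_ids(self) -> list[str]:
        return [l.snp_id for l in self.loci]

    @property
    def breed_codes(self) -> np.ndarray:
        return np.asarray([i.breed_code for i in self.individuals])

    @property
    def positions_bp(self) -> np.ndarray:
        return np.asarray([l.position_bp for l in self.loci], dtype=np.int64)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.asarray([l.chromosome for l in self.loci])

    def valid_mask(self) -> np.ndarray:
        return self.calls >= 0

    # ---- per-axis statistics --------------------------------------------

    def snp_call_rate(self) -> np.ndarray:
        return self.valid_mask().mean(axis=0)

    def ind_call_rate(self) -> np.ndarray:
        return self.valid_mask().mean(axis=1)

    def snp_allele_freq(self) -> np.ndarray:
        """Overall frequency of the B allele over non-missing calls (NaN if none)."""
        valid = self.valid_mask()
        n = valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(valid, self.calls, 0).sum(axis=0) / (2.0 * n)

    def snp_maf(self) -> np.ndarray:
        p = self.snp_allele_freq()
        return np.minimum(p, 1.0 - p)

    def breed_indices(self) -> dict[str, np.ndarray]:
        codes = self.breed_codes
        return {b: np.flatnonzero(codes == b) for b in dict.fromkeys(codes)}

    # ---- subsetting ------------------------------------------------------

    def take_individuals(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        haps = self.haplotypes[idx] if self.haplotypes is not None else None
        return GenotypeMatrix(
            [self.individuals[i] for i in idx], list(self.loci),
            self.calls[idx], self.phased, haps,
        )

    def take_loci(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        haps = self.haplotypes[:, :, idx] if self.haplotypes is not None else None
        return GenotypeMatrix(
            list(self.individuals), [self.loci[j] for j in idx],
            self.calls[:, idx], self.phased, haps,
        )

    def select_snp_ids(self, keep: Sequence[str]) -> "GenotypeMatrix":
        keep = set(keep)
        return self.take_loci([j for j, l in enumerate(self.loci) if l.snp_id in keep])

    def refresh_missing_rates(self) -> None:
        rates = 1.0 - self.ind_call_rate()
        for ind, r in zip(self.individuals, rates):
            ind.missing_rate = float(r)


@dataclass
class BreedFrequencyTable:
    """Per-group allele frequencies of each locus's B allele.

    ``freq``/``n`` are DataFrames indexed by group label with one column per
    snp_id: frequency over non-missing calls, and the non-missing sample
    count that produced it.  Loci with no calls in a group hold NaN.
    """

    freq: pd.DataFrame
    n: pd.DataFrame

    def maf(self) -> pd.DataFrame:
        return np.minimum(self.freq, 1.0 - self.freq)

    @property
    def groups(self) -> list[str]:
        return list(self.freq.index)


def allele_frequencies(
    g: GenotypeMatrix,
    grouping: Mapping[str, str] | Sequence[str] | None = None,
) -> BreedFrequencyTable:
    """Allele frequency of the B allele per (group, locus).

    ``grouping`` defaults to breed labels; alternatively a per-individual
    label sequence or a mapping from sample_id to group.  Frequencies use
    non-missing calls only: p = (B-allele copies) / (2 * non-missing).
    """
    if grouping is None:
        labels = g.breed_codes
    elif isinstance(grouping, Mapping):
        try:
            labels = np.asarray([grouping[s] for s in g.sample_ids])
        except KeyError as exc:
            raise EmptyGroupError(f"sample {exc.args[0]} has no group") from exc
    else:
        labels = np.asarray(list(grouping))
        if labels.shape[0] != g.n_individuals:
            raise ValueError("grouping length does not match individuals")

    valid = g.valid_mask()
    copies = np.where(valid, g.calls, 0)
    groups = list(dict.fromkeys(labels))
    freq_rows, n_rows = [], []
    for grp in groups:
        idx = np.flatnonzero(labels == grp)
        if idx.size == 0:
            raise EmptyGroupError(f"group {grp!r} is empty")
        nn = valid[idx].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = copies[idx].sum(axis=0) / (2.0 * nn)
        freq_rows.append(p)
        n_rows.append(nn)
    snp_ids = g.snp_ids
    return BreedFrequencyTable(
        freq=pd.DataFrame(freq_rows, index=groups, columns=snp_ids, dtype=float),
        n=pd.DataFrame(n_rows, index=groups, columns=snp_ids, dtype=int),
    )


# ---------------------------------------------------------------------------
# PLINK text I/O
# ---------------------------------------------------------------------------

def read_map_text(map_path: str | Path) -> list[tuple[str, str, int]]:
    rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) == 4:
            chrom, snp_id, _cm, bp = f
        elif len(f) == 3:
            chrom, snp_id, bp = f
        else:
            raise MalformedFileError(f"{map_path}: line {ln} has {len(f)} columns")
        rows.append((chrom, snp_id, int(bp)))
    return rows


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Load a PED/MAP pair into a :class:`GenotypeMatrix`.

    The B allele of each locus is the minor allele among observed calls
    (ties broken toward the lexicographically later symbol); a "0" allele
    marks the call missing.  Breed codes come from the family-ID column.
    """
    map_rows = read_map_text(map_path)
    m = len(map_rows)

    meta: list[list[str]] = []
    allele_rows: list[list[str]] = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 6 + 2 * m:
            raise MalformedFileError(
                f"{ped_path}: line {ln} has {len(f)} columns, expected {6 + 2 * m} "
                f"for a {m}-SNP panel"
            )
        for tok in f[6:]:
            if tok not in VALID_ALLELES:
                raise MalformedFileError(
                    f"{ped_path}: line {ln}: unknown allele symbol {tok!r}"
                )
        meta.append(f[:6])
        allele_rows.append(f[6:])

    n = len(meta)
    alleles = np.asarray(allele_rows).reshape(n, m, 2) if n else np.empty((0, m, 2), dtype="U1")

    loci: list[SNPLocus] = []
    calls = np.full((n, m), MISSING, dtype=np.int8)
    for j, (chrom, snp_id, bp) in enumerate(map_rows):
        col = alleles[:, j, :]
        missing = (col == "0").any(axis=1)
        observed = col[~missing]
        symbols, counts = np.unique(observed, return_counts=True)
        if symbols.size > 2:
            raise MalformedFileError(f"{ped_path}: {snp_id} has >2 alleles: {list(symbols)}")
        if symbols.size == 2:
            # minor allele becomes B; tie -> lexicographically later symbol
            if counts[0] < counts[1]:
                a, b = symbols[1], symbols[0]
            else:
                a, b = symbols[0], symbols[1]
        elif symbols.size == 1:
            a, b = symbols[0], "0"
        else:
            a, b = "A", "B"
        loci.append(SNPLocus(snp_id, chrom, bp, str(a), str(b)))
        code = (col == b).sum(axis=1).astype(np.int8)
        code[missing] = MISSING
        calls[:, j] = code

    individuals = [
        Individual(sample_id=f[1], breed_code=f[0]) for f in meta
    ]
    g = GenotypeMatrix(individuals, loci, calls)
    g.refresh_missing_rates()
    return g


def write_plink_text(g: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    with open(map_path, "w") as fh:
        for l in g.loci:
            fh.write(f"{l.chromosome}\t{l.snp_id}\t0\t{l.position_bp}\n")
    allele_lut = np.asarray(
        [[l.allele_a, l.allele_a, l.allele_a, l.allele_b, l.allele_b, l.allele_b]
         for l in g.loci]
    )  # columns: code0 a/a, code1 a/b, code2 b/b laid out pairwise below
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(g.individuals):
            fields = [ind.breed_code, ind.sample_id, "0", "0", "0", "-9"]
            row = g.calls[i]
            for j, code in enumerate(row):
                if code < 0:
                    fields += ["0", "0"]
                else:
                    fields += [allele_lut[j, 2 * code], allele_lut[j, 2 * code + 1]]
            fh.write(" ".join(fields) + "\n")


def write_haplotype_table(g: GenotypeMatrix, path: str | Path) -> None:
    """Phased haplotypes as TSV: sample_id, hap (1/2), then 0/1 B-allele codes."""
    if not g.phased or g.haplotypes is None:
        raise ValueError("matrix is not phased")
    with open(path, "w") as fh:
        fh.write("sample_id\thap\t" + "\t".join(g.snp_ids) + "\n")
        for i, ind in enumerate(g.individuals):
            for h in (0, 1):
                codes = "\t".join(str(int(x)) for x in g.haplotypes[i, h])
                fh.write(f"{ind.sample_id}\t{h + 1}\t{codes}\n")


def read_haplotype_table(path: str | Path, g: GenotypeMatrix) -> GenotypeMatrix:
    """Attach phased haplotypes from :func:`write_haplotype_table` output."""
    df = pd.read_csv(path, sep="\t")
    snp_cols = list(df.columns[2:])
    if snp_cols != g.snp_ids:
        raise MalformedFileError(f"{path}: snp columns do not match panel")
    haps = np.zeros((g.n_individuals, 2, g.n_snps), dtype=np.int8)
    order = {s: i for i, s in enumerate(g.sample_ids)}
    for _, row in df.iterrows():
        sid = row.iloc[0]
        if sid not in order:
            raise MalformedFileError(f"{path}: unknown sample {sid!r}")
        haps[order[sid], int(row.iloc[1]) - 1] = row.iloc[2:].to_numpy(dtype=np.int8)
    return GenotypeMatrix(list(g.individuals), list(g.loci), g.calls, True, haps)


def read_breed_table(path: str | Path) -> pd.DataFrame:
    """Breed metadata TSV: breed_code, name, latitude, longitude."""
    df = pd.read_csv(path, sep="\t", dtype={"breed_code": str})
    required = {"breed_code"}
    if not required <= set(df.columns):
        raise MalformedFileError(f"{path}: missing columns {required - set(df.columns)}")
    return df
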