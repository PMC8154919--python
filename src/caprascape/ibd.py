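"""Identity-by-descent segment handling and the breed haplotype-sharing matrix.

Segments are consumed in the RefinedIBD tab-separated layout
(sample_a, hap_a, sample_b, hap_b, chromosome, start_bp, end_bp, score).
A naive detector for synthetic phased data reports maximal runs of
identical alleles between haplotype pairs; the probabilistic HMM used on
real data is out of scope and its output is simply ingested.

The breed-level summary is the median, over every inter-breed individual
pair, of the per-pair total shared length (pairs sharing nothing count as
zero) -- reported in Mb.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

SEGMENT_COLUMNS = ["sample_a", "hap_a", "sample_b", "hap_b", "chromosome",
                   "start_bp", "end_bp", "score"]


class SegmentError(ValueError):
    pass


@dataclass
class IBDSegmentSet:
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.segments
        missing = [c for c in SEGMENT_COLUMNS if c not in df.columns and c != "score"]
        if missing:
            raise SegmentError(f"segment table missing columns {missing}")
        if "score" not in df.columns:
            df = df.assign(score=np.nan)
        df = df.astype({"start_bp": np.int64, "end_bp": np.int64,
                        "hap_a": int, "hap_b": int, "chromosome": str,
                        "sample_a": str, "sample_b": str})
        if len(df) and not (df["end_bp"] > df["start_bp"]).all():
            raise SegmentError("segments must satisfy end_bp > start_bp")
        if len(df) and (df["sample_a"] == df["sample_b"]).any():
            raise SegmentError("segment samples must be distinct")
        self.segments = df[SEGMENT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def lengths_bp(self) -> np.ndarray:
        return (self.segments["end_bp"] - self.segments["start_bp"]).to_numpy()

    @classmethod
    def read_refinedibd(cls, path: str | Path) -> "IBDSegmentSet":
        df = pd.read_csv(path, sep="\t", header=None, names=SEGMENT_COLUMNS,
                         comment="#", dtype={"chromosome": str, "sample_a": str,
                                             "sample_b": str})
        return cls(df)

    def write_refinedibd(self, path: str | Path) -> None:
        self.segments.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class SharingMatrix:
    labels: list[str]
    values_mb: np.ndarray          # median shared length per breed pair, Mb
    pair_counts: np.ndarray        # individual pairs considered per entry

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(np.round(self.values_mb, 3), index=self.labels,
                            columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def write_circos_links(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, a in enumerate(self.labels):
                for j in range(i + 1, len(self.labels)):
                    v = self.values_mb[i, j]
                    if v > 0:
                        fh.write(f"{a}\t{self.labels[j]}\t{v:.3f}\n")


def _runs_of_true(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs (stop inclusive)."""
    if not mask.any():
        return
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for s, e in zip(edges[::2], edges[1::2]):
        yield int(s), int(e - 1)


def detect_ibd_naive(g: GenotypeMatrix, min_len_bp: int = 200_000) -> IBDSegmentSet:
    """Report maximal identical-allele runs between every haplotype pair.

    Construction-exact: a run is emitted when its physical span
    (last position - first position) reaches ``min_len_bp``.  Intended for
    synthetic phased data, where planted segments are literal copies.
    """
    if not g.phased or g.haplotypes is None:
        raise SegmentError(
            "matrix is unphased; ingest an external segment file via "
            "IBDSegmentSet.read_refinedibd instead"
        )
    records = []
    chroms = g.chromosomes
    for chrom in dict.fromkeys(chroms):
        cols = np.flatnonzero(chroms == chrom)
        pos = g.positions_bp[cols]
        H = g.haplotypes[:, :, cols]
        n = g.n_individuals
        for i in range(n):
            for j in range(i + 1, n):
                for hi in (0, 1):
                    diffs = H[i, hi][None, :] != H[j]  # (2, m_c)
                    for hj in (0, 1):
                        for s, e in _runs_of_true(~diffs[hj]):
                            if e == s:
                                continue  # a single SNP has no physical span
                            span = int(pos[e] - pos[s])
                            if span >= min_len_bp:
                                records.append((
                                    g.sample_ids[i], hi + 1, g.sample_ids[j], hj + 1,
                                    str(chrom), int(pos[s]), int(pos[e]), np.nan,
                                ))
    df = pd.DataFrame(records, columns=SEGMENT_COLUMNS)
    return IBDSegmentSet(df)


def breed_sharing_matrix(
    segs: IBDSegmentSet,
    individuals: GenotypeMatrix | Mapping[str, str],
    mode: str = "pair_sum",
) -> SharingMatrix:
    """Breed x breed median haplotype-sharing matrix in Mb.

    For each individual pair, the shared quantity is the summed length of
    its segments over all four haplotype pairings (``pair_sum``, default),
    and the breed-pair entry is the median of that quantity over all
    possible inter-breed individual pairs, zero-filled for pairs without
    sharing.  ``mode="segment_pool"`` instead takes the median of the pooled
    individual segment lengths, with one zero per non-sharing pair.
    """
    if mode not in ("pair_sum", "segment_pool"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(individuals, GenotypeMatrix):
        breed_of = {i.sample_id: i.breed_code for i in individuals.individuals}
    else:
        breed_of = dict(individuals)
    df = segs.segments
    unknown = set(df["sample_a"]) | set(df["sample_b"]) - set(breed_of)
    unknown -= set(breed_of)
    if unknown:
        raise SegmentError(f"segments name unknown samples: {sorted(unknown)[:5]}")

    breeds = list(dict.fromkeys(breed_of.values()))
    members: dict[str, list[str]] = {b: [] for b in breeds}
    for s, b in breed_of.items():
        members[b].append(s)
    nb = len(breeds)
    values = np.zeros((nb, nb))
    counts = np.zeros((nb, nb), dtype=int)

    # per-individual-pair totals and per-pair segment length lists
    lengths = df["end_bp"].to_numpy() - df["start_bp"].to_numpy()
    pair_total: dict[tuple[str, str], float] = {}
    pair_segs: dict[tuple[str, str], list[float]] = {}
    for (sa, sb), grp_len in zip(
        zip(df["sample_a"], df["sample_b"]), lengths
    ):
        key = (sa, sb) if sa <= sb else (sb, sa)
        pair_total[key] = pair_total.get(key, 0.0) + float(grp_len)
        pair_segs.setdefault(key, []).append(float(grp_len))

    for a in range(nb):
        for b in range(a, nb):
            if a == b:
                pairs = [(x, y) for k, x in enumerate(members[breeds[a]])
                         for y in members[breeds[a]][k + 1:]]
            else:
                pairs = [(x, y) for x in members[breeds[a]] for y in members[breeds[b]]]
            counts[a, b] = counts[b, a] = len(pairs)
            if not pairs:
                continue
            if mode == "pair_sum":
                vals = [pair_total.get((x, y) if x <= y else (y, x), 0.0)
                        for x, y in pairs]
            else:
                vals = []
                for x, y in pairs:
                    key = (x, y) if x <= y else (y, x)
                    vals.extend(pair_segs.get(key, [0.0]))
            med = float(np.median(vals)) if vals else 0.0
            values[a, b] = values[b, a] = med / 1e6
    return SharingMatrix(labels=breeds, values_mb=values, pair_counts=counts)
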