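"""Virtual-4C trans-interaction calling from Capture Hi-C pair records.

All pair records with at least one end in a baited viewpoint (e.g. the Igh,
Igk or Igl locus) are reduced to a 4C-like profile: the "other ends" landing
on different chromosomes are counted in fixed 500-kb genome-wide bins. Raw
counts per replicate are scored with the Iglewicz-Hoaglin modified Z-score

    z_i = 0.6745 * (x_i - median) / MAD,     MAD = median(|x_i - median|)

and a bin is a significant trans partner when z > 3.5 in every biological
replicate (strict inequality). The first 3 Mb of each chromosome, blacklist
intervals and any custom exclusion zones are ineligible; the viewpoint's own
chromosome(s) are excluded entirely (cis is removed). Interaction profiles
log2(average z + 1) can be compared across viewpoints/conditions by
hierarchical clustering (Euclidean distance, complete linkage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .contact_matrix import ContactPair

logger = logging.getLogger(__name__)

__all__ = [
    "ViewpointDef",
    "TransCountTable",
    "ZScoreResult",
    "virtual4c_bin_counts",
    "modified_zscore",
    "call_significant",
    "overlap_sets",
    "cluster_profiles",
    "read_bed",
    "read_chrom_sizes",
]

MODIFIED_Z_CONSTANT = 0.6745
MEANAD_CONSTANT = 1.253314
DEFAULT_Z_THRESHOLD = 3.5
DEFAULT_BIN_SIZE = 500_000
DEFAULT_CENTROMERIC_EXCLUSION = 3_000_000


@dataclass(frozen=True)
class ViewpointDef:
    """A named baited region: merged half-open 0-based intervals."""

    name: str
    intervals: tuple[tuple[str, int, int], ...]

    @staticmethod
    def from_intervals(name: str, intervals: Iterable[tuple[str, int, int]]) -> "ViewpointDef":
        by_chrom: dict[str, list[list[int]]] = {}
        for chrom, lo, hi in intervals:
            if hi <= lo:
                raise ValueError(f"empty interval {chrom}:{lo}-{hi}")
            by_chrom.setdefault(chrom, []).append([lo, hi])
        merged = []
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom])
            cur = ivs[0]
            for lo, hi in ivs[1:]:
                if lo <= cur[1]:
                    cur[1] = max(cur[1], hi)
                else:
                    merged.append((chrom, cur[0], cur[1]))
                    cur = [lo, hi]
            merged.append((chrom, cur[0], cur[1]))
        return ViewpointDef(name, tuple(merged))

    @property
    def chromosomes(self) -> frozenset[str]:
        return frozenset(c for c, _, _ in self.intervals)

    def contains(self, chrom: str, pos_1based: int) -> bool:
        p = pos_1based - 1
        return any(c == chrom and lo <= p < hi for c, lo, hi in self.intervals)


@dataclass
class TransCountTable:
    """Genome-wide fixed-grid trans bins with per-replicate raw counts."""

    bins: pd.DataFrame  # columns: chrom, start, eligible, count_rep1..count_repK
    bin_size: int
    viewpoint: str = ""
    skipped_pairs: int = 0

    @property
    def n_replicates(self) -> int:
        return sum(c.startswith("count_rep") for c in self.bins.columns)

    def counts(self, replicate: int) -> np.ndarray:
        return self.bins[f"count_rep{replicate}"].to_numpy()


@dataclass
class ZScoreResult:
    """Per-bin modified Z per replicate, the significance call, and profiles."""

    table: pd.DataFrame  # chrom, start, z_rep*, significant, avg_z, log2_avg_z1
    threshold: float

    @property
    def significant_bins(self) -> set[tuple[str, int]]:
        hits = self.table.loc[self.table["significant"]]
        return set(zip(hits["chrom"], hits["start"]))


def read_bed(path) -> list[tuple[str, int, int]]:
    """Minimal BED reader: chrom, start, end (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def read_chrom_sizes(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                out[chrom] = int(size)
    return out


def _grid(genome: Mapping[str, int], bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom in genome:
        for start in range(0, genome[chrom], bin_size):
            rows.append((chrom, start))
    return pd.DataFrame(rows, columns=["chrom", "start"])


def virtual4c_bin_counts(
    pairs_per_replicate: Sequence[Iterable[ContactPair | tuple]],
    viewpoint: ViewpointDef,
    genome: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    centromeric_exclusion: int = DEFAULT_CENTROMERIC_EXCLUSION,
    blacklist: Sequence[tuple[str, int, int]] = (),
    custom_exclusions: Sequence[tuple[str, int, int]] = (),
) -> TransCountTable:
    """Count viewpoint-anchored trans other-ends in fixed genome-wide bins.

    A pair contributes when one end overlaps the viewpoint and the other end
    lies on a chromosome carrying no viewpoint interval (cis removed). Bins
    overlapping the centromeric exclusion (first ``centromeric_exclusion``
    bp of every chromosome), the blacklist, or a custom exclusion zone by
    >= 1 bp are ineligible; viewpoint chromosomes are entirely ineligible.
    Pairs on chromosomes missing from ``genome`` are skipped with a tally.
    """
    grid = _grid(genome, bin_size)
    key_to_row = {(c, s): i for i, (c, s) in enumerate(zip(grid["chrom"], grid["start"]))}
    eligible = np.ones(len(grid), dtype=bool)
    vp_chroms = viewpoint.chromosomes
    exclusions = list(blacklist) + list(custom_exclusions)
    if centromeric_exclusion > 0:
        exclusions += [(c, 0, centromeric_exclusion) for c in genome]
    ends = grid["start"].to_numpy() + bin_size
    starts = grid["start"].to_numpy()
    chroms = grid["chrom"].to_numpy()
    eligible &= ~np.isin(chroms, sorted(vp_chroms))
    for chrom, lo, hi in exclusions:
        overlap = (chroms == chrom) & (starts < hi) & (ends > lo)
        eligible[overlap] = False

    counts = []
    skipped = 0
    for rep_pairs in pairs_per_replicate:
        vec = np.zeros(len(grid), dtype=np.int64)
        for rec in rep_pairs:
            if not isinstance(rec, ContactPair):
                rec = ContactPair(str(rec[0]), int(rec[1]), str(rec[2]), int(rec[3]))
            a_in = viewpoint.contains(rec.chrom_a, rec.pos_a)
            b_in = viewpoint.contains(rec.chrom_b, rec.pos_b)
            if a_in == b_in:
                continue  # neither end baited, or baited-to-baited (not trans 4C signal)
            other_chrom, other_pos = (
                (rec.chrom_b, rec.pos_b) if a_in else (rec.chrom_a, rec.pos_a)
            )
            if other_chrom in vp_chroms:
                continue  # cis removed
            if other_chrom not in genome:
                skipped += 1
                continue
            row = key_to_row.get((other_chrom, (other_pos - 1) // bin_size * bin_size))
            if row is None:
                skipped += 1
                continue
            if eligible[row]:
                vec[row] += 1
        counts.append(vec)
    if skipped:
        logger.warning("virtual4c: skipped %d pairs on unknown chromosomes/bins", skipped)
    table = grid.copy()
    table["eligible"] = eligible
    for k, vec in enumerate(counts, start=1):
        vec = vec.copy()
        vec[~eligible] = 0
        table[f"count_rep{k}"] = vec
    return TransCountTable(table, bin_size, viewpoint.name, skipped)


def modified_zscore(counts: np.ndarray) -> np.ndarray:
    """Iglewicz-Hoaglin modified Z-score of a count vector.

    Falls back to 1.253314 x mean absolute deviation when the MAD is zero;
    if that is also zero every score is 0. Invariant under positive affine
    rescaling of the counts.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 eligible bins")
    med = np.median(x)
    dev = x - med
    mad = np.median(np.abs(dev))
    if mad > 0:
        return MODIFIED_Z_CONSTANT * dev / mad
    meanad = np.abs(dev).mean()
    if meanad > 0:
        return dev / (MEANAD_CONSTANT * meanad)
    return np.zeros_like(x)


def call_significant(
    count_table: TransCountTable,
    threshold: float = DEFAULT_Z_THRESHOLD,
) -> ZScoreResult:
    """Call bins with modified Z strictly above threshold in every replicate.

    Z-scores are computed over the pooled eligible trans bins per replicate.
    Significant bins get an average Z across replicates and the
    log2(average Z + 1) profile value; a single-replicate table is allowed
    (with a warning) and the threshold then applies to it alone.
    """
    n_reps = count_table.n_replicates
    if n_reps == 0:
        raise ValueError("count table has no replicate columns")
    if n_reps == 1:
        logger.warning("single replicate: significance rests on one library")
    tab = count_table.bins.copy()
    eligible = tab["eligible"].to_numpy()
    if not eligible.any():
        raise ValueError("no eligible bins")
    zcols = []
    for k in range(1, n_reps + 1):
        z = np.full(len(tab), np.nan)
        z[eligible] = modified_zscore(tab[f"count_rep{k}"].to_numpy()[eligible])
        tab[f"z_rep{k}"] = z
        zcols.append(f"z_rep{k}")
    zmat = tab[zcols].to_numpy()
    significant = eligible & np.all(zmat > threshold, axis=1)
    avg_z = np.full(len(tab), np.nan)
    avg_z[significant] = zmat[significant].mean(axis=1)
    tab["significant"] = significant
    tab["avg_z"] = avg_z
    tab["log2_avg_z1"] = np.where(significant, np.log2(avg_z + 1.0), 0.0)
    return ZScoreResult(tab, threshold)


def overlap_sets(hit_sets: Mapping[str, set]) -> pd.DataFrame:
    """Pairwise and k-way intersection counts over significant-bin sets.

    All sets must use identical binning (bin identifiers are compared as
    opaque keys, so mixing bin sizes is the caller's error guarded upstream).
    Returns a tidy table with one row per non-empty combination of set names.
    """
    names = list(hit_sets)
    rows = []
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(set(hit_sets[n]) for n in combo))
            rows.append({"sets": "&".join(combo), "degree": r, "count": len(inter)})
    return pd.DataFrame(rows)


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int | None = None,
    cut_height: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchically cluster log2(avgZ+1) profiles (rows = samples).

    Euclidean distance and complete linkage; missing bins must be imputed
    as 0 by the caller (columns are the union of bins). Returns the linkage
    matrix and flat labels (all 1s if no k/cut given).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    X = profiles.fillna(0.0).to_numpy(dtype=float)
    Z = linkage(pdist(X, metric="euclidean"), method="complete")
    if cut_height is not None:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    elif k is not None:
        labels = fcluster(Z, t=k, criterion="maxclust")
    else:
        labels = np.ones(len(profiles), dtype=int)
    return Z, labels
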