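"""Binned Hi-C contact matrices: construction, balancing, distance correction.

A locus of interest (for the mouse Igh model region, chr12:113,090,000-
116,170,000 at 20-kb resolution) is divided into fixed, non-overlapping bins
and ligation-pair records are accumulated into a symmetric count matrix.
Coverage biases are removed by iterative proportional fitting ("iterative
correction" / ICE balancing) and, optionally, the genomic-distance decay is
divided out to give an observed-over-expected map.

Bins with too little coverage (the "white lines" of a Capture Hi-C heatmap)
are masked: their rows and columns are zeroed and excluded from every
downstream computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContactPair",
    "BinningScheme",
    "ContactMatrix",
    "bin_contacts",
    "mask_low_coverage",
    "ice_balance",
    "distance_correct",
    "read_pairs_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

PAIR_COLUMNS = ("chrom_a", "pos_a", "chrom_b", "pos_b")


@dataclass(frozen=True)
class ContactPair:
    """One ligation event: two genomic ends, 1-based positions."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int

    def __post_init__(self) -> None:
        if not self.chrom_a or not self.chrom_b:
            raise ValueError("chromosome names must be non-empty")
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError("positions are 1-based and must be >= 1")


@dataclass(frozen=True)
class BinningScheme:
    """Fixed-grid binning of a half-open, 0-based genomic region.

    The trailing partial bin (when the region length is not a multiple of
    ``bin_size``) is kept as a bin of its own.
    """

    chrom: str
    start: int
    end: int
    bin_size: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region: [{self.start}, {self.end})")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_bins(self) -> int:
        return -((self.start - self.end) // self.bin_size)  # ceil division

    def bin_of(self, pos_1based: int) -> int | None:
        """Bin index of a 1-based position, or None if outside the region."""
        p = pos_1based - 1  # to 0-based
        if p < self.start or p >= self.end:
            return None
        return (p - self.start) // self.bin_size

    def bin_labels(self) -> list[str]:
        out = []
        for i in range(self.n_bins):
            lo = self.start + i * self.bin_size
            hi = min(lo + self.bin_size, self.end)
            out.append(f"{self.chrom}:{lo}-{hi}")
        return out


@dataclass
class ContactMatrix:
    """Symmetric binned interaction matrix with a per-bin validity mask."""

    values: np.ndarray
    mask: np.ndarray  # True = valid bin
    scheme: BinningScheme
    normalization_state: str = "raw"  # raw | balanced | distance_corrected

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.scheme.n_bins
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match scheme ({n} bins)"
            )
        if self.mask.shape != (n,):
            raise ValueError("mask length does not match bin count")
        if not np.allclose(self.values, self.values.T, atol=1e-8, rtol=1e-8):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.scheme.n_bins

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.values.copy(), self.mask.copy(), self.scheme, self.normalization_state
        )


def _apply_mask(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    values = values.copy()
    values[~mask, :] = 0.0
    values[:, ~mask] = 0.0
    return values


def bin_contacts(
    pairs: Iterable[ContactPair | tuple], scheme: BinningScheme
) -> ContactMatrix:
    """Accumulate pair records into a raw symmetric count matrix.

    A pair is counted only if both ends fall inside the scheme's region
    (matching chromosome and coordinates); each accepted pair increments one
    (i, j) entry and its mirror, so the upper triangle including the diagonal
    sums to the number of accepted pairs.
    """
    n = scheme.n_bins
    values = np.zeros((n, n), dtype=float)
    for lineno, rec in enumerate(pairs, start=1):
        if not isinstance(rec, ContactPair):
            try:
                rec = ContactPair(str(rec[0]), int(rec[1]), str(rec[2]), int(rec[3]))
            except (ValueError, TypeError, IndexError) as exc:
                raise ValueError(f"malformed pair record at line {lineno}: {rec!r}") from exc
        if rec.chrom_a != scheme.chrom or rec.chrom_b != scheme.chrom:
            continue
        i = scheme.bin_of(rec.pos_a)
        j = scheme.bin_of(rec.pos_b)
        if i is None or j is None:
            continue
        values[i, j] += 1.0
        if i != j:
            values[j, i] += 1.0
    return ContactMatrix(values, np.ones(n, dtype=bool), scheme, "raw")


def mask_low_coverage(matrix: ContactMatrix, min_fraction: float = 0.2) -> ContactMatrix:
    """Mask bins whose marginal is below ``min_fraction`` x median positive marginal.

    The masked matrix has the offending rows and columns zeroed; masking
    every bin is an error (the matrix would carry no information).
    """
    marginals = matrix.values.sum(axis=1)
    positive = marginals[marginals > 0]
    if positive.size == 0:
        raise ValueError("matrix has no coverage at all; cannot mask")
    threshold = min_fraction * np.median(positive)
    mask = matrix.mask & (marginals >= threshold) & (marginals > 0)
    if not mask.any():
        raise ValueError("low-coverage filter masked every bin")
    values = _apply_mask(matrix.values, mask)
    return ContactMatrix(values, mask, matrix.scheme, matrix.normalization_state)


def ice_balance(
    matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-6
) -> ContactMatrix:
    """Iterative correction (matrix balancing) of a masked raw matrix.

    Iterative proportional fitting with per-sweep symmetrization: each sweep
    divides rows and columns by the square root of their relative marginal,
    until unmasked marginals agree to relative ``tol``. Total matrix mass is
    rescaled to the input mass so balancing only redistributes counts.
    """
    mask = matrix.mask
    if not mask.any():
        raise ValueError("cannot balance a fully masked matrix")
    values = _apply_mask(matrix.values, mask)
    total = values.sum()
    if total == 0:
        raise ValueError("cannot balance an all-zero matrix")
    work = values.copy()
    residual = np.inf
    for _ in range(max_iter):
        marg = work.sum(axis=1)
        live = mask & (marg > 0)
        if not live.any():
            raise ValueError("balancing degenerated: all marginals zero")
        mean = marg[live].mean()
        scale = np.ones_like(marg)
        scale[live] = np.sqrt(marg[live] / mean)
        work = work / np.outer(scale, scale)
        work[~mask, :] = 0.0
        work[:, ~mask] = 0.0
        marg = work.sum(axis=1)[live]
        residual = (marg.max() - marg.min()) / marg.mean()
        if residual <= tol:
            break
    else:
        raise RuntimeError(
            f"iterative correction did not converge in {max_iter} sweeps "
            f"(residual {residual:.3e} > tol {tol:.3e})"
        )
    work *= total / work.sum()
    work = (work + work.T) / 2.0  # remove numerical asymmetry
    return ContactMatrix(work, mask.copy(), matrix.scheme, "balanced")


def distance_correct(matrix: ContactMatrix) -> ContactMatrix:
    """Divide each entry by the mean unmasked entry at the same |i - j|.

    Produces the observed-over-expected map. Diagonals whose expected value
    is zero cannot be corrected: those entries are left at zero (they carry
    no unmasked signal anyway).
    """
    n = matrix.n_bins
    mask = matrix.mask
    values = matrix.values.copy()
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    valid2d = np.outer(mask, mask)
    out = np.zeros_like(values)
    for d in range(n):
        sel = (sep == d) & valid2d
        if not sel.any():
            continue
        expected = values[sel].mean()
        if expected > 0:
            out[sel] = values[sel] / expected
        # expected == 0: whole diagonal carries no signal; leave zeros
    return ContactMatrix(out, mask.copy(), matrix.scheme, "distance_corrected")


# ---------------------------------------------------------------------------
# I/O

def read_pairs_tsv(path) -> list[ContactPair]:
    """Read pair records from TSV (chrom_a, pos_a, chrom_b, pos_b; '#' comments)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=list(PAIR_COLUMNS),
        dtype={"chrom_a": str, "chrom_b": str},
    )
    return [
        ContactPair(r.chrom_a, int(r.pos_a), r.chrom_b, int(r.pos_b))
        for r in df.itertuples(index=False)
    ]


def write_matrix_tsv(matrix: ContactMatrix, path, mask_path=None) -> None:
    labels = matrix.scheme.bin_labels()
    df = pd.DataFrame(matrix.values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.10g")
    if mask_path is not None:
        pd.DataFrame({"bin": labels, "valid": matrix.mask.astype(int)}).to_csv(
            mask_path, sep="\t", index=False
        )


def _parse_bin_label(label: str) -> tuple[str, int, int]:
    chrom, span = label.rsplit(":", 1)
    lo, hi = span.split("-")
    return chrom, int(lo), int(hi)


def read_matrix_tsv(path, mask_path=None, normalization_state: str = "raw") -> ContactMatrix:
    """Read a dense labeled matrix TSV (labels "chrom:start-end") back."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = list(df.index)
    chrom, start, first_hi = _parse_bin_label(labels[0])
    _, _, end = _parse_bin_label(labels[-1])
    scheme = BinningScheme(chrom, start, end, first_hi - start)
    mask = np.ones(len(labels), dtype=bool)
    if mask_path is not None:
        mdf = pd.read_csv(mask_path, sep="\t")
        mask = mdf["valid"].to_numpy().astype(bool)
    return ContactMatrix(df.to_numpy(dtype=float), mask, scheme, normalization_state)
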