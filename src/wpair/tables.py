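"""2 x k genotype-combination contingency tables for pairs of diallelic loci.

For two SNPs with dosage coding 0/1/2 (count of the minor allele, dosage 0 =
homozygous for allele 1) there are nine possible genotype combinations.  A
case/control sample is summarised by a 2 x 9 table of counts: row 0 holds the
control counts ``n0i``, row 1 the case counts ``n1i``, with columns in
lexicographic order (SNP1 genotype outer, SNP2 genotype inner)::

    1/1x1/1, 1/1x1/2, 1/1x2/2, 1/2x1/1, 1/2x1/2, 1/2x2/2,
    2/2x1/1, 2/2x1/2, 2/2x2/2

Sparse data produce empty cells; the two reduction rules used by downstream
tests (drop columns empty in *both* rows, or empty in *either* row) are
implemented by :func:`observed_columns`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "N_CATEGORIES",
    "GENOTYPE_PAIR_LABELS",
    "PairTable",
    "ReducedTable",
    "EmptyReductionError",
    "build_table",
    "observed_columns",
]

N_CATEGORIES = 9

_GENO_LABEL = {0: "1/1", 1: "1/2", 2: "2/2"}

#: Column labels in table order: index 3*u + v for dosages (u, v).
GENOTYPE_PAIR_LABELS = tuple(
    f"{_GENO_LABEL[u]}x{_GENO_LABEL[v]}" for u in range(3) for v in range(3)
)


class EmptyReductionError(ValueError):
    """Raised when a reduction retains no usable genotype category."""


@dataclass(frozen=True)
class PairTable:
    """2 x 9 contingency table of genotype-combination counts.

    Attributes
    ----------
    counts
        Integer array of shape (2, 9); row 0 = controls, row 1 = cases.
    """

    counts: np.ndarray
    column_labels: tuple = GENOTYPE_PAIR_LABELS

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (2, N_CATEGORIES):
            raise ValueError(f"counts must be 2x{N_CATEGORIES}, got {counts.shape}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)) or np.any(counts < 0):
                raise ValueError("counts must be non-negative integers")
            counts = np.round(counts).astype(np.int64)
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))

    @property
    def n0(self) -> int:
        """Number of controls (row-0 total)."""
        return int(self.counts[0].sum())

    @property
    def n1(self) -> int:
        """Number of cases (row-1 total)."""
        return int(self.counts[1].sum())

    @property
    def n(self) -> int:
        return self.n0 + self.n1

    def swap_snps(self) -> "PairTable":
        """Exchange the roles of SNP1 and SNP2 (transpose the 3x3 grid)."""
        perm = [3 * v + u for u in range(3) for v in range(3)]
        # perm[3u+v] = 3v+u: column (u, v) receives old column (v, u)
        return PairTable(self.counts[:, perm])

    def swap_rows(self) -> "PairTable":
        """Exchange the case and control rows."""
        return PairTable(self.counts[::-1].copy())


@dataclass(frozen=True)
class ReducedTable:
    """A 2 x k table restricted to retained genotype categories."""

    counts: np.ndarray
    columns: np.ndarray  # original column indices, ascending
    n0: int
    n1: int

    @property
    def k(self) -> int:
        return self.counts.shape[1]


def _clean_genotypes(g, name: str) -> np.ndarray:
    g = np.asarray(g, dtype=float).ravel()
    missing = np.isnan(g) | (g < 0)
    valid = g[~missing]
    if valid.size and not np.isin(valid, (0.0, 1.0, 2.0)).all():
        raise ValueError(f"{name} contains values outside {{0, 1, 2, missing}}")
    return np.where(missing, np.nan, g)


def build_table(geno1, geno2, phenotype) -> PairTable:
    """Tabulate a SNP pair into a 2 x 9 case/control contingency table.

    Parameters
    ----------
    geno1, geno2
        Dosage vectors in {0, 1, 2}; NaN or negative values are missing.
    phenotype
        Binary vector, control = 0 / case = 1; NaN or negative = missing.

    Individuals missing either genotype or the phenotype are excluded
    (complete-case per pair).
    """
    g1 = _clean_genotypes(geno1, "geno1")
    g2 = _clean_genotypes(geno2, "geno2")
    ph = np.asarray(phenotype, dtype=float).ravel()
    if not (g1.size == g2.size == ph.size):
        raise ValueError(
            f"length mismatch: geno1={g1.size}, geno2={g2.size}, phenotype={ph.size}"
        )
    ph_missing = np.isnan(ph) | (ph < 0)
    ph_valid = ph[~ph_missing]
    if ph_valid.size and not np.isin(ph_valid, (0.0, 1.0)).all():
        raise ValueError("phenotype contains values outside {0, 1, missing}")

    keep = ~(np.isnan(g1) | np.isnan(g2) | ph_missing)
    if not keep.any():
        raise ValueError("no complete records")
    cat = (3 * g1[keep] + g2[keep]).astype(np.int64)
    row = ph[keep].astype(np.int64)
    counts = np.bincount(row * N_CATEGORIES + cat, minlength=2 * N_CATEGORIES)
    return PairTable(counts.reshape(2, N_CATEGORIES))


def observed_columns(table: PairTable, mode: str = "any_row_zero") -> ReducedTable:
    """Drop unusable genotype-category columns.

    Parameters
    ----------
    table
        Full 2 x 9 table.
    mode
        ``"both_rows_zero"`` drops columns whose total count is zero (the
        convention of the reduced chi-squared test).  ``"any_row_zero"``
        additionally drops columns empty in either row, or where one row's
        count equals its total (the complement count is zero) — exactly the
        cells where the per-category log-odds standard error is undefined.

    Returns
    -------
    ReducedTable
        Retained columns in original order.

    Raises
    ------
    EmptyReductionError
        If no column survives the reduction.
    """
    c = table.counts
    totals = c.sum(axis=0)
    if mode == "both_rows_zero":
        keep = totals > 0
    elif mode == "any_row_zero":
        n0, n1 = table.n0, table.n1
        keep = (c[0] > 0) & (c[1] > 0) & (c[0] < n0) & (c[1] < n1)
    else:
        raise ValueError(f"unknown reduction mode: {mode!r}")
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise EmptyReductionError(f"empty reduction (mode={mode})")
    return ReducedTable(
        counts=c[:, idx].copy(), columns=idx, n0=table.n0, n1=table.n1
    )
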