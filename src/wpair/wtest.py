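"""The W-test: a scaled chi-squared statistic over per-category log odds ratios.

For each observed genotype combination ``i`` the case and control proportions
``p1_i = n1i/N1`` and ``p0_i = n0i/N0`` give a normalized log odds ratio

    z_i = log[ (p1_i/(1-p1_i)) / (p0_i/(1-p0_i)) ] / SE_i,
    SE_i = sqrt(1/n0i + 1/n1i + 1/(N0-n0i) + 1/(N1-n1i)).

The k retained z_i are dependent (the cells of a multinomial sum to the group
totals), so their combination

    W = h * sum_i z_i**2

is referred to a chi-squared distribution with possibly non-integer degrees of
freedom f.  Defaults are h = (k-1)/k and f = k-1; alternatively (h, f) are
estimated per category-count k by a null-permutation bootstrap over many SNP
pairs, moment-matching the scaled chi-squared mean and variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .assoc import TestResult
from .tables import EmptyReductionError, PairTable, ReducedTable, observed_columns

__all__ = [
    "CellStats",
    "HFParams",
    "cell_stats",
    "w_statistic",
    "default_hf",
    "bootstrap_hf",
    "w_test",
    "multinomial_covariance",
    "write_hf_table",
    "read_hf_table",
]


@dataclass(frozen=True)
class CellStats:
    """Per-category proportions, SEs and normalized log odds ratios."""

    phat1: np.ndarray
    phat0: np.ndarray
    se: np.ndarray
    z: np.ndarray

    @property
    def k(self) -> int:
        return self.z.size


@dataclass(frozen=True)
class HFParams:
    """Scale h and degrees of freedom f of the W reference distribution.

    ``k`` is the observed-category count this pair of values applies to;
    ``source`` records whether they are the defaults ((k-1)/k, k-1), a
    bootstrap estimate, or externally supplied fixed values.
    """

    h: float
    f: float
    k: int
    source: str = "default"

    def __post_init__(self):
        if not (self.h > 0 and self.f > 0):
            raise ValueError("h and f must be positive")


def default_hf(k: int) -> HFParams:
    """Default parameters h = (k-1)/k, f = k-1 for k >= 2 categories."""
    if k < 2:
        raise ValueError(f"need at least 2 categories, got k={k}")
    return HFParams(h=(k - 1) / k, f=float(k - 1), k=k, source="default")


def cell_stats(reduced: ReducedTable) -> CellStats:
    """Normalized log odds ratios for a table reduced by ``any_row_zero``.

    Every retained cell must satisfy 0 < n_ji < N_j in both rows, so all
    standard errors are finite and positive.
    """
    n0i = reduced.counts[0].astype(float)
    n1i = reduced.counts[1].astype(float)
    n0, n1 = float(reduced.n0), float(reduced.n1)
    if np.any(n0i <= 0) or np.any(n1i <= 0) or np.any(n0i >= n0) or np.any(n1i >= n1):
        raise ValueError("cell_stats requires 0 < n_ji < N_j in every retained cell")
    phat0 = n0i / n0
    phat1 = n1i / n1
    se = np.sqrt(1 / n0i + 1 / n1i + 1 / (n0 - n0i) + 1 / (n1 - n1i))
    logor = np.log(phat1 / (1 - phat1)) - np.log(phat0 / (1 - phat0))
    return CellStats(phat1=phat1, phat0=phat0, se=se, z=logor / se)


def w_statistic(cells: CellStats, hf: HFParams) -> TestResult:
    """Combine cell z-scores into W = h * sum(z^2) ~ chi-squared_f.

    The upper-tail probability is evaluated through the regularized upper
    incomplete gamma function, valid for non-integer f.
    """
    if hf.k != cells.k:
        raise ValueError(f"hf is for k={hf.k} but cells have k={cells.k}")
    stat = float(hf.h * np.sum(cells.z**2))
    p = float(special.gammaincc(hf.f / 2.0, stat / 2.0))
    return TestResult("W", stat, hf.f, p, True, note=f"h={hf.h:.6g}, k={hf.k}")


def w_test(table: PairTable, hf_table: dict | None = None) -> TestResult:
    """W-test on a full 2 x 9 table.

    Reduces the table to the k categories observed in both rows, then applies
    ``w_statistic`` with parameters looked up by k: from ``hf_table`` (a
    mapping k -> HFParams, e.g. a bootstrap estimate) when given, otherwise
    the defaults h=(k-1)/k, f=k-1.
    """
    try:
        reduced = observed_columns(table, "any_row_zero")
    except EmptyReductionError:
        return TestResult.undefined("W", "empty reduction")
    if reduced.k < 2:
        return TestResult.undefined("W", "fewer than 2 informative categories")
    cells = cell_stats(reduced)
    hf = hf_table.get(reduced.k) if hf_table else None
    if hf is None:
        hf = default_hf(reduced.k)
    return w_statistic(cells, hf)


# ---------------------------------------------------------------------------
# Bootstrap estimation of (h, f)


def _pair_s_and_k(counts18: np.ndarray, n0: int, n1: int):
    """(sum of z^2, k) for one 2 x 9 count table; None when k < 2."""
    c0, c1 = counts18[:9].astype(float), counts18[9:].astype(float)
    keep = (c0 > 0) & (c1 > 0) & (c0 < n0) & (c1 < n1)
    k = int(keep.sum())
    if k < 2:
        return None
    a0, a1 = c0[keep], c1[keep]
    se2 = 1 / a0 + 1 / a1 + 1 / (n0 - a0) + 1 / (n1 - a1)
    logor = np.log(a1 / (n1 - a1)) - np.log(a0 / (n0 - a0))
    return float(np.sum(logor**2 / se2)), k


def bootstrap_hf(
    genotypes,
    n_cases: int,
    B: int = 200,
    n_pairs: int = 1000,
    n_individuals: int = 1000,
    seed: int | None = None,
) -> dict:
    """Estimate (h, f) per observed-category count k by a null bootstrap.

    Each of ``B`` replicates samples ``N_B = min(n_individuals, N)``
    individuals and ``P_B = min(n_pairs, M*(M-1)/2)`` SNP pairs without
    replacement, assigns phenotypes by permuting labels with ``n_cases`` cases
    (independent of genotype, i.e. under the null), and records
    ``S = sum(z^2)`` together with k for every sampled pair.  Pooled values
    are moment-matched per k: since h*S ~ chi2_f implies E[S] = f/h and
    Var[S] = 2f/h^2,

        h_k = 2*mean(S)/var(S),   f_k = 2*mean(S)^2/var(S).

    k values with fewer than two pooled statistics fall back to the defaults.

    Parameters
    ----------
    genotypes
        N x M dosage matrix (NaN = missing).
    n_cases
        Number of case labels in the permuted phenotype.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2:
        raise ValueError("genotypes must be an N x M matrix")
    n, m = g.shape
    if m < 2:
        raise ValueError("need at least 2 SNPs for pairwise bootstrap")
    if n < 4 or n_cases < 2 or n - n_cases < 2:
        raise ValueError("need at least 2 cases and 2 controls among >= 4 individuals")

    rng = np.random.default_rng(seed)
    nb = min(n_individuals, n)
    iu, ju = np.triu_indices(m, 1)
    n_all_pairs = iu.size
    pb = min(n_pairs, n_all_pairs)
    labels = np.zeros(n, dtype=np.int64)
    labels[:n_cases] = 1

    pooled: dict[int, list] = {}
    for _ in range(B):
        idx = (
            np.arange(n) if nb == n else rng.choice(n, size=nb, replace=False)
        )
        pheno = rng.permutation(labels)[idx]
        pairs = (
            np.arange(n_all_pairs)
            if pb == n_all_pairs
            else rng.choice(n_all_pairs, size=pb, replace=False)
        )
        gsub = g[idx]
        for pidx in pairs:
            g1 = gsub[:, iu[pidx]]
            g2 = gsub[:, ju[pidx]]
            ok = ~(np.isnan(g1) | np.isnan(g2))
            if not ok.any():
                continue
            cat = (3 * g1[ok] + g2[ok]).astype(np.int64)
            counts = np.bincount(pheno[ok] * 9 + cat, minlength=18)
            n0 = int(counts[:9].sum())
            n1 = int(counts[9:].sum())
            if n0 == 0 or n1 == 0:
                continue
            sk = _pair_s_and_k(counts, n0, n1)
            if sk is not None:
                pooled.setdefault(sk[1], []).append(sk[0])

    if not pooled:
        raise RuntimeError("no SNP pair yielded a computable statistic in any replicate")

    out = {}
    for k in range(2, 10):
        vals = np.asarray(pooled.get(k, []), dtype=float)
        if vals.size >= 2 and vals.var(ddof=1) > 0:
            mean, var = vals.mean(), vals.var(ddof=1)
            out[k] = HFParams(
                h=2 * mean / var, f=2 * mean**2 / var, k=k, source="bootstrap"
            )
        else:
            out[k] = default_hf(k)
    return out


# ---------------------------------------------------------------------------
# Theory helper and (h, f) persistence


def multinomial_covariance(probs, n: int) -> np.ndarray:
    """Asymptotic covariance [Diag(pi) - pi pi^T]/N of multinomial proportions."""
    pi = np.asarray(probs, dtype=float).ravel()
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("probs must be non-negative and sum to 1")
    if n < 1:
        raise ValueError("N must be >= 1")
    return (np.diag(pi) - np.outer(pi, pi)) / n


def write_hf_table(hf_table: dict, path) -> None:
    """Write a k -> (h, f) mapping as plain text: ``k h f source`` per line."""
    with open(path, "w") as fh:
        fh.write("# k\th\tf\tsource\n")
        for k in sorted(hf_table):
            p = hf_table[k]
            fh.write(f"{k}\t{float(p.h):.17g}\t{float(p.f):.17g}\t{p.source}\n")


def read_hf_table(path) -> dict:
    """Read a mapping written by :func:`write_hf_table`."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, h, f, source = line.split("\t")
            out[int(k)] = HFParams(h=float(h), f=float(f), k=int(k), source=source)
    return out
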