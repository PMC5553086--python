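"""Comparator association tests for a SNP pair.

Two Pearson chi-squared conventions and four logistic-regression
likelihood-ratio tests (LRTs), all operating on the 2 x 9 genotype-combination
table:

* ``CHI-f`` — Pearson chi-squared on the *full* 2 x 9 table (8 df).  Undefined
  whenever any genotype category is unobserved, because an expected count of
  zero makes the statistic incomputable.
* ``CHI-r`` — Pearson chi-squared after removing categories unobserved in the
  whole sample, on k'-1 df.
* ``LR8`` — saturated genotypic logistic regression (one log-odds parameter per
  genotype combination) against an intercept-only null; 8 df when all nine
  categories are observed, fewer when categories are structurally absent.
* ``LR3`` — allelic (dosage-coded) model a + b*x1 + g*x2 + i*x1*x2 against the
  intercept-only null; 3 df.
* ``LR1`` — the same alternative against the main-effects model; a 1-df test of
  pure interaction under the allelic model.
* ``LRI`` — interaction term only against the intercept; 1 df.

All tests are computed from the contingency table via a weighted logistic fit
(18 covariate-pattern rows with the cell counts as prior weights), which is
likelihood-equivalent to the individual-level fit.  No continuity correction is
applied anywhere, including tables that reduce to 2 x 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, special, stats

from .tables import N_CATEGORIES, PairTable

__all__ = [
    "TestResult",
    "LogisticSpec",
    "LogisticFit",
    "LR_SPECS",
    "chisq_full",
    "chisq_reduced",
    "fit_logistic",
    "lr_test",
    "lr_suite",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one association test on one SNP pair.

    ``defined=False`` encodes the 'NA' state (e.g. a chi-squared test on a
    table with an empty category); ``statistic``, ``df`` and ``p_value`` are
    then NaN and ``note`` carries the reason.
    """

    test_name: str
    statistic: float
    df: float
    p_value: float
    defined: bool
    note: str = ""

    @classmethod
    def undefined(cls, test_name: str, note: str) -> "TestResult":
        return cls(test_name, np.nan, np.nan, np.nan, False, note)

    def significant(self, alpha: float) -> bool:
        return bool(self.defined and self.p_value <= alpha)


@dataclass(frozen=True)
class LogisticSpec:
    """Alternative/null term lists defining one likelihood-ratio test.

    Terms are drawn from {"1", "x1", "x2", "x1:x2"} for allelic dosage coding
    or {"1", "geno"} where "geno" expands to the eight genotypic indicator and
    interaction columns of the saturated model.
    """

    name: str
    alt_terms: tuple
    null_terms: tuple
    coding: str  # "genotypic_indicators" | "allelic_dosage"

    def __post_init__(self):
        if not set(self.null_terms) <= set(self.alt_terms):
            raise ValueError(f"{self.name}: null terms must nest within alt terms")


LR_SPECS = {
    "LR8": LogisticSpec("LR8", ("1", "geno"), ("1",), "genotypic_indicators"),
    "LR3": LogisticSpec("LR3", ("1", "x1", "x2", "x1:x2"), ("1",), "allelic_dosage"),
    "LR1": LogisticSpec(
        "LR1", ("1", "x1", "x2", "x1:x2"), ("1", "x1", "x2"), "allelic_dosage"
    ),
    "LRI": LogisticSpec("LRI", ("1", "x1:x2"), ("1",), "allelic_dosage"),
}


# ---------------------------------------------------------------------------
# Pearson chi-squared


def _pearson(counts: np.ndarray, df: int, name: str) -> TestResult:
    """Pearson X^2 with fixed df; undefined on any zero expected count."""
    try:
        res = stats.chi2_contingency(counts, correction=False)
    except ValueError:
        # zero row or column margin => zero expected count
        return TestResult.undefined(name, "zero expected count")
    assert res.dof == df
    return TestResult(name, float(res.statistic), float(df), float(res.pvalue), True)


def chisq_full(table: PairTable) -> TestResult:
    """Pearson chi-squared on the full 2 x 9 table (CHI-f), 8 df.

    Returns an undefined result if any of the nine genotype categories is
    unobserved in the sample (or a row total is zero).
    """
    return _pearson(table.counts.astype(float), N_CATEGORIES - 1, "CHI-f")


def chisq_reduced(table: PairTable) -> TestResult:
    """Pearson chi-squared dropping unobserved categories (CHI-r), k'-1 df."""
    counts = table.counts.astype(float)
    keep = counts.sum(axis=0) > 0
    kprime = int(keep.sum())
    if kprime < 2:
        return TestResult.undefined("CHI-r", "fewer than 2 observed categories")
    return _pearson(counts[:, keep], kprime - 1, "CHI-r")


# ---------------------------------------------------------------------------
# Weighted logistic regression by IRLS

_MAX_ITER = 100
_LL_RTOL = 1e-8
_ETA_SEPARATION = 12.0  # |logit| beyond which a pattern is effectively 0/1


@dataclass
class LogisticFit:
    """Maximum-likelihood weighted logistic fit.

    ``rank`` counts the estimable parameters after aliased columns were
    dropped; ``dropped`` lists the indices of the removed design columns.
    ``separated`` flags fits that hit the iteration cap with diverging
    coefficients (the log-likelihood is still valid at its boundary limit).
    """

    loglik: float
    beta: np.ndarray  # full-length, NaN for dropped columns
    rank: int
    dropped: np.ndarray
    cov: np.ndarray  # covariance of the estimable coefficients
    converged: bool
    separated: bool
    n_iter: int


def _estimable_columns(x: np.ndarray, w: np.ndarray):
    """Indices of a maximal linearly independent column subset (weighted)."""
    xw = x[w > 0]
    if xw.shape[0] == 0:
        return np.array([], dtype=int)
    _, _, piv = linalg.qr(xw, mode="economic", pivoting=True)
    r = np.linalg.matrix_rank(xw)
    return np.sort(piv[:r])


def fit_logistic(design, response, weights=None) -> LogisticFit:
    """Fit a binomial logit model by iteratively reweighted least squares.

    Parameters
    ----------
    design
        n x p matrix of covariates.
    response
        Binary outcome per row (0 = control, 1 = case).
    weights
        Optional non-negative prior weights (e.g. covariate-pattern counts);
        default 1.  Zero-weight rows are ignored.

    Rank-deficient designs are reduced to an estimable column basis before
    fitting (dropped columns get NaN coefficients).  Perfectly separated
    patterns drive coefficients towards infinity; the iteration cap returns
    the boundary log-likelihood with ``separated=True``.
    """
    x = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("design rows must match response length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float).ravel()
    if w.size != y.size or np.any(w < 0):
        raise ValueError("weights must be non-negative, one per row")

    cols = _estimable_columns(x, w)
    dropped = np.setdiff1d(np.arange(x.shape[1]), cols)
    xr = x[:, cols]
    p = xr.shape[1]

    beta = np.zeros(p)
    if p:
        # start from the intercept-only fit when an intercept column exists
        const = np.flatnonzero((xr == 1).all(axis=0))
        if const.size and w.sum() > 0:
            ybar = np.clip(float(np.average(y, weights=w)), 1e-12, 1 - 1e-12)
            beta[const[0]] = special.logit(ybar)
    eta = xr @ beta if p else np.zeros_like(y)
    mu = special.expit(eta)

    def _ll(mu):
        mu = np.clip(mu, 1e-300, 1 - 1e-16)
        return float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log1p(-mu))))

    ll = _ll(mu)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        if p == 0:
            converged = True
            break
        v = np.clip(mu * (1 - mu), 1e-10, None)
        wk = w * v
        z = eta + (y - mu) / v
        sw = np.sqrt(wk)
        beta_new, *_ = np.linalg.lstsq(sw[:, None] * xr, sw * z, rcond=None)
        eta = xr @ beta_new
        mu = special.expit(np.clip(eta, -700, 700))
        ll_new = _ll(mu)
        beta = beta_new
        if abs(ll_new - ll) <= _LL_RTOL * (abs(ll_new) + 1e-10):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    separated = (not converged) and bool(
        np.any(np.abs(eta[w > 0]) > _ETA_SEPARATION)
    )

    if p:
        v = np.clip(mu * (1 - mu), 1e-10, None)
        info = (xr * (w * v)[:, None]).T @ xr
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
    else:
        cov = np.zeros((0, 0))

    beta_full = np.full(x.shape[1], np.nan)
    beta_full[cols] = beta
    return LogisticFit(
        loglik=ll,
        beta=beta_full,
        rank=p,
        dropped=dropped,
        cov=cov,
        converged=converged,
        separated=separated,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# Design construction over the 9 genotype combinations


def _category_covariates():
    """Dosage pairs (x1, x2) for the 9 table columns in canonical order."""
    u = np.repeat(np.arange(3), 3).astype(float)
    v = np.tile(np.arange(3), 3).astype(float)
    return u, v


def _design_for_terms(terms, coding: str) -> np.ndarray:
    """9 x p design matrix over the genotype-combination categories."""
    u, v = _category_covariates()
    cols = []
    for t in terms:
        if t == "1":
            cols.append(np.ones(N_CATEGORIES))
        elif t == "geno":
            if coding != "genotypic_indicators":
                raise ValueError("'geno' term requires genotypic_indicators coding")
            for a in (1, 2):
                cols.append((u == a).astype(float))
            for b in (1, 2):
                cols.append((v == b).astype(float))
            for a in (1, 2):
                for b in (1, 2):
                    cols.append(((u == a) & (v == b)).astype(float))
        elif t == "x1":
            cols.append(u)
        elif t == "x2":
            cols.append(v)
        elif t == "x1:x2":
            cols.append(u * v)
        else:
            raise ValueError(f"unknown model term: {t!r}")
    return np.column_stack(cols)


def _table_rows(table: PairTable):
    """Expand the table into 18 weighted covariate-pattern rows."""
    y = np.concatenate([np.zeros(N_CATEGORIES), np.ones(N_CATEGORIES)])
    w = np.concatenate([table.counts[0], table.counts[1]]).astype(float)
    return y, w


def _fit_terms(table: PairTable, terms, coding: str) -> LogisticFit:
    base = _design_for_terms(terms, coding)
    x = np.vstack([base, base])
    y, w = _table_rows(table)
    return fit_logistic(x, y, w)


def lr_test(table: PairTable, spec: LogisticSpec) -> TestResult:
    """Likelihood-ratio test comparing the spec's nested logistic models.

    The statistic is 2*(l_alt - l_null); df is the difference in estimable
    parameter counts after rank reduction; undefined when that difference is
    zero or the phenotype is degenerate.
    """
    if table.n0 == 0 or table.n1 == 0:
        return TestResult.undefined(spec.name, "degenerate phenotype")
    alt = _fit_terms(table, spec.alt_terms, spec.coding)
    null = _fit_terms(table, spec.null_terms, spec.coding)
    df = alt.rank - null.rank
    if df <= 0:
        return TestResult.undefined(spec.name, "no estimable alternative parameters")
    stat = max(2.0 * (alt.loglik - null.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df))
    note = "separation: boundary likelihood" if alt.separated else ""
    return TestResult(spec.name, stat, float(df), p, True, note)


def lr_suite(table: PairTable, which=("LR8", "LR3", "LR1", "LRI")) -> dict:
    """Evaluate several LR tests on one table, sharing nested-model fits."""
    if table.n0 == 0 or table.n1 == 0:
        return {
            name: TestResult.undefined(name, "degenerate phenotype") for name in which
        }
    cache: dict = {}

    def fit(terms, coding):
        key = (terms, coding)
        if key not in cache:
            cache[key] = _fit_terms(table, terms, coding)
        return cache[key]

    out = {}
    for name in which:
        spec = LR_SPECS[name]
        alt = fit(spec.alt_terms, spec.coding)
        null = fit(spec.null_terms, spec.coding)
        df = alt.rank - null.rank
        if df <= 0:
            out[name] = TestResult.undefined(name, "no estimable alternative parameters")
            continue
        stat = max(2.0 * (alt.loglik - null.loglik), 0.0)
        p = float(stats.chi2.sf(stat, df))
        note = "separation: boundary likelihood" if alt.separated else ""
        out[name] = TestResult(name, stat, float(df), p, True, note)
    return out
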