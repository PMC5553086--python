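"""Replicate-loop evaluation of type-I error and power, plus scan diagnostics.

Each simulation replicate is tabulated and every selected test is run; the
aggregate reports, per test, how many replicates produced a defined result and
how many were significant at the chosen alpha, under two denominator
conventions:

* ``power_defined`` — significant / defined (undefined results ignored; the
  convention under which a test that rarely evaluates can still look good, or
  be 0/0-undefined altogether);
* ``power_total`` — significant / total replicates (an undefined result counts
  as a non-detection; the "prime" accounting convention).

Under a null scenario the same quantities are read as type-I error.  Q-Q
expected quantiles and the genomic-control inflation factor lambda are
provided for scan-level diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc, wtest
from .simulate import sample_replicate
from .tables import build_table

__all__ = [
    "ALL_TESTS",
    "PowerTable",
    "run_tests_on_table",
    "run_scenario",
    "qq_data",
    "genomic_lambda",
]

#: Canonical test battery. "W" uses default (h, f) = ((k-1)/k, k-1); "W-hf"
#: uses an externally supplied k -> HFParams table (bootstrap or fixed).
ALL_TESTS = ("W", "W-hf", "CHI-f", "CHI-r", "LR8", "LR3", "LR1", "LRI")

_LR_NAMES = ("LR8", "LR3", "LR1", "LRI")


@dataclass
class PowerTable:
    """Per-test rejection accounting over a replicate set."""

    label: str
    alpha: float
    seed: int
    n_replicates: int
    n_defined: dict
    n_significant: dict

    def power_defined(self, test: str) -> float:
        """Significant / defined; NaN when no replicate was defined (0/0)."""
        nd = self.n_defined[test]
        return self.n_significant[test] / nd if nd > 0 else float("nan")

    def power_total(self, test: str) -> float:
        """Significant / total replicates (undefined counts as non-detection)."""
        return self.n_significant[test] / self.n_replicates

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.n_defined:
            rows.append(
                {
                    "test": t,
                    "n_replicates": self.n_replicates,
                    "n_defined": self.n_defined[t],
                    "n_significant": self.n_significant[t],
                    "power_defined": self.power_defined(t),
                    "power_total": self.power_total(t),
                }
            )
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        """Delimited text with a metadata header."""
        with open(path, "w") as fh:
            fh.write(f"# scenario: {self.label}\n")
            fh.write(f"# seed: {self.seed}\n")
            fh.write(f"# alpha: {self.alpha}\n")
            fh.write(f"# replicates: {self.n_replicates}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, na_rep="NA")


def run_tests_on_table(table, tests=ALL_TESTS, hf_table=None) -> dict:
    """Run the selected tests on one 2 x 9 table; never raises per-test."""
    out = {}
    lr_wanted = tuple(t for t in tests if t in _LR_NAMES)
    if lr_wanted:
        out.update(assoc.lr_suite(table, lr_wanted))
    for t in tests:
        if t == "W":
            out[t] = wtest.w_test(table)
        elif t == "W-hf":
            if hf_table is None:
                raise ValueError("test 'W-hf' requires an hf_table")
            r = wtest.w_test(table, hf_table=hf_table)
            out[t] = assoc.TestResult(
                "W-hf", r.statistic, r.df, r.p_value, r.defined, r.note
            )
        elif t == "CHI-f":
            out[t] = assoc.chisq_full(table)
        elif t == "CHI-r":
            out[t] = assoc.chisq_reduced(table)
        elif t in _LR_NAMES:
            pass
        else:
            raise ValueError(f"unknown test {t!r}")
    return out


def run_scenario(
    scenario,
    tests=("W", "CHI-f", "CHI-r", "LR8", "LR3", "LR1", "LRI"),
    alpha: float = 0.05,
    hf_table=None,
    collect_pvalues: bool = False,
):
    """Simulate a scenario and tally defined / significant results per test.

    Returns a :class:`PowerTable`, or ``(PowerTable, {test: p-value array})``
    when ``collect_pvalues`` is set (undefined results as NaN).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n_defined = {t: 0 for t in tests}
    n_significant = {t: 0 for t in tests}
    pvals = {t: np.full(scenario.replicates, np.nan) for t in tests}
    for rep in range(scenario.replicates):
        g1, g2, ph = sample_replicate(scenario, rep)
        table = build_table(g1, g2, ph)
        results = run_tests_on_table(table, tests, hf_table=hf_table)
        for t in tests:
            r = results[t]
            if r.defined:
                n_defined[t] += 1
                pvals[t][rep] = r.p_value
                if r.p_value <= alpha:
                    n_significant[t] += 1
    pt = PowerTable(
        label=scenario.label,
        alpha=alpha,
        seed=scenario.seed,
        n_replicates=scenario.replicates,
        n_defined=n_defined,
        n_significant=n_significant,
    )
    return (pt, pvals) if collect_pvalues else pt


def qq_data(p_values):
    """Expected vs observed -log10 p for a Q-Q plot.

    The i-th smallest of n p-values is paired with the expected quantile
    (i - 0.5)/n; both are returned on the -log10 scale, ascending in p.
    NaN entries (undefined tests) are excluded.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no defined p-values")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    n = obs.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return -np.log10(expected), -np.log10(obs)


_CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # ~0.4549


def genomic_lambda(chisq_1df_stats) -> float:
    """Genomic-control inflation: median statistic / null chi2_1 median."""
    s = np.asarray(chisq_1df_stats, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("need at least one statistic")
    if np.any(s < 0):
        raise ValueError("chi-squared statistics must be non-negative")
    return float(np.median(s) / _CHI2_1DF_MEDIAN)
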