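"""Genotype-panel readers/writers and the pairwise scan driver.

Supported text dialects:

* PLINK ``.ped``/``.map`` — two alleles per SNP per individual, ``0`` =
  missing allele, phenotype column coded 1 = control / 2 = case / 0 or -9 =
  missing.  Alleles are recoded to minor-allele dosage counts on load.
* PLINK ``.raw`` (``--recodeA`` output) — header row then one dosage column
  per SNP, ``NA`` = missing.
* Delimited dosage table — ``sample_id``, ``phenotype`` then one 0/1/2 column
  per SNP (the round-trippable native format).

Dosages are oriented so that they count the less frequent allele in the
loaded panel; on a frequency tie the alphabetically first allele becomes
the reference (dosage 0) where alleles are known.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import build_table
from .wtest import bootstrap_hf
from .benchmark import run_tests_on_table

__all__ = ["GenotypePanel", "read_panel", "write_dosage", "scan_pairs"]


@dataclass
class GenotypePanel:
    """Individual-level dosage data for N samples at M SNPs."""

    dosages: np.ndarray  # N x M float, NaN = missing
    snp_ids: list
    sample_ids: list
    phenotype: np.ndarray | None = None  # length N, 0/1, NaN = missing

    def __post_init__(self):
        d = np.asarray(self.dosages, dtype=float)
        if d.ndim != 2:
            raise ValueError("dosages must be an N x M matrix")
        n, m = d.shape
        if len(self.snp_ids) != m or len(self.sample_ids) != n:
            raise ValueError("id lists inconsistent with dosage dimensions")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp_ids must be unique")
        self.dosages = d
        if self.phenotype is not None:
            ph = np.asarray(self.phenotype, dtype=float).ravel()
            if ph.size != n:
                raise ValueError("phenotype length mismatch")
            self.phenotype = ph

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def orient_to_minor(self) -> None:
        """Flip any SNP whose counted allele has frequency above 0.5."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        flip = freq > 0.5
        self.dosages[:, flip] = 2.0 - self.dosages[:, flip]


def _parse_phenotype_12(col: np.ndarray) -> np.ndarray:
    """PLINK 1/2 phenotype coding to 0/1 with NaN for missing."""
    ph = np.full(col.shape, np.nan)
    ph[col == 1] = 0.0
    ph[col == 2] = 1.0
    return ph


def _read_ped_map(path: Path) -> GenotypePanel:
    path = Path(path)
    ped = path if path.suffix == ".ped" else path.with_suffix(".ped")
    mapf = ped.with_suffix(".map")
    snp_ids = []
    with open(mapf) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"{mapf}:{ln}: expected 4 fields, got {len(parts)}")
            snp_ids.append(parts[1])
    m = len(snp_ids)

    sample_ids, pheno_raw, allele_rows = [], [], []
    with open(ped) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            try:
                pheno_raw.append(float(parts[5]))
            except ValueError:
                raise ValueError(f"{ped}:{ln}: field 6: bad phenotype {parts[5]!r}")
            allele_rows.append(parts[6:])
    alleles = np.asarray(allele_rows, dtype=object).reshape(len(sample_ids), m, 2)

    dosages = np.full((len(sample_ids), m), np.nan)
    for j in range(m):
        a = alleles[:, j, :]
        seen = sorted(set(a.ravel()) - {"0"})
        if len(seen) > 2:
            raise ValueError(f"{ped}: SNP {snp_ids[j]} has more than two alleles")
        if not seen:
            continue
        # count the minor allele; on a tie the alphabetically first allele
        # becomes the reference (dosage 0), so the other one is counted
        counts = {al: int((a == al).sum()) for al in seen}
        min_count = min(counts.values())
        minor = max((al for al in seen if counts[al] == min_count))
        missing = (a == "0").any(axis=1)
        dos = (a == minor).sum(axis=1).astype(float)
        dos[missing] = np.nan
        dosages[:, j] = dos

    ph = _parse_phenotype_12(np.asarray(pheno_raw))
    return GenotypePanel(dosages, snp_ids, sample_ids, ph)


def _read_plink_raw(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing_meta = [c for c in meta if c not in df.columns]
    if missing_meta:
        raise ValueError(f"{path}: missing .raw header columns {missing_meta}")
    snp_cols = [c for c in df.columns if c not in meta]
    dosages = df[snp_cols].to_numpy(dtype=float)
    # strip the counted-allele suffix PLINK appends (rs123_A -> rs123)
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    if len(set(snp_ids)) != len(snp_ids):
        snp_ids = snp_cols
    ph = _parse_phenotype_12(df["PHENOTYPE"].to_numpy(dtype=float))
    panel = GenotypePanel(dosages, snp_ids, df["IID"].astype(str).tolist(), ph)
    panel.orient_to_minor()
    return panel


def _read_dosage(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    has_pheno = len(df.columns) > 1 and df.columns[1] == "phenotype"
    snp_cols = list(df.columns[2:]) if has_pheno else list(df.columns[1:])
    panel = GenotypePanel(
        df[snp_cols].to_numpy(dtype=float),
        snp_cols,
        df["sample_id"].astype(str).tolist(),
        df["phenotype"].to_numpy(dtype=float) if has_pheno else None,
    )
    panel.orient_to_minor()
    return panel


_READERS = {
    "plink_ped_map": _read_ped_map,
    "plink_raw": _read_plink_raw,
    "delimited_dosage": _read_dosage,
}


def read_panel(path, format: str = "delimited_dosage") -> GenotypePanel:
    """Load a genotype panel from one of the supported text dialects."""
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(
            f"unknown format {format!r}; choose from {sorted(_READERS)}"
        ) from None
    return reader(Path(path))


def write_dosage(panel: GenotypePanel, path) -> None:
    """Write the native delimited dosage table (tab-separated, NA missing)."""
    cols = {"sample_id": panel.sample_ids}
    if panel.phenotype is not None:
        ph = pd.array(panel.phenotype).astype("Int64")
        cols["phenotype"] = ph
    df = pd.DataFrame(cols)
    dos = pd.DataFrame(panel.dosages, columns=panel.snp_ids).astype("Int64")
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def scan_pairs(
    panel: GenotypePanel,
    tests=("W", "CHI-f", "CHI-r", "LR8", "LR3", "LR1", "LRI"),
    hf_mode: str = "default",
    hf_table=None,
    alpha: float = 0.05,
    bootstrap_seed: int | None = None,
) -> pd.DataFrame:
    """Run every selected test on all M*(M-1)/2 SNP pairs of a panel.

    ``hf_mode`` controls the W-test parameters: ``"default"`` uses
    h=(k-1)/k, f=k-1; ``"fixed"`` uses the supplied ``hf_table``;
    ``"bootstrap"`` estimates (h, f) once from the whole panel and reuses the
    estimates for every pair.  Returns one row per pair per test.
    """
    if panel.phenotype is None or np.all(np.isnan(panel.phenotype)):
        raise ValueError("panel has no phenotype; a scan requires case/control status")
    if panel.n_snps < 2:
        raise ValueError("need at least 2 SNPs to form pairs")

    effective_tests = list(tests)
    if hf_mode == "bootstrap":
        n_cases = int(np.nansum(panel.phenotype == 1))
        hf_table = bootstrap_hf(panel.dosages, n_cases=n_cases, seed=bootstrap_seed)
    elif hf_mode == "fixed":
        if hf_table is None:
            raise ValueError("hf_mode='fixed' requires an hf_table")
    elif hf_mode != "default":
        raise ValueError(f"unknown hf_mode {hf_mode!r}")
    if hf_mode in ("bootstrap", "fixed"):
        effective_tests = ["W-hf" if t == "W" else t for t in effective_tests]

    rows = []
    for i, j in itertools.combinations(range(panel.n_snps), 2):
        table = build_table(
            panel.dosages[:, i], panel.dosages[:, j], panel.phenotype
        )
        results = run_tests_on_table(table, tuple(effective_tests), hf_table=hf_table)
        for t in effective_tests:
            r = results[t]
            rows.append(
                {
                    "snp1": panel.snp_ids[i],
                    "snp2": panel.snp_ids[j],
                    "test": "W" if t == "W-hf" else t,
                    "statistic": r.statistic,
                    "df": r.df,
                    "p_value": r.p_value,
                    "defined": r.defined,
                    "significant": r.significant(alpha),
                    "note": r.note,
                }
            )
    return pd.DataFrame(rows)


def write_results(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a scan results table with a commented metadata header."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        out = df.copy()
        for col in ("statistic", "df"):
            if col in out:
                out[col] = out[col].map(lambda x: "NA" if pd.isna(x) else f"{x:.6g}")
        if "p_value" in out:
            # scientific notation, 6 significant digits
            out["p_value"] = out["p_value"].map(
                lambda x: "NA" if pd.isna(x) else f"{x:.5e}"
            )
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")
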