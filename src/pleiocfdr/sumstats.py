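"""Reading, validation, genomic control and harmonization of GWAS summary statistics.

A summary-statistic table holds one row per SNP with the association
results for a single trait: identifier, position, alleles, effect size
``beta`` with standard error ``se``, z-score, two-sided p-value, minor
allele frequency and sample size.  Everything downstream (conditional
Q-Q, cFDR, MR) consumes the harmonized two-trait merge produced here.

Conventions
-----------
* coordinates are 1-based; chromosomes are strings ("1".."22", "X", "Y");
* p-values live in (0, 1]; an input p of exactly 0 is floored to 1e-300
  (the empirical cFDR needs strictly positive p) and logged;
* z and (beta, se) must agree (z = beta/se) when both are present;
* strand-ambiguous SNPs (A/T or C/G) are dropped during merging, the
  conservative default when allele frequencies cannot arbitrate strand.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger("pleiocfdr")

P_FLOOR = 1e-300

#: median of the chi-square distribution with 1 degree of freedom,
#: the null expectation of median(z^2) used by genomic control
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names; a column map translates file headers to these
STANDARD_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "z",
    "p",
    "maf",
    "n",
)

_NUMERIC_COLUMNS = ("pos", "beta", "se", "z", "p", "maf", "n")


def _chrom_key(chrom: pd.Series) -> pd.Series:
    """Sort key for chromosome labels: 1..22 < X < Y < MT < others."""
    c = chrom.astype(str).str.removeprefix("chr").str.upper()
    return c.map(lambda v: _CHROM_ORDER.get(v, 100)), c


@dataclass
class SumstatsTable:
    """Per-SNP association results for one trait, sorted by (chrom, pos).

    Parameters
    ----------
    df
        DataFrame with (a subset of) :data:`STANDARD_COLUMNS`; ``snp_id``,
        ``chrom``, ``pos``, ``p`` and ``z`` are always present after
        :func:`read_sumstats`.
    trait_label
        Human-readable trait name, e.g. ``"LS-BMD"``.
    gc_lambda
        Genomic-control inflation factor that has been applied
        (1.0 means unadjusted).
    """

    df: pd.DataFrame
    trait_label: str = ""
    gc_lambda: float = 1.0

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MergedPair:
    """SNP-intersected, allele-harmonized two-trait table.

    ``df`` has columns snp_id, chrom, pos, p1, z1, p2, z2 and (when
    available) maf; z1 and z2 refer to the same effect allele.  Slot 1
    is the principal-candidate trait, slot 2 the conditional trait.
    """

    df: pd.DataFrame
    trait1_label: str = "trait1"
    trait2_label: str = "trait2"
    n_dropped_ambiguous: int = 0
    n_dropped_mismatch: int = 0

    def __len__(self) -> int:
        return len(self.df)

    def swapped(self) -> "MergedPair":
        """The same table with the two trait slots exchanged."""
        df = self.df.rename(columns={"p1": "p2", "p2": "p1", "z1": "z2", "z2": "z1"})
        return MergedPair(
            df,
            trait1_label=self.trait2_label,
            trait2_label=self.trait1_label,
            n_dropped_ambiguous=self.n_dropped_ambiguous,
            n_dropped_mismatch=self.n_dropped_mismatch,
        )


def load_column_map(path) -> dict:
    """Read a flat key: value config file mapping standard names to file headers."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, dict):
        raise ValueError(f"column map {path!r} is not a flat key-value mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_sumstats(path, column_map: dict | None = None, trait_label: str = "") -> SumstatsTable:
    """Read a tab-delimited summary-statistic file into a validated table.

    Parameters
    ----------
    path
        Tab-delimited text file with a header row; ``.gz`` accepted.
    column_map
        Mapping from standard names (:data:`STANDARD_COLUMNS`) to the
        file's header names.  Standard names already present in the file
        need not be mapped.
    trait_label
        Label stored on the returned table.

    The file must provide ``snp_id``, ``chrom``, ``pos`` and at least one
    of ``p``, ``z`` or (``beta``, ``se``); missing z is derived as
    beta/se and missing p from z (two-sided normal).  p-values of
    exactly 0 are floored to ``1e-300`` with a logged warning.

    Raises
    ------
    ValueError
        On unparseable rows (naming the file line number), p outside
        (0, 1] after flooring, duplicate snp_id, or missing required
        columns.
    """
    with _open_text(path) as fh:
        raw = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    rename = {}
    if column_map:
        for std, src in column_map.items():
            if std not in STANDARD_COLUMNS:
                raise ValueError(f"unknown standard column {std!r} in column map")
            if src not in raw.columns:
                raise ValueError(f"mapped column {src!r} not found in {path}")
            rename[src] = std
    raw = raw.rename(columns=rename)
    raw = raw[[c for c in STANDARD_COLUMNS if c in raw.columns]]

    for col in ("snp_id", "chrom", "pos"):
        if col not in raw.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    if "p" not in raw.columns and "z" not in raw.columns and not (
        "beta" in raw.columns and "se" in raw.columns
    ):
        raise ValueError(f"{path}: need 'p', 'z', or both 'beta' and 'se'")

    df = pd.DataFrame({"snp_id": raw["snp_id"].astype(str), "chrom": raw["chrom"].astype(str)})
    df["chrom"] = df["chrom"].str.removeprefix("chr")
    # header is file line 1; data row i (0-based) is file line i + 2
    for col in _NUMERIC_COLUMNS:
        if col not in raw.columns:
            continue
        vals = raw[col].replace({"": None, "NA": None, ".": None})
        num = pd.to_numeric(vals, errors="coerce")
        bad = num.isna() & vals.notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(
                f"{path}: unparseable value {vals.iloc[line - 2]!r} for column "
                f"{col!r} at line {line}"
            )
        df[col] = num.astype(float)
    for col in ("effect_allele", "other_allele"):
        if col in raw.columns:
            df[col] = raw[col].astype(str).str.upper()

    if df["pos"].isna().any():
        line = int(np.flatnonzero(df["pos"].isna().to_numpy())[0]) + 2
        raise ValueError(f"{path}: missing position at line {line}")
    df["pos"] = df["pos"].astype(np.int64)

    dup = df["snp_id"][df["snp_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate snp_id: {sorted(set(dup))}")

    if "z" not in df.columns and "beta" in df.columns and "se" in df.columns:
        df["z"] = df["beta"] / df["se"]
    if "p" in df.columns:
        n_zero = int((df["p"] == 0).sum())
        if n_zero:
            logger.warning("%s: floored %d p-values of 0 to %.0e", path, n_zero, P_FLOOR)
            df.loc[df["p"] == 0, "p"] = P_FLOOR
        bad_p = df["p"].notna() & ((df["p"] <= 0) | (df["p"] > 1))
        if bad_p.any():
            line = int(np.flatnonzero(bad_p.to_numpy())[0]) + 2
            raise ValueError(f"{path}: p-value outside (0, 1] at line {line}")
        if "z" in df.columns and df["p"].isna().any():
            gap = df["p"].isna() & df["z"].notna()
            df.loc[gap, "p"] = p_from_z(df.loc[gap, "z"].to_numpy())
    elif "z" in df.columns:
        df["p"] = p_from_z(df["z"].to_numpy())

    _validate(df, path)
    order_key, chrom_norm = _chrom_key(df["chrom"])
    df = (
        df.assign(_ck=order_key.to_numpy(), chrom=chrom_norm.to_numpy())
        .sort_values(["_ck", "chrom", "pos"], kind="mergesort")
        .drop(columns="_ck")
        .reset_index(drop=True)
    )
    return SumstatsTable(df, trait_label=trait_label)


def _validate(df: pd.DataFrame, path) -> None:
    if "se" in df.columns:
        bad = df["se"].notna() & (df["se"] <= 0)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"{path}: non-positive standard error at line {line}")
    if "maf" in df.columns:
        bad = df["maf"].notna() & ((df["maf"] <= 0) | (df["maf"] > 0.5))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"{path}: MAF outside (0, 0.5] at line {line}")
    if {"z", "beta", "se"}.issubset(df.columns):
        both = df["z"].notna() & df["beta"].notna() & df["se"].notna()
        if both.any():
            z = df.loc[both, "z"].to_numpy()
            ratio = (df.loc[both, "beta"] / df.loc[both, "se"]).to_numpy()
            denom = np.maximum(np.abs(z), 1e-12)
            off = np.abs(z - ratio) / denom > 1e-6
            if off.any():
                line = int(np.flatnonzero(both.to_numpy())[np.flatnonzero(off)[0]]) + 2
                raise ValueError(f"{path}: z inconsistent with beta/se at line {line}")
    if {"effect_allele", "other_allele"}.issubset(df.columns):
        same = df["effect_allele"] == df["other_allele"]
        if same.any():
            line = int(np.flatnonzero(same.to_numpy())[0]) + 2
            raise ValueError(f"{path}: effect allele equals other allele at line {line}")


def write_sumstats(table: SumstatsTable, path) -> None:
    """Write a table as tab-delimited text (gzip when path ends in .gz)."""
    path = str(path)
    if path.endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            table.df.to_csv(fh, sep="\t", index=False)
    else:
        table.df.to_csv(path, sep="\t", index=False)


def p_from_z(z: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value for a z-score."""
    return 2.0 * stats.norm.sf(np.abs(z))


def z_from_p(p: np.ndarray, sign: np.ndarray | None = None) -> np.ndarray:
    """|z| implied by a two-sided p-value, with optional signs reattached."""
    z = stats.norm.isf(np.asarray(p) / 2.0)
    if sign is not None:
        z = z * np.sign(sign)
    return z


def genomic_control(table: SumstatsTable) -> SumstatsTable:
    """Apply standard genomic control to a summary-statistic table.

    The inflation factor is lambda = median(z^2) / median(chi^2_1).
    When lambda > 1 every z^2 is divided by lambda (signs preserved),
    the standard errors are inflated by sqrt(lambda) so beta/se stays
    consistent, and p-values are recomputed; lambda <= 1 leaves the
    statistics untouched (no deflation).  The factor is recorded on the
    returned table either way.
    """
    df = table.df
    if len(df) < 2:
        raise ValueError("genomic control needs at least 2 records (median undefined for inference)")
    if "z" not in df.columns or df["z"].isna().any():
        raise ValueError("genomic control requires a z-score for every record")
    lam = float(np.median(df["z"].to_numpy() ** 2) / CHI2_MEDIAN_1DF)
    if lam <= 1.0:
        return replace(table, gc_lambda=lam)
    out = df.copy()
    out["z"] = df["z"].to_numpy() / np.sqrt(lam)
    if "se" in out.columns:
        out["se"] = df["se"].to_numpy() * np.sqrt(lam)
    out["p"] = p_from_z(out["z"].to_numpy())
    logger.info("genomic control: lambda=%.4f applied to %s", lam, table.trait_label or "table")
    return SumstatsTable(out, trait_label=table.trait_label, gc_lambda=lam)


def _is_ambiguous(ea: pd.Series, oa: pd.Series) -> pd.Series:
    """A/T and C/G pairs cannot be strand-resolved without frequencies."""
    return ((ea == "A") & (oa == "T")) | ((ea == "T") & (oa == "A")) | (
        (ea == "C") & (oa == "G")
    ) | ((ea == "G") & (oa == "C"))


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(_COMPLEMENT).fillna("N")


def harmonize_and_merge(t1: SumstatsTable, t2: SumstatsTable) -> MergedPair:
    """Intersect two tables by snp_id and harmonize effect alleles.

    Trait 1 is the principal-candidate slot.  If trait 2 reports the
    swapped allele pair its z2 changes sign; complementary-strand
    records are flipped to trait 1's strand before comparison;
    strand-ambiguous SNPs (A/T, C/G) and irreconcilable allele pairs
    are dropped, with counts logged.

    Raises
    ------
    ValueError
        If the snp_id intersection (after drops) is empty.
    """
    c1 = ["snp_id", "chrom", "pos", "p", "z"] + (["maf"] if "maf" in t1.df.columns else [])
    a1 = {"effect_allele", "other_allele"}.issubset(t1.df.columns)
    a2 = {"effect_allele", "other_allele"}.issubset(t2.df.columns)
    left = t1.df[c1 + (["effect_allele", "other_allele"] if a1 else [])].rename(
        columns={"p": "p1", "z": "z1", "effect_allele": "ea1", "other_allele": "oa1"}
    )
    right = t2.df[["snp_id", "p", "z"] + (["effect_allele", "other_allele"] if a2 else [])].rename(
        columns={"p": "p2", "z": "z2", "effect_allele": "ea2", "other_allele": "oa2"}
    )
    merged = left.merge(right, on="snp_id", how="inner")
    if merged.empty:
        raise ValueError("empty snp_id intersection between the two tables")

    n_ambiguous = n_mismatch = 0
    if a1 and a2:
        ambiguous = _is_ambiguous(merged["ea1"], merged["oa1"]) | _is_ambiguous(
            merged["ea2"], merged["oa2"]
        )
        cea2, coa2 = _complement(merged["ea2"]), _complement(merged["oa2"])
        direct = (merged["ea2"] == merged["ea1"]) & (merged["oa2"] == merged["oa1"])
        swapped = (merged["ea2"] == merged["oa1"]) & (merged["oa2"] == merged["ea1"])
        comp_direct = (cea2 == merged["ea1"]) & (coa2 == merged["oa1"])
        comp_swapped = (cea2 == merged["oa1"]) & (coa2 == merged["ea1"])
        keep = ~ambiguous & (direct | swapped | comp_direct | comp_swapped)
        flip = ~ambiguous & ~direct & ~comp_direct & (swapped | comp_swapped)
        n_ambiguous = int(ambiguous.sum())
        n_mismatch = int((~keep & ~ambiguous).sum())
        if n_ambiguous:
            logger.info("harmonize: dropped %d strand-ambiguous SNPs", n_ambiguous)
        if n_mismatch:
            logger.info("harmonize: dropped %d SNPs with irreconcilable alleles", n_mismatch)
        merged.loc[flip, "z2"] = -merged.loc[flip, "z2"]
        merged = merged[keep]
    elif a1 != a2:
        logger.info("harmonize: allele columns present in only one table; assuming shared effect allele")

    merged = merged.drop(columns=[c for c in ("ea1", "oa1", "ea2", "oa2") if c in merged.columns])
    merged = merged.reset_index(drop=True)
    if merged.empty:
        raise ValueError("no SNPs left after allele harmonization")
    return MergedPair(
        merged,
        trait1_label=t1.trait_label or "trait1",
        trait2_label=t2.trait_label or "trait2",
        n_dropped_ambiguous=n_ambiguous,
        n_dropped_mismatch=n_mismatch,
    )
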