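"""Empirical conditional FDR, conjunction FDR and stratified conditional Q-Q.

For a SNP with observed p-values (p1, p2) for a principal and a
conditional trait, the conditional false discovery rate is the
probability of a false positive association with the principal trait
given that both p-values are at least as small as observed.  It is
estimated empirically as

    cFDR(p1 | p2) = min(1, p1 * n_cond / n_joint)

where, over the merged (pruned) SNP panel,

    n_cond  = #{ SNPs with p2' <= p2 }
    n_joint = #{ SNPs with p1' <= p1 and p2' <= p2 },

i.e. p1 divided by the empirical conditional cdf of p1 given p2' <= p2.
Comparisons are inclusive, so an index SNP always counts itself and
n_joint >= 1.  The conjunction cFDR (ccFDR) is the maximum of the two
trait orderings; ccFDR < 0.05 flags a pleiotropic locus.

Counting is exact (sort + Fenwick-tree sweep, O(M log M)); a brute-force
double loop over SNP pairs gives identical counts and is used as the
test oracle.

Cross-trait enrichment is visualized by stratified conditional Q-Q
curves: the quantiles of the principal trait's p-values within nested
subsets defined by successively more stringent conditional-trait
cutoffs (p2 < 1, 0.1, 0.01, 0.001, 0.0001).  Leftward deflection of a
stratum's curve from the identity line signals pleiotropic enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pleiocfdr.sumstats import MergedPair

DEFAULT_THRESHOLDS = (1.0, 0.1, 0.01, 0.001, 0.0001)
SIGNIFICANCE_THRESHOLD = 0.05
MIN_STRATUM_WARN = 10


@dataclass
class QqStrata:
    """Stratified conditional Q-Q curves on a shared quantile grid.

    ``grid`` holds the empirical -log10(q) x-values; ``curves`` maps each
    conditional threshold to the nominal -log10(p) quantile curve of the
    principal trait within that stratum.  ``enrichment`` is a scalar
    summary per stratum: the nominal -log10 p at empirical q = 0.01,
    relative to the all-SNP stratum.  Strata are nested by construction.
    """

    thresholds: tuple
    sizes: dict
    grid: np.ndarray
    curves: dict
    enrichment: dict
    principal_label: str = ""
    conditional_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"neglog10_q": self.grid})
        for t in self.thresholds:
            out[f"neglog10_p_thresh_{t:g}"] = self.curves[t]
        return out


class _Fenwick:
    """Prefix-sum tree over ranks, for exact inclusive dominance counting."""

    __slots__ = ("n", "tree")

    def __init__(self, n: int) -> None:
        self.n = n
        self.tree = [0] * (n + 1)

    def add(self, i: int) -> None:
        i += 1
        while i <= self.n:
            self.tree[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:
        # count of inserted ranks <= i
        i += 1
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return s


def _exceedance_counts(p1: np.ndarray, p2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-SNP counts (n_cond_i, n_joint_i) with inclusive comparisons.

    n_cond_i = #{j: p2_j <= p2_i}; n_joint_i = #{j: p1_j <= p1_i and
    p2_j <= p2_i}.  Ties are counted inclusively: SNPs sharing a p2
    value all see each other, so self-inclusion holds and n_joint >= 1.
    """
    m = len(p1)
    sorted_p2 = np.sort(p2)
    n_cond = np.searchsorted(sorted_p2, p2, side="right")

    uniq_p1 = np.unique(p1)
    rank1 = np.searchsorted(uniq_p1, p1)  # dense rank; ties share a rank
    order = np.lexsort((p1, p2))  # ascending p2, then p1
    tree = _Fenwick(len(uniq_p1))
    n_joint = np.empty(m, dtype=np.int64)
    i = 0
    while i < m:
        j = i
        while j < m and p2[order[j]] == p2[order[i]]:
            j += 1
        for k in order[i:j]:  # insert the whole p2-tie group first
            tree.add(rank1[k])
        for k in order[i:j]:
            n_joint[k] = tree.prefix(rank1[k])
        i = j
    return n_cond, n_joint


def joint_exceedance_counts(p1_obs: float, p2_obs: float, data: MergedPair) -> tuple[int, int]:
    """Counts (n_cond, n_joint) for one query point over a merged table.

    n_cond = #{SNPs with p2 <= p2_obs}; n_joint additionally requires
    p1 <= p1_obs.  Comparisons are inclusive.
    """
    if len(data) == 0:
        raise ValueError("empty merged table")
    if not (0 < p1_obs <= 1 and 0 < p2_obs <= 1):
        raise ValueError("query p-values must lie in (0, 1]")
    p1 = data.df["p1"].to_numpy()
    p2 = data.df["p2"].to_numpy()
    cond = p2 <= p2_obs
    return int(cond.sum()), int((cond & (p1 <= p1_obs)).sum())


def cfdr(data: MergedPair, principal: int | str = 1) -> np.ndarray:
    """Per-SNP empirical cFDR for the requested trait ordering.

    ``principal`` selects the principal-trait slot: 1 (or the slot-1
    trait label) conditions trait 1 on trait 2; 2 the reverse.  The
    returned array is aligned with the rows of ``data``.
    """
    if len(data) == 0:
        raise ValueError("empty merged table")
    slot = _resolve_slot(data, principal)
    df = data.df
    if slot == 1:
        p1, p2 = df["p1"].to_numpy(), df["p2"].to_numpy()
    else:
        p1, p2 = df["p2"].to_numpy(), df["p1"].to_numpy()
    n_cond, n_joint = _exceedance_counts(p1, p2)
    if (n_joint < 1).any():
        raise AssertionError("n_joint < 1: self-inclusion violated")
    # lower clamp at p1 guards the cFDR >= p invariant against the one-ulp
    # rounding of p1 * n / n when the two counts coincide
    return np.minimum(1.0, np.maximum(p1, p1 * n_cond / n_joint))


def _resolve_slot(data: MergedPair, principal: int | str) -> int:
    if principal in (1, 2):
        return int(principal)
    if principal == data.trait1_label:
        return 1
    if principal == data.trait2_label:
        return 2
    raise ValueError(f"unknown principal trait {principal!r}")


def cfdr_table(data: MergedPair, threshold: float = SIGNIFICANCE_THRESHOLD) -> pd.DataFrame:
    """Both cFDR orderings, the conjunction ccFDR and significance flags.

    Returns one row per SNP with columns snp_id, chrom, pos, p1, p2,
    cfdr_1_given_2, cfdr_2_given_1, ccfdr, sig_1_given_2,
    sig_2_given_1, sig_conjunction.
    """
    out = data.df[["snp_id", "chrom", "pos", "p1", "p2"]].copy()
    out["cfdr_1_given_2"] = cfdr(data, 1)
    out["cfdr_2_given_1"] = cfdr(data, 2)
    out = conjunction(out)
    out, _ = call_significant(out, threshold)
    return out


def conjunction(records: pd.DataFrame) -> pd.DataFrame:
    """Add the conjunction cFDR: the maximum of the two trait orderings."""
    for col in ("cfdr_1_given_2", "cfdr_2_given_1"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}; compute both orderings first")
        if records[col].isna().any():
            raise ValueError(f"records contain missing values in {col!r}")
    out = records.copy()
    out["ccfdr"] = np.maximum(out["cfdr_1_given_2"], out["cfdr_2_given_1"])
    return out


def call_significant(
    records: pd.DataFrame, threshold: float = SIGNIFICANCE_THRESHOLD
) -> tuple[pd.DataFrame, dict]:
    """Flag per-ordering and conjunction significance (strict inequality).

    Returns the flagged records and a summary dict with counts per
    ordering and for the conjunction.
    """
    out = records.copy()
    out["sig_1_given_2"] = out["cfdr_1_given_2"] < threshold
    out["sig_2_given_1"] = out["cfdr_2_given_1"] < threshold
    if "ccfdr" in out.columns:
        out["sig_conjunction"] = out["ccfdr"] < threshold
    summary = {
        "threshold": threshold,
        "n_sig_1_given_2": int(out["sig_1_given_2"].sum()),
        "n_sig_2_given_1": int(out["sig_2_given_1"].sum()),
        "n_sig_conjunction": int(out["sig_conjunction"].sum()) if "ccfdr" in out.columns else 0,
    }
    return out, summary


def _quantile_curve(p: np.ndarray, q_grid: np.ndarray) -> np.ndarray:
    """Nominal -log10 p at each empirical quantile level q (lower tail)."""
    sorted_p = np.sort(p)
    n = len(sorted_p)
    # empirical quantile at level q: the ceil(q*n)-th smallest value
    k = np.ceil(q_grid * n).astype(int)
    k = np.clip(k, 1, n)
    return -np.log10(sorted_p[k - 1])


def stratified_qq(
    data: MergedPair,
    principal: int | str = 1,
    thresholds: tuple = DEFAULT_THRESHOLDS,
    n_grid: int = 512,
) -> QqStrata:
    """Stratified conditional Q-Q curves of the principal trait.

    For each conditional threshold t the stratum is the set of SNPs
    with conditional-trait p strictly below t (matching "p < 0.1"
    stratification); the curve gives the nominal -log10 p quantiles of
    the principal trait within the stratum on a shared grid of
    empirical -log10(q) values from 0 to log10(m).  The enrichment
    summary per stratum is the nominal -log10 p at empirical q = 0.01
    minus the same quantity in the all-SNP (t = 1) stratum; under
    pleiotropic enrichment it grows as t tightens.

    Raises
    ------
    ValueError
        If the table or any stratum is empty (naming the threshold).
    """
    if len(data) == 0:
        raise ValueError("empty merged table")
    slot = _resolve_slot(data, principal)
    df = data.df
    if slot == 1:
        p_prin, p_cond = df["p1"].to_numpy(), df["p2"].to_numpy()
        labels = (data.trait1_label, data.trait2_label)
    else:
        p_prin, p_cond = df["p2"].to_numpy(), df["p1"].to_numpy()
        labels = (data.trait2_label, data.trait1_label)

    thresholds = tuple(sorted(set(float(t) for t in thresholds), reverse=True))
    m = len(p_prin)
    grid_neglog_q = np.linspace(0.0, np.log10(m), n_grid)
    q_grid = 10.0 ** (-grid_neglog_q)

    sizes, curves, enrich = {}, {}, {}
    baseline = None
    for t in thresholds:
        mask = p_cond < t if t < 1.0 else np.ones(m, dtype=bool)
        n_t = int(mask.sum())
        if n_t == 0:
            raise ValueError(f"empty stratum for conditional threshold {t:g}")
        if n_t < MIN_STRATUM_WARN:
            import logging

            logging.getLogger("pleiocfdr").warning(
                "stratum p<%g has only %d SNPs; curve unstable", t, n_t
            )
        sizes[t] = n_t
        curve = _quantile_curve(p_prin[mask], q_grid)
        curves[t] = curve
        at_q01 = float(_quantile_curve(p_prin[mask], np.array([0.01]))[0])
        if baseline is None:
            baseline = at_q01
        enrich[t] = at_q01 - baseline
    return QqStrata(
        thresholds=thresholds,
        sizes=sizes,
        grid=grid_neglog_q,
        curves=curves,
        enrichment=enrich,
        principal_label=labels[0],
        conditional_label=labels[1],
    )


def qq_null_band(n: int, grid_neglog_q: np.ndarray, alpha: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Simultaneous (1 - alpha) Kolmogorov–Smirnov band around the identity line.

    For a stratum of ``n`` independent Uniform(0, 1) p-values the whole
    empirical quantile curve stays inside the band with probability
    1 - alpha: at quantile level q the curve lies between the
    -log10 transforms of q ± c(alpha)/sqrt(n), clipped to (0, 1].
    Returns (lower, upper) bounds on the nominal -log10 p scale.
    """
    from scipy import stats as _st

    c = _st.kstwobign.isf(alpha) / np.sqrt(n)
    q = 10.0 ** (-np.asarray(grid_neglog_q, dtype=float))
    hi_p = np.clip(q + c, 1e-300, 1.0)   # larger p => lower -log10
    lo_p = np.clip(q - c, 1e-300, 1.0)
    return -np.log10(hi_p), -np.log10(lo_p)
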