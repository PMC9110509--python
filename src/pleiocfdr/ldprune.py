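"""Windowed r²-based LD pruning of a reference genotype panel.

Before computing the empirical cFDR, the SNP panel is thinned so that
no pair of retained SNPs in close proximity is in strong linkage
disequilibrium: within a sliding window of consecutive retained SNPs,
whenever a pair has squared Pearson correlation r² above the threshold,
the member with the smaller minor allele frequency is removed.  The
window then advances a fixed number of SNPs and the whole scan repeats
until no removal occurs, which guarantees that no window of
``window`` consecutive retained SNPs contains a pair with r² above the
threshold.

The default parameters (window of 50 SNPs, step of 5, r² > 0.2 triggers
removal) are the standard sliding-window pruning settings for
cross-trait cFDR analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pleiocfdr.sumstats import MergedPair


@dataclass
class LdPanel:
    """Dosage matrix (SNPs x samples, values 0/1/2, NaN = missing) plus metadata.

    ``meta`` has one row per dosage row, columns snp_id, chrom, pos and
    maf, sorted by (chrom, pos) in the same order as the matrix.
    """

    dosages: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (SNPs x samples)")
        if len(self.meta) != self.dosages.shape[0]:
            raise ValueError("metadata rows do not match dosage rows")
        for col in ("snp_id", "chrom", "pos"):
            if col not in self.meta.columns:
                raise ValueError(f"panel metadata missing column {col!r}")

    def __len__(self) -> int:
        return self.dosages.shape[0]

    @property
    def maf(self) -> np.ndarray:
        if "maf" in self.meta.columns:
            return self.meta["maf"].to_numpy(dtype=float)
        freq = np.nanmean(self.dosages, axis=1) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class PruneResult:
    """Outcome of a pruning run.

    ``removals`` records, per removed SNP, the partner it exceeded the
    r² threshold with and the offending r² value.
    """

    retained: list[str]
    removals: pd.DataFrame  # columns: snp_id, partner, r2
    window: int
    step: int
    r2_max: float

    @property
    def removed(self) -> list[str]:
        return self.removals["snp_id"].tolist()


def compute_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing genotypes (NaN) are handled by pairwise-complete deletion.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 2 complete pairs, or zero
        variance (monomorphic SNP) after deletion.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise ValueError("fewer than 2 pairwise-complete samples")
    xc = x[ok] - x[ok].mean()
    yc = y[ok] - y[ok].mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        raise ValueError("zero variance: monomorphic SNP in pairwise-complete samples")
    r = float(xc @ yc) / np.sqrt(vx * vy)
    return min(r * r, 1.0)


def _prune_pass(
    order: list[int],
    dosages: np.ndarray,
    maf: np.ndarray,
    snp_ids: np.ndarray,
    window: int,
    step: int,
    r2_max: float,
    r2_cache: dict,
    removals: list,
) -> bool:
    """One sliding-window scan over the retained list; returns True if it removed anything.

    ``order`` is mutated in place.  Windows start every ``step``
    positions of the *current* retained list; within a window pairs are
    examined in position order and the smaller-MAF member of a violating
    pair is removed immediately (MAF ties: the later SNP goes).
    """
    removed_any = False
    w = 0
    while w < len(order):
        members = order[w : w + window]
        dead: set[int] = set()
        for a in range(len(members)):
            i = members[a]
            if i in dead:
                continue
            for b in range(a + 1, len(members)):
                j = members[b]
                if i in dead:
                    break
                if j in dead:
                    continue
                key = (i, j)
                r2 = r2_cache.get(key)
                if r2 is None:
                    r2 = compute_r2(dosages[i], dosages[j])
                    r2_cache[key] = r2
                if r2 > r2_max:
                    victim = j if maf[j] < maf[i] or maf[j] == maf[i] else i
                    partner = i if victim == j else j
                    dead.add(victim)
                    removals.append((snp_ids[victim], snp_ids[partner], r2))
                    removed_any = True
        if dead:
            order[:] = [k for k in order if k not in dead]
        w += step
    return removed_any


def window_prune(
    panel: LdPanel, window: int = 50, step: int = 5, r2_max: float = 0.2
) -> PruneResult:
    """Sliding-window LD pruning, per chromosome, to a fixpoint.

    Scans windows of ``window`` consecutive currently-retained SNPs,
    removing the smaller-MAF member of any pair with r² strictly above
    ``r2_max`` (pairs at exactly the threshold are kept), advancing
    ``step`` SNPs between windows, and repeating whole passes until a
    scan removes nothing.  A final step-1 audit pass guarantees the
    post-condition for *every* window of consecutive retained SNPs, not
    only those aligned with the step.

    Returns a :class:`PruneResult`; removal order is deterministic.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not (1 <= step <= window):
        raise ValueError("step must satisfy 1 <= step <= window")
    maf = panel.maf
    snp_ids = panel.meta["snp_id"].to_numpy()
    removals: list = []
    retained: list[str] = []

    chroms = panel.meta["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = list(np.flatnonzero(chroms == chrom))
        cache: dict = {}
        while True:
            while _prune_pass(
                idx, panel.dosages, maf, snp_ids, window, step, r2_max, cache, removals
            ):
                pass
            # audit with step 1 so off-step windows are covered too
            if not _prune_pass(
                idx, panel.dosages, maf, snp_ids, window, 1, r2_max, cache, removals
            ):
                break
        retained.extend(snp_ids[k] for k in idx)

    removals_df = pd.DataFrame(removals, columns=["snp_id", "partner", "r2"])
    return PruneResult(retained, removals_df, window=window, step=step, r2_max=r2_max)


def intersect_after_prune(pruned: PruneResult, merged: MergedPair) -> MergedPair:
    """Restrict a merged two-trait table to the retained SNPs, order preserved."""
    keep = set(pruned.retained)
    df = merged.df[merged.df["snp_id"].isin(keep)].reset_index(drop=True)
    if df.empty:
        raise ValueError("no merged SNPs survive pruning")
    return MergedPair(
        df,
        trait1_label=merged.trait1_label,
        trait2_label=merged.trait2_label,
        n_dropped_ambiguous=merged.n_dropped_ambiguous,
        n_dropped_mismatch=merged.n_dropped_mismatch,
    )
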