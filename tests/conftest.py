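import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from pleiocfdr.ldprune import LdPanel
from pleiocfdr.sumstats import MergedPair, SumstatsTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_sumstats(
    snp_ids, chroms, positions, z=None, p=None, maf=None, alleles=None, trait="t"
) -> SumstatsTable:
    df = pd.DataFrame(
        {"snp_id": snp_ids, "chrom": [str(c) for c in chroms], "pos": positions}
    )
    if z is not None:
        df["z"] = np.asarray(z, dtype=float)
    if p is not None:
        df["p"] = np.asarray(p, dtype=float)
    elif z is not None:
        from pleiocfdr.sumstats import p_from_z

        df["p"] = p_from_z(df["z"].to_numpy())
    if maf is not None:
        df["maf"] = np.asarray(maf, dtype=float)
    if alleles is not None:
        df["effect_allele"] = [a for a, _ in alleles]
        df["other_allele"] = [b for _, b in alleles]
    return SumstatsTable(df, trait_label=trait)


def make_merged(p1, p2, chrom=None, pos=None) -> MergedPair:
    m = len(p1)
    df = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(m)],
            "chrom": ["1"] * m if chrom is None else [str(c) for c in chrom],
            "pos": np.arange(1, m + 1) * 100 if pos is None else pos,
            "p1": np.asarray(p1, dtype=float),
            "z1": 0.0,
            "p2": np.asarray(p2, dtype=float),
            "z2": 0.0,
        }
    )
    return MergedPair(df)


def make_panel(dosages, mafs=None, chrom="1") -> LdPanel:
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[0]
    meta = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(m)],
            "chrom": [chrom] * m,
            "pos": np.arange(1, m + 1) * 1000,
        }
    )
    if mafs is not None:
        meta["maf"] = np.asarray(mafs, dtype=float)
    return LdPanel(dosages, meta)


# ---------------------------------------------------------------- oracles


def brute_force_counts(p1, p2):
    """O(M^2) inclusive dominance counts: the cFDR counting oracle."""
    p1 = np.asarray(p1)[:, None]
    p2 = np.asarray(p2)[:, None]
    cond = p2.T <= p2  # cond[i, j] = (p2_j <= p2_i)
    joint = cond & (p1.T <= p1)
    return cond.sum(axis=1), joint.sum(axis=1)


def brute_force_cfdr(p1, p2):
    n_cond, n_joint = brute_force_counts(p1, p2)
    p1 = np.asarray(p1)
    return np.minimum(1.0, np.maximum(p1, p1 * n_cond / n_joint))


def oracle_window_prune(panel: LdPanel, window: int, step: int, r2_max: float):
    """Naive transcription of the sliding-window pruning procedure.

    Re-checks every window until a full scan (at the working step, then
    at step 1) removes nothing; r2 recomputed from dosages every time;
    the smaller-MAF member of a violating pair is removed immediately,
    MAF ties dropping the later SNP.
    """
    maf = panel.maf
    ids = panel.meta["snp_id"].to_numpy()
    chroms = panel.meta["chrom"].to_numpy()

    def corr2(i, j):
        x, y = panel.dosages[i], panel.dosages[j]
        ok = ~(np.isnan(x) | np.isnan(y))
        r = np.corrcoef(x[ok], y[ok])[0, 1]
        return min(r * r, 1.0)

    def one_pass(live, use_step):
        removed = False
        w = 0
        while w < len(live):
            members = live[w : w + window]
            dead = set()
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    i, j = members[a], members[b]
                    if i in dead:
                        break
                    if j in dead:
                        continue
                    if corr2(i, j) > r2_max:
                        victim = j if maf[j] <= maf[i] else i
                        dead.add(victim)
                        removed = True
            if dead:
                live[:] = [k for k in live if k not in dead]
            w += use_step
        return removed

    retained = []
    for chrom in pd.unique(chroms):
        live = list(np.flatnonzero(chroms == chrom))
        while True:
            while one_pass(live, step):
                pass
            if not one_pass(live, 1):
                break
        retained.extend(ids[k] for k in live)
    return retained


def audit_prune_postcondition(panel: LdPanel, retained, window: int, r2_max: float) -> bool:
    """Exhaustive check: no window of `window` consecutive retained SNPs has r2 > r2_max."""
    keep = set(retained)
    chroms = panel.meta["chrom"].to_numpy()
    ids = panel.meta["snp_id"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = [i for i in np.flatnonzero(chroms == chrom) if ids[i] in keep]
        for w in range(len(idx)):
            members = idx[w : w + window]
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    x, y = panel.dosages[members[a]], panel.dosages[members[b]]
                    ok = ~(np.isnan(x) | np.isnan(y))
                    r = np.corrcoef(x[ok], y[ok])[0, 1]
                    if r * r > r2_max:
                        return False
    return True
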