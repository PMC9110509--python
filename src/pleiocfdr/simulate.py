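"""Synthetic paired GWAS summary statistics and a toy LD reference panel.

The generator emulates the situation the cFDR pipeline is built for:
two traits measured on overlapping SNP panels whose z-scores follow a
four-group mixture — null for both traits (component "00"), associated
with trait 1 only ("10"), with trait 2 only ("01"), or with both
("11", the pleiotropic group).  A SNP in a non-null group for a trait
has its z-score drawn from N(0, 1 + sigma^2) instead of N(0, 1), i.e.
a normal effect-size prior added on top of sampling noise.

Summary statistics are simulated directly on the z scale and
independently across SNPs: the pipeline prunes for LD before computing
cFDR, so post-pruning independence is the operative assumption.  The
genotype panel used to exercise pruning is generated separately, as a
thresholded latent Gaussian AR(1) within blocks — the simplest
construction with a tunable adjacent-SNP r².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pleiocfdr.ldprune import LdPanel
from pleiocfdr.sumstats import SumstatsTable, p_from_z

N_CHROM = 22

COMPONENTS = ("00", "10", "01", "11")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the two-trait simulator.

    Parameters
    ----------
    m
        Number of SNPs (defaults to the order of a pruned genome-wide
        overlap panel).
    pi00, pi10, pi01, pi11
        Mixture proportions of the four components (null /
        trait-1-only / trait-2-only / pleiotropic); must sum to 1.
    sigma1, sigma2
        Standard deviation of the non-null effect inflation on the z
        scale per trait: non-null z ~ N(0, 1 + sigma^2).
    rho_block
        Adjacent-SNP latent correlation inside an LD block, in [0, 1).
    block_size
        SNPs per LD block in the genotype panel.
    n_samples
        Diploid sample count of the genotype panel.
    maf_range
        (low, high) bounds for per-SNP minor allele frequencies.
    n_chrom
        Number of chromosomes the panel is spread over (contiguous,
        roughly equal chunks).
    seed
        Seed for all randomness.
    """

    m: int = 100_000
    pi00: float = 0.90
    pi10: float = 0.04
    pi01: float = 0.04
    pi11: float = 0.02
    sigma1: float = 3.0
    sigma2: float = 3.0
    rho_block: float = 0.8
    block_size: int = 50
    n_samples: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_chrom: int = N_CHROM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        pis = np.array([self.pi00, self.pi10, self.pi01, self.pi11], dtype=float)
        if (pis < 0).any():
            raise ValueError("mixture proportions must be non-negative")
        if abs(pis.sum() - 1.0) > 1e-12:
            raise ValueError(f"mixture proportions sum to {pis.sum()!r}, not 1")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("sigma1 and sigma2 must be >= 0")
        if not (0 <= self.rho_block < 1):
            raise ValueError("rho_block must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")

    @property
    def pis(self) -> np.ndarray:
        return np.array([self.pi00, self.pi10, self.pi01, self.pi11], dtype=float)


def _snp_grid(m: int, n_chrom: int = N_CHROM) -> pd.DataFrame:
    """Deterministic SNP identifiers and positions over ``n_chrom`` chromosomes."""
    idx = np.arange(m)
    n_chrom = min(n_chrom, m)
    chrom_idx = (idx * n_chrom) // max(m, 1)  # contiguous, roughly equal chunks
    chrom = (chrom_idx + 1).astype(str)
    # restart positions on each chromosome, 10 kb spacing
    start = np.searchsorted(chrom_idx, chrom_idx)
    pos = (idx - start + 1) * 10_000
    return pd.DataFrame(
        {"snp_id": [f"rs{i + 1}" for i in idx], "chrom": chrom, "pos": pos.astype(np.int64)}
    )


def simulate_two_trait_sumstats(
    config: SimulationConfig,
) -> tuple[SumstatsTable, SumstatsTable, pd.DataFrame]:
    """Draw paired summary statistics with known mixture labels.

    Returns
    -------
    (table1, table2, truth)
        Two :class:`~pleiocfdr.sumstats.SumstatsTable` on an identical
        SNP panel, and a truth DataFrame with one row per SNP holding
        the component label and the per-trait z-score scales used.
    """
    rng = np.random.default_rng(config.seed)
    meta = _snp_grid(config.m, config.n_chrom)
    comp = rng.choice(4, size=config.m, p=config.pis)
    label = np.array(COMPONENTS)[comp]
    nonnull1 = (comp == 1) | (comp == 3)
    nonnull2 = (comp == 2) | (comp == 3)
    scale1 = np.where(nonnull1, np.sqrt(1.0 + config.sigma1**2), 1.0)
    scale2 = np.where(nonnull2, np.sqrt(1.0 + config.sigma2**2), 1.0)
    z1 = rng.standard_normal(config.m) * scale1
    z2 = rng.standard_normal(config.m) * scale2
    maf = rng.uniform(*config.maf_range, size=config.m)

    tables = []
    for z, trait in ((z1, "trait1"), (z2, "trait2")):
        df = meta.copy()
        df["z"] = z
        df["p"] = p_from_z(z)
        df["maf"] = maf
        tables.append(SumstatsTable(df, trait_label=trait))
    truth = meta[["snp_id"]].copy()
    truth["component"] = label
    truth["scale1"] = scale1
    truth["scale2"] = scale2
    return tables[0], tables[1], truth


def simulate_genotype_panel(config: SimulationConfig) -> LdPanel:
    """Simulate a diploid dosage panel with block-structured LD.

    Within a block of ``block_size`` SNPs, each haplotype's latent
    Gaussian follows an AR(1) with parameter ``rho_block`` and is
    thresholded at the normal quantile of the SNP's target allele
    frequency; dosages are the sum of two independent haplotypes.
    Blocks are mutually independent.  Metadata MAFs are the realized
    minor-allele frequencies of the generated dosages.
    """
    if config.n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(config.seed + 1)
    m, n = config.m, config.n_samples
    meta = _snp_grid(m, config.n_chrom)
    target_f = rng.uniform(*config.maf_range, size=m)
    thresh = stats.norm.ppf(target_f)

    # blocks never straddle a chromosome boundary
    chrom_starts = np.flatnonzero(np.r_[True, meta["chrom"].to_numpy()[1:] != meta["chrom"].to_numpy()[:-1]])
    block_starts = sorted(
        {
            int(cs) + off
            for cs, nxt in zip(chrom_starts, np.r_[chrom_starts[1:], m])
            for off in range(0, int(nxt - cs), config.block_size)
        }
    )
    is_block_start = np.zeros(m, dtype=bool)
    is_block_start[block_starts] = True

    dosage = np.zeros((m, n), dtype=float)
    rho = config.rho_block
    innov_sd = np.sqrt(1.0 - rho**2)
    for _ in range(2):  # two haplotypes per diploid sample
        latent = np.empty((m, n))
        for j in range(m):
            if is_block_start[j]:
                latent[j] = rng.standard_normal(n)
            else:
                latent[j] = rho * latent[j - 1] + innov_sd * rng.standard_normal(n)
        dosage += (latent < thresh[:, None]).astype(float)

    freq = dosage.mean(axis=1) / 2.0
    meta["maf"] = np.minimum(freq, 1.0 - freq)
    return LdPanel(dosage, meta)
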