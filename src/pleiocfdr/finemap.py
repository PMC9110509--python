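"""Shared-single-causal-variant fine-mapping from two-trait z-scores.

Each SNP at a locus gets a Wakefield-style approximate Bayes factor
(ABF) per trait, comparing z ~ N(0, 1 + W) (an effect drawn from a
normal prior with variance W on the z² scale) against z ~ N(0, 1):

    ABF(z, W) = sqrt(1 / (1 + W)) * exp(z² W / (2 (1 + W)))

Under the assumption of exactly one causal variant shared by both
traits, the per-trait Bayes factors multiply, and the posterior
probability that SNP k is the shared causal variant is the normalized
prior-weighted product.  Everything is computed in log space with a
log-sum-exp normalization, so |z| of GWAS magnitude cannot overflow.

This is a deliberate simplification of annotation-aware multi-causal
fine-mapping frameworks: with exactly one causal variant the marginal
z-score at the causal SNP is sufficient for ranking, and an LD matrix,
when supplied, is carried for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_PRIOR_VARIANCE = 10.0


@dataclass
class LocusData:
    """z-scores for both traits at the SNPs of one genomic region.

    ``prior`` defaults to uniform over the SNPs; ``ld``, when given,
    must be square/symmetric with unit diagonal and is used only for
    reporting alongside the posteriors.
    """

    snp_id: list
    pos: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    ld: np.ndarray | None = None
    prior_variance: float = DEFAULT_PRIOR_VARIANCE
    prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.z1 = np.asarray(self.z1, dtype=float)
        self.z2 = np.asarray(self.z2, dtype=float)
        k = len(self.snp_id)
        if k < 1:
            raise ValueError("locus must contain at least one SNP")
        if not (len(self.pos) == len(self.z1) == len(self.z2) == k):
            raise ValueError("locus field lengths disagree")
        if self.prior_variance <= 0:
            raise ValueError("prior variance W must be > 0")
        if self.ld is not None:
            ld = np.asarray(self.ld, dtype=float)
            if ld.shape != (k, k) or not np.allclose(ld, ld.T) or not np.allclose(
                np.diag(ld), 1.0
            ):
                raise ValueError("LD matrix must be symmetric with unit diagonal")
            self.ld = ld
        if self.prior is None:
            self.prior = np.full(k, 1.0 / k)
        else:
            self.prior = np.asarray(self.prior, dtype=float)
            if len(self.prior) != k or (self.prior < 0).any() or self.prior.sum() <= 0:
                raise ValueError("prior must be a non-negative vector over the locus SNPs")
            self.prior = self.prior / self.prior.sum()


@dataclass
class FineMapResult:
    """Per-SNP Bayes factors and causal posterior probabilities."""

    table: pd.DataFrame  # snp_id, pos, z1, z2, log_bf1, log_bf2, log_bf, posterior
    map_snp: str

    @property
    def posteriors(self) -> np.ndarray:
        return self.table["posterior"].to_numpy()


def log_abf(z, W: float):
    """log approximate Bayes factor (alternative vs null) for a z-score."""
    if W <= 0:
        raise ValueError("prior variance W must be > 0")
    z = np.asarray(z, dtype=float)
    return 0.5 * np.log(1.0 / (1.0 + W)) + (z**2) * W / (2.0 * (1.0 + W))


def abf(z, W: float):
    """Approximate Bayes factor; see :func:`log_abf` for the formula."""
    return np.exp(log_abf(z, W))


def shared_causal_posterior(locus: LocusData) -> FineMapResult:
    """Posterior probability that each SNP is the shared causal variant.

    BF_k = ABF(z1_k, W) * ABF(z2_k, W); posterior_k proportional to
    prior_k * BF_k, normalized over the locus via log-sum-exp.  The MAP
    SNP is the argmax, ties broken by smaller position.

    Raises
    ------
    ValueError
        On non-finite z-scores.
    """
    if not (np.isfinite(locus.z1).all() and np.isfinite(locus.z2).all()):
        raise ValueError("non-finite z-score in locus")
    W = locus.prior_variance
    lbf1 = log_abf(locus.z1, W)
    lbf2 = log_abf(locus.z2, W)
    lbf = lbf1 + lbf2
    with np.errstate(divide="ignore"):
        log_w = lbf + np.log(locus.prior)
    a = log_w.max()
    post = np.exp(log_w - a)
    post /= post.sum()

    best = np.flatnonzero(post == post.max())
    map_idx = best[np.argmin(locus.pos[best])]
    table = pd.DataFrame(
        {
            "snp_id": locus.snp_id,
            "pos": locus.pos,
            "z1": locus.z1,
            "z2": locus.z2,
            "log_bf1": lbf1,
            "log_bf2": lbf2,
            "log_bf": lbf,
            "posterior": post,
        }
    )
    return FineMapResult(table=table, map_snp=str(locus.snp_id[map_idx]))


def read_locus(path, ld_path=None, prior_variance: float = DEFAULT_PRIOR_VARIANCE) -> LocusData:
    """Read a locus TSV (snp_id, pos, z1, z2) and optional square LD matrix TSV."""
    df = pd.read_csv(path, sep="\t")
    for col in ("snp_id", "pos", "z1", "z2"):
        if col not in df.columns:
            raise ValueError(f"locus file missing column {col!r}")
    ld = None
    if ld_path is not None:
        ld = pd.read_csv(ld_path, sep="\t", header=None).to_numpy(dtype=float)
    return LocusData(
        snp_id=df["snp_id"].astype(str).tolist(),
        pos=df["pos"].to_numpy(),
        z1=df["z1"].to_numpy(),
        z2=df["z2"].to_numpy(),
        ld=ld,
        prior_variance=prior_variance,
    )
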