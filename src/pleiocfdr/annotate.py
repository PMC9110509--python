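"""Offline SNP annotation, novelty flagging and Manhattan-plot tables.

Significant cFDR SNPs are mapped to genes from a user-supplied BED file
(containment first, otherwise nearest gene within a distance cap) and
compared, together with their high-LD proxies, against a user-supplied
catalog of previously reported associations to separate known from
potentially novel hits.  The original analyses of this kind query live
web databases; everything here runs from offline files so results are
reproducible.

Coordinate conventions: BED intervals are 0-based half-open; SNP
positions are 1-based (converted internally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MAX_DIST = 100_000
GWAS_P = 5e-8
PROXY_R2 = 0.8
REFERENCE_NEGLOG_FDR = 1.3  # -log10(0.05), the significance guide line


@dataclass(frozen=True)
class GeneInterval:
    gene_symbol: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_symbol}: start must be < end")


def read_gene_bed(path) -> list[GeneInterval]:
    """Parse a BED file of gene intervals (chrom, start, end, name).

    Raises
    ------
    ValueError
        On malformed lines, naming the line number.
    """
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >= 4 BED columns")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer interval") from exc
            if start_i >= end_i:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            genes.append(
                GeneInterval(name, chrom.removeprefix("chr"), start_i, end_i)
            )
    return genes


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes: list[GeneInterval],
    max_dist: int = DEFAULT_MAX_DIST,
) -> pd.DataFrame:
    """Assign genes to SNPs: containment, else nearest within ``max_dist``.

    ``snps`` needs columns snp_id, chrom, pos (1-based).  A SNP inside
    one or more intervals gets all overlapping genes at distance 0;
    otherwise the nearest gene within ``max_dist`` base pairs of an
    interval edge; otherwise no assignment.  Ties are broken by
    (distance, gene_symbol lexicographic); genes need not be sorted.

    Returns one row per (snp, gene) assignment with the edge distance,
    ordered per SNP by the tie-break key.
    """
    gene_df = pd.DataFrame(
        {
            "gene_symbol": [g.gene_symbol for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
        }
    )
    rows = []
    for _, snp in snps.iterrows():
        pos0 = int(snp["pos"]) - 1  # convert 1-based SNP to 0-based
        g = gene_df[gene_df["chrom"] == str(snp["chrom"])]
        if g.empty:
            continue
        inside = g[(g["start"] <= pos0) & (pos0 < g["end"])]
        if len(inside):
            chosen = inside.assign(distance=0)
        else:
            dist = np.where(
                pos0 < g["start"], g["start"] - pos0, np.maximum(pos0 - (g["end"] - 1), 0)
            )
            g2 = g.assign(distance=dist)
            g2 = g2[g2["distance"] <= max_dist]
            if g2.empty:
                continue
            chosen = g2[g2["distance"] == g2["distance"].min()]
        chosen = chosen.sort_values(["distance", "gene_symbol"], kind="mergesort")
        for _, gr in chosen.iterrows():
            rows.append(
                (snp["snp_id"], gr["gene_symbol"], int(gr["distance"]))
            )
    return pd.DataFrame(rows, columns=["snp_id", "gene_symbol", "distance"])


def flag_novel(
    hits: list[str],
    catalog: pd.DataFrame,
    proxies: dict[str, list[tuple[str, float]]] | None = None,
    p_gwas: float = GWAS_P,
    r2_proxy: float = PROXY_R2,
    trait: str | None = None,
) -> pd.DataFrame:
    """Flag each hit as KNOWN or NOVEL against a reported-association catalog.

    A hit is KNOWN if it — or any LD proxy with r² strictly above
    ``r2_proxy`` — appears in the catalog with reported p below
    ``p_gwas`` (optionally restricted to one trait label); otherwise
    NOVEL.  ``catalog`` needs columns snp_id, trait, p.
    """
    cat = catalog
    if trait is not None:
        cat = cat[cat["trait"] == trait]
    known_set = set(cat.loc[cat["p"] < p_gwas, "snp_id"])
    proxies = proxies or {}
    rows = []
    for snp in hits:
        known = snp in known_set
        if not known:
            for proxy, r2 in proxies.get(snp, []):
                if r2 > r2_proxy and proxy in known_set:
                    known = True
                    break
        rows.append((snp, "KNOWN" if known else "NOVEL"))
    return pd.DataFrame(rows, columns=["snp_id", "status"])


def manhattan_data(records: pd.DataFrame, mode: str = "conjunction") -> tuple[pd.DataFrame, dict]:
    """Plot-ready Manhattan table of -log10 FDR values.

    ``mode`` selects the FDR column: "1_given_2", "2_given_1" or
    "conjunction" (ccfdr).  Chromosomes are laid out consecutively: the
    x-coordinate is the raw position plus the cumulative maximum
    position of all preceding chromosomes.  Metadata carries the
    reference guide line at -log10(0.05) = 1.3.
    """
    col = {"1_given_2": "cfdr_1_given_2", "2_given_1": "cfdr_2_given_1", "conjunction": "ccfdr"}[
        mode
    ]
    from pleiocfdr.sumstats import _chrom_key

    key, chrom = _chrom_key(records["chrom"])
    df = records.assign(_ck=key.to_numpy(), chrom=chrom.to_numpy()).sort_values(
        ["_ck", "pos"], kind="mergesort"
    )
    offset = 0
    xs = np.empty(len(df), dtype=np.int64)
    color = np.empty(len(df), dtype=np.int64)
    for ci, (_, grp) in enumerate(df.groupby("_ck", sort=True)):
        idx = df.index.get_indexer(grp.index)
        xs[idx] = grp["pos"].to_numpy() + offset
        color[idx] = ci % 2
        offset += int(grp["pos"].max())
    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"].to_numpy(),
            "chrom": df["chrom"].to_numpy(),
            "x": xs,
            "neglog10_fdr": -np.log10(df[col].to_numpy()),
            "color_index": color,
        }
    )
    meta = {"mode": mode, "reference_line": REFERENCE_NEGLOG_FDR}
    return out.reset_index(drop=True), meta
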