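"""Reading and writing LD reference panels (dosage TSV and VCF)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from pleiocfdr.ldprune import LdPanel

_META_COLS = ["snp_id", "chrom", "pos", "maf"]


def write_dosage_tsv(panel: LdPanel, path) -> None:
    """Tab-delimited panel: metadata columns then one dosage column per sample."""
    n = panel.dosages.shape[1]
    meta = panel.meta[[c for c in _META_COLS if c in panel.meta.columns]]
    samples = pd.DataFrame(
        panel.dosages, columns=[f"sample{j + 1}" for j in range(n)], index=meta.index
    )
    pd.concat([meta, samples], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path) -> LdPanel:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta_cols = [c for c in _META_COLS if c in df.columns]
    for col in ("snp_id", "chrom", "pos"):
        if col not in meta_cols:
            raise ValueError(f"dosage matrix {path}: missing metadata column {col!r}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    meta = df[meta_cols].copy()
    meta["chrom"] = meta["chrom"].astype(str)
    dosages = df[sample_cols].to_numpy(dtype=float)
    return LdPanel(dosages, meta)


def read_panel_vcf(path) -> LdPanel:
    """Build a dosage panel from the GT field of a VCF."""
    rows, meta = [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            dose = np.full(len(samples), np.nan)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is not None and None not in gt:
                    dose[i] = sum(1 for a in gt if a and a > 0)
            rows.append(dose)
            meta.append((rec.id or f"{rec.chrom}:{rec.pos}", str(rec.chrom), rec.pos))
    if not rows:
        raise ValueError(f"no variant records in {path}")
    dosages = np.array(rows)
    meta_df = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos"])
    freq = np.nanmean(dosages, axis=1) / 2.0
    meta_df["maf"] = np.minimum(freq, 1.0 - freq)
    return LdPanel(dosages, meta_df)


def write_panel_vcf(panel: LdPanel, path) -> None:
    """Render a dosage panel as an unphased biallelic VCF (A/G placeholder alleles)."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in pd.unique(panel.meta["chrom"].astype(str)):
        end = int(panel.meta.loc[panel.meta["chrom"].astype(str) == chrom, "pos"].max()) + 1
        header.contigs.add(chrom, length=end)
    n = panel.dosages.shape[1]
    for j in range(n):
        header.add_sample(f"sample{j + 1}")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, row in panel.meta.reset_index(drop=True).iterrows():
            rec = vcf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=("A", "G"),
                id=str(row["snp_id"]),
            )
            for j in range(n):
                d = panel.dosages[i, j]
                if np.isnan(d):
                    rec.samples[j]["GT"] = (None, None)
                else:
                    d = int(round(d))
                    rec.samples[j]["GT"] = (1, 1) if d == 2 else ((0, 1) if d == 1 else (0, 0))
            vcf.write(rec)
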