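"""Fine-map the strongest conjunction locus under a shared-causal-variant model.

Takes the top ccFDR SNP from 04_cfdr_conjunction.py, extracts the
surrounding window of SNPs, and computes each SNP's posterior
probability of being the single causal variant shared by both traits
(product of per-trait approximate Bayes factors, W = 10).
"""

from pathlib import Path

import pandas as pd

from pleiocfdr.finemap import LocusData, shared_causal_posterior
from pleiocfdr.plots import plot_finemap

ROOT = Path(__file__).resolve().parents[1]
WINDOW_SNPS = 50  # SNPs on each side of the index SNP


def main() -> None:
    out = ROOT / "results"
    records = pd.read_csv(out / "cfdr_records.tsv", sep="\t", dtype={"chrom": str})
    top = records.loc[records["ccfdr"].idxmin()]
    region = records[records["chrom"] == top["chrom"]].reset_index(drop=True)
    center = int(region.index[region["snp_id"] == top["snp_id"]][0])
    locus_df = region.iloc[max(0, center - WINDOW_SNPS): center + WINDOW_SNPS + 1]

    from pleiocfdr.sumstats import z_from_p

    locus = LocusData(
        snp_id=locus_df["snp_id"].tolist(),
        pos=locus_df["pos"].to_numpy(),
        z1=z_from_p(locus_df["p1"].to_numpy()),
        z2=z_from_p(locus_df["p2"].to_numpy()),
    )
    result = shared_causal_posterior(locus)
    result.table.to_csv(out / "finemap_posteriors.tsv", sep="\t", index=False)
    plot_finemap(result.table, out / "finemap.png")

    best = result.table.loc[result.table["posterior"].idxmax()]
    print(f"locus around {top['snp_id']} (chr{top['chrom']}, {len(locus_df)} SNPs): "
          f"MAP SNP {result.map_snp} with posterior {best['posterior']:.3f}")


if __name__ == "__main__":
    main()
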