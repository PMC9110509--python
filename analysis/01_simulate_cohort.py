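"""Simulate the paired-trait study: two summary-statistic panels + LD reference.

Generates a genome-scale pair of GWAS summary statistics under the
four-group mixture (2% pleiotropic SNPs, sigma = 3) together with a
block-LD genotype panel, and writes everything under results/data/.
"""

import argparse
from pathlib import Path

from pleiocfdr.panel_io import write_dosage_tsv, write_panel_vcf
from pleiocfdr.simulate import (
    SimulationConfig,
    simulate_genotype_panel,
    simulate_two_trait_sumstats,
)
from pleiocfdr.sumstats import write_sumstats

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--m", type=int, default=100_000)
    parser.add_argument("--panel-m", type=int, default=2_000)
    args = parser.parse_args()

    out = ROOT / "results" / "data"
    out.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(m=args.m, seed=args.seed)
    t1, t2, truth = simulate_two_trait_sumstats(cfg)
    t1.trait_label, t2.trait_label = "LS-BMD-like", "BW-like"
    write_sumstats(t1, out / "trait1.sumstats.tsv")
    write_sumstats(t2, out / "trait2.sumstats.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    panel_cfg = SimulationConfig(m=args.panel_m, n_samples=500, rho_block=0.8,
                                 block_size=50, seed=args.seed)
    panel = simulate_genotype_panel(panel_cfg)
    write_dosage_tsv(panel, out / "panel.dosage.tsv")
    write_panel_vcf(panel, out / "panel.vcf")

    n_pleio = int((truth["component"] == "11").sum())
    print(f"wrote {args.m} SNPs per trait ({n_pleio} truly pleiotropic) "
          f"and a {args.panel_m}-SNP x {panel_cfg.n_samples}-sample LD panel -> {out}")


if __name__ == "__main__":
    main()
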