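"""Thin the LD reference panel with sliding-window r² pruning (50 / 5 / 0.2).

Reads the panel written by 01_simulate_cohort.py, prunes so that no
window of 50 consecutive retained SNPs contains a pair with r² > 0.2
(removing the smaller-MAF member), and writes the retained list plus a
removal audit.
"""

from pathlib import Path

from pleiocfdr.ldprune import window_prune
from pleiocfdr.panel_io import read_dosage_tsv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "results" / "data"
    panel = read_dosage_tsv(data / "panel.dosage.tsv")
    result = window_prune(panel, window=50, step=5, r2_max=0.2)

    out = ROOT / "results"
    (out / "retained_snps.txt").write_text("\n".join(result.retained) + "\n")
    result.removals.to_csv(out / "prune_removals.tsv", sep="\t", index=False)
    print(f"retained {len(result.retained)} / {len(panel)} panel SNPs; "
          f"removals logged with partner and offending r2")


if __name__ == "__main__":
    main()
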