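#!/usr/bin/env python
"""Plasma-EV proteomics group comparison at the study's scale.

Generates a synthetic 1150-protein, 8-early vs 8-metastatic intensity
table with 16 planted differential proteins at the reported top effect
(log2FC 2.47), runs the mean-based fold changes with two-sided unpaired
t-tests and writes the volcano-classified table.
"""

import argparse
from pathlib import Path

from evsort.io import ensure_dir, write_intensity_table, write_results
from evsort.proteomics import ttest_volcano
from evsort.simulate import generate_intensity_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    table, truth = generate_intensity_table(
        n_proteins=1150, n_per_group=8, n_signal=16, effect_log2=2.47,
        noise_sd=1.0, seed=args.seed)
    out = ensure_dir(args.out)
    write_intensity_table(table, out / "protein_intensities.tsv",
                          out / "protein_groups.tsv")
    res = ttest_volcano(table, alpha=0.05)
    write_results(res, out / "protein_stats.tsv", index_label="protein_id")

    n_sig = int(res["significant"].sum())
    n_up = int((res["direction"] == "up").sum())
    sens = res.loc[truth, "significant"].mean()
    print(f"{n_sig} of {len(res)} proteins significant at raw p < 0.05 "
          f"({n_up} up in metastatic)")
    print(f"planted proteins recovered at {sens:.2f} sensitivity; mean "
          f"estimated log2FC {res.loc[truth, 'log2fc'].mean():.3f} "
          "(planted 2.47)")


if __name__ == "__main__":
    main()
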