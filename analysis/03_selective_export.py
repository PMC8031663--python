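#!/usr/bin/env python
"""Classify selectively exported miRNAs by fold enrichment.

Joins the EV and cell log2FC tables (from 02_differential_abundance.py),
computes FE = log2FC_EV - log2FC_cell and flags miRNAs with
log2FC_EV <= -1 and FE <= -0.5. Compares the flags with the planted truth
when available.
"""

import argparse
from pathlib import Path

import pandas as pd

from evsort.export import ExportConfig, classify_selective_export, \
    merge_contrasts
from evsort.io import write_results


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    ev = pd.read_csv(args.results / "differential_EV.tsv", sep="\t", index_col=0)
    cell = pd.read_csv(args.results / "differential_cell.tsv", sep="\t",
                       index_col=0)
    out = classify_selective_export(merge_contrasts(ev, cell), ExportConfig())
    write_results(out, args.results / "selective_export.tsv",
                  index_label="mirna_id")
    n_sel = int(out["selected"].sum())
    print(f"{n_sel} of {len(out)} miRNAs classified as selectively exported "
          "(log2FC_EV <= -1 and FE <= -0.5)")

    truth_path = args.results / "data" / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col=0)
        exported = set(truth.index[truth["is_exported"]])
        selected = set(out.index[out["selected"]])
        tp = len(exported & selected)
        print(f"truth: sensitivity {tp / len(exported):.3f}, "
              f"false-discovery proportion "
              f"{(len(selected - exported) / len(selected)) if selected else 0:.3f}")


if __name__ == "__main__":
    main()
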