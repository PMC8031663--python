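#!/usr/bin/env python
"""Filter, normalize and test the simulated counts per compartment.

Reads results/data/ (from 01_simulate.py), removes miRNAs with fewer than
20 total counts, estimates median-of-ratios size factors and one RUV
factor from empirical controls, fits the per-miRNA NB model and writes the
CAVIN1-vs-CONT log2 fold-change tables for the EV and cell compartments.
"""

import argparse
from pathlib import Path

from evsort.diffabund import (DiffConfig, estimate_size_factors,
                              filter_low_counts, nb_differential,
                              ruv_normalize, select_empirical_controls)
from evsort.io import ensure_dir, read_count_table, write_results


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    counts = read_count_table(args.data / "counts.tsv",
                              args.data / "sample_meta.tsv")
    cfg = DiffConfig()
    filtered = filter_low_counts(counts, cfg.min_total_count)
    print(f"{len(filtered.mirna_ids)} of {len(counts.mirna_ids)} miRNAs "
          f"retained at total count >= {cfg.min_total_count}")

    out = ensure_dir(args.out)
    for comp in ("EV", "cell"):
        sub = filtered.compartment(comp)
        sf = estimate_size_factors(sub)
        controls = select_empirical_controls(sub, cfg.n_empirical_controls,
                                             size_factors=sf, config=cfg)
        offsets = ruv_normalize(sub, controls, cfg.ruv_k, size_factors=sf)
        res = nb_differential(sub, offsets, cfg, size_factors=sf)
        write_results(res, out / f"differential_{comp}.tsv",
                      index_label="mirna_id")
        n_sig = int((res["bh_q"] < cfg.alpha).sum())
        print(f"{comp}: {len(res)} tested, {n_sig} at BH q < {cfg.alpha}")


if __name__ == "__main__":
    main()
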