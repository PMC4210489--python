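#!/usr/bin/env python
"""Lineage-through-time curves of the simulated chronogram sample.

Reads results/fixture/trees.nwk, writes the first tree's LTT curve and the
pointwise-median curve over all replicates (the summary the replicate LTT
figure is built from) to results/ltt/.
"""

import argparse
from pathlib import Path

import numpy as np

from divshift.trees import ltt_curve, median_ltt, read_trees, write_ltt_tsv


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--trees", default="results/fixture/trees.nwk")
    ap.add_argument("--out", default="results/ltt")
    args = ap.parse_args()

    chronos = read_trees(args.trees, "newick")
    curves = [ltt_curve(c) for c in chronos]
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    write_ltt_tsv(curves[0], out / "ltt_main.tsv")
    grid = np.linspace(0.0, max(c.crown_age for c in chronos), 512)
    med = median_ltt(curves, grid)
    write_ltt_tsv(med, out / "ltt_median.tsv")

    # where does the median curve reach half its final (log-)height?
    n0 = med.counts[0]
    print(f"{len(chronos)} trees; main tree n={chronos[0].n_tips}, "
          f"crown {chronos[0].crown_age:.1f} Ma")
    print(f"median LTT: {n0:.0f} lineages at present, "
          f"{med.count_at([50.0])[0]:.0f} at 50 Ma, {med.count_at([103.0])[0]:.0f} at 103 Ma")
    print(f"wrote {out}/ltt_main.tsv and {out}/ltt_median.tsv")


if __name__ == "__main__":
    main()
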