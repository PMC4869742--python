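#!/usr/bin/env python
"""Per-subset pairwise correlations for every built-in partition.

For each of the five partitions (polyamine class, meJAS class, mulch
system, and black-plastic vs hairy-vetch within each polyamine class),
computes Pearson r, pairwise n, and Fisher z for every retained metabolite
pair in both subsets — the long-format listing downstream stages consume.
Writes results/correlations.csv.
"""

from pathlib import Path

import pandas as pd

from diffcornet import builtin_partitions, pairwise_correlations, read_metabolite_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_metabolite_table(RESULTS / "synthetic_table.csv")
    frames = []
    for scheme in builtin_partitions():
        ids_a, ids_b = scheme.apply(table)
        for ids, label in ((ids_a, scheme.subset_a_label),
                           (ids_b, scheme.subset_b_label)):
            cs = pairwise_correlations(table, ids, label=label)
            long = cs.to_long_frame()
            long.insert(0, "partition", scheme.name)
            frames.append(long)
            print(f"{scheme.name} / {label}: n={len(ids)}, "
                  f"{len(cs.pairs)} pairs retained")
    out = RESULTS / "correlations.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
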