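#!/usr/bin/env python
"""Chemical-group summaries of standardized metabolite levels.

Standardizes each metabolite to mean 0 / SD 1 (equal weighting), then
averages standardized values within chemical groups per mulch system and
per genotype — the first-moment summary that motivates the later
correlation-level analysis. Writes results/group_means_{mulch,genotype}.csv.
"""

from pathlib import Path

from diffcornet import group_standardized_means, read_metabolite_table, standardize

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = standardize(read_metabolite_table(RESULTS / "synthetic_table.csv"))
    for factor in ("mulch", "genotype"):
        means = group_standardized_means(table, factor)
        out = RESULTS / f"group_means_{factor}.csv"
        means.to_csv(out)
        print(f"wrote {out}")
        print(means.round(3).to_string(), "\n")
    print(
        "With no planted mean shifts the group means hover near zero; "
        "the planted signals in this dataset are second-moment (correlation) "
        "changes, invisible to this summary."
    )


if __name__ == "__main__":
    main()
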