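#!/usr/bin/env python
"""Generate the study-shaped synthetic dataset used by the later steps.

Emulates the field trial: 7 tomato genotypes × 4 mulch systems × 2 years
× 2 fruit stages × 3 replicates (bare soil in 2007 only), 30 NMR-profiled
metabolites plus the uncharacterized "B". Three correlation changes are
planted — one per main partition — so the downstream steps have known
signals to find:

  ALA–CIT   r 0.1 -> 0.7 from low- to high-polyamine genotypes
  GABA–SUCC r 0.6 -> 0.0 from meJAS-deficient to normal genotypes
  FRU–bGLC  r 0.1 -> 0.6 from bare/black-plastic to cover-crop mulches

Writes results/synthetic_table.csv.
"""

from pathlib import Path

from diffcornet import PlantedChange, simulate_table, study_spec, write_metabolite_table

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2006

PLANTED = (
    PlantedChange(("ALA", "CIT"), 0.1, 0.7, "polyamine"),
    PlantedChange(("GABA", "SUCC"), 0.6, 0.0, "mejas"),
    PlantedChange(("FRU", "bGLC"), 0.1, 0.6, "mulch"),
)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = study_spec(seed=SEED, replicates=3, planted=PLANTED)
    table = simulate_table(spec)
    out = RESULTS / "synthetic_table.csv"
    write_metabolite_table(table, out)
    print(f"wrote {out}")
    print(f"  {table.n_samples} samples × {len(table.metabolites)} metabolites")
    print(f"  planted changes: {[(c.pair, c.r_a, c.r_b, c.partition) for c in PLANTED]}")


if __name__ == "__main__":
    main()
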