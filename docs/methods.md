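# Methods

## Model and procedure

The pipeline treats a metabolomics experiment as a wide table: one row per
fruit sample, one column per metabolite concentration (arbitrary units —
all statistics used are scale-invariant or computed after explicit
standardization), plus categorical factors (genotype, mulch system, year,
fruit stage, replicate). The analysis proceeds in four stages.

**1. Standardization and group means (first moments).** Each metabolite is
scaled to mean 0, SD 1 over its non-missing values, using the sample SD
(n−1 denominator). Standardized values are averaged within chemical groups
(amino acids, organic acids, sugars, energy metabolites, other) per factor
level. This is a descriptive summary; the package deliberately does not
fit the mixed-model ANOVAs that a full field-trial analysis would add,
since its focus is the correlation layer.

**2. Per-subset correlations.** For each side of a partition (a named
binary split of samples by factor levels), Pearson r is computed for every
unordered metabolite pair over pairwise-complete observations, with the
pairwise n recorded and carried into the change test. Pairs are dropped
from a subset when n < n_min (default 4 — the change test needs n − 3 > 0,
plus one observation of slack) or when either member has zero variance on
the joint support. Pairs with |r| = 1 keep their r but are flagged
saturated and excluded from all Fisher-z analyses: clamping them would
manufacture arbitrary z magnitudes. The uncharacterized metabolite coded
"B" is excluded from pairing entirely. Correlations are computed on raw
concentrations; Pearson r is invariant to positive affine rescaling, so
standardizing first would change nothing.

**3. Change test and differential network.** For a pair retained in both
subsets, the no-change hypothesis is tested with
q = (z_B − z_A)/√(1/(n_A−3) + 1/(n_B−3)), p = 2(1 − Φ(|q|)), where
z = atanh(r). Significance defaults to raw two-tailed P < 0.05;
Benjamini–Hochberg FDR is available (`multiplicity="bh"`) for users who
prefer multiplicity control over per-pair error. Each significant edge
records Δr, Δz, q, p, a direction (increase iff Δz > 0 — defined by the
sign of Δz so that negative correlations are handled coherently), a color
(blue = increase, red = decrease by default; a swap flag inverts the
convention since published figure captions disagree with their methods
text on this), and a display width mapped linearly from |Δr| with anchors
0.1 → 1.0 and 0.7 → 7.0, clamped outside. Subset A is always the
reference ("from") side; the built-in partitions orient low → high
polyamine, deficient → normal meJAS, bare+black-plastic → cover-crop
mulch, and black-plastic → hairy-vetch. Networks export as Cytoscape-
importable edge CSVs or GraphML with identical attributes.

**4. Stability map.** For every pair, the sample SD (n−1; with six values
the n vs n−1 choice shifts results ~10%, so it is fixed and stated) of its
z values across the six subsets of the three main partitions, skipping
subsets where the pair was excluded and dropping pairs usable in fewer
than three. The nested black-plastic vs hairy-vetch schemes are excluded
from this calculation to avoid double-counting samples. The companion
mean correlation is averaged on the r scale (it summarizes typical
association strength; the SD is on the z scale where sampling variance is
stabilized). Bins: sd_z < 0.19 → bin 1 (most stable, yellow);
sd_z > 0.35 → bin 5 (least stable, darkest red); the interior [0.19,
0.35] splits into three equal-width bins. The published thresholds fix
only the outer bins; the equal-width interior is this package's choice
for determinism. Bin-1/bin-5 membership is strict at the outer thresholds
and interior boundaries belong to the lower bin. Per-metabolite
stable-association counts use strict sd_z < 0.19.

## Built-in partitions

Genotype codes follow the study: low-polyamine lines {2, 5, 12} vs
high-polyamine {4, 8, 10, 20}; meJAS-deficient {12, 20} vs normal
{2, 4, 5, 8, 10}; mulches bare soil + black polyethylene vs hairy vetch +
rye. Partitions pool all other factors; bare soil exists only in the
second year and no year adjustment is made — subsets simply contain the
samples that match. The factor registry is user-extensible through the
pipeline config, but the built-in schemes require the study's levels and
fail loudly otherwise.

## Synthetic data generator

The generator emulates the study's structure: a factorial design of 7
genotypes × 4 mulches × 2 years × 2 fruit stages × r replicates (bare
soil in 2007 only; default r = 3 → 294 samples), 30 named metabolites in
the study's chemical groups plus the excluded "B". Concentrations are
multivariate normal with a group-block base correlation (0.4 within a
chemical group, 0.1 between — moderate within-pathway coupling typical of
primary-metabolite panels), shifted/scaled to per-group concentration
means and SDs (sugars 50 ± 10, organic acids 20 ± 5, amino acids 10 ± 3,
energy and minor compounds 5 ± 1.5, arbitrary units). A planted change
ties a pair to a partition: samples on side A draw from a matrix with the
pair's correlation set to r_A, side B to r_B; matrices are repaired to
positive semi-definiteness by eigenvalue clipping and diagonal rescaling
(returned untouched when already valid). Missingness is injected
completely at random at a configurable rate (default 0). A log-normal
option (moment-matched to the same mean/SD) exists because real NMR
concentrations are non-negative, but analyses and tests use the Gaussian
path for analytic tractability.

Randomness: one integer seed drives a separate substream per metabolite
column (and per column for the missingness mask), so extending the
metabolite roster never perturbs previously generated columns, and
identical spec + seed reproduces tables bit for bit.

What the generator does *not* emulate: mean shifts between treatments
(planted signals are purely second-moment), replicate/block random
effects, year-by-treatment interactions, non-Gaussian tails, informative
missingness, or quantification error. Passing recovery tests therefore
demonstrates that the pipeline detects correlation changes of the planted
size at the study's ns under clean conditions; they say nothing about
robustness to outliers or structured noise in real spectra.

## Numerical choices

- Canonical ordering: tables sort samples by id and metabolites by code at
  construction, making every downstream number exactly invariant to input
  row/column order and pipeline outputs byte-reproducible.
- Missing cells: blank, `NA`, `NaN` accepted at load; any other
  non-numeric concentration is a hard error naming row and column.
- Saturated pairs error in the change test rather than being clamped; the
  caller must filter (the network builder does).
- Matrix repair uses a single eigenvalue-clip + rescale projection, exact
  when few eigenvalues are negative — always the case for block matrices
  with a handful of planted overrides; Cholesky factorization adds 1e-12
  jitter on the diagonal.
- A sample SD of six z-draws has expectation c₄(6)·σ ≈ 0.952·σ, slightly
  below the Fisher sampling SD √(1/(n−3)); calibration checks therefore
  compare the mean pair sd_z at Monte-Carlo tolerance rather than
  expecting exact equality.

## Problem sizes in the checks

The statistical checks run at the sizes the method targets: n = 40 per
subset (2,000 replicates) for type-I calibration, n = 40 (1,000
replicates) for power against the closed form Φ(|Δζ|/SE − z₀.₀₂₅) ≈ 0.971
at ρ 0.2 → 0.8, n = 100 per subset for recovery of three planted
|Δρ| = 0.6 changes among 20 metabolites, and six subsets of n = 200 for
stability calibration. The bundled pipeline fixture is a 28-sample,
one-replicate version of the factorial purely to exercise plumbing.

## Known limitations

- The change test is asymptotic; at n near n_min its size is only
  approximate, and heterogeneous subsets (mixtures of different
  correlation regimes, as arise in nested contrasts of this design)
  genuinely overdisperse r̂ beyond the Fisher variance, inflating edge
  counts — a property of the data structure, not a software artifact.
- Raw P < 0.05 across ~435 pairs implies ~22 expected false edges per
  partition; the BH option trades that for FDR control.
- Stability with six subsets is a high-variance statistic; its bins are
  descriptive, not inferential.
- No partial correlations, robust/rank correlations, or graphical models;
  the analysis characterizes marginal pairwise association changes only.
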