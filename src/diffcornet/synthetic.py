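"""Synthetic metabolite tables with planted correlation differences.

The generator emulates the study's data structure — a factorial field
design (7 genotypes × 4 mulch systems × 2 years × 2 fruit stages ×
replicates, bare soil present in the second year only) with ~30 NMR-
profiled metabolites in four chemical groups — and lets tests plant known
*changes* in pairwise correlation between the two sides of any built-in
partition. Concentrations are multivariate normal (optionally log-normal)
with a per-subset correlation matrix, shifted and scaled to per-metabolite
concentration means and SDs, with optional missingness completely at
random.

Randomness is driven by one global seed through per-column substreams, so
adding a metabolite to a spec never perturbs the values of earlier
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    FactorRegistry,
    MetaboliteRegistry,
    MetaboliteTable,
    PartitionScheme,
    builtin_partitions,
    get_partition,
)
from .errors import ConfigError, DataValidationError

# concentration scales per chemical group (arbitrary NMR-derived units):
# sugars dominate fruit pericarp extracts, amino and organic acids are
# intermediate, energy metabolites and minor compounds are low-abundance.
_GROUP_MEAN = {"sugar": 50.0, "organic acid": 20.0, "amino acid": 10.0,
               "energy": 5.0, "other": 5.0}
_GROUP_SD = {"sugar": 10.0, "organic acid": 5.0, "amino acid": 3.0,
             "energy": 1.5, "other": 1.5}


def nearest_correlation_repair(matrix: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Repair a symmetric unit-diagonal matrix into a valid correlation matrix.

    Eigenvalues are clipped at ``eps`` (default 0) and the reconstruction
    rescaled to unit diagonal — one Higham-style projection step, which is
    exact whenever only a few eigenvalues are negative. A matrix that is
    already positive semi-definite is returned unchanged.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigError(f"correlation matrix must be square; got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ConfigError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise ConfigError("correlation matrix must have unit diagonal")
    w = np.linalg.eigvalsh(m)
    if w.min() >= -1e-12:
        return m.copy()
    w, v = np.linalg.eigh(m)
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


@dataclass(frozen=True)
class PlantedChange:
    """A known correlation difference between the two sides of a partition."""

    pair: tuple[str, str]
    r_a: float
    r_b: float
    partition: str

    def __post_init__(self):
        if not (-1 < self.r_a < 1 and -1 < self.r_b < 1):
            raise ConfigError(
                f"planted correlations must lie in (-1, 1); got "
                f"({self.r_a}, {self.r_b}) for pair {self.pair}"
            )

    @property
    def delta_r(self) -> float:
        return self.r_b - self.r_a


@dataclass(frozen=True)
class DesignCell:
    genotype: str
    mulch: str
    year: str
    stage: str
    replicates: int


def study_design(
    replicates: int = 3,
    genotypes: Sequence[str] = ("2", "4", "5", "8", "10", "12", "20"),
    mulches: Sequence[str] = ("BP", "HV", "RY", "BS"),
    years: Sequence[str] = ("2006", "2007"),
    stages: Sequence[str] = ("pink", "red"),
) -> list[DesignCell]:
    """The study's factorial design; bare soil ran in 2007 only."""
    cells = []
    for g in genotypes:
        for m in mulches:
            for y in years:
                if m == "BS" and y != "2007":
                    continue
                for s in stages:
                    cells.append(DesignCell(g, m, y, s, replicates))
    return cells


def two_group_design(n_a: int, n_b: int) -> list[DesignCell]:
    """Minimal design with n_a low-polyamine and n_b high-polyamine samples.

    Uses genotypes 2 (subset A of the polyamine partition) and 8 (subset
    B); handy for planting a single two-subset contrast.
    """
    return [
        DesignCell("2", "BP", "2006", "red", n_a),
        DesignCell("8", "BP", "2006", "red", n_b),
    ]


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete recipe for one synthetic metabolite table."""

    metabolites: tuple[str, ...]
    groups: Mapping[str, str]
    design: tuple[DesignCell, ...]
    base_correlation: np.ndarray
    planted: tuple[PlantedChange, ...] = ()
    means: Mapping[str, float] | None = None
    sds: Mapping[str, float] | None = None
    missing_rate: float = 0.0
    seed: int = 0
    lognormal: bool = False

    def __post_init__(self):
        if len(set(self.metabolites)) != len(self.metabolites):
            raise ConfigError("duplicate metabolite codes in spec")
        k = len(self.metabolites)
        if self.base_correlation.shape != (k, k):
            raise ConfigError(
                f"base correlation is {self.base_correlation.shape}, need ({k}, {k})"
            )
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must lie in [0, 1)")
        roster = set(self.metabolites)
        for ch in self.planted:
            if ch.pair[0] not in roster or ch.pair[1] not in roster:
                raise ConfigError(f"planted change references unknown pair {ch.pair}")
            if ch.pair[0] == ch.pair[1]:
                raise ConfigError("planted change must reference two distinct metabolites")
            get_partition(ch.partition)  # raises on unknown name

    def registry(self) -> MetaboliteRegistry:
        return MetaboliteRegistry.from_tuples(
            ((m, m, self.groups.get(m, "other")) for m in self.metabolites),
            excluded=tuple(m for m in self.metabolites if m == "B") or ("B",),
        )

    def mean_of(self, code: str) -> float:
        if self.means is not None and code in self.means:
            return float(self.means[code])
        return _GROUP_MEAN[self.groups.get(code, "other")]

    def sd_of(self, code: str) -> float:
        if self.sds is not None and code in self.sds:
            return float(self.sds[code])
        return _GROUP_SD[self.groups.get(code, "other")]


def study_metabolite_groups(include_b: bool = True) -> dict[str, str]:
    """Code → chemical group for the study roster (optionally with ``B``)."""
    reg = MetaboliteRegistry.study_default()
    groups = {code: info.group for code, info in reg.entries.items()}
    if not include_b:
        groups.pop("B", None)
    return groups


def block_correlation(
    metabolites: Sequence[str],
    groups: Mapping[str, str],
    within: float = 0.4,
    between: float = 0.1,
) -> np.ndarray:
    """Group-block base correlation: ``within`` inside a chemical group,
    ``between`` across groups, repaired to positive semi-definiteness."""
    k = len(metabolites)
    g = [groups.get(m, "other") for m in metabolites]
    c = np.full((k, k), between)
    for i in range(k):
        for j in range(k):
            if g[i] == g[j]:
                c[i, j] = within
    np.fill_diagonal(c, 1.0)
    return nearest_correlation_repair(c)


def study_spec(
    seed: int = 0,
    replicates: int = 3,
    planted: Iterable[PlantedChange] = (),
    missing_rate: float = 0.0,
    include_b: bool = True,
) -> SyntheticSpec:
    """Default spec emulating the study: 30 metabolites (+ the excluded
    ``B``), group-block correlations, full factorial design."""
    groups = study_metabolite_groups(include_b=include_b)
    mets = tuple(sorted(groups))
    return SyntheticSpec(
        metabolites=mets,
        groups=groups,
        design=tuple(study_design(replicates=replicates)),
        base_correlation=block_correlation(mets, groups),
        planted=tuple(planted),
        missing_rate=missing_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _sample_factors(design: Sequence[DesignCell]) -> pd.DataFrame:
    rows = []
    for cell in design:
        for rep in range(1, cell.replicates + 1):
            sid = f"G{cell.genotype}_{cell.mulch}_{cell.year}_{cell.stage}_r{rep}"
            rows.append(
                (sid, cell.genotype, cell.mulch, cell.year, cell.stage, str(rep))
            )
    frame = pd.DataFrame(
        rows, columns=["sample_id", "genotype", "mulch", "year", "stage", "replicate"]
    ).set_index("sample_id")
    if frame.index.has_duplicates:
        raise ConfigError("design produces duplicate sample ids")
    return frame


def _subset_matrix(spec: SyntheticSpec, assignment: Mapping[str, str]) -> np.ndarray:
    """Base correlation with the planted overrides for one assignment combo."""
    idx = {m: i for i, m in enumerate(spec.metabolites)}
    c = spec.base_correlation.copy()
    for ch in spec.planted:
        side = assignment.get(ch.partition)
        if side is None:
            continue
        r = ch.r_a if side == "a" else ch.r_b
        i, j = idx[ch.pair[0]], idx[ch.pair[1]]
        c[i, j] = c[j, i] = r
    return nearest_correlation_repair(c)


def simulate_table(spec: SyntheticSpec) -> MetaboliteTable:
    """Draw one table from the spec; identical spec + seed ⇒ identical table.

    Each sample's metabolite vector is multivariate normal with the
    correlation matrix of its partition-assignment combination (base matrix
    plus any planted overrides that apply to it), then shifted/scaled to
    the per-metabolite concentration mean/SD (or mapped through a moment-
    matched log-normal when ``spec.lognormal``). Missing cells are injected
    completely at random at ``spec.missing_rate``.
    """
    factors = _sample_factors(spec.design)
    n, k = len(factors), len(spec.metabolites)

    # one substream per metabolite column: column j of the standard-normal
    # seed matrix depends only on (seed, j), never on k
    z = np.empty((n, k))
    for j in range(k):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, j]))
        z[:, j] = rng.standard_normal(n)

    # per-sample assignment over the partitions referenced by planted changes
    part_names = sorted({ch.partition for ch in spec.planted})
    schemes = {name: get_partition(name) for name in part_names}
    combos: dict[tuple, list[int]] = {}
    for pos, (_, row) in enumerate(factors.iterrows()):
        key = tuple(
            (name, schemes[name].assign(row)) for name in part_names
        )
        combos.setdefault(key, []).append(pos)

    x = np.empty((n, k))
    for key, positions in combos.items():
        c = _subset_matrix(spec, dict(key))
        try:
            L = np.linalg.cholesky(c + 1e-12 * np.eye(k))
        except np.linalg.LinAlgError as exc:
            raise DataValidationError(
                f"correlation matrix for combination {key} is not positive "
                f"definite after repair: {exc}"
            ) from exc
        x[positions] = z[positions] @ L.T

    mu = np.array([spec.mean_of(m) for m in spec.metabolites])
    sd = np.array([spec.sd_of(m) for m in spec.metabolites])
    if spec.lognormal:
        # moment-matched log-normal: E = mu, SD = sd, support (0, inf)
        s2 = np.log1p((sd / mu) ** 2)
        values = np.exp(np.log(mu) - s2 / 2 + np.sqrt(s2) * x)
    else:
        values = mu + sd * x

    if spec.missing_rate > 0:
        for j in range(k):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 1_000_003, j])
            )
            values[rng.random(n) < spec.missing_rate, j] = np.nan

    frame = pd.DataFrame(values, index=factors.index, columns=list(spec.metabolites))
    return MetaboliteTable(
        frame, factors, spec.registry(),
        FactorRegistry.study_default(),
    )


def ground_truth_edges(spec: SyntheticSpec, partition: str) -> list[PlantedChange]:
    """Planted changes of one partition with a genuine difference (Δr ≠ 0)."""
    get_partition(partition)
    return [
        ch for ch in spec.planted
        if ch.partition == partition and ch.r_a != ch.r_b
    ]


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    return replace(spec, seed=seed)
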