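"""Tabular data model for metabolite quantification tables.

The single input format of the pipeline is a wide table: one row per fruit
sample, one column per metabolite concentration (arbitrary NMR-derived
units), plus categorical factor columns describing the sample (genotype,
mulch system, year, fruit stage, replicate).

This module defines

* :class:`MetaboliteRegistry` — metabolite code -> full name, chemical
  group, and an exclusion flag (the uncharacterized metabolite ``B`` is
  excluded from all correlation analyses by default);
* :class:`FactorRegistry` — the declared categorical levels for genotype
  and mulch; unknown levels are rejected at load time;
* :class:`MetaboliteTable` — the validated container;
* :func:`read_metabolite_table` / :func:`write_metabolite_table` — delimited
  text I/O;
* :func:`standardize` — per-metabolite scaling to mean 0, SD 1 (sample SD,
  n−1 denominator);
* :func:`group_standardized_means` — chemical-group means of standardized
  values per factor level;
* :func:`builtin_partitions` — the study's binary sample splits (genotype
  polyamine class, methyl-jasmonate class, mulch system, and the nested
  black-plastic vs hairy-vetch contrasts within each polyamine class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataValidationError, ZeroVarianceError

logger = logging.getLogger(__name__)

#: Chemical groups used to summarize metabolites.
METABOLITE_GROUPS = ("amino acid", "organic acid", "sugar", "energy", "other")

#: Strings accepted as missing values in input files. Anything else
#: non-numeric in a concentration cell is a hard error.
NA_STRINGS = frozenset({"", "NA", "NaN", "nan"})


# ---------------------------------------------------------------------------
# registries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaboliteInfo:
    code: str
    name: str
    group: str
    excluded: bool = False

    def __post_init__(self):
        if self.group not in METABOLITE_GROUPS:
            raise ConfigError(
                f"unknown chemical group {self.group!r} for metabolite "
                f"{self.code!r}; expected one of {METABOLITE_GROUPS}"
            )


# The study's metabolite roster: 30 characterized metabolites profiled by
# NMR, in four chemical groups plus choline/nucleic-acid-related compounds,
# and the uncharacterized metabolite "B" which is excluded from correlation
# analyses.
_STUDY_METABOLITES: tuple[tuple[str, str, str], ...] = (
    ("ALA", "alanine", "amino acid"),
    ("ASN", "asparagine", "amino acid"),
    ("ASP", "aspartate", "amino acid"),
    ("GABA", "gamma-aminobutyrate", "amino acid"),
    ("GLN", "glutamine", "amino acid"),
    ("GLU", "glutamate", "amino acid"),
    ("HIS", "histidine", "amino acid"),
    ("ILE", "isoleucine", "amino acid"),
    ("PHE", "phenylalanine", "amino acid"),
    ("THR", "threonine", "amino acid"),
    ("TRP", "tryptophan", "amino acid"),
    ("TYR", "tyrosine", "amino acid"),
    ("VAL", "valine", "amino acid"),
    ("CIT", "citrate", "organic acid"),
    ("FOR", "formate", "organic acid"),
    ("FUM", "fumarate", "organic acid"),
    ("MAL", "malate", "organic acid"),
    ("SUCC", "succinate", "organic acid"),
    ("aGLC", "alpha-glucose", "sugar"),
    ("bGLC", "beta-glucose", "sugar"),
    ("FRU", "fructose", "sugar"),
    ("INO", "myo-inositol", "sugar"),
    ("SUCR", "sucrose", "sugar"),
    ("AMP", "adenosine monophosphate", "energy"),
    ("ATP", "adenosine triphosphate", "energy"),
    ("ADEN", "adenosine", "energy"),
    ("CHOL", "choline", "other"),
    ("mNAM", "N-methylnicotinamide", "other"),
    ("NU1", "nucleoside 1", "other"),
    ("NU2", "nucleoside 2", "other"),
)


@dataclass(frozen=True)
class MetaboliteRegistry:
    """Resolves metabolite codes to names, groups, and exclusion flags."""

    entries: Mapping[str, MetaboliteInfo]

    @classmethod
    def from_tuples(
        cls,
        rows: Iterable[tuple[str, str, str]],
        excluded: Iterable[str] = ("B",),
    ) -> "MetaboliteRegistry":
        excluded = set(excluded)
        entries: dict[str, MetaboliteInfo] = {}
        for code, name, group in rows:
            if code in entries:
                raise ConfigError(f"duplicate metabolite code {code!r}")
            entries[code] = MetaboliteInfo(code, name, group, code in excluded)
        for code in excluded - entries.keys():
            entries[code] = MetaboliteInfo(code, "uncharacterized", "other", True)
        return cls(entries)

    @classmethod
    def study_default(cls) -> "MetaboliteRegistry":
        """The study roster plus the excluded uncharacterized metabolite B."""
        return cls.from_tuples(_STUDY_METABOLITES, excluded=("B",))

    @classmethod
    def minimal(
        cls, codes: Sequence[str], group: str = "other",
        excluded: Iterable[str] = ("B",),
    ) -> "MetaboliteRegistry":
        """Registry for ad-hoc tables: every code in one group."""
        return cls.from_tuples(
            ((c, c, group) for c in codes), excluded=excluded
        )

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def info(self, code: str) -> MetaboliteInfo:
        try:
            return self.entries[code]
        except KeyError:
            raise ConfigError(f"metabolite code {code!r} not in registry") from None

    def group_of(self, code: str) -> str:
        return self.info(code).group

    def is_excluded(self, code: str) -> bool:
        return self.info(code).excluded

    def retained(self, codes: Iterable[str]) -> list[str]:
        """Codes not flagged for exclusion, in the given order."""
        return [c for c in codes if not self.is_excluded(c)]

    def require(self, codes: Iterable[str]) -> None:
        missing = [c for c in codes if c not in self.entries]
        if missing:
            raise ConfigError(
                f"metabolite codes not resolvable in registry: {missing}"
            )


@dataclass(frozen=True)
class FactorRegistry:
    """Declared categorical levels per factor; unknown levels are rejected.

    Only factors listed in ``levels`` are checked; factors such as year,
    stage, and replicate are free-form. Levels are compared as strings.
    """

    levels: Mapping[str, frozenset[str]]

    @classmethod
    def study_default(cls) -> "FactorRegistry":
        return cls(
            {
                "genotype": frozenset({"2", "4", "5", "8", "10", "12", "20"}),
                "mulch": frozenset({"BP", "HV", "RY", "BS"}),
            }
        )

    def extended(self, extra: Mapping[str, Iterable[str]]) -> "FactorRegistry":
        merged = {k: set(v) for k, v in self.levels.items()}
        for factor, lv in extra.items():
            merged.setdefault(factor, set()).update(str(x) for x in lv)
        return FactorRegistry({k: frozenset(v) for k, v in merged.items()})

    def validate(self, factors: pd.DataFrame) -> None:
        for factor, allowed in self.levels.items():
            if factor not in factors.columns:
                continue
            seen = set(factors[factor].astype(str).unique())
            unknown = seen - allowed
            if unknown:
                raise DataValidationError(
                    f"unknown {factor} level(s) {sorted(unknown)}; "
                    f"declared levels are {sorted(allowed)}"
                )


# ---------------------------------------------------------------------------
# the table
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteTable:
    """Samples × metabolites with per-sample factor metadata.

    ``values`` holds float concentrations (NaN = missing) indexed by sample
    id; ``factors`` holds the categorical metadata on the same index. Both
    are kept in canonical order (samples sorted by id, metabolites sorted by
    code) so downstream computations are invariant to input ordering.
    """

    values: pd.DataFrame
    factors: pd.DataFrame
    registry: MetaboliteRegistry = field(default_factory=MetaboliteRegistry.study_default)
    factor_registry: FactorRegistry = field(default_factory=FactorRegistry.study_default)

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise DataValidationError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise DataValidationError(f"duplicate metabolite codes: {dups}")
        if not self.values.index.equals(self.factors.index):
            missing = self.values.index.symmetric_difference(self.factors.index)
            raise DataValidationError(
                f"values and factors disagree on samples: {missing.tolist()}"
            )
        self.registry.require(self.values.columns)
        self.factors = self.factors.astype(str)
        self.factor_registry.validate(self.factors)
        # canonical ordering: exact invariance to row/column permutations
        order = np.argsort(self.values.index.astype(str))
        self.values = self.values.iloc[order]
        self.factors = self.factors.iloc[order]
        self.values = self.values[sorted(self.values.columns)]
        self.values = self.values.astype(float)

    # -- basic views --------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def select_samples(self, ids: Sequence[str]) -> "MetaboliteTable":
        ids = list(ids)
        return MetaboliteTable(
            self.values.loc[ids], self.factors.loc[ids],
            self.registry, self.factor_registry,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableSchema:
    """Column mapping for :func:`read_metabolite_table`.

    ``metabolite_columns=None`` means "all columns not named as sample id or
    factors". ``delimiter=None`` auto-detects comma vs tab from the header.
    """

    sample_id: str = "sample_id"
    factor_columns: tuple[str, ...] = (
        "genotype", "mulch", "year", "stage", "replicate"
    )
    metabolite_columns: tuple[str, ...] | None = None
    delimiter: str | None = None
    exclude: tuple[str, ...] = ("B",)


def _detect_delimiter(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_metabolite_table(
    path: str | Path,
    schema: TableSchema = TableSchema(),
    registry: MetaboliteRegistry | None = None,
    factor_registry: FactorRegistry | None = None,
) -> MetaboliteTable:
    """Read and validate a wide delimited-text metabolite table.

    Blank cells, ``NA`` and ``NaN`` become missing values; any other
    non-numeric concentration cell raises :class:`DataValidationError`
    naming the offending row and column. A load report (sample, metabolite,
    and missing-cell counts) is logged at INFO level.
    """
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"input table not found: {path}")
    sep = schema.delimiter or _detect_delimiter(path)
    header = path.open("r", encoding="utf-8").readline().rstrip("\n").split(sep)
    dup_cols = {c for c in header if header.count(c) > 1}
    if dup_cols:
        raise DataValidationError(
            f"duplicated column names in {path.name}: {sorted(dup_cols)}"
        )
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    for col in (schema.sample_id, *schema.factor_columns):
        if col not in raw.columns:
            raise DataValidationError(f"required column {col!r} missing from {path.name}")
    if raw[schema.sample_id].duplicated().any():
        dups = raw.loc[raw[schema.sample_id].duplicated(), schema.sample_id].tolist()
        raise DataValidationError(f"duplicate sample ids in {path.name}: {dups}")

    met_cols = (
        list(schema.metabolite_columns)
        if schema.metabolite_columns is not None
        else [c for c in raw.columns
              if c != schema.sample_id and c not in schema.factor_columns]
    )
    if len(set(met_cols)) != len(met_cols):
        raise DataValidationError("duplicated metabolite column names")

    raw = raw.set_index(schema.sample_id)
    values = pd.DataFrame(index=raw.index, columns=met_cols, dtype=float)
    for col in met_cols:
        cells = raw[col].str.strip()
        is_na = cells.isin(NA_STRINGS)
        numeric = pd.to_numeric(cells.where(~is_na), errors="coerce")
        bad = (~is_na) & numeric.isna()
        if bad.any():
            sample = cells.index[bad][0]
            raise DataValidationError(
                f"non-numeric concentration {cells[bad].iloc[0]!r} "
                f"at sample {sample!r}, metabolite {col!r}"
            )
        values[col] = numeric

    if registry is None:
        known = MetaboliteRegistry.study_default()
        if all(c in known for c in met_cols):
            registry = known
        else:
            registry = MetaboliteRegistry.minimal(met_cols, excluded=schema.exclude)
    factor_registry = factor_registry or FactorRegistry.study_default()

    table = MetaboliteTable(
        values, raw[list(schema.factor_columns)], registry, factor_registry
    )
    logger.info(
        "loaded %s: %d samples, %d metabolites, %d missing cells",
        path.name, table.n_samples, len(table.metabolites), table.n_missing(),
    )
    return table


def write_metabolite_table(
    table: MetaboliteTable, path: str | Path, delimiter: str = ","
) -> None:
    """Write the wide format back out (factors first, then metabolites)."""
    out = pd.concat([table.factors, table.values], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep=delimiter, na_rep="NA")


# ---------------------------------------------------------------------------
# standardization and group means
# ---------------------------------------------------------------------------

def standardize(table: MetaboliteTable) -> MetaboliteTable:
    """Scale each metabolite to mean 0, SD 1 over its non-missing entries.

    Sample SD (n−1 denominator). Missing entries stay missing. A metabolite
    with fewer than two observations or zero variance is an error — equal
    weighting is impossible for a constant column.
    """
    values = table.values.copy()
    for code in values.columns:
        col = values[code]
        n_obs = col.notna().sum()
        if n_obs < 2:
            raise ZeroVarianceError(code, context=f"only {n_obs} observed values")
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ZeroVarianceError(code)
        values[code] = (col - col.mean()) / sd
    return replace(table, values=values)


def group_standardized_means(
    table: MetaboliteTable, factor: str
) -> pd.DataFrame:
    """Mean standardized value per (factor level × chemical group).

    Every standardized observation of every member metabolite contributes;
    rows are factor levels, columns are the chemical groups present in the
    table. Excluded metabolites (e.g. the uncharacterized ``B``) still
    count toward their group here — exclusion applies to correlation
    analyses only.
    """
    if factor not in table.factors.columns:
        raise ConfigError(f"unknown factor {factor!r}")
    groups = {m: table.registry.group_of(m) for m in table.metabolites}
    present = sorted(set(groups.values()), key=METABOLITE_GROUPS.index)
    levels = sorted(table.factors[factor].unique())
    out = pd.DataFrame(index=pd.Index(levels, name=factor),
                       columns=present, dtype=float)
    for g in present:
        members = [m for m, grp in groups.items() if grp == g]
        if not members:
            raise DataValidationError(f"empty metabolite group {g!r}")
        sub = table.values[members]
        for level in levels:
            mask = (table.factors[factor] == level).to_numpy()
            out.loc[level, g] = float(np.nanmean(sub.to_numpy()[mask]))
    return out


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionScheme:
    """A named rule splitting samples into exactly two labeled subsets.

    Assignment is by factor levels: a sample whose ``factor`` level is in
    ``a_levels`` goes to subset A, in ``b_levels`` to subset B, otherwise to
    neither. An optional stratum restricts which samples participate at
    all. ``pooled_factors`` documents the factors deliberately ignored.
    """

    name: str
    factor: str
    a_levels: frozenset[str]
    b_levels: frozenset[str]
    subset_a_label: str
    subset_b_label: str
    stratum_factor: str | None = None
    stratum_levels: frozenset[str] = frozenset()
    pooled_factors: tuple[str, ...] = ()

    def __post_init__(self):
        if self.a_levels & self.b_levels:
            raise ConfigError(
                f"partition {self.name!r}: levels "
                f"{sorted(self.a_levels & self.b_levels)} appear in both subsets"
            )

    def assign(self, factor_row: Mapping[str, str]) -> str | None:
        """Return ``'a'``, ``'b'`` or ``None`` for one sample's factors."""
        if self.stratum_factor is not None:
            if str(factor_row[self.stratum_factor]) not in self.stratum_levels:
                return None
        level = str(factor_row[self.factor])
        if level in self.a_levels:
            return "a"
        if level in self.b_levels:
            return "b"
        return None

    def apply(self, table: MetaboliteTable) -> tuple[list[str], list[str]]:
        """Sample-id lists (subset A, subset B); both must be non-empty."""
        factors = table.factors
        col = factors[self.factor].astype(str)
        in_stratum = (
            factors[self.stratum_factor].astype(str).isin(self.stratum_levels)
            if self.stratum_factor is not None
            else pd.Series(True, index=factors.index)
        )
        ids_a = factors.index[in_stratum & col.isin(self.a_levels)].tolist()
        ids_b = factors.index[in_stratum & col.isin(self.b_levels)].tolist()
        if not ids_a or not ids_b:
            raise DataValidationError(
                f"partition {self.name!r} leaves an empty subset "
                f"(|A|={len(ids_a)}, |B|={len(ids_b)}); the built-in schemes "
                "require the study's genotype and mulch levels"
            )
        return ids_a, ids_b

    @property
    def subset_labels(self) -> tuple[str, str]:
        return self.subset_a_label, self.subset_b_label


LOW_POLYAMINE_GENOTYPES = frozenset({"2", "5", "12"})
HIGH_POLYAMINE_GENOTYPES = frozenset({"4", "8", "10", "20"})
MEJAS_DEFICIENT_GENOTYPES = frozenset({"12", "20"})
MEJAS_NORMAL_GENOTYPES = frozenset({"2", "4", "5", "8", "10"})


def builtin_partitions() -> list[PartitionScheme]:
    """The study's partitions, with subset A always the reference ("from").

    * ``polyamine`` — low (genotypes 2, 5, 12) vs high (4, 8, 10, 20)
      fruit polyamine content; mulches pooled.
    * ``mejas`` — methyl-jasmonate deficient (12, 20) vs normal
      (2, 4, 5, 8, 10); mulches pooled.
    * ``mulch`` — bare soil + black polyethylene vs hairy vetch + rye
      cover mulches; genotypes pooled.
    * ``mulch_within_highPA`` / ``mulch_within_lowPA`` — black plastic vs
      hairy vetch, restricted to the high / low polyamine genotypes.
    """
    return [
        PartitionScheme(
            "polyamine", "genotype",
            LOW_POLYAMINE_GENOTYPES, HIGH_POLYAMINE_GENOTYPES,
            "low polyamine", "high polyamine",
            pooled_factors=("mulch", "year", "stage", "replicate"),
        ),
        PartitionScheme(
            "mejas", "genotype",
            MEJAS_DEFICIENT_GENOTYPES, MEJAS_NORMAL_GENOTYPES,
            "low meJAS", "normal meJAS",
            pooled_factors=("mulch", "year", "stage", "replicate"),
        ),
        PartitionScheme(
            "mulch", "mulch",
            frozenset({"BS", "BP"}), frozenset({"HV", "RY"}),
            "bare + black plastic", "hairy vetch + rye",
            pooled_factors=("genotype", "year", "stage", "replicate"),
        ),
        PartitionScheme(
            "mulch_within_highPA", "mulch",
            frozenset({"BP"}), frozenset({"HV"}),
            "black plastic (high PA)", "hairy vetch (high PA)",
            stratum_factor="genotype", stratum_levels=HIGH_POLYAMINE_GENOTYPES,
            pooled_factors=("year", "stage", "replicate"),
        ),
        PartitionScheme(
            "mulch_within_lowPA", "mulch",
            frozenset({"BP"}), frozenset({"HV"}),
            "black plastic (low PA)", "hairy vetch (low PA)",
            stratum_factor="genotype", stratum_levels=LOW_POLYAMINE_GENOTYPES,
            pooled_factors=("year", "stage", "replicate"),
        ),
    ]


def get_partition(name: str) -> PartitionScheme:
    for scheme in builtin_partitions():
        if scheme.name == name:
            return scheme
    raise ConfigError(
        f"unknown partition {name!r}; built-ins are "
        f"{[s.name for s in builtin_partitions()]}"
    )


#: The six subsets entering the stability calculation: both sides of the
#: three main partitions. The nested mulch-within-polyamine schemes are
#: deliberately excluded to avoid double-counting samples.
STABILITY_PARTITIONS = ("polyamine", "mejas", "mulch")
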