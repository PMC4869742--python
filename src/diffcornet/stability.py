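"""Cross-partition stability of metabolite-pair correlations.

A pair's stability is the sample standard deviation of its Fisher-z
transformed correlations across the subsets of all data partitions — six
subsets by default (both sides of the polyamine, methyl-jasmonate, and
mulch partitions). Small sd_z means the association persists across
genetic and agroecosystem perturbation; large sd_z marks the linkages that
rewire. The companion summary is the mean correlation (on the r scale)
over the same subsets; the two triangles of the stability heat map carry
mean r (upper right) and sd_z (lower left).

The five-color binning follows the published thresholds: pairs with
sd_z < 0.19 are the most stable (bin 1, yellow), sd_z > 0.35 the least
stable (bin 5, darkest red); the interior is split into three equal-width
bins, interior boundaries assigned to the lower bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation import CorrelationSet, pairwise_correlations
from .data_model import (
    STABILITY_PARTITIONS,
    MetaboliteTable,
    get_partition,
)
from .errors import ConfigError

logger = logging.getLogger(__name__)

SD_STABLE = 0.19     # below: most stable (bin 1)
SD_UNSTABLE = 0.35   # above: least stable (bin 5)
MIN_SUBSETS = 3      # a pair must be retained in at least this many subsets


def bin_stability(sd_z: float) -> int:
    """Five-bin stability class, 1 = most stable ... 5 = least stable.

    Bin 1 iff sd_z < 0.19 (strict); bin 5 iff sd_z > 0.35 (strict); the
    interior [0.19, 0.35] is split into three equal-width bins with
    boundaries assigned to the lower bin.
    """
    if sd_z < 0:
        raise ValueError("sd_z must be non-negative")
    if sd_z < SD_STABLE:
        return 1
    if sd_z > SD_UNSTABLE:
        return 5
    third = (SD_UNSTABLE - SD_STABLE) / 3.0
    if sd_z <= SD_STABLE + third:
        return 2
    if sd_z <= SD_STABLE + 2 * third:
        return 3
    return 4


def stability_sd(z_values) -> float:
    """Sample SD (n−1) of a pair's z values across subsets."""
    z = np.asarray(z_values, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < MIN_SUBSETS:
        raise ConfigError(
            f"stability needs the pair retained in >= {MIN_SUBSETS} subsets; got {len(z)}"
        )
    return float(np.std(z, ddof=1))


def mean_correlation(r_values) -> float:
    """Arithmetic mean of r (correlation scale) across subsets."""
    r = np.asarray(r_values, dtype=float)
    r = r[np.isfinite(r)]
    if len(r) < MIN_SUBSETS:
        raise ConfigError(
            f"stability needs the pair retained in >= {MIN_SUBSETS} subsets; got {len(r)}"
        )
    return float(np.mean(r))


@dataclass
class StabilityMap:
    """Per-pair stability scores over a set of partition subsets.

    ``pairs`` is indexed by (metabolite_i, metabolite_j) with columns
    ``sd_z``, ``mean_r``, ``bin``, ``subsets_used``. ``dropped`` records
    pairs retained in too few subsets. ``subset_labels`` documents which
    subsets entered the calculation.
    """

    pairs: pd.DataFrame
    subset_labels: tuple[str, ...]
    threshold: float = SD_STABLE
    dropped: list[tuple[tuple[str, str], str]] = field(default_factory=list)

    def stable_association_counts(self, threshold: float | None = None) -> pd.Series:
        """Per-metabolite count of pairs with sd_z strictly below threshold."""
        thr = self.threshold if threshold is None else threshold
        mets = sorted({m for pair in self.pairs.index for m in pair})
        counts = pd.Series(0, index=pd.Index(mets, name="metabolite"))
        stable = self.pairs[self.pairs["sd_z"] < thr]
        for i, j in stable.index:
            counts[i] += 1
            counts[j] += 1
        return counts

    def extremes(self) -> tuple[pd.Series, pd.Series]:
        """(most stable pair row, least stable pair row)."""
        most = self.pairs.loc[self.pairs["sd_z"].idxmin()]
        least = self.pairs.loc[self.pairs["sd_z"].idxmax()]
        return most, least


def build_stability_map(
    correlation_sets: list[CorrelationSet],
    threshold: float = SD_STABLE,
    min_subsets: int = MIN_SUBSETS,
) -> StabilityMap:
    """Score every pair's sd_z and mean r across the given subsets.

    Saturated or excluded pairs simply do not contribute that subset's
    value; pairs usable in fewer than ``min_subsets`` subsets are dropped
    with a recorded reason.
    """
    if len(correlation_sets) < min_subsets:
        raise ConfigError(
            f"need at least {min_subsets} subsets, got {len(correlation_sets)}"
        )
    all_pairs = sorted(
        set().union(*(set(cs.usable().index) for cs in correlation_sets))
    )
    rows, dropped = [], []
    for pair in all_pairs:
        z_vals, r_vals = [], []
        for cs in correlation_sets:
            if pair in cs.pairs.index and cs.pairs.loc[pair, "flag"] == "":
                z_vals.append(float(cs.pairs.loc[pair, "z"]))
                r_vals.append(float(cs.pairs.loc[pair, "r"]))
        if len(z_vals) < min_subsets:
            dropped.append((pair, f"usable in only {len(z_vals)} subsets"))
            continue
        sd = float(np.std(z_vals, ddof=1))
        rows.append((pair, sd, float(np.mean(r_vals)), bin_stability(sd), len(z_vals)))

    index = pd.MultiIndex.from_tuples(
        [p for p, *_ in rows], names=["metabolite_i", "metabolite_j"]
    ) if rows else pd.MultiIndex.from_tuples([], names=["metabolite_i", "metabolite_j"])
    pairs = pd.DataFrame(
        [(sd, mr, b, k) for _, sd, mr, b, k in rows],
        index=index, columns=["sd_z", "mean_r", "bin", "subsets_used"],
    )
    if rows:
        pairs = pairs.astype({"sd_z": float, "mean_r": float, "bin": int, "subsets_used": int})
    logger.info(
        "stability map: %d pairs scored over %d subsets, %d dropped",
        len(pairs), len(correlation_sets), len(dropped),
    )
    return StabilityMap(
        pairs, tuple(cs.label for cs in correlation_sets), threshold, dropped
    )


def stability_subsets(
    table: MetaboliteTable,
    partition_names: tuple[str, ...] = STABILITY_PARTITIONS,
    n_min: int | None = None,
) -> list[CorrelationSet]:
    """Correlation sets for both sides of each named partition (6 by default)."""
    from .correlation import DEFAULT_N_MIN

    out = []
    for name in partition_names:
        scheme = get_partition(name)
        ids_a, ids_b = scheme.apply(table)
        for ids, label in ((ids_a, scheme.subset_a_label), (ids_b, scheme.subset_b_label)):
            out.append(
                pairwise_correlations(
                    table, ids, label=f"{name}:{label}",
                    n_min=n_min or DEFAULT_N_MIN,
                )
            )
    return out


def heatmap_matrix(
    stability_map: StabilityMap, order: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Square two-triangle matrix over an ordered metabolite roster.

    Returns ``(values, bins)``. In ``values`` the upper-right triangle
    holds mean r, the lower-left triangle sd_z, the diagonal is empty. In
    ``bins`` the lower-left triangle holds the five-color bin class.
    """
    known = {m for pair in stability_map.pairs.index for m in pair}
    unknown = [m for m in order if m not in known]
    if unknown:
        raise ConfigError(f"metabolites not in stability map: {unknown}")
    k = len(order)
    pos = {m: i for i, m in enumerate(order)}
    values = pd.DataFrame(np.full((k, k), np.nan), index=order, columns=order)
    bins = pd.DataFrame(np.full((k, k), np.nan), index=order, columns=order)
    for (mi, mj), row in stability_map.pairs.iterrows():
        if mi not in pos or mj not in pos:
            continue
        a, b = pos[mi], pos[mj]
        # upper-right triangle (row < col): mean r; lower-left: sd_z
        values.iloc[min(a, b), max(a, b)] = row["mean_r"]
        values.iloc[max(a, b), min(a, b)] = row["sd_z"]
        bins.iloc[max(a, b), min(a, b)] = row["bin"]
    return values, bins
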