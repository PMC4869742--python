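"""Differential correlation networks.

A pair of metabolites earns an edge when its correlation *changes*
significantly between two sample subsets. The test compares Fisher-z
transformed correlations with the normal-theory statistic

    q = (z_b − z_a) / sqrt(1/(n_a − 3) + 1/(n_b − 3)),
    p = 2 · (1 − Φ(|q|)),

the classic two-independent-correlations test. The default significance
rule is the raw two-tailed P < 0.05; Benjamini–Hochberg FDR adjustment is
available as an option. Edges carry a sign class (increase / decrease in
correlation from subset A to subset B), a display color, and a line width
mapped linearly from |Δr| for Cytoscape rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .correlation import CorrelationSet, fisher_z
from .errors import DataValidationError, SaturatedCorrelationError

logger = logging.getLogger(__name__)

#: Line-width anchors: |Δr| = 0.1 maps to the thinnest line, 0.7 to the
#: thickest; outside that range the width is clamped.
DELTA_R_THIN = 0.1
DELTA_R_THICK = 0.7
WIDTH_MIN = 1.0
WIDTH_MAX = 7.0

#: Default color convention: blue marks an increase in correlation from
#: subset A to subset B, red a decrease. ``swap_colors`` inverts it.
COLOR_INCREASE = "blue"
COLOR_DECREASE = "red"

EDGE_COLUMNS = [
    "source", "target", "r_a", "r_b", "delta_r", "delta_z",
    "q", "p", "direction", "color", "width",
]


def correlation_change_test(r_a, n_a, r_b, n_b):
    """Two-tailed test of no change in correlation between two subsets.

    Returns ``(q, p)``. Requires n > 3 in both subsets and |r| < 1 in both
    (saturated correlations must be filtered upstream). Swapping the
    subsets negates q and leaves p unchanged. Accepts scalars or arrays.
    """
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    if np.any(n_a <= 3) or np.any(n_b <= 3):
        raise DataValidationError(
            "correlation_change_test requires n > 3 in both subsets "
            f"(got n_a={n_a}, n_b={n_b})"
        )
    z_a = fisher_z(r_a)
    z_b = fisher_z(r_b)
    se = np.sqrt(1.0 / (n_a - 3.0) + 1.0 / (n_b - 3.0))
    q = (np.asarray(z_b) - np.asarray(z_a)) / se
    p = 2.0 * stats.norm.sf(np.abs(q))
    if q.ndim == 0:
        return q.item(), p.item()
    return q, p


def change_test_power(rho_a: float, n_a: int, rho_b: float, n_b: int,
                      alpha: float = 0.05) -> float:
    """Normal-approximation power of the change test at given truth.

    Power = Φ(|Δζ|/SE − z_{α/2}) + Φ(−|Δζ|/SE − z_{α/2}) where
    ζ = atanh(ρ) and SE = sqrt(1/(n_a−3) + 1/(n_b−3)).
    """
    dz = abs(fisher_z(rho_b) - fisher_z(rho_a))
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    crit = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.cdf(dz / se - crit) + stats.norm.cdf(-dz / se - crit))


def display_width(delta_r_magnitude,
                  w_min: float = WIDTH_MIN, w_max: float = WIDTH_MAX):
    """Linear |Δr| → line-width map, clamped at the 0.1 / 0.7 anchors."""
    m = np.asarray(delta_r_magnitude, dtype=float)
    if np.any(m < 0):
        raise ValueError("delta_r magnitude must be non-negative")
    frac = (m - DELTA_R_THIN) / (DELTA_R_THICK - DELTA_R_THIN)
    out = w_min + np.clip(frac, 0.0, 1.0) * (w_max - w_min)
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class EdgeChange:
    """One significant change in correlation between subsets A and B."""

    pair: tuple[str, str]
    r_a: float
    n_a: int
    z_a: float
    r_b: float
    n_b: int
    z_b: float
    q: float
    p: float
    direction: str          # "increase" | "decrease" (sign of delta_z)
    width: float

    @property
    def delta_z(self) -> float:
        return self.z_b - self.z_a

    @property
    def delta_r(self) -> float:
        return self.r_b - self.r_a


@dataclass
class DifferentialNetwork:
    """Significant edge set between two subsets of one partition."""

    partition: str
    subset_a_label: str
    subset_b_label: str
    edges: list[EdgeChange]
    alpha: float
    multiplicity: str
    n_tested: int
    skipped: list[tuple[tuple[str, str], str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def edge_frame(self, swap_colors: bool = False) -> pd.DataFrame:
        """Canonically sorted edge table in the Cytoscape CSV layout."""
        inc = COLOR_DECREASE if swap_colors else COLOR_INCREASE
        dec = COLOR_INCREASE if swap_colors else COLOR_DECREASE
        rows = [
            {
                "source": e.pair[0], "target": e.pair[1],
                "r_a": e.r_a, "r_b": e.r_b,
                "delta_r": e.delta_r, "delta_z": e.delta_z,
                "q": e.q, "p": e.p, "direction": e.direction,
                "color": inc if e.direction == "increase" else dec,
                "width": e.width,
            }
            for e in self.edges
        ]
        frame = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        return frame.sort_values(["source", "target"]).reset_index(drop=True)


def build_differential_network(
    set_a: CorrelationSet,
    set_b: CorrelationSet,
    alpha: float = 0.05,
    multiplicity: str = "none",
    partition: str = "custom",
    provenance: dict | None = None,
) -> DifferentialNetwork:
    """Test every shared pair and keep the significant changes.

    Both correlation sets must cover the same metabolite roster. Pairs
    retained (finite z) in only one subset are skipped with a recorded
    reason. ``multiplicity='bh'`` applies Benjamini–Hochberg FDR to the
    shared-pair p-values before thresholding at ``alpha``.
    """
    if multiplicity not in ("none", "bh"):
        raise DataValidationError(f"unknown multiplicity mode {multiplicity!r}")
    if set(set_a.metabolites) != set(set_b.metabolites):
        raise DataValidationError(
            "correlation sets were computed on different metabolite rosters: "
            f"{sorted(set(set_a.metabolites) ^ set(set_b.metabolites))}"
        )
    usable_a = set_a.usable()
    usable_b = set_b.usable()
    shared = usable_a.index.intersection(usable_b.index)
    skipped = [
        (tuple(pair), "not retained in both subsets")
        for pair in set_a.pairs.index.union(set_b.pairs.index).difference(shared)
    ]
    for pair, reason in skipped:
        logger.debug("partition %s: skipped pair %s (%s)", partition, pair, reason)

    a = usable_a.loc[shared]
    b = usable_b.loc[shared]
    if len(shared):
        q, p = correlation_change_test(
            a["r"].to_numpy(), a["n"].to_numpy(),
            b["r"].to_numpy(), b["n"].to_numpy(),
        )
        p_eff = multipletests(p, method="fdr_bh")[1] if multiplicity == "bh" else p
        sig = p_eff < alpha
    else:
        q = p = p_eff = np.array([])
        sig = np.array([], dtype=bool)

    edges = []
    for k, pair in enumerate(shared):
        if not sig[k]:
            continue
        dz = float(b["z"].iloc[k] - a["z"].iloc[k])
        dr = float(b["r"].iloc[k] - a["r"].iloc[k])
        edges.append(
            EdgeChange(
                pair=tuple(pair),
                r_a=float(a["r"].iloc[k]), n_a=int(a["n"].iloc[k]),
                z_a=float(a["z"].iloc[k]),
                r_b=float(b["r"].iloc[k]), n_b=int(b["n"].iloc[k]),
                z_b=float(b["z"].iloc[k]),
                q=float(q[k]), p=float(p_eff[k]),
                direction="increase" if dz > 0 else "decrease",
                width=display_width(abs(dr)),
            )
        )
    edges.sort(key=lambda e: e.pair)
    logger.info(
        "partition %s: %d pairs tested, %d significant (alpha=%g, %s)",
        partition, len(shared), len(edges), alpha, multiplicity,
    )
    return DifferentialNetwork(
        partition=partition,
        subset_a_label=set_a.label,
        subset_b_label=set_b.label,
        edges=edges,
        alpha=alpha,
        multiplicity=multiplicity,
        n_tested=len(shared),
        skipped=skipped,
        provenance=provenance or {},
    )


def export_network(
    net: DifferentialNetwork,
    path: str | Path,
    format: str = "edge-csv",
    swap_colors: bool = False,
) -> Path:
    """Write the network as a Cytoscape-importable edge CSV or GraphML.

    Output is byte-identical for identical input and configuration: edges
    are canonically sorted and floats serialized with repr-precision.
    """
    path = Path(path)
    frame = net.edge_frame(swap_colors=swap_colors)
    if format == "edge-csv":
        frame.to_csv(path, index=False)
    elif format == "graphml":
        g = nx.Graph(
            partition=net.partition,
            subset_a=net.subset_a_label,
            subset_b=net.subset_b_label,
            alpha=net.alpha,
            multiplicity=net.multiplicity,
        )
        for _, row in frame.iterrows():
            attrs = {k: row[k] for k in EDGE_COLUMNS[2:]}
            g.add_edge(row["source"], row["target"], **attrs)
        nx.write_graphml(g, path)
    else:
        raise DataValidationError(f"unknown export format {format!r}")
    return path


def read_edge_csv(path: str | Path) -> pd.DataFrame:
    """Re-import an exported edge CSV with all attributes intact."""
    frame = pd.read_csv(path)
    missing = set(EDGE_COLUMNS) - set(frame.columns)
    if missing:
        raise DataValidationError(f"edge CSV {path} missing columns {sorted(missing)}")
    return frame
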